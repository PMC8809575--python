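"""Synthetic GWAS study generator with known causal structure.

The generative model mirrors the exposure→mediator→outcome design of a
chronotype/sex-hormone/cancer study: a 5-category ordinal exposure score X
built from a latent liability, a continuous (SD-scale) hormone-like mediator
M, and a binary disease outcome Y on the logistic scale. SNP classes:

* *valid* instruments affect the latent exposure only;
* *pleiotropic* SNPs additionally carry a direct effect on the mediator or
  the outcome (balanced or directional; optionally correlated with
  instrument strength to violate InSIDE);
* *reverse* SNPs affect the mediator first; they associate with the exposure
  only through the mediator→exposure path (theta_MX), giving Steiger
  filtering something real to remove.

A shared confounder U feeds all three traits. Two-sample summary statistics
are produced by within-sample GWAS scans (linear regression for the ordinal
score and the mediator, logistic regression for the outcome), vectorised
across SNPs so hundreds of replicates run in seconds. Everything is a pure
function of the config (seed mandatory): reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .sumstats import LDMatrix, SummaryStats, write_sumstats

logger = logging.getLogger(__name__)

# ordered non-palindromic allele pairs (effect, other)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass
class PleiotropyConfig:
    """Direct (horizontal-pleiotropy) SNP effects on the analysed outcome.

    ``fraction_direct`` of SNPs get a direct effect drawn N(mean, sd²);
    ``balanced=True`` forces mean 0. ``inside_violation=True`` makes the
    direct effect proportional to the SNP's instrument strength (violating
    InSIDE, the assumption MR-Egger needs). ``target`` selects whether the
    direct effects enter the mediator M or the binary outcome Y.
    """

    fraction_direct: float = 0.0
    mean_direct_effect: float = 0.0
    sd_direct_effect: float = 0.0
    balanced: bool = True
    inside_violation: bool = False
    target: str = "mediator"

    def validate(self):
        if not 0 <= self.fraction_direct <= 1:
            raise ValueError("fraction_direct must be in [0,1]")
        if self.target not in ("mediator", "outcome"):
            raise ValueError("pleiotropy target must be 'mediator' or 'outcome'")


@dataclass
class SimulationConfig:
    """Full generative-model parameterisation (desk scale by default).

    Effect-size defaults follow the female chronotype/testosterone pattern
    of the emulated study: OR 0.93 per category for exposure→outcome, -0.08
    SD per category for exposure→mediator, OR 1.10 per SD for
    mediator→outcome, and a weak reverse mediator→exposure path. Heritability
    defaults are chosen so desk-scale samples (n = 20,000) give instrument
    strength in the same mean-F regime as the full-scale study (F ≈ 20-80).
    """

    seed: int
    n_snps: int = 100
    maf_range: tuple = (0.05, 0.5)
    n_sample_exposure: int = 20_000
    n_sample_outcome: int = 20_000
    overlap_fraction: float = 0.0
    exposure_h2: float = 0.2
    mediator_h2: float = 0.15
    theta_XM: float = -0.08       # SD of mediator per exposure category
    theta_XY: float = -0.0726     # log-odds of outcome per exposure category
    theta_MY: float = 0.0953      # log-odds of outcome per mediator SD
    theta_MX: float = 0.0         # exposure categories per mediator SD (reverse path)
    confounder_strengths: tuple = (0.3, 0.3, 0.3)   # (U->X, U->M, U->Y)
    effect_truncation: float = 0.0  # |raw effect| floor (sd units); emulates
    #                                 the effect-size floor of significance-
    #                                 selected instruments
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    reverse_snp_fraction: float = 0.0
    exposure_categories: int = 5
    case_fraction: float = 0.5
    ld_blocks: list = field(default_factory=list)   # [(size, within-block r), ...]

    def validate(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("overlap_fraction", "reverse_snp_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0,1)")
        if self.exposure_categories < 2:
            raise ValueError("exposure_categories must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        self.pleiotropy.validate()
        bU, cU, _ = self.confounder_strengths
        if self.mediator_h2 + cU**2 > 1:
            raise ValueError("mediator_h2 + cU^2 exceeds unit variance")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["pleiotropy"] = PleiotropyConfig(**d.get("pleiotropy", {}))
        d["maf_range"] = tuple(d["maf_range"])
        d["confounder_strengths"] = tuple(d["confounder_strengths"])
        d["ld_blocks"] = [tuple(b) for b in d.get("ld_blocks", [])]
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class TruthRecord:
    """Ground truth for recovery tests."""

    snp_class: np.ndarray         # 'valid' | 'pleiotropic' | 'reverse' per SNP
    variant_ids: list
    theta_XM: float
    theta_XY: float
    theta_MY: float
    theta_MX: float
    exposure_effects: np.ndarray  # per-SNP effect on latent exposure
    mediator_effects: np.ndarray  # per-SNP direct effect on mediator (reverse SNPs)
    direct_effects: np.ndarray    # per-SNP horizontal-pleiotropy effect

    @property
    def total_effect(self) -> float:
        """Expected total exposure->outcome effect (direct + mediated)."""
        return self.theta_XY + self.theta_XM * self.theta_MY

    @property
    def valid_ids(self):
        return [v for v, c in zip(self.variant_ids, self.snp_class) if c == "valid"]

    @property
    def exposure_snp_ids(self):
        return [v for v, c in zip(self.variant_ids, self.snp_class) if c != "reverse"]

    @property
    def reverse_ids(self):
        return [v for v, c in zip(self.variant_ids, self.snp_class) if c == "reverse"]

    def to_json(self) -> str:
        d = {
            "snp_class": list(self.snp_class), "variant_ids": list(self.variant_ids),
            "theta_XM": self.theta_XM, "theta_XY": self.theta_XY,
            "theta_MY": self.theta_MY, "theta_MX": self.theta_MX,
            "total_effect": self.total_effect,
            "exposure_effects": [float(v) for v in self.exposure_effects],
            "mediator_effects": [float(v) for v in self.mediator_effects],
            "direct_effects": [float(v) for v in self.direct_effects],
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class Cohort:
    """Individual-level draw from the generative model."""

    genotypes: np.ndarray         # (n, L) effect-allele counts
    freqs: np.ndarray
    alleles: list                 # [(effect, other), ...]
    variant_ids: list
    U: np.ndarray
    X_latent: np.ndarray
    X_category: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    truth: TruthRecord
    config: SimulationConfig

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


def _draw_genotypes(rng, n: int, freqs: np.ndarray, ld_blocks) -> np.ndarray:
    """Binomial(2, f) genotypes, optionally with block LD via a Gaussian
    copula on latent liabilities."""
    L = len(freqs)
    if not ld_blocks:
        return rng.binomial(2, freqs, size=(n, L)).astype(np.int8)
    Z = rng.standard_normal((n, L))
    pos = 0
    for size, r in ld_blocks:
        size = int(size)
        if size > 1 and r != 0:
            shared = rng.standard_normal(n)
            block = Z[:, pos:pos + size]
            Z[:, pos:pos + size] = (np.sqrt(abs(r)) * np.sign(r) * shared[:, None]
                                    + np.sqrt(1 - abs(r)) * block)
        pos += size
    # remaining SNPs (beyond listed blocks) stay independent
    G = stats.binom.ppf(stats.norm.cdf(Z), 2, freqs[None, :]).astype(np.int8)
    return G


def _scaled_effects(rng, mask: np.ndarray, freqs: np.ndarray, h2: float,
                    truncation: float = 0.0) -> np.ndarray:
    """Random effects on masked SNPs, scaled so Σ 2f(1-f)β² = h2 exactly.

    ``truncation`` > 0 draws magnitudes from a |N(0,1)| truncated below at
    that value (an effect-size floor, as significance-selected instruments
    have); 0 gives plain normal draws."""
    eff = np.zeros(len(freqs))
    k = int(mask.sum())
    if k == 0 or h2 == 0:
        return eff
    if truncation > 0:
        u = rng.uniform(size=k)
        lo = 2 * stats.norm.cdf(truncation) - 1     # P(|N| <= t)
        mag = stats.norm.ppf((1 + lo + u * (1 - lo)) / 2)
        raw = rng.choice([-1.0, 1.0], size=k) * mag
    else:
        raw = rng.standard_normal(k)
    var = 2 * freqs[mask] * (1 - freqs[mask])
    scale = np.sqrt(h2 / np.sum(var * raw**2))
    eff[mask] = raw * scale
    return eff


def simulate_cohort(config: SimulationConfig, n: int | None = None,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Draw one cohort (genotypes, confounder, X, M, Y) from the config.

    ``n`` defaults to ``n_sample_exposure``; pass an explicit ``rng`` to
    chain draws inside a larger reproducible design.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n is None:
        n = config.n_sample_exposure
    L = config.n_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=L)
    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=L)]
    variant_ids = [f"rs{i+1:05d}" for i in range(L)]

    # SNP classes: reverse first, then pleiotropic among the rest
    classes = np.array(["valid"] * L, dtype=object)
    n_rev = int(round(config.reverse_snp_fraction * L))
    n_ple = int(round(config.pleiotropy.fraction_direct * (L - n_rev)))
    idx = rng.permutation(L)
    rev_idx = idx[:n_rev]
    ple_idx = idx[n_rev:n_rev + n_ple]
    classes[rev_idx] = "reverse"
    classes[ple_idx] = "pleiotropic"
    exp_mask = classes != "reverse"
    rev_mask = classes == "reverse"

    a = _scaled_effects(rng, exp_mask, freqs, config.exposure_h2,
                        config.effect_truncation)
    c = _scaled_effects(rng, rev_mask, freqs,
                        config.mediator_h2 if n_rev else 0.0,
                        config.effect_truncation)

    # horizontal pleiotropy: directional effects are defined relative to the
    # exposure-increasing allele (sign(a)), since estimators re-orient
    # instruments that way — unsigned draws would average out as balanced
    p = config.pleiotropy
    d = np.zeros(L)
    if n_ple:
        mu = 0.0 if p.balanced else p.mean_direct_effect
        sgn = np.sign(a[ple_idx])
        noise = rng.normal(0, p.sd_direct_effect, size=n_ple)
        if p.inside_violation:
            strength = np.abs(a[ple_idx])
            base = strength / np.sqrt(np.mean(strength**2))
            d[ple_idx] = sgn * (mu * base + noise)
        else:
            d[ple_idx] = sgn * (mu + noise)

    G = _draw_genotypes(rng, n, freqs, config.ld_blocks)
    Gc = G - 2 * freqs[None, :]          # centred genotypes
    U = rng.standard_normal(n)
    bU, cU, dU = config.confounder_strengths

    # mediator's pre-exposure component (unit variance)
    em0 = 1.0 - (config.mediator_h2 if n_rev else 0.0) - cU**2
    M0 = Gc @ c + cU * U + rng.normal(0, np.sqrt(max(em0, 0.0)), size=n)

    var_x = (config.exposure_h2 + config.theta_MX**2 + bU**2
             + 2 * config.theta_MX * cU * bU)
    ex2 = 1.0 - var_x
    if ex2 < 0:
        raise ValueError("exposure variance components exceed 1; reduce "
                         "exposure_h2 / theta_MX / confounder strength")
    X_latent = (Gc @ a + config.theta_MX * M0 + bU * U
                + rng.normal(0, np.sqrt(ex2), size=n))

    K = config.exposure_categories
    cuts = stats.norm.ppf(np.arange(1, K) / K)
    X_category = (np.searchsorted(cuts, X_latent) + 1).astype(float)
    cat_c = X_category - (K + 1) / 2.0

    M = M0 + config.theta_XM * cat_c
    if p.target == "mediator":
        M = M + Gc @ d

    eta = config.theta_XY * cat_c + config.theta_MY * M + dU * U
    if p.target == "outcome":
        eta = eta + Gc @ d
    alpha = _solve_intercept(eta, config.case_fraction)
    Y = (rng.random(n) < expit(alpha + eta)).astype(np.int8)

    truth = TruthRecord(snp_class=classes, variant_ids=variant_ids,
                        theta_XM=config.theta_XM, theta_XY=config.theta_XY,
                        theta_MY=config.theta_MY, theta_MX=config.theta_MX,
                        exposure_effects=a, mediator_effects=c, direct_effects=d)
    return Cohort(genotypes=G, freqs=freqs, alleles=alleles,
                  variant_ids=variant_ids, U=U, X_latent=X_latent,
                  X_category=X_category, M=M, Y=Y, truth=truth, config=config)


def _solve_intercept(eta: np.ndarray, case_fraction: float) -> float:
    """Bisection for the logistic intercept hitting the target case share."""
    lo, hi = -30.0, 30.0
    f = lambda a: float(np.mean(expit(a + eta))) - case_fraction
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"case_fraction {case_fraction} unattainable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# GWAS scans (vectorised across SNPs)
# ---------------------------------------------------------------------------

_TRAIT_ALIASES = {"X_category": "X_category", "exposure": "X_category",
                  "M": "M", "mediator": "M", "Y": "Y", "outcome": "Y"}
_TRAIT_TYPES = {"X_category": "ordinal_category", "M": "continuous_sd",
                "Y": "binary_logodds"}


def _linear_scan(G: np.ndarray, y: np.ndarray):
    n, L = G.shape
    gbar = G.mean(axis=0)
    ybar = y.mean()
    gc = G - gbar
    yc = y - ybar
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = yc @ gc
    beta = sxy / sxx
    syy = float(yc @ yc)
    rss = syy - beta * sxy            # per-SNP residual sum of squares
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def _logistic_scan(G: np.ndarray, y: np.ndarray, max_iter: int = 30,
                   tol: float = 1e-10):
    """Per-SNP univariable logistic regression by Newton iterations run
    simultaneously for all SNPs (intercept + slope per SNP)."""
    n, L = G.shape
    Gf = G.astype(float)
    a = np.full(L, logit(np.clip(y.mean(), 1e-9, 1 - 1e-9)))
    b = np.zeros(L)
    for _ in range(max_iter):
        eta = a[None, :] + Gf * b[None, :]
        p = expit(eta)
        w = p * (1 - p)
        r = (y[:, None] - p)
        s0 = r.sum(axis=0)
        s1 = np.einsum("ij,ij->j", Gf, r)
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", Gf, w)
        h11 = np.einsum("ij,ij,ij->j", Gf, Gf, w)
        det = h00 * h11 - h01**2
        da = (h11 * s0 - h01 * s1) / det
        db = (h00 * s1 - h01 * s0) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    eta = a[None, :] + Gf * b[None, :]
    p = expit(eta)
    w = p * (1 - p)
    h00 = w.sum(axis=0)
    h01 = np.einsum("ij,ij->j", Gf, w)
    h11 = np.einsum("ij,ij,ij->j", Gf, Gf, w)
    det = h00 * h11 - h01**2
    se = np.sqrt(h00 / det)
    bad = ~np.isfinite(b) | ~np.isfinite(se)
    if bad.any():
        logger.warning("logistic scan: %d SNPs failed to converge", int(bad.sum()))
        b[bad] = np.nan
        se[bad] = np.nan
    return b, se


def gwas_scan(cohort: Cohort, trait: str, subsample_ids=None,
              trait_name: str | None = None) -> SummaryStats:
    """Univariable per-SNP association scan within a subsample.

    Linear regression for the ordinal exposure score and the mediator,
    logistic regression (log-odds betas) for the binary outcome.
    """
    key = _TRAIT_ALIASES.get(trait)
    if key is None:
        raise ValueError(f"unknown trait {trait!r}")
    if subsample_ids is None:
        subsample_ids = np.arange(cohort.n)
    subsample_ids = np.asarray(subsample_ids)
    if subsample_ids.size == 0:
        raise ValueError("empty subsample")
    G = cohort.genotypes[subsample_ids]
    y = getattr(cohort, key)[subsample_ids].astype(float)
    if key == "Y":
        beta, se = _logistic_scan(G, y)
    else:
        beta, se = _linear_scan(G, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        pval = 2 * stats.norm.sf(np.abs(beta / se))
    table = pd.DataFrame({
        "variant_id": cohort.variant_ids,
        "effect_allele": [a for a, _ in cohort.alleles],
        "other_allele": [o for _, o in cohort.alleles],
        "eaf": G.mean(axis=0) / 2.0,
        "beta": beta, "se": se, "pval": pval,
        "n": float(len(subsample_ids)),
    })
    ok = table["se"].notna() & (table["se"] > 0)
    table = table[ok].reset_index(drop=True)
    return SummaryStats(table, trait_name=trait_name or key,
                        trait_type=_TRAIT_TYPES[key],
                        sample_size=len(subsample_ids))


# ---------------------------------------------------------------------------
# two-sample study bundles
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Two-sample summary statistics with ground truth.

    Exposure/mediator scans come from sample 1, outcome (and reverse-MR
    outcome-side exposure/mediator) scans from sample 2; ``overlap_fraction``
    of sample 2 individuals are shared with sample 1. Halves A/B are disjoint
    random splits of sample 1 for split-sample MR.
    """

    exposure: SummaryStats                 # X on sample 1
    mediator: SummaryStats | None          # M on sample 1
    outcome: SummaryStats | None           # Y on sample 2
    exposure_s2: SummaryStats | None       # X on sample 2 (reverse-MR outcome side)
    mediator_s2: SummaryStats | None       # M on sample 2
    halves: dict | None                    # {'exposure_a','mediator_a','exposure_b','mediator_b'}
    ld: LDMatrix
    truth: TruthRecord
    config: SimulationConfig
    sample1_ids: np.ndarray
    sample2_ids: np.ndarray


def theoretical_ld(cohort_or_cfg, variant_ids=None) -> LDMatrix:
    cfg = cohort_or_cfg.config if isinstance(cohort_or_cfg, Cohort) else cohort_or_cfg
    if variant_ids is None:
        variant_ids = [f"rs{i+1:05d}" for i in range(cfg.n_snps)]
    r2 = np.eye(cfg.n_snps)
    pos = 0
    for size, r in cfg.ld_blocks:
        size = int(size)
        blk = slice(pos, pos + size)
        r2[blk, blk] = r * r
        pos += size
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(variant_ids, r2)


def generate_two_sample_study(config: SimulationConfig,
                              include_binary: bool = True,
                              include_splits: bool = True,
                              include_reverse: bool = True) -> StudyBundle:
    """Simulate one cohort pool and derive the full two-sample bundle.

    The pool has n1 + n2 - overlap individuals; sample 1 is the first n1,
    sample 2 the last n2, so exactly ``overlap_fraction`` of the smaller
    sample is shared. The optional include flags skip scans a caller does
    not need (they change nothing else about the draw).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n_sample_exposure, config.n_sample_outcome
    shared = int(round(config.overlap_fraction * min(n1, n2)))
    total = n1 + n2 - shared
    cohort = simulate_cohort(config, n=total, rng=rng)
    s1 = np.arange(n1)
    s2 = np.arange(total - n2, total)

    exposure = gwas_scan(cohort, "exposure", s1, trait_name="exposure")
    mediator = gwas_scan(cohort, "mediator", s1, trait_name="mediator")
    outcome = gwas_scan(cohort, "outcome", s2, trait_name="outcome") if include_binary else None
    exposure_s2 = gwas_scan(cohort, "exposure", s2, trait_name="exposure") if include_reverse else None
    mediator_s2 = gwas_scan(cohort, "mediator", s2, trait_name="mediator") if include_reverse else None

    halves = None
    if include_splits:
        perm = rng.permutation(n1)
        half_a, half_b = perm[: n1 // 2], perm[n1 // 2:]
        halves = {
            "exposure_a": gwas_scan(cohort, "exposure", half_a, trait_name="exposure"),
            "mediator_a": gwas_scan(cohort, "mediator", half_a, trait_name="mediator"),
            "exposure_b": gwas_scan(cohort, "exposure", half_b, trait_name="exposure"),
            "mediator_b": gwas_scan(cohort, "mediator", half_b, trait_name="mediator"),
            "ids_a": half_a, "ids_b": half_b,
        }
    return StudyBundle(exposure=exposure, mediator=mediator, outcome=outcome,
                       exposure_s2=exposure_s2, mediator_s2=mediator_s2,
                       halves=halves, ld=theoretical_ld(cohort),
                       truth=cohort.truth, config=config,
                       sample1_ids=s1, sample2_ids=s2)


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Write the bundle as TSVs + truth/config JSON (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {"exposure.tsv": bundle.exposure, "mediator.tsv": bundle.mediator,
              "outcome.tsv": bundle.outcome, "exposure_s2.tsv": bundle.exposure_s2,
              "mediator_s2.tsv": bundle.mediator_s2}
    if bundle.halves:
        for k in ("exposure_a", "mediator_a", "exposure_b", "mediator_b"):
            tables[f"{k}.tsv"] = bundle.halves[k]
    for name, tab in tables.items():
        if tab is not None:
            write_sumstats(tab, outdir / name)
    bundle.ld.to_frame().to_csv(outdir / "ld.tsv", sep="\t", index=False,
                                float_format="%.17g")
    (outdir / "truth.json").write_text(bundle.truth.to_json() + "\n")
    (outdir / "config.json").write_text(bundle.config.to_json() + "\n")


def simulate_correlated_pair(config: SimulationConfig,
                             effect_correlation: float = 0.60):
    """Two cohorts (e.g. the two sexes) whose true per-SNP exposure effects
    are bivariate-normal with the given correlation; returns the two scanned
    exposure tables plus the true effect vectors.

    Emulates re-estimating one instrument list in two sex-specific GWAS of
    the same trait where the genetic architecture is only partially shared.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.n_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=L)
    rho = effect_correlation
    z = rng.standard_normal((L, 2))
    raw_a = z[:, 0]
    raw_b = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    var = 2 * freqs * (1 - freqs)
    eff_a = raw_a * np.sqrt(config.exposure_h2 / np.sum(var * raw_a**2))
    eff_b = raw_b * np.sqrt(config.exposure_h2 / np.sum(var * raw_b**2))
    tables = []
    for eff in (eff_a, eff_b):
        n = config.n_sample_exposure
        G = rng.binomial(2, freqs, size=(n, L))
        x = (G - 2 * freqs) @ eff + rng.normal(0, np.sqrt(1 - config.exposure_h2), n)
        beta, se = _linear_scan(G, x)
        alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(L)]
        tab = pd.DataFrame({
            "variant_id": [f"rs{i+1:05d}" for i in range(L)],
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [o for _, o in alleles],
            "eaf": G.mean(axis=0) / 2.0, "beta": beta, "se": se,
            "pval": 2 * stats.norm.sf(np.abs(beta / se)), "n": float(n),
        })
        tables.append(SummaryStats(tab, trait_name="exposure",
                                   trait_type="ordinal_category", sample_size=n))
    return tables[0], tables[1], eff_a, eff_b
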