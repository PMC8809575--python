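"""GWAS summary-statistic tables: I/O, instrument selection, LD clumping and
exposure-outcome harmonization.

The central container is :class:`SummaryStats`, a thin wrapper around a pandas
DataFrame with one row per variant and the canonical columns

    variant_id, effect_allele, other_allele, eaf, beta, se, pval, n

Effects are per copy of the effect allele, on the trait's native scale
(category units for an ordinal chronotype-like score, SD units for a
continuous hormone-like trait, log-odds for a binary disease outcome).
:func:`harmonize` aligns one or more exposure tables with an outcome table
into a :class:`HarmonizedSet`, the input of every MR estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a summary-statistics table
COLUMNS = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

#: default header-name mapping accepted by :func:`read_sumstats`
DEFAULT_DIALECT = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

TRAIT_TYPES = ("ordinal_category", "continuous_sd", "binary_logodds")

UNIT_LABELS = {
    "ordinal_category": "per category",
    "continuous_sd": "per SD",
    "binary_logodds": "log-odds",
}


class ConfigurationError(ValueError):
    """A table/dialect/run configuration is unusable."""


class EmptyInstrumentError(ValueError):
    """Instrument construction produced zero variants."""


class SummaryStats:
    """One trait's GWAS summary statistics.

    Parameters
    ----------
    table
        DataFrame with the canonical columns (:data:`COLUMNS`); ``eaf`` and
        ``n`` may contain NaN.
    trait_name, trait_type, sex_label
        Metadata propagated to every downstream result. ``trait_type`` fixes
        the unit label of causal estimates for this trait.
    sample_size
        Overall GWAS sample size; defaults to the median per-SNP ``n``.
    """

    def __init__(self, table: pd.DataFrame, trait_name: str = "trait",
                 trait_type: str = "continuous_sd", sex_label: str = "",
                 sample_size: int | None = None):
        if trait_type not in TRAIT_TYPES:
            raise ConfigurationError(f"unknown trait_type {trait_type!r}")
        missing = [c for c in COLUMNS if c not in table.columns]
        if missing:
            raise ConfigurationError(f"missing columns: {missing}")
        table = table.loc[:, COLUMNS].reset_index(drop=True)
        if table["variant_id"].duplicated().any():
            dup = table.loc[table["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ConfigurationError(f"duplicate variant_id {dup!r}")
        if (table["se"] <= 0).any():
            raise ConfigurationError("se must be positive for all records")
        self.table = table
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.sex_label = sex_label
        if sample_size is None:
            nmed = table["n"].median()
            sample_size = int(nmed) if np.isfinite(nmed) else 0
        self.sample_size = int(sample_size)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> pd.Series:
        return self.table["variant_id"]

    @property
    def unit(self) -> str:
        return UNIT_LABELS[self.trait_type]

    def _replace(self, table: pd.DataFrame) -> "SummaryStats":
        return SummaryStats(table, self.trait_name, self.trait_type,
                            self.sex_label, self.sample_size)

    def equals(self, other: "SummaryStats") -> bool:
        a = self.table.reset_index(drop=True)
        b = other.table.reset_index(drop=True)
        return a.shape == b.shape and bool(
            np.all(a["variant_id"].values == b["variant_id"].values)
            and np.allclose(a[["eaf", "beta", "se", "pval", "n"]].fillna(-1),
                            b[["eaf", "beta", "se", "pval", "n"]].fillna(-1),
                            rtol=0, atol=1e-12)
        )


def read_sumstats(path, dialect: dict | None = None, sep: str = "\t",
                  **meta) -> SummaryStats:
    """Read a delimited summary-statistics file into a :class:`SummaryStats`.

    ``dialect`` maps canonical names to the file's column headers, e.g.
    ``{"variant_id": "SNP", "pval": "P"}``; unmapped canonical names fall
    back to :data:`DEFAULT_DIALECT`. Rows with a missing beta or se, a
    non-positive se, or a non-ACGT allele are dropped with a logged count.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    raw = pd.read_csv(path, sep=sep)
    required = ["variant_id", "effect_allele", "other_allele", "beta", "se"]
    for canon in required:
        if mapping[canon] not in raw.columns:
            raise ConfigurationError(
                f"required column {mapping[canon]!r} (for {canon!r}) absent from {path}")
    out = pd.DataFrame()
    for canon in COLUMNS:
        col = mapping.get(canon)
        out[canon] = raw[col] if col in raw.columns else np.nan

    out["effect_allele"] = out["effect_allele"].astype(str).str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.upper()

    n0 = len(out)
    keep = out["beta"].notna() & out["se"].notna() & (out["se"] > 0)
    bad_allele = (~out["effect_allele"].isin(VALID_ALLELES)
                  | ~out["other_allele"].isin(VALID_ALLELES)
                  | (out["effect_allele"] == out["other_allele"]))
    keep &= ~bad_allele
    dropped = n0 - int(keep.sum())
    if dropped:
        logger.warning("read_sumstats: dropped %d/%d rows (missing beta/se, "
                       "non-positive se, or invalid alleles)", dropped, n0)
    out = out.loc[keep].reset_index(drop=True)
    return SummaryStats(out, **meta)


def write_sumstats(ss: SummaryStats, path, sep: str = "\t") -> None:
    """Write a table in the canonical layout (floats at full precision)."""
    ss.table.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_snp_list(path) -> list[str]:
    """Read a one-variant-id-per-line instrument list (blank lines and
    ``#`` comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# ---------------------------------------------------------------------------
# instrument construction
# ---------------------------------------------------------------------------

def select_instruments(ss: SummaryStats, mode: str = "de_novo",
                       p_threshold: float = 5e-8,
                       external_ids=None) -> SummaryStats:
    """Select instrument SNPs either de novo or from an external list.

    ``de_novo`` keeps rows with ``pval < p_threshold`` (genome-wide
    significance in the trait's own GWAS). ``external_list`` keeps the
    intersection with ``external_ids`` irrespective of significance — the
    design used when instruments come from a larger published GWAS and only
    their effect estimates are re-extracted from the analysis sample.
    """
    if mode == "de_novo":
        kept = ss.table[ss.table["pval"] < p_threshold]
    elif mode == "external_list":
        if external_ids is None:
            raise ConfigurationError("external_list mode requires external_ids")
        wanted = list(external_ids)
        present = ss.table["variant_id"].isin(set(wanted))
        absent = set(wanted) - set(ss.table["variant_id"])
        if absent:
            logger.info("select_instruments: %d listed ids absent from table", len(absent))
        kept = ss.table[present]
    else:
        raise ConfigurationError(f"unknown instrument mode {mode!r}")
    if kept.empty:
        raise EmptyInstrumentError(
            f"no instruments selected for {ss.trait_name!r} (mode={mode})")
    return ss._replace(kept.reset_index(drop=True))


@dataclass
class LDMatrix:
    """Squared-correlation matrix over an ordered set of variants."""

    variant_ids: list
    r2: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 shape does not match variant_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @classmethod
    def identity(cls, variant_ids) -> "LDMatrix":
        ids = list(variant_ids)
        return cls(ids, np.eye(len(ids)))

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.r2, columns=self.variant_ids)
        df.insert(0, "variant_id", self.variant_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDMatrix":
        ids = df["variant_id"].tolist()
        return cls(ids, df[ids].to_numpy(dtype=float))


def ld_clump(ss: SummaryStats, ld: LDMatrix, r2_threshold: float = 0.001) -> SummaryStats:
    """Greedy LD clumping at a squared-correlation threshold.

    Repeatedly keeps the remaining variant with the smallest p-value and
    discards all remaining variants correlated with it at r² > threshold.
    Ties on p-value are broken by lexicographic variant_id so the result is
    deterministic.
    """
    for v in ss.table["variant_id"]:
        if v not in ld._index:
            raise KeyError(f"variant {v!r} absent from LD matrix")
    order = ss.table.sort_values(["pval", "variant_id"], kind="mergesort")
    remaining = list(order["variant_id"])
    kept: list[str] = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top)
        remaining = [v for v in remaining if ld.lookup(top, v) <= r2_threshold]
    kept_set = set(kept)
    out = ss.table[ss.table["variant_id"].isin(kept_set)].reset_index(drop=True)
    return ss._replace(out)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

KEPT = "kept"
PALINDROMIC = "palindromic_ambiguous"
INCOMPATIBLE = "incompatible_alleles"
MISSING = "missing_in_outcome"


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


@dataclass
class HarmonizedSet:
    """Per-SNP exposure and outcome effects on a shared allele orientation.

    ``table`` has one row per exposure SNP with columns ``variant_id,
    beta_exposure, se_exposure, eaf_exposure, beta_outcome, se_outcome,
    eaf_outcome, exclusion_flag`` plus, for K>1 exposures, suffixed columns
    ``beta_exposure_2, se_exposure_2, ...``. Only rows flagged ``kept`` feed
    the estimators (:meth:`kept`).
    """

    table: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    exposure_type: str = "continuous_sd"
    outcome_type: str = "continuous_sd"
    exposure_names: list = field(default_factory=list)
    n_exposure: int = 0
    n_outcome: int = 0

    def __post_init__(self):
        if not self.exposure_names:
            self.exposure_names = [self.exposure_name]

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)

    def kept(self) -> pd.DataFrame:
        return self.table[self.table["exclusion_flag"] == KEPT].reset_index(drop=True)

    def exposure_beta_matrix(self) -> np.ndarray:
        """(L, K) matrix of kept exposure betas (column 0 = primary)."""
        k = self.kept()
        cols = ["beta_exposure"] + [f"beta_exposure_{i}" for i in range(2, self.n_exposures + 1)]
        return k[cols].to_numpy(dtype=float)

    def exposure_se_matrix(self) -> np.ndarray:
        k = self.kept()
        cols = ["se_exposure"] + [f"se_exposure_{i}" for i in range(2, self.n_exposures + 1)]
        return k[cols].to_numpy(dtype=float)

    def arrays(self):
        """Kept (variant_id, bx, sx, by, sy) arrays for univariable MR."""
        k = self.kept()
        return (k["variant_id"].to_numpy(),
                k["beta_exposure"].to_numpy(dtype=float),
                k["se_exposure"].to_numpy(dtype=float),
                k["beta_outcome"].to_numpy(dtype=float),
                k["se_outcome"].to_numpy(dtype=float))

    def subset(self, variant_ids) -> "HarmonizedSet":
        wanted = set(variant_ids)
        tab = self.table[self.table["variant_id"].isin(wanted)].reset_index(drop=True)
        return HarmonizedSet(tab, self.exposure_name, self.outcome_name,
                             self.exposure_type, self.outcome_type,
                             list(self.exposure_names), self.n_exposure, self.n_outcome)

    def drop(self, variant_ids) -> "HarmonizedSet":
        unwanted = set(variant_ids)
        tab = self.table[~self.table["variant_id"].isin(unwanted)].reset_index(drop=True)
        return HarmonizedSet(tab, self.exposure_name, self.outcome_name,
                             self.exposure_type, self.outcome_type,
                             list(self.exposure_names), self.n_exposure, self.n_outcome)


def _align_one(exp_row, out_row, palindrome_maf: float):
    """Align one outcome record to the exposure's allele orientation.

    Returns (flag, beta_outcome, eaf_outcome) after any sign flip /
    frequency complement.
    """
    ea_e, oa_e = exp_row["effect_allele"], exp_row["other_allele"]
    ea_o, oa_o = out_row["effect_allele"], out_row["other_allele"]
    beta_o, eaf_o = out_row["beta"], out_row["eaf"]

    if (ea_o, oa_o) == (ea_e, oa_e):
        flipped = False
    elif (ea_o, oa_o) == (oa_e, ea_e):
        flipped, beta_o = True, -beta_o
        eaf_o = 1.0 - eaf_o if np.isfinite(eaf_o) else np.nan
    else:
        return INCOMPATIBLE, np.nan, np.nan

    if _is_palindromic(ea_e, oa_e):
        eaf_e = exp_row["eaf"]
        if not (np.isfinite(eaf_e) and np.isfinite(eaf_o)):
            return PALINDROMIC, np.nan, np.nan
        maf_e = min(eaf_e, 1 - eaf_e)
        maf_o = min(eaf_o, 1 - eaf_o)
        if maf_e >= palindrome_maf or maf_o >= palindrome_maf:
            return PALINDROMIC, np.nan, np.nan
        # strand is unobservable for palindromes: infer alignment from which
        # allele is minor on each side; discordance means a strand flip
        if (eaf_e < 0.5) != (eaf_o < 0.5):
            beta_o = -beta_o
            eaf_o = 1.0 - eaf_o
    return KEPT, beta_o, eaf_o


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindrome_maf: float = 0.3,
              extra_exposures: list | None = None) -> HarmonizedSet:
    """Align outcome (and any extra exposure) effects to the exposure alleles.

    Matching is on variant_id. If the outcome's effect allele equals the
    exposure's other allele the outcome beta is negated and its frequency
    complemented. Palindromic SNPs (A/T, C/G) are kept only when both sides'
    minor-allele frequencies are below ``palindrome_maf`` and the inferred
    strand alignment agrees; otherwise they are flagged
    ``palindromic_ambiguous``. With extra exposures, only SNPs aligned and
    kept in every table survive.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise EmptyInstrumentError("harmonize requires non-empty tables")
    out_idx = outcome.table.set_index("variant_id")
    extra_idx = [t.table.set_index("variant_id") for t in (extra_exposures or [])]

    rows = []
    for _, erow in exposure.table.iterrows():
        vid = erow["variant_id"]
        rec = {
            "variant_id": vid,
            "beta_exposure": erow["beta"], "se_exposure": erow["se"],
            "eaf_exposure": erow["eaf"], "pval_exposure": erow["pval"],
            "n_exposure": erow["n"],
        }
        if vid not in out_idx.index:
            rec.update(exclusion_flag=MISSING, beta_outcome=np.nan,
                       se_outcome=np.nan, eaf_outcome=np.nan)
            rows.append(rec)
            continue
        orow = out_idx.loc[vid]
        flag, beta_o, eaf_o = _align_one(erow, orow, palindrome_maf)
        rec.update(exclusion_flag=flag, beta_outcome=beta_o,
                   se_outcome=orow["se"] if flag == KEPT else np.nan,
                   eaf_outcome=eaf_o,
                   n_outcome=orow["n"] if flag == KEPT else np.nan)
        # extra exposures for MVMR: aligned to the same orientation
        for j, tidx in enumerate(extra_idx, start=2):
            if vid not in tidx.index:
                rec["exclusion_flag"] = MISSING
                continue
            trow = tidx.loc[vid]
            tflag, beta_t, eaf_t = _align_one(erow, trow, palindrome_maf)
            if tflag != KEPT:
                rec["exclusion_flag"] = tflag
                continue
            rec[f"beta_exposure_{j}"] = beta_t
            rec[f"se_exposure_{j}"] = trow["se"]
            rec[f"eaf_exposure_{j}"] = eaf_t
        rows.append(rec)

    table = pd.DataFrame(rows)
    names = [exposure.trait_name] + [t.trait_name for t in (extra_exposures or [])]
    hset = HarmonizedSet(table, exposure.trait_name, outcome.trait_name,
                         exposure.trait_type, outcome.trait_type,
                         exposure_names=names,
                         n_exposure=exposure.sample_size,
                         n_outcome=outcome.sample_size)
    if len(hset.kept()) == 0:
        raise EmptyInstrumentError(
            f"harmonization of {exposure.trait_name!r} vs {outcome.trait_name!r} kept 0 SNPs")
    n_flagged = int((table["exclusion_flag"] != KEPT).sum())
    if n_flagged:
        logger.info("harmonize: %d/%d SNPs excluded", n_flagged, len(table))
    return hset


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

def variance_explained(beta, se, eaf, n, trait_type: str) -> np.ndarray:
    """Per-SNP r² on the trait scale.

    SD-scale traits use 2f(1-f)β². Binary and ordinal-category traits use the
    scale-free approximation z²/(z²+n) (z = β/se), which matches additive
    variance bookkeeping when the phenotypic variance is not 1.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    eaf = np.asarray(eaf, float)
    n = np.asarray(n, float)
    if trait_type == "continuous_sd":
        r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    else:
        z2 = (beta / se) ** 2
        r2 = z2 / (z2 + n)
    return r2


@dataclass
class InstrumentStrength:
    per_snp_f: np.ndarray
    mean_f: float
    per_snp_r2: np.ndarray
    combined_r2: float
    regression_f: float
    n_snp: int


def instrument_strength(ss: SummaryStats) -> InstrumentStrength:
    """Univariable instrument strength: per-SNP F, mean F, combined r².

    The regression-form F uses r²(n-k-1)/((1-r²)k) with k = number of SNPs.
    SNPs with missing eaf are excluded from the combined r² (with a warning)
    but still contribute their F statistic.
    """
    t = ss.table
    f = (t["beta"] / t["se"]).to_numpy(dtype=float) ** 2
    r2 = variance_explained(t["beta"], t["se"], t["eaf"], t["n"], ss.trait_type)
    have = np.isfinite(r2)
    if not have.all():
        logger.warning("instrument_strength: %d SNPs lack eaf/n; excluded from r²",
                       int((~have).sum()))
    combined = float(np.nansum(np.where(have, r2, 0.0)))
    k = len(t)
    n = ss.sample_size
    if 0 < combined < 1 and n > k + 1:
        reg_f = combined * (n - k - 1) / ((1 - combined) * k)
    else:
        reg_f = np.nan
    return InstrumentStrength(per_snp_f=f, mean_f=float(np.mean(f)),
                              per_snp_r2=r2, combined_r2=combined,
                              regression_f=float(reg_f), n_snp=k)


def check_pval_consistency(ss: SummaryStats, sig: int = 2) -> np.ndarray:
    """Flag rows whose p disagrees with |beta/se| under a normal reference.

    Returns a boolean mask of consistent rows (2 significant figures)."""
    z = np.abs(ss.table["beta"] / ss.table["se"])
    p_expect = 2 * stats.norm.sf(z)
    p_obs = ss.table["pval"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = np.isclose(p_obs, p_expect, rtol=10.0 ** (1 - sig), atol=1e-300)
    return ok | ~np.isfinite(p_obs)


def cross_trait_effect_correlation(a: SummaryStats, b: SummaryStats) -> float:
    """Pearson correlation of per-SNP betas across two tables (shared SNPs),
    after aligning table *b* to *a*'s effect alleles."""
    merged = a.table.merge(b.table, on="variant_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared variants")
    sign = np.where(
        (merged["effect_allele_b"] == merged["effect_allele_a"])
        & (merged["other_allele_b"] == merged["other_allele_a"]), 1.0,
        np.where((merged["effect_allele_b"] == merged["other_allele_a"])
                 & (merged["other_allele_b"] == merged["effect_allele_a"]), -1.0, np.nan))
    ok = np.isfinite(sign)
    x = merged.loc[ok, "beta_a"].to_numpy(dtype=float)
    y = sign[ok] * merged.loc[ok, "beta_b"].to_numpy(dtype=float)
    return float(np.corrcoef(x, y)[0, 1])
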