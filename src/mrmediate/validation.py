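"""Repeated-simulation validation studies for the MR pipeline.

Each function runs a self-contained simulation study at desk scale
(100 SNPs, samples of 20,000, a few hundred replicates) and returns the
summary quantities a methodologist would check: estimator bias and type-I
error, pleiotropy robustness orderings, mediation/attenuation recovery,
Steiger directionality recovery and sample-overlap bias. They power both the
test suite (at reduced replicate counts) and the acceptance script.

All replicate seeds are derived deterministically from one base seed.
"""

from __future__ import annotations

import numpy as np

from .mr import MRModel, cochran_q, fixed_effect_meta, i2_from_q
from .mvmr import MVMRModel
from .sensitivity import split_sample_mr, steiger_filter
from .simulate import (PleiotropyConfig, SimulationConfig,
                       generate_two_sample_study, simulate_correlated_pair)
from .sumstats import harmonize, select_instruments

_MOD = 2**31 - 1


def _seeds(base_seed: int, n: int, stream: int) -> list[int]:
    """Deterministic per-replicate seeds, distinct across streams."""
    rng = np.random.default_rng([base_seed, stream])
    return [int(s) for s in rng.integers(1, _MOD, size=n)]


# ---------------------------------------------------------------------------
# printed-number identities
# ---------------------------------------------------------------------------

def heterogeneity_identity(Q: float = 262.0, n_snp: int = 195) -> float:
    """I² (percent) implied by a heterogeneity statistic over n_snp
    instruments (df = n_snp - 1)."""
    return i2_from_q(Q, n_snp - 1)


def cross_sex_correlation(seed: int, n_reps: int = 5, n_snps: int = 341,
                          n_sample: int = 20_000, h2: float = 0.3,
                          rho: float = 0.60) -> dict:
    """Pearson correlation of per-SNP effect estimates for one instrument
    list re-estimated in two cohorts whose true effects correlate at
    ``rho`` (the partially shared male/female genetic architecture).

    The estimate correlation is mildly attenuated below ``rho`` by GWAS
    sampling noise; averaging over replicates reduces Monte-Carlo error.
    """
    rs = []
    for s in _seeds(seed, n_reps, stream=1):
        cfg = SimulationConfig(seed=s, n_snps=n_snps,
                               n_sample_exposure=n_sample, exposure_h2=h2)
        ta, tb, _, _ = simulate_correlated_pair(cfg, effect_correlation=rho)
        rs.append(float(np.corrcoef(ta.table["beta"], tb.table["beta"])[0, 1]))
    return {"correlation": float(np.mean(rs)), "n_reps": n_reps,
            "n_snps": n_snps}


# ---------------------------------------------------------------------------
# estimator oracles
# ---------------------------------------------------------------------------

def oracle_equivalence(seed: int, n_instances: int = 20, L: int = 10) -> dict:
    """Max |implementation - independent oracle| for IVW, Egger, weighted
    median and multivariable IVW over random instances."""
    worst = 0.0
    for s in _seeds(seed, n_instances, stream=2):
        rng = np.random.default_rng(s)
        bx = rng.uniform(0.05, 0.4, L)
        sx = np.full(L, 0.02)
        sy = rng.uniform(0.02, 0.08, L)
        by = rng.normal(0.4 * bx, 0.05)
        m = MRModel.from_arrays(bx, sx, by, sy)
        w = 1 / sy**2

        ivw = m.fit_ivw(weighting="fixed").estimate
        worst = max(worst, abs(ivw - np.sum(w * bx * by) / np.sum(w * bx**2)))

        slope, inter = m.fit_egger()
        X = np.column_stack([np.ones(L), bx])
        coef = np.linalg.solve(X.T * w @ X, X.T @ (w * by))
        worst = max(worst, abs(inter.estimate - coef[0]),
                    abs(slope.estimate - coef[1]))

        med = m.fit_weighted_median(n_boot=0).estimate
        ratios, wr = by / bx, bx**2 / sy**2
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], wr[order] / wr.sum()
        cum = np.cumsum(w_s) - w_s / 2
        worst = max(worst, abs(med - np.interp(0.5, cum, r_s)))

        X2 = np.column_stack([bx, rng.uniform(0.05, 0.4, L)])
        y2 = X2 @ np.array([0.4, 0.1]) + rng.normal(0, 0.02, L)
        mv = MVMRModel.from_arrays(X2, np.full((L, 2), 0.02), y2, sy)
        est = mv.fit_ivw(conditional_f=False).estimates
        W = np.diag(w)
        oracle = np.linalg.solve(X2.T @ W @ X2, X2.T @ W @ y2)
        worst = max(worst, float(np.max(np.abs(est - oracle))))
    return {"max_abs_deviation": float(worst), "n_instances": n_instances}


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def _recovery_config(seed: int, **overrides) -> SimulationConfig:
    base = dict(seed=seed, n_snps=100, n_sample_exposure=20_000,
                n_sample_outcome=20_000, exposure_h2=0.3, theta_XM=-0.2,
                theta_XY=0.0, theta_MY=0.0,
                confounder_strengths=(0.3, 0.3, 0.0))
    base.update(overrides)
    return SimulationConfig(**base)


def _forward_ivw(cfg: SimulationConfig, weighting: str = "auto"):
    """IVW of the exposure on the continuous mediator, all true instruments."""
    b = generate_two_sample_study(cfg, include_binary=False,
                                  include_splits=False)
    inst = select_instruments(b.exposure, mode="external_list",
                              external_ids=b.truth.exposure_snp_ids)
    hset = harmonize(inst, b.mediator_s2)
    return MRModel(hset).fit_ivw(weighting=weighting), b


def parameter_recovery(seed: int, n_seeds: int = 200,
                       theta: float = -0.2) -> dict:
    """Mean IVW bias (relative to |θ|) with strong valid instruments, and
    empirical type-I error of the IVW test under θ = 0 with confounding.

    Both arms use the fixed-effects IVW: the scenario generates no
    heterogeneity, and the multiplicative-random-effects variant (whose
    overdispersion factor is bounded below at 1) is conservative by
    construction, so calibration is assessed on the textbook z-test.
    """
    ests = []
    for s in _seeds(seed, n_seeds, stream=3):
        res, _ = _forward_ivw(_recovery_config(s, theta_XM=theta),
                              weighting="fixed")
        ests.append(res.estimate)
    bias = float(np.mean(ests) - theta)

    rejections = 0
    for s in _seeds(seed, n_seeds, stream=4):
        res, _ = _forward_ivw(_recovery_config(s, theta_XM=0.0),
                              weighting="fixed")
        rejections += res.pval < 0.05
    return {"mean_estimate": float(np.mean(ests)), "theta": theta,
            "relative_bias": bias / abs(theta),
            "type1_error": rejections / n_seeds, "n_seeds": n_seeds}


def pleiotropy_robustness(seed: int, n_seeds: int = 200,
                          theta: float = -0.2) -> dict:
    """Directional pleiotropy under InSIDE (Egger consistent, IVW biased)
    and InSIDE-violating pleiotropy (mode <= median <= IVW bias ordering).

    Instrument effects are drawn with a magnitude floor
    (``effect_truncation``): directional pleiotropy is defined relative to
    the exposure-increasing allele, and near-null instruments whose
    estimated orientation flips would mechanically violate InSIDE, which
    this scenario asserts to hold. The Egger arm additionally uses a large
    exposure GWAS (n = 100,000) so that the no-measurement-error (NOME)
    assumption holds to good approximation (I²GX > 98%) — MR-Egger is only
    consistent under InSIDE *and* NOME, and its NOME dilution at equal desk
    sample sizes is exactly the phenomenon I²GX/SIMEX exist to flag.
    """
    inside = PleiotropyConfig(fraction_direct=0.3, mean_direct_effect=0.03,
                              sd_direct_effect=0.01, balanced=False,
                              inside_violation=False)
    viol = PleiotropyConfig(fraction_direct=0.3, mean_direct_effect=0.05,
                            sd_direct_effect=0.01, balanced=False,
                            inside_violation=True)
    acc = {"ivw_inside": [], "egger_inside": [],
           "ivw_viol": [], "median_viol": [], "mode_viol": []}
    for s in _seeds(seed, n_seeds, stream=5):
        cfg = _recovery_config(s, theta_XM=theta, pleiotropy=inside,
                               effect_truncation=0.3,
                               n_sample_exposure=100_000)
        b = generate_two_sample_study(cfg, include_binary=False,
                                      include_splits=False)
        inst = select_instruments(b.exposure, mode="external_list",
                                  external_ids=b.truth.exposure_snp_ids)
        m = MRModel(harmonize(inst, b.mediator_s2))
        acc["ivw_inside"].append(m.fit_ivw().estimate)
        acc["egger_inside"].append(m.fit_egger()[0].estimate)

        cfg2 = _recovery_config(s + 1, theta_XM=theta, pleiotropy=viol,
                                effect_truncation=0.5)
        b2 = generate_two_sample_study(cfg2, include_binary=False,
                                       include_splits=False)
        inst2 = select_instruments(b2.exposure, mode="external_list",
                                   external_ids=b2.truth.exposure_snp_ids)
        m2 = MRModel(harmonize(inst2, b2.mediator_s2))
        acc["ivw_viol"].append(m2.fit_ivw().estimate)
        acc["median_viol"].append(m2.fit_weighted_median(n_boot=0).estimate)
        acc["mode_viol"].append(m2.fit_weighted_mode(n_boot=0).estimate)
    out = {k + "_bias": float(np.mean(v) - theta) for k, v in acc.items()}
    out["egger_inside_mc_se"] = float(np.std(acc["egger_inside"], ddof=1)
                                      / np.sqrt(n_seeds))
    out["mode_viol_mc_se"] = float(np.std(acc["mode_viol"], ddof=1)
                                   / np.sqrt(n_seeds))
    out["theta"] = theta
    out["n_seeds"] = n_seeds
    return out


# ---------------------------------------------------------------------------
# mediation recovery
# ---------------------------------------------------------------------------

def mediation_recovery(seed: int, n_seeds: int = 200) -> dict:
    """Full-mediation vs no-mediation attenuation patterns.

    Full mediation (θ_XY = 0, θ_XM·θ_MY ≠ 0): the univariable total-effect
    CI should exclude zero while the multivariable direct-effect CI includes
    it. No mediation (θ_XM = 0): univariable and multivariable exposure
    estimates agree within 2 SE.
    """
    full_hits = 0
    for s in _seeds(seed, n_seeds, stream=6):
        cfg = _recovery_config(s, theta_XM=-0.4, theta_MY=0.5, theta_XY=0.0,
                               reverse_snp_fraction=0.3, mediator_h2=0.15)
        uv, mv = _uv_and_mv(cfg)
        if uv.ci_excludes_null() and mv.ci_low[0] <= 0 <= mv.ci_high[0]:
            full_hits += 1

    none_hits = 0
    for s in _seeds(seed, n_seeds, stream=7):
        cfg = _recovery_config(s, theta_XM=0.0, theta_XY=-0.2, theta_MY=0.3,
                               reverse_snp_fraction=0.3, mediator_h2=0.15)
        uv, mv = _uv_and_mv(cfg)
        se = max(mv.ses[0], uv.se)
        if abs(uv.estimate - mv.estimates[0]) < 2 * se:
            none_hits += 1
    return {"full_mediation_rate": full_hits / n_seeds,
            "no_mediation_agreement_rate": none_hits / n_seeds,
            "n_seeds": n_seeds}


def _uv_and_mv(cfg: SimulationConfig):
    b = generate_two_sample_study(cfg, include_splits=False,
                                  include_reverse=False)
    exp_inst = select_instruments(b.exposure, mode="external_list",
                                  external_ids=b.truth.exposure_snp_ids)
    uv = MRModel(harmonize(exp_inst, b.outcome)).fit_ivw()
    # union of exposure and mediator instruments for the joint model
    mv_hset = harmonize(b.exposure, b.outcome, extra_exposures=[b.mediator])
    mv = MVMRModel(mv_hset).fit_ivw(conditional_f=False)
    return uv, mv


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------

def directionality_recovery(seed: int, n_seeds: int = 200) -> dict:
    """Steiger-filtered bidirectional MR on one-way vs two-way structures,
    plus the per-SNP Steiger classification rates on significant instruments."""
    oneway_hits = 0
    for s in _seeds(seed, n_seeds, stream=8):
        cfg = _recovery_config(s, theta_XM=-0.25, theta_MX=0.0,
                               reverse_snp_fraction=0.3, mediator_h2=0.15)
        fwd, rev, _ = _bidirectional_once(cfg)
        if fwd is not None and rev is not None:
            if fwd.ci_excludes_null() and not rev.ci_excludes_null():
                oneway_hits += 1

    # reverse SNPs only enter the forward instrument when the reverse path
    # is strong enough for them to reach genome-wide significance in the
    # exposure GWAS, so the Steiger classification rates come from this
    # contaminated-instrument scenario
    both_hits = 0
    removed_rev = kept_val = tot_rev = tot_val = 0
    for s in _seeds(seed, n_seeds, stream=9):
        cfg = _recovery_config(s, theta_XM=-0.25, theta_MX=-0.3,
                               reverse_snp_fraction=0.2, mediator_h2=0.25)
        fwd, rev, cls = _bidirectional_once(cfg)
        if fwd is not None and rev is not None:
            if fwd.ci_excludes_null() and rev.ci_excludes_null():
                both_hits += 1
        removed_rev += cls[0]
        tot_rev += cls[1]
        kept_val += cls[2]
        tot_val += cls[3]
    return {"one_way_rate": oneway_hits / n_seeds,
            "bidirectional_rate": both_hits / n_seeds,
            "steiger_reverse_removed_rate": removed_rev / max(tot_rev, 1),
            "steiger_valid_kept_rate": kept_val / max(tot_val, 1),
            "n_seeds": n_seeds}


def _bidirectional_once(cfg: SimulationConfig):
    b = generate_two_sample_study(cfg, include_binary=False,
                                  include_splits=False)
    # forward: genome-wide-significant exposure instruments
    try:
        inst_f = select_instruments(b.exposure, mode="de_novo", p_threshold=5e-8)
        h_f = harmonize(inst_f, b.mediator_s2)
        st_f, filt_f = steiger_filter(h_f)
        fwd = MRModel(filt_f).fit_ivw()
    except Exception:
        fwd, st_f, inst_f = None, None, None
    try:
        inst_r = select_instruments(b.mediator, mode="de_novo", p_threshold=5e-8)
        h_r = harmonize(inst_r, b.exposure_s2)
        _, filt_r = steiger_filter(h_r)
        rev = MRModel(filt_r).fit_ivw()
    except Exception:
        rev = None
    cls = (0, 0, 0, 0)
    if st_f is not None:
        rev_ids = set(b.truth.reverse_ids) & set(inst_f.variant_ids)
        val_ids = set(b.truth.valid_ids) & set(inst_f.variant_ids)
        removed = set(st_f.removed_ids)
        cls = (len(rev_ids & removed), len(rev_ids),
               len(val_ids - removed), len(val_ids))
    return fwd, rev, cls


# ---------------------------------------------------------------------------
# sample overlap
# ---------------------------------------------------------------------------

def split_sample_overlap(seed: int, n_seeds: int = 200) -> dict:
    """Under the null with weak instruments and 100% exposure/outcome sample
    overlap, compare the bias of the naive full-overlap IVW with the pooled
    split-sample (cross-half) estimate."""
    full_est, split_est = [], []
    for s in _seeds(seed, n_seeds, stream=10):
        cfg = _recovery_config(s, theta_XM=0.0, exposure_h2=0.05,
                               overlap_fraction=1.0,
                               confounder_strengths=(0.5, 0.5, 0.0))
        b = generate_two_sample_study(cfg, include_binary=False)
        inst = b.truth.exposure_snp_ids
        exp = select_instruments(b.exposure, mode="external_list",
                                 external_ids=inst)
        full = MRModel(harmonize(exp, b.mediator_s2)).fit_ivw()
        full_est.append(full.estimate)
        pooled = split_sample_mr(
            (select_instruments(b.halves["exposure_a"], mode="external_list",
                                external_ids=inst), b.halves["mediator_a"]),
            (select_instruments(b.halves["exposure_b"], mode="external_list",
                                external_ids=inst), b.halves["mediator_b"]))
        split_est.append(pooled.estimate)
    return {"full_overlap_bias": float(np.mean(full_est)),
            "split_sample_bias": float(np.mean(split_est)),
            "n_seeds": n_seeds}
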