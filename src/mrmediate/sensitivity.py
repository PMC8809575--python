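"""Instrument-validity diagnostics.

Radial-MR outlier detection, leave-one-out influence analysis, Steiger
directionality filtering (with sensitivity ratios), the I²GX measure of
exposure-beta measurement error with SIMEX-corrected Egger, and split-sample
MR for sample-overlap control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mr import MRModel, MRResults, fixed_effect_meta
from .sumstats import HarmonizedSet, SummaryStats, harmonize, variance_explained


# ---------------------------------------------------------------------------
# radial MR
# ---------------------------------------------------------------------------

@dataclass
class RadialResult:
    """Per-SNP radial Q decomposition and flagged outliers."""

    table: pd.DataFrame           # variant_id, Qj, Qj_pval, is_outlier
    global_Q: float
    global_Q_pval: float
    estimate: float
    alpha_used: float
    outlier_ids: list = field(default_factory=list)


def radial_ivw(data: HarmonizedSet, alpha="bonferroni") -> RadialResult:
    """First-order radial regression of βY/σY on βX/σY through the origin.

    Each SNP's squared residual Qj follows χ²₁ under homogeneity; SNPs with
    Qj_pval < alpha are flagged as outliers. ``alpha="bonferroni"`` resolves
    to 0.05/L.
    """
    model = MRModel(data)
    if model.L < 2:
        raise ValueError("radial MR requires >= 2 SNPs")
    bx, by, sy = model.bx, model.by, model.sy
    # radial coordinates: y* = by/sy regressed on x* = bx/sy, no intercept
    xs, ys = bx / sy, by / sy
    est = float(np.sum(xs * ys) / np.sum(xs**2))
    qj = (ys - est * xs) ** 2
    alpha_used = 0.05 / model.L if alpha == "bonferroni" else float(alpha)
    pj = stats.chi2.sf(qj, 1)
    out_mask = pj < alpha_used
    table = pd.DataFrame({
        "variant_id": model.variant_ids, "Qj": qj, "Qj_pval": pj,
        "is_outlier": out_mask,
    })
    Q = float(qj.sum())
    return RadialResult(table=table, global_Q=Q,
                        global_Q_pval=float(stats.chi2.sf(Q, model.L - 1)),
                        estimate=est, alpha_used=alpha_used,
                        outlier_ids=list(model.variant_ids[out_mask]))


def remove_radial_outliers(data: HarmonizedSet, radial: RadialResult) -> HarmonizedSet:
    return data.drop(radial.outlier_ids)


def leave_one_out(data: HarmonizedSet, weighting: str = "auto") -> list[MRResults]:
    """L IVW fits each omitting one SNP, labelled by the omitted id."""
    model = MRModel(data)
    if model.L < 3:
        raise ValueError("leave-one-out requires >= 3 SNPs")
    ids = list(model.variant_ids)
    out = []
    for vid in ids:
        res = MRModel(data.drop([vid])).fit_ivw(weighting=weighting)
        res.extra["omitted"] = vid
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

@dataclass
class SteigerResult:
    table: pd.DataFrame       # per-SNP r2_exposure, r2_outcome, direction_correct, steiger_pval
    kept_ids: list
    removed_ids: list
    sensitivity_ratio: float
    r2_exposure_total: float
    r2_outcome_total: float


def _steiger_sensitivity_ratio(r2x: float, r2y: float, grid: int = 20,
                               lo: float = 0.1, hi: float = 1.0) -> float:
    """Volume ratio over a grid of measurement-reliability pairs.

    Observed r² understate the true ones when traits are measured with
    reliability < 1: true r² = observed / reliability. Over a grid of
    (reliability_x, reliability_y) in [lo, hi]², R = (# grid cells where the
    inferred direction is unchanged) / (# cells where it reverses). R = inf
    when no cell reverses.
    """
    rel = np.linspace(lo, hi, grid)
    rx = r2x / rel[:, None]     # rows: exposure reliability
    ry = r2y / rel[None, :]
    unchanged = int(np.sum(rx > ry))
    reversed_ = int(np.sum(rx <= ry))
    if reversed_ == 0:
        return float("inf")
    return unchanged / reversed_


def steiger_filter(data: HarmonizedSet, nX: int | None = None,
                   nY: int | None = None, mode: str = "direction_only",
                   p_threshold: float = 0.05):
    """Remove SNPs that explain more variance in the outcome than in the
    exposure (wrong causal orientation), with a Steiger z-test of the
    r difference.

    Per-SNP r² uses 2f(1-f)β² on SD-scale traits and z²/(z²+n) otherwise.
    A tie (r²X = r²Y) counts as wrong direction. In ``direction_and_p`` mode
    a SNP must additionally have steiger_pval < p_threshold to be kept.
    Returns ``(SteigerResult, filtered HarmonizedSet)``.
    """
    if mode not in ("direction_only", "direction_and_p"):
        raise ValueError(f"unknown mode {mode!r}")
    k = data.kept()
    nX = int(nX if nX is not None else data.n_exposure)
    nY = int(nY if nY is not None else data.n_outcome)
    if nX < 4 or nY < 4:
        raise ValueError("Steiger test requires sample sizes >= 4")
    r2x = variance_explained(k["beta_exposure"], k["se_exposure"],
                             k["eaf_exposure"], nX, data.exposure_type)
    r2y = variance_explained(k["beta_outcome"], k["se_outcome"],
                             k["eaf_outcome"], nY, data.outcome_type)
    rx = np.sqrt(np.clip(r2x, 0, 1 - 1e-12))
    ry = np.sqrt(np.clip(r2y, 0, 1 - 1e-12))
    z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(1 / (nX - 3) + 1 / (nY - 3))
    pval = 2 * stats.norm.sf(np.abs(z))
    direction = r2x > r2y
    keep = direction.copy()
    if mode == "direction_and_p":
        keep &= pval < p_threshold
    table = pd.DataFrame({
        "variant_id": k["variant_id"], "r2_exposure": r2x, "r2_outcome": r2y,
        "direction_correct": direction, "steiger_z": z, "steiger_pval": pval,
        "kept": keep,
    })
    kept_ids = list(k.loc[keep, "variant_id"])
    removed_ids = list(k.loc[~keep, "variant_id"])
    tot_x = float(np.nansum(r2x[keep]))
    tot_y = float(np.nansum(r2y[keep]))
    R = _steiger_sensitivity_ratio(tot_x, tot_y) if kept_ids else np.nan
    result = SteigerResult(table=table, kept_ids=kept_ids,
                           removed_ids=removed_ids, sensitivity_ratio=R,
                           r2_exposure_total=tot_x, r2_outcome_total=tot_y)
    return result, data.subset(kept_ids)


# ---------------------------------------------------------------------------
# NOME violation: I2_GX and SIMEX
# ---------------------------------------------------------------------------

def i2_gx(data: HarmonizedSet, weighted: bool = True) -> float:
    """I²GX: how far exposure betas depart from the no-measurement-error
    (NOME) assumption behind MR-Egger, in percent.

    Q_GX is the heterogeneity of the oriented exposure betas about their
    (inverse-σX²-weighted or unweighted) mean, standardised by σX; I²GX =
    100·max(0, (Q_GX - (L-1))/Q_GX). Values near 100 mean exposure betas are
    measured essentially without error; low values signal Egger dilution.
    """
    model = MRModel(data)
    if model.L < 2:
        raise ValueError("I2_GX requires >= 2 SNPs")
    bx, sx = model.bx, model.sx
    w = 1.0 / sx**2
    mu = np.sum(w * bx) / np.sum(w) if weighted else np.mean(bx)
    Q = float(np.sum(w * (bx - mu) ** 2))
    if Q <= 0:
        return 0.0
    return 100.0 * max(0.0, (Q - (model.L - 1)) / Q)


@dataclass
class IGXResult:
    i2gx_unweighted: float
    i2gx_weighted: float
    simex_slope: float
    simex_se: float
    simex_intercept: float
    raw_slope: float
    raw_se: float
    lambdas: np.ndarray
    n_sim: int
    extrapolation: str = "quadratic"


def simex_egger(data: HarmonizedSet, lambdas=None, n_sim: int = 200,
                seed: int = 1, extrapolate: bool = True) -> IGXResult:
    """Simulation-extrapolation correction of the Egger slope for exposure
    measurement error.

    For each λ in the grid, n_sim replicates add N(0, λσXj²) noise to the
    exposure betas, the Egger fit is repeated and averaged; a quadratic in λ
    is then extrapolated to λ = -1 (the no-measurement-error limit).
    """
    model = MRModel(data)
    slope, _ = model.fit_egger()
    if lambdas is None:
        lambdas = np.arange(0.0, 2.0 + 1e-9, 0.25)
    lambdas = np.asarray(lambdas, float)
    if not extrapolate:
        return IGXResult(i2_gx(data, weighted=False), i2_gx(data, weighted=True),
                         slope.estimate, slope.se, _eg_intercept(model),
                         slope.estimate, slope.se, lambdas, n_sim,
                         extrapolation="none")
    if len(lambdas) < 2:
        raise ValueError("SIMEX needs >= 2 lambda values to extrapolate")
    rng = np.random.default_rng(seed)
    mean_slope, mean_inter, mean_se = [], [], []
    for lam in lambdas:
        if lam == 0:
            mean_slope.append(slope.estimate)
            mean_inter.append(_eg_intercept(model))
            mean_se.append(slope.se)
            continue
        s_acc, i_acc, se_acc = np.empty(n_sim), np.empty(n_sim), np.empty(n_sim)
        for b in range(n_sim):
            bx_b = model.bx + rng.normal(0.0, np.sqrt(lam) * model.sx)
            m = MRModel.from_arrays(bx_b, model.sx, model.by, model.sy)
            s, i_ = m.fit_egger()
            s_acc[b], i_acc[b], se_acc[b] = s.estimate, i_.estimate, s.se
        mean_slope.append(s_acc.mean())
        mean_inter.append(i_acc.mean())
        mean_se.append(se_acc.mean())
    deg = min(2, len(lambdas) - 1)
    slope_fit = np.polyfit(lambdas, mean_slope, deg)
    inter_fit = np.polyfit(lambdas, mean_inter, deg)
    se_fit = np.polyfit(lambdas, mean_se, deg)
    return IGXResult(
        i2gx_unweighted=i2_gx(data, weighted=False),
        i2gx_weighted=i2_gx(data, weighted=True),
        simex_slope=float(np.polyval(slope_fit, -1.0)),
        simex_se=float(np.polyval(se_fit, -1.0)),
        simex_intercept=float(np.polyval(inter_fit, -1.0)),
        raw_slope=slope.estimate, raw_se=slope.se,
        lambdas=lambdas, n_sim=n_sim)


def _eg_intercept(model: MRModel) -> float:
    return model.fit_egger()[1].estimate


# ---------------------------------------------------------------------------
# split-sample MR (sample-overlap control)
# ---------------------------------------------------------------------------

def split_sample_mr(sample_a: tuple[SummaryStats, SummaryStats],
                    sample_b: tuple[SummaryStats, SummaryStats],
                    palindrome_maf: float = 0.3,
                    weighting: str = "auto") -> MRResults:
    """Cross-half MR: exposure betas from one half against outcome betas
    from the other, both ways, pooled by fixed-effects meta-analysis.

    ``sample_a`` and ``sample_b`` are (exposure GWAS, outcome GWAS) pairs
    computed on disjoint halves; the two cross pairings remove within-sample
    overlap between the exposure and outcome GWAS.
    """
    exp_a, out_a = sample_a
    exp_b, out_b = sample_b
    res_ab = MRModel(harmonize(exp_a, out_b, palindrome_maf)).fit_ivw(weighting=weighting)
    res_ba = MRModel(harmonize(exp_b, out_a, palindrome_maf)).fit_ivw(weighting=weighting)
    pooled = fixed_effect_meta([res_ab.estimate, res_ba.estimate],
                               [res_ab.se, res_ba.se],
                               exposure_name=exp_a.trait_name,
                               outcome_name=out_a.trait_name,
                               outcome_binary=(out_a.trait_type == "binary_logodds"))
    pooled.extra["half_ab"] = res_ab.estimate
    pooled.extra["half_ba"] = res_ba.estimate
    pooled.n_snp = res_ab.n_snp
    return pooled
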