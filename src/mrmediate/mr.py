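"""Univariable two-sample MR estimators.

The interface follows the statsmodels pattern: :class:`MRModel` is built from
a :class:`~mrmediate.sumstats.HarmonizedSet` and ``fit(method=...)`` returns
an :class:`MRResults` carrying the causal estimate, its uncertainty,
heterogeneity diagnostics and a ``summary()`` table. ``fit_all()`` produces
the full sensitivity panel (IVW, MR-Egger slope/intercept, weighted median,
weighted mode, with a Wald-ratio fallback for single-SNP instruments).

Estimator conventions
---------------------
* IVW is the zero-intercept weighted regression of outcome betas on exposure
  betas with weights 1/se_outcome²; exposure betas are oriented positive
  first (the estimate is invariant to this).
* Cochran's Q is computed about the fitted slope; I² = 100·max(0, (Q-df)/Q).
* Egger keeps a free intercept (average directional pleiotropy) and reports
  t-based p-values on L-2 degrees of freedom; both Egger and the
  multiplicative-random-effects IVW scale their standard errors by an
  overdispersion factor bounded below at 1.
* The weighted median interpolates the inverse-variance-weighted empirical
  CDF of per-SNP Wald ratios at probability 0.5; the weighted mode maximises
  a Gaussian-kernel density of the ratios with a modified Silverman
  bandwidth. Both get parametric-bootstrap standard errors (seeded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MRResults:
    """One method's causal estimate with diagnostics.

    ``estimate`` is on the outcome scale per unit of exposure (log-odds per
    category/SD when the outcome is binary). ``odds_ratio`` fields are
    populated only for binary outcomes.
    """

    method: str
    estimate: float
    se: float
    n_snp: int
    pval: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    Q: float = np.nan
    Q_df: float = np.nan
    Q_pval: float = np.nan
    I2: float = np.nan
    outcome_binary: bool = False
    exposure_name: str = ""
    outcome_name: str = ""
    unit: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isnan(self.ci_low):
            self.ci_low = self.estimate - Z95 * self.se
            self.ci_high = self.estimate + Z95 * self.se
        if np.isnan(self.pval) and self.se > 0:
            self.pval = 2 * stats.norm.sf(abs(self.estimate) / self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate)) if self.outcome_binary else np.nan

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low)) if self.outcome_binary else np.nan

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high)) if self.outcome_binary else np.nan

    def ci_excludes_null(self) -> bool:
        return bool(self.ci_low > 0 or self.ci_high < 0)

    def to_dict(self) -> dict:
        d = {
            "method": self.method, "exposure": self.exposure_name,
            "outcome": self.outcome_name, "estimate": self.estimate,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval, "n_snp": self.n_snp, "Q": self.Q,
            "Q_df": self.Q_df, "Q_pval": self.Q_pval, "I2": self.I2,
        }
        if self.outcome_binary:
            d.update(odds_ratio=self.odds_ratio, or_ci_low=self.or_ci_low,
                     or_ci_high=self.or_ci_high)
        d.update(self.extra)
        return d

    def summary(self) -> str:
        lines = [
            f"MR results: {self.exposure_name} -> {self.outcome_name} [{self.method}]",
            f"  n_snp      {self.n_snp}",
            f"  estimate   {self.estimate:+.4f}  ({self.unit})" if self.unit
            else f"  estimate   {self.estimate:+.4f}",
            f"  se         {self.se:.4f}",
            f"  95% CI     ({self.ci_low:+.4f}, {self.ci_high:+.4f})",
            f"  p-value    {self.pval:.3g}",
        ]
        if self.outcome_binary:
            lines.append(f"  OR (95% CI) {self.odds_ratio:.3f} "
                         f"({self.or_ci_low:.3f}, {self.or_ci_high:.3f})")
        if np.isfinite(self.Q):
            lines.append(f"  Q = {self.Q:.2f} on {self.Q_df:.0f} df "
                         f"(p = {self.Q_pval:.3g}); I2 = {self.I2:.1f}%")
        for k, v in self.extra.items():
            lines.append(f"  {k} = {v:.4g}" if isinstance(v, float) else f"  {k} = {v}")
        return "\n".join(lines)


def _i2(Q: float, df: float) -> float:
    if Q <= 0:
        return 0.0
    return 100.0 * max(0.0, (Q - df) / Q)


def cochran_q(bx, by, sy, beta_hat: float):
    """Cochran heterogeneity about a causal slope.

    Q = Σ wj (βYj - β̂·βXj)² with wj = 1/σYj²; df = L-1; p from the χ²
    upper tail; I² = 100·max(0, (Q-df)/Q).
    """
    bx, by, sy = (np.asarray(v, float) for v in (bx, by, sy))
    w = 1.0 / sy**2
    Q = float(np.sum(w * (by - beta_hat * bx) ** 2))
    df = len(bx) - 1
    pval = float(stats.chi2.sf(Q, df)) if df > 0 else np.nan
    return Q, df, pval, _i2(Q, df)


def i2_from_q(Q: float, df: float) -> float:
    """Higgins I² (percent) from a heterogeneity statistic and its df."""
    return _i2(Q, df)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MRResults:
    """Single-SNP causal estimate βY/βX with first-order delta-method se."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined: exposure beta is 0")
    est = by / bx
    se = sy / abs(bx)
    return MRResults(method="wald", estimate=float(est), se=float(se), n_snp=1)


class MRModel:
    """Two-sample univariable MR model over a harmonized SNP set."""

    def __init__(self, data: HarmonizedSet):
        self.data = data
        ids, bx, sx, by, sy = data.arrays()
        if len(bx) == 0:
            raise InsufficientInstrumentsError("no kept SNPs")
        # orientation convention: exposure effects positive
        sign = np.where(bx < 0, -1.0, 1.0)
        self.variant_ids = ids
        self.bx, self.sx = bx * sign, sx
        self.by, self.sy = by * sign, sy
        self.L = len(bx)

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_arrays(cls, bx, sx, by, sy, variant_ids=None,
                    outcome_binary: bool = False, **meta) -> "MRModel":
        bx = np.asarray(bx, float)
        n = len(bx)
        if variant_ids is None:
            variant_ids = [f"snp{i+1}" for i in range(n)]
        tab = pd.DataFrame({
            "variant_id": variant_ids,
            "beta_exposure": bx, "se_exposure": np.asarray(sx, float),
            "eaf_exposure": np.nan,
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(sy, float), "eaf_outcome": np.nan,
            "exclusion_flag": "kept",
        })
        hs = HarmonizedSet(tab,
                           outcome_type="binary_logodds" if outcome_binary else "continuous_sd",
                           **meta)
        return cls(hs)

    def _meta(self) -> dict:
        d = self.data
        return dict(outcome_binary=(d.outcome_type == "binary_logodds"),
                    exposure_name=d.exposure_name, outcome_name=d.outcome_name,
                    unit=f"outcome per {d.exposure_type.split('_')[-1]} unit of exposure")

    # -- estimators --------------------------------------------------------
    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        if method in ("ivw", "ivw_fixed", "ivw_mre"):
            if method != "ivw":
                kwargs.setdefault(
                    "weighting",
                    "fixed" if method == "ivw_fixed" else "multiplicative_random_effects")
            return self.fit_ivw(**kwargs)
        if method == "wald":
            return self.fit_wald(**kwargs)
        if method == "egger":
            return self.fit_egger(**kwargs)[0]
        if method == "weighted_median":
            return self.fit_weighted_median(**kwargs)
        if method == "weighted_mode":
            return self.fit_weighted_mode(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    def fit_wald(self) -> MRResults:
        if self.L != 1:
            raise InsufficientInstrumentsError("wald applies to a single SNP")
        res = wald_ratio(self.bx[0], self.sx[0], self.by[0], self.sy[0])
        return MRResults(**{**res.__dict__, **self._meta()})

    def fit_ivw(self, weighting: str = "auto") -> MRResults:
        """Inverse-variance-weighted estimate.

        ``weighting``: "fixed", "multiplicative_random_effects", or "auto"
        (random effects when L > 3 and Q/df > 1, else fixed). A single SNP
        falls back to the Wald ratio.
        """
        if self.L < 2:
            res = self.fit_wald()
            res.extra["note"] = "single SNP: Wald ratio substituted for IVW"
            return res
        w = 1.0 / self.sy**2
        sxx = float(np.sum(w * self.bx**2))
        est = float(np.sum(w * self.bx * self.by)) / sxx
        se_fixed = sxx ** -0.5
        Q, df, Qp, I2 = cochran_q(self.bx, self.by, self.sy, est)
        overdisp = max(1.0, np.sqrt(Q / df)) if df > 0 else 1.0
        if weighting == "auto":
            use_mre = self.L > 3 and Q / df > 1
        elif weighting == "multiplicative_random_effects":
            use_mre = True
        elif weighting == "fixed":
            use_mre = False
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        se = se_fixed * overdisp if use_mre else se_fixed
        method = "ivw_mre" if use_mre else "ivw_fixed"
        return MRResults(method=method, estimate=est, se=float(se), n_snp=self.L,
                         Q=Q, Q_df=df, Q_pval=Qp, I2=I2, **self._meta())

    def cochran_q(self, beta_hat: float | None = None):
        if beta_hat is None:
            beta_hat = self.fit_ivw(weighting="fixed").estimate
        return cochran_q(self.bx, self.by, self.sy, beta_hat)

    def fit_egger(self):
        """MR-Egger: weighted regression of βY on βX with a free intercept.

        Returns ``(slope_results, intercept_results)``. The intercept
        estimates average directional pleiotropy; Rücker's Q' is reported on
        L-2 df; p-values use the t distribution on L-2 df.
        """
        if self.L < 3:
            raise InsufficientInstrumentsError("MR-Egger requires >= 3 SNPs")
        w = 1.0 / self.sy**2
        X = np.column_stack([np.ones(self.L), self.bx])
        WX = X * w[:, None]
        xtx = X.T @ WX
        coef = np.linalg.solve(xtx, WX.T @ self.by)
        resid = self.by - X @ coef
        Qp_stat = float(np.sum(w * resid**2))
        df = self.L - 2
        overdisp2 = max(1.0, Qp_stat / df)
        cov = np.linalg.inv(xtx) * overdisp2
        inter, slope = coef
        se_i, se_s = np.sqrt(np.diag(cov))
        Qp_pval = float(stats.chi2.sf(Qp_stat, df))
        I2 = _i2(Qp_stat, df)
        tcrit = stats.t.ppf(0.975, df)
        meta = self._meta()

        def _res(method, est, se):
            return MRResults(
                method=method, estimate=float(est), se=float(se), n_snp=self.L,
                pval=float(2 * stats.t.sf(abs(est) / se, df)),
                ci_low=float(est - tcrit * se), ci_high=float(est + tcrit * se),
                Q=Qp_stat, Q_df=df, Q_pval=Qp_pval, I2=I2, **meta)

        slope_res = _res("egger_slope", slope, se_s)
        inter_res = _res("egger_intercept", inter, se_i)
        inter_res.outcome_binary = False  # the intercept is not an OR
        return slope_res, inter_res

    # -- ratio-based robust estimators -------------------------------------
    def _ratios(self):
        return self.by / self.bx

    def _ratio_weights(self) -> np.ndarray:
        """Inverse-variance weights of the per-SNP Wald ratios (first-order):
        1/var(ratio) = βX²/σY²."""
        return self.bx**2 / self.sy**2

    @staticmethod
    def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
        order = np.argsort(ratios)
        r = ratios[order]
        w = weights[order] / weights.sum()
        cum = np.cumsum(w) - 0.5 * w
        return float(np.interp(0.5, cum, r))

    def fit_weighted_median(self, n_boot: int = 1000, seed: int | None = None) -> MRResults:
        """Weighted-median estimate: consistent when >= 50% of the weight
        comes from valid instruments. Bootstrap se (parametric, seeded)."""
        if self.L < 3:
            raise InsufficientInstrumentsError("weighted median requires >= 3 SNPs")
        est = self._weighted_median(self._ratios(), self._ratio_weights())
        se = self._bootstrap_se(self._median_stat, n_boot, seed)
        return MRResults(method="weighted_median", estimate=est, se=se,
                         n_snp=self.L, **self._meta())

    def _median_stat(self, bx, by):
        return self._weighted_median(by / bx, bx**2 / self.sy**2)

    @staticmethod
    def mode_bandwidth(ratios: np.ndarray, phi: float = 1.0) -> float:
        """Modified Silverman rule on the ratio sample:
        h = phi * 0.9 * s * n^(-1/5) with s the smallest positive of the
        sample sd, the normal-consistent MAD and IQR/1.349 (robust spread
        measures keep the bandwidth tight when a minority of ratios are
        outlying). A small floor avoids a degenerate zero bandwidth when all
        ratios coincide."""
        n = len(ratios)
        sd = np.std(ratios, ddof=1)
        mad = stats.median_abs_deviation(ratios, scale="normal")
        iqr = np.subtract(*np.percentile(ratios, [75, 25])) / 1.349
        positive = [v for v in (sd, mad, iqr) if v > 0]
        s = min(positive) if positive else 0.0
        h = phi * 0.9 * s * n ** (-0.2)
        if h <= 0:
            h = 1e-12
        return float(h)

    @staticmethod
    def _mode_estimate(ratios, weights, h):
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
        dens = np.sum(weights[:, None]
                      * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
                      axis=0)
        return float(grid[np.argmax(dens)])

    def fit_weighted_mode(self, phi: float = 1.0, n_boot: int = 1000,
                          seed: int | None = None) -> MRResults:
        """Weighted-mode estimate: the maximiser of an inverse-variance-
        weighted Gaussian kernel density over per-SNP ratios (plurality-valid
        assumption). Bandwidth = phi x modified Silverman; bootstrap se."""
        if self.L < 3:
            raise InsufficientInstrumentsError("weighted mode requires >= 3 SNPs")
        ratios = self._ratios()
        weights = self._ratio_weights()
        h = self.mode_bandwidth(ratios, phi)
        est = self._mode_estimate(ratios, weights, h)
        se = self._bootstrap_se(lambda bx, by: self._mode_stat(bx, by, phi),
                                n_boot, seed)
        res = MRResults(method="weighted_mode", estimate=est, se=se,
                        n_snp=self.L, **self._meta())
        res.extra["bandwidth"] = h
        return res

    def _mode_stat(self, bx, by, phi):
        ratios = by / bx
        return self._mode_estimate(ratios, bx**2 / self.sy**2,
                                   self.mode_bandwidth(ratios, phi))

    def _bootstrap_se(self, statistic, n_boot: int, seed: int | None) -> float:
        if n_boot <= 0:
            return np.nan
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            bx = rng.normal(self.bx, self.sx) if np.all(np.isfinite(self.sx)) \
                else self.bx
            by = rng.normal(self.by, self.sy)
            draws[b] = statistic(bx, by)
        return float(np.std(draws, ddof=1))

    # -- panel --------------------------------------------------------------
    def fit_all(self, n_boot: int = 1000, seed: int = 1, phi: float = 1.0,
                weighting: str = "auto") -> dict[str, MRResults]:
        """Full estimator panel; degrades gracefully for small L."""
        out: dict[str, MRResults] = {}
        if self.L == 1:
            out["wald"] = self.fit_wald()
            return out
        out["ivw"] = self.fit_ivw(weighting=weighting)
        if self.L >= 3:
            slope, inter = self.fit_egger()
            out["egger_slope"] = slope
            out["egger_intercept"] = inter
            out["weighted_median"] = self.fit_weighted_median(n_boot=n_boot, seed=seed)
            out["weighted_mode"] = self.fit_weighted_mode(phi=phi, n_boot=n_boot,
                                                          seed=seed + 1)
        return out

    def scatter_data(self) -> pd.DataFrame:
        """Per-SNP (βX, βY, σX, σY) on the oriented scale for scatter plots."""
        return pd.DataFrame({"variant_id": self.variant_ids,
                             "beta_exposure": self.bx, "se_exposure": self.sx,
                             "beta_outcome": self.by, "se_outcome": self.sy})


def fixed_effect_meta(estimates, ses, **meta) -> MRResults:
    """Inverse-variance fixed-effects pooling of independent estimates."""
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if est.shape != se.shape:
        raise ValueError("estimates and ses must have equal length")
    if np.any(se <= 0):
        raise ValueError("ses must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    return MRResults(method="meta_fixed", estimate=pooled, se=pooled_se,
                     n_snp=len(est), **meta)


def subtype_heterogeneity(results: list[MRResults]):
    """Meta-analytic heterogeneity across causal estimates (e.g. disease
    subtypes): Q about the pooled fixed-effects mean, weights 1/se²."""
    if len(results) < 2:
        raise ValueError("need >= 2 results")
    est = np.array([r.estimate for r in results])
    se = np.array([r.se for r in results])
    w = 1.0 / se**2
    mu = np.sum(w * est) / np.sum(w)
    Q = float(np.sum(w * (est - mu) ** 2))
    df = len(results) - 1
    return Q, df, float(stats.chi2.sf(Q, df)), _i2(Q, df)
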