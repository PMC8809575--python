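"""Multivariable MR: joint direct effects of several exposures on one outcome.

:class:`MVMRModel` regresses outcome betas on the matrix of exposure betas
(no intercept, weights 1/se_outcome²). ``fit()`` gives the IVW direct
effects; ``conditional_f()`` quantifies each exposure's instrument strength
given the others; ``fit_qhet()`` re-estimates the direct effects by
minimising a heterogeneity statistic whose weights account for uncertainty
in the exposure betas (robust to weak instruments; flagged experimental).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mr import Z95
from .sumstats import HarmonizedSet

logger = logging.getLogger(__name__)

COND_WARN_THRESHOLD = 1e6


class IdentifiabilityError(ValueError):
    pass


@dataclass
class MVMRResults:
    """Direct-effect estimates for K exposures from L instruments."""

    exposures: list
    estimates: np.ndarray
    ses: np.ndarray
    method: str
    n_snp: int
    Q_A: float
    Q_df: int
    Q_pval: float
    conditional_F: np.ndarray | None = None
    outcome_binary: bool = False
    outcome_name: str = "outcome"
    experimental: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> np.ndarray:
        return self.estimates - Z95 * self.ses

    @property
    def ci_high(self) -> np.ndarray:
        return self.estimates + Z95 * self.ses

    @property
    def pvals(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.estimates) / self.ses)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "exposure": self.exposures, "estimate": self.estimates,
            "se": self.ses, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pvals,
        })
        if self.outcome_binary:
            df["odds_ratio"] = np.exp(df["estimate"])
            df["or_ci_low"] = np.exp(df["ci_low"])
            df["or_ci_high"] = np.exp(df["ci_high"])
        if self.conditional_F is not None:
            df["conditional_F"] = self.conditional_F
        return df

    def summary(self) -> str:
        head = (f"Multivariable MR [{self.method}] on {self.outcome_name}: "
                f"L={self.n_snp} SNPs, K={len(self.exposures)} exposures")
        if self.experimental:
            head += "  (experimental)"
        body = self.to_frame().to_string(index=False, float_format=lambda v: f"{v: .4f}")
        tail = (f"Q_A = {self.Q_A:.2f} on {self.Q_df} df (p = {self.Q_pval:.3g})")
        return "\n".join([head, body, tail])


class MVMRModel:
    """Multivariable MR model over a harmonized set with K >= 1 exposures."""

    def __init__(self, data: HarmonizedSet, phenotypic_cov: np.ndarray | None = None):
        self.data = data
        self.exposures = list(data.exposure_names)
        self.K = len(self.exposures)
        self.X = data.exposure_beta_matrix()          # (L, K)
        self.SX = data.exposure_se_matrix()
        kept = data.kept()
        self.y = kept["beta_outcome"].to_numpy(dtype=float)
        self.sy = kept["se_outcome"].to_numpy(dtype=float)
        self.variant_ids = kept["variant_id"].to_numpy()
        self.L = len(self.y)
        if self.L <= self.K:
            raise IdentifiabilityError(
                f"need more SNPs ({self.L}) than exposures ({self.K})")
        if phenotypic_cov is None:
            phenotypic_cov = np.zeros((self.K, self.K))
        self.phenotypic_cov = np.asarray(phenotypic_cov, dtype=float)

    @classmethod
    def from_arrays(cls, X, SX, y, sy, exposures=None,
                    outcome_binary: bool = False, **kw) -> "MVMRModel":
        X = np.asarray(X, float)
        SX = np.asarray(SX, float)
        L, K = X.shape
        if exposures is None:
            exposures = [f"exposure_{k+1}" for k in range(K)]
        cols = {"variant_id": [f"snp{i+1}" for i in range(L)],
                "beta_exposure": X[:, 0], "se_exposure": SX[:, 0],
                "eaf_exposure": np.nan,
                "beta_outcome": np.asarray(y, float),
                "se_outcome": np.asarray(sy, float), "eaf_outcome": np.nan,
                "exclusion_flag": "kept"}
        for k in range(1, K):
            cols[f"beta_exposure_{k+1}"] = X[:, k]
            cols[f"se_exposure_{k+1}"] = SX[:, k]
        hs = HarmonizedSet(pd.DataFrame(cols), exposure_names=list(exposures),
                           outcome_type="binary_logodds" if outcome_binary
                           else "continuous_sd")
        return cls(hs, **kw)

    def _meta(self) -> dict:
        return dict(outcome_binary=(self.data.outcome_type == "binary_logodds"),
                    outcome_name=self.data.outcome_name)

    # -- IVW ---------------------------------------------------------------
    def fit(self, method: str = "ivw", **kw) -> MVMRResults:
        if method == "ivw":
            return self.fit_ivw(**kw)
        if method == "qhet":
            return self.fit_qhet(**kw)
        raise ValueError(f"unknown method {method!r}")

    def fit_ivw(self, conditional_f: bool = True) -> MVMRResults:
        """Weighted multivariable regression of βY on (βX1..βXK), no
        intercept, weights 1/σY²; SEs carry a multiplicative overdispersion
        factor bounded below at 1; Q_A is the weighted residual sum of
        squares on L-K df."""
        w = 1.0 / self.sy**2
        Xw = self.X * np.sqrt(w)[:, None]
        yw = self.y * np.sqrt(w)
        xtx = Xw.T @ Xw
        cond = np.linalg.cond(xtx)
        if cond > COND_WARN_THRESHOLD:
            warnings.warn(f"exposure betas nearly collinear (cond={cond:.3g}); "
                          "direct effects are unstable", RuntimeWarning,
                          stacklevel=2)
        theta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        resid = self.y - self.X @ theta
        Q_A = float(np.sum(w * resid**2))
        df = self.L - self.K
        phi = max(1.0, Q_A / df) if df > 0 else 1.0
        cov = np.linalg.pinv(xtx) * phi
        ses = np.sqrt(np.diag(cov))
        res = MVMRResults(
            exposures=self.exposures, estimates=theta, ses=ses, method="mvivw",
            n_snp=self.L, Q_A=Q_A, Q_df=df,
            Q_pval=float(stats.chi2.sf(Q_A, df)), **self._meta())
        if conditional_f and self.K >= 2:
            res.conditional_F = self.conditional_f()
        return res

    # -- conditional instrument strength ------------------------------------
    def conditional_f(self, n_iter: int = 2) -> np.ndarray:
        """Sanderson-Windmeijer-style conditional F per exposure.

        Exposure k's betas are regressed on the other exposures' betas; the
        residual heterogeneity Q_xk (with weights combining the exposure-beta
        variances and the supplied cross-trait covariance, re-estimated over
        ``n_iter`` passes) divided by L-K+1 gives the conditional F.
        """
        if self.K < 2:
            raise IdentifiabilityError("conditional F needs >= 2 exposures")
        out = np.empty(self.K)
        for k in range(self.K):
            others = [j for j in range(self.K) if j != k]
            xk = self.X[:, k]
            Z = self.X[:, others]
            sxk = self.SX[:, k]
            SZ = self.SX[:, others]
            w = 1.0 / sxk**2
            delta = np.zeros(len(others))
            for _ in range(n_iter):
                Zw = Z * np.sqrt(w)[:, None]
                delta = np.linalg.lstsq(Zw, xk * np.sqrt(w), rcond=None)[0]
                var = sxk**2 + (SZ**2 @ delta**2)
                for i, j in enumerate(others):
                    rho = self.phenotypic_cov[k, j]
                    var -= 2 * delta[i] * rho * sxk * SZ[:, i]
                var = np.maximum(var, 1e-12)
                w = 1.0 / var
            Q_xk = float(np.sum(w * (xk - Z @ delta) ** 2))
            out[k] = Q_xk / (self.L - self.K + 1)
        return out

    # -- Q-minimisation estimator -------------------------------------------
    def _qstat(self, theta: np.ndarray) -> float:
        num = self.y - self.X @ theta
        den = self.sy**2 + (self.SX**2 @ theta**2)
        return float(np.sum(num**2 / den))

    def _minimise_q(self, start: np.ndarray, n_starts: int, rng,
                    tol: float = 1e-8):
        best = None
        for s in range(n_starts):
            x0 = start if s == 0 else start + rng.normal(0, 0.25, size=self.K)
            res = optimize.minimize(self._qstat, x0, method="L-BFGS-B",
                                    options={"ftol": tol, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError(f"qhet optimiser failed: {best}")
        return best

    def fit_qhet(self, n_boot: int = 200, seed: int = 1,
                 n_starts: int = 5) -> MVMRResults:
        """Direct effects by minimising the heterogeneity statistic

            Q_A(θ) = Σj (βYj - Σk θk βXkj)² / (σYj² + Σk θk² σXkj²),

        whose weights propagate exposure-beta uncertainty (weak-instrument
        robust). CIs come from a seeded parametric bootstrap.
        """
        rng = np.random.default_rng(seed)
        start = self.fit_ivw(conditional_f=False).estimates
        best = self._minimise_q(start, n_starts, rng)
        theta = best.x
        boots = np.empty((n_boot, self.K))
        for b in range(n_boot):
            Xb = self.X + rng.normal(size=self.X.shape) * self.SX
            yb = self.y + rng.normal(size=self.L) * self.sy
            mb = MVMRModel.from_arrays(Xb, self.SX, yb, self.sy, self.exposures)
            boots[b] = mb._minimise_q(theta, 1, rng).x
        ses = boots.std(axis=0, ddof=1) if n_boot > 1 else np.full(self.K, np.nan)
        df = self.L - self.K
        res = MVMRResults(
            exposures=self.exposures, estimates=theta, ses=ses, method="qhet",
            n_snp=self.L, Q_A=float(best.fun), Q_df=df,
            Q_pval=float(stats.chi2.sf(best.fun, df)), experimental=True,
            **self._meta())
        res.extra["n_boot"] = n_boot
        res.extra["seed"] = seed
        return res
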