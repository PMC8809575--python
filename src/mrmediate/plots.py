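"""Minimal scatter and forest plots for MR results.

These render the two figures practitioners actually look at: the per-SNP
effect scatter with fitted method lines (consistency across estimators) and
the forest plot of estimates with 95% CIs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mr import MRModel, MRResults


def scatter_plot(model: MRModel, results: dict[str, MRResults] | None = None,
                 ax=None):
    """Per-SNP βX vs βY with +-1 SE error bars and one fitted line per
    method (zero intercept except MR-Egger)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(model.bx, model.by, xerr=model.sx, yerr=model.sy,
                fmt="o", ms=3, lw=0.6, color="0.4", ecolor="0.75", zorder=1)
    xs = np.array([0, model.bx.max() * 1.05])
    for name, res in (results or {}).items():
        if name == "egger_intercept":
            continue
        intercept = 0.0
        if name == "egger_slope" and results and "egger_intercept" in results:
            intercept = results["egger_intercept"].estimate
        ax.plot(xs, intercept + res.estimate * xs, label=name, lw=1.2)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    if results:
        ax.legend(fontsize=7)
    return ax


def forest_plot(results: list[MRResults], labels: list[str] | None = None,
                exponentiate: bool = False, ax=None):
    """Estimates with 95% CIs, one row per result; ``exponentiate`` shows
    odds ratios for binary outcomes (null line at 1 instead of 0)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.5 * len(results) + 1))
    labels = labels or [f"{r.exposure_name}->{r.outcome_name} [{r.method}]"
                        for r in results]
    ys = np.arange(len(results))[::-1]
    for y, r in zip(ys, results):
        est, lo, hi = r.estimate, r.ci_low, r.ci_high
        if exponentiate:
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        ax.plot([lo, hi], [y, y], color="0.3", lw=1.2)
        ax.plot(est, y, "s", color="C0", ms=5)
    ax.axvline(1.0 if exponentiate else 0.0, color="k", lw=0.7, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("odds ratio (95% CI)" if exponentiate else "estimate (95% CI)")
    return ax
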