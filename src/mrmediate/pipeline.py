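"""Study orchestration: univariable, bidirectional and multivariable MR with
the four-criterion mediator/confounder screen, and report rendering.

The study design has four steps: (1) univariable MR of the exposure on the
disease outcome; (2) univariable MR of each candidate mediator on the
outcome; (3) bidirectional MR between the exposure and each mediator with
Steiger filtering; (4) multivariable MR of the exposure plus screened
mediators for direct effects. A candidate counts as a mediator when
(i) exposure→outcome, (ii) exposure→mediator and (iii) mediator→outcome all
show evidence of effect and (iv) there is no strong reverse mediator→exposure
effect; with criteria i-iii met but a strong reverse effect it can both
confound and mediate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mr import MRModel, MRResults, fixed_effect_meta
from .mvmr import MVMRModel, MVMRResults
from .sensitivity import (RadialResult, SteigerResult, i2_gx, leave_one_out,
                          radial_ivw, simex_egger, split_sample_mr,
                          steiger_filter)
from .sumstats import (EmptyInstrumentError, HarmonizedSet, SummaryStats,
                       harmonize, instrument_strength, select_instruments)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# univariable panel
# ---------------------------------------------------------------------------

@dataclass
class UnivariablePanel:
    """Full estimator + sensitivity panel for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    results: dict = field(default_factory=dict)       # method -> MRResults
    hset: HarmonizedSet | None = None
    radial: RadialResult | None = None
    loo: list | None = None
    strength: object | None = None
    i2gx_weighted: float = np.nan
    i2gx_unweighted: float = np.nan
    simex: object | None = None
    skipped: bool = False
    skip_reason: str = ""

    @property
    def primary(self) -> MRResults | None:
        """Headline estimate: IVW, or the Wald ratio for 1-SNP instruments."""
        for key in ("ivw", "wald"):
            if key in self.results:
                return self.results[key]
        return None

    def to_frame(self) -> pd.DataFrame:
        if self.skipped:
            return pd.DataFrame([{"exposure": self.exposure_name,
                                  "outcome": self.outcome_name,
                                  "method": "skipped", "note": self.skip_reason}])
        return pd.DataFrame([r.to_dict() for r in self.results.values()])


def run_univariable(exposure: SummaryStats, outcome: SummaryStats,
                    instrument_ids=None, palindrome_maf: float = 0.3,
                    weighting: str = "auto", n_boot: int = 1000, seed: int = 1,
                    sensitivity: bool = True, run_simex: bool = False) -> UnivariablePanel:
    """One exposure-outcome pair: estimator panel plus sensitivity block.

    With a single surviving instrument the Wald ratio is substituted and the
    sensitivity block is left empty. An empty harmonized set yields a
    ``skipped`` panel rather than an exception, so multi-pair runs continue.
    """
    panel = UnivariablePanel(exposure.trait_name, outcome.trait_name)
    try:
        if instrument_ids is not None:
            exposure = select_instruments(exposure, mode="external_list",
                                          external_ids=instrument_ids)
        hset = harmonize(exposure, outcome, palindrome_maf)
    except EmptyInstrumentError as exc:
        panel.skipped, panel.skip_reason = True, str(exc)
        logger.warning("univariable %s->%s skipped: %s", exposure.trait_name,
                       outcome.trait_name, exc)
        return panel
    panel.hset = hset
    model = MRModel(hset)
    panel.results = model.fit_all(n_boot=n_boot, seed=seed, weighting=weighting)
    panel.strength = instrument_strength(exposure)
    if sensitivity and model.L >= 2:
        panel.radial = radial_ivw(hset)
        panel.i2gx_weighted = i2_gx(hset, weighted=True)
        panel.i2gx_unweighted = i2_gx(hset, weighted=False)
        if model.L >= 3:
            panel.loo = leave_one_out(hset, weighting=weighting)
            if run_simex:
                panel.simex = simex_egger(hset, seed=seed)
    return panel


# ---------------------------------------------------------------------------
# bidirectional MR
# ---------------------------------------------------------------------------

@dataclass
class BidirectionalResult:
    forward: MRResults | None
    reverse: MRResults | None
    steiger_forward: SteigerResult | None = None
    steiger_reverse: SteigerResult | None = None
    split_forward: MRResults | None = None


def run_bidirectional(forward_exposure: SummaryStats, forward_outcome: SummaryStats,
                      reverse_exposure: SummaryStats, reverse_outcome: SummaryStats,
                      instruments_forward=None, instruments_reverse=None,
                      palindrome_maf: float = 0.3, weighting: str = "auto",
                      steiger_mode: str = "direction_only",
                      split_halves: dict | None = None) -> BidirectionalResult:
    """Both causal directions between two traits, Steiger-filtered.

    The A→B direction uses A's instruments with A-effects from one sample and
    B-effects from the other; B→A is symmetric. ``split_halves`` (mapping
    with exposure_a/mediator_a/exposure_b/mediator_b tables from disjoint
    half-samples) additionally runs the forward split-sample analysis.
    """

    def _one_direction(exp, out, ids):
        try:
            if ids is not None:
                exp = select_instruments(exp, mode="external_list", external_ids=ids)
            hset = harmonize(exp, out, palindrome_maf)
            st, filtered = steiger_filter(hset, mode=steiger_mode)
            res = MRModel(filtered).fit_ivw(weighting=weighting)
            return res, st
        except (EmptyInstrumentError, ValueError) as exc:
            logger.warning("bidirectional direction skipped: %s", exc)
            return None, None

    fwd, st_f = _one_direction(forward_exposure, forward_outcome, instruments_forward)
    rev, st_r = _one_direction(reverse_exposure, reverse_outcome, instruments_reverse)
    split = None
    if split_halves is not None:
        split = split_sample_mr(
            (split_halves["exposure_a"], split_halves["mediator_a"]),
            (split_halves["exposure_b"], split_halves["mediator_b"]),
            palindrome_maf=palindrome_maf, weighting=weighting)
    return BidirectionalResult(forward=fwd, reverse=rev, steiger_forward=st_f,
                               steiger_reverse=st_r, split_forward=split)


# ---------------------------------------------------------------------------
# mediation screen
# ---------------------------------------------------------------------------

VERDICTS = ("candidate_mediator", "candidate_confounder_and_mediator", "excluded")


@dataclass
class MediationAssessment:
    """Four-criterion decision record for one candidate mediator."""

    mediator_name: str
    criterion_i: bool | None      # exposure -> outcome effect present
    criterion_ii: bool | None     # exposure -> mediator effect present
    criterion_iii: bool | None    # mediator -> outcome effect present
    criterion_iv: bool | None     # no strong reverse mediator -> exposure effect
    verdict: str
    evidence_rule: str
    results: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"mediator": self.mediator_name, "criterion_i": self.criterion_i,
                "criterion_ii": self.criterion_ii, "criterion_iii": self.criterion_iii,
                "criterion_iv": self.criterion_iv, "verdict": self.verdict,
                "evidence_rule": self.evidence_rule, "notes": list(self.notes)}


def _has_effect(res: MRResults | None, rule: str, p_threshold: float):
    if res is None:
        return None
    if rule == "ci_excludes_null":
        return res.ci_excludes_null()
    if rule == "p_threshold":
        return bool(res.pval < p_threshold)
    raise ValueError(f"unknown evidence rule {rule!r}")


def assess_mediation(mediator_name: str,
                     exposure_outcome: MRResults | None,
                     exposure_mediator: MRResults | None,
                     mediator_outcome: MRResults | None,
                     mediator_exposure: MRResults | None,
                     evidence_rule: str = "ci_excludes_null",
                     p_threshold: float = 0.05,
                     reverse_ratio: float = 0.5) -> MediationAssessment:
    """Apply the four mediation criteria to one candidate.

    Criterion iv ("no strong bidirectional effect") holds when the reverse
    mediator→exposure estimate shows no evidence of effect OR its magnitude
    is below ``reverse_ratio`` x the forward exposure→mediator magnitude;
    both components are recorded in the notes. A missing result marks its
    criterion indeterminate and excludes the candidate.
    """
    notes = []
    c1 = _has_effect(exposure_outcome, evidence_rule, p_threshold)
    c2 = _has_effect(exposure_mediator, evidence_rule, p_threshold)
    c3 = _has_effect(mediator_outcome, evidence_rule, p_threshold)
    if mediator_exposure is None or exposure_mediator is None:
        c4 = None
    else:
        rev_effect = _has_effect(mediator_exposure, evidence_rule, p_threshold)
        small = abs(mediator_exposure.estimate) < reverse_ratio * abs(exposure_mediator.estimate)
        c4 = (not rev_effect) or small
        notes.append(f"reverse effect evidence={rev_effect}, "
                     f"|reverse|<{reverse_ratio}x|forward|={small}")
    missing = [n for n, c in zip("i ii iii iv".split(), (c1, c2, c3, c4)) if c is None]
    if missing:
        notes.append(f"indeterminate criteria: {missing}")
        verdict = "excluded"
    elif c1 and c2 and c3 and c4:
        verdict = "candidate_mediator"
    elif c1 and c2 and c3 and not c4:
        verdict = "candidate_confounder_and_mediator"
    else:
        verdict = "excluded"
    return MediationAssessment(
        mediator_name=mediator_name, criterion_i=c1, criterion_ii=c2,
        criterion_iii=c3, criterion_iv=c4, verdict=verdict,
        evidence_rule=evidence_rule,
        results={"exposure_outcome": exposure_outcome,
                 "exposure_mediator": exposure_mediator,
                 "mediator_outcome": mediator_outcome,
                 "mediator_exposure": mediator_exposure},
        notes=notes)


# ---------------------------------------------------------------------------
# multivariable stage
# ---------------------------------------------------------------------------

@dataclass
class MVMRStage:
    mv_results: MVMRResults
    uv_results: dict                       # exposure name -> MRResults
    attenuation: pd.DataFrame              # uv vs mv per exposure
    qhet: MVMRResults | None = None


def run_mvmr_stage(exposure: SummaryStats, mediators: list[SummaryStats],
                   outcome: SummaryStats, instrument_ids=None,
                   third_exposure: SummaryStats | None = None,
                   palindrome_maf: float = 0.3, run_qhet: bool = False,
                   seed: int = 1) -> MVMRStage:
    """Direct effects of the exposure and screened mediator(s) on the outcome.

    Instruments are the union of the supplied id list over all exposures
    (default: every exposure-table SNP), re-harmonized jointly so each SNP
    carries aligned betas for all K exposures. The attenuation summary puts
    the univariable total effect beside the multivariable direct effect with
    their difference and ratio.
    """
    extra = list(mediators) + ([third_exposure] if third_exposure is not None else [])
    if not extra:
        raise ValueError("mvMR stage needs at least one screened mediator")
    exp = exposure
    if instrument_ids is not None:
        exp = select_instruments(exp, mode="external_list", external_ids=instrument_ids)
    hset = harmonize(exp, outcome, palindrome_maf, extra_exposures=extra)
    model = MVMRModel(hset)
    mv = model.fit_ivw()
    uv = {}
    for tab in [exposure] + extra:
        panel = run_univariable(tab, outcome, instrument_ids=instrument_ids
                                if tab is exposure else None,
                                sensitivity=False, n_boot=0, seed=seed)
        uv[tab.trait_name] = panel.primary
    rows = []
    for k, name in enumerate(mv.exposures):
        uv_res = uv.get(name)
        uv_est = uv_res.estimate if uv_res else np.nan
        mv_est = float(mv.estimates[k])
        rows.append({"exposure": name, "uv_estimate": uv_est,
                     "mv_direct_estimate": mv_est,
                     "difference": uv_est - mv_est,
                     "ratio": mv_est / uv_est if uv_est else np.nan})
    stage = MVMRStage(mv_results=mv, uv_results=uv,
                      attenuation=pd.DataFrame(rows))
    if run_qhet:
        stage.qhet = model.fit_qhet(seed=seed)
    return stage


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def render_report(outdir, panels: list[UnivariablePanel] | None = None,
                  bidirectional: dict | None = None,
                  assessments: list[MediationAssessment] | None = None,
                  mvmr_stage: MVMRStage | None = None,
                  settings: dict | None = None) -> dict:
    """Write the report bundle: forest-plot TSV, per-pair scatter TSVs,
    machine-readable JSON of every setting, and a text summary.

    Returns the paths written. Missing blocks render as explicit
    "not computed" markers rather than disappearing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    forest_rows = []
    for panel in panels or []:
        if panel.skipped:
            forest_rows.append({"exposure": panel.exposure_name,
                                "outcome": panel.outcome_name,
                                "method": "skipped", "note": panel.skip_reason})
            continue
        for res in panel.results.values():
            forest_rows.append(res.to_dict())
        scatter = MRModel(panel.hset).scatter_data()
        spath = outdir / f"scatter_{panel.exposure_name}_{panel.outcome_name}.tsv"
        scatter.to_csv(spath, sep="\t", index=False, float_format="%.10g")
        written[spath.name] = str(spath)
    if bidirectional:
        for name, bd in bidirectional.items():
            for direction, res in (("forward", bd.forward), ("reverse", bd.reverse),
                                   ("split_forward", bd.split_forward)):
                if res is not None:
                    d = res.to_dict()
                    d["method"] = f"{name}:{direction}:{d['method']}"
                    forest_rows.append(d)
    if forest_rows:
        fpath = outdir / "forest.tsv"
        pd.DataFrame(forest_rows).to_csv(fpath, sep="\t", index=False,
                                         float_format="%.10g")
        written["forest.tsv"] = str(fpath)

    summary_lines = []
    for panel in panels or []:
        if panel.skipped:
            summary_lines.append(f"{panel.exposure_name} -> {panel.outcome_name}: "
                                 f"SKIPPED ({panel.skip_reason})")
        else:
            summary_lines.append(panel.primary.summary())
            if panel.radial is None:
                summary_lines.append("  sensitivity block: not computed")
            else:
                summary_lines.append(
                    f"  radial outliers: {panel.radial.outlier_ids or 'none'}; "
                    f"I2GX (weighted) = {panel.i2gx_weighted:.1f}%")
        summary_lines.append("")
    for a in assessments or []:
        summary_lines.append(f"mediator screen [{a.mediator_name}]: {a.verdict} "
                             f"(i={a.criterion_i}, ii={a.criterion_ii}, "
                             f"iii={a.criterion_iii}, iv={a.criterion_iv})")
    if mvmr_stage is not None:
        summary_lines.append("")
        summary_lines.append(mvmr_stage.mv_results.summary())
        apath = outdir / "attenuation.tsv"
        mvmr_stage.attenuation.to_csv(apath, sep="\t", index=False,
                                      float_format="%.10g")
        written["attenuation.tsv"] = str(apath)
    tpath = outdir / "summary.txt"
    tpath.write_text("\n".join(summary_lines) + "\n")
    written["summary.txt"] = str(tpath)

    meta = {"settings": settings or {},
            "assessments": [a.to_dict() for a in assessments or []],
            "panels": [{"exposure": p.exposure_name, "outcome": p.outcome_name,
                        "skipped": p.skipped} for p in panels or []]}
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written["report.json"] = str(jpath)
    return written


# ---------------------------------------------------------------------------
# file-driven run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and settings for a file-driven study run."""

    exposure_path: str
    outcome_path: str
    output_dir: str
    mediator_paths: list = field(default_factory=list)
    instrument_mode: str = "de_novo"
    p_threshold: float = 5e-8
    instrument_list_path: str | None = None
    palindrome_maf: float = 0.3
    weighting: str = "auto"
    n_boot: int = 1000
    seed: int = 1
    evidence_rule: str = "ci_excludes_null"

    REQUIRED = ("exposure_path", "outcome_path", "output_dir")

    def validate(self):
        for name in self.REQUIRED:
            if not getattr(self, name):
                raise ValueError(f"RunConfig.{name} is required")
        if self.instrument_mode not in ("de_novo", "external_list"):
            raise ValueError(f"unknown instrument_mode {self.instrument_mode!r}")
        if self.instrument_mode == "external_list" and not self.instrument_list_path:
            raise ValueError("external_list mode requires instrument_list_path")
        if not 0 < self.palindrome_maf <= 0.5:
            raise ValueError("palindrome_maf must be in (0, 0.5]")
        if self.evidence_rule not in ("ci_excludes_null", "p_threshold"):
            raise ValueError(f"unknown evidence_rule {self.evidence_rule!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        cfg = cls(**json.loads(Path(path).read_text()))
        cfg.validate()
        return cfg
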