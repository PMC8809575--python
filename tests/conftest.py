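import numpy as np
import pandas as pd
import pytest

from mrmediate import SimulationConfig, SummaryStats, generate_two_sample_study


def make_table(variant_ids, beta, se, pval=None, eaf=None, n=10_000,
               effect_allele="A", other_allele="G", **meta):
    """Small hand-built summary-statistics table."""
    L = len(variant_ids)
    if pval is None:
        from scipy import stats
        pval = 2 * stats.norm.sf(np.abs(np.asarray(beta) / np.asarray(se)))
    if eaf is None:
        eaf = np.full(L, 0.3)
    ea = [effect_allele] * L if isinstance(effect_allele, str) else effect_allele
    oa = [other_allele] * L if isinstance(other_allele, str) else other_allele
    tab = pd.DataFrame({
        "variant_id": variant_ids, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": pval,
        "n": np.full(L, float(n)),
    })
    return SummaryStats(tab, **meta)


@pytest.fixture(scope="session")
def study_bundle():
    """One mid-size synthetic two-sample study with mediation and a reverse
    path, shared across pipeline tests."""
    cfg = SimulationConfig(
        seed=7, n_snps=80, n_sample_exposure=8000, n_sample_outcome=8000,
        exposure_h2=0.25, mediator_h2=0.15, reverse_snp_fraction=0.25,
        theta_XM=-0.25, theta_MY=0.4, theta_XY=-0.15, theta_MX=-0.15,
    )
    return generate_two_sample_study(cfg)
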