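import numpy as np
import pandas as pd
import pytest

import targetmr as tmr
from targetmr.synthetic import simulate_study


@pytest.fixture(scope="session")
def default_study():
    """Paper-scale synthetic study: 3 targets, 100 outcomes, n=3443."""
    return simulate_study(tmr.default_config(seed=7))


@pytest.fixture(scope="session")
def fixture_study():
    """Selection stress fixture: 5 strong planted + 50 decoy variants."""
    return simulate_study(tmr.selection_fixture_config(seed=3))


@pytest.fixture(scope="session")
def small_bundle():
    """A fast end-to-end pipeline run on a reduced outcome panel."""
    from targetmr.pipeline import PipelineConfig, run_pipeline

    cfg = tmr.default_config(seed=11, n_outcomes=12)
    study = simulate_study(cfg)
    bundle = run_pipeline(study, PipelineConfig(seed=11, m_imputations=3))
    return study, bundle


def make_records(rows):
    """Canonical summary-stat frame from dict rows with defaults."""
    base = dict(chrom="5", pos=74_640_000, effect_allele="A", other_allele="G",
                eaf=0.3, beta=0.1, se=0.01, n=146_492)
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d["variant_id"] = f"rs{i+1}"
        d.update(r)
        if "pvalue" not in d:
            from scipy import stats
            z = abs(d["beta"] / d["se"]) if d["se"] > 0 else np.inf
            d["pvalue"] = float(2 * stats.norm.sf(z)) or 1e-320
        out.append(d)
    from targetmr.sumstats import CANONICAL_COLUMNS
    return pd.DataFrame(out, columns=CANONICAL_COLUMNS)
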