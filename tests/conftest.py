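import numpy as np
import pandas as pd
import pytest

from exmirna.effects import compute_effects
from exmirna.qc import run_qc
from exmirna.synth import CohortConfig, generate_cohort, generate_ct_panel


@pytest.fixture(scope="session")
def cohort():
    """Default-size synthetic cohort (31 control / 37 exposed) with panel,
    metadata and QC'd expression for the first timepoint."""
    config = CohortConfig(seed=42)
    records, truth = generate_cohort(config)
    t2 = [r for r in records if r.timepoint == "T2wk"]
    panel = generate_ct_panel(t2, config)
    meta = pd.DataFrame(
        {
            "group": [r.group for r in t2],
            "sex": [r.sex for r in t2],
            "cigarettes_per_day": [r.cigarettes_per_day for r in t2],
            "aa_per_day": [r.aa_per_day for r in t2],
            "weight_z": [r.weight_z for r in t2],
            "length_z": [r.length_z for r in t2],
            "hc_z": [r.hc_z for r in t2],
            "ftii_novelty": [r.ftii_novelty for r in t2],
        },
        index=[r.sample_id for r in t2],
    )
    expr, report = run_qc(panel, meta["group"])
    return {
        "config": config,
        "records": records,
        "truth": truth,
        "panel": panel,
        "meta": meta,
        "expr": expr,
        "report": report,
    }


@pytest.fixture(scope="session")
def effect_table(cohort):
    return compute_effects(
        cohort["expr"].delta_ct,
        cohort["meta"]["group"],
        cohort["meta"]["cigarettes_per_day"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
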