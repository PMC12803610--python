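"""Shared fixtures: cohorts are generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

from hfpef_pipeline import phenotyping as ph
from hfpef_pipeline import synthcohort as sc


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-conditions cohort: n=2000, 6.7% HFpEF prevalence."""
    cfg = sc.CohortConfig(n_participants=2000, seed=1)
    records, truth = sc.generate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    _, records, _ = default_cohort
    labels, counts = ph.label_cohort(records)
    return labels, counts


@pytest.fixture(scope="session")
def feature_table(default_cohort):
    """All four omics blocks concatenated, 'modality:feature' columns."""
    _, records, _ = default_cohort
    return pd.concat(
        [sc.omics_matrix(records, m).add_prefix(f"{m}:") for m in sc.MODALITIES],
        axis=1)


def make_record(pid="X0", age=55.0, sex=1, bmi=25.0, events=(), meds=(),
                nt=np.nan, lvef=np.nan, followup=10.0, death=False,
                onset=np.nan, n_feat=3):
    """Minimal hand-built participant for decision-tree walks."""
    omics = {m: np.zeros(n_feat) for m in sc.MODALITIES}
    return sc.ParticipantRecord(
        id=pid, age_years=age, sex=sex, menopause=False, bmi=bmi,
        clinical_events=sorted([(c, d) for c, d in events], key=lambda e: e[1]),
        medications=set(meds), nt_probnp=nt, lvef_percent=lvef, omics=omics,
        followup_years=followup, death=death, symptom_onset_years=onset)
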