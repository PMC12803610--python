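"""Multi-stage HFpEF case/control labeling with a full audit trail.

No single criterion alone suffices to identify heart failure with preserved
ejection fraction in a population cohort without a dedicated diagnostic code.
The decision tree combines, in order: a symptom/diagnostic gate, an imaging
branch (ejection fraction plus an NT-proBNP percentile rule), and — when no
imaging is available — a clinical pre-test probability (H2FPEF-style point
score) with confirmatory criteria at mid-range risk.  Participants who fail
every HFpEF route are assigned to exclusive control groups (HFrEF > diabetic
> obese > non-HF) or left unassigned when symptomatic but unconfirmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .synthcohort import (AF_CODE, HF_DIAG_CODE, HFREF_EVIDENCE_CODE,
                          MED_ANTIHTN_1, MED_ANTIHTN_2, PH_CODE, SYMPTOM_CODE,
                          T2D_CODE, ParticipantRecord)


class Group(str, Enum):
    HFPEF = "HFPEF"
    HFREF = "HFREF"
    HFMREF_EXCLUDED = "HFMREF_EXCLUDED"
    NON_HF_CONTROL = "NON_HF_CONTROL"
    DIABETIC_CONTROL = "DIABETIC_CONTROL"
    OBESE_CONTROL = "OBESE_CONTROL"
    UNASSIGNED = "UNASSIGNED"


# Approximation of the published H2FPEF point-score nomogram (score 0-9 ->
# pre-test probability of HFpEF); monotone, overridable via PhenotypingParams.
DEFAULT_H2FPEF_MAPPING: dict[int, float] = {
    0: 0.20, 1: 0.32, 2: 0.46, 3: 0.61, 4: 0.74,
    5: 0.84, 6: 0.91, 7: 0.95, 8: 0.97, 9: 0.98,
}

# Point weights of the six score components (obesity and atrial fibrillation
# weighted most heavily, per the validated score).
DEFAULT_H2FPEF_WEIGHTS: dict[str, int] = {
    "obese": 2, "hypertensive": 1, "atrial_fibrillation": 3,
    "pulmonary_hypertension": 1, "elder": 1, "elevated_filling_pressure": 1,
}


@dataclass
class PhenotypingParams:
    ef_preserved_min_exclusive: float = 49.0
    ef_hfref_max: float = 40.0
    ntprobnp_percentile: float = 90.0
    risk_high: float = 0.90
    risk_mid: float = 0.70
    obesity_bmi_min: float = 30.0
    h2fpef_age_min: float = 60.0
    h2fpef_bmi_min: float = 30.0
    symptom_codes: frozenset = frozenset({SYMPTOM_CODE})
    hf_diag_codes: frozenset = frozenset({HF_DIAG_CODE})
    hfref_evidence_codes: frozenset = frozenset({HFREF_EVIDENCE_CODE})
    t2d_codes: frozenset = frozenset({T2D_CODE})
    af_codes: frozenset = frozenset({AF_CODE})
    ph_codes: frozenset = frozenset({PH_CODE})
    antihypertensive_meds: frozenset = frozenset({MED_ANTIHTN_1, MED_ANTIHTN_2})
    h2fpef_mapping: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_H2FPEF_MAPPING))
    h2fpef_weights: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_H2FPEF_WEIGHTS))

    def __post_init__(self) -> None:
        if not 0 < self.risk_mid < self.risk_high < 1:
            raise ValueError("need 0 < risk_mid < risk_high < 1")
        if self.ef_hfref_max >= self.ef_preserved_min_exclusive:
            raise ValueError("ef_hfref_max must be below ef_preserved_min_exclusive")
        scores = sorted(self.h2fpef_mapping)
        probs = [self.h2fpef_mapping[s] for s in scores]
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValueError("h2fpef_mapping must be monotone non-decreasing")


@dataclass
class PhenotypeLabel:
    id: str
    group: Group
    rule_fired: str
    inputs_used: dict

    def __post_init__(self) -> None:
        if self.group is not Group.UNASSIGNED and not self.rule_fired:
            raise ValueError("rule_fired required for assigned labels")


@dataclass
class H2fpefInputs:
    age_years: float
    bmi: float
    atrial_fibrillation: bool
    hypertensive: bool
    pulmonary_hypertension: bool
    elevated_filling_pressure: bool

    def __post_init__(self) -> None:
        if self.age_years <= 0 or self.bmi <= 0:
            raise ValueError("age and bmi must be positive")


def ntprobnp_threshold(values, p: float = 90.0) -> float:
    """Percentile threshold from all participants with available measurements.

    Linear interpolation between order statistics; missing values are
    excluded from the reference.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no non-missing NT-proBNP values in reference")
    return float(np.percentile(arr, p, method="linear"))


def h2fpef_pretest_risk(inputs: H2fpefInputs,
                        params: PhenotypingParams | None = None
                        ) -> tuple[int, float]:
    """Point score over the six clinical components and its mapped pre-test
    probability of HFpEF."""
    params = params or PhenotypingParams()
    w = params.h2fpef_weights
    score = (w["obese"] * (inputs.bmi >= params.h2fpef_bmi_min)
             + w["hypertensive"] * inputs.hypertensive
             + w["atrial_fibrillation"] * inputs.atrial_fibrillation
             + w["pulmonary_hypertension"] * inputs.pulmonary_hypertension
             + w["elder"] * (inputs.age_years > params.h2fpef_age_min)
             + w["elevated_filling_pressure"] * inputs.elevated_filling_pressure)
    score = int(score)
    if score not in params.h2fpef_mapping:
        raise ValueError(f"score {score} outside mapping domain "
                         f"{sorted(params.h2fpef_mapping)}")
    return score, float(params.h2fpef_mapping[score])


def _codes(record: ParticipantRecord) -> set[str]:
    return {code for code, _ in record.clinical_events}


def h2fpef_inputs_from_record(record: ParticipantRecord,
                              params: PhenotypingParams) -> H2fpefInputs:
    codes = _codes(record)
    n_antihtn = len(record.medications & params.antihypertensive_meds)
    return H2fpefInputs(
        age_years=record.age_years, bmi=record.bmi,
        atrial_fibrillation=bool(codes & params.af_codes),
        hypertensive=n_antihtn >= 2,
        pulmonary_hypertension=bool(codes & params.ph_codes),
        elevated_filling_pressure=False)   # no echo data: treated as absent


def classify_participant(record: ParticipantRecord, params: PhenotypingParams,
                         ntprobnp_thr: float) -> PhenotypeLabel:
    """Walk the multi-stage decision tree for one participant.

    Order of evaluation: (1) symptom/diagnostic gate, (2) imaging branch,
    (3) direct assignment at very high pre-test risk, (4) mid-risk assignment
    with confirmatory criteria and no conflicting reduced-EF evidence,
    (5) symptomatic-unconfirmed, (6) exclusive control assignment.
    """
    codes = _codes(record)
    symptomatic = bool(codes & (params.symptom_codes | params.hf_diag_codes))
    ef = record.lvef_percent
    has_ef = np.isfinite(ef)
    nt = record.nt_probnp
    nt_above = np.isfinite(nt) and nt > ntprobnp_thr
    hfref_evidence = bool(codes & params.hfref_evidence_codes)
    inputs_used = {"symptomatic": symptomatic, "ef": ef if has_ef else None,
                   "nt_probnp_above_threshold": bool(nt_above),
                   "pretest_risk": None}

    if symptomatic:
        if has_ef:
            if ef <= params.ef_hfref_max:
                return PhenotypeLabel(record.id, Group.HFREF, "imaging_hfref", inputs_used)
            if ef <= params.ef_preserved_min_exclusive:
                return PhenotypeLabel(record.id, Group.HFMREF_EXCLUDED,
                                      "imaging_hfmref_excluded", inputs_used)
            if nt_above:
                return PhenotypeLabel(record.id, Group.HFPEF,
                                      "imaging_hfpef", inputs_used)
        else:
            _, risk = h2fpef_pretest_risk(h2fpef_inputs_from_record(record, params),
                                          params)
            inputs_used["pretest_risk"] = risk
            if risk > params.risk_high:
                return PhenotypeLabel(record.id, Group.HFPEF,
                                      "risk_high_hfpef", inputs_used)
            hf_code = bool(codes & params.hf_diag_codes)
            if (risk > params.risk_mid and (nt_above or hf_code)
                    and not hfref_evidence):
                return PhenotypeLabel(record.id, Group.HFPEF,
                                      "risk_mid_confirmed_hfpef", inputs_used)
        if hfref_evidence:
            return PhenotypeLabel(record.id, Group.HFREF, "code_hfref", inputs_used)
        return PhenotypeLabel(record.id, Group.UNASSIGNED,
                              "symptomatic_unconfirmed", inputs_used)

    # control assignment among the non-symptomatic pool
    if hfref_evidence:
        return PhenotypeLabel(record.id, Group.HFREF, "control_hfref", inputs_used)
    if codes & params.t2d_codes:
        return PhenotypeLabel(record.id, Group.DIABETIC_CONTROL,
                              "control_diabetic", inputs_used)
    if record.bmi >= params.obesity_bmi_min:
        return PhenotypeLabel(record.id, Group.OBESE_CONTROL,
                              "control_obese", inputs_used)
    return PhenotypeLabel(record.id, Group.NON_HF_CONTROL,
                          "control_non_hf", inputs_used)


def label_cohort(records: list[ParticipantRecord],
                 params: PhenotypingParams | None = None
                 ) -> tuple[list[PhenotypeLabel], dict[str, int]]:
    """Label every participant; returns labels plus per-branch counts.

    The NT-proBNP threshold is computed from all participants with available
    measurements as the reference.
    """
    if not records:
        raise ValueError("cohort is empty")
    params = params or PhenotypingParams()
    try:
        thr = ntprobnp_threshold([r.nt_probnp for r in records],
                                 params.ntprobnp_percentile)
    except ValueError:
        # no measured NT-proBNP anywhere: the biomarker criterion can never
        # fire, equivalent to an infinite threshold
        thr = np.inf
    labels = [classify_participant(r, params, thr) for r in records]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab.rule_fired] = counts.get(lab.rule_fired, 0) + 1
    return labels, counts


def labels_frame(labels: list[PhenotypeLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": l.id, "group": l.group.value, "rule_fired": l.rule_fired}
         for l in labels]).set_index("id")


def stratified_split(labels: dict[str, object], fraction: float = 0.8,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/validation split stratified on the label.

    Per-stratum train sizes use largest-remainder allocation, so each
    stratum's train fraction is within one participant of the target.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    strata: dict[object, list[str]] = {}
    for pid in sorted(labels):
        strata.setdefault(labels[pid], []).append(pid)
    train: list[str] = []
    val: list[str] = []
    for key in sorted(strata, key=str):
        ids = strata[key]
        if not ids:
            raise ValueError(f"empty stratum {key!r}")
        perm = rng.permutation(len(ids))
        exact = fraction * len(ids)
        n_train = int(math_floor_half_up(exact))
        train.extend(ids[i] for i in perm[:n_train])
        val.extend(ids[i] for i in perm[n_train:])
    return train, val


def math_floor_half_up(x: float) -> int:
    """Largest-remainder rounding for a single stratum: floor, plus one when
    the fractional part is >= 0.5."""
    base = int(np.floor(x))
    return base + (1 if x - base >= 0.5 else 0)
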