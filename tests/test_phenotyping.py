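"""Decision-tree labeling: percentile rule, pre-test score, branch walks."""

import numpy as np
import pytest

from conftest import make_record
from hfpef_pipeline import phenotyping as ph
from hfpef_pipeline import synthcohort as sc
from hfpef_pipeline.phenotyping import Group

SYM = sc.SYMPTOM_CODE
HFD = sc.HF_DIAG_CODE
HFR = sc.HFREF_EVIDENCE_CODE
T2D = sc.T2D_CODE
AF = sc.AF_CODE
AH1, AH2 = sc.MED_ANTIHTN_1, sc.MED_ANTIHTN_2


# --------------------------------------------------------------------------
# NT-proBNP percentile threshold
# --------------------------------------------------------------------------

class TestNtprobnpThreshold:
    def test_linear_interpolation_convention(self):
        assert ph.ntprobnp_threshold(np.arange(1, 101), 90) == pytest.approx(90.1)

    def test_single_value_and_constant(self):
        assert ph.ntprobnp_threshold([7.0], 90) == 7.0
        assert ph.ntprobnp_threshold([3.0] * 10, 50) == 3.0

    def test_missing_excluded_from_reference(self):
        vals = list(np.arange(1, 101)) + [np.nan] * 50
        assert ph.ntprobnp_threshold(vals, 90) == pytest.approx(90.1)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            ph.ntprobnp_threshold([np.nan, np.nan], 90)

    def test_at_most_ten_percent_strictly_exceed(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(5, 1, 500)
        thr = ph.ntprobnp_threshold(vals, 90)
        assert (vals > thr).mean() <= 0.10 + 1e-12


# --------------------------------------------------------------------------
# H2FPEF-style pre-test risk
# --------------------------------------------------------------------------

class TestPretestRisk:
    def test_floor_of_scale(self):
        inp = ph.H2fpefInputs(50, 25, False, False, False, False)
        score, prob = ph.h2fpef_pretest_risk(inp)
        assert score == 0
        assert prob == ph.DEFAULT_H2FPEF_MAPPING[0]

    def test_ceiling_of_scale(self):
        inp = ph.H2fpefInputs(70, 35, True, True, True, True)
        score, prob = ph.h2fpef_pretest_risk(inp)
        assert score == 9
        assert prob == ph.DEFAULT_H2FPEF_MAPPING[9]

    def test_mid_scale_worked_case(self):
        # obesity (2) + hypertension (1) + age > 60 (1) = 4 points -> 0.74
        inp = ph.H2fpefInputs(65, 32, False, True, False, False)
        score, prob = ph.h2fpef_pretest_risk(inp)
        assert score == 4
        assert prob == pytest.approx(0.74)

    def test_score_outside_mapping_errors(self):
        params = ph.PhenotypingParams(h2fpef_mapping={0: 0.1, 1: 0.2})
        inp = ph.H2fpefInputs(70, 35, True, True, True, True)
        with pytest.raises(ValueError, match="outside mapping"):
            ph.h2fpef_pretest_risk(inp, params)

    def test_mapping_must_be_monotone(self):
        with pytest.raises(ValueError, match="monotone"):
            ph.PhenotypingParams(h2fpef_mapping={0: 0.5, 1: 0.3})


# --------------------------------------------------------------------------
# Single-participant decision tree
# --------------------------------------------------------------------------

THR = 1000.0


class TestClassifyParticipant:
    def _classify(self, record):
        return ph.classify_participant(record, ph.PhenotypingParams(), THR)

    def test_imaging_branch_hfpef(self):
        rec = make_record(events=[(SYM, -10)], lvef=55.0, nt=5000.0)
        lab = self._classify(rec)
        assert lab.group is Group.HFPEF and lab.rule_fired == "imaging_hfpef"

    def test_reduced_ef_overrides_ntprobnp(self):
        rec = make_record(events=[(SYM, -10)], lvef=35.0, nt=5000.0)
        assert self._classify(rec).group is Group.HFREF

    def test_mildly_reduced_ef_excluded(self):
        rec = make_record(events=[(SYM, -10)], lvef=45.0, nt=5000.0)
        assert self._classify(rec).group is Group.HFMREF_EXCLUDED

    def test_obese_control_branch(self):
        rec = make_record(bmi=33.0)
        assert self._classify(rec).group is Group.OBESE_CONTROL

    def test_very_high_risk_direct_assignment(self):
        rec = make_record(age=65, bmi=32, events=[(SYM, -10), (AF, -100)])
        lab = self._classify(rec)
        assert lab.group is Group.HFPEF and lab.rule_fired == "risk_high_hfpef"
        assert lab.inputs_used["pretest_risk"] > 0.90

    def test_mid_risk_without_confirmation_unassigned(self):
        # risk 0.74, NT-proBNP below threshold, no HF diagnostic code
        rec = make_record(age=65, bmi=32, events=[(SYM, -10)],
                          meds=[AH1, AH2], nt=100.0)
        lab = self._classify(rec)
        assert lab.group is Group.UNASSIGNED
        assert lab.rule_fired == "symptomatic_unconfirmed"

    def test_mid_risk_with_hf_code_assigned(self):
        rec = make_record(age=65, bmi=32, events=[(SYM, -10), (HFD, -5)],
                          meds=[AH1, AH2])
        assert self._classify(rec).rule_fired == "risk_mid_confirmed_hfpef"

    def test_mid_risk_conflicting_hfref_evidence(self):
        rec = make_record(age=65, bmi=32,
                          events=[(SYM, -10), (HFD, -5), (HFR, -5)],
                          meds=[AH1, AH2])
        assert self._classify(rec).group is Group.HFREF

    def test_control_priority_diabetic_over_obese(self):
        rec = make_record(bmi=34.0, events=[(T2D, -100)])
        assert self._classify(rec).group is Group.DIABETIC_CONTROL


# --------------------------------------------------------------------------
# Cohort labeling: hand-enumerated 20-record fixture
# --------------------------------------------------------------------------

def twenty_record_fixture():
    recs = [make_record(pid=f"R{i:02d}", nt=100.0) for i in range(1, 11)]
    recs[3].bmi = 33.0                          # R04 obese
    recs[4].bmi = 31.0                          # R05 obese
    recs[5].clinical_events = [(T2D, -100.0)]   # R06 diabetic
    recs[6].clinical_events = [(T2D, -100.0)]   # R07 diabetic + obese
    recs[6].bmi = 34.0
    recs[7].clinical_events = [(HFR, -100.0)]   # R08 control HFrEF
    recs[8].bmi = 29.9                          # R09 lean
    recs[9].lvef_percent = 60.0                 # R10 asymptomatic with imaging
    recs += [
        make_record(pid="R11", events=[(SYM, -1)], lvef=55.0, nt=7000.0),
        make_record(pid="R12", events=[(SYM, -1)], lvef=60.0, nt=8000.0),
        make_record(pid="R13", events=[(SYM, -1)], lvef=35.0),
        make_record(pid="R14", events=[(SYM, -1)], lvef=45.0),
        make_record(pid="R15", events=[(SYM, -1)], lvef=55.0, nt=300.0),
        make_record(pid="R16", age=65, bmi=32, events=[(SYM, -1), (AF, -9)]),
        make_record(pid="R17", age=65, bmi=32, events=[(SYM, -1), (HFD, -9)],
                    meds=[AH1, AH2]),
        make_record(pid="R18", age=65, bmi=32, events=[(SYM, -1)],
                    meds=[AH1, AH2], nt=100.0),
        make_record(pid="R19", age=65, bmi=32,
                    events=[(SYM, -1), (HFD, -9), (HFR, -9)], meds=[AH1, AH2]),
        make_record(pid="R20", age=50, bmi=25, events=[(SYM, -1)], nt=100.0),
    ]
    return recs


# hand enumeration of the fixture walk (reference NT values: twelve 100s,
# one 300, 7000, 8000 -> 90th percentile threshold 4320; above: 7000, 8000)
EXPECTED_BRANCH_COUNTS = {
    "control_non_hf": 5, "control_obese": 2, "control_diabetic": 2,
    "control_hfref": 1, "imaging_hfpef": 2, "imaging_hfref": 1,
    "imaging_hfmref_excluded": 1, "symptomatic_unconfirmed": 3,
    "risk_high_hfpef": 1, "risk_mid_confirmed_hfpef": 1, "code_hfref": 1,
}


class TestLabelCohort:
    def test_fixture_branch_counts_match_hand_enumeration(self):
        labels, counts = ph.label_cohort(twenty_record_fixture())
        assert counts == EXPECTED_BRANCH_COUNTS
        assert len(labels) == 20

    def test_fixture_threshold(self):
        recs = twenty_record_fixture()
        thr = ph.ntprobnp_threshold([r.nt_probnp for r in recs], 90)
        assert thr == pytest.approx(4320.0)

    def test_all_asymptomatic_lean_healthy(self):
        recs = [make_record(pid=f"L{i}", bmi=24.0) for i in range(10)]
        labels, _ = ph.label_cohort(recs)
        assert all(l.group is Group.NON_HF_CONTROL for l in labels)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            ph.label_cohort([])

    def test_planted_labels_recovered(self, default_cohort, default_labels):
        """Plant-consistent generator cases classify to their true groups."""
        _, _, truth = default_cohort
        labels, _ = default_labels
        expect = {"hfpef": Group.HFPEF, "hfref": Group.HFREF,
                  "diabetic": Group.DIABETIC_CONTROL,
                  "obese": Group.OBESE_CONTROL,
                  "non_hf": Group.NON_HF_CONTROL,
                  "other": Group.NON_HF_CONTROL}
        mismatch = [l.id for l in labels
                    if l.group is not expect[truth.group[l.id]]]
        assert mismatch == []


def _random_records(n, seed):
    rng = np.random.default_rng(seed)
    codes = [SYM, HFD, HFR, T2D, AF, sc.OTHER_DX_CODE]
    out = []
    for i in range(n):
        events = [(codes[j], float(rng.uniform(-3000, 3000)))
                  for j in range(6) if rng.random() < 0.2]
        out.append(make_record(
            pid=f"Z{i}", age=float(rng.uniform(40, 80)),
            bmi=float(rng.uniform(17, 45)), events=events,
            meds=[m for m in (AH1, AH2) if rng.random() < 0.3],
            nt=float(rng.lognormal(5, 1)) if rng.random() < 0.8 else np.nan,
            lvef=float(rng.uniform(20, 75)) if rng.random() < 0.3 else np.nan))
    return out


class TestInvariants:
    def test_partition_and_ef_consistency_on_random_records(self):
        """Every record gets exactly one label; nobody labeled HFpEF has a
        recorded EF at or below the preserved-EF cut."""
        recs = _random_records(1000, seed=17)
        labels, counts = ph.label_cohort(recs)
        assert len(labels) == len(recs)
        assert sum(counts.values()) == len(recs)
        assert len({l.id for l in labels}) == len(recs)
        params = ph.PhenotypingParams()
        for rec, lab in zip(recs, labels):
            if lab.group is Group.HFPEF and np.isfinite(rec.lvef_percent):
                assert rec.lvef_percent > params.ef_preserved_min_exclusive

    def test_raising_percentile_never_increases_hfpef(self):
        recs = _random_records(1000, seed=23)
        counts = []
        for p in (80.0, 90.0, 97.0):
            labels, _ = ph.label_cohort(recs, ph.PhenotypingParams(
                ntprobnp_percentile=p))
            counts.append(sum(l.group is Group.HFPEF for l in labels))
        assert counts[0] >= counts[1] >= counts[2]


# --------------------------------------------------------------------------
# Stratified split
# --------------------------------------------------------------------------

class TestStratifiedSplit:
    def test_single_stratum_exact(self):
        labels = {f"i{k}": "a" for k in range(100)}
        train, val = ph.stratified_split(labels, 0.8, seed=0)
        assert len(train) == 80 and len(val) == 20

    def test_two_strata_largest_remainder(self):
        labels = {f"s{k}": "small" for k in range(10)}
        labels.update({f"b{k}": "big" for k in range(90)})
        train, val = ph.stratified_split(labels, 0.8, seed=0)
        small_train = [i for i in train if i.startswith("s")]
        big_train = [i for i in train if i.startswith("b")]
        assert len(small_train) == 8 and len(big_train) == 72
        assert len(val) == 20

    def test_deterministic_and_partition(self):
        rng = np.random.default_rng(4)
        labels = {f"i{k}": str(rng.integers(3)) for k in range(157)}
        t1, v1 = ph.stratified_split(labels, 0.8, seed=11)
        t2, v2 = ph.stratified_split(labels, 0.8, seed=11)
        assert t1 == t2 and v1 == v2
        assert set(t1) | set(v1) == set(labels)
        assert not set(t1) & set(v1)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            ph.stratified_split({"a": 1}, 1.5)
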