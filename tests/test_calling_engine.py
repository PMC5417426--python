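"""dCt computation, sample classification, plate QC and the repeat workflow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castkit import (
    AssayRole,
    CallState,
    Plate,
    Recommendation,
    RuleSet,
    SampleCall,
    WellKind,
    WellMeasurement,
    call_plate,
    classify_sample,
    compute_delta_ct,
    qc_plate,
    resolve_repeats,
)
from castkit.errors import ParameterError, QCError, WorkflowError

from oracles import decision_table_classify


class TestComputeDeltaCt:
    @pytest.mark.parametrize(
        "mut, ref, expected",
        [(27.5, 23.5, 4.0), (25.0, 25.0, 0.0), (33.3, 33.3, 0.0), (None, 25.0, None)],
    )
    def test_definition(self, mut, ref, expected):
        assert compute_delta_ct(mut, ref) == expected

    def test_absent_reference_is_a_contract_violation(self):
        with pytest.raises(ParameterError):
            compute_delta_ct(27.5, None)


class TestClassifySample:
    @pytest.mark.parametrize(
        "ref, mut, state, rec, confirmed",
        [
            # worked example: dCt 4 -> detected outright
            (23.5, 27.5, CallState.MUTATION_DETECTED, Recommendation.NONE, True),
            # too much input DNA
            (17.0, 25.0, CallState.REFERENCE_FAIL, Recommendation.REPEAT_LESS_DNA, False),
            # too little input DNA
            (31.0, 36.0, CallState.REFERENCE_FAIL, Recommendation.REPEAT_MORE_DNA, False),
            (None, 36.0, CallState.REFERENCE_FAIL, Recommendation.REPEAT_MORE_DNA, False),
            # confirmation band [7, 8.1)
            (25.0, 32.5, CallState.MUTATION_DETECTED, Recommendation.REPEAT_DUPLICATE_CONFIRM, False),
            # clearly negative
            (25.0, 38.5, CallState.MUTATION_NOT_DETECTED, Recommendation.NONE, False),
            # late mutant Ct with small dCt -> undetermined
            (30.0, 37.5, CallState.UNDETERMINED, Recommendation.REPEAT_DUPLICATE_UNDETERMINED, False),
            # no mutant signal with mid-window reference -> negative
            (25.0, None, CallState.MUTATION_NOT_DETECTED, Recommendation.NONE, False),
            # no mutant signal with late reference -> cannot rule out
            (29.5, None, CallState.UNDETERMINED, Recommendation.REPEAT_DUPLICATE_UNDETERMINED, False),
        ],
    )
    def test_decision_rules(self, rules, ref, mut, state, rec, confirmed):
        call = classify_sample(ref, mut, 24.0, 24.0, rules)
        assert (call.state, call.recommendation, call.confirmed) == (state, rec, confirmed)

    @pytest.mark.parametrize("ipc_mut, ipc_ref", [(None, 24.0), (24.0, None), (31.0, 24.0), (24.0, 30.5)])
    def test_ipc_failure_in_either_assay_fails_sample(self, rules, ipc_mut, ipc_ref):
        call = classify_sample(23.5, 27.5, ipc_mut, ipc_ref, rules)
        assert call.state is CallState.ASSAY_FAIL
        assert call.recommendation is Recommendation.REPEAT_SAMPLE

    def test_detected_state_implies_delta_below_cutoff(self, rules):
        call = classify_sample(23.5, 27.5, 24.0, 24.0, rules)
        assert call.delta_ct is not None and call.delta_ct < rules.delta_ct_detect

    def test_truth_table_equivalence_with_decision_table(self, rules):
        """The engine agrees with an independently coded transcription of the
        interpretation table on a dense Ct grid, and reaches every state."""
        ct_refs = [None] + list(np.arange(10.0, 40.01, 0.5))
        ct_muts = [None] + list(np.arange(10.0, 45.01, 0.5))
        seen = set()
        n = 0
        for ref in ct_refs:
            for mut in ct_muts:
                for ipc_ok in (True, False):
                    ipc = 24.0 if ipc_ok else None
                    got = classify_sample(ref, mut, ipc, 24.0, rules)
                    want = decision_table_classify(ref, mut, ipc_ok, True, rules)
                    assert (got.state.value, got.recommendation.value, got.confirmed) == want, (
                        f"disagreement at ct_ref={ref}, ct_mut={mut}, ipc_ok={ipc_ok}"
                    )
                    seen.add(got.state)
                    n += 1
        assert n > 8000
        assert seen == set(CallState)

    @settings(derandomize=True, max_examples=200)
    @given(
        ref=st.floats(18.0, 30.0),
        mut1=st.floats(10.0, 45.0),
        bump=st.floats(0.0, 10.0),
    )
    def test_increasing_mutant_ct_never_creates_a_detection(self, ref, mut1, bump):
        rules = RuleSet()
        c1 = classify_sample(ref, mut1, 24.0, 24.0, rules)
        c2 = classify_sample(ref, mut1 + bump, 24.0, 24.0, rules)
        if c1.state is CallState.MUTATION_NOT_DETECTED:
            assert c2.state is not CallState.MUTATION_DETECTED

    def test_determinism(self, rules):
        a = classify_sample(25.0, 32.5, 24.0, 24.0, rules)
        b = classify_sample(25.0, 32.5, 24.0, 24.0, rules)
        assert a == b


def _ntc(ct, idx=1):
    return [
        WellMeasurement(f"NTC{idx}", AssayRole.MUTANT, ct, 24.0, WellKind.NTC),
        WellMeasurement(f"NTC{idx}", AssayRole.REFERENCE, None, 24.0, WellKind.NTC),
    ]


def _sample(sid, ct_ref, ct_mut, rep=1):
    return [
        WellMeasurement(sid, AssayRole.MUTANT, ct_mut, 24.0, WellKind.SAMPLE, rep),
        WellMeasurement(sid, AssayRole.REFERENCE, ct_ref, 24.0, WellKind.SAMPLE, rep),
    ]


class TestPlateQC:
    def test_silent_ntcs_pass(self, rules):
        plate = Plate("p", _ntc(None, 1) + _ntc(None, 2))
        qc = qc_plate(plate, rules)
        assert qc.ntc_pass and qc.plate_state.value == "pass"

    def test_early_ntc_signal_fails_and_is_listed(self, rules):
        plate = Plate("p", _ntc(28.0, 1) + _ntc(None, 2))
        qc = qc_plate(plate, rules)
        assert not qc.ntc_pass
        assert any("NTC1" in w for w in qc.failed_wells)

    def test_ntc_exactly_at_bound_passes(self, rules):
        plate = Plate("p", _ntc(30.0, 1) + _ntc(None, 2))
        assert qc_plate(plate, rules).ntc_pass

    def test_no_ntc_wells_is_a_qc_error(self, rules):
        with pytest.raises(QCError):
            qc_plate(Plate("p", _sample("S1", 25.0, 30.0)), rules)


def _call(state, rec=Recommendation.NONE, delta=None, confirmed=False):
    return SampleCall("S", delta, state, rec, confirmed)


class TestResolveRepeats:
    def test_empty_duplicates_is_a_workflow_error(self):
        with pytest.raises(WorkflowError):
            resolve_repeats(_call(CallState.MUTATION_DETECTED), [])

    def test_all_duplicate_outcome_pairs_follow_the_and_rule(self):
        """Exhaustive enumeration of duplicate outcome pairs for a
        confirm-band initial call: detected only when both re-detect."""
        outcomes = [CallState.MUTATION_DETECTED, CallState.MUTATION_NOT_DETECTED, CallState.UNDETERMINED]
        initial = _call(CallState.MUTATION_DETECTED, Recommendation.REPEAT_DUPLICATE_CONFIRM, 7.5)
        for s1 in outcomes:
            for s2 in outcomes:
                final = resolve_repeats(initial, [_call(s1, delta=6.0), _call(s2, delta=6.5)])
                both_detect = s1 is CallState.MUTATION_DETECTED and s2 is CallState.MUTATION_DETECTED
                if both_detect:
                    assert final.state is CallState.MUTATION_DETECTED and final.confirmed
                    assert final.delta_ct == pytest.approx(6.25)  # mean of repeat dCts
                else:
                    assert final.state is CallState.MUTATION_NOT_DETECTED

    def test_unevaluable_duplicates_yield_assay_fail(self):
        initial = _call(CallState.UNDETERMINED, Recommendation.REPEAT_DUPLICATE_UNDETERMINED)
        dups = [_call(CallState.REFERENCE_FAIL, Recommendation.REPEAT_MORE_DNA)] * 2
        assert resolve_repeats(initial, dups).state is CallState.ASSAY_FAIL

    def test_persistent_undetermined_caps_at_one_round(self):
        initial = _call(CallState.UNDETERMINED, Recommendation.REPEAT_DUPLICATE_UNDETERMINED)
        dups = [_call(CallState.UNDETERMINED)] * 2
        final = resolve_repeats(initial, dups)
        assert final.state is CallState.UNDETERMINED
        assert final.recommendation is Recommendation.NONE

    def test_history_is_retained(self):
        initial = _call(CallState.MUTATION_DETECTED, Recommendation.REPEAT_DUPLICATE_CONFIRM, 7.2)
        dups = [_call(CallState.MUTATION_DETECTED, delta=6.8)] * 2
        final = resolve_repeats(initial, dups)
        assert len(final.history) == 3 and final.history[0] is initial


class TestCallPlate:
    def _clean_plate(self, n=48, mutants=(7, 41)):
        wells = _ntc(None, 1) + _ntc(None, 2)
        for i in range(1, n + 1):
            # spiked mutants at dCt ~ 4, everything else deep negative
            wells += _sample(f"S{i:03d}", 24.0, 28.0 if i in mutants else None)
        return Plate("p", wells)

    def test_spiked_mutants_are_the_only_detections(self, rules):
        calls, qc = call_plate(self._clean_plate(), rules)
        assert qc.ntc_pass
        detected = [c.sample_id for c in calls if c.state is CallState.MUTATION_DETECTED]
        assert detected == ["S007", "S041"]
        assert len(calls) == 48

    def test_failing_ntc_voids_every_sample(self, rules):
        plate = self._clean_plate()
        plate.wells[0] = WellMeasurement("NTC1", AssayRole.MUTANT, 25.0, 24.0, WellKind.NTC)
        calls, qc = call_plate(plate, rules)
        assert not qc.ntc_pass
        assert all(c.state is CallState.ASSAY_FAIL for c in calls)
        assert all(c.recommendation is Recommendation.REPEAT_SAMPLE for c in calls)

    def test_empty_sample_set_still_evaluates_qc(self, rules):
        calls, qc = call_plate(Plate("p", _ntc(None, 1) + _ntc(None, 2)), rules)
        assert calls == [] and qc.ntc_pass

    def test_recalling_a_plate_is_identical(self, rules):
        plate = self._clean_plate()
        assert call_plate(plate, rules) == call_plate(plate, rules)

    def test_on_plate_duplicates_confirm_a_band_call(self, rules):
        wells = _ntc(None, 1) + _ntc(None, 2)
        wells += _sample("S1", 25.0, 32.5, rep=1)  # dCt 7.5: confirmation band
        wells += _sample("S1", 25.0, 31.0, rep=2)
        wells += _sample("S1", 25.0, 31.2, rep=3)
        calls, _ = call_plate(Plate("p", wells), rules)
        [c] = calls
        assert c.state is CallState.MUTATION_DETECTED and c.confirmed
        assert len(c.history) == 3
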