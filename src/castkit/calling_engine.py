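"""Interpretation rules for a two-well allele-specific qPCR mutation assay.

A sample is measured by two reactions: the mutant-allele assay (wild-type
amplification suppressed by an MGB blocker) and a gene-reference assay in the
same gene.  The call is driven by dCt = Ct(mutant) - Ct(reference): abundant
mutant template crosses threshold only a few cycles after the reference, so a
small dCt means mutation detected.  Every constant lives in :class:`RuleSet`
so a laboratory can re-derive and swap its own thresholds.

Rule evaluation order (each sample on a QC-passing plate):

1. internal positive control (IPC) failed in either well -> assay fail,
   repeat the sample;
2. reference Ct below the window -> too much input DNA, repeat with less;
3. reference Ct above the window or no signal -> repeat with more DNA;
4. dCt at or above the detection cut-off -> mutation not detected;
5. dCt below the cut-off with an evaluable mutant Ct -> mutation detected;
   confirmed outright below the confirmation band, otherwise flagged for a
   duplicate confirmation run;
6. dCt below the cut-off but mutant Ct beyond the evaluable bound ->
   undetermined, repeat in duplicate.

A mutant reaction with no signal is unambiguously negative unless the
reference Ct sits so high that even a mutant Ct just past the evaluable bound
would still fall under the detection cut-off; that corner is reported
undetermined rather than negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import yaml

from .errors import ParameterError, QCError, WorkflowError
from .plate_model import AssayRole, Plate, WellKind, WellMeasurement

__all__ = [
    "RuleSet",
    "CallState",
    "Recommendation",
    "SampleCall",
    "PlateQC",
    "PlateState",
    "compute_delta_ct",
    "classify_sample",
    "qc_plate",
    "resolve_repeats",
    "call_plate",
]


class CallState(str, Enum):
    MUTATION_DETECTED = "mutation_detected"
    MUTATION_NOT_DETECTED = "mutation_not_detected"
    UNDETERMINED = "undetermined"
    REFERENCE_FAIL = "reference_fail"
    ASSAY_FAIL = "assay_fail"


class Recommendation(str, Enum):
    NONE = "none"
    REPEAT_LESS_DNA = "repeat_less_dna"
    REPEAT_MORE_DNA = "repeat_more_dna"
    REPEAT_DUPLICATE_CONFIRM = "repeat_duplicate_confirm"
    REPEAT_DUPLICATE_UNDETERMINED = "repeat_duplicate_undetermined"
    REPEAT_SAMPLE = "repeat_sample"


class PlateState(str, Enum):
    PASS = "pass"
    FAIL = "fail"


@dataclass(frozen=True)
class RuleSet:
    """Classification constants, in cycles.

    Defaults are the validated FFPE thresholds: reference window [18, 30]
    (closed), mutant assay evaluable through Ct 37, detection cut-off
    dCt < 8.1 (strict), confirmation band [7, 8.1), IPC must fire by cycle 30,
    and any NTC signal before cycle 30 fails the plate.
    """

    ref_ct_min: float = 18.0
    ref_ct_max: float = 30.0
    mut_ct_max: float = 37.0
    delta_ct_detect: float = 8.1
    delta_ct_confirm_band_low: float = 7.0
    ipc_ct_max: float = 30.0
    ntc_ct_min: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.ref_ct_min < self.ref_ct_max:
            raise ParameterError("require 0 < ref_ct_min < ref_ct_max")
        if not self.delta_ct_confirm_band_low < self.delta_ct_detect:
            raise ParameterError("require delta_ct_confirm_band_low < delta_ct_detect")
        for name, v in asdict(self).items():
            if not math.isfinite(v):
                raise ParameterError(f"{name} must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SampleCall:
    """Outcome of classifying one sample (possibly after repeats)."""

    sample_id: str
    delta_ct: float | None
    state: CallState
    recommendation: Recommendation = Recommendation.NONE
    confirmed: bool = False
    history: list["SampleCall"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "delta_ct": self.delta_ct,
            "state": self.state.value,
            "recommendation": self.recommendation.value,
            "confirmed": self.confirmed,
            "history": [h.to_dict() for h in self.history],
        }


@dataclass
class PlateQC:
    ntc_pass: bool
    failed_wells: list[str]
    plate_state: PlateState


def compute_delta_ct(ct_mutant: float | None, ct_reference: float | None) -> float | None:
    """dCt = Ct(mutant) - Ct(reference); absent when the mutant assay gave no
    signal.  The reference Ct must be present (route reference failures first)."""
    if ct_reference is None:
        raise ParameterError("ct_reference is absent; classify the reference failure first")
    if ct_mutant is None:
        return None
    return ct_mutant - ct_reference


def _ipc_failed(ipc_ct: float | None, rules: RuleSet) -> bool:
    return ipc_ct is None or ipc_ct > rules.ipc_ct_max


def classify_sample(
    ct_reference: float | None,
    ct_mutant: float | None,
    ipc_ct_mutant: float | None,
    ipc_ct_reference: float | None,
    rules: RuleSet = RuleSet(),
    sample_id: str = "",
) -> SampleCall:
    """Apply the interpretation rules to one sample's paired reactions.

    Returns exactly one state and recommendation (see the module docstring for
    the evaluation order).
    """
    if _ipc_failed(ipc_ct_mutant, rules) or _ipc_failed(ipc_ct_reference, rules):
        return SampleCall(sample_id, None, CallState.ASSAY_FAIL, Recommendation.REPEAT_SAMPLE)
    if ct_reference is not None and ct_reference < rules.ref_ct_min:
        return SampleCall(sample_id, None, CallState.REFERENCE_FAIL, Recommendation.REPEAT_LESS_DNA)
    if ct_reference is None or ct_reference > rules.ref_ct_max:
        return SampleCall(sample_id, None, CallState.REFERENCE_FAIL, Recommendation.REPEAT_MORE_DNA)

    delta = compute_delta_ct(ct_mutant, ct_reference)
    if ct_mutant is None:
        # No mutant signal: negative, unless the reference is so late that a
        # mutant Ct just beyond the evaluable bound would still beat the
        # cut-off — then the status cannot be ruled on.
        if ct_reference > rules.mut_ct_max - rules.delta_ct_detect:
            return SampleCall(
                sample_id, None, CallState.UNDETERMINED, Recommendation.REPEAT_DUPLICATE_UNDETERMINED
            )
        return SampleCall(sample_id, None, CallState.MUTATION_NOT_DETECTED)

    if delta >= rules.delta_ct_detect:
        return SampleCall(sample_id, delta, CallState.MUTATION_NOT_DETECTED)
    if ct_mutant <= rules.mut_ct_max:
        if delta < rules.delta_ct_confirm_band_low:
            return SampleCall(sample_id, delta, CallState.MUTATION_DETECTED, confirmed=True)
        return SampleCall(
            sample_id,
            delta,
            CallState.MUTATION_DETECTED,
            Recommendation.REPEAT_DUPLICATE_CONFIRM,
            confirmed=False,
        )
    return SampleCall(
        sample_id, delta, CallState.UNDETERMINED, Recommendation.REPEAT_DUPLICATE_UNDETERMINED
    )


def qc_plate(plate: Plate, rules: RuleSet = RuleSet()) -> PlateQC:
    """Plate-level QC: any no-template-control signal before ``ntc_ct_min``
    cycles (in either assay) fails the whole plate."""
    ntc_wells = [w for w in plate.wells if w.well_kind is WellKind.NTC]
    if not ntc_wells:
        raise QCError(f"plate {plate.plate_id!r} has no NTC wells; QC cannot be evaluated")
    failed = [
        f"{w.sample_id}/{w.assay_role.value}/rep{w.replicate_index}"
        for w in ntc_wells
        if w.ct is not None and w.ct < rules.ntc_ct_min
    ]
    state = PlateState.FAIL if failed else PlateState.PASS
    return PlateQC(ntc_pass=not failed, failed_wells=failed, plate_state=state)


def resolve_repeats(initial: SampleCall, duplicates: list[SampleCall]) -> SampleCall:
    """Fold a duplicate confirmation run into a final call.

    The final call is mutation detected only when *both* duplicate wells
    independently detect the mutation (at any confidence) — the conservative
    rule that protects against false positives.  Failed duplicates with no
    evaluable signal yield an overall assay failure; a persistent undetermined
    stays undetermined after one repeat round; everything else resolves to
    mutation not detected.  The full history is retained on the result.
    """
    if not duplicates:
        raise WorkflowError("resolve_repeats called with no duplicate calls")
    history = [initial, *duplicates]
    detected = [d for d in duplicates if d.state is CallState.MUTATION_DETECTED]
    if len(detected) == len(duplicates):
        deltas = [d.delta_ct for d in detected if d.delta_ct is not None]
        mean_delta = sum(deltas) / len(deltas) if deltas else None
        return SampleCall(
            initial.sample_id,
            mean_delta,
            CallState.MUTATION_DETECTED,
            Recommendation.NONE,
            confirmed=True,
            history=history,
        )
    evaluable = {CallState.MUTATION_DETECTED, CallState.MUTATION_NOT_DETECTED, CallState.UNDETERMINED}
    if all(d.state not in evaluable for d in duplicates):
        return SampleCall(
            initial.sample_id,
            None,
            CallState.ASSAY_FAIL,
            Recommendation.REPEAT_SAMPLE,
            history=history,
        )
    if initial.state is CallState.UNDETERMINED and all(
        d.state is CallState.UNDETERMINED or d.state not in evaluable for d in duplicates
    ):
        # One repeat round only; a persistent undetermined is reported, not
        # looped.
        return SampleCall(initial.sample_id, initial.delta_ct, CallState.UNDETERMINED, history=history)
    return SampleCall(
        initial.sample_id, initial.delta_ct, CallState.MUTATION_NOT_DETECTED, history=history
    )


def _classify_pair(
    mut: WellMeasurement, ref: WellMeasurement, rules: RuleSet, sample_id: str
) -> SampleCall:
    return classify_sample(
        ct_reference=ref.ct,
        ct_mutant=mut.ct,
        ipc_ct_mutant=mut.ipc_ct,
        ipc_ct_reference=ref.ipc_ct,
        rules=rules,
        sample_id=sample_id,
    )


def call_plate(plate: Plate, rules: RuleSet = RuleSet()) -> tuple[list[SampleCall], PlateQC]:
    """Call every sample on a plate.

    A failing plate QC voids the run: every sample is reported as an assay
    failure to be repeated.  Otherwise each sample's first replicate pair is
    classified; when further replicate pairs exist on the same plate and the
    first call requested a duplicate run, they are folded in via
    :func:`resolve_repeats`.  Output is ordered by sample id.
    """
    plate.validate()
    qc = qc_plate(plate, rules)
    sample_ids = plate.sample_ids()
    if qc.plate_state is PlateState.FAIL:
        calls = [
            SampleCall(sid, None, CallState.ASSAY_FAIL, Recommendation.REPEAT_SAMPLE)
            for sid in sample_ids
        ]
        return calls, qc

    calls = []
    repeat_recs = {
        Recommendation.REPEAT_DUPLICATE_CONFIRM,
        Recommendation.REPEAT_DUPLICATE_UNDETERMINED,
    }
    for sid in sample_ids:
        muts = plate.wells_for(sid, AssayRole.MUTANT)
        refs = plate.wells_for(sid, AssayRole.REFERENCE)
        pairs = list(zip(muts, refs))
        per_rep = [_classify_pair(m, r, rules, sid) for m, r in pairs]
        final = per_rep[0]
        if len(per_rep) > 1 and final.recommendation in repeat_recs:
            final = resolve_repeats(final, per_rep[1:])
        calls.append(final)
    return calls, qc
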