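"""Analytical-validation statistics for allele-specific PCR assays.

Covers the desk side of an assay validation: replicate summaries of reference
standard runs, derivation of the dCt detection cut-off from wild-type
observations, limit-of-blank (LoB) estimation, per-level hit rates of a
quantitative method against its detection cut-off, qualitative concordance
between two methods (overall / positive / negative percent agreement) and
ordinary least-squares regression of paired MAF measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CalibrationError, PairingError, ParameterError, RegressionError
from .plate_model import Call, MafTable, ReferenceLevelRun

__all__ = [
    "LevelSummary",
    "BlankPanel",
    "MethodProfile",
    "MethodComparison",
    "summarize_level",
    "derive_cutoff",
    "estimate_lob",
    "hit_rate_by_level",
    "classify_maf",
    "concordance",
    "regress_maf",
    "pair_replicates_to_level",
]


@dataclass
class LevelSummary:
    """Mean/SD of one reference-standard level's replicate dCt values.

    Runs with no mutant-assay signal are counted in ``n_absent`` and excluded
    from the moments — they are censored, not zero.
    """

    level_maf: float
    n_present: int
    mean_delta_ct: float | None
    sd_delta_ct: float | None
    n_absent: int


@dataclass
class BlankPanel:
    """MAF measurements from mutation-negative specimens (one per donor)."""

    blank_mafs: list[float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.blank_mafs):
            raise ParameterError("blank MAFs must be >= 0")

    @property
    def n(self) -> int:
        return len(self.blank_mafs)


@dataclass(frozen=True)
class MethodProfile:
    """A detection method and its qualitative MAF cut-off."""

    name: str
    detection_cutoff_maf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_cutoff_maf < 1.0:
            raise ParameterError("detection_cutoff_maf must lie in (0, 1)")


@dataclass
class MethodComparison:
    """Agreement and regression summaries for two methods on shared samples.

    Percent-agreement orientation: method A is the comparator, so PPA is the
    fraction of A-positives that B also calls positive and NPA the fraction of
    A-negatives that B also calls negative.
    """

    paired_calls: list[tuple[str, Call, Call]] = field(default_factory=list)
    paired_mafs: list[tuple[float, float]] = field(default_factory=list)
    opa: float | None = None
    ppa: float | None = None
    npa: float | None = None
    discordant_ids: list[str] = field(default_factory=list)
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    p_value: float | None = None
    orientation: str = "method_a_is_comparator"


def summarize_level(run: ReferenceLevelRun) -> LevelSummary:
    """Mean and sample (n-1) standard deviation of the present dCt values."""
    present = run.present_values
    mean = float(np.mean(present)) if present else None
    sd = float(np.std(present, ddof=1)) if len(present) >= 2 else None
    return LevelSummary(
        level_maf=run.level_maf,
        n_present=len(present),
        mean_delta_ct=mean,
        sd_delta_ct=sd,
        n_absent=run.n_absent,
    )


def derive_cutoff(wild_type_delta_cts: list[float], guard: float = 0.0) -> float:
    """Largest dCt cut-off that classifies no supplied wild-type observation
    as detected, minus a safety ``guard``.

    Works on magnitudes so either dCt sign convention can be fed in.
    """
    present = [abs(v) for v in wild_type_delta_cts if v is not None]
    if not present:
        raise CalibrationError("no wild-type dCt observations supplied")
    return min(present) - guard


def estimate_lob(
    panel: BlankPanel, confidence: float = 0.95, method: str = "parametric"
) -> float:
    """Limit of blank as a MAF fraction.

    ``parametric``: mean + z(confidence) * SD with the one-sided normal
    quantile (z = 1.645 at 95%).  ``nonparametric``: the empirical percentile
    at ``confidence`` with linear interpolation, requiring n >= 20 for a
    stable upper tail.
    """
    if not 0.0 < confidence < 1.0:
        raise ParameterError("confidence must lie in (0, 1)")
    values = np.asarray(panel.blank_mafs, dtype=float)
    if method == "parametric":
        if panel.n < 2:
            raise ParameterError("parametric LoB needs >= 2 blank measurements")
        return float(values.mean() + stats.norm.ppf(confidence) * values.std(ddof=1))
    if method == "nonparametric":
        if panel.n < 20:
            raise ParameterError("nonparametric LoB needs >= 20 blank measurements")
        return float(np.quantile(values, confidence, method="linear"))
    raise ParameterError(f"unknown LoB method {method!r}")


def classify_maf(maf: float, profile: MethodProfile) -> Call:
    """Qualitative call of a quantitative MAF against a method's cut-off."""
    return Call.DETECTED if maf >= profile.detection_cutoff_maf else Call.NOT_DETECTED


def hit_rate_by_level(calls: MafTable) -> dict[float, float]:
    """Fraction of replicates called detected at each expected level,
    keyed by level MAF ascending."""
    rates: dict[float, float] = {}
    for level in calls.levels():
        recs = [r for r in calls.records if r.level_expected_maf == level]
        rates[level] = sum(r.call is Call.DETECTED for r in recs) / len(recs)
    return rates


def concordance(
    calls_a: dict[str, Call] | list[tuple[str, Call]],
    calls_b: dict[str, Call] | list[tuple[str, Call]],
) -> MethodComparison:
    """Qualitative agreement between two methods on the same samples.

    OPA = concordant / total; PPA and NPA are computed with method A as the
    comparator.  PPA (or NPA) is None when A has no positives (negatives).
    """
    a = dict(calls_a)
    b = dict(calls_b)
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))
        only_b = sorted(set(b) - set(a))
        raise PairingError(f"sample sets differ (only in A: {only_a}, only in B: {only_b})")
    if not a:
        raise PairingError("no paired samples supplied")
    paired = [(sid, a[sid], b[sid]) for sid in sorted(a)]
    agree = [sid for sid, ca, cb in paired if ca is cb]
    a_pos = [(ca, cb) for _, ca, cb in paired if ca is Call.DETECTED]
    a_neg = [(ca, cb) for _, ca, cb in paired if ca is Call.NOT_DETECTED]
    opa = 100.0 * len(agree) / len(paired)
    ppa = 100.0 * sum(cb is Call.DETECTED for _, cb in a_pos) / len(a_pos) if a_pos else None
    npa = 100.0 * sum(cb is Call.NOT_DETECTED for _, cb in a_neg) / len(a_neg) if a_neg else None
    return MethodComparison(
        paired_calls=paired,
        opa=opa,
        ppa=ppa,
        npa=npa,
        discordant_ids=[sid for sid, ca, cb in paired if ca is not cb],
    )


def regress_maf(pairs: list[tuple[float, float]]) -> MethodComparison:
    """Ordinary least squares of method B on method A over paired MAFs.

    Returns slope, intercept, R^2 (squared Pearson correlation) and the
    standard t-based p-value of the slope.
    """
    if len(pairs) < 3:
        raise RegressionError(f"need >= 3 pairs, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if math.isclose(float(x.var()), 0.0, abs_tol=1e-30):
        raise RegressionError("method A values have zero variance")
    fit = stats.linregress(x, y)
    return MethodComparison(
        paired_mafs=list(pairs),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def pair_replicates_to_level(table: MafTable, include_blank: bool = True) -> list[tuple[float, float]]:
    """Pair each replicate's method-B MAF with its level's method-A value.

    With a single comparator measurement per level, every replicate at that
    level shares the same method-A abscissa.  ``include_blank`` keeps or drops
    the zero-expected-MAF level; including it is the default pairing for
    cross-method regression.
    """
    pairs = []
    for r in table.records:
        if not include_blank and r.level_expected_maf == 0.0:
            continue
        pairs.append((r.method_a_maf, r.method_b_maf))
    return pairs
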