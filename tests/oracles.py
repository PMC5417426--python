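"""Independent reference implementations used as test oracles.

These are deliberately written as literal transcriptions (decision-table rows,
two-pass statistics, textbook regression formulas) so they share no code path
with the package implementations they check.
"""

from __future__ import annotations

import math


def decision_table_classify(ct_ref, ct_mut, ipc_mut_ok, ipc_ref_ok, rules):
    """Row-by-row transcription of the printed interpretation table.

    Returns (state, recommendation, confirmed) as plain strings/bool.
    Rows are checked in the printed order: IPC, reference window, then the
    mutant-assay rows on dCt and mutant Ct.
    """
    if not (ipc_mut_ok and ipc_ref_ok):
        return ("assay_fail", "repeat_sample", False)
    if ct_ref is not None and ct_ref < rules.ref_ct_min:
        return ("reference_fail", "repeat_less_dna", False)
    if ct_ref is None or ct_ref > rules.ref_ct_max:
        return ("reference_fail", "repeat_more_dna", False)
    # reference assay passed; evaluate the mutant-assay rows
    if ct_mut is None:
        # no mutant signal: negative unless a mutant Ct just beyond the
        # evaluable bound would still fall under the detection cut-off
        if rules.mut_ct_max - ct_ref < rules.delta_ct_detect:
            return ("undetermined", "repeat_duplicate_undetermined", False)
        return ("mutation_not_detected", "none", False)
    delta = ct_mut - ct_ref
    rows = [
        # (mutant Ct condition, dCt condition, state, recommendation, confirmed)
        (ct_mut > rules.mut_ct_max, delta < rules.delta_ct_detect,
         "undetermined", "repeat_duplicate_undetermined", False),
        (True, delta >= rules.delta_ct_detect,
         "mutation_not_detected", "none", False),
        (ct_mut <= rules.mut_ct_max, delta < rules.delta_ct_confirm_band_low,
         "mutation_detected", "none", True),
        (ct_mut <= rules.mut_ct_max,
         rules.delta_ct_confirm_band_low <= delta < rules.delta_ct_detect,
         "mutation_detected", "repeat_duplicate_confirm", False),
    ]
    for ct_cond, dct_cond, state, rec, confirmed in rows:
        if ct_cond and dct_cond:
            return (state, rec, confirmed)
    raise AssertionError(f"decision table has a hole at ct_ref={ct_ref}, ct_mut={ct_mut}")


def two_pass_mean_sd(values):
    """Two-pass mean and n-1 standard deviation, plain Python."""
    n = len(values)
    if n == 0:
        return None, None
    mean = sum(values) / n
    if n == 1:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def ols_direct(pairs):
    """Slope/intercept/R^2 from the covariance formulas, plain Python."""
    n = len(pairs)
    mx = sum(p[0] for p in pairs) / n
    my = sum(p[1] for p in pairs) / n
    sxy = sum((x - mx) * (y - my) for x, y in pairs)
    sxx = sum((x - mx) ** 2 for x, _ in pairs)
    syy = sum((y - my) ** 2 for _, y in pairs)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else float("nan")
    return slope, intercept, r2


def min_minus_guard(values, guard):
    """Exhaustive-scan cut-off: the largest threshold with zero observed
    wild-type positives, minus the guard."""
    best = None
    for v in values:
        m = abs(v)
        if best is None or m < best:
            best = m
    return best - guard
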