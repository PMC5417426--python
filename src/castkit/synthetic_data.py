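"""Generators emulating allele-specific qPCR and digital-PCR measurements.

The qPCR model is a log-linear idealization of the two-well assay: with
amplification efficiency ``E`` (1 = perfect doubling), a reaction seeded with
``s`` amplifiable copies crosses threshold at

    Ct = intercept - log(s) / log(1 + E) + noise,

with the mutant-assay intercept sitting ``assay_offset_delta`` cycles above
the reference intercept (the blocker and allele-specific priming cost cycles
even on pure mutant template).  The blocker is imperfect: a fraction
``wt_breakthrough`` of wild-type copies amplifies in the mutant assay, which
sets the deep-negative dCt floor seen on mutation-negative material.  In the
noise-free limit with no breakthrough and E = 1 this gives the closed form
dCt = log2(1/MAF) + assay_offset_delta.  Reactions whose Ct lands beyond
``no_signal_ct`` report no signal — the censoring that produces "-" entries
in replicate run tables.  Formalin-fixed (FFPE) material is emulated purely
as inflated Ct noise.

Digital PCR is modelled per molecule: each loaded molecule is mutant with
probability ``maf + (1 - maf) * error_rate``, the error term emulating the
polymerase-induced false-mutant floor (G>A-like) of bead-emulsion assays.

All randomness flows through an explicit ``numpy.random.Generator``; when the
Ct noise SD is zero the qPCR generator also uses expected (non-Poisson)
template counts, so the deterministic limit is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .plate_model import (
    AssayRole,
    Material,
    Plate,
    ReferenceLevelRun,
    WellKind,
    WellMeasurement,
)

__all__ = [
    "QpcrSimParams",
    "DigitalSimParams",
    "simulate_qpcr_sample",
    "simulate_reference_series",
    "simulate_digital_measurement",
    "simulate_cohort",
]


@dataclass(frozen=True)
class QpcrSimParams:
    """Tunables of the qPCR measurement model.

    Defaults are calibrated once against the replicate behaviour of published
    heterozygous-line reference standards: ``assay_offset_delta = 3.5`` cycles
    reproduces a dCt near 4.5 on 50% MAF material and ``wt_breakthrough =
    6.3e-5`` puts the mutation-negative dCt floor near 17.5 cycles.
    ``ct_noise_sd_base`` is the per-reaction Ct noise; dCt is a difference of
    two reactions, so its SD is sqrt(2) times larger — 0.17 cycles per
    reaction gives the 0.24-cycle dCt dispersion of high-quality material,
    and the x2.1 FFPE multiplier its 0.50-cycle counterpart.
    """

    intercept_reference: float = 37.0
    assay_offset_delta: float = 3.5
    efficiency: float = 1.0
    wt_breakthrough: float = 6.3e-5
    ct_noise_sd_base: float = 0.17
    ffpe_noise_multiplier: float = 2.1
    ipc_ct_mean: float = 24.0
    no_signal_ct: float = 40.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.wt_breakthrough < 1.0:
            raise ParameterError("wt_breakthrough must lie in [0, 1)")
        if not 0.0 < self.efficiency <= 1.0:
            raise ParameterError("efficiency must lie in (0, 1]")
        if self.ct_noise_sd_base < 0 or self.ffpe_noise_multiplier < 0:
            raise ParameterError("noise parameters must be >= 0")

    @property
    def intercept_mutant(self) -> float:
        return self.intercept_reference + self.assay_offset_delta

    def noise_sd(self, material: Material) -> float:
        mult = self.ffpe_noise_multiplier if material is Material.FFPE else 1.0
        return self.ct_noise_sd_base * mult

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class DigitalSimParams:
    """Tunables of the per-molecule digital-PCR model.

    ``molecules_loaded`` defaults to a 2 mL plasma input at 6e4 locus
    copies/mL; ``error_rate = 3.5e-5`` is calibrated to the 0.003-0.004%
    false-mutant floor bead-emulsion assays show on blank plasma.
    """

    n_partitions: int = 3_000_000
    molecules_loaded: int = 120_000
    error_rate: float = 3.5e-5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.001:
            raise ParameterError("error_rate must lie in [0, 0.001]")
        if self.n_partitions <= 0 or self.molecules_loaded <= 0:
            raise ParameterError("counts must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _ct_from_copies(copies: float, intercept: float, efficiency: float) -> float | None:
    if copies <= 0:
        return None
    return intercept - math.log(copies) / math.log(1.0 + efficiency)


def simulate_qpcr_sample(
    maf: float,
    total_copies: float,
    material: Material,
    params: QpcrSimParams,
    rng: np.random.Generator,
) -> tuple[float | None, float | None, float]:
    """Simulate one sample's (reference Ct, mutant Ct, IPC Ct).

    ``total_copies`` is the locus copy number loaded into each reaction.  The
    mutant template count is Poisson around ``maf * total_copies`` (expected
    count exactly when the noise SD is zero); the mutant assay additionally
    sees ``wt_breakthrough`` of the wild-type copies.  Either Ct is absent
    when its reaction has nothing to amplify or would cross threshold after
    ``no_signal_ct`` cycles.
    """
    if not 0.0 <= maf <= 1.0:
        raise ParameterError("maf must lie in [0, 1]")
    if total_copies <= 0:
        raise ParameterError("total_copies must be > 0")
    sd = params.noise_sd(material)
    deterministic = sd == 0.0
    m = maf * total_copies if deterministic else float(rng.poisson(maf * total_copies))
    s = m + params.wt_breakthrough * (total_copies - m)

    ct_ref = _ct_from_copies(total_copies, params.intercept_reference, params.efficiency)
    ct_mut = _ct_from_copies(s, params.intercept_mutant, params.efficiency)
    if not deterministic:
        if ct_ref is not None:
            ct_ref += rng.normal(0.0, sd)
        if ct_mut is not None:
            ct_mut += rng.normal(0.0, sd)
    if ct_ref is not None and ct_ref > params.no_signal_ct:
        ct_ref = None
    if ct_mut is not None and ct_mut > params.no_signal_ct:
        ct_mut = None
    ipc = params.ipc_ct_mean if deterministic else params.ipc_ct_mean + rng.normal(0.0, 0.1)
    return ct_ref, ct_mut, ipc


def simulate_reference_series(
    levels: list[float],
    runs: int,
    material: Material,
    params: QpcrSimParams,
    rng: np.random.Generator,
    copies_per_ml: float = 2e5,
    reaction_fraction_ml: float = 0.06,
) -> list[ReferenceLevelRun]:
    """Simulate a replicate run table: ``runs`` dCt values per level.

    ``reaction_fraction_ml`` converts the standard's concentration into the
    copies actually loaded per reaction (default 0.06 mL-equivalents, i.e.
    1.2e4 copies from a 2e5 copies/mL standard — a 20 ng load at 3.3 pg per
    haploid equivalent).  dCt entries are absent whenever the mutant assay
    produced no Ct.
    """
    if runs < 1:
        raise ParameterError("runs must be >= 1")
    total_copies = copies_per_ml * reaction_fraction_ml
    out = []
    for level in levels:
        values: list[float | None] = []
        for _ in range(runs):
            ct_ref, ct_mut, _ipc = simulate_qpcr_sample(level, total_copies, material, params, rng)
            if ct_ref is None or ct_mut is None:
                values.append(None)
            else:
                values.append(ct_mut - ct_ref)
        out.append(
            ReferenceLevelRun(
                level_maf=level,
                input_copies_per_ml=copies_per_ml,
                delta_ct_values=values,
                material=material,
            )
        )
    return out


def simulate_digital_measurement(
    maf_true: float,
    params: DigitalSimParams,
    rng: np.random.Generator,
) -> tuple[float, int, int]:
    """Simulate one digital-PCR MAF measurement.

    Returns ``(observed_maf, mutant_count, total_count)``.  Expectation of the
    observed MAF is ``maf_true + (1 - maf_true) * error_rate``.
    """
    if not 0.0 <= maf_true <= 1.0:
        raise ParameterError("maf_true must lie in [0, 1]")
    p = maf_true + (1.0 - maf_true) * params.error_rate
    k = int(rng.binomial(params.molecules_loaded, p))
    return k / params.molecules_loaded, k, params.molecules_loaded


def simulate_cohort(
    n_samples: int,
    prevalence: float,
    material: Material,
    params: QpcrSimParams,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.05, 0.5),
    total_copies: float = 12_000.0,
    samples_per_plate: int = 48,
    positive_control_maf: float = 0.5,
) -> tuple[list[Plate], dict[str, float]]:
    """Simulate a screening cohort as ready-to-call plates plus truth labels.

    Each sample is mutation-bearing with probability ``prevalence``; its MAF
    is drawn uniformly from ``maf_range`` (a tumor-content-bounded range),
    wild-type samples have MAF 0.  Plates carry ``samples_per_plate`` samples,
    two clean no-template controls and one positive-control admixture.
    Returns the plates and a map of sample id to true MAF (0.0 = wild type).
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    if not 0.0 <= prevalence <= 1.0:
        raise ParameterError("prevalence must lie in [0, 1]")
    truth: dict[str, float] = {}
    plates: list[Plate] = []
    n_plates = math.ceil(n_samples / samples_per_plate)
    sample_no = 0
    for p in range(n_plates):
        wells: list[WellMeasurement] = []
        for i in range(2):
            wells.append(
                WellMeasurement(f"NTC{i + 1}", AssayRole.MUTANT, None, params.ipc_ct_mean, WellKind.NTC)
            )
            wells.append(
                WellMeasurement(f"NTC{i + 1}", AssayRole.REFERENCE, None, params.ipc_ct_mean, WellKind.NTC)
            )
        ct_ref, ct_mut, ipc = simulate_qpcr_sample(
            positive_control_maf, total_copies, material, params, rng
        )
        wells.append(WellMeasurement("PC1", AssayRole.MUTANT, ct_mut, ipc, WellKind.POSITIVE_CONTROL))
        wells.append(WellMeasurement("PC1", AssayRole.REFERENCE, ct_ref, ipc, WellKind.POSITIVE_CONTROL))
        for _ in range(min(samples_per_plate, n_samples - sample_no)):
            sample_no += 1
            sid = f"S{sample_no:04d}"
            is_mut = rng.random() < prevalence
            maf = float(rng.uniform(*maf_range)) if is_mut else 0.0
            truth[sid] = maf
            ct_ref, ct_mut, ipc = simulate_qpcr_sample(maf, total_copies, material, params, rng)
            wells.append(WellMeasurement(sid, AssayRole.MUTANT, ct_mut, ipc, WellKind.SAMPLE))
            wells.append(WellMeasurement(sid, AssayRole.REFERENCE, ct_ref, ipc, WellKind.SAMPLE))
        plates.append(Plate(plate_id=f"plate{p + 1:02d}", wells=wells).validate())
    return plates, truth
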