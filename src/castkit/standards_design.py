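"""Calculators for DNA admixture reference standards and plasma spike-ins.

A mutation-positive reference standard is built by blending DNA from a
mutant-bearing cell line (usually heterozygous, so half its alleles at the
locus carry the mutation) into wild-type DNA.  To hit a target mutant allele
fraction (MAF) ``m`` with a line of allelic fraction ``f``, a fraction
``g = m / f`` of the blended genomes must come from the mutant line.  Masses
follow from the genomic-equivalent mass (3.3 pg per haploid equivalent by
default), and circulating-tumor-DNA standards add a dilution correction for
wild-type locus copies already present in the carrier plasma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import DesignError, ParameterError

__all__ = [
    "GenomeModel",
    "AdmixtureRecipe",
    "SpikePlan",
    "copies_to_mass",
    "design_admixture",
    "design_spike",
]

logger = logging.getLogger(__name__)

PG_PER_NG = 1000.0


@dataclass(frozen=True)
class GenomeModel:
    """Constants linking copies, mass and allele counts.

    ``pg_per_genomic_equivalent`` converts one counted copy to mass (3.3 pg
    per haploid genomic equivalent).  ``copies_unit`` records whether counted
    copies are haploid locus copies or diploid genomes; it changes reported
    allele counts only — mass arithmetic and blend fractions are invariant.
    """

    pg_per_genomic_equivalent: float = 3.3
    alleles_per_genome: int = 2
    mutant_line_maf: float = 0.5
    copies_unit: str = "locus"

    def __post_init__(self) -> None:
        if self.pg_per_genomic_equivalent <= 0:
            raise ParameterError("pg_per_genomic_equivalent must be > 0")
        if not 0.0 < self.mutant_line_maf <= 1.0:
            raise ParameterError("mutant_line_maf must lie in (0, 1]")
        if self.copies_unit not in ("locus", "genome"):
            raise ParameterError("copies_unit must be 'locus' or 'genome'")

    def alleles_per_copy(self) -> int:
        return 1 if self.copies_unit == "locus" else self.alleles_per_genome


@dataclass
class AdmixtureRecipe:
    """Blend of mutant-line and wild-type DNA hitting a target MAF."""

    target_maf: float
    total_copies_per_ml: float
    fraction_mutant_line_genomes: float
    mass_mutant_line_per_ml: float  # pg/mL
    mass_wildtype_per_ml: float  # pg/mL
    model: GenomeModel = field(default_factory=GenomeModel)

    def achieved_maf(self) -> float:
        """Forward-computed MAF of the blend (round-trip check)."""
        mutant_alleles = (
            self.fraction_mutant_line_genomes
            * self.total_copies_per_ml
            * self.model.alleles_per_copy()
            * self.model.mutant_line_maf
        )
        total_alleles = self.total_copies_per_ml * self.model.alleles_per_copy()
        return mutant_alleles / total_alleles

    def total_mass_per_ml(self) -> float:
        return self.mass_mutant_line_per_ml + self.mass_wildtype_per_ml


@dataclass
class SpikePlan:
    """Spike of sheared admixture DNA into carrier plasma.

    The plasma contributes ``background_wt_copies_per_ml`` wild-type locus
    copies, so each level's admixture MAF is inflated by
    ``target_total / spike`` to land on the requested final MAF after
    dilution.
    """

    target_total_copies_per_ml: float
    background_wt_copies_per_ml: float
    spike_copies_per_ml: float
    levels: list[float]
    admixture_mafs: list[float]
    recipes: list[AdmixtureRecipe]
    fragment_size_bp: float = 170.0  # documentation only; enters no arithmetic

    def achieved_level(self, i: int) -> float:
        """Final plasma MAF of level *i*, forward-computed."""
        mutant = self.admixture_mafs[i] * self.spike_copies_per_ml
        return mutant / self.target_total_copies_per_ml


def copies_to_mass(copies: float, model: GenomeModel = GenomeModel()) -> float:
    """Mass in pg of ``copies`` counted genomic equivalents."""
    if copies < 0:
        raise ParameterError(f"copies must be >= 0, got {copies}")
    return copies * model.pg_per_genomic_equivalent


def design_admixture(
    target_maf: float,
    total_copies_per_ml: float,
    model: GenomeModel = GenomeModel(),
) -> AdmixtureRecipe:
    """Blend fractions and masses to reach ``target_maf`` at a fixed total
    copy concentration.

    Infeasible when the target exceeds the mutant line's own allelic fraction
    (no amount of blending can concentrate the mutant allele).
    """
    if not 0.0 <= target_maf <= 1.0:
        raise ParameterError("target_maf must lie in [0, 1]")
    if total_copies_per_ml < 0:
        raise ParameterError("total_copies_per_ml must be >= 0")
    if target_maf > model.mutant_line_maf:
        raise DesignError(
            f"target MAF {target_maf} exceeds the mutant line's allelic fraction "
            f"{model.mutant_line_maf}"
        )
    g = target_maf / model.mutant_line_maf
    mutant_copies = g * total_copies_per_ml
    wildtype_copies = (1.0 - g) * total_copies_per_ml
    return AdmixtureRecipe(
        target_maf=target_maf,
        total_copies_per_ml=total_copies_per_ml,
        fraction_mutant_line_genomes=g,
        mass_mutant_line_per_ml=copies_to_mass(mutant_copies, model),
        mass_wildtype_per_ml=copies_to_mass(wildtype_copies, model),
        model=model,
    )


def design_spike(
    levels: list[float],
    target_total: float,
    background: float = 0.0,
    model: GenomeModel = GenomeModel(),
) -> SpikePlan:
    """Plan spiking sheared admixtures into plasma.

    ``target_total`` is the wanted locus-copy concentration in the final
    plasma (copies/mL), ``background`` the wild-type copies the plasma already
    carries.  Each level's admixture is designed at an inflated MAF so the
    final plasma MAF equals the requested level after background dilution.
    """
    if background >= target_total:
        raise DesignError(
            f"plasma background ({background}/mL) already meets or exceeds the "
            f"target copy concentration ({target_total}/mL)"
        )
    if background == 0.0:
        logger.warning(
            "design_spike: plasma background copies assumed 0/mL; supply a measured "
            "value for quantitative spike levels"
        )
    spike = target_total - background
    admix_mafs = []
    recipes = []
    for level in levels:
        if not 0.0 <= level <= 1.0:
            raise ParameterError(f"spike level must be a fraction, got {level}")
        admix_maf = level * target_total / spike
        if admix_maf > model.mutant_line_maf:
            raise DesignError(
                f"level {level} needs an admixture MAF of {admix_maf}, beyond the "
                f"mutant line's allelic fraction {model.mutant_line_maf}"
            )
        admix_mafs.append(admix_maf)
        recipes.append(design_admixture(admix_maf, spike, model))
    return SpikePlan(
        target_total_copies_per_ml=target_total,
        background_wt_copies_per_ml=background,
        spike_copies_per_ml=spike,
        levels=list(levels),
        admixture_mafs=admix_mafs,
        recipes=recipes,
    )
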