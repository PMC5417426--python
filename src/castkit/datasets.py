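"""Bundled example datasets.

Two small delimited tables from a published analytical validation of AKT1
E17K mutation detection are shipped with the package:

* ``akt1_e17k_reference_runs.csv`` — replicate castPCR dCt results of two DNA
  reference standards (high-quality cell-line admixtures and FFPE cell-line
  admixtures) across eleven runs per level, including mutation-negative
  levels at two copy concentrations.  Values are printed in the
  reference-minus-mutant sign convention (negative dCt on mutant-bearing
  material) and mix hyphen-minus and en-dash signs, as instrument/report
  exports often do; "-" marks runs where the mutant assay produced no Ct.
* ``akt1_e17k_beaming_vs_ddpcr.csv`` — triplicate bead-emulsion digital PCR
  (method B) MAF measurements of a ctDNA reference standard at six expected
  levels, paired with one droplet-digital-PCR measurement per level
  (method A), plus the qualitative calls at the 0.02% cut-off.
"""

from __future__ import annotations

from importlib import resources

from .plate_model import Dialect, MafTable, ReferenceLevelRun, read_maf_table, read_reference_runs

__all__ = ["load_reference_standard_runs", "load_ctdna_maf_table"]


def _data_path(name: str):
    return resources.files("castkit.data").joinpath(name)


def load_reference_standard_runs(normalize_sign: bool = False) -> list[ReferenceLevelRun]:
    """The bundled replicate reference-standard run table.

    By default values keep the printed reference-minus-mutant sign (negative
    on mutant-bearing levels); pass ``normalize_sign=True`` to flip to the
    package's stored mutant-minus-reference convention.
    """
    dialect = Dialect(negated_delta_ct=normalize_sign)
    with resources.as_file(_data_path("akt1_e17k_reference_runs.csv")) as path:
        return read_reference_runs(path, dialect)


def load_ctdna_maf_table() -> MafTable:
    """The bundled cross-method ctDNA MAF table (fractions in memory)."""
    with resources.as_file(_data_path("akt1_e17k_beaming_vs_ddpcr.csv")) as path:
        return read_maf_table(path)
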