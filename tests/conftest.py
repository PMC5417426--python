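import textwrap

import pytest

from castkit import RuleSet, load_ctdna_maf_table, load_reference_standard_runs


@pytest.fixture(scope="session")
def rules():
    return RuleSet()


@pytest.fixture(scope="session")
def reference_runs():
    """Bundled replicate reference-standard run table (printed sign)."""
    return load_reference_standard_runs()


@pytest.fixture(scope="session")
def maf_table():
    """Bundled triplicate digital-PCR vs ddPCR MAF table (fractions)."""
    return load_ctdna_maf_table()


@pytest.fixture
def plate_csv(tmp_path):
    """Write a plate CSV from inline text and return its path."""

    def _write(text, name="plate.csv"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text).strip() + "\n", encoding="utf-8")
        return path

    return _write


#: two-well export of the worked example: reference Ct 23.5, mutant Ct 27.5
FIG_EXAMPLE_PLATE = """
sample_id,assay_role,ct,ipc_ct,well_kind
S1,mutant,27.5,24.0,sample
S1,reference,23.5,24.1,sample
NTC1,mutant,Undetermined,24.0,ntc
NTC1,reference,Undetermined,24.2,ntc
NTC2,mutant,-,24.1,ntc
NTC2,reference,,24.0,ntc
"""
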