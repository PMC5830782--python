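import pytest

import pouchyoung as py


@pytest.fixture
def reference_table() -> py.MeasurementTable:
    """Published litter-mean CRL series (thylacine litters only)."""
    return py.reference_crl_table()


@pytest.fixture
def two_anchor_model() -> py.GrowthModel:
    """CRL growth line through the neonate (1.5 wk) and oldest (12 wk) anchors."""
    anchors = py.reference_anchors()["crown_rump_length"]
    return py.fit_growth_line([(a.age, a.length) for a in anchors])


@pytest.fixture
def measurement_csv(tmp_path):
    """Write a long-format measurement CSV and return its path."""

    def _write(rows, header="specimen_id,litter_id,trait,bone_context,side,value,unit"):
        path = tmp_path / "measurements.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write
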