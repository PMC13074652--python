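import pytest

from pepperfw.synthetic import DesignRow, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-design dataset (303 records, seed 42)."""
    return generate_dataset(SimConfig(seed=42))


def small_design(n_per_cell: int = 8):
    """A compact 2-treatment, 4-stage design for fast CV-level tests."""
    rows = []
    for trt in ("CT", "FR"):
        for dat in (40, 80, 120, 150):
            rows.append(DesignRow(2021, "spring", "Mavera", trt, dat, n_per_cell))
    return tuple(rows)


@pytest.fixture(scope="session")
def small_dataset():
    """64 records over 8 groups; enough structure for model fits."""
    return generate_dataset(SimConfig(design=small_design(), seed=7))
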