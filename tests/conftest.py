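import numpy as np
import pandas as pd
import pytest

from aggregome.io import SampleDesign, SampleInfo


@pytest.fixture
def small_design() -> SampleDesign:
    """4 vs 4 aggregate-fraction design."""
    samples = [
        SampleInfo(label=f"case_{i}", condition="case", replicate=i) for i in range(1, 5)
    ] + [
        SampleInfo(label=f"ctrl_{i}", condition="control", replicate=i) for i in range(1, 5)
    ]
    return SampleDesign(samples)


@pytest.fixture
def protein_groups_file(tmp_path, small_design):
    """MaxQuant-dialect fixture: 3 rows, one reverse-flagged, one zero
    intensity (= non-detection)."""

    def _write(rows=None):
        header = (
            ["Majority protein IDs", "Gene names", "Razor + unique peptides"]
            + [f"LFQ intensity {label}" for label in small_design.labels]
            + ["Potential contaminant", "Reverse"]
        )
        rows = rows if rows is not None else [
            ["P10000;Q10000", "GENA", "4"] + ["8"] * 8 + ["", ""],
            ["P20000", "GENB;ALTB", "3"] + ["0"] + ["16"] * 7 + ["", "+"],
            ["P30000", "GENC", "2"] + ["32"] * 8 + ["+", ""],
        ]
        path = tmp_path / "proteinGroups.txt"
        path.write_text("\n".join("\t".join(r) for r in [header, *rows]) + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_log_matrix(values, design):
    """Log-intensity matrix helper for diffagg tests."""
    from aggregome.diffagg import LogIntensityMatrix

    frame = pd.DataFrame(
        np.asarray(values, dtype=float),
        columns=design.labels,
        index=[f"P{i}" for i in range(len(values))],
    )
    return LogIntensityMatrix(values=frame, design=design)
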