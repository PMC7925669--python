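import numpy as np
import pandas as pd
import pytest

import dietmap as dm


@pytest.fixture(scope="session")
def tiny_atlas() -> dm.LabelAtlas:
    """16^3 grid, 6 contiguous structures, deterministic."""
    return dm.make_synthetic_atlas((16, 16, 16), 6, seed=1)


@pytest.fixture(scope="session")
def printed_cohort():
    """Offspring and dam tables replicating the study's printed scan counts."""
    return dm.make_design()


def balanced_design(n_per_cell: int, with_sex: bool = True) -> dm.SubjectTable:
    rows = []
    for diet in ("LF10", "HF45", "HF60"):
        sexes = ("F", "M") if with_sex else (None,)
        for sex in sexes:
            for i in range(n_per_cell):
                row = {
                    "subject_id": f"{diet}_{sex or 'x'}_{i}",
                    "diet": diet,
                    "fat_pct": dm.DIET_FAT_PCT[diet],
                }
                if with_sex:
                    row["sex"] = sex
                rows.append(row)
    return dm.SubjectTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_design() -> dm.SubjectTable:
    """Balanced 4-per-cell factorial design (24 subjects)."""
    return balanced_design(4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
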