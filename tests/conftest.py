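import numpy as np
import pandas as pd
import pytest

from thermolipids.nomenclature import (
    ARCHAEAL_CLASSES,
    NONARCHAEAL_CLASSES,
    example_species_for_class,
)
from thermolipids.quantification import annotate_lipids
from thermolipids.synthdata import SyntheticConfig, generate_dataset


def make_abundance(rows, sample_id="smp1"):
    """Build an annotated abundance table from (lipid, concentration) pairs."""
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "lipid": [r[0] for r in rows],
            "concentration_ug_g": [r[1] for r in rows],
        }
    )
    return annotate_lipids(df)


@pytest.fixture(scope="session")
def species_catalogue():
    """Parseable species names covering every registry class plus ring,
    double-bond and methyl variants."""
    names = []
    for cls in ARCHAEAL_CLASSES:
        if cls == "G-AR":
            names.append("G-AR")
        elif "Uns" in cls:
            names += [f"{cls}-0:{d}" for d in (1, 2, 4)]
        elif cls in ("G-GDGT", "2G-GDGT"):
            names += [f"{cls}-{r}" for r in range(5)]
            if cls == "G-GDGT":
                names.append("G-GDGT-Cren")
        else:
            max_r = 2
            names += [f"{cls}-{r}" for r in range(max_r + 1)]
    # archaeal core pool
    names += [f"GDGT-{r}" for r in range(5)] + ["GDGT-Cren", "Uns-GDGT-0:2"]
    names += ["H-GDGT-0", "H-GDGT-2", "H-1Me-GDGT-0", "H-3Me-GDGT-1", "H-4Me-GDGT-0"]
    for cls in NONARCHAEAL_CLASSES:
        sp = example_species_for_class(cls)
        names.append(sp.canonical_name)
        if cls.startswith("sP"):
            names.append(f"{cls}-CER(20:1/16:0)")
        else:
            names += [f"{cls}-DAG(30:0)", f"{cls}-DAG(36:2)"]
    assert len(names) == len(set(names))
    return names


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default synthetic dataset shared across tests."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_abundance(default_dataset):
    from thermolipids.quantification import quantify

    return quantify(
        default_dataset.peaks,
        default_dataset.metadata,
        default_dataset.response_factors,
    )
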