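import numpy as np
import pandas as pd
import pytest

from endoprofiler.io_model import (
    AnnotationTable,
    ChannelDesign,
    ProteinQuantTable,
)
from endoprofiler.synthetic_data import TruthSpec, generate_proteomics


@pytest.fixture(scope="session")
def design() -> ChannelDesign:
    return ChannelDesign.default_8plex()


@pytest.fixture
def small_quant(design) -> ProteinQuantTable:
    """Three hand-written proteins with simple round-number intensities."""
    rows = {
        "A": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 4.0, 6.0],
        "B": [8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0],
        "C": [100.0, 90.0, 80.0, 10.0, 20.0, 30.0, 5.0, 5.0],
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(design.channel_ids))
    df.insert(0, "unique_peptides", [3, 1, 5])
    df.index.name = "protein_id"
    return ProteinQuantTable(data=df, design=design)


@pytest.fixture
def small_annotations() -> AnnotationTable:
    df = pd.DataFrame(
        {
            "has_signal_peptide": [True, False, True],
            "has_tm_domain": [False, False, True],
            "is_secreted": [True, False, False],
            "gene_id": ["g_A", "g_B", "g_C"],
            "receptor_ids": [("C",), (), ()],
        },
        index=pd.Index(["A", "B", "C"], name="protein_id"),
    )
    return AnnotationTable(data=df)


@pytest.fixture(scope="session")
def default_synthetic():
    """One shared draw at the default study conditions (G = 2,000)."""
    spec = TruthSpec(seed=20)
    return spec, generate_proteomics(spec)


@pytest.fixture(scope="session")
def clean_synthetic():
    """Zero-noise, all-proteins-quantifiable draw for exactness checks."""
    spec = TruthSpec(
        n_proteins=400, noise_sd_log2=0.0, frac_low_peptide=0.0, seed=21
    )
    return spec, generate_proteomics(spec)


def random_quant_frame(rng: np.random.Generator, design: ChannelDesign, n: int) -> pd.DataFrame:
    df = pd.DataFrame(
        rng.uniform(1.0, 1e6, size=(n, len(design.channel_ids))),
        index=pd.Index([f"P{i}" for i in range(n)], name="protein_id"),
        columns=list(design.channel_ids),
    )
    df.insert(0, "unique_peptides", rng.integers(1, 20, size=n))
    return df
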