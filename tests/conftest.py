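import numpy as np
import pandas as pd
import pytest

from ntermflow.io_formats import AnalysisConfig, Compartment, ProteinEntry, QuantTable, design_from_columns


@pytest.fixture
def cfg():
    return AnalysisConfig(rng_seed=42)


@pytest.fixture
def plastid_protein():
    """Plastid-targeted protein, 100 residues, transit peptide ends at 50."""
    rng = np.random.default_rng(7)
    seq = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=99))
    return ProteinEntry("PLAST1", seq, Compartment.PLASTID, cleavage_pos=50)


@pytest.fixture
def tiny_proteome():
    return {
        "P1": ProteinEntry("P1", "MASTKLLQEGR"),
        "P2": ProteinEntry(
            "P2", "M" + "A" * 59 + "SERLK" + "G" * 35, Compartment.PLASTID, cleavage_pos=60
        ),
        "P3": ProteinEntry(
            "P3", "M" + "C" * 44 + "TLDHR" + "W" * 50, Compartment.MITOCHONDRION, cleavage_pos=45
        ),
    }


def make_quant_table(values, genotypes=("wt", "mi", "ox"), n_reps=4, index=None):
    """QuantTable from a (features x samples) array; NaN = missing."""
    cols = [f"{g}_{r}" for g in genotypes for r in range(1, n_reps + 1)]
    values = np.asarray(values, dtype=float)
    idx = index if index is not None else [f"prot{i}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(idx, name="accession"), columns=cols)
    return QuantTable(data=data, design=design_from_columns(cols))


@pytest.fixture
def quant_factory():
    return make_quant_table
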