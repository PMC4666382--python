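import numpy as np
import pandas as pd
import pytest

from mirblock import CountMatrix, LibraryMeta, design_blocker
from mirblock.known import MIRBASE_V19, mir16_family, mirna


@pytest.fixture(scope="session")
def mir16():
    return mirna("hsa-miR-16-5p")


@pytest.fixture(scope="session")
def family():
    return mir16_family()


@pytest.fixture(scope="session")
def mir16_blocker(mir16):
    return design_blocker(mir16, mode="five_prime", overhang_length=12)


@pytest.fixture
def mature_fasta(tmp_path):
    """miRBase-dialect mature FASTA with accession/description tokens."""
    lines = []
    for i, (name, seq) in enumerate(MIRBASE_V19.items()):
        lines.append(f">{name} MIMAT{i:07d} Homo sapiens {name[4:]}")
        lines.append(seq)
    path = tmp_path / "mature.fa"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_matrix(columns, metadata=None, species=None):
    if species is not None:
        cols = {
            lib: (
                pd.Series(vals).reindex(species).fillna(0)
                if isinstance(vals, dict)
                else pd.Series(list(vals), index=species)
            )
            for lib, vals in columns.items()
        }
        df = pd.DataFrame(cols, dtype="int64")
    else:
        df = pd.DataFrame(columns, dtype="int64")
    meta = {
        lib: LibraryMeta(**fields) for lib, fields in (metadata or {}).items()
    }
    return CountMatrix(df, meta)
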