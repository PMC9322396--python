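import numpy as np
import pytest

from hrp import domains, synth

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# standard-code codons per amino acid, for hand-built gene fixtures
from Bio.Data.CodonTable import standard_dna_table as _tbl  # noqa: E402

CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_tbl.forward_table.items()):
    CODONS.setdefault(_aa, []).append(_codon)


def random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def encode_protein(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous coding sequence (no stop codon appended)."""
    return "".join(CODONS[a][rng.integers(len(CODONS[a]))] for a in protein)


@pytest.fixture(scope="session")
def library() -> domains.ProfileLibrary:
    return domains.ProfileLibrary.bundled()


@pytest.fixture(scope="session")
def small_truth() -> synth.SyntheticTruth:
    """A compact benchmark genome shared by pipeline-level tests."""
    spec = synth.GenomeSpec(
        length=200_000,
        classes=["CNL"] * 8 + ["TNL"] * 2,
        n_te_decoys=3,
        n_background_genes=8,
        n_omitted=3,
        n_fused=1,
        n_split=1,
    )
    return synth.generate_genome_with_truth(spec, 42)
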