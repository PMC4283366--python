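import numpy as np
import pytest

from caridelim.morphoscreen import CharacterMatrix, Specimen
from caridelim.seqio import Alignment, SequenceRecord


def make_alignment(seqs: dict[str, str], **meta) -> Alignment:
    return Alignment(
        tuple(SequenceRecord(id=k, residues=v, **meta) for k, v in seqs.items())
    )


def random_acgt_alignment(rng: np.random.Generator, n_seqs: int, length: int) -> Alignment:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return make_alignment(
        {
            f"s{i}": bases[rng.integers(0, 4, size=length)].tobytes().decode()
            for i in range(n_seqs)
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_alignment():
    # 4 sequences, hand-designed site patterns
    return make_alignment(
        {
            "a": "ACGTACGT",
            "b": "ACGTACGA",
            "c": "ACGTACGT",
            "d": "ACGAACGT",
        }
    )


def make_character_matrix(
    rows: list[tuple[str, str, str, str, bool, dict[str, str]]],
    characters: list[str],
) -> CharacterMatrix:
    """rows: (id, lot, clade, stage, voucher, {character: state})."""
    specs = tuple(Specimen(r[0], r[1], r[2], r[3], r[4]) for r in rows)
    states = tuple(
        tuple(r[5].get(c, "unknown") for c in characters) for r in rows
    )
    return CharacterMatrix(specimens=specs, characters=tuple(characters), states=states)
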