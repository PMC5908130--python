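"""Small sequence helpers shared across modules.

Sequences are stored internally in the DNA alphabet (ACGT); user-facing
miRNA output is reported in the RNA alphabet (U for T) where noted.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA or RNA input; DNA output alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 array of base indices 0..3."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("non-ACGT character in sequence")
    return arr


def decode_rows(idx: np.ndarray) -> list[str]:
    """(n, L) base-index matrix -> list of n ACGT strings."""
    ascii_arr = _BASE_ARR[idx]
    width = idx.shape[1]
    flat = np.ascontiguousarray(ascii_arr).view(f"S{width}").ravel()
    return [b.decode() for b in flat]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings, early exit past `limit`."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm
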