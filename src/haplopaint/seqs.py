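"""Byte-level sequence codec shared across the pipeline.

Sequences are held internally as ``numpy.uint8`` arrays over the code
alphabet A=0, C=1, G=2, T=3, '-'=4 (alignment gap / deletion), N=5.
Strings appear only at the I/O boundary (FASTA/FASTQ, TSV reports).
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT-N"
GAP = 4
N_CODE = 5

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray, drop_gaps: bool = False) -> str:
    """Decode a code array back to a string; optionally strip gap codes."""
    codes = np.asarray(codes, dtype=np.uint8)
    if drop_gaps:
        codes = codes[codes != GAP]
    return _DECODE[codes].tobytes().decode()


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing positions between equal-length code arrays."""
    if a.shape != b.shape:
        raise ValueError("hamming distance requires equal-length sequences")
    return int(np.count_nonzero(a != b))


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8).astype(np.uint8)


def mutate(
    seq: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
    forbidden: dict[int, set[int]] | None = None,
) -> np.ndarray:
    """Substitute a different random base at each of ``positions``.

    ``forbidden`` optionally maps position -> base codes the new allele must
    also avoid (used when planting alleles guaranteed novel in a cohort).
    """
    out = seq.copy()
    for p in np.asarray(positions, dtype=int):
        banned = {int(out[p])}
        if forbidden and p in forbidden:
            banned |= {int(x) for x in forbidden[p]}
        choices = [b for b in range(4) if b not in banned]
        if not choices:
            raise ValueError(f"no free allele available at position {p}")
        out[p] = rng.choice(choices)
    return out


def phred_string(qualities: np.ndarray) -> str:
    """Sanger Phred+33 encoding of an integer quality array."""
    return (np.asarray(qualities, dtype=np.uint8) + 33).tobytes().decode()
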