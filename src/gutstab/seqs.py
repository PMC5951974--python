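"""Small DNA-sequence utilities shared across the package.

Sequences are plain upper-case ACGT(N) strings; coordinates are 1-based
inclusive everywhere in the public API (BED/bedGraph exports convert to
0-based half-open at the boundary).
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with the requested expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode()


def mutate_substitutions(
    seq: str, n_subs: int, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Apply ``n_subs`` substitutions at distinct positions (0-based returned).

    Each substituted base is drawn uniformly from the three non-reference bases.
    """
    if n_subs == 0:
        return seq, []
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = bytearray(seq.encode())
    for pos in positions:
        ref = chr(out[pos])
        alt = "ACGT".replace(ref, "")[rng.integers(3)]
        out[pos] = ord(alt)
    return out.decode(), sorted(int(p) for p in positions)


def seq_to_codes(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3 (other characters -> -1) as an int8 array."""
    return _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    """Number of mismatching columns between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    return int(
        np.count_nonzero(
            np.frombuffer(a.encode(), np.uint8) != np.frombuffer(b.encode(), np.uint8)
        )
    )


def write_fasta(path, records) -> None:
    """Write ``(name, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def interval_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def complement_intervals(
    intervals: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Complement of intervals within [1, length]."""
    out = []
    cursor = 1
    for s, e in merge_intervals(intervals):
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= length:
        out.append((cursor, length))
    return out
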