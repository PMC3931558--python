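"""Reference-genome containers.

Two interchangeable genome backends are used throughout the package: a
:class:`SparseGenome`, which stores only the bases the simulation has had to
commit to (gene bodies, marker sites, mutated positions) and invents the rest
lazily, and a :class:`DictGenome` wrapping fully materialized per-chromosome
strings read from FASTA.  Both expose ``get_base`` / ``fetch`` with 1-based,
inclusive coordinates, which is the convention used by every module here
(conversion to BED's 0-based half-open happens only in :mod:`supmap.io`).
"""

from __future__ import annotations

from bisect import bisect_right

import numpy as np

BASES = "ACGT"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement(base: str) -> str:
    return _COMP[base]


class SparseGenome:
    """A lazily materialized random genome.

    Bases are committed in construction order: segments (gene bodies) first,
    then any point bases (marker reference alleles, mutation sites).  Given a
    fixed seed and a fixed construction order the genome — including a later
    full materialization — is deterministic.
    """

    def __init__(self, chrom_lengths: dict[str, int], seed: int):
        for name, length in chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chrom_lengths = dict(chrom_lengths)
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)
        # per chromosome: sorted list of (start, seq) segments and {pos: base}
        self._segments: dict[str, list[tuple[int, str]]] = {c: [] for c in chrom_lengths}
        self._points: dict[str, dict[int, str]] = {c: {} for c in chrom_lengths}

    # -- construction ------------------------------------------------------
    def add_segment(self, chrom: str, start: int, seq: str) -> None:
        """Commit ``seq`` at 1-based ``start``.  Segments must not overlap."""
        end = start + len(seq) - 1
        if start < 1 or end > self.chrom_lengths[chrom]:
            raise ValueError(f"segment {chrom}:{start}-{end} outside chromosome bounds")
        for s, q in self._segments[chrom]:
            if start <= s + len(q) - 1 and s <= end:
                raise ValueError(f"segment {chrom}:{start}-{end} overlaps an existing segment")
        self._segments[chrom].append((start, seq))
        self._segments[chrom].sort()

    def _segment_base(self, chrom: str, pos: int) -> str | None:
        segs = self._segments[chrom]
        i = bisect_right(segs, (pos, chr(0x10FFFF))) - 1
        if i >= 0:
            s, q = segs[i]
            if s <= pos <= s + len(q) - 1:
                return q[pos - s]
        return None

    def get_base(self, chrom: str, pos: int) -> str:
        if not 1 <= pos <= self.chrom_lengths[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
        base = self._segment_base(chrom, pos)
        if base is not None:
            return base
        pts = self._points[chrom]
        if pos not in pts:
            pts[pos] = BASES[self._rng.integers(4)]
        return pts[pos]

    def ensure_base(self, chrom: str, pos: int, allowed: str) -> str:
        """Return the base at ``pos``; if uncommitted, commit one drawn from ``allowed``."""
        base = self._segment_base(chrom, pos)
        if base is not None:
            return base
        pts = self._points[chrom]
        if pos not in pts:
            pts[pos] = allowed[self._rng.integers(len(allowed))]
        return pts[pos]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice (assembles base by base outside segments)."""
        return "".join(self.get_base(chrom, p) for p in range(start, end + 1))

    # -- materialization ---------------------------------------------------
    def materialize(self, chrom: str) -> str:
        """Full chromosome sequence; uncommitted background is drawn from a
        dedicated per-chromosome stream so the result does not depend on how
        much of the genome was queried before this call."""
        length = self.chrom_lengths[chrom]
        idx = list(self.chrom_lengths).index(chrom)
        bg_rng = np.random.default_rng([self.seed, 0x5E9, idx])
        arr = np.frombuffer(b"ACGT", dtype="S1")[bg_rng.integers(0, 4, size=length)]
        seq = bytearray(arr.tobytes())
        for start, q in self._segments[chrom]:
            seq[start - 1 : start - 1 + len(q)] = q.encode()
        for pos, base in self._points[chrom].items():
            if self._segment_base(chrom, pos) is None:
                seq[pos - 1] = ord(base)
        return seq.decode()


class DictGenome:
    """Genome backed by fully materialized per-chromosome strings."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = sequences
        self.chrom_lengths = {c: len(s) for c, s in sequences.items()}

    def get_base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start - 1 : end]
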