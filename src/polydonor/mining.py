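"""Microsatellite (SSR) mining in nucleotide sequences.

Detects perfect and imperfect di-/tri-/tetra-nucleotide tandem repeats of at
least ``min_len`` nucleotides.  An imperfect repeat is a maximal window that
matches a perfect tandem array of its motif, in the same phase, at Hamming
distance <= ``max_mismatch``.  Motifs are canonicalised into families closed
under cyclic rotation and reverse complement, so e.g. GA, AG, TC and CT all
report family AG.

Coordinates are 0-based half-open.  Characters outside A/C/G/T break runs.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")

DEFAULT_MIN_LEN = 15
DEFAULT_UNIT_LENS = (2, 3, 4)
DEFAULT_MAX_MISMATCH = 2

#: amplifiable product-size window for candidate markers (bp)
PRODUCT_SIZE_RANGE = (90, 300)


@dataclass(frozen=True)
class SSRHit:
    """One detected repeat region (0-based half-open interval)."""

    seq_id: str
    start: int
    end: int
    motif: str
    family: str
    unit_len: int
    mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MiningSummary:
    n_sequences: int
    total_bases: int
    counts_by_unit_len: dict[int, int]
    counts_by_family: dict[str, int]
    density_bp_per_ssr: Optional[float]

    @property
    def n_hits(self) -> int:
        return sum(self.counts_by_unit_len.values())


def _is_degenerate(motif: str) -> bool:
    """True when the motif is a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return True
    return False


def canonical_family(motif: str) -> str:
    """Canonical family label: the lexicographically smallest cyclic rotation
    of the motif or of its reverse complement.  Idempotent; partitions all
    non-degenerate 2-4-mers into strand- and phase-independent families."""
    if not 2 <= len(motif) <= 4:
        raise ValueError(f"motif length must be 2-4, got {motif!r}")
    if set(motif) - _ACGT:
        raise ValueError(f"motif {motif!r} is not over A/C/G/T")
    if _is_degenerate(motif):
        raise ValueError(f"motif {motif!r} is a repetition of a shorter unit")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(candidates)


def _segments(seq: str) -> Iterable[tuple[int, int]]:
    """Maximal A/C/G/T stretches of the sequence, as (start, end)."""
    start = None
    for i, ch in enumerate(seq):
        if ch in _ACGT:
            if start is None:
                start = i
        elif start is not None:
            yield start, i
            start = None
    if start is not None:
        yield start, len(seq)


def find_perfect_ssrs(
    seq: str,
    min_len: int = DEFAULT_MIN_LEN,
    unit_lens: Sequence[int] = DEFAULT_UNIT_LENS,
    seq_id: str = "",
) -> list[SSRHit]:
    """Maximal exact tandem runs of length >= ``min_len`` and zero mismatches.

    Runs whose repeat unit is itself a repetition of a shorter unit (e.g.
    ATAT) are suppressed; they are reported at the shorter unit length.
    """
    seq = seq.upper()
    hits: list[SSRHit] = []
    for segL, segR in _segments(seq):
        for u in unit_lens:
            if segR - segL < max(min_len, 2 * u):
                continue
            j = segL + u
            run_start = None  # first j with seq[j] == seq[j - u]
            while j <= segR:
                ok = j < segR and seq[j] == seq[j - u]
                if ok and run_start is None:
                    run_start = j
                if not ok and run_start is not None:
                    start, end = run_start - u, j
                    if end - start >= min_len:
                        motif = seq[start:start + u]
                        if not _is_degenerate(motif):
                            hits.append(SSRHit(
                                seq_id, start, end, motif,
                                canonical_family(motif), u, 0,
                            ))
                    run_start = None
                j += 1
    hits.sort(key=lambda h: (h.start, h.unit_len, h.end))
    return hits


def _maximal_windows(
    mismatch_positions: list[int], segL: int, segR: int, k: int
) -> Iterable[tuple[int, int]]:
    """Maximal half-open windows inside [segL, segR) containing <= k of the
    given positions.  Windows are yielded left to right."""
    P = [segL - 1] + mismatch_positions + [segR]
    prev_end = None
    for a in range(len(P) - 1):
        b = min(a + k + 1, len(P) - 1)
        start, end = P[a] + 1, P[b]
        if end <= start:
            continue
        if prev_end is not None and end <= prev_end:
            continue  # contained in the previous window
        prev_end = end
        yield start, end


def find_imperfect_ssrs(
    seq: str,
    min_len: int = DEFAULT_MIN_LEN,
    unit_lens: Sequence[int] = DEFAULT_UNIT_LENS,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    seq_id: str = "",
) -> list[SSRHit]:
    """Maximal windows at Hamming distance <= ``max_mismatch`` from a perfect
    tandem array of a 2-4 nt motif, in the same phase, length >= ``min_len``.

    Overlapping candidate windows of the same family are resolved to the
    single best (longest, then fewest mismatches, then smallest start); two
    kept hits of one family never share a full repeat unit.  Perfect runs are
    reported with ``mismatches = 0``; with ``max_mismatch = 0`` the output
    equals :func:`find_perfect_ssrs`.
    """
    seq = seq.upper()
    raw: dict[tuple[int, int, int, str], SSRHit] = {}
    for segL, segR in _segments(seq):
        seg = seq[segL:segR]
        seg_arr = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
        pos = np.arange(segL, segR)
        for u in unit_lens:
            if segR - segL < min_len:
                continue
            # candidate (motif, phase): any window >= min_len with <= 2
            # mismatches contains at least one exact in-phase motif copy,
            # so seeding on observed u-mers is exhaustive.
            cand: set[tuple[str, int]] = set()
            for q in range(len(seg) - u + 1):
                m = seg[q:q + u]
                if not _is_degenerate(m):
                    cand.add((m, (segL + q) % u))
            unit_idx = {p: (pos - p) % u for p in range(u)}
            for m, phase in sorted(cand):
                m_arr = np.frombuffer(m.encode("ascii"), dtype=np.uint8)
                mism = (
                    segL
                    + np.nonzero(seg_arr != m_arr[unit_idx[phase]])[0]
                ).tolist()
                for start, end in _maximal_windows(mism, segL, segR, max_mismatch):
                    if end - start < min_len:
                        continue
                    n_mm = bisect_left(mism, end) - bisect_right(mism, start - 1)
                    off = (start - phase) % u
                    motif = m[off:] + m[:off]
                    fam = canonical_family(m)
                    key = (start, end, u, fam)
                    prev = raw.get(key)
                    if prev is None or n_mm < prev.mismatches:
                        raw[key] = SSRHit(seq_id, start, end, motif, fam, u, n_mm)

    # within-family overlap resolution: longest, fewest mismatches, leftmost
    kept: list[SSRHit] = []
    by_family: dict[tuple[str, int], list[SSRHit]] = {}
    order = sorted(
        raw.values(), key=lambda h: (-h.length, h.mismatches, h.start, h.end)
    )
    for h in order:
        fam_hits = by_family.setdefault((h.family, h.unit_len), [])
        # overlap counts when at least one full unit is shared; abutting
        # phase-shifted runs sharing a partial unit are distinct arrays
        if any(
            min(h.end, o.end) - max(h.start, o.start) >= h.unit_len
            for o in fam_hits
        ):
            continue
        fam_hits.append(h)
        kept.append(h)
    kept.sort(key=lambda h: (h.start, h.unit_len, h.end))
    return kept


def mine_fasta(
    path,
    min_len: int = DEFAULT_MIN_LEN,
    unit_lens: Sequence[int] = DEFAULT_UNIT_LENS,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[MiningSummary, pd.DataFrame]:
    """Mine every record of a FASTA file; returns a summary and a hit table
    sorted by (seq_id, start)."""
    seen: set[str] = set()
    hits: list[SSRHit] = []
    n_seq = 0
    total_bases = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA record id {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {record.id!r} has an empty sequence")
        n_seq += 1
        total_bases += len(seq)
        hits.extend(
            find_imperfect_ssrs(
                seq, min_len=min_len, unit_lens=unit_lens,
                max_mismatch=max_mismatch, seq_id=record.id,
            )
        )
    if n_seq == 0:
        raise ValueError(f"no FASTA records found in {path}")
    hits.sort(key=lambda h: (h.seq_id, h.start, h.unit_len))
    table = pd.DataFrame(
        [
            {
                "seq_id": h.seq_id, "start": h.start, "end": h.end,
                "motif": h.motif, "family": h.family, "unit_len": h.unit_len,
                "length": h.length, "mismatches": h.mismatches,
            }
            for h in hits
        ],
        columns=["seq_id", "start", "end", "motif", "family", "unit_len",
                 "length", "mismatches"],
    )
    counts_u = {u: 0 for u in unit_lens}
    counts_f: dict[str, int] = {}
    for h in hits:
        counts_u[h.unit_len] += 1
        counts_f[h.family] = counts_f.get(h.family, 0) + 1
    n_hits = len(hits)
    density = total_bases / n_hits if n_hits else None
    summary = MiningSummary(
        n_sequences=n_seq,
        total_bases=total_bases,
        counts_by_unit_len=counts_u,
        counts_by_family=dict(sorted(counts_f.items())),
        density_bp_per_ssr=density,
    )
    return summary, table


def repeat_class_percentages(counts_by_unit_len: dict[int, int]) -> dict[int, float]:
    """Percent of hits per repeat unit length, rounded to one decimal."""
    if any(c < 0 for c in counts_by_unit_len.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts_by_unit_len.values())
    if total == 0:
        raise ValueError("all counts are zero")
    return {u: round(100.0 * c / total, 1) for u, c in counts_by_unit_len.items()}


def product_size_in_range(
    size: int, size_range: tuple[int, int] = PRODUCT_SIZE_RANGE
) -> bool:
    """Whether a candidate amplicon size falls in the designable window."""
    lo, hi = size_range
    return lo <= size <= hi
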