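"""Tandem-repeat detection in assembled contigs.

Candidate monomer periods come from exact k-mer self-match spacings; each
candidate region is validated by wraparound dynamic programming against a
provisional period consensus under the weights match +2, mismatch -3,
indel -5 and a minimum alignment score (default 50). The probabilistic
detection phase of classic tandem-repeat finders is deliberately replaced
by this deterministic procedure; only the weights and threshold carry over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["TandemArray", "find_tandem_repeats", "self_dotplot", "dominant_offset"]

MATCH_WEIGHT = 2
MISMATCH_WEIGHT = 3
INDEL_WEIGHT = 5


@dataclass(frozen=True)
class TandemArray:
    """A detected tandem array (0-based half-open contig coordinates)."""

    contig_id: str
    start: int
    end: int
    period: int
    copy_number_in_array: float
    array_consensus: str
    score: int

    def __post_init__(self) -> None:
        if self.period < 2:
            raise ValueError("period must be >= 2")
        if self.end - self.start < 2 * self.period:
            raise ValueError("array must span at least two monomer copies")


def _majority_consensus(region: str, period: int) -> str:
    """Majority base per column (position mod period); ties alphabetical."""
    cols: list[dict[str, int]] = [dict() for _ in range(period)]
    for i, base in enumerate(region):
        col = cols[i % period]
        col[base] = col.get(base, 0) + 1
    out = []
    for col in cols:
        if not col:
            out.append("A")
            continue
        best = max(sorted(col.items()), key=lambda kv: kv[1])
        out.append(best[0])
    return "".join(out)


def _phase_scan_scores(region: str, consensus: str) -> np.ndarray:
    """Per-position +match/-mismatch scores at phase 0 (no indels)."""
    p = len(consensus)
    scores = np.empty(len(region), dtype=np.int64)
    for i, base in enumerate(region):
        scores[i] = MATCH_WEIGHT if base == consensus[i % p] else -MISMATCH_WEIGHT
    return scores


def wraparound_score(region: str, consensus: str,
                     match: int = MATCH_WEIGHT, mismatch: int = MISMATCH_WEIGHT,
                     indel: int = INDEL_WEIGHT) -> int:
    """Best wraparound-DP score of ``region`` against the cyclic ``consensus``.

    The consensus phase is free at both ends; every region base is scored
    (+match, -mismatch) or paid for as a gap (-indel), as is every skipped
    consensus base inside the path.
    """
    p = len(consensus)
    NEG = -(10 ** 9)
    prev = np.zeros(p, dtype=np.int64)  # free starting phase
    for base in region:
        sub = np.array([match if base == c else -mismatch for c in consensus],
                       dtype=np.int64)
        diag = np.roll(prev, 1) + sub          # consume region base + consensus base
        up = prev - indel                      # gap in consensus (region base unpaired)
        cur = np.maximum(diag, up)
        # deletion moves (skip consensus bases) within the row; two sweeps
        # propagate across the wrap column
        for _ in range(2):
            cur = np.maximum(cur, np.roll(cur, 1) - indel)
        prev = cur
    return int(prev.max())


def _candidate_periods(seq: str, k: int, lo: int, hi: int) -> list[int]:
    """Periods suggested by spacings between repeated k-mers, most-voted first."""
    positions: dict[str, int] = {}
    votes: dict[int, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in positions:
            d = i - positions[kmer]
            if lo <= d <= hi:
                votes[d] = votes.get(d, 0) + 1
        positions[kmer] = i
    ranked = sorted(votes, key=lambda d: (-votes[d], d))
    # small periods (< k) are caught because a k-mer inside a period-d array
    # recurs at spacing d even when d < k
    return ranked[:20]


def _regions_for_period(seq: str, d: int) -> list[tuple[int, int]]:
    """Maximal intervals where seq[i] == seq[i+d] holds densely."""
    L = len(seq)
    if L < 2 * d:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    m = arr[:-d] == arr[d:]
    regions: list[tuple[int, int]] = []
    i = 0
    n = len(m)
    while i < n:
        if not m[i]:
            i += 1
            continue
        j = i
        gap = 0
        last_true = i
        while j < n:
            if m[j]:
                last_true = j
                gap = 0
            else:
                gap += 1
                if gap > d:
                    break
            j += 1
        regions.append((i, last_true + 1 + d))  # include the trailing copy
        i = last_true + 1
    return [(s, e) for s, e in regions if e - s >= 2 * d]


def _refine_bounds(seq: str, start: int, end: int,
                   consensus: str) -> tuple[int, int, int]:
    """Trim mismatching flanks: keep the max-score subarray of the phase scan."""
    scores = _phase_scan_scores(seq[start:end], consensus)
    # Kadane with position tracking
    best, best_lo, best_hi = None, 0, 0
    cur, lo = 0, 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur, lo = int(s), i
        else:
            cur += int(s)
        if best is None or cur > best:
            best, best_lo, best_hi = cur, lo, i + 1
    return start + best_lo, start + best_hi, int(best or 0)


def find_tandem_repeats(
    sequence: str,
    contig_id: str = "contig",
    match: int = MATCH_WEIGHT,
    mismatch: int = MISMATCH_WEIGHT,
    indel: int = INDEL_WEIGHT,
    min_score: int = 50,
    period_range: tuple[int, int] = (2, 2000),
    kmer: int = 7,
) -> list[TandemArray]:
    """Detect tandem arrays and their monomer period.

    Overlapping reports are merged keeping the higher score; among
    overlapping candidates within 95% of the best score, the smallest
    period wins (preferring the primitive monomer over its multiples).
    """
    seq = sequence.upper()
    lo, hi = period_range
    hi = min(hi, len(seq) // 2)
    candidates: list[TandemArray] = []
    for d in _candidate_periods(seq, kmer, lo, hi):
        for r_start, r_end in _regions_for_period(seq, d):
            consensus = _majority_consensus(seq[r_start:r_end], d)
            s, e, _ = _refine_bounds(seq, r_start, r_end, consensus)
            if e - s < 2 * d:
                continue
            consensus = _majority_consensus(seq[s:e], d)
            s, e, scan_score = _refine_bounds(seq, s, e, consensus)
            if e - s < 2 * d:
                continue
            score = max(scan_score, wraparound_score(seq[s:e], consensus,
                                                     match, mismatch, indel))
            if score < min_score:
                continue
            candidates.append(TandemArray(contig_id, s, e, d,
                                          round((e - s) / d, 2),
                                          consensus, score))
    return _merge_overlaps(candidates)


def _merge_overlaps(candidates: list[TandemArray]) -> list[TandemArray]:
    """Group overlapping candidates; per group report one array.

    The winner is the smallest period scoring at least 95% of the group's
    best score; ties on period resolve to the higher score.
    """
    if not candidates:
        return []
    ordered = sorted(candidates, key=lambda a: (a.start, a.end))
    groups: list[list[TandemArray]] = [[ordered[0]]]
    group_end = ordered[0].end
    for arr in ordered[1:]:
        if arr.start < group_end:
            groups[-1].append(arr)
            group_end = max(group_end, arr.end)
        else:
            groups.append([arr])
            group_end = arr.end
    out = []
    for group in groups:
        best_score = max(a.score for a in group)
        eligible = [a for a in group if a.score >= 0.95 * best_score]
        winner = min(eligible, key=lambda a: (a.period, -a.score))
        out.append(winner)
    return sorted(out, key=lambda a: a.start)


def self_dotplot(sequence: str, window: int,
                 min_identity: float) -> list[tuple[int, int, int]]:
    """Self-comparison diagonals: (offset, start, length) runs of window
    pairs with identity >= ``min_identity`` at each off-diagonal offset.

    The dominant offset estimates the monomer size of a tandem array.
    """
    seq = sequence.upper()
    if window < 4:
        raise ValueError("window must be >= 4")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(arr)
    hits: list[tuple[int, int, int]] = []
    kernel = np.ones(window, dtype=np.int64)
    for offset in range(1, L - window + 1):
        eq = (arr[:-offset] == arr[offset:]).astype(np.int64)
        if len(eq) < window:
            break
        idents = np.convolve(eq, kernel, mode="valid") / window
        ok = idents >= min_identity
        i = 0
        while i < len(ok):
            if ok[i]:
                j = i
                while j < len(ok) and ok[j]:
                    j += 1
                hits.append((offset, i, (j - i - 1) + window))
                i = j
            else:
                i += 1
    return hits


def dominant_offset(hits: Sequence[tuple[int, int, int]]) -> Optional[int]:
    """Offset with the largest total matched length, or None."""
    totals: dict[int, int] = {}
    for offset, _, length in hits:
        totals[offset] = totals.get(offset, 0) + length
    if not totals:
        return None
    return min(totals, key=lambda o: (-totals[o], o))
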