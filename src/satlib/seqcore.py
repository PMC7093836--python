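"""Core sequence primitives: distances, local alignment against dimer
references, and consensus derivation from monomer copies.

Satellite-DNA (satDNA) families are described by a consensus monomer; reads
are mapped against a *dimer* of that monomer (two concatenated copies) so
that fragments straddling the monomer junction still align contiguously.
Divergence of each aligned fragment from the reference is expressed as a
Kimura 2-parameter (K2P) distance, which corrects the observed proportions
of transitions (P) and transversions (Q) for multiple hits:

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentSummary",
    "DivergenceValue",
    "FragmentAlignment",
    "SaturationError",
    "SatFamily",
    "align_fragment_to_dimer",
    "consensus_from_monomers",
    "k2p_distance",
    "k2p_from_pair",
    "p_distance",
    "reverse_complement",
]

MATCH_SCORE = 2
MISMATCH_SCORE = -3
GAP_SCORE = -5

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class SaturationError(ValueError):
    """K2P distance undefined: observed divergence beyond the correctable range."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentSummary:
    """Site counts of one pairwise alignment.

    ``aligned_sites`` counts gap-free, N-free compared columns; transitions
    and transversions partition the mismatching subset of those columns.
    """

    aligned_sites: int
    transitions: int
    transversions: int
    gaps: int = 0
    score: int = 0

    def __post_init__(self) -> None:
        if min(self.aligned_sites, self.transitions, self.transversions, self.gaps) < 0:
            raise ValueError("alignment counts must be non-negative")
        if self.transitions + self.transversions > self.aligned_sites:
            raise ValueError("more substitutions than aligned sites")

    @property
    def p(self) -> float:
        return self.transitions / self.aligned_sites

    @property
    def q(self) -> float:
        return self.transversions / self.aligned_sites


@dataclass(frozen=True)
class DivergenceValue:
    """A K2P distance in substitutions/site; ``k2p_pct`` is the percent form."""

    k2p: float

    def __post_init__(self) -> None:
        if self.k2p < 0:
            raise ValueError("K2P distance must be non-negative")

    @property
    def k2p_pct(self) -> float:
        return 100.0 * self.k2p


@dataclass(frozen=True)
class SatFamily:
    """A satDNA family: consensus monomer plus the dimer mapping reference."""

    family_id: str
    consensus: str

    def __post_init__(self) -> None:
        seq = self.consensus.upper()
        if not seq:
            raise ValueError(f"family {self.family_id}: empty consensus")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"family {self.family_id}: invalid bases {sorted(bad)}")
        object.__setattr__(self, "consensus", seq)

    @property
    def monomer_size(self) -> int:
        return len(self.consensus)

    @property
    def at_percent(self) -> float:
        at = sum(1 for b in self.consensus if b in "AT")
        return 100.0 * at / len(self.consensus)

    @property
    def dimer(self) -> str:
        return self.consensus + self.consensus


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two aligned sequences.

    Columns containing a gap (``-``) or ``N`` in either sequence are
    excluded (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    compared = diffs = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    return diffs / compared


def k2p_distance(summary: AlignmentSummary) -> DivergenceValue:
    """Kimura 2-parameter distance from transition/transversion counts."""
    if summary.aligned_sites <= 0:
        raise ValueError("aligned_sites must be positive")
    p, q = summary.p, summary.q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P saturated: P={p:.3f}, Q={q:.3f} (1-2P-Q={w1:.3f}, 1-2Q={w2:.3f})"
        )
    k = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DivergenceValue(max(k, 0.0))


def _count_pair(a: str, b: str) -> tuple[int, int, int, int]:
    """(aligned_sites, transitions, transversions, gaps) over aligned strings."""
    sites = ts = tv = gaps = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == "N" or y == "N":
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return sites, ts, tv, gaps


def k2p_from_pair(a: str, b: str) -> DivergenceValue:
    """K2P distance between two aligned sequences (pairwise deletion)."""
    if len(a) != len(b):
        raise ValueError("aligned lengths differ")
    sites, ts, tv, gaps = _count_pair(a, b)
    if sites == 0:
        raise ValueError("no comparable sites")
    return k2p_distance(AlignmentSummary(sites, ts, tv, gaps))


def _make_aligner() -> Align.PairwiseAligner:
    # N scores 0 against everything so ambiguous bases neither reward nor
    # punish the local alignment; they are excluded from site counts too.
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if "N" in (x, y):
                matrix[x, y] = 0
            else:
                matrix[x, y] = MATCH_SCORE if x == y else MISMATCH_SCORE
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner

_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class FragmentAlignment:
    """Best local alignment of a fragment against a family dimer.

    Coordinates are 0-based half-open on the dimer. ``strand`` is "+" when
    the fragment aligned as given, "-" when its reverse complement did.
    """

    family_id: str
    strand: str
    start: int
    end: int
    summary: AlignmentSummary

    @property
    def score(self) -> int:
        return self.summary.score


def local_alignment_score(query: str, target: str) -> float:
    """Score of the best Smith-Waterman local alignment (+2/-3, linear -5)."""
    return _ALIGNER.score(target, query.upper())


def _summarize_alignment(alignment) -> tuple[AlignmentSummary, int, int]:
    target, query = alignment.target, alignment.query
    blocks_t, blocks_q = alignment.aligned
    sites = ts = tv = gaps = 0
    prev_t = prev_q = None
    for (ts_, te_), (qs_, qe_) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            gaps += (ts_ - prev_t) + (qs_ - prev_q)
        prev_t, prev_q = te_, qe_
        s, t, v, _ = _count_pair(str(target[ts_:te_]), str(query[qs_:qe_]))
        sites += s
        ts += t
        tv += v
    start = int(blocks_t[0][0])
    end = int(blocks_t[-1][1])
    summary = AlignmentSummary(sites, ts, tv, gaps, score=int(alignment.score))
    return summary, start, end


def align_fragment_to_dimer(
    fragment: str,
    family: SatFamily,
    both_strands: bool = True,
    min_length: int = 20,
) -> FragmentAlignment:
    """Best local alignment of ``fragment`` against the family's dimer.

    Both strands are tried when ``both_strands``; ties go to the forward
    strand, then to the leftmost start on the dimer (Biopython's first
    optimal alignment). Fragments shorter than ``min_length`` are rejected.
    """
    fragment = fragment.upper()
    if len(fragment) < min_length:
        raise ValueError(
            f"fragment length {len(fragment)} below minimum {min_length}"
        )
    dimer = family.dimer
    fwd_score = _ALIGNER.score(dimer, fragment)
    strand, query, best = "+", fragment, fwd_score
    if both_strands:
        rc = reverse_complement(fragment)
        rev_score = _ALIGNER.score(dimer, rc)
        if rev_score > fwd_score:
            strand, query, best = "-", rc, rev_score
    alignment = _ALIGNER.align(dimer, query)[0]
    summary, start, end = _summarize_alignment(alignment)
    return FragmentAlignment(family.family_id, strand, start, end, summary)


def align_pair_local(a: str, b: str) -> AlignmentSummary:
    """Site counts of the best local alignment of two unaligned sequences.

    Useful for distances between independently derived consensuses whose
    ends may not correspond exactly; interior structure is assumed
    colinear (no rotation handling).
    """
    alignment = _ALIGNER.align(a.upper(), b.upper())[0]
    summary, _, _ = _summarize_alignment(alignment)
    return summary


def consensus_from_monomers(monomers: Sequence[str]) -> str:
    """Column-majority consensus via a center-star multiple alignment.

    The longest monomer is the center; every other monomer is locally
    aligned to it with the fragment scoring, and its bases are projected
    onto the center's coordinates (insertions relative to the center are
    dropped). Per column, the majority base wins, ties break alphabetically,
    and columns that are gaps in more than half the monomers are removed.
    """
    monomers = [m.upper() for m in monomers]
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers for a consensus")
    center = max(monomers, key=len)
    n_cols = len(center)
    columns: list[list[str]] = [[] for _ in range(n_cols)]
    for col, base in enumerate(center):
        columns[col].append(base)
    for mono in monomers:
        if mono is center:
            continue
        alignment = _ALIGNER.align(center, mono)[0]
        covered = ["-"] * n_cols
        blocks_t, blocks_q = alignment.aligned
        for (ts_, te_), (qs_, qe_) in zip(blocks_t, blocks_q):
            for off in range(te_ - ts_):
                covered[ts_ + off] = mono[qs_ + off]
        for col, base in enumerate(covered):
            columns[col].append(base)
    out = []
    half = len(monomers) / 2.0
    for col in columns:
        n_gap = col.count("-")
        if n_gap > half:
            continue
        bases = [b for b in col if b not in "-N"]
        if not bases:
            continue
        counts = {b: bases.count(b) for b in "ACGT"}
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        out.append(best[0])
    return "".join(out)
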