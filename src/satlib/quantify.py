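"""Read masking against satDNA family references and the derived
per-species quantities: abundance, copy number, nucleotide-weighted
divergence, and repeat landscapes.

Abundance follows the proportion-of-nucleotides definition: the summed
aligned length of all masked fragments over the total number of
nucleotides in the read library, expressed as a percentage. The repeat
landscape redistributes the same nucleotides into K2P-divergence bins, so
recent amplifications pile up in the low-divergence bins while old,
unamplified families sit out at their equilibrium divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord
from .seqcore import (
    DivergenceValue,
    SatFamily,
    SaturationError,
    align_fragment_to_dimer,
    k2p_distance,
    local_alignment_score,
    reverse_complement,
)

__all__ = [
    "MaskedFragment",
    "SpeciesProfile",
    "RepeatLandscape",
    "mask_reads",
    "profile_from_fragments",
    "copy_number",
    "build_landscape",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 40
MIN_FRAGMENT_LENGTH = 20


@dataclass(frozen=True)
class MaskedFragment:
    """One read assigned to a family, with its aligned length and K2P."""

    read_id: str
    family_id: str
    strand: str
    aligned_nt: int
    k2p: DivergenceValue
    score: int


@dataclass(frozen=True)
class SpeciesProfile:
    """Per species x family: abundance, copy number, mean divergence."""

    species_code: str
    family_id: str
    monomer_size: int
    at_percent: float
    abundance_pct: float
    copy_number: int
    mean_k2p_pct: Optional[float]  # None when no fragments were masked

    def __post_init__(self) -> None:
        if not 0.0 <= self.abundance_pct <= 100.0:
            raise ValueError("abundance_pct outside [0, 100]")
        if self.copy_number < 0:
            raise ValueError("copy_number must be non-negative")


@dataclass(frozen=True)
class RepeatLandscape:
    """Abundance binned by K2P divergence for one species x family.

    ``bins`` maps [lower, upper) K2P-percent intervals to the percentage
    of library nucleotides falling in that divergence band; the bin sum
    equals the family's total abundance.
    """

    species_code: str
    family_id: str
    bin_width: float
    bins: tuple[tuple[float, float, float], ...]  # (lower, upper, abundance_pct)

    @property
    def total_abundance_pct(self) -> float:
        return float(sum(b[2] for b in self.bins))

    def modal_bin(self) -> Optional[tuple[float, float]]:
        """[lower, upper) of the most abundant bin, or None if empty."""
        occupied = [b for b in self.bins if b[2] > 0]
        if not occupied:
            return None
        lo, hi, _ = max(occupied, key=lambda b: (b[2], -b[0]))
        return (lo, hi)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"species": self.species_code, "family": self.family_id,
                 "bin_lower": lo, "bin_upper": hi, "abundance_pct": ab}
                for lo, hi, ab in self.bins
            ]
        )


def mask_reads(
    reads: Sequence[SequenceRecord],
    families: Sequence[SatFamily],
    min_score: int = DEFAULT_MIN_SCORE,
) -> list[MaskedFragment]:
    """Assign each read to its best-scoring family (or none).

    Every read is locally aligned to every family dimer on both strands;
    only the best family is kept (one fragment per read, so each masked
    base is counted once). Score ties break to the alphabetically first
    family id, then the forward strand. Reads scoring below ``min_score``
    or shorter than 20 nt yield no fragment; fragments whose divergence
    saturates the K2P correction are discarded and logged.
    """
    if not families:
        raise ValueError("at least one family is required")
    ids = [f.family_id for f in families]
    if len(ids) != len(set(ids)):
        raise ValueError(f"duplicate family ids: {sorted(ids)}")
    ordered = sorted(families, key=lambda f: f.family_id)
    fragments: list[MaskedFragment] = []
    n_saturated = 0
    for read in reads:
        if len(read) < MIN_FRAGMENT_LENGTH:
            continue
        seq = read.sequence
        rc = reverse_complement(seq)
        best: Optional[tuple[float, SatFamily]] = None
        for fam in ordered:
            score = max(local_alignment_score(seq, fam.dimer),
                        local_alignment_score(rc, fam.dimer))
            if best is None or score > best[0]:
                best = (score, fam)
        if best is None or best[0] < min_score:
            continue
        aln = align_fragment_to_dimer(seq, best[1], both_strands=True)
        if aln.score < min_score or aln.summary.aligned_sites == 0:
            continue
        try:
            k2p = k2p_distance(aln.summary)
        except SaturationError:
            n_saturated += 1
            continue
        fragments.append(
            MaskedFragment(read.id, best[1].family_id, aln.strand,
                           aln.summary.aligned_sites, k2p, aln.score)
        )
    if n_saturated:
        logger.warning("discarded %d fragment(s) with saturated K2P", n_saturated)
    return fragments


def copy_number(abundance_pct: float, genome_size_nt: int,
                monomer_size: int) -> int:
    """Monomer copies implied by an abundance and a genome size."""
    if monomer_size <= 0:
        raise ValueError("monomer_size must be positive")
    if genome_size_nt <= 0:
        raise ValueError("genome_size_nt must be positive")
    return round(abundance_pct / 100.0 * genome_size_nt / monomer_size)


def profile_from_fragments(
    fragments: Iterable[MaskedFragment],
    total_library_nt: int,
    genome_size_nt: int,
    family: SatFamily,
    species_code: str = "",
) -> SpeciesProfile:
    """Abundance (% of library nt), copy number and nt-weighted mean K2P.

    The mean divergence weights each fragment's K2P by its aligned length,
    matching how landscape nucleotides are apportioned. With no fragments
    the abundance is 0 and the divergence is reported missing, not zero.
    """
    if total_library_nt <= 0:
        raise ValueError("total_library_nt must be positive")
    fam_frags = [f for f in fragments if f.family_id == family.family_id]
    total_nt = sum(f.aligned_nt for f in fam_frags)
    abundance = 100.0 * total_nt / total_library_nt
    if total_nt > 0:
        mean_k2p = sum(f.aligned_nt * f.k2p.k2p_pct for f in fam_frags) / total_nt
    else:
        mean_k2p = None
    return SpeciesProfile(
        species_code=species_code,
        family_id=family.family_id,
        monomer_size=family.monomer_size,
        at_percent=family.at_percent,
        abundance_pct=abundance,
        copy_number=copy_number(abundance, genome_size_nt, family.monomer_size),
        mean_k2p_pct=mean_k2p,
    )


def build_landscape(
    fragments: Iterable[MaskedFragment],
    total_library_nt: int,
    bin_width: float = 1.0,
    species_code: str = "",
    family_id: str = "",
    max_divergence_pct: float = 50.0,
) -> RepeatLandscape:
    """Bin masked nucleotides by fragment K2P divergence.

    Each fragment's aligned length falls entirely into the bin containing
    its K2P percent ([0,w), [w,2w), ...); bin contents are expressed as a
    percentage of the library, so the bins sum to the family's abundance.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if total_library_nt <= 0:
        raise ValueError("total_library_nt must be positive")
    fam_frags = [f for f in fragments
                 if not family_id or f.family_id == family_id]
    n_bins = int(np.ceil(max_divergence_pct / bin_width))
    counts = np.zeros(n_bins, dtype=float)
    for f in fam_frags:
        idx = int(f.k2p.k2p_pct // bin_width)
        if idx >= n_bins:  # beyond the plotted range: widen
            counts = np.concatenate([counts, np.zeros(idx - n_bins + 1)])
            n_bins = idx + 1
        counts[idx] += f.aligned_nt
    bins = tuple(
        (round(i * bin_width, 10), round((i + 1) * bin_width, 10),
         100.0 * counts[i] / total_library_nt)
        for i in range(n_bins)
    )
    return RepeatLandscape(species_code, family_id, bin_width, bins)
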