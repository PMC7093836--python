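"""End-to-end analysis of a simulated satDNA survey.

Runs the full loop the field applies to real data: simulate library
evolution along the dated tree, shotgun-sequence every species, derive
each species' family consensuses from its monomer copies (the assembly
step's stand-in), mask the reads against those consensuses, and compute
abundances, landscapes, z-scores and consensus distance matrices. Because
the simulator also returns the ground truth, every estimate can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .libstats import clade_distance_test, z_scores
from .phylo import DistanceMatrix, pairwise_distance_matrix
from .quantify import (
    RepeatLandscape,
    SpeciesProfile,
    build_landscape,
    mask_reads,
    profile_from_fragments,
)
from .seqcore import (
    SatFamily,
    align_pair_local,
    consensus_from_monomers,
    k2p_distance,
)
from .simulate import (
    LibraryModelConfig,
    SimulationTruth,
    emit_genome_and_reads,
    simulate_library_evolution,
)

__all__ = ["SurveyResult", "run_simulated_survey"]


@dataclass
class SurveyResult:
    """Everything the simulated survey measured, next to its ground truth."""

    config: LibraryModelConfig
    truth: SimulationTruth
    profiles: list[SpeciesProfile]
    landscapes: dict[tuple[str, str], RepeatLandscape]
    consensus: dict[str, dict[str, str]]  # species -> family -> estimated consensus
    genome_sizes: dict[str, int]

    def profile(self, species: str, family: str) -> SpeciesProfile:
        for p in self.profiles:
            if p.species_code == species and p.family_id == family:
                return p
        raise KeyError((species, family))

    def profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"species": p.species_code, "family": p.family_id,
                 "abundance_pct": p.abundance_pct,
                 "copy_number": p.copy_number,
                 "mean_k2p_pct": p.mean_k2p_pct}
                for p in self.profiles
            ]
        )

    def abundance_by_species(self, family: str) -> dict[str, float]:
        return {p.species_code: p.abundance_pct for p in self.profiles
                if p.family_id == family}

    def divergence_by_species(self, family: str) -> dict[str, float]:
        out = {}
        for p in self.profiles:
            if p.family_id == family and p.mean_k2p_pct is not None:
                out[p.species_code] = p.mean_k2p_pct
        return out

    def z_scores(self, family: str,
                 exclude: Optional[str] = None) -> tuple[dict, dict]:
        """(zs-abun, zs-div) maps for one family."""
        excl = [exclude] if exclude else None
        return (z_scores(self.abundance_by_species(family), excl),
                z_scores(self.divergence_by_species(family), excl))

    def consensus_distance_matrix(self, family: str,
                                  metric: str = "p") -> DistanceMatrix:
        """Pairwise distances between per-species estimated consensuses.

        Because each consensus was derived independently, their ends may
        not correspond exactly; each pair is therefore locally aligned
        before the distance is computed.
        """
        labels = tuple(sorted(self.consensus))
        seqs = [self.consensus[sp][family] for sp in labels]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s = align_pair_local(seqs[i], seqs[j])
                if s.aligned_sites == 0:
                    raise ValueError(
                        f"incomparable pair ({labels[i]}, {labels[j]})")
                if metric == "p":
                    dij = (s.transitions + s.transversions) / s.aligned_sites
                else:
                    dij = k2p_distance(s).k2p
                d[i, j] = d[j, i] = dij
        return DistanceMatrix(labels, d)


def run_simulated_survey(
    config: LibraryModelConfig,
    coverage: float = 5.0,
    read_length: int = 100,
    bin_width: float = 1.0,
    consensus_sample: int = 30,
    min_score: int = 40,
) -> SurveyResult:
    """Simulate, sequence and re-measure every species in ``config``.

    Each species' reads are masked against its own estimated family
    consensuses (majority consensus of a random sample of its monomer
    copies), mirroring how per-species references are assembled from real
    libraries; intraspecific divergence is therefore divergence to the
    species' own consensus.
    """
    arrays, truth = simulate_library_evolution(config)
    rng = np.random.default_rng(config.seed)
    read_seeds = {sp: int(rng.integers(0, 2**31 - 1))
                  for sp in sorted(arrays)}
    profiles: list[SpeciesProfile] = []
    landscapes: dict[tuple[str, str], RepeatLandscape] = {}
    consensus: dict[str, dict[str, str]] = {}
    genome_sizes: dict[str, int] = {}
    for species in sorted(arrays):
        fams = arrays[species]
        est: dict[str, str] = {}
        for fid in sorted(fams):
            copies = fams[fid]
            if len(copies) >= 2:
                k = min(consensus_sample, len(copies))
                idx = rng.choice(len(copies), size=k, replace=False)
                est[fid] = consensus_from_monomers([copies[i] for i in idx])
            else:
                est[fid] = copies[0]
        consensus[species] = est
        genome, reads = emit_genome_and_reads(
            fams, config.background_genome_length, read_length, coverage,
            seed=read_seeds[species], species_code=species)
        genome_sizes[species] = len(genome.sequence)
        families = [SatFamily(fid, est[fid]) for fid in sorted(est)]
        total_nt = sum(len(r) for r in reads)
        fragments = mask_reads(reads, families, min_score=min_score)
        for fam in families:
            profiles.append(
                profile_from_fragments(fragments, total_nt,
                                       len(genome.sequence), fam,
                                       species_code=species))
            landscapes[(species, fam.family_id)] = build_landscape(
                fragments, total_nt, bin_width, species, fam.family_id)
    return SurveyResult(config, truth, profiles, landscapes, consensus,
                        genome_sizes)
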