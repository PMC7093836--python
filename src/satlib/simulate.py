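"""Simulator for satDNA library evolution along a dated phylogeny.

Each family starts as an array of identical copies of an ancestral
consensus in the root genome. Along every branch, copies accumulate point
mutations (Poisson per copy, rate mu substitutions/site/Myr), and
branch-specific events reshape the array:

* amplification: a random contiguous window of copies is replicated until
  the copy count has grown by the given factor; the new copies are exact
  duplicates at event time, which is the homogenizing effect that drives
  intraspecific divergence down after an amplification (array-local window
  copying approximates unequal crossing over);
* contraction: a given fraction of copies, chosen uniformly, is removed.

Recent amplifications therefore leave a signature of high abundance with
low intraspecific divergence, whereas old, quiescent families drift to
high divergence - the pattern the downstream z-score standardization is
designed to read. Indels are not simulated (monomer length is fixed).

Leaf arrays can be embedded in a random background genome and sequenced
into uniform shotgun reads, giving every downstream stage a fully known
ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .io import SequenceRecord
from .seqcore import SatFamily, p_distance, reverse_complement

__all__ = [
    "AmplificationEvent",
    "ContractionEvent",
    "LibraryModelConfig",
    "SimulationTruth",
    "TruthRecord",
    "simulate_library_evolution",
    "emit_genome_and_reads",
    "random_monomer",
    "default_config",
    "DEFAULT_NEWICK",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AmplificationEvent:
    """Replicate a window of ``window`` copies until count x= ``factor``."""

    branch: str  # label of the branch's child node
    time_ma: float  # age (Ma) at which the event fires; within the branch
    family_id: str
    window: int
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 1:
            raise ValueError("amplification factor must exceed 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass(frozen=True)
class ContractionEvent:
    """Remove a uniform random ``fraction`` of the copies."""

    branch: str
    time_ma: float
    family_id: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction removed must lie in (0, 1)")


@dataclass(frozen=True)
class LibraryModelConfig:
    """Full specification of one library-evolution simulation.

    ``tree`` is a dated Newick string (branch lengths in Myr, internal
    nodes labelled so events can address their branches). ``families``
    maps each ancestral family to its initial copy count. ``mu`` is the
    per-copy point-mutation rate in substitutions/site/Myr.
    """

    newick: str
    families: tuple[tuple[SatFamily, int], ...]
    mu: float
    amp_events: tuple[AmplificationEvent, ...] = ()
    contr_events: tuple[ContractionEvent, ...] = ()
    background_genome_length: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        ids = [f.family_id for f, _ in self.families]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate family ids")

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick",
                                 preserve_underscores=True)


@dataclass(frozen=True)
class TruthRecord:
    species_code: str
    family_id: str
    copy_count: int
    abundance_fraction: float
    mean_pairwise_divergence: float


@dataclass(frozen=True)
class SimulationTruth:
    records: tuple[TruthRecord, ...]
    event_log: tuple[tuple, ...]  # (species-or-node, age, family, kind, detail)

    def get(self, species: str, family: str) -> TruthRecord:
        for r in self.records:
            if r.species_code == species and r.family_id == family:
                return r
        raise KeyError((species, family))


def random_monomer(length: int, rng: np.random.Generator,
                   at_fraction: float = 0.57) -> str:
    """Random monomer with a target A+T fraction (satDNA is AT-rich)."""
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return "".join(rng.choice(list("ATCG"), size=length,
                              p=[p_at, p_at, p_gc, p_gc]))


def _mutate(copies: list[np.ndarray], mu: float, dt: float,
            rng: np.random.Generator) -> None:
    if mu <= 0 or dt <= 0:
        return
    for arr in copies:
        k = rng.poisson(mu * len(arr) * dt)
        if k == 0:
            continue
        sites = rng.integers(0, len(arr), size=k)
        for s in sites:
            choices = _BASES[_BASES != arr[s]]
            arr[s] = choices[rng.integers(0, 3)]


def _node_ages(tree: dendropy.Tree) -> dict:
    tree.calc_node_ages(ultrametricity_precision=1e-6)
    return {}


def _label(node: dendropy.Node) -> Optional[str]:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def simulate_library_evolution(
    config: LibraryModelConfig,
) -> tuple[dict[str, dict[str, list[str]]], SimulationTruth]:
    """Evolve the ancestral arrays down the tree; return leaf arrays + truth.

    Returns ``(arrays, truth)`` where ``arrays[species][family_id]`` is the
    list of monomer copies carried by that species. Identical seeds give
    identical output.
    """
    tree = config.tree()
    tree.calc_node_ages(ultrametricity_precision=1e-2)
    rng = np.random.default_rng(config.seed)
    known = {_label(n) for n in tree if _label(n)}
    events: dict[str, list] = {}
    for ev in itertools.chain(config.amp_events, config.contr_events):
        if ev.branch not in known:
            raise ValueError(f"event addresses unknown branch {ev.branch!r}")
        events.setdefault(ev.branch, []).append(ev)
    fam_by_id = {f.family_id: f for f, _ in config.families}
    for evs in events.values():
        for ev in evs:
            if ev.family_id not in fam_by_id:
                raise ValueError(f"event addresses unknown family {ev.family_id!r}")

    root_state = {
        f.family_id: [np.frombuffer(f.consensus.encode(), dtype=np.uint8).copy()
                      for _ in range(n0)]
        for f, n0 in config.families
    }
    event_log: list[tuple] = []
    arrays: dict[str, dict[str, list[str]]] = {}

    def _descend(node: dendropy.Node, state: dict[str, list[np.ndarray]]) -> None:
        label = _label(node)
        if node.parent_node is not None:
            parent_age = node.parent_node.age
            child_age = node.age
            branch_events = sorted(events.get(label, []),
                                   key=lambda e: -e.time_ma)
            t = parent_age
            for ev in branch_events:
                if not child_age - 1e-9 <= ev.time_ma <= parent_age + 1e-9:
                    raise ValueError(
                        f"event age {ev.time_ma} outside branch {label!r} "
                        f"span [{child_age:.3g}, {parent_age:.3g}]"
                    )
                for fid in state:
                    _mutate(state[fid], config.mu, t - ev.time_ma, rng)
                copies = state[ev.family_id]
                if isinstance(ev, AmplificationEvent):
                    target = round(len(copies) * ev.factor)
                    w = min(ev.window, len(copies))
                    start = int(rng.integers(0, len(copies) - w + 1))
                    window = [c.copy() for c in copies[start:start + w]]
                    new = []
                    for i in range(target - len(copies)):
                        new.append(window[i % w].copy())
                    copies[start + w:start + w] = new
                    event_log.append((label, ev.time_ma, ev.family_id,
                                      "amplification", ev.factor))
                else:
                    n_remove = round(len(copies) * ev.fraction)
                    n_remove = min(n_remove, len(copies) - 1)
                    drop = set(rng.choice(len(copies), size=n_remove,
                                          replace=False).tolist())
                    state[ev.family_id] = [c for i, c in enumerate(copies)
                                           if i not in drop]
                    event_log.append((label, ev.time_ma, ev.family_id,
                                      "contraction", ev.fraction))
                t = ev.time_ma
            for fid in state:
                _mutate(state[fid], config.mu, t - child_age, rng)
        if node.is_leaf():
            arrays[label] = {
                fid: [c.tobytes().decode() for c in copies]
                for fid, copies in state.items()
            }
        else:
            for child in node.child_nodes():
                _descend(child, {fid: [c.copy() for c in copies]
                                 for fid, copies in state.items()})

    _descend(tree.seed_node, root_state)

    records = []
    for species, fams in sorted(arrays.items()):
        sat_nt = sum(len(fam_by_id[fid].consensus) * len(copies)
                     for fid, copies in fams.items())
        genome_nt = config.background_genome_length + sat_nt
        for fid, copies in sorted(fams.items()):
            mono = len(fam_by_id[fid].consensus)
            records.append(TruthRecord(
                species, fid, len(copies),
                mono * len(copies) / genome_nt,
                _mean_pairwise_divergence(copies, rng),
            ))
    return arrays, SimulationTruth(tuple(records), tuple(event_log))


def _mean_pairwise_divergence(copies: Sequence[str], rng: np.random.Generator,
                              max_sample: int = 120) -> float:
    if len(copies) < 2:
        return 0.0
    if len(copies) > max_sample:
        idx = rng.choice(len(copies), size=max_sample, replace=False)
        copies = [copies[i] for i in idx]
    total = 0.0
    n = 0
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            total += p_distance(copies[i], copies[j])
            n += 1
    return total / n


def emit_genome_and_reads(
    arrays: Mapping[str, list[str]],
    background_length: int,
    read_length: int,
    coverage: float,
    seed: int,
    species_code: str = "sim",
) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """Build one species' genome and shotgun-sequence it.

    Each family's copies are concatenated into a single tandem block and
    the blocks are inserted at random positions of a seeded random
    background. Reads of fixed length are drawn uniformly, from either
    strand with probability 1/2; the read count is
    round(coverage x genome_length / read_length).
    """
    if read_length < 50:
        raise ValueError("read_length must be >= 50")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    background = "".join(rng.choice(list("ACGT"), size=background_length))
    blocks = ["".join(copies) for _, copies in sorted(arrays.items())]
    cut_points = sorted(rng.integers(0, background_length + 1,
                                     size=len(blocks)).tolist())
    genome_parts = []
    prev = 0
    for cut, block in zip(cut_points, blocks):
        genome_parts.append(background[prev:cut])
        genome_parts.append(block)
        prev = cut
    genome_parts.append(background[prev:])
    genome = "".join(genome_parts)
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    n_reads = round(coverage * len(genome) / read_length)
    reads = []
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    for i, (start, minus) in enumerate(zip(starts, strands)):
        seq = genome[start:start + read_length]
        if minus:
            seq = reverse_complement(seq)
        reads.append(SequenceRecord(f"{species_code}_read{i}", seq,
                                    (40,) * read_length))
    return SequenceRecord(f"{species_code}_genome", genome), reads


# --- default study design -------------------------------------------------

# Ten species: the outgroup splits 7.9 Ma; the ingroup radiates into four
# clades ({SFLA,SCAR}, {SPAL,SCAN}, {SSEC,SAME}, {SDAM,{SCER,SRUB}}) with
# node ages 5.0, 4.0, 2.5, 2.0, 1.5 Ma matching the dated phylogeny the
# analysis is calibrated on.
DEFAULT_NEWICK = (
    "(SGRE:7.9,((SFLA:1.5,SCAR:1.5)c1:3.5,((SPAL:2.0,SCAN:2.0)c2:2.0,"
    "((SSEC:2.5,SAME:2.5)c3:1.5,(SDAM:2.5,(SCER:1.5,SRUB:1.5)c44:1.0)"
    "c4:1.5)c34:0.0)c234:1.0)amer:2.9)root;"
)


def default_config(seed: int = 0,
                   background_genome_length: int = 50_000,
                   mu: float = 0.015) -> LibraryModelConfig:
    """A ten-species design emulating the study system.

    Three families (170, 350 and 170 bp monomers, ~57% A+T). The outgroup
    branch carries large recent amplifications of families FAM1 and FAM2
    (the zs-abun >> 0, zs-div << 0 signature); clade c1 shares an ancestral
    FAM1 amplification; every clade stem amplifies FAM3 so its consensus
    distances track the phylogeny; clade-4 species contract FAM1, and FAM2
    contracts across clades 3-4 except for a recent burst in SRUB.
    mu = 0.015 substitutions/site/Myr gives fragment divergences and
    per-lineage rates on the scale observed in real satDNA surveys.
    """
    rng = np.random.default_rng(seed)
    fam1 = SatFamily("FAM1", random_monomer(170, rng))
    fam2 = SatFamily("FAM2", random_monomer(350, rng))
    fam3 = SatFamily("FAM3", random_monomer(170, rng))
    # Homogenizing amplifications replicate a single source copy
    # (window=1): the duplicated variant becomes the array majority, so
    # the species consensus tracks it and intraspecific divergence drops -
    # the driftlike consensus dynamics the library model predicts.
    amp = (
        AmplificationEvent("SGRE", 0.3, "FAM1", window=1, factor=4.0),
        AmplificationEvent("SGRE", 0.4, "FAM2", window=1, factor=3.0),
        AmplificationEvent("c1", 4.0, "FAM1", window=1, factor=3.0),
        AmplificationEvent("SPAL", 1.0, "FAM1", window=1, factor=2.5),
        AmplificationEvent("SRUB", 0.5, "FAM2", window=1, factor=3.0),
        # every clade stem amplifies FAM3, so its consensus distances
        # carry the phylogenetic signal (within < between clades)
        AmplificationEvent("c1", 4.5, "FAM3", window=1, factor=3.0),
        AmplificationEvent("c2", 3.0, "FAM3", window=1, factor=3.0),
        AmplificationEvent("c3", 3.0, "FAM3", window=1, factor=3.0),
        AmplificationEvent("c4", 3.0, "FAM3", window=1, factor=3.0),
    )
    contr = (
        ContractionEvent("SCER", 1.0, "FAM1", fraction=0.8),
        ContractionEvent("SRUB", 1.0, "FAM1", fraction=0.7),
        ContractionEvent("SSEC", 1.5, "FAM2", fraction=0.6),
        ContractionEvent("SAME", 1.5, "FAM2", fraction=0.6),
        ContractionEvent("SDAM", 1.5, "FAM2", fraction=0.6),
        ContractionEvent("SCER", 1.0, "FAM2", fraction=0.5),
    )
    return LibraryModelConfig(
        newick=DEFAULT_NEWICK,
        families=((fam1, 60), (fam2, 25), (fam3, 40)),
        mu=mu,
        amp_events=amp,
        contr_events=contr,
        background_genome_length=background_genome_length,
        seed=seed,
    )
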