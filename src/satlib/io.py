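"""Reading and writing the pipeline's file formats.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; this module adds the
validation the pipeline relies on (DNA alphabet, unique ids, quality length)
plus seed-deterministic read subsampling and the tabular outputs
(per-species profiles, species tables with clade and FISH-locus metadata).
"""

from __future__ import annotations

import gzip
import io as _io
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "SpeciesInfo",
    "SpeciesTable",
    "read_sequences",
    "write_sequences",
    "subsample_reads",
    "write_profile_table",
    "read_profile_table",
    "read_species_table",
    "read_config",
    "round_half_up",
]

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence (read, contig or consensus), optionally with qualities."""

    id: str
    sequence: str
    quality: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if self.quality is not None:
            if len(self.quality) != len(seq):
                raise ValueError(
                    f"record {self.id!r}: quality length {len(self.quality)} "
                    f"!= sequence length {len(seq)}"
                )
            object.__setattr__(self, "quality", tuple(self.quality))

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path, format: Optional[str] = None) -> list[SequenceRecord]:
    """Parse a FASTA or FASTQ file into validated SequenceRecords.

    ``format`` is "fasta" or "fastq"; when omitted it is inferred from the
    file extension. Lowercase bases are uppercased; ids must be unique.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        ext = stem.rsplit(".", 1)[-1].lower()
        format = {"fa": "fasta", "fasta": "fasta", "fna": "fasta",
                  "fq": "fastq", "fastq": "fastq"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer sequence format from {path.name!r}")
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown sequence format {format!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, format)):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            qual = rec.letter_annotations.get("phred_quality")
            try:
                records.append(
                    SequenceRecord(rec.id, str(rec.seq),
                                   tuple(qual) if qual is not None else None)
                )
            except ValueError as exc:
                raise ValueError(f"{path}, record {i + 1}: {exc}") from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path,
                    format: str = "fasta") -> None:
    """Write records as FASTA or FASTQ (Sanger qualities)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown sequence format {format!r}")
    out = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        if format == "fastq":
            qual = rec.quality if rec.quality is not None else (40,) * len(rec)
            sr.letter_annotations["phred_quality"] = list(qual)
        out.append(sr)
    with _open_text(path, "wt") as handle:
        SeqIO.write(out, handle, format)


def subsample_reads(records: Sequence[SequenceRecord], n: int,
                    seed: int) -> list[SequenceRecord]:
    """Uniform sample of ``n`` records without replacement, seed-deterministic.

    The sampled records are returned in their original file order.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > len(records):
        raise ValueError(
            f"requested {n} reads but only {len(records)} are available"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=n, replace=False))
    return [records[i] for i in idx]


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up (2.5 -> 3), as printed tables round."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def read_config(path) -> dict:
    """Read a key:value run configuration (YAML; flat key:value suffices).

    Typical keys: reads, families, species table, genome size, seed,
    bin width. Returned as a plain dict; callers validate what they use.
    """
    import yaml

    with _open_text(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a key:value mapping")
    return data


_PROFILE_COLUMNS = ["species", "family", "monomer_size", "at_percent",
                    "abundance_pct", "copy_number", "mean_k2p_pct"]


def write_profile_table(profiles: Sequence, path) -> None:
    """Serialize SpeciesProfile rows as TSV at reporting precision.

    Abundance and mean K2P are rounded half-up to 2 decimals; a missing
    divergence (no masked fragments) is written as NA.
    """
    if not profiles:
        raise ValueError("no profiles to write")
    rows = []
    for p in profiles:
        rows.append({
            "species": p.species_code,
            "family": p.family_id,
            "monomer_size": p.monomer_size,
            "at_percent": round_half_up(p.at_percent, 1),
            "abundance_pct": round_half_up(p.abundance_pct, 2),
            "copy_number": p.copy_number,
            "mean_k2p_pct": (round_half_up(p.mean_k2p_pct, 2)
                             if p.mean_k2p_pct is not None else "NA"),
        })
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profile_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(_PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    return df


@dataclass(frozen=True)
class SpeciesInfo:
    species_code: str
    clade: str  # clade label, or "outgroup"
    loci_counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def is_outgroup(self) -> bool:
        return self.clade == "outgroup"


@dataclass(frozen=True)
class SpeciesTable:
    """Clade assignments, FISH locus counts and the radiation date."""

    species: tuple[SpeciesInfo, ...]
    divergence_time_myr: float

    def __post_init__(self) -> None:
        codes = [s.species_code for s in self.species]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate species codes")
        outgroups = [s for s in self.species if s.is_outgroup]
        if len(outgroups) > 1:
            raise ValueError("at most one outgroup species is permitted")
        if self.divergence_time_myr <= 0:
            raise ValueError("divergence time must be positive")
        for s in self.species:
            if any(v < 0 for v in s.loci_counts.values()):
                raise ValueError(f"{s.species_code}: negative locus count")

    @property
    def outgroup(self) -> Optional[str]:
        for s in self.species:
            if s.is_outgroup:
                return s.species_code
        return None

    def clade_map(self, include_outgroup: bool = False) -> dict[str, str]:
        return {s.species_code: s.clade for s in self.species
                if include_outgroup or not s.is_outgroup}

    def loci(self, family_id: str) -> dict[str, int]:
        return {s.species_code: s.loci_counts[family_id] for s in self.species
                if family_id in s.loci_counts}


def read_species_table(path) -> SpeciesTable:
    """Read a species TSV: columns ``species``, ``clade``,
    ``divergence_time_myr`` and any number of ``loci_<FAMILY>`` columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"species", "clade", "divergence_time_myr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    loci_cols = [c for c in df.columns if c.startswith("loci_")]
    species = []
    for _, row in df.iterrows():
        loci = {c[len("loci_"):]: int(row[c]) for c in loci_cols
                if not pd.isna(row[c])}
        species.append(SpeciesInfo(str(row["species"]), str(row["clade"]), loci))
    times = df["divergence_time_myr"].dropna().unique()
    if len(times) != 1:
        raise ValueError("divergence_time_myr must be a single shared value")
    return SpeciesTable(tuple(species), float(times[0]))
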