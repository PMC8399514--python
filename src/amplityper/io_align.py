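"""Aligned-FASTA and population-metadata I/O.

Sequences are stored uppercase over the IUPAC nucleotide alphabet plus the
gap character ``-``.  All alignment coordinates reported anywhere in this
package are 1-based column indices in alignment space; degapped (read)
coordinates appear only inside the phasing forward model and are labelled
as such.

FASTA headers carry per-sequence metadata in a ``|``-separated dialect::

    >id|species|population|provenance

Absent fields default to ``unknown`` / ``direct``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: provenance values for a sequence: read directly from a clear chromatogram,
#: recovered from a heterozygous individual by base subtraction, or the
#: dominant copy of a skewed mixture.
PROVENANCES = ("direct", "extracted_from_heterozygote", "dominant_only")

MARKERS = ("ITS", "trnL-trnF", "rpl32-trnL", "other")


class AlignmentShapeError(ValueError):
    """Records in one alignment have differing lengths."""


class CharacterError(ValueError):
    """A residue outside the IUPAC nucleotide alphabet (+ gap)."""


class SchemaError(ValueError):
    """Malformed or inconsistent population metadata."""


@dataclass(frozen=True)
class AlignedSequence:
    """One gapped sequence with its sample metadata."""

    id: str
    residues: str
    species: str = "unknown"
    population: str = "unknown"
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        residues = self.residues.upper().replace("U", "T")
        if "U" in self.residues.upper():
            logger.info("sequence %s: mapped U to T", self.id)
        object.__setattr__(self, "residues", residues)
        for col, ch in enumerate(residues, start=1):
            if ch not in IUPAC_CHARS:
                raise CharacterError(
                    f"sequence {self.id!r}: illegal character {ch!r} at column {col}"
                )

    def degapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """An ordered, equal-length collection of aligned sequences."""

    sequences: list[AlignedSequence]
    marker: str = "other"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment needs at least one sequence")
        lengths = {len(s.residues) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"ragged alignment: record lengths {sorted(lengths)}"
            )
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")

    @property
    def length(self) -> int:
        return len(self.sequences[0].residues)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def column(self, position: int) -> str:
        """States of 1-based alignment column `position`, one per sequence."""
        if not 1 <= position <= self.length:
            raise IndexError(f"column {position} outside 1..{self.length}")
        return "".join(s.residues[position - 1] for s in self.sequences)

    def get(self, seq_id: str) -> AlignedSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)


@dataclass(frozen=True)
class PopulationRecord:
    """Sampling locality of one population."""

    population: str
    country: str
    latitude: float
    longitude: float
    species: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


def _parse_header(header: str) -> tuple[str, str, str, str]:
    parts = header.split("|")
    parts += ["unknown"] * (4 - len(parts))
    seq_id, species, population, provenance = parts[:4]
    if provenance in ("", "unknown"):
        provenance = "direct"
    if species == "":
        species = "unknown"
    if population == "":
        population = "unknown"
    return seq_id, species, population, provenance


def read_sequences(path: str | Path) -> list[AlignedSequence]:
    """Read a (possibly ragged) multi-FASTA, e.g. ungapped direct reads."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    out = []
    for rec in records:
        seq_id, species, population, provenance = _parse_header(rec.description)
        out.append(AlignedSequence(id=seq_id, residues=str(rec.seq),
                                   species=species, population=population,
                                   provenance=provenance))
    return out


def read_aligned_fasta(path: str | Path, marker: str = "other") -> Alignment:
    """Read a gapped multi-FASTA into an :class:`Alignment`.

    Metadata is parsed from the ``id|species|population|provenance`` header
    convention when present; bare headers get defaults.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    seqs = []
    for rec in records:
        seq_id, species, population, provenance = _parse_header(rec.description)
        seqs.append(
            AlignedSequence(
                id=seq_id,
                residues=str(rec.seq),
                species=species,
                population=population,
                provenance=provenance,
            )
        )
    return Alignment(sequences=seqs, marker=marker)


def write_aligned_fasta(aln: Alignment, path: str | Path) -> Path:
    """Write an alignment; re-reading reproduces ids, residues and order."""
    path = Path(path)
    with open(path, "w") as fh:
        for s in aln:
            fh.write(f">{s.id}|{s.species}|{s.population}|{s.provenance}\n")
            fh.write(s.residues + "\n")
    return path


_POP_COLUMNS = ("population", "country", "latitude", "longitude", "species")


def read_population_table(path: str | Path) -> list[PopulationRecord]:
    """Read population metadata CSV (population,country,latitude,longitude,species)."""
    df = pd.read_csv(path, dtype={"population": str, "country": str, "species": str})
    missing = [c for c in _POP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records = []
    seen: dict[str, PopulationRecord] = {}
    for _, row in df.iterrows():
        rec = PopulationRecord(
            population=str(row["population"]),
            country=str(row["country"]),
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            species=str(row["species"]),
        )
        if rec.population in seen and seen[rec.population] != rec:
            raise SchemaError(
                f"population {rec.population!r} duplicated with differing records"
            )
        seen[rec.population] = rec
        records.append(rec)
    # collapse exact duplicates, keep first occurrence order
    out, done = [], set()
    for rec in records:
        if rec.population not in done:
            out.append(rec)
            done.add(rec.population)
    return out


def write_population_table(records: Iterable[PopulationRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "population": r.population,
                "country": r.country,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "species": r.species,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    return path
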