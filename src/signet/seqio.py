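"""Sequence and tabular I/O for the signature-discovery toolkit.

This module owns the basic domain objects (sequence records with species
labels and role classes, reference panels, product records), FASTA reading
and writing, and access to the packaged fixtures: the four published
nucleotide signatures, the six species-specific primer pairs, the qPCR
dilution table and the two market-survey tables.

Conventions
-----------
* All coordinates are 0-based, half-open, on the forward strand of the
  stored sequence.
* Sequences are uppercase IUPAC DNA; ``-`` is the only gap character and
  is legal only in records flagged ``is_gapped``.
* Species names are full binomials ("Cynomorium songaricum"); the
  abbreviations used in the source tables ("Cy. songaricum") are mapped
  through :data:`SPECIES_SYNONYMS`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "Role",
    "DoseForm",
    "SeqRecord",
    "ReferencePanel",
    "ProductRecord",
    "AlphabetError",
    "FastaFormatError",
    "FixtureError",
    "IUPAC_SETS",
    "COMPLEMENT",
    "SPECIES_SYNONYMS",
    "normalize_species",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "load_signature_fixture",
    "load_primer_fixture",
    "load_survey_fixture",
    "data_path",
]

# --- alphabet ---------------------------------------------------------------

#: IUPAC nucleotide codes mapped to the set of concrete bases they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

GAP = "-"

#: Complement of every IUPAC code (ambiguity sets map to complemented sets).
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

#: Abbreviated genus names, as printed in the source tables, to binomials.
SPECIES_SYNONYMS: dict[str, str] = {
    "Cy. songaricum": "Cynomorium songaricum",
    "Ci. deserticola": "Cistanche deserticola",
    "Ci. tubulosa": "Cistanche tubulosa",
    "Ci. sinensis": "Cistanche sinensis",
    "Ci. salsa": "Cistanche salsa",
    "B. rossica": "Boschniakia rossica",
    "O. coerulescens": "Orobanche coerulescens",
    "S. miltiorrhiza": "Salvia miltiorrhiza",
}


def normalize_species(name: str) -> str:
    """Return the full binomial for *name*, resolving known abbreviations."""
    name = name.replace("_", " ").strip()
    return SPECIES_SYNONYMS.get(name, name)


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""


class FastaFormatError(ValueError):
    """A FASTA file violates the expected dialect (ids, gaps, duplicates)."""


class FixtureError(RuntimeError):
    """A packaged data fixture is missing or corrupt."""


class Role(str, Enum):
    """Role of a species in the reference universe."""

    OFFICIAL = "official"
    ADULTERANT = "adulterant"
    OTHER = "other"
    UNKNOWN = "unknown"


class DoseForm(str, Enum):
    SLICE = "slice"
    POWDER = "powder"
    EXTRACT = "extract"
    PILL = "pill"
    CAPSULE = "capsule"
    PARTICLE = "particle"


# --- domain types -----------------------------------------------------------


@dataclass(frozen=True)
class SeqRecord:
    """A labeled DNA sequence.

    Parameters
    ----------
    id:
        Record identifier, unique within a panel.
    seq:
        Uppercase IUPAC DNA; ``-`` allowed only when ``is_gapped``.
    species:
        Full binomial, or ``""`` when unknown.
    role:
        Role class of the species in the reference universe.
    is_gapped:
        Whether the record belongs to an aligned (gapped) dialect.
    """

    id: str
    seq: str
    species: str = ""
    role: Role = Role.UNKNOWN
    is_gapped: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        allowed = set(IUPAC_SETS)
        if self.is_gapped:
            allowed.add(GAP)
        for i, ch in enumerate(self.seq):
            if ch not in allowed:
                raise AlphabetError(
                    f"record {self.id!r}: illegal character {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def degapped(self) -> "SeqRecord":
        """Return an ungapped copy (identity if already ungapped)."""
        if not self.is_gapped:
            return self
        return SeqRecord(
            id=self.id,
            seq=self.seq.replace(GAP, ""),
            species=self.species,
            role=self.role,
            is_gapped=False,
        )


@dataclass
class ReferencePanel:
    """Labeled sequence universe against which diagnosticity is defined."""

    records: list[SeqRecord]
    species_roles: dict[str, Role] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaFormatError(f"duplicate record id {rec.id!r} in panel")
            seen.add(rec.id)
        for rec in self.records:
            if rec.species and rec.species not in self.species_roles:
                self.species_roles[rec.species] = rec.role

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.species and rec.species not in out:
                out.append(rec.species)
        return out

    def records_for(self, species: str) -> list[SeqRecord]:
        return [r for r in self.records if r.species == species]

    def role_of(self, species: str) -> Role:
        return self.species_roles.get(species, Role.UNKNOWN)

    def official_species(self) -> set[str]:
        return {s for s, r in self.species_roles.items() if r is Role.OFFICIAL}

    def adulterant_species(self) -> set[str]:
        return {s for s, r in self.species_roles.items() if r is Role.ADULTERANT}


@dataclass(frozen=True)
class ProductRecord:
    """One commercial product and the species detected in it."""

    product_id: str
    label: str
    dose_form: DoseForm
    detected_species: frozenset[str] = frozenset()


# --- basic sequence ops -----------------------------------------------------


def revcomp(seq: str) -> str:
    """Reverse complement of an ungapped IUPAC DNA string.

    Ambiguity codes map to their complements (R<->Y, K<->M, S/W/N fixed).
    """
    out = []
    for i, ch in enumerate(reversed(seq)):
        c = COMPLEMENT.get(ch.upper())
        if c is None:
            raise AlphabetError(
                f"illegal character {ch!r} at position {len(seq) - 1 - i} in revcomp"
            )
        out.append(c)
    return "".join(out)


# --- FASTA ------------------------------------------------------------------


def _parse_header(line: str) -> tuple[str, dict[str, str]]:
    parts = line[1:].strip().split()
    if not parts:
        raise FastaFormatError("FASTA header with no id")
    rec_id = parts[0]
    kv: dict[str, str] = {}
    for tok in parts[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            kv[k] = v
    return rec_id, kv


def read_fasta(
    path: str | Path,
    role_map: Optional[Mapping[str, Role | str]] = None,
) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, in file order.

    Headers are ``>id key=value ...``; a ``species=`` key (with underscores
    for spaces) labels the record, and roles come from the optional
    *role_map* (species -> role) or a ``role=`` header key.

    If any record contains ``-`` the file is treated as the aligned dialect:
    every record must then have the same length and all records are flagged
    gapped. Mixed gapped/ungapped input of unequal lengths is rejected.
    """
    path = Path(path)
    raw: list[tuple[str, dict[str, str], str]] = []
    rec_id: Optional[str] = None
    kv: dict[str, str] = {}
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if rec_id is not None:
                    raw.append((rec_id, kv, "".join(chunks)))
                rec_id, kv = _parse_header(line)
                chunks = []
            else:
                if rec_id is None:
                    raise FastaFormatError(f"{path}: sequence before first header")
                chunks.append(line.strip())
        if rec_id is not None:
            raw.append((rec_id, kv, "".join(chunks)))
    if not raw:
        raise FastaFormatError(f"{path}: no records")

    seen: set[str] = set()
    any_gap = any(GAP in seq for _, _, seq in raw)
    if any_gap:
        lengths = {len(seq) for _, _, seq in raw}
        if len(lengths) != 1:
            raise FastaFormatError(
                f"{path}: gapped (aligned) dialect requires equal-length records"
            )

    records: list[SeqRecord] = []
    for rid, keys, seq in raw:
        if rid in seen:
            raise FastaFormatError(f"{path}: duplicate id {rid!r}")
        seen.add(rid)
        species = normalize_species(keys.get("species", ""))
        role = Role.UNKNOWN
        if role_map and species in role_map:
            role = Role(role_map[species])
        elif "role" in keys:
            role = Role(keys["role"])
        records.append(
            SeqRecord(
                id=rid,
                seq=seq.upper(),
                species=species,
                role=role,
                is_gapped=any_gap,
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 70) -> None:
    """Write records as FASTA, 70-column wrap, species/role as key=value."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.species:
                header += f" species={rec.species.replace(' ', '_')}"
            if rec.role is not Role.UNKNOWN:
                header += f" role={rec.role.value}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


# --- packaged fixtures ------------------------------------------------------


def data_path(name: str) -> Path:
    """Path to a packaged data file (signatures, primers, tables)."""
    p = resources.files("signet.data").joinpath(name)
    try:
        return Path(str(p))
    except Exception as exc:  # pragma: no cover
        raise FixtureError(f"packaged fixture {name!r} unavailable: {exc}") from exc


def load_signature_fixture() -> list[SeqRecord]:
    """The four published species-diagnostic signatures (30/34/37/31 bp)."""
    path = data_path("signatures.fasta")
    if not path.exists():
        raise FixtureError("signatures.fasta fixture missing")
    recs = read_fasta(path)
    if len(recs) != 4:
        raise FixtureError(f"signatures.fasta: expected 4 records, got {len(recs)}")
    return recs


def load_primer_fixture() -> list[dict]:
    """The six published primer pairs as raw dicts (see assay module)."""
    path = data_path("primers.json")
    if not path.exists():
        raise FixtureError("primers.json fixture missing")
    with open(path) as fh:
        entries = json.load(fh)
    if len(entries) != 6:
        raise FixtureError(f"primers.json: expected 6 assays, got {len(entries)}")
    return entries


def _read_product_csv(path: Path) -> list[ProductRecord]:
    out: list[ProductRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            detected = frozenset(
                normalize_species(s)
                for s in row["detected_species"].split(";")
                if s.strip()
            )
            out.append(
                ProductRecord(
                    product_id=row["product_id"],
                    label=row["label"],
                    dose_form=DoseForm(row["dose_form"]),
                    detected_species=detected,
                )
            )
    return out


def load_survey_fixture() -> list[ProductRecord]:
    """All 66 surveyed products (35 slices/powders/extracts + 31 medicines)."""
    records: list[ProductRecord] = []
    for name, expected in (("survey_table1.csv", 35), ("survey_table2.csv", 31)):
        path = data_path(name)
        if not path.exists():
            raise FixtureError(f"{name} fixture missing")
        part = _read_product_csv(path)
        if len(part) != expected:
            raise FixtureError(f"{name}: expected {expected} rows, got {len(part)}")
        records.extend(part)
    ids = [r.product_id for r in records]
    if len(set(ids)) != len(ids):
        raise FixtureError("duplicate product ids across survey tables")
    return records
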