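"""Domain types and table readers/writers.

All tabular formats are plain-text: comma-separated UTF-8 with a header row,
except the chemical-protein links table which mirrors the STITCH links
dialect (tab-separated: chemical, protein, combined_score).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .fingerprints import DEFAULT_BACKEND, DEFAULT_N_BITS, Fingerprint, fingerprint_from_smiles

logger = logging.getLogger(__name__)

SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DrugRecord:
    """One library compound, keyed by an opaque string id."""

    drug_id: str
    smiles: Optional[str] = None
    fingerprint: Optional[Fingerprint] = None

    def require_fingerprint(self) -> Fingerprint:
        if self.fingerprint is None:
            raise ValueError(f"drug {self.drug_id!r} has no fingerprint")
        return self.fingerprint


#: A drug library is an insertion-ordered mapping drug_id -> DrugRecord.
DrugLibrary = Dict[str, DrugRecord]


@dataclass
class TargetMap:
    """Drug -> protein-target sets over a fixed protein universe.

    ``universe_size`` is the number of proteins in the reference interactome;
    when an explicit roster is given, membership of every target set in the
    roster is enforced.
    """

    associations: Dict[str, FrozenSet[str]]
    universe_size: int
    universe: Optional[FrozenSet[str]] = None

    def __post_init__(self) -> None:
        union: set = set()
        for targets in self.associations.values():
            union.update(targets)
        if self.universe is not None:
            stray = union - self.universe
            if stray:
                raise ValueError(f"target proteins outside the universe roster: {sorted(stray)[:5]}")
            if self.universe_size != len(self.universe):
                raise ValueError("universe_size does not match the roster length")
        if self.universe_size < len(union):
            raise ValueError(
                f"universe_size {self.universe_size} smaller than the union of "
                f"target sets ({len(union)})")

    def targets_of(self, drug_id: str) -> FrozenSet[str]:
        return self.associations.get(drug_id, frozenset())


@dataclass
class ResponseMatrix:
    """Monotherapy pIC50 responses, at most one value per (drug, cell line)."""

    entries: Dict[Tuple[str, str], float]
    cell_line_tissue: Dict[str, str] = field(default_factory=dict)

    def profile(self, drug_id: str) -> Dict[str, float]:
        """The drug's cell_line -> pIC50 map (its pharmacological profile)."""
        return {cell: v for (d, cell), v in self.entries.items() if d == drug_id}

    def drug_ids(self) -> List[str]:
        seen: Dict[str, None] = {}
        for drug, _cell in self.entries:
            seen.setdefault(drug, None)
        return list(seen)


@dataclass(frozen=True)
class SynergyRecord:
    """One drug pair x cell line with its synergy score (the unit of augmentation).

    Pairs are canonicalized so that ``drug_a < drug_b`` lexicographically;
    self-pairs are rejected.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    synergy_score: float
    tissue: str

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-pair rejected: {self.drug_a!r}")
        if self.drug_b < self.drug_a:
            a, b = self.drug_b, self.drug_a
            object.__setattr__(self, "drug_a", a)
            object.__setattr__(self, "drug_b", b)

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.drug_a, self.drug_b)

    @property
    def key(self) -> Tuple[str, str, str]:
        """Deduplication key: canonical pair + cell line."""
        return (self.drug_a, self.drug_b, self.cell_line)


@dataclass(frozen=True)
class AugmentedRecord:
    """A single-substitution copy of a parent SynergyRecord with the label transferred.

    Exactly one slot of the parent pair is replaced; cell line and synergy
    score are inherited from the parent.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    synergy_score: float
    tissue: str
    parent_a: str
    parent_b: str
    substituted_slot: str  # "first" | "second"
    substitute_id: str
    dacs_to_parent: float

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-pair rejected: {self.drug_a!r}")
        if self.drug_b < self.drug_a:
            a, b = self.drug_b, self.drug_a
            object.__setattr__(self, "drug_a", a)
            object.__setattr__(self, "drug_b", b)
        if self.substituted_slot not in ("first", "second"):
            raise ValueError(f"substituted_slot must be 'first' or 'second', got {self.substituted_slot!r}")
        if self.substitute_id in (self.parent_a, self.parent_b):
            raise ValueError("substitute equals a parent-pair member")

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.drug_a, self.drug_b)

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.drug_a, self.drug_b, self.cell_line)

    @property
    def parent_key(self) -> Tuple[str, str, str]:
        a, b = sorted((self.parent_a, self.parent_b))
        return (a, b, self.cell_line)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_drug_library(path: str | Path, dialect: str = "smiles_csv",
                      n_bits: int = DEFAULT_N_BITS,
                      backend: str = DEFAULT_BACKEND) -> DrugLibrary:
    """Load a drug library CSV.

    ``smiles_csv`` expects columns ``drug_id,smiles``; fingerprints are
    computed from SMILES. ``fingerprint_csv`` expects
    ``drug_id,fingerprint[,n_bits][,backend][,smiles]`` with on-bit indices
    ';'-joined.
    """
    if dialect not in ("smiles_csv", "fingerprint_csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str)
    if "drug_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'drug_id'")

    dupes = df["drug_id"][df["drug_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate drug_id {dupes[0]!r}")

    library: DrugLibrary = {}
    for idx, row in df.iterrows():
        drug_id = row["drug_id"]
        smiles = row.get("smiles")
        smiles = None if pd.isna(smiles) else str(smiles)
        if dialect == "smiles_csv":
            if smiles is None:
                raise ValueError(f"{path} row {idx}: missing SMILES for {drug_id!r}")
            try:
                fp = fingerprint_from_smiles(smiles, n_bits=n_bits, backend=backend)
            except ValueError as exc:
                raise ValueError(f"{path} row {idx}: {exc}") from exc
        else:
            raw = row.get("fingerprint")
            raw = "" if pd.isna(raw) else str(raw)
            row_bits = int(row["n_bits"]) if "n_bits" in df.columns and not pd.isna(row.get("n_bits")) else n_bits
            row_backend = str(row["backend"]) if "backend" in df.columns and not pd.isna(row.get("backend")) else backend
            fp = Fingerprint.from_string(raw, n_bits=row_bits, backend=row_backend)
        library[drug_id] = DrugRecord(drug_id=drug_id, smiles=smiles, fingerprint=fp)
    return library


def read_target_links(path: str | Path, score_min: float = 0.0,
                      roster: Optional[Iterable[str]] = None) -> TargetMap:
    """Load a STITCH-dialect chemical-protein links TSV into a TargetMap.

    Rows with score below ``score_min`` are dropped; malformed rows are
    skipped and their count logged. Without an explicit protein roster the
    universe is the union of proteins seen in the file (before score
    filtering).
    """
    associations: Dict[str, set] = {}
    proteins_seen: set = set()
    n_rows = n_skipped = n_filtered = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty links file")
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            n_rows += 1
            if len(row) < 3:
                n_skipped += 1
                continue
            chemical, protein = row[0].strip(), row[1].strip()
            try:
                score = float(row[2])
            except ValueError:
                n_skipped += 1
                continue
            proteins_seen.add(protein)
            if score < score_min:
                n_filtered += 1
                continue
            associations.setdefault(chemical, set()).add(protein)
    if n_skipped:
        logger.warning("%s: skipped %d malformed link rows (of %d)", path, n_skipped, n_rows)
    if not associations:
        logger.warning("%s: no chemical-protein links at score_min=%s", path, score_min)
    if roster is not None:
        universe = frozenset(roster)
    else:
        universe = frozenset(proteins_seen)
    return TargetMap(
        associations={k: frozenset(v) for k, v in associations.items()},
        universe_size=len(universe),
        universe=universe,
    )


def read_response_table(path: str | Path) -> ResponseMatrix:
    """Load a monotherapy response CSV with columns drug_id, cell_line, pic50[, tissue]."""
    df = pd.read_csv(path)
    required = {"drug_id", "cell_line", "pic50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    entries: Dict[Tuple[str, str], float] = {}
    tissues: Dict[str, str] = {}
    for idx, row in df.iterrows():
        key = (str(row["drug_id"]), str(row["cell_line"]))
        if key in entries:
            raise ValueError(f"{path} row {idx}: duplicate (drug, cell line) entry {key}")
        entries[key] = float(row["pic50"])
        if "tissue" in df.columns and not pd.isna(row["tissue"]):
            tissues[key[1]] = str(row["tissue"])
    return ResponseMatrix(entries=entries, cell_line_tissue=tissues)


def read_synergy_table(path: str | Path) -> List[SynergyRecord]:
    """Load a synergy CSV (drug_a, drug_b, cell_line, tissue, synergy_score)."""
    df = pd.read_csv(path, dtype={"drug_a": str, "drug_b": str, "cell_line": str, "tissue": str})
    required = {"drug_a", "drug_b", "cell_line", "tissue", "synergy_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: List[SynergyRecord] = []
    for idx, row in df.iterrows():
        try:
            score = float(row["synergy_score"])
        except (TypeError, ValueError):
            raise ValueError(f"{path} row {idx}: non-numeric synergy score {row['synergy_score']!r}")
        try:
            rec = SynergyRecord(
                drug_a=row["drug_a"], drug_b=row["drug_b"],
                cell_line=row["cell_line"], synergy_score=score, tissue=row["tissue"])
        except ValueError as exc:
            raise ValueError(f"{path} row {idx}: {exc}") from exc
        records.append(rec)
    return records


def read_augmented_table(path: str | Path) -> List[AugmentedRecord]:
    df = pd.read_csv(path, dtype=str)
    records: List[AugmentedRecord] = []
    for _, row in df.iterrows():
        slot = row["substituted_slot"]
        kept_parent = row["parent_b"] if slot == "first" else row["parent_a"]
        substitute = row["drug_b"] if row["drug_a"] == kept_parent else row["drug_a"]
        records.append(AugmentedRecord(
            drug_a=row["drug_a"], drug_b=row["drug_b"], cell_line=row["cell_line"],
            synergy_score=float(row["synergy_score"]), tissue=row["tissue"],
            parent_a=row["parent_a"], parent_b=row["parent_b"],
            substituted_slot=slot, substitute_id=substitute,
            dacs_to_parent=float(row["dacs_to_parent"])))
    return records


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_AUGMENTED_COLUMNS = ["drug_a", "drug_b", "cell_line", "tissue", "synergy_score",
                      "parent_a", "parent_b", "substituted_slot", "dacs_to_parent"]


def write_augmented_table(records: Iterable[AugmentedRecord], path: str | Path) -> None:
    """Write augmented records as CSV; byte-stable for identical input order."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_AUGMENTED_COLUMNS)
        for r in records:
            writer.writerow([r.drug_a, r.drug_b, r.cell_line, r.tissue,
                             repr(float(r.synergy_score)),
                             r.parent_a, r.parent_b, r.substituted_slot,
                             repr(float(r.dacs_to_parent))])


def write_synergy_table(records: Iterable[SynergyRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["drug_a", "drug_b", "cell_line", "tissue", "synergy_score"])
        for r in records:
            writer.writerow([r.drug_a, r.drug_b, r.cell_line, r.tissue,
                             repr(float(r.synergy_score))])


def write_drug_library(library: DrugLibrary, path: str | Path) -> None:
    """Write a library as fingerprint_csv (SMILES preserved when present)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["drug_id", "smiles", "fingerprint", "n_bits", "backend"])
        for rec in library.values():
            fp = rec.fingerprint
            writer.writerow([
                rec.drug_id, rec.smiles or "",
                fp.to_string() if fp else "",
                fp.n_bits if fp else "", fp.backend if fp else ""])


def write_target_links(target_map: TargetMap, path: str | Path, score: float = 900.0) -> None:
    """Write associations in STITCH links dialect (one uniform score)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chemical", "protein", "combined_score"])
        for drug in sorted(target_map.associations):
            for protein in sorted(target_map.associations[drug]):
                writer.writerow([drug, protein, int(score)])


def write_response_table(responses: ResponseMatrix, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["drug_id", "cell_line", "pic50", "tissue"])
        for (drug, cell), value in responses.entries.items():
            writer.writerow([drug, cell, repr(float(value)),
                             responses.cell_line_tissue.get(cell, "")])
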