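"""Molecule normalization, identity and file I/O.

All structure handling in the package funnels through this module: SMILES
are canonicalized once (RDKit canonical form, implicit hydrogens) and
structural identity is decided by the full 27-character standard InChIKey,
so stereoisomers count as distinct structures.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

RELATIONAL_COLUMNS = ("source_id", "source_name", "smiles", "reference")
REPORT_COLUMNS = (
    "source_id",
    "source_name",
    "natural_product_smiles",
    "artifact_smiles",
    "reaction_class",
    "predictor",
    "reference",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed and sanitized."""


class FormatError(ValueError):
    """Raised when an input table is missing required columns."""


def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def is_valid(smiles: str) -> bool:
    """True iff *smiles* parses to a sanitizable structure (empty -> False)."""
    return _mol_from_smiles(smiles) is not None


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES (implicit hydrogens) for *smiles*.

    Idempotent: canonicalizing the output returns the identical string.
    Raises :class:`SmilesParseError` on unparsable input.
    """
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def structure_key(smiles: str) -> str:
    """Full 27-character standard InChIKey of the structure.

    Invariant under SMILES respelling of the same structure; stereoisomers
    get distinct keys. Raises :class:`SmilesParseError` on invalid input.
    """
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToInchiKey(mol)


@dataclass(frozen=True)
class Molecule:
    """A compound: raw SMILES as supplied, canonical form, structure key."""

    raw_smiles: str
    canonical_smiles: str
    structure_key: str

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        mol = _mol_from_smiles(smiles)
        if mol is None:
            raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
        return cls(
            raw_smiles=smiles,
            canonical_smiles=Chem.MolToSmiles(mol),
            structure_key=Chem.MolToInchiKey(mol),
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_smiles


@dataclass
class RelationalRecord:
    """One biological source together with its reported compound cohort.

    Compounds are deduplicated by structure key on construction (first
    occurrence wins; references of merged duplicates are concatenated).
    """

    source_id: str
    source_name: str
    compounds: list[Molecule] = field(default_factory=list)
    references: list[str] = field(default_factory=list)

    def add(self, mol: Molecule, reference: str = "") -> None:
        for i, existing in enumerate(self.compounds):
            if existing.structure_key == mol.structure_key:
                if reference and reference not in self.references[i]:
                    joined = "; ".join(filter(None, [self.references[i], reference]))
                    self.references[i] = joined
                return
        self.compounds.append(mol)
        self.references.append(reference)

    def reference_for(self, mol: Molecule) -> str:
        for existing, ref in zip(self.compounds, self.references):
            if existing.structure_key == mol.structure_key:
                return ref
        return ""


def read_relational_table(path: str | Path) -> list[RelationalRecord]:
    """Read a relational compound table (CSV) into records grouped by source.

    Expected header: ``source_id,source_name,smiles,reference``. Rows with
    invalid SMILES are dropped with a logged warning; duplicate structures
    within one source are merged. Records are returned in first-seen order.
    """
    path = Path(path)
    records: dict[str, RelationalRecord] = {}
    n_dropped = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = [c for c in RELATIONAL_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"missing column(s) {missing} in {path}")
        for row in reader:
            sid = row["source_id"]
            try:
                mol = Molecule.from_smiles(row["smiles"])
            except SmilesParseError:
                n_dropped += 1
                log.warning(
                    "dropping invalid SMILES %r (source %s)", row["smiles"], sid
                )
                continue
            rec = records.get(sid)
            if rec is None:
                rec = RelationalRecord(source_id=sid, source_name=row["source_name"])
                records[sid] = rec
            rec.add(mol, row.get("reference", ""))
    if n_dropped:
        log.warning("dropped %d invalid row(s) from %s", n_dropped, path)
    return [r for r in records.values() if r.compounds]


def write_relational_table(
    records: Iterable[RelationalRecord], path: str | Path
) -> None:
    """Write records back to the relational CSV dialect (lossless inverse)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RELATIONAL_COLUMNS)
        for rec in records:
            for mol, ref in zip(rec.compounds, rec.references):
                writer.writerow(
                    [rec.source_id, rec.source_name, mol.canonical_smiles, ref]
                )


def write_candidate_report(cases: Sequence, path: str | Path) -> None:
    """Write screened candidate cases as CSV, sorted for stable output.

    Row order: by source_id, then natural-product SMILES, then artifact
    SMILES, then reaction class.
    """
    rows = sorted(
        cases,
        key=lambda c: (
            c.source_id,
            c.natural_product.canonical_smiles,
            c.artifact.canonical_smiles,
            c.reaction_class.value,
        ),
    )
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for c in rows:
            writer.writerow(
                [
                    c.source_id,
                    c.source_name,
                    c.natural_product.canonical_smiles,
                    c.artifact.canonical_smiles,
                    c.reaction_class.value,
                    c.predictor_provenance,
                    c.reference,
                ]
            )


def read_candidate_report(path: str | Path) -> list[dict[str, str]]:
    """Read a candidate report back as a list of plain dict rows."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in REPORT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"missing column(s) {missing} in {path}")
        return list(reader)
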