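"""Synthetic relational tables and training corpora.

Real screening runs over a literature-derived compound/source database
that this package does not ship.  This module builds structurally similar
synthetic inputs instead: relational tables in which each biological
source carries one or more *planted* reactive pairs — a scaffold and the
product the reaction-template engine derives from it — diluted with
template-inert decoy compounds, together with the exact ground-truth case
list a correct screen must recover.  It also generates per-class training
corpora for the neural translator by template application over a built-in
scaffold library.

The synthetic structures are deliberately small (SMILES well under 60
characters) and carry none of the stereochemical or glycosidic complexity
of real natural products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .chemio import Molecule, RelationalRecord
from .templates import (
    GenerationError,
    ReactionClass,
    ReactionPair,
    apply_templates,
    builtin_templates,
    generate_pairs,
)

# Scaffold library: short molecules carrying the functional groups the
# template engine recognises (acids, phenols, quinones, diols, catechols,
# ketones, short-chain esters, aryl methyl ethers, benzylic alcohols,
# hydroquinones), across a few ring systems.
SCAFFOLDS: tuple[str, ...] = (
    # carboxylic acids
    "OC(=O)c1ccccc1", "OC(=O)c1ccc(C)cc1", "OC(=O)c1ccco1",
    "OC(=O)c1cccs1", "OC(=O)c1cccnc1", "OC(=O)Cc1ccccc1",
    "OC(=O)/C=C/c1ccccc1", "OC(=O)c1ccc2ccccc2c1", "OC(=O)C1CCCCC1",
    "OC(=O)CCc1ccccc1",
    # phenols
    "Oc1ccccc1", "Oc1ccc(C)cc1", "Oc1cccc2ccccc12", "Oc1ccc(CC)cc1",
    "Oc1ccc(F)cc1",
    # para-quinones
    "O=C1C=CC(=O)C=C1", "CC1=CC(=O)C=CC1=O",
    # 1,2- and 1,3-diols
    "OCC(O)c1ccccc1", "CC(O)CO", "OCC(O)CC", "OCC(C)CO", "OCCCO",
    "OCC(O)c1ccco1",
    # catechols
    "Oc1ccccc1O", "Cc1ccc(O)c(O)c1", "Oc1cc2ccc(=O)oc2cc1O",
    # ketones
    "CC(=O)c1ccccc1", "CCC(=O)c1ccccc1", "CC(=O)c1ccco1",
    # short-chain esters and aryl methyl ethers
    "COC(=O)c1ccccc1", "CCOC(=O)c1ccccc1", "COC(=O)/C=C/c1ccccc1",
    "COC(=O)c1ccco1", "COc1ccccc1", "COc1ccc(C)cc1", "COc1cccc2ccccc12",
    # benzylic alcohols
    "OCc1ccccc1", "CC(O)c1ccccc1", "OCc1ccco1", "OCc1ccc(C)cc1",
    "CC(O)c1cccs1", "OCc1cccc2ccccc12",
    # para-hydroquinones
    "Oc1ccc(O)cc1", "Cc1cc(O)ccc1O", "CCc1cc(O)ccc1O",
)

# Decoy pool: verified template-inert (no acid/ester/phenol/diol/ketone/
# quinone/aryl-OMe/benzylic-alcohol chemistry the engine recognises).
DECOYS: tuple[str, ...] = (
    "c1ccncc1", "Cc1ccncc1", "c1ccc2ncccc2c1", "Cn1ccc2ccccc21",
    "Cc1ccccc1", "CCc1ccccc1", "c1ccc2ccccc2c1", "CC(C)c1ccccc1",
    "Fc1ccccc1", "Clc1ccccc1", "c1ccsc1", "Cc1ccsc1", "c1ccoc1",
    "CCCCCC", "CC(C)CC(C)C", "C1CCCCC1", "C1CCOC1", "CCOCC",
    "CCN(CC)CC", "CC#N", "CSC", "c1cnc2ccccc2c1", "Cc1cccnc1",
    "CCCOCCC", "FC(F)(F)c1ccccc1",
)

SOURCE_NAMES = (
    "Syntheticum alpha", "Syntheticum beta", "Syntheticum gamma",
    "Fictivia delta", "Fictivia epsilon", "Fictivia zeta",
    "Simulata eta", "Simulata theta", "Simulata iota", "Simulata kappa",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic relational table."""

    n_sources: int = 20
    planted_per_source: int = 1
    decoys_per_source: int = 5
    reaction_classes: tuple[ReactionClass, ...] = (ReactionClass.METHANOL,)
    seed: int = 0

    def __post_init__(self):
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.planted_per_source < 0 or self.decoys_per_source < 0:
            raise ValueError("counts must be >= 0")
        if not self.reaction_classes:
            raise ValueError("at least one reaction class required")


@dataclass(frozen=True)
class GroundTruthCase:
    source_id: str
    reactant_key: str
    product_key: str
    reaction_class: ReactionClass

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (
            self.source_id,
            self.reactant_key,
            self.product_key,
            self.reaction_class.value,
        )


@dataclass
class FixtureGroundTruth:
    """The complete set of cases a rule-engine screen must recover."""

    planted_cases: list[GroundTruthCase] = field(default_factory=list)

    def case_set(self) -> set[tuple[str, str, str, str]]:
        return {c.as_tuple() for c in self.planted_cases}

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "source_id": c.source_id,
                "reactant_key": c.reactant_key,
                "product_key": c.product_key,
                "reaction_class": c.reaction_class.value,
            }
            for c in self.planted_cases
        ]
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


@lru_cache(maxsize=None)
def _scaffold_molecules() -> tuple[Molecule, ...]:
    return tuple(Molecule.from_smiles(s) for s in SCAFFOLDS)


@lru_cache(maxsize=None)
def scaffolds_for_class(reaction_class: ReactionClass) -> tuple[Molecule, ...]:
    """Scaffolds the class templates can transform."""
    return tuple(
        m for m in _scaffold_molecules() if apply_templates(m, reaction_class)
    )


@lru_cache(maxsize=None)
def inert_decoys(
    classes: tuple[ReactionClass, ...] = tuple(ReactionClass),
) -> tuple[Molecule, ...]:
    """The decoy pool, verified inert under every given reaction class."""
    out = []
    for smi in DECOYS:
        mol = Molecule.from_smiles(smi)
        if all(not apply_templates(mol, c) for c in classes):
            out.append(mol)
    return tuple(out)


def _enumerate_cases(
    source_id: str,
    cohort: list[Molecule],
    classes: tuple[ReactionClass, ...],
) -> list[GroundTruthCase]:
    """All (reactant, product, class) relations present in a cohort.

    Direct template application + key matching — intentionally simpler
    than the screening machinery it validates.  Captures reverse cases of
    bidirectional chemistry (e.g. ester -> acid under water) so the ground
    truth is complete for any class subset.
    """
    keys = {m.structure_key: m for m in cohort}
    found = []
    for reactant in cohort:
        for reaction_class in classes:
            for product in apply_templates(reactant, reaction_class):
                if (
                    product.structure_key in keys
                    and product.structure_key != reactant.structure_key
                ):
                    found.append(
                        GroundTruthCase(
                            source_id,
                            reactant.structure_key,
                            product.structure_key,
                            reaction_class,
                        )
                    )
    return found


def make_relational_fixture(
    spec: FixtureSpec,
) -> tuple[list[RelationalRecord], FixtureGroundTruth]:
    """Build a synthetic relational table with planted reactive pairs.

    Each source receives ``planted_per_source`` (reactant, template
    product) co-occurrences drawn from the scaffold library under a
    round-robin of the spec's reaction classes, plus ``decoys_per_source``
    template-inert decoys.  Deterministic given ``spec.seed``.  The
    returned ground truth enumerates every case the rule engine can find
    in the table (planted pairs plus any reverse relations they imply).
    """
    rng = np.random.default_rng(spec.seed)
    decoy_pool = inert_decoys(spec.reaction_classes)
    records: list[RelationalRecord] = []
    truth = FixtureGroundTruth()
    for i in range(spec.n_sources):
        source_id = f"SRC{i + 1:04d}"
        source_name = SOURCE_NAMES[i % len(SOURCE_NAMES)]
        record = RelationalRecord(source_id=source_id, source_name=source_name)
        for j in range(spec.planted_per_source):
            reaction_class = spec.reaction_classes[
                (i * spec.planted_per_source + j) % len(spec.reaction_classes)
            ]
            compatible = scaffolds_for_class(reaction_class)
            if not compatible:
                raise GenerationError(
                    f"no scaffold matches class {reaction_class.value}"
                )
            reactant = compatible[int(rng.integers(len(compatible)))]
            products = apply_templates(reactant, reaction_class)
            product = products[int(rng.integers(len(products)))]
            record.add(reactant, reference="synthetic fixture")
            record.add(product, reference="synthetic fixture")
        n_decoys = min(spec.decoys_per_source, len(decoy_pool))
        for k in rng.choice(len(decoy_pool), size=n_decoys, replace=False):
            record.add(decoy_pool[int(k)], reference="synthetic fixture")
        records.append(record)
        truth.planted_cases.extend(
            _enumerate_cases(source_id, record.compounds, spec.reaction_classes)
        )
    return records, truth


def make_training_corpus(
    reaction_class: ReactionClass,
    n: int,
    seed: int,
    max_smiles_length: int = 60,
    template_ids: tuple[str, ...] | None = None,
) -> list[ReactionPair]:
    """Generate *n* training pairs for one class from the scaffold library.

    With ``template_ids`` the corpus is restricted to those templates (e.g.
    a pure esterification corpus), emulating a curated single-reaction
    data set; otherwise all templates of the class contribute.
    """
    if n < 10:
        raise ValueError("a corpus needs at least 10 pairs")
    templates = None
    if template_ids is not None:
        templates = [t for t in builtin_templates(reaction_class)
                     if t.id in template_ids]
        if not templates:
            raise ValueError(f"no class template matches ids {template_ids}")
    compatible = [
        m for m in _scaffold_molecules()
        if apply_templates(m, reaction_class, templates)
    ]
    if not compatible:
        raise GenerationError(f"no scaffold matches class {reaction_class.value}")
    return generate_pairs(
        compatible,
        reaction_class,
        n,
        seed,
        max_smiles_length=max_smiles_length,
        templates=templates,
    )
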