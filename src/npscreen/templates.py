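"""Reaction-template engine for the seven artifact-forming reaction classes.

Extraction artifacts arise mainly from solvolysis (reaction of a natural
product with the extraction solvent: methanol, ethanol, acetone,
dichloromethane, chloroform, water) and from oxidation on exposure to air
or light.  Each class is realized here as one or more reaction-SMARTS
templates capturing the exemplar chemistry of the field: esterification of
carboxylic acids in alcohols, O-alkylation of phenols, nucleophilic
addition of methanol to quinones, acetonide formation on diols,
methylenedioxy bridging of catechols by dichloromethane, hydrolysis of
short-chain esters and aryl methyl ethers by water, and oxidation of
benzylic alcohols and hydroquinones.

The engine is deterministic and serves three roles: a rule-based predictor
for screening, an oracle against the neural translator, and the generator
of synthetic training corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import Molecule

SOLVOLYSIS = "solvolysis"
OXIDATION = "oxidation"


class ReactionClass(Enum):
    """The seven artifact-forming reaction classes."""

    METHANOL = "methanol"
    ETHANOL = "ethanol"
    ACETONE = "acetone"
    DICHLOROMETHANE = "dichloromethane"
    CHLOROFORM = "chloroform"
    WATER = "water"
    OXIDATION = "oxidation"

    @property
    def category(self) -> str:
        return OXIDATION if self is ReactionClass.OXIDATION else SOLVOLYSIS

    @classmethod
    def from_name(cls, name: str) -> "ReactionClass":
        try:
            return cls(name.lower())
        except ValueError:
            raise ValueError(f"unknown reaction class {name!r}") from None


class GenerationError(RuntimeError):
    """Raised when a training-pair corpus cannot be generated."""


@dataclass(frozen=True)
class Template:
    """One reaction-SMARTS transformation rule.

    ``smarts`` is a single-reactant, single-product reaction SMARTS; the
    solvent/oxidant is implicit in the reaction class.  ``doc_example`` is a
    reactant SMILES the template is known to transform, used as a self-test
    hook.
    """

    id: str
    reaction_class: ReactionClass
    smarts: str
    description: str
    doc_example: str
    low_confidence: bool = False

    def reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None:  # pragma: no cover - malformed builtin
            raise ValueError(f"bad reaction SMARTS in template {self.id}")
        return rxn

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "class": self.reaction_class.value,
            "smarts": self.smarts,
            "description": self.description,
            "doc_example": self.doc_example,
            "low_confidence": self.low_confidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Template":
        return cls(
            id=d["id"],
            reaction_class=ReactionClass.from_name(d["class"]),
            smarts=d["smarts"],
            description=d.get("description", ""),
            doc_example=d.get("doc_example", ""),
            low_confidence=bool(d.get("low_confidence", False)),
        )


@dataclass(frozen=True)
class ReactionPair:
    """A (reactant, product) training/validation unit for one class."""

    reactant: str
    product: str
    reaction_class: ReactionClass


_BUILTIN = [
    # --- solvolysis: methanol -------------------------------------------
    Template(
        "esterification_methyl",
        ReactionClass.METHANOL,
        "[C:1](=[O:2])[OX2H1:3]>>[C:1](=[O:2])[O:3][CH3]",
        "Carboxylic acid + methanol -> methyl ester",
        "OC(=O)c1ccccc1",
    ),
    Template(
        "phenol_O_methylation",
        ReactionClass.METHANOL,
        "[c:1][OX2H1:2]>>[c:1][O:2][CH3]",
        "Phenol -> aryl methyl ether (methylation in methanol/on media)",
        "Oc1ccccc1",
    ),
    Template(
        "quinone_methanol_addition",
        ReactionClass.METHANOL,
        "[O:1]=[C:2]1[CH:3]=[CH:4][C:5](=[O:6])[CH:7]=[CH:8]1"
        ">>[O:1]=[C:2]1[C:3](OC)=[CH:4][C:5](=[O:6])[CH:7]=[CH:8]1",
        "Nucleophilic addition of methanol to a para-quinone ring",
        "O=C1C=CC(=O)C=C1",
    ),
    # --- solvolysis: ethanol --------------------------------------------
    Template(
        "esterification_ethyl",
        ReactionClass.ETHANOL,
        "[C:1](=[O:2])[OX2H1:3]>>[C:1](=[O:2])[O:3][CH2][CH3]",
        "Carboxylic acid + ethanol -> ethyl ester",
        "OC(=O)c1ccccc1",
    ),
    Template(
        "phenol_O_ethylation",
        ReactionClass.ETHANOL,
        "[c:1][OX2H1:2]>>[c:1][O:2][CH2][CH3]",
        "Phenol -> aryl ethyl ether",
        "Oc1ccccc1",
    ),
    # --- solvolysis: acetone --------------------------------------------
    Template(
        "acetonide_12_diol",
        ReactionClass.ACETONE,
        "[C:1]([OX2H1:2])[C:3]([OX2H1:4])>>[C:1]1[O:2]C(C)(C)[O:4][C:3]1",
        "1,2-diol + acetone -> five-membered acetonide",
        "OCC(O)c1ccccc1",
    ),
    Template(
        "acetonide_13_diol",
        ReactionClass.ACETONE,
        "[C:1]([OX2H1:2])[C:5][C:3]([OX2H1:4])"
        ">>[C:1]1[O:2]C(C)(C)[O:4][C:3][C:5]1",
        "1,3-diol + acetone -> six-membered acetonide",
        "OCC(C)CO",
    ),
    # --- solvolysis: dichloromethane ------------------------------------
    Template(
        "catechol_methylenedioxy",
        ReactionClass.DICHLOROMETHANE,
        "[c:1]([OX2H1:2]):[c:3]([OX2H1:4])>>[c:1]1[O:2]C[O:4][c:3]:1",
        "Catechol + dichloromethane -> methylenedioxy bridge",
        "Oc1ccccc1O",
    ),
    # --- solvolysis: chloroform -----------------------------------------
    Template(
        "ketone_trichloromethyl_carbinol",
        ReactionClass.CHLOROFORM,
        "[#6:1][C:2](=[O:3])[#6:4]"
        ">>[#6:1][C:2]([OX2H1:3])(C(Cl)(Cl)Cl)[#6:4]",
        "Ketone + chloroform -> trichloromethyl carbinol adduct",
        "CC(=O)c1ccccc1",
        low_confidence=True,
    ),
    # --- solvolysis: water ----------------------------------------------
    Template(
        "methyl_ester_hydrolysis",
        ReactionClass.WATER,
        "[C:1](=[O:2])[OX2:3][CH3]>>[C:1](=[O:2])[OX2H1:3]",
        "Methyl ester + water -> carboxylic acid",
        "COC(=O)c1ccccc1",
    ),
    Template(
        "ethyl_ester_hydrolysis",
        ReactionClass.WATER,
        "[C:1](=[O:2])[OX2:3][CH2][CH3]>>[C:1](=[O:2])[OX2H1:3]",
        "Ethyl ester + water -> carboxylic acid",
        "CCOC(=O)c1ccccc1",
    ),
    Template(
        "aryl_methyl_ether_hydrolysis",
        ReactionClass.WATER,
        "[c:1][OX2:2][CH3]>>[c:1][OX2H1:2]",
        "Aryl methyl ether -> phenol (hydrolytic demethylation)",
        "COc1ccccc1",
    ),
    # --- oxidation -------------------------------------------------------
    Template(
        "sec_benzylic_alcohol_to_ketone",
        ReactionClass.OXIDATION,
        "[c:1][CH1:2]([OX2H1:3])[#6:4]>>[c:1][C:2](=[O:3])[#6:4]",
        "Secondary benzylic alcohol -> aryl ketone",
        "CC(O)c1ccccc1",
    ),
    Template(
        "prim_benzylic_alcohol_to_aldehyde",
        ReactionClass.OXIDATION,
        "[c:1][CH2:2][OX2H1:3]>>[c:1][CH1:2]=[O:3]",
        "Primary benzylic alcohol -> aryl aldehyde",
        "OCc1ccccc1",
    ),
    Template(
        "hydroquinone_to_quinone",
        ReactionClass.OXIDATION,
        "[OX2H1:1][c:2]1[cH:3][cH:4][c:5]([OX2H1:6])[cH:7][cH:8]1"
        ">>[O:1]=[C:2]1[CH:3]=[CH:4][C:5](=[O:6])[CH:7]=[CH:8]1",
        "para-hydroquinone -> para-quinone",
        "Oc1ccc(O)cc1",
    ),
]


def builtin_templates(
    reaction_class: ReactionClass | None = None,
) -> list[Template]:
    """The built-in template registry, optionally filtered to one class.

    Every reaction class is covered by at least one template.
    """
    if reaction_class is None:
        return list(_BUILTIN)
    return [t for t in _BUILTIN if t.reaction_class is reaction_class]


def save_templates(templates: Iterable[Template], path: str | Path) -> None:
    payload = [t.to_dict() for t in templates]
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_templates(path: str | Path) -> list[Template]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [Template.from_dict(d) for d in payload]


def apply_templates(
    mol: Molecule,
    reaction_class: ReactionClass,
    templates: Sequence[Template] | None = None,
) -> list[Molecule]:
    """All distinct products of the class templates applied to *mol*.

    One product per matching site; products are canonicalized, deduplicated
    by structure key, and never include the reactant's own structure.
    Returns an empty list when nothing matches.
    """
    if templates is None:
        templates = builtin_templates(reaction_class)
    else:
        templates = [t for t in templates if t.reaction_class is reaction_class]
    rd_mol = Chem.MolFromSmiles(mol.canonical_smiles)
    if rd_mol is None:
        return []
    seen: dict[str, Molecule] = {}
    for tpl in templates:
        for products in tpl.reaction().RunReactants((rd_mol,)):
            prod = products[0]
            try:
                Chem.SanitizeMol(prod)
            except Exception:
                continue
            out = Molecule.from_smiles(Chem.MolToSmiles(prod))
            if out.structure_key == mol.structure_key:
                continue
            seen.setdefault(out.structure_key, out)
    return list(seen.values())


# Substituent decoration alphabet: methyl, methoxy, hydroxy, halogens —
# small groups keeping SMILES short.
_SUBSTITUENTS = ("C", "OC", "O", "F", "Cl")


def decorate(mol: Molecule, rng: np.random.Generator) -> Molecule:
    """Attach one random small substituent at a random aromatic CH site.

    Returns the input molecule unchanged when it has no aromatic CH or when
    the decorated structure fails to sanitize.
    """
    rd_mol = Chem.MolFromSmiles(mol.canonical_smiles)
    sites = [
        a.GetIdx()
        for a in rd_mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() == 1
    ]
    if not sites:
        return mol
    site = int(rng.choice(sites))
    group = str(rng.choice(_SUBSTITUENTS))
    combined = Chem.RWMol(Chem.CombineMols(rd_mol, Chem.MolFromSmiles(group)))
    combined.AddBond(site, rd_mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
        return Molecule.from_smiles(Chem.MolToSmiles(out))
    except Exception:
        return mol


def generate_pairs(
    scaffolds: Sequence[Molecule],
    reaction_class: ReactionClass,
    n: int,
    seed: int,
    max_smiles_length: int = 60,
    decorate_fraction: float = 0.7,
    templates: Sequence[Template] | None = None,
) -> list[ReactionPair]:
    """Generate *n* distinct reaction pairs for one class from scaffolds.

    Scaffolds are drawn at random, optionally decorated with one small
    substituent, and transformed by the class templates; one product is
    drawn per attempt.  Deterministic given *seed*.  Raises
    :class:`GenerationError` when the templates cannot produce enough
    distinct pairs within a bounded number of attempts.
    """
    if not scaffolds:
        raise GenerationError("no scaffolds supplied")
    if n < 1:
        raise GenerationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[ReactionPair] = []
    seen: set[tuple[str, str]] = set()
    max_attempts = max(200, 60 * n)
    attempts = 0
    while len(pairs) < n and attempts < max_attempts:
        attempts += 1
        base = scaffolds[int(rng.integers(len(scaffolds)))]
        reactant = base
        if rng.random() < decorate_fraction:
            for _ in range(int(rng.integers(1, 3))):
                reactant = decorate(reactant, rng)
        if len(reactant.canonical_smiles) > max_smiles_length:
            continue
        products = apply_templates(reactant, reaction_class, templates)
        products = [
            p for p in products if len(p.canonical_smiles) <= max_smiles_length
        ]
        if not products:
            continue
        product = products[int(rng.integers(len(products)))]
        key = (reactant.canonical_smiles, product.canonical_smiles)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            ReactionPair(
                reactant=reactant.canonical_smiles,
                product=product.canonical_smiles,
                reaction_class=reaction_class,
            )
        )
    if len(pairs) < n:
        raise GenerationError(
            f"could only generate {len(pairs)}/{n} pairs for class "
            f"{reaction_class.value}: templates match too few scaffolds"
        )
    return pairs


def write_corpus(pairs: Iterable[ReactionPair], path: str | Path) -> None:
    """Write pairs as two-column TSV: reactant<TAB>product."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(f"{p.reactant}\t{p.product}\n")


def read_corpus(path: str | Path, reaction_class: ReactionClass) -> list[ReactionPair]:
    """Read a two-column TSV corpus for one reaction class."""
    pairs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        reactant, product = line.split("\t")
        pairs.append(ReactionPair(reactant, product, reaction_class))
    return pairs
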