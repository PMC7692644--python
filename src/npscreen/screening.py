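"""Virtual screening for reactive natural products and probable artifacts.

The screening loop walks relational records (one biological source with
its reported compound cohort).  For each compound it predicts the
solvolysis and oxidation products under each reaction class, and matches
the valid predicted products — by structure key — against the *other*
compounds reported from the same source.  A hit means a plausible
(reactive natural product, extraction artifact) pair co-occurring in the
literature for that source, and is emitted as a candidate case labelled
with the reaction class that explains it.

Both directions of a reversible transformation (e.g. acid -> ester under
methanol, ester -> acid under water) are retained as separate cases.
Products may be predicted by the rule-template engine, by the neural
translators, or by their ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .chemio import Molecule, RelationalRecord
from .seq2seq import PredictionOutcome, TranslationModel
from .templates import ReactionClass, Template, apply_templates, builtin_templates

log = logging.getLogger(__name__)

ALL_CLASSES = tuple(ReactionClass)


class Predictor(Protocol):
    """Per-class product prediction over all seven reaction classes."""

    provenance: str

    def predict_products(
        self, mol: Molecule, reaction_class: ReactionClass
    ) -> list[PredictionOutcome]: ...


class RulePredictor:
    """Deterministic predictor backed by the reaction-template engine."""

    provenance = "rules"

    def __init__(self, templates: Sequence[Template] | None = None):
        self.templates = list(templates) if templates is not None else builtin_templates()

    def predict_products(
        self, mol: Molecule, reaction_class: ReactionClass
    ) -> list[PredictionOutcome]:
        return [
            PredictionOutcome(
                reactant=mol,
                reaction_class=reaction_class,
                generated_smiles=p.canonical_smiles,
                valid=True,
                product=p,
            )
            for p in apply_templates(mol, reaction_class, self.templates)
        ]


class ModelPredictor:
    """Predictor backed by one trained translation model per class.

    Classes without a model yield no outcomes.
    """

    provenance = "model"

    def __init__(self, models: Mapping[ReactionClass, TranslationModel]):
        for cls_, model in models.items():
            if model.reaction_class is not cls_:
                raise ValueError(
                    f"model for {cls_.value} reports class "
                    f"{model.reaction_class.value}"
                )
        self.models = dict(models)

    @classmethod
    def from_directory(cls, models_dir: str | Path) -> "ModelPredictor":
        """Load every per-class model bundle found under *models_dir*.

        Bundles are subdirectories named after reaction classes.
        """
        models: dict[ReactionClass, TranslationModel] = {}
        for sub in sorted(Path(models_dir).iterdir()):
            if sub.is_dir() and (sub / "config.json").exists():
                model = TranslationModel.load(sub)
                models[model.reaction_class] = model
        if not models:
            raise FileNotFoundError(f"no model bundles under {models_dir}")
        return cls(models)

    def predict_products(
        self, mol: Molecule, reaction_class: ReactionClass
    ) -> list[PredictionOutcome]:
        model = self.models.get(reaction_class)
        if model is None:
            return []
        return [model.predict(mol)]


class EnsemblePredictor:
    """Union of the rule engine and the neural models."""

    provenance = "ensemble"

    def __init__(self, rules: RulePredictor, models: ModelPredictor):
        self.rules = rules
        self.models = models

    def predict_products(
        self, mol: Molecule, reaction_class: ReactionClass
    ) -> list[PredictionOutcome]:
        return self.rules.predict_products(mol, reaction_class) + (
            self.models.predict_products(mol, reaction_class)
        )


@dataclass(frozen=True)
class CandidateCase:
    """A screened (reactive natural product, probable artifact) hit."""

    source_id: str
    source_name: str
    natural_product: Molecule
    artifact: Molecule
    reaction_class: ReactionClass
    predictor_provenance: str
    reference: str = ""

    def key(self) -> tuple[str, str, str, str]:
        return (
            self.source_id,
            self.natural_product.structure_key,
            self.artifact.structure_key,
            self.reaction_class.value,
        )


def predict_all_classes(
    predictor: Predictor,
    mol: Molecule,
    classes: Sequence[ReactionClass] = ALL_CLASSES,
) -> dict[ReactionClass, list[PredictionOutcome]]:
    """Run the predictor for every reaction class, keeping all outcomes."""
    return {c: predictor.predict_products(mol, c) for c in classes}


def prediction_status(
    outcomes: Mapping[ReactionClass, Sequence[PredictionOutcome]],
) -> str:
    """'successful' / 'partially successful' / 'failed' for one compound.

    A compound is successful when at least one class yields a valid product
    string, and partially successful when exactly one class does.
    """
    n_valid_classes = sum(
        1 for outs in outcomes.values() if any(o.valid for o in outs)
    )
    if n_valid_classes == 0:
        return "failed"
    if n_valid_classes == 1:
        return "partially successful"
    return "successful"


def match_cohort(
    predicted: Sequence[Molecule],
    cohort: Sequence[Molecule],
    query: Molecule,
) -> list[Molecule]:
    """Cohort members whose structure key matches a predicted product.

    The query molecule itself is excluded; matches are deduplicated and
    returned in cohort order.
    """
    predicted_keys = {p.structure_key for p in predicted}
    predicted_keys.discard(query.structure_key)
    matched, seen = [], set()
    for member in cohort:
        k = member.structure_key
        if k == query.structure_key or k in seen:
            continue
        if k in predicted_keys:
            matched.append(member)
            seen.add(k)
    return matched


def screen_source(
    record: RelationalRecord,
    predictor: Predictor,
    classes: Sequence[ReactionClass] = ALL_CLASSES,
) -> list[CandidateCase]:
    """Screen one biological source; deterministic case order."""
    cases: list[CandidateCase] = []
    if len(record.compounds) < 2:
        return cases
    for compound in record.compounds:
        per_class = predict_all_classes(predictor, compound, classes)
        if prediction_status(per_class) == "failed":
            continue
        for reaction_class in classes:
            products = [
                o.product for o in per_class[reaction_class]
                if o.valid and o.product is not None
            ]
            if not products:
                continue
            for artifact in match_cohort(products, record.compounds, compound):
                cases.append(
                    CandidateCase(
                        source_id=record.source_id,
                        source_name=record.source_name,
                        natural_product=compound,
                        artifact=artifact,
                        reaction_class=reaction_class,
                        predictor_provenance=predictor.provenance,
                        reference=record.reference_for(compound),
                    )
                )
    return cases


def screen_all(
    records: Iterable[RelationalRecord],
    predictor: Predictor,
    classes: Sequence[ReactionClass] = ALL_CLASSES,
) -> list[CandidateCase]:
    """Screen every relational record and concatenate the candidate cases."""
    cases: list[CandidateCase] = []
    n_records = 0
    for record in records:
        found = screen_source(record, predictor, classes)
        cases.extend(found)
        n_records += 1
        if found:
            log.info(
                "source %s (%s): %d candidate case(s)",
                record.source_id, record.source_name, len(found),
            )
    log.info(
        "screened %d source(s): %d candidate case(s) in total",
        n_records, len(cases),
    )
    return cases
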