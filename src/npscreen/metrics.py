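"""Evaluation metrics for SMILES-to-SMILES product prediction.

Three quantities summarize a model on a validation set:

* **Success** — percentage of generated strings that parse as molecules.
* **Concordance** — average sequence match ratio between target and
  generated strings (0 = totally different, 1 = exact match), computed as
  the Ratcliff-Obershelp gestalt similarity 2M / (|a| + |b|) where M is the
  number of characters matched under recursive longest-common-block
  decomposition.
* **Accuracy** — percentage of predictions whose structure key (InChIKey)
  equals the target's; invalid strings count as mismatches.

A structure match requires a valid string, so accuracy <= success always.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from difflib import SequenceMatcher
from pathlib import Path
from typing import Iterable, Sequence

from .chemio import Molecule
from .templates import ReactionClass, ReactionPair


@dataclass(frozen=True)
class MetricsReport:
    reaction_class: ReactionClass
    success_percent: float
    concordance: float
    accuracy_percent: float
    n_pairs: int
    concordance_valid_only: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["reaction_class"] = self.reaction_class.value
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def write_csv_row(self, path: str | Path, append: bool = False) -> None:
        """One row of a Class / Success / Concordance / Accuracy table."""
        p = Path(path)
        new = not (append and p.exists())
        with p.open("a" if append else "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            if new:
                w.writerow(["Class", "Success", "Concordance", "Accuracy", "N"])
            w.writerow(
                [
                    self.reaction_class.value,
                    f"{self.success_percent:.2f}",
                    f"{self.concordance:.2f}",
                    f"{self.accuracy_percent:.2f}",
                    self.n_pairs,
                ]
            )


def success_rate(outcomes: Sequence) -> float:
    """Percentage of outcomes flagged valid."""
    if not outcomes:
        raise ValueError("no outcomes")
    return 100.0 * sum(1 for o in outcomes if o.valid) / len(outcomes)


def concordance(target: str, predicted: str) -> float:
    """Sequence match ratio of two strings in [0, 1]; 1 iff identical.

    Computed as the Ratcliff-Obershelp gestalt ratio with the target as
    the first argument.  The recursive longest-block decomposition breaks
    ties toward the first argument, so the (target, predicted) order is
    part of the definition; swapping arguments can change the value for
    strings with repeated blocks.
    """
    if not target or not predicted:
        raise ValueError("concordance requires non-empty strings")
    return SequenceMatcher(None, target, predicted, autojunk=False).ratio()


def mean_concordance(pairs: Iterable[tuple[str, str]]) -> float:
    """Arithmetic mean of concordance over (target, predicted) pairs."""
    values = [concordance(t, p) for t, p in pairs]
    if not values:
        raise ValueError("no pairs")
    return sum(values) / len(values)


def structure_accuracy(pairs: Sequence[tuple[Molecule, object]]) -> float:
    """Percentage of predictions matching the target structure key.

    Each pair is (target Molecule, PredictionOutcome); invalid predictions
    count as mismatches.
    """
    if not pairs:
        raise ValueError("no pairs")
    hits = 0
    for target, outcome in pairs:
        if outcome.valid and outcome.product is not None:
            if outcome.product.structure_key == target.structure_key:
                hits += 1
    return 100.0 * hits / len(pairs)


def evaluate(model, validation: Sequence[ReactionPair]) -> MetricsReport:
    """Predict every validation reactant and assemble a metrics report.

    *model* is anything with ``reaction_class`` and
    ``predict(reactant: Molecule) -> PredictionOutcome``; models with a
    batched ``predict_many`` are used as such.
    """
    if not validation:
        raise ValueError("empty validation set")
    if any(p.reaction_class is not model.reaction_class for p in validation):
        raise ValueError("validation pairs must match the model's class")
    reactants = [Molecule.from_smiles(p.reactant) for p in validation]
    if hasattr(model, "predict_many"):
        outcomes = model.predict_many(reactants)
    else:
        outcomes = [model.predict(r) for r in reactants]
    targets = [Molecule.from_smiles(p.product) for p in validation]
    conc_pairs = [
        (p.product, o.generated_smiles or " ")
        for p, o in zip(validation, outcomes)
    ]
    valid_conc = [
        concordance(p.product, o.generated_smiles)
        for p, o in zip(validation, outcomes)
        if o.valid and o.generated_smiles
    ]
    return MetricsReport(
        reaction_class=model.reaction_class,
        success_percent=success_rate(outcomes),
        concordance=mean_concordance(conc_pairs),
        accuracy_percent=structure_accuracy(list(zip(targets, outcomes))),
        n_pairs=len(validation),
        concordance_valid_only=(
            sum(valid_conc) / len(valid_conc) if valid_conc else None
        ),
    )
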