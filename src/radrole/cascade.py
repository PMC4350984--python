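"""Missing-data model cascade: ranked trees over predictor subsets.

Administrative treatment records frequently lack one or more classification
variables, and a tree grown on all four cannot classify such records. The
cascade strategy grows one tree per predictor subset (by default the seven
subsets of {fraction_size, site_group, body_region_group, days_from_first}
that always retain days_from_first, the only variable complete by
construction), ranks the trees by their misclassification rate on a
validation partition, and classifies each record with the highest-ranked
tree whose predictors the record actually has. Records carrying only
days_from_first are reported as unclassifiable rather than defaulted —
there is no time-only model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chaid import ClassificationTree, InductionParams, grow_tree
from .records import CURATIVE, PALLIATIVE

logger = logging.getLogger(__name__)

#: the seven default predictor subsets (model 1 = full model)
DEFAULT_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("fraction_size", "site_group", "body_region_group", "days_from_first"),
    ("fraction_size", "body_region_group", "days_from_first"),
    ("fraction_size", "site_group", "days_from_first"),
    ("fraction_size", "days_from_first"),
    ("site_group", "body_region_group", "days_from_first"),
    ("body_region_group", "days_from_first"),
    ("site_group", "days_from_first"),
)


@dataclass
class ModelSpec:
    model_id: int
    variables: tuple[str, ...]
    tree: ClassificationTree
    valid_misclassification: float
    rank: int = 0


@dataclass
class ModelCascade:
    models: list[ModelSpec]  # ordered by rank (1 = best)
    metadata: dict = field(default_factory=dict)

    def by_rank(self) -> list[ModelSpec]:
        return sorted(self.models, key=lambda m: m.rank)

    def model(self, model_id: int) -> ModelSpec:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(f"no model with id {model_id}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "radrole-cascade-v1",
            "metadata": self.metadata,
            "models": [
                {
                    "model_id": m.model_id,
                    "variables": list(m.variables),
                    "valid_misclassification": m.valid_misclassification,
                    "rank": m.rank,
                    "tree": m.tree.to_dict(),
                }
                for m in self.models
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelCascade":
        models = [
            ModelSpec(
                model_id=md["model_id"],
                variables=tuple(md["variables"]),
                tree=ClassificationTree.from_dict(md["tree"]),
                valid_misclassification=md["valid_misclassification"],
                rank=md["rank"],
            )
            for md in d["models"]
        ]
        models.sort(key=lambda m: m.rank)
        return cls(models=models, metadata=d.get("metadata", {}))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ModelCascade":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def misclassification_rate(tree: ClassificationTree, data: pd.DataFrame, outcome="intent_flag") -> float:
    """Fraction of records the tree labels differently from the outcome."""
    predicted = tree.classify_frame(data)["label"]
    return float((predicted.to_numpy() != data[outcome].to_numpy()).mean())


def build_cascade(
    train_set: pd.DataFrame,
    valid_set: pd.DataFrame,
    subsets=DEFAULT_SUBSETS,
    params: InductionParams | None = None,
    outcome: str = "intent_flag",
) -> ModelCascade:
    """Grow one tree per predictor subset and rank them.

    Trees are grown on ``train_set`` restricted to each subset and ranked
    ascending by misclassification on ``valid_set`` (ties: larger subset
    first, then model id). Rows not complete on the union of subsets (or
    with a missing outcome) are dropped with a log message.
    """
    if params is None:
        params = InductionParams()
    subsets = tuple(tuple(s) for s in subsets)
    if len(subsets) == 0:
        raise ValueError("at least one variable subset is required")
    for s in subsets:
        if len(s) == 0:
            raise ValueError("empty variable subset")
    union = sorted({v for s in subsets for v in s})

    def restrict(df, name):
        complete = df[union + [outcome]].notna().all(axis=1)
        if not complete.all():
            logger.info("%s: dropping %d rows incomplete on %s or outcome",
                        name, int((~complete).sum()), union)
        return df[complete]

    train = restrict(train_set, "train")
    valid = restrict(valid_set, "valid")
    if len(train) == 0 or len(valid) == 0:
        raise ValueError("no complete rows available for cascade induction")

    models = []
    for i, subset in enumerate(subsets, start=1):
        tree = grow_tree(train, subset, params, outcome, provenance=f"cascade model {i}")
        mis = misclassification_rate(tree, valid, outcome)
        models.append(ModelSpec(model_id=i, variables=subset, tree=tree, valid_misclassification=mis))

    order = sorted(models, key=lambda m: (m.valid_misclassification, -len(m.variables), m.model_id))
    for rank, m in enumerate(order, start=1):
        m.rank = rank
    return ModelCascade(
        models=order,
        metadata={
            "n_train": int(len(train)),
            "n_valid": int(len(valid)),
            "params": {"alpha": params.alpha, "min_node": params.min_node},
        },
    )


def applicable_models(cascade: ModelCascade, record) -> list[ModelSpec]:
    """Models whose every variable is non-missing on the record, best rank first."""
    out = []
    for m in cascade.by_rank():
        values = []
        for v in m.variables:
            try:
                values.append(record[v])
            except (KeyError, IndexError):
                values.append(None)
        if all(not pd.isna(v) for v in values):
            out.append(m)
    return out


def classify_with_cascade(cascade: ModelCascade, record):
    """Classify one record with the best-ranked applicable model.

    Returns ``(label, model_id)``, or ``None`` if no model applies
    (unclassifiable — reported, never defaulted to a class).
    """
    models = applicable_models(cascade, record)
    if not models:
        return None
    m = models[0]
    label, _, _ = m.tree.classify(record)
    return label, m.model_id


def classify_frame_with_cascade(cascade: ModelCascade, frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorised cascade classification.

    Returns a frame aligned with the input with columns ``label`` (C/P or
    missing when unclassifiable), ``model_id`` and ``rule_id`` (the leaf's
    rule number within the model used, matching
    :func:`radrole.rules.extract_rules` ordering).
    """
    labels = pd.Series(index=frame.index, dtype=object)
    model_ids = pd.Series(np.nan, index=frame.index)
    rule_ids = pd.Series(np.nan, index=frame.index)
    unassigned = pd.Series(True, index=frame.index)
    for m in cascade.by_rank():
        if not unassigned.any():
            break
        ok = unassigned & frame[list(m.variables)].notna().all(axis=1)
        if not ok.any():
            continue
        result = m.tree.classify_frame(frame[ok])
        labels[ok] = result["label"].to_numpy()
        model_ids[ok] = m.model_id
        # leaf ids -> 1-based rule numbers in left-first leaf order
        leaf_order = {leaf.node_id: i + 1 for i, leaf in enumerate(m.tree.leaves())}
        rule_ids[ok] = result["leaf_id"].map(leaf_order).to_numpy()
        unassigned &= ~ok
    return pd.DataFrame({"label": labels, "model_id": model_ids, "rule_id": rule_ids})
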