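"""Lineage assignment by marker-score gating and CD8⁺ compartment selection.

Instead of graph clustering plus cluster-level annotation, lineages are
assigned per cell from canonical markers: each candidate label carries a
required-positive and required-negative gene set, the score is the mean
normalized expression of positives minus the mean of negatives, and the
cell takes the best-scoring label above threshold (else ``unassigned``).
This keeps the selection rule the clonality analysis depends on — CD8⁺
cells minus anything expressing CD4, TRDC or CD68 — deterministic and
directly testable.

The CD8 selection step mirrors the subsetting-plus-exclusion convention:
cells labeled CD8_T are kept only if their CD4, TRDC and CD68 expression
is at or below an exclusion threshold ("expressing" defaults to raw
count > 0, the strictest reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .tenx import CountMatrix

__all__ = [
    "MarkerRule",
    "MarkerRuleSet",
    "default_rules",
    "load_rules",
    "score_and_assign",
    "select_cd8",
    "LINEAGE_LABELS",
    "CD8_EXCLUSION_GENES",
]

logger = logging.getLogger(__name__)

LINEAGE_LABELS = ("CD8_T", "CD4_T", "gd_T", "B", "myeloid", "pDC", "nonimmune", "unassigned")
CD8_EXCLUSION_GENES = ("CD4", "TRDC", "CD68")


@dataclass
class MarkerRule:
    positive: list[str]
    negative: list[str]
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.positive:
            raise ValueError("marker rule needs at least one positive gene")
        if self.threshold < 0:
            raise ValueError("marker rule threshold must be >= 0")


@dataclass
class MarkerRuleSet:
    """Label → rule mapping with a fixed tie-break priority order."""

    rules: dict[str, MarkerRule]
    priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("empty marker rule set")
        if not self.priority:
            self.priority = list(self.rules)
        if set(self.priority) != set(self.rules):
            raise ValueError("priority list must name exactly the rule labels")

    def validate_against(self, genes: list[str]) -> None:
        feature_set = set(genes)
        for label, rule in self.rules.items():
            missing = (set(rule.positive) | set(rule.negative)) - feature_set
            if missing:
                raise ValueError(f"rule {label!r}: genes not in features: {sorted(missing)}")


def load_rules(path: str | Path) -> MarkerRuleSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules = {
        label: MarkerRule(
            positive=list(spec["positive"]),
            negative=list(spec.get("negative", [])),
            threshold=float(spec.get("threshold", 0.0)),
        )
        for label, spec in doc["rules"].items()
    }
    return MarkerRuleSet(rules=rules, priority=list(doc.get("priority", [])))


def default_rules() -> MarkerRuleSet:
    """The marker rule set shipped with the package (editable YAML)."""
    ref = resources.files("clonotrack").joinpath("data/marker_rules.yaml")
    with resources.as_file(ref) as path:
        return load_rules(path)


def score_and_assign(
    normalized: CountMatrix,
    rules: MarkerRuleSet | None = None,
) -> pd.DataFrame:
    """Assign a lineage label to every cell by marker-score gating.

    Returns a DataFrame (barcode, lineage, score) in matrix cell order.
    Score per label = mean(normalized positives) − mean(normalized
    negatives); label = argmax over labels with score ≥ threshold, else
    ``unassigned``.  Exact ties break by the rule set's priority order and
    are logged.
    """
    rules = rules if rules is not None else default_rules()
    rules.validate_against(normalized.genes)
    X = sp.csr_matrix(normalized.counts)
    labels = list(rules.priority)
    scores = np.zeros((len(labels), normalized.n_cells))
    for li, label in enumerate(labels):
        rule = rules.rules[label]
        pos_idx = [normalized.gene_index(g) for g in rule.positive]
        pos = np.asarray(X[pos_idx, :].mean(axis=0)).ravel()
        if rule.negative:
            neg_idx = [normalized.gene_index(g) for g in rule.negative]
            neg = np.asarray(X[neg_idx, :].mean(axis=0)).ravel()
        else:
            neg = 0.0
        scores[li] = pos - neg
    thresholds = np.array([rules.rules[l].threshold for l in labels])[:, None]
    qualifies = scores >= thresholds
    # argmax in priority order: earlier label wins exact ties
    best = np.argmax(scores, axis=0)
    n_ties = int(np.sum(np.sum(scores == scores[best, np.arange(scores.shape[1])], axis=0) > 1))
    if n_ties:
        logger.info("score_and_assign: %d cells had tied top scores (priority order applied)", n_ties)
    assigned = [
        labels[b] if qualifies[b, j] else "unassigned"
        for j, b in enumerate(best)
    ]
    return pd.DataFrame(
        {
            "barcode": normalized.barcodes,
            "lineage": assigned,
            "score": scores[best, np.arange(scores.shape[1])],
        }
    )


def select_cd8(
    annotations: pd.DataFrame,
    raw: CountMatrix,
    exclusion_genes: tuple[str, ...] = CD8_EXCLUSION_GENES,
    exclusion_threshold: float = 0.0,
) -> set[str]:
    """CD8⁺ compartment: CD8_T-labeled cells not expressing CD4, TRDC or CD68.

    ``exclusion_threshold`` is compared against values in ``raw`` (raw
    counts by default; pass a normalized matrix with a nonzero threshold
    for a normalized-value cutoff).  A cell is excluded if any exclusion
    gene exceeds the threshold.
    """
    missing = [g for g in exclusion_genes if g not in raw.genes]
    if missing:
        raise ValueError(f"exclusion genes not in features: {missing}")
    cd8_barcodes = set(annotations.loc[annotations["lineage"] == "CD8_T", "barcode"])
    idx = [raw.gene_index(g) for g in exclusion_genes]
    sub = np.asarray(sp.csr_matrix(raw.counts)[idx, :].todense())
    expressing = np.any(sub > exclusion_threshold, axis=0)
    excluded = {bc for bc, e in zip(raw.barcodes, expressing) if e}
    return {bc for bc in cd8_barcodes if bc not in excluded}
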