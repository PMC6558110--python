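"""Performance evaluation: confusion-matrix indexes, ROC-AUC, and
leave-one-species-out cross-validation with AUC-based reference curation.

"Essential" is the positive class throughout.  Indexes whose denominator
is zero are reported as ``None`` (undefined), never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .cvdist import composition_vector, cv_distance
from .io import LabelTable, Proteome
from .orthology import AlignmentParams, OrthologMap, rbh_orthologs
from .scoring import (
    DISTANCE_FLOOR,
    DistanceVector,
    MappingMatrix,
    essentiality_scores,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_auc",
    "loocv",
    "curate_reference_set",
    "DEFAULT_AUC_CUTOFF",
]

#: References whose leave-one-out AUC does not exceed this are dropped.
DEFAULT_AUC_CUTOFF = 0.60


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five confusion-matrix indexes plus (optionally) ROC-AUC.

    ``None`` means the index is undefined for these counts (zero
    denominator).
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f_measure: Optional[float]
    mcc: Optional[float]
    auc: Optional[float] = None


def confusion(predicted: Mapping[str, bool], truth: LabelTable) -> ConfusionCounts:
    """Tally predictions against truth labels; unlabeled genes are excluded."""
    tp = fp = tn = fn = 0
    for gene, call in predicted.items():
        label = truth.labels.get(gene)
        if label is None:
            continue
        if call and label:
            tp += 1
        elif call and not label:
            fp += 1
        elif not call and label:
            fn += 1
        else:
            tn += 1
    if tp + fp + tn + fn == 0:
        raise ValueError("no labeled genes among the predictions")
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, precision, F-measure and MCC from counts."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    prec = _ratio(c.tp, c.tp + c.fp)
    if sens is None or prec is None or sens + prec == 0:
        f_measure = None
    else:
        f_measure = 2 * sens * prec / (sens + prec)
    denom = (c.tn + c.fn) * (c.tn + c.fp) * (c.tp + c.fn) * (c.tp + c.fp)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom > 0 else None
    return MetricsReport(sens, spec, prec, f_measure, mcc)


def roc_auc(scores: Mapping[str, float], truth: LabelTable) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Tied scores contribute half per tied essential/non-essential pair.
    Only genes with a truth label participate.
    """
    y, s = [], []
    for gene, score in scores.items():
        label = truth.labels.get(gene)
        if label is not None:
            y.append(label)
            s.append(score)
    if not y:
        raise ValueError("no labeled genes to evaluate")
    if all(y) or not any(y):
        raise ValueError("ROC-AUC needs both an essential and a non-essential gene")
    return float(roc_auc_score(np.asarray(y, dtype=bool), np.asarray(s, dtype=float)))


def loocv(
    collection: Sequence[Tuple[Proteome, LabelTable]],
    k: int = 6,
    params: AlignmentParams | None = None,
) -> Dict[str, float]:
    """Leave-one-species-out cross-validation over an annotated collection.

    Each genome in turn serves as the query, with all remaining genomes as
    the reference set; its genes are scored and ranked against its own
    labels, yielding one AUC per genome.  Composition vectors and RBH
    ortholog maps are computed once per genome / genome pair and shared
    across folds, which leaves every fold's result identical to a direct
    pipeline run.
    """
    if len(collection) < 2:
        raise ValueError("cross-validation needs at least two genomes")
    params = params or AlignmentParams()
    proteomes = [p for p, _ in collection]
    labels = {p.genome_id: t for p, t in collection}
    for p in proteomes:
        t = labels[p.genome_id]
        if t.n_essential == 0 or t.n_nonessential == 0:
            raise ValueError(
                f"genome {p.genome_id!r} lacks one label class; cannot evaluate"
            )

    cvs = {p.genome_id: composition_vector(p, k) for p in proteomes}
    omaps: Dict[Tuple[str, str], OrthologMap] = {}
    for a, b in combinations(proteomes, 2):
        m = rbh_orthologs(a, b, params)
        omaps[(a.genome_id, b.genome_id)] = m
        omaps[(b.genome_id, a.genome_id)] = m.reversed()

    aucs: Dict[str, float] = {}
    for q in proteomes:
        refs = [p for p in proteomes if p.genome_id != q.genome_id]
        index = {g: i for i, g in enumerate(q.gene_ids)}
        M = np.zeros((len(q), len(refs)), dtype=np.int8)
        for j, r in enumerate(refs):
            rlab = labels[r.genome_id]
            for g, h in omaps[(q.genome_id, r.genome_id)].pairs:
                if rlab.is_essential(h):
                    M[index[g], j] = 1
        ref_ids = tuple(r.genome_id for r in refs)
        D = np.maximum(
            np.array([cv_distance(cvs[q.genome_id], cvs[r]) for r in ref_ids]),
            DISTANCE_FLOOR,
        )
        raw = essentiality_scores(
            MappingMatrix(q.gene_ids, ref_ids, M), DistanceVector(ref_ids, D)
        )
        aucs[q.genome_id] = roc_auc(dict(zip(q.gene_ids, raw)), labels[q.genome_id])
    return aucs


def curate_reference_set(
    aucs: Mapping[str, float], cutoff: float = DEFAULT_AUC_CUTOFF
) -> Tuple[List[str], Dict[str, float]]:
    """Keep genomes whose cross-validation AUC strictly exceeds `cutoff`.

    Returns the kept genome ids (sorted) and the dropped genomes with
    their AUCs, so the curation step is auditable.
    """
    if not aucs:
        raise ValueError("empty AUC table")
    kept = sorted(g for g, a in aucs.items() if a > cutoff)
    dropped = {g: a for g, a in sorted(aucs.items()) if a <= cutoff}
    return kept, dropped
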