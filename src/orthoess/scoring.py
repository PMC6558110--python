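"""The essentiality score: ortholog transfer weighted by phylogenetic distance.

For query gene i and N annotated reference proteomes,

    S_i = (1/N) * sum_j  M_ij / D_j

where M_ij is 1 iff gene i has a reciprocal-best-hit ortholog in reference
j that is labeled essential (0 otherwise) and D_j is the composition-vector
distance between query and reference proteomes.  A close relative whose
ortholog is essential therefore contributes much more than a distant one.
D_j is clamped below at 0.01 so that an identical genome in the reference
set (D = 0) does not divide by zero.

Raw scores are min-max normalized over the query proteome,

    S_final = (S_i - Min) / (Max - Min),

and a gene is called essential when S_final exceeds the decision threshold
(default 0.24).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .cvdist import CompositionVector, composition_vector, cv_distance
from .io import LabelTable, Proteome
from .orthology import AlignmentParams, rbh_orthologs

__all__ = [
    "DISTANCE_FLOOR",
    "DEFAULT_THRESHOLD",
    "MappingMatrix",
    "DistanceVector",
    "ScoreTable",
    "mapping_scores",
    "reference_distances",
    "essentiality_scores",
    "normalize_scores",
    "classify",
    "build_score_table",
    "score_query",
]

#: Lower clamp on the CV distance; an identical reference genome (D = 0)
#: is treated as if at distance 0.01.
DISTANCE_FLOOR = 0.01

#: Default decision threshold on the normalized score.
DEFAULT_THRESHOLD = 0.24


@dataclass(frozen=True)
class MappingMatrix:
    """Binary ortholog-essentiality indicators, query genes x references."""

    gene_ids: Tuple[str, ...]
    reference_ids: Tuple[str, ...]
    M: np.ndarray  # shape (n_genes, N), values in {0, 1}


@dataclass(frozen=True)
class DistanceVector:
    """Clamped CV distances to each reference, aligned with a MappingMatrix."""

    reference_ids: Tuple[str, ...]
    D: np.ndarray  # shape (N,), values in [0.01, 1]


@dataclass(frozen=True)
class ScoreTable:
    """Final per-gene scores and calls for one query proteome."""

    gene_ids: Tuple[str, ...]
    raw: Tuple[float, ...]
    normalized: Tuple[float, ...]
    predicted: Tuple[bool, ...]
    threshold: float

    def as_mapping(self, which: str = "normalized") -> Dict[str, float]:
        values = getattr(self, which)
        return dict(zip(self.gene_ids, values))


def mapping_scores(
    query: Proteome,
    references: Sequence[Tuple[Proteome, LabelTable]],
    params: AlignmentParams | None = None,
) -> MappingMatrix:
    """M_ij = 1 iff query gene i has an RBH ortholog labeled essential in j.

    Genes without orthologs, or whose ortholog is non-essential or
    unlabeled, get 0.
    """
    if not references:
        raise ValueError("reference list must not be empty")
    params = params or AlignmentParams()
    n = len(query)
    M = np.zeros((n, len(references)), dtype=np.int8)
    index = {g: i for i, g in enumerate(query.gene_ids)}
    for j, (ref, labels) in enumerate(references):
        omap = rbh_orthologs(query, ref, params)
        for g, h in omap.pairs:
            if labels.is_essential(h):
                M[index[g], j] = 1
    return MappingMatrix(query.gene_ids, tuple(r.genome_id for r, _ in references), M)


def reference_distances(
    query: Proteome,
    references: Sequence[Proteome],
    k: int = 6,
    *,
    query_cv: CompositionVector | None = None,
    reference_cvs: Sequence[CompositionVector] | None = None,
) -> DistanceVector:
    """Clamped CV distance from the query to every reference proteome.

    Precomputed composition vectors may be supplied to avoid recomputation
    across cross-validation folds.
    """
    qcv = query_cv if query_cv is not None else composition_vector(query, k)
    if reference_cvs is None:
        reference_cvs = [composition_vector(r, k) for r in references]
    D = np.array([cv_distance(qcv, rcv) for rcv in reference_cvs], dtype=float)
    D = np.maximum(D, DISTANCE_FLOOR)
    return DistanceVector(tuple(r.genome_id for r in references), D)


def essentiality_scores(M: MappingMatrix, D: DistanceVector) -> np.ndarray:
    """Raw score S_i = (1/N) * sum_j M_ij / D_j for every query gene."""
    if M.reference_ids != D.reference_ids:
        raise ValueError("mapping matrix and distance vector reference different genomes")
    if np.any(D.D <= 0):
        raise ValueError("non-positive distance: clamp was skipped upstream")
    # canonical column order makes the float sum independent of the order
    # in which the caller listed the references
    order = np.argsort(np.asarray(M.reference_ids))
    return (M.M[:, order] / D.D[order]).sum(axis=1) / len(D.reference_ids)


def normalize_scores(raw: Sequence[float]) -> np.ndarray:
    """Min-max normalization of raw scores onto [0, 1].

    When all raw scores are equal the formula is undefined; every
    normalized score is then 0 (no gene stands out, none is called).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("at least one gene required")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def classify(normalized: Sequence[float], threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Call a gene essential iff its normalized score strictly exceeds `threshold`."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return np.asarray(normalized, dtype=float) > threshold


def build_score_table(
    gene_ids: Sequence[str],
    raw: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> ScoreTable:
    """Normalize raw scores and classify, producing a finalized table."""
    normalized = normalize_scores(raw)
    predicted = classify(normalized, threshold)
    return ScoreTable(
        gene_ids=tuple(gene_ids),
        raw=tuple(float(x) for x in raw),
        normalized=tuple(float(x) for x in normalized),
        predicted=tuple(bool(x) for x in predicted),
        threshold=threshold,
    )


def score_query(
    query: Proteome,
    references: Sequence[Tuple[Proteome, LabelTable]],
    *,
    params: AlignmentParams | None = None,
    k: int = 6,
    threshold: float = DEFAULT_THRESHOLD,
) -> ScoreTable:
    """Run the whole scoring pipeline for one query proteome (serial)."""
    M = mapping_scores(query, references, params)
    D = reference_distances(query, [r for r, _ in references], k)
    return build_score_table(query.gene_ids, essentiality_scores(M, D), threshold)
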