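"""Ortholog detection by reciprocal best hit (RBH) over exact local alignment.

Two genes, one per genome, are called orthologs when each is the other's
highest-scoring match in an all-versus-all Smith-Waterman comparison.  The
dynamic program is an affine-gap (Gotoh) kernel compiled with numba; the
first residue of a gap costs ``gap_open`` and every further residue
``gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .io import Proteome

__all__ = [
    "AlignmentParams",
    "HitTable",
    "OrthologMap",
    "align_score",
    "score_matrix",
    "best_hits",
    "rbh_orthologs",
]

# Alphabet of the standard BLOSUM matrices; selenocysteine (U) is scored as X.
_MATRIX_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_CODES = {c: i for i, c in enumerate(_MATRIX_ALPHABET)}
_CODES["U"] = _CODES["X"]


@dataclass(frozen=True)
class AlignmentParams:
    """Parameters of the local-alignment search behind RBH.

    ``min_score`` is a raw-score acceptance floor: subject genes scoring
    below it are not recorded as hits at all.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_score: float = 50.0

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


@dataclass(frozen=True)
class HitTable:
    """Best subject hit per query gene for one genome pair direction."""

    direction: Tuple[str, str]  # (query genome id, subject genome id)
    hits: Dict[str, Tuple[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one ortholog pairs between a query and a reference genome."""

    query_id: str
    reference_id: str
    pairs: FrozenSet[Tuple[str, str]]

    def as_dict(self) -> Dict[str, str]:
        return {q: r for q, r in self.pairs}

    def reversed(self) -> "OrthologMap":
        return OrthologMap(
            self.reference_id, self.query_id,
            frozenset((r, q) for q, r in self.pairs),
        )


@lru_cache(maxsize=None)
def _load_matrix(name: str) -> np.ndarray:
    mat = substitution_matrices.load(name)
    sub = np.zeros((len(_MATRIX_ALPHABET), len(_MATRIX_ALPHABET)), dtype=np.int32)
    for a in _MATRIX_ALPHABET:
        for b in _MATRIX_ALPHABET:
            sub[_CODES[a], _CODES[b]] = int(mat[a, b])
    return sub


def _encode(seq: str) -> np.ndarray:
    if not seq:
        raise ValueError("empty sequence cannot be aligned")
    try:
        return np.array([_CODES[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"illegal character {exc.args[0]!r} in sequence") from None


@njit(cache=True)
def _sw_kernel(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros(m + 1, dtype=np.int32)
    E = np.zeros(m + 1, dtype=np.int32)
    best = 0
    for i in range(1, n + 1):
        diag = 0
        F = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = H[j] - gap_open
            if E[j] - gap_extend > e:
                e = E[j] - gap_extend
            E[j] = e
            f = H[j - 1] - gap_open
            if F - gap_extend > f:
                f = F - gap_extend
            F = f
            h = diag + sub[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


def align_score(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> float:
    """Optimal Smith-Waterman local alignment score of two protein sequences."""
    params = params or AlignmentParams()
    sub = _load_matrix(params.substitution_matrix)
    return float(
        _sw_kernel(_encode(seq_a), _encode(seq_b), sub, params.gap_open, params.gap_extend)
    )


def score_matrix(
    query: Proteome, subject: Proteome, params: AlignmentParams | None = None
) -> np.ndarray:
    """All-versus-all local alignment scores, shape (n_query, n_subject)."""
    params = params or AlignmentParams()
    sub = _load_matrix(params.substitution_matrix)
    enc_q = [_encode(rec.sequence) for rec in query]
    enc_s = [_encode(rec.sequence) for rec in subject]
    out = np.zeros((len(enc_q), len(enc_s)), dtype=np.int32)
    for i, a in enumerate(enc_q):
        for j, b in enumerate(enc_s):
            out[i, j] = _sw_kernel(a, b, sub, params.gap_open, params.gap_extend)
    return out


def _best_per_row(
    matrix: np.ndarray, row_ids: Tuple[str, ...], col_ids: Tuple[str, ...],
    min_score: float,
) -> Dict[str, Tuple[str, float]]:
    # Ties go to the lexicographically smallest subject gene id so results
    # do not depend on record order in the FASTA file.
    hits: Dict[str, Tuple[str, float]] = {}
    for i, gid in enumerate(row_ids):
        row = matrix[i]
        top = row.max()
        if top < min_score:
            continue
        best = min(col_ids[j] for j in np.flatnonzero(row == top))
        hits[gid] = (best, float(top))
    return hits


def best_hits(
    query: Proteome, subject: Proteome, params: AlignmentParams | None = None
) -> HitTable:
    """Best subject hit for every query gene reaching ``min_score``."""
    params = params or AlignmentParams()
    matrix = score_matrix(query, subject, params)
    hits = _best_per_row(matrix, query.gene_ids, subject.gene_ids, params.min_score)
    return HitTable((query.genome_id, subject.genome_id), hits)


def rbh_orthologs(
    query: Proteome, reference: Proteome, params: AlignmentParams | None = None
) -> OrthologMap:
    """Reciprocal-best-hit ortholog map between two proteomes.

    A pair (g, h) is kept iff h is g's best hit in the reference and g is
    h's best hit in the query.  The score matrix is computed once and
    reused for both directions (local alignment is symmetric).
    """
    params = params or AlignmentParams()
    matrix = score_matrix(query, reference, params)
    fwd = _best_per_row(matrix, query.gene_ids, reference.gene_ids, params.min_score)
    rev = _best_per_row(matrix.T, reference.gene_ids, query.gene_ids, params.min_score)
    pairs = frozenset(
        (g, h)
        for g, (h, _) in fwd.items()
        if rev.get(h, (None,))[0] == g
    )
    return OrthologMap(query.genome_id, reference.genome_id, pairs)
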