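"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately avoids the package's own code path: alignment
scores come from Biopython's PairwiseAligner, composition vectors from a
dense 20^k array, and AUC from explicit enumeration of positive-negative
pairs.
"""

from itertools import product

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def biopython_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(a, b))


def brute_rbh(query, subject, min_score: float):
    """All-vs-all reciprocal best hits via Biopython, ties to smallest id."""
    scores = {}
    for qr in query:
        for sr in subject:
            scores[(qr.gene_id, sr.gene_id)] = biopython_score(qr.sequence, sr.sequence)

    def best(row_ids, col_ids, lookup):
        out = {}
        for r in row_ids:
            ranked = sorted(((-lookup(r, c), c) for c in col_ids))
            top_score = -ranked[0][0]
            if top_score >= min_score:
                out[r] = ranked[0][1]
        return out

    q_ids = [r.gene_id for r in query]
    s_ids = [r.gene_id for r in subject]
    fwd = best(q_ids, s_ids, lambda q, s: scores[(q, s)])
    rev = best(s_ids, q_ids, lambda s, q: scores[(q, s)])
    return {(q, s) for q, s in fwd.items() if rev.get(s) == q}


def dense_cv(proteome, k=3):
    """Dense composition vector over all 20^k strings."""

    def dense_counts(kk):
        counts = {"".join(w): 0 for w in product(STANDARD_AA, repeat=kk)}
        total = 0
        for rec in proteome:
            seq = rec.sequence
            for i in range(len(seq) - kk + 1):
                w = seq[i : i + kk]
                if all(c in STANDARD_AA for c in w):
                    counts[w] += 1
                    total += 1
        return counts, total

    ck, tk = dense_counts(k)
    c1, t1 = dense_counts(k - 1)
    c2, t2 = dense_counts(k - 2)
    vec = {}
    for w in ck:
        p, s, m = w[:-1], w[1:], w[1:-1]
        if c1[p] and c1[s] and c2[m]:
            f0 = (c1[p] / t1) * (c1[s] / t1) / (c2[m] / t2)
            vec[w] = (ck[w] / tk - f0) / f0
        else:
            vec[w] = 0.0
    return vec


def dense_cv_distance(proteome_a, proteome_b, k=3):
    va = dense_cv(proteome_a, k)
    vb = dense_cv(proteome_b, k)
    a = np.array([va[w] for w in sorted(va)])
    b = np.array([vb[w] for w in sorted(vb)])
    c = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    return (1.0 - c) / 2.0


def pairwise_auc(scores, labels):
    """AUC by enumerating all positive-negative pairs, ties count half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
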