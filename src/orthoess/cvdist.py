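"""Composition-vector (CV) distances between whole proteomes.

The composition vector of a proteome collects, for every amino-acid
k-string, the relative deviation of its observed frequency from the
frequency predicted by a (k-2)-order Markov model of the shorter strings:

    a(s) = (f(s) - f0(s)) / f0(s),
    f0(a1..ak) = f(a1..a_{k-1}) * f(a2..ak) / f(a2..a_{k-1}).

Subtracting the Markov expectation suppresses the neutral compositional
background and leaves the selective signal; the cosine correlation C of
two vectors then yields the alignment-free evolutionary distance
D = (1 - C) / 2 in [0, 1].  These distances weight reference genomes in
the essentiality score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Dict, Sequence

import pandas as pd

from .io import Proteome

__all__ = [
    "KmerCounts",
    "CompositionVector",
    "kmer_counts",
    "composition_vector",
    "cv_distance",
    "distance_matrix",
    "STANDARD_AA",
]

#: The 20 standard amino acids; k-mer windows containing anything else
#: (ambiguity letters) are skipped rather than expanded.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STD = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class KmerCounts:
    """Sparse counts of overlapping k-strings in a proteome."""

    k: int
    counts: Dict[str, int] = field(default_factory=dict)
    total: int = 0


@dataclass(frozen=True)
class CompositionVector:
    """Sparse background-subtracted k-string composition vector."""

    k: int
    components: Dict[str, float] = field(default_factory=dict)
    norm: float = 0.0


def kmer_counts(proteome: Proteome, k: int) -> KmerCounts:
    """Count overlapping length-k windows in every protein.

    Windows never span two proteins.  A window containing a letter outside
    the 20-letter alphabet is skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Dict[str, int] = {}
    total = 0
    for rec in proteome:
        seq = rec.sequence
        n = len(seq)
        # blocked[i] = index of the next non-standard letter at or after i
        blocked = [n] * n
        nb = n
        for i in range(n - 1, -1, -1):
            if seq[i] not in _STD:
                nb = i
            blocked[i] = nb
        for i in range(n - k + 1):
            if blocked[i] >= i + k:
                s = seq[i : i + k]
                counts[s] = counts.get(s, 0) + 1
                total += 1
    return KmerCounts(k, counts, total)


def composition_vector(proteome: Proteome, k: int = 6) -> CompositionVector:
    """Background-subtracted composition vector of a proteome.

    Requires k >= 3 and a proteome long enough to populate counts at
    lengths k, k-1 and k-2.  Components are stored sparsely: a k-string
    appears only if its observed or Markov-predicted frequency is nonzero
    (strings observed zero times but predicted positive carry the value -1).
    """
    if k < 3:
        raise ValueError("composition vectors require k >= 3")
    ck = kmer_counts(proteome, k)
    c1 = kmer_counts(proteome, k - 1)
    c2 = kmer_counts(proteome, k - 2)
    if ck.total == 0 or c1.total == 0 or c2.total == 0:
        raise ValueError(
            f"proteome {proteome.genome_id!r} too short to populate "
            f"{k - 2}-mer through {k}-mer counts"
        )

    # Enumerate every s = a1 + m + ak with f0(s) > 0, i.e. both (k-1)-mer
    # halves observed (which forces the middle (k-2)-mer m observed too).
    left: Dict[str, list] = {}
    right: Dict[str, list] = {}
    for p in c1.counts:
        left.setdefault(p[1:], []).append(p[0])
        right.setdefault(p[:-1], []).append(p[-1])

    components: Dict[str, float] = {}
    sq = 0.0
    t1_sq_t2 = c1.total * c1.total  # f0 denominator pieces kept as integers
    for m, lefts in left.items():
        rights = right.get(m)
        if not rights:
            continue
        cm = c2.counts[m]
        for a1 in lefts:
            cp = c1.counts[a1 + m]
            for ak in rights:
                cs = c1.counts[m + ak]
                s = a1 + m + ak
                # a = f/f0 - 1 with f/f0 expressed as an exact integer ratio,
                # so identities like f == f0 give exactly 0
                num = ck.counts.get(s, 0) * t1_sq_t2 * cm
                den = ck.total * cp * cs * c2.total
                a = num / den - 1.0
                if a != 0.0:
                    components[s] = a
                    sq += a * a
    return CompositionVector(k, components, sqrt(sq))


def cv_distance(a: CompositionVector, b: CompositionVector) -> float:
    """Evolutionary distance D = (1 - C) / 2 from the cosine correlation C.

    Exactly symmetric in its arguments and 0 for identical vectors.
    """
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    if a.norm == 0.0 or b.norm == 0.0:
        raise ValueError("degenerate composition vector (zero norm)")
    small, large = (a, b) if len(a.components) <= len(b.components) else (b, a)
    # fixed summation order keeps cv_distance(a, b) == cv_distance(b, a) exactly
    dot = 0.0
    for s in sorted(small.components):
        v = large.components.get(s)
        if v is not None:
            dot += small.components[s] * v
    c = dot / (a.norm * b.norm)
    c = min(1.0, max(-1.0, c))
    return (1.0 - c) / 2.0


def distance_matrix(proteomes: Sequence[Proteome], k: int = 6) -> pd.DataFrame:
    """Symmetric pairwise CV distance matrix with genome ids as labels."""
    vectors = [composition_vector(p, k) for p in proteomes]
    ids = [p.genome_id for p in proteomes]
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = cv_distance(vectors[i], vectors[j])
            mat.iat[i, j] = d
            mat.iat[j, i] = d
    return mat
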