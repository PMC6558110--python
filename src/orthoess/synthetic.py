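"""Synthetic clades of diverged proteomes with heritable, noisy
essentiality labels.

A single ancestral proteome is drawn i.i.d. from fixed amino-acid
background frequencies and a fraction of its gene families is marked
essential.  Each genome of the clade is an independent descendant (star
phylogeny): every site is substituted with a given probability, whole
genes are lost with a given probability, and inherited essentiality
labels are flipped with a given probability.  Gene ids encode the
ancestral family, so ground-truth orthology is known and recovery by
reciprocal best hit can be measured.  Everything is reproducible from the
seed.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .io import LabelTable, Proteome, ProteinRecord, write_fasta, write_labels

__all__ = [
    "CladeParams",
    "generate_clade",
    "write_clade",
    "family_of",
    "AA_FREQUENCIES",
]

#: Amino-acid background frequencies (Robinson & Robinson 1991), the
#: standard composition underlying the BLOSUM/BLAST statistics.
AA_FREQUENCIES = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

_AA = np.array(list(AA_FREQUENCIES), dtype="U1")
_FREQS = np.array(list(AA_FREQUENCIES.values()))
_FREQS = _FREQS / _FREQS.sum()

_MIN_LENGTH = 50


@dataclass(frozen=True)
class CladeParams:
    """Study conditions for one simulated clade.

    The defaults describe the strong-signal regime: moderate sequence
    divergence (15% of sites substituted per descendant), occasional gene
    loss, and 5% label noise on an annotation where 30% of genes are
    essential.
    """

    n_genomes: int = 5
    n_genes: int = 400
    mean_protein_length: int = 300
    essential_fraction: float = 0.3
    substitution_rate: float = 0.15
    gene_loss_prob: float = 0.05
    label_flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.mean_protein_length < _MIN_LENGTH:
            raise ValueError(f"mean_protein_length must be >= {_MIN_LENGTH}")
        if not 0.0 < self.essential_fraction < 1.0:
            raise ValueError("essential_fraction must lie in (0, 1)")
        if self.n_genes * self.essential_fraction < 1:
            raise ValueError("n_genes * essential_fraction must be >= 1")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must lie in [0, 1)")
        if not 0.0 <= self.gene_loss_prob < 1.0:
            raise ValueError("gene_loss_prob must lie in [0, 1)")
        if not 0.0 <= self.label_flip_prob <= 0.5:
            raise ValueError("label_flip_prob must lie in [0, 0.5]")


def family_of(gene_id: str) -> int:
    """Ancestral family index encoded in a synthetic gene id."""
    m = re.search(r"_f(\d+)$", gene_id)
    if not m:
        raise ValueError(f"{gene_id!r} does not encode an ancestral family")
    return int(m.group(1))


def _draw_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(len(_AA), size=length, p=_FREQS)


def generate_clade(params: CladeParams) -> List[Tuple[Proteome, LabelTable]]:
    """Simulate a clade of descendant proteomes with essentiality labels.

    Returns one ``(Proteome, LabelTable)`` pair per genome, ids ``G01``,
    ``G02``, ...; gene ids are ``<genome>_f<family>`` so that true
    orthology between any two genomes is the identity on shared families.
    """
    rng = np.random.default_rng(params.seed)
    lengths = np.maximum(
        _MIN_LENGTH, rng.geometric(1.0 / params.mean_protein_length, params.n_genes)
    )
    ancestor = [_draw_sequence(rng, int(n)) for n in lengths]
    n_essential = int(round(params.n_genes * params.essential_fraction))
    essential_families = set(
        rng.choice(params.n_genes, size=n_essential, replace=False).tolist()
    )

    clade: List[Tuple[Proteome, LabelTable]] = []
    for g in range(params.n_genomes):
        genome_id = f"G{g + 1:02d}"
        records: List[ProteinRecord] = []
        labels = {}
        for fam, anc_seq in enumerate(ancestor):
            if rng.random() < params.gene_loss_prob:
                continue
            seq = anc_seq.copy()
            mask = rng.random(seq.size) < params.substitution_rate
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = rng.choice(len(_AA), size=n_mut, p=_FREQS)
            label = fam in essential_families
            if rng.random() < params.label_flip_prob:
                label = not label
            gene_id = f"{genome_id}_f{fam:04d}"
            records.append(
                ProteinRecord(gene_id, f"family {fam}", "".join(_AA[seq]))
            )
            labels[gene_id] = label
        clade.append((Proteome(genome_id, tuple(records)), LabelTable(genome_id, labels)))
    return clade


def write_clade(
    clade: List[Tuple[Proteome, LabelTable]], directory: os.PathLike | str
) -> None:
    """Write each genome as ``<id>.faa`` plus ``<id>.tsv`` into `directory`."""
    os.makedirs(directory, exist_ok=True)
    for proteome, labels in clade:
        write_fasta(os.path.join(directory, f"{proteome.genome_id}.faa"), proteome)
        write_labels(os.path.join(directory, f"{proteome.genome_id}.tsv"), labels)
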