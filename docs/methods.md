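# Methods

## Model

`orthoess` estimates gene essentiality by homology transfer. The premise
is biological: essentiality is largely conserved among orthologs, and the
reliability of the transfer decays with evolutionary distance. For query
gene *i* against *N* annotated reference proteomes the score is

    S_i = (1/N) * Σ_{j=1..N} M_ij / D_j

an arithmetic mean of per-reference contributions. A reference only
contributes when the query gene has a reciprocal-best-hit ortholog there
*and* that ortholog is annotated essential (M_ij = 1); absence of an
ortholog and a non-essential or unlabeled ortholog are treated
identically (M_ij = 0). Contributions are inversely weighted by the
proteome-level composition-vector distance D_j, so phylogenetically close
references dominate. Scores are min–max normalized per query proteome and
thresholded (default 0.24) to call essential genes.

Implicit assumptions: orthology is adequately captured by one-to-one
reciprocal best hits (in-paralog families are not resolved); essentiality
annotations of the references are trustworthy, which is why reference
collections are curated by cross-validation before use; and a gene
missing from every ortholog map is scored 0 rather than dropped, so the
output always covers the whole query proteome.

## Orthology

Reciprocal best hits are computed from exact Smith–Waterman local
alignment with affine gaps (Gotoh recurrence; the first gapped position
costs `gap_open`, each further one `gap_extend`). Defaults: BLOSUM62,
gap open 11, gap extend 1, and a raw-score acceptance floor
`min_score = 50` below which a subject gene is not recorded as a hit at
all. A raw-score floor is used instead of an E-value because it is
deterministic and needs no database-size calibration; exact alignment
rather than seeded heuristic search keeps the best-hit relation exactly
reproducible. Best-hit ties are broken toward the lexicographically
smallest subject gene id, so results are independent of record order in
the input files. Selenocysteine (U) is scored as X; other ambiguity
letters (B, Z, X, `*`) use their BLOSUM62 rows.

The kernel is a numba-compiled score-only dynamic program; the test suite
cross-checks it against Biopython's `PairwiseAligner` on randomized
sequence pairs, which serves as the independent alignment oracle
throughout.

## Composition-vector distance

For word length k (default 6, configurable 3–7, the usual range for
proteome-scale CV analysis), frequencies f of all overlapping k-, (k−1)-
and (k−2)-peptides are collected per protein (windows never span two
proteins; a window containing a non-standard letter is skipped, not
expanded). The background-subtracted component of k-string
s = a₁…a_k is

    a(s) = (f(s) − f0(s)) / f0(s),
    f0(s) = f(a₁…a_{k−1}) · f(a₂…a_k) / f(a₂…a_{k−1})

with a(s) = 0 whenever f0(s) = 0. The ratio f/f0 is evaluated as an
exact integer ratio of counts before the final division, so identities
such as f ≡ f0 (e.g. a single-letter proteome) yield exactly zero
components rather than rounding residue. The distance is
D = (1 − C)/2 where C is the cosine correlation of two vectors; the dot
product is accumulated in sorted key order so D(a, b) equals D(b, a)
bit-for-bit.

The clamp for degenerate distances lives in the scoring layer, not here:
every D_j entering the score is raised to at least 0.01, which both
handles an identical genome in the reference set (D = 0) and guarantees
the documented invariant D_j ≥ 0.01 for near-duplicates.

## Evaluation

Sensitivity, specificity, precision, F-measure and the Matthews
correlation coefficient are computed from the confusion matrix with
"essential" as the positive class. These formulas are partial functions:
any index with a zero denominator is reported as undefined (`None`),
never silently coerced to 0. ROC-AUC uses the rank (Mann–Whitney)
formulation with the half-credit tie convention, delegated to
scikit-learn and cross-checked in tests against explicit enumeration of
positive–negative pairs.

Leave-one-species-out cross-validation scores each annotated genome
against all the others. Composition vectors are computed once per genome
and RBH maps once per genome pair and shared across folds; this is a pure
cache — a fold's result is identical to a from-scratch pipeline run, and
a test asserts so. Reference curation keeps genomes whose AUC is
strictly greater than 0.60 and reports the dropped ones with their AUCs.

## Synthetic clades

The simulator emulates the situation the predictor is built for: a set of
related annotated genomes. One ancestral proteome is drawn i.i.d. from
the Robinson–Robinson amino-acid background frequencies (protein lengths
geometric around `mean_protein_length`, floored at 50 residues; 300 is
the biologically typical default, smaller values are used in tests to
keep alignment work proportionate). A fixed fraction (default 0.3) of
gene families is marked essential. Every genome of the clade is an
independent descendant — a star phylogeny, which is enough to create a
gradient of CV distances without modelling tree shape: each site is
substituted with probability `substitution_rate` (replacement drawn from
the same background, so back-substitutions occur), whole genes are lost
with `gene_loss_prob`, and inherited labels flip with `label_flip_prob`.
Gene ids encode the ancestral family, making true orthology available as
ground truth.

Deliberate simplifications: no insertions/deletions (substitution-only
evolution keeps alignment scores analytically predictable), no paralogs
or horizontal transfer, and i.i.d. sites. Passing tests on these clades
therefore demonstrate that the pipeline recovers a planted
ortholog-essentiality signal under sequence divergence and label noise —
not that real annotations are free of the systematic biases
(condition-dependent essentiality, operon polarity effects) that real
screens carry.

Default study conditions are `n_genomes = 5`, `n_genes = 400`,
`substitution_rate = 0.15`, `gene_loss_prob = 0.05`,
`label_flip_prob = 0.05`. The gene count was fixed by a power analysis
of the label-noise process: with 5% label noise the per-genome AUC of an
ideal transfer predictor concentrates near 0.93, and several hundred
genes per genome are needed before the minimum AUC over a 5-genome clade
clears 0.9 reliably. The end-to-end tests run this clade at
`mean_protein_length = 120` (and the label-randomized control at
`n_genes = 200`), sizes chosen so a full leave-one-out sweep stays a
few minutes of alignment on one core.

## Determinism and parallelism

The unit of parallel work is the reference genome: each reference's RBH
map and CV distance are independent, computed in worker processes, and
merged by sorted genome id. The score sum itself is evaluated in
canonical (sorted-reference) order inside `essentiality_scores`, so the
floating-point result — and hence the written score table, which sorts
rows by normalized score then gene id and prints shortest-round-trip
floats — is byte-identical for any worker count and any directory
listing order. Other conventions: classification uses a strict
inequality (a score exactly at the threshold is non-essential), curation
likewise (`AUC = 0.60` is dropped), and when all raw scores are equal the
normalization maps every gene to 0 and nothing is called essential — the
conservative completion of a formula that is undefined there.

## Limitations

Raw-score RBH is not calibrated across very different protein lengths
the way an E-value would be; the default floor of 50 is conservative for
full-length bacterial proteins but should be lowered for short peptides.
CV distances saturate for very distant proteomes, compressing the
weighting between far references. The decision threshold 0.24 is a
default inherited from the score's design regime, not a universal
optimum; users trading precision against recall should sweep it.
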