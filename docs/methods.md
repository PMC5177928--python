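# Methods

## Model

`hatpred` predicts which of seven lysine acetyltransferases (HATs/KATs:
CREBBP, EP300, HAT1, KAT2A, KAT2B, KAT5, KAT8) is likely to acetylate a
given lysine, from sequence context alone. The underlying assumption is the
group-based one: short peptides that look alike behave alike, so a candidate
site is scored by how similar its flanking peptide is to the enzyme's known
substrate peptides.

A site peptide is the window of `m` residues upstream and `n` residues
downstream of the central lysine (termini padded with `*`). The similarity
of two windows A and B is

    S(A, B) = Σ_i w_i · M[A_i, B_i],   clamped to 0 if negative,

where `M` is an integer substitution matrix (initially BLOSUM62) and `w` a
vector of non-negative integer position weights (initially all 1). The model
score of a query window is the arithmetic mean of its similarity to every
positive training peptide of that enzyme; during leave-one-out (LOO)
validation a positive's own peptide is withheld, keyed by its
(protein, position) identity so that identical sequences from different
proteins are not accidentally excluded.

Positives for an enzyme are its annotated sites; negatives are **all other
lysines of the same substrate proteins**, including lysines annotated only
for a different enzyme. This convention makes the negative set realistic
(same protein composition) but inevitably contaminated by undiscovered true
sites — reported specificities are therefore conservative.

## Training

Training maximizes the LOO sensitivity (Sn) at a fixed specificity anchor
(Sp = 0.90 by default) in three steps, by default in this order:

1. **Window selection** — exhaustive search over (m, n) in 1..30 × 1..30
   with unit weights and unmutated BLOSUM62; ties break toward the smaller
   window (smaller m+n, then smaller m).
2. **Weight training** — random ±1 moves on single position weights.
3. **Matrix mutation** — random ±1 moves on single residue-pair entries of
   the 20×20 block (pad/unknown rows stay 0). The matrix is stored as an
   ordered-pair lookup and may become asymmetric: the query residue indexes
   rows, the training-peptide residue indexes columns.

Steps 2–3 use simulated annealing: an improving move is always accepted, a
worsening one with probability `exp(ΔSn/T)` under geometric cooling
(T₀ = 0.05, factor 0.995 per proposal). A step stops after 500 consecutive
*rejected* proposals or a hard cap of 2,000 proposals — the cap is the
de-facto terminator because lateral moves are always accepted, and by
proposal 2,000 the temperature has decayed by 10⁻⁵ so the chain is
effectively greedy; measured objective gains plateau well before the cap.
The returned state is always the best seen, so the best-so-far objective is
monotone non-decreasing along the trace, which every training run logs.

**Objective tie-break.** Sn over k positives moves in steps of 1/k, so
almost every single ±1 proposal is exactly lateral and hill-climbing on Sn
alone stalls — especially after window selection, which has already
maximized the same Sn over up to 900 windows. States are therefore compared
lexicographically as (Sn, margin), where the margin is the mean positive
score minus the anchored cutoff, divided by the summed standard deviations
of positive and negative scores. The normalization makes the margin
invariant under uniform weight scaling, so it cannot be improved by simply
inflating all weights. The annealing acceptance probability for worsening
moves uses the Sn difference only.

**Cutoff convention.** The cutoff at a target specificity is the smallest
observed score value such that the fraction of negatives *strictly below*
it reaches the target; tied negative scores push the cutoff above the whole
tied block, and if no observed value qualifies the cutoff sits just above
the maximum negative score. Prediction is inclusive: a site is called
positive when score ≥ cutoff.

**Step-order shuffling.** The step order is configurable. Weight vectors
are not transferable across window shapes, so whenever the window-selection
step runs it re-evaluates candidate windows with unit weights and the
current matrix, then resets the weights to 1 for the chosen shape.

Enzymes with fewer than two annotated sites are refused rather than trained
degenerately.

## Evaluation and thresholds

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Pr = TP/(TP+FP); undefined 0/0 ratios are
reported as missing, never as 0. ROC curves are built over all distinct
cutoffs with tied scores grouped (one vertex per distinct score); the
trapezoidal AUC then equals the Mann–Whitney statistic with half credit for
ties, which the tests verify against a pairwise oracle to 1e-9.

k-fold cross-validation splits positives and negatives into k folds
independently (stratified) with a seeded RNG; each fold is scored against
the other folds' positives. By default the weights and matrix are *not*
re-trained per fold — only the reference peptides are re-partitioned —
since the scoring model is an average over references; per-fold re-training
is available behind a flag.

Prediction tiers high/medium/low are score cutoffs calibrated on the LOO
score distribution at specificities of ~0.95/0.90/0.85; the permissive
`all` tier reports every lysine with its score (cutoff 0).

## Orthology screen

Before applying the models to another species, reciprocal best hits (RBH)
between the reference and target proteomes decide which enzymes exist
there. The similarity search is external; the package consumes 12-column
BLAST-tabular files. Best hit = highest bitscore, ties broken by lower
e-value then lexicographic subject id; no e-value ceiling is applied by
default (a filter is exposed). Only enzymes with a detected ortholog are
used for large-scale prediction in that species.

## Synthetic studies

The generator emulates a curated site table: substrate proteins drawn
i.i.d. from a background distribution (uniform over the 20 residues by
default; a SwissProt-like preset exists), with planted acetyl-lysines whose
informative offsets carry an enriched residue with a set probability.
Presets mirror the qualitative motif structure of the real enzymes
(e.g. CREBBP-like: G at −1, S at +1, K at +3..+5; KAT2B-like: G at −2 and
−4). Background lysines become natural negatives. Planted sites are spaced
at least 61 residues apart so labels stay unambiguous up to the maximal
(30, 30) window.

Effect sizes: the enrichment probability is 0.6 for `clean` and 0.4 for
`weak`. 0.6 was fixed after inspecting the unit-weight baseline: it yields
a strong but non-saturating signal (baseline LOO AUC ≈ 0.97, Sn@Sp90
≈ 0.93 on the default 60-substrate study), which matters because a
saturated objective (Sn = 1 everywhere) would make weight training vacuous;
it is also closer to real site logos, where enrichments are far from
deterministic. A null preset plants label-independent sites, and a
label-shuffling control reassigns annotations to random lysines.

What passing synthetic tests do **not** show: real substrates are not
i.i.d. sequences — they have compositional bias, disorder, structural
context and correlated motif positions — and real negatives contain
unknown true sites. Synthetic recovery demonstrates the machinery is
correct and calibrated, not that real-data accuracy will match.

## Problem sizes and numerical choices

Default study size for the simulation experiments: 60 substrates × 3 sites
(180 positives, ~900 background-lysine negatives, sequence length 300).
The training engine keeps per-position contribution tensors so that a ±1
weight or matrix proposal updates scores incrementally instead of
rescoring; exhaustive window search uses cumulative sums over positions,
making each of the 900 (m, n) combinations a two-slice difference. A full
three-step training run on the default study takes a few seconds on one
core. Objective comparisons use an absolute tolerance of 1e-12; all
randomness flows from a single integer seed through
`numpy.random.default_rng`, and repeated runs are bit-identical.

## Known limitations

- The curated experimental site collections are small and biased toward
  well-studied substrates; the two largest enzymes dominate.
- Negatives are unverified non-annotated lysines (see above).
- The matrix-mutation step can overfit small positive sets; the LOO
  objective limits but does not eliminate this.
- Sequence-only scoring ignores structure, accessibility and
  protein–protein interaction context.
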