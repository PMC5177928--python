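# hatpred

Prediction of acetyltransferase-specific lysine acetylation sites from
protein sequences.

Tens of thousands of lysine acetylation sites are known from mass
spectrometry, but for most of them the upstream enzyme — the histone/lysine
acetyltransferase (HAT/KAT) that writes the mark — is unknown. `hatpred`
assigns candidate enzymes to lysines for seven well-characterized HATs
(CREBBP, EP300, HAT1, KAT2A, KAT2B, KAT5, KAT8), for researchers who want a
shortlist of enzyme–substrate hypotheses worth testing.

## Method

A candidate lysine is represented by its peptide window ASP(m, n): the m
residues upstream and n downstream of the central K. Its score for an
enzyme is the mean similarity to that enzyme's known substrate peptides,

S′(A, B) = max(0, Σᵢ wᵢ·M[Aᵢ, Bᵢ]),

with M an integer substitution matrix initialized to BLOSUM62 and w
non-negative integer position weights. Training tunes (m, n) exhaustively,
then w and M by annealed ±1 moves, maximizing leave-one-out sensitivity at
fixed specificity (Sp = 90%). Score cutoffs for the high/medium/low
prediction tiers are calibrated at LOO specificities of ~95/90/85%. A
reciprocal-best-hit ortholog screen decides which enzyme models apply in a
given species. See `docs/methods.md` for the full model description and
design choices.

## Worked example

Generate a synthetic study with a planted CREBBP-like motif (G at −1, S at
+1, K at +3..+5), train a model, evaluate it and predict:

```
$ hatpred synth --preset crebbp-like --n 30 --sites 2 --seq-len 150 --seed 7 --out fix/
wrote 30 substrates, 60 sites to fix

$ hatpred train --fasta fix/substrates.fa --sites fix/sites.tsv --hat CREBBP \
      --seed 7 --m-max 6 --n-max 6 --out models/crebbp.model.json
trained CREBBP: window (5,5), thresholds high=13.667 medium=10.733 low=9.317

$ hatpred eval --fasta fix/substrates.fa --sites fix/sites.tsv \
      --model models/crebbp.model.json --out eval/
CREBBP loo AUC = 0.959

$ hatpred predict --fasta fix/substrates.fa --models models/ --tier high --out pred.tsv
71 predictions at tier high -> pred.tsv
```

The trained model selected a (5, 5) window around the lysine; the three
thresholds are the score cutoffs whose LOO specificity reached 95/90/85%.
The LOO AUC of 0.959 says the model ranks held-out planted sites above
background lysines. `pred.tsv` lists every lysine whose score clears the
high cutoff:

```
protein_id  position  hat     score   tier  window
SYN0000     42        CREBBP  14.567  high  IATEGKMTPRC
SYN0000     109       CREBBP  57.183  high  MVHNGKSSKKK
```

The second row is a planted site — note the motif residues G at −1, S at
+1 and the downstream lysines — scoring far above the 13.667 cutoff.

`hatpred annotate` restricts scoring to the lysines of an acetylome site
table (the recommended large-scale mode; scanning whole proteomes ab
initio yields too many false positives) and reports how many sites and
proteins get at least one enzyme, and how many enzymes share each site.
`hatpred orthology` turns a pair of BLAST tabular files into the per-species
presence flags that `annotate` uses to drop absent enzymes.

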