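# sdpscan

Detection of **specificity-determining positions** in protein families: given a
multiple sequence alignment whose sequences are partitioned into groups of
orthologues (each group carrying a different function), `sdpscan` ranks
alignment columns by how strongly they appear responsible for the functional
divergence between the groups.

Instead of a single proprietary score, the package implements a *decomposable*
scoring algebra, so the source of every prediction can be traced to its
ingredients:

1. **Within-group conservation** per column and group: plain entropy
   *H* = −Σ<sub>α</sub> *f*<sub>α</sub> ln *f*<sub>α</sub> (`e`), its
   free-evolution-corrected form *H*<sup>o</sup> − *H*<sup>e</sup>(*t*<sub>eff</sub>)
   (`r`), or Jensen–Shannon divergence from the stationary background (`j`).
2. **Between-group overlap** per column and group pair: the normalized
   dot-product overlap *o* = 2 *p*·*q* / (*p*·*p* + *q*·*q*) (`o`), the sum of
   squared differences (`f`), the exchangeability-corrected overlap
   *o*<sup>o</sup> − *o*<sup>e</sup>(*t*<sub>eff</sub>) (`r`), or pairwise mutual
   information (`m`).
3. **A combiner** — Euclidean (`e`) or linear (`l`) — and an **evolutionary
   model** deciding which penalty terms enter:
   * *discriminant*: every group conserved, every pair non-overlapping
     ("constant but different");
   * *determinant*: only the target group must be conserved and only its
     pairs non-overlapping — the other groups may evolve at any rate
     (heterotachy).

Exchangeability of residue types enters through a continuous-time Markov model
of amino-acid replacement: a rate matrix *Q* (WAG by default, any PAML-dialect
matrix accepted) with transition probabilities *P*(*t*) = exp(*Qt*) and
stationary distribution π. Each column's "expected" behavior is that of a
position drifting freely from a single ancestral type for the family's
effective divergence time *t*<sub>eff</sub>, itself estimated from the
alignment by maximizing free-vs-observed overlap per column.

A scorer is named by a three-letter identifier — conservation, overlap,
combiner — e.g. `rol` = corrected entropy + normalized overlap + linear, plus
the model and target. Rankings are evaluated by ROC curves against annotated
residues, and a planted-signal alignment simulator provides families with
known determinant/discriminant/free/conserved columns for validation.

## Worked example

A toy family of two groups of four sequences with three columns: column 1
conserved everywhere, column 2 partially diverged, column 3 conserved as `A`
in group A and variable in group B — the signature of a determinant of
group A.

```sh
sdpscan scan --alignment toy.fasta --groups toy_groups.tsv \
             --scorer eoe --model determinant --target A
```

```
# scorer=eoe model=determinant target=A rate_matrix=wag t_eff=0.335407
position	conservation_A	conservation_B	overlap_A_B	score	high_gap	rank
3	1.000000	0.000000	0.000000	0.000000	False	1
2	1.000000	0.500000	0.666667	0.471405	False	2
1	1.000000	1.000000	1.000000	0.707107	False	3
```

Positions are 1-based; smaller scores mean more specific. Column 3 scores a
perfect 0 under the determinant model — fully conserved in the target group,
no overlap with the other group — while the family-wide conserved column 1
ranks last (its overlap of 1 is maximally penalized). The header echoes the
effective divergence time estimated from the alignment.

The other subcommands: `sdpscan evaluate` computes a ROC/AUC report from an
annotation file (`--mode non_positive` counts every non-positive residue in
the x-axis; `--mode confirmed_negative` uses confirmed negatives only),
`sdpscan sweep` tabulates AUCs for the full scorer grid, and
`sdpscan simulate` writes a synthetic family with planted column classes.
Everything is also available as a library (`import sdpscan`).

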