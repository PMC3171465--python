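# Methods

## The free-evolution model

Every score in the package is relative to one multiple sequence alignment
whose rows are partitioned into G ≥ 2 groups of orthologues. At each column
and for each group, the distribution of residue types is estimated by the
observed frequencies f<sub>α</sub> over the 20 canonical amino acids (gaps
and `X` excluded, frequencies renormalized). Sequences are assumed to be a
fair, comparably broad sample per group; no sequence weighting or tree is
used — phylogeny-freeness is a deliberate feature, trading resolution for
robustness and applicability when the branching order is itself uncertain.

Constraint-free drift of a column is modeled by a reversible continuous-time
Markov chain on the 20 types: a rate matrix Q assembled from a PAML-dialect
file as Q<sub>ij</sub> = s<sub>ij</sub>π<sub>j</sub> (i ≠ j), diagonal set so
rows sum to zero, globally rescaled so −Σ<sub>i</sub> π<sub>i</sub>Q<sub>ii</sub> = 1.
Time is therefore measured in expected substitutions per site. The bundled
default is the WAG replacement matrix; any other general matrix can be
substituted (`--rate-matrix`), since the framework is matrix-agnostic. The
transition probabilities are P(t) = exp(Qt); for large t every row approaches
the stationary distribution π, the model's background. A *free distribution*
is a row of P(t): the expected type distribution of a position that started
from a single ancestral type and evolved without constraints.

P(t) is computed by symmetrizing eigendecomposition (B = D<sup>1/2</sup>Q
D<sup>−1/2</sup> with D = diag π is symmetric for a reversible chain), cached
per model, with a dense `expm` fallback for non-reversible user input; rows
are clipped at 0 and renormalized, keeping row sums exact to ~1e−15. P(0) is
returned as the exact identity.

## Effective divergence time

The one trait all columns share is the time since the family's last common
ancestor. It is estimated per column as the t that maximizes the overlap
(the normalized dot product, below) between the observed distribution and
the free distribution seeded at the column's ancestral type — the majority
type, with frequency ties resolved toward the candidate whose free
distribution can achieve the larger overlap, and any remaining tie by
alphabet order. The search uses a grid {0} ∪ 64 log-spaced points in
[10<sup>−3</sup>, 20], refined by golden-section to |Δt| < 10<sup>−3</sup>;
the refinement tracks the best point seen including bracket endpoints, so a
boundary maximum (a fully conserved column, maximized at t = 0) is returned
exactly. The family-wide t<sub>eff</sub> is the unweighted mean over all
non-empty (column × group) profiles, and this single value feeds every
observed-minus-expected correction. A per-group or per-position time would
also be defensible; the family-wide choice matches the premise that the
groups cover the same evolutionary breadth, and it makes corrections
comparable across columns.

## Conservation scores

* `e` — entropy H<sup>o</sup> = −Σ f<sub>α</sub> ln f<sub>α</sub> (nats;
  0 · ln 0 = 0). Natural logs throughout; the base cancels after rescaling.
* `r` — corrected entropy H<sup>o</sup> − H<sup>e</sup>(t<sub>eff</sub>),
  where H<sup>e</sup> is the entropy of the free distribution from the
  column's ancestral type. This encodes exchangeability in the intuitive
  direction: isoleucine drifts easily into valine/leucine, so a *conserved*
  isoleucine column (observed entropy 0, large expected entropy) signals
  stronger constraint than a conserved tryptophan column. Divergences from
  the stationary distribution — KL (Σ f ln(f/π)) and its smoothed JS
  variant (`j`) — prefer rare types instead (conserved W above conserved I),
  the counterintuitive direction the correction repairs; both are provided,
  and the direction contrast is asserted in the test suite.
* `0` — no conservation: the constant ½, so combiners stay well-defined and
  ranking depends on overlap alone.

Raw values are min–max rescaled per group across columns (a degenerate,
constant column set maps to 0). `e` and `r` measure variability, so the
conservation coordinate is C = 1 − rescaled; `j` already grows with
conservation and is used as-is. Whether to rescale before or after the
correction is an open choice; all conservation variants are rescaled
identically for comparability.

## Overlap scores

For two group distributions p, q at one column:

* `o` — normalized dot product 2 p·q / (p·p + q·q): 1 for identical
  distributions *irrespective of their variability*, 0 for disjoint
  supports. This is the preferred measure because it cleanly separates
  overlap from conservation.
* `eq9` — the raw dot product p·q: 0 for disjoint supports, but its value
  for identical distributions depends on their spread (1 for matching
  indicators, ¼ for matching uniform-on-4).
* `f` — sum of squared differences Σ (p<sub>α</sub> − q<sub>α</sub>)²: 0 iff
  identical; its disjoint-support value depends on variability (2 for
  disjoint indicators, 1 for disjoint two-type uniforms).
* `klg` — KL(p‖q), with the reference floored at 10<sup>−6</sup> and
  renormalized so the value stays finite when p has mass where q has none;
  asymmetric. `sh` — its symmetrized Jensen–Shannon cousin (0 iff identical,
  ln 2 for any disjoint pair).
* `m` — mutual information between residue type and group membership,
  restricted to the pair; the multi-group MI over all G groups is the
  baseline "ultimate discriminant" measure. Group marginals use counted
  (non-gap) residues so gapped columns cannot fake assortment signal.
* `r` — corrected overlap: observed `o` minus the `o`-overlap of the two
  groups' free distributions (seeded at each group's ancestral type, evolved
  for t<sub>eff</sub>), the observed-minus-expected form, in [−1, 1]. Two
  groups locked on *exchangeable* types (I vs L) have a large expected
  overlap, so their corrected value is more negative than that of a
  non-exchangeable pair (I vs W): unrealized easy exchange reads as stronger
  divergence, mirroring the corrected-entropy direction.

Before combination every overlap id is oriented so that lower = more
diverged and mapped to [0, 1] across columns: `o` passes through unchanged;
`r` is min–max rescaled (orientation preserved); `f`, `m`, `eq9`, `klg`,
`sh` are negated then rescaled. A family in which a pair's score is constant
across columns maps to 1 (no divergence signal anywhere).

## Combined scores

Each scored column yields conservation C<sub>g</sub> per group and overlap
v<sub>gh</sub> per pair, a point in the conservation/overlap cube whose
corners are the canonical behaviors (all-conserved-same, discriminant,
determinant-of-g, fully variable). A model selects penalty terms:

* determinant(T): (1 − C<sub>T</sub>) and v<sub>Tg</sub> for g ≠ T — the
  score is exactly independent of all other groups' conservation and of
  pairs not involving T (asserted bit-exactly in tests);
* discriminant: (1 − C<sub>g</sub>) for every g and v for every pair;
* conservation-only: (1 − C<sub>g</sub>) for every g;
* nonconserved-nonoverlap: C<sub>g</sub> and v for every pair (the
  "interesting-looking" opposite corner; in practice a poor strategy, kept
  for completeness).

The Euclidean combiner is the root of the mean of squared terms, the linear
combiner the plain mean. Dividing by the number of terms is a normalization
choice so both lie in [0, 1]; since evaluation is rank-based (ROC), any
positive constant factor is immaterial, and the rank-invariance is tested.
Smaller = more specific; ties broken by column index.

## ROC evaluation

Rankings are swept threshold-by-threshold, one step per distinct score, with
y = fraction of annotated positives recovered and x either the fraction of
*all* non-positive residues (mode `non_positive`, honest when true negatives
are unknown) or of confirmed negatives only (mode `confirmed_negative`). The
trapezoid area then equals the probability that a random positive outranks a
random negative with ties counted ½ — an identity verified against a
brute-force pairwise oracle and against scikit-learn on tie-free inputs.
Positions fully conserved across the entire family are removed from positive
sets at annotation load: they cannot confer specificity by construction.

## The synthetic generator

`simulate_family` draws each column independently under the same model the
scores assume: an ancestral type from π, then a star phylogeny in which each
sequence is an independent draw. Classes: conserved (all sequences =
ancestor), determinant of g (group g frozen at the ancestor, all other
groups i.i.d. from the free distribution at the family divergence time),
discriminant (each group frozen at a distinct type, the first at the
ancestor, the others uniform without replacement — deliberately free of
exchangeability bias, so the corrected overlap has signal to find), and free
(all i.i.d. from the free distribution). The benchmark conditions are two
groups of 40 sequences and 200 columns (20/20/80/80
determinant/discriminant/free/conserved) at divergence time 2.0 — sizes
representative of a curated two-paralogue family with a realistic class
imbalance, small enough that the full grid sweep runs in seconds.

What the generator does *not* emulate: tree structure and correlated
descent, rate variation within a class, indels, alignment error, and
imperfect within-group conservation of planted columns. Consequently
recovery results show scorer behavior under the model's own assumptions, not
robustness to real-data noise. One visible consequence: because a planted
determinant column assorts its target group perfectly into one residue bin,
multi-group mutual information is near its ceiling on these families and is
*not* systematically beaten by the determinant scorers here, although both
sit near AUC 1; MI's known weakness on determinant-type divergence is a
real-data phenomenon driven by imperfect conservation and noisy overlap,
which this generator idealizes away. The determinant-over-discriminant
pattern, by contrast, reproduces robustly: across the
{e,r,j,0}×{o,f,r,m}×{e,l} grid the determinant model's AUC on planted
determinants is never worse than the discriminant model's and is strictly
better in every cell except the conservation-`0` scorers — for two groups
those reduce both models to the identical overlap ranking, so such cells are
counted as ½ in the reported win fraction (the same tie convention as the
AUC).

## Numerical and interface choices

* Alphabet order is the PAML convention (A R N D C Q E G H I L K M F P S T W
  Y V) everywhere, shared with the rate-matrix file dialect.
* Gap policy: gaps and `X` never enter frequencies; columns > 50% gapped in
  any group are flagged (`high_gap`) but still scored; columns empty in any
  group are excluded from scoring. How to treat a column entirely gapped in
  one group is genuinely open; exclusion-with-flag is the package's choice.
* Columns are 0-based in the API, 1-based in all files and CLI output.
* KL floor 10<sup>−6</sup>; 0 · ln 0 = 0 throughout; JS uses the
  equal-weight ½/½ mixture.
* t<sub>eff</sub> is computed once per scan and echoed in output headers.
* Effective-time search granularity (64 grid points, refinement to
  10<sup>−3</sup>) is far below the sampling noise of realistic alignments.

## Limitations

Scores are relative to one alignment — absolute values carry no meaning
across families. The method inherits the quality of the input grouping and
alignment; it does not detect orthologous groups, handle alignment
reliability, or map scores to structure. Residue-type exchangeability enters
only through a single family-wide average replacement process; site-specific
or lineage-specific rate matrices are out of scope. With very few sequences
per group (< ~10) the frequency estimates, and hence all downstream scores,
are dominated by sampling noise.
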