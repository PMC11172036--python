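# Methods

## Scope and pipeline

`sitelink` analyses a protein MSA in five stages:

1. **Read** a FASTA or CSV alignment (CSV in either one-character-per-cell
   or whole-sequence-string dialect, auto-detected). Characters are
   upper-cased; `-` and `.` are both gaps and are normalised to `-`; the
   rare/ambiguous residue codes B, Z, X, U, O are kept as ordinary distinct
   symbols for counting (they are too rare in curated alignments to disturb
   entropy or NMI, and discarding them would silently change row counts).
   `*` and whitespace inside sequences are hard errors.
2. **First-row mapping**: columns where the reference (first) row holds a
   gap are removed and the survivors are numbered 1..N along the reference
   sequence. All downstream positions are these 1-based reference
   coordinates. Mapping is applied before the non-insertion filter, so the
   post-mapping width equals the reference protein's length.
3. **Non-insertion filter**: a column survives when its fraction of non-gap
   characters is at least `pct/100`. The boundary is inclusive (a column at
   exactly the threshold is kept).
4. **Entropy filter**: plug-in Shannon entropy in nats over non-gap
   frequencies; columns with entropy *at or below* the threshold are
   removed from clustering but reported. All-gap columns have no defined
   entropy; they are reported in a separate `excluded` bucket and never
   clustered.
5. **Clustering**: pairwise NMI over retained columns, then greedy nested
   agglomeration up to the requested order, scored by SRMode.

## Entropy

The estimator is the plug-in (maximum-likelihood) entropy; no small-sample
correction (Miller–Madow etc.) is applied. With ~100 rows the bias is a few
hundredths of a nat, uniform across columns, and the filter threshold scale
(0–0.25 nats) is calibrated directly against deviation counts: at 105 rows a
single deviant residue scores 0.0538, two identical deviations 0.0943, two
distinct deviations 0.1075. A threshold of 0.1 therefore removes sites that
change at most once; 0.11 additionally removes double-change sites. The
threshold comparison is inclusive (`entropy ≤ t` removes).

Units: entropy filtering is in **nats** throughout. Sequence-logo
information content (reporting module) is in **bits**, `log2 20 − H₂`,
matching logo convention. The two scales are never mixed.

## NMI

For columns X and Y, rows with a gap in either column are dropped and the
joint table is formed over the remainder; marginals are recomputed on that
same row subset so that `I(X;Y) = H(X) + H(Y) − H(X,Y)` is always
non-negative up to rounding (values are clipped to [0, 1]). Normalization is

    NMI = I(X;Y) / min(H(X), H(Y)),

chosen so that NMI = 1 exactly when one column functionally determines the
other (a bijective recoding scores 1 under this and the common alternative
normalizations, but only the min-entropy form also gives 1 for surjective
determination). If either marginal entropy is zero the pair is scored 0 —
an invariant column cannot evidence interdependency. Pairs whose jointly
non-gap row count falls below a configurable fraction of the alignment
depth (default 50%) are scored 0 rather than trusting a tiny contingency
table.

Plug-in MI is biased upward for independent columns, roughly
`(k_x−1)(k_y−1)/(2n)` nats; at 105 rows and 4–6 residue states this puts the
independent-column NMI floor near 0.03–0.07. No phylogenetic or
average-product correction is applied; the entropy pre-filter and the
bias floor are what the cluster ranking is calibrated against, and the
Monte-Carlo null tests pin the floor's magnitude.

## SRMode and cluster construction

A cluster of n members is scored

    SRMode = (2/n) × mean pairwise NMI,

which reduces to NMI for a pair and has ceiling 2/n (0.667, 0.50, 0.40,
0.20 at orders 3, 4, 5, 10), attained iff every member pair is fully
redundant. The 2/n factor penalises order: a large cluster must be
substantially redundant throughout to outrank a smaller one.

Construction is greedy and deterministic:

* **Order 2** — every retained column nominates its best partner by NMI;
  the deduplicated pairs are ranked by NMI descending.
* **Order k > 2** — every (k−1)-cluster is extended by the single retained
  column maximizing the resulting SRMode; duplicate member sets are
  reported once. Every k-cluster therefore contains its (k−1)-parent,
  giving a nested hierarchy.
* **Ties** break toward the lowest position number; cluster ranking breaks
  SRMode ties by ascending member tuple. Identical input and parameters
  give byte-identical CSV reports.
* **Spread** `s` restricts pairwise evaluation to column pairs whose index
  distance in the retained list is a multiple of `s` (a speed knob);
  `s = 1` — the only setting used in practice — is exhaustive.
* A column may appear in several same-order clusters by default, since
  real interdependent sites do recur across clusters; `allow_overlap=False`
  instead assigns each column to at most one cluster per order, greedily in
  rank order.

Exact SRMode decimals from other implementations of this score are not
reproduced: the formula here is reconstructed from its printed
order-dependent maxima and its reduction to NMI at order 2, and the package
pins the maxima and the ranking behaviour, not third-party decimal output.

## Synthetic data generator

`SyntheticSpec` plants known structure so every stage is testable without
external data: invariant columns; near-invariant columns with exactly 1 or 2
deviant rows (never the reference row); coupled groups driven by a shared
per-species latent state (default 4 states) where each member column carries
its own injective state→residue code and each cell flips to a random other
residue with probability `noise`; background columns i.i.d. uniform over a
6-letter sub-alphabet (roughly the per-column residue diversity of variable
sites in deep protein alignments); per-cell gaps at `gap_rate`, never in the
reference row, so first-row mapping is the identity and planted indices
coincide with reported positions.

Defaults are 105 species — the depth of the chordate topoisomerase IIα
alignment this tool family is used on — with noise and gap rate 0 unless
specified. Latent states are drawn independently per species: the generator,
like the clustering method itself, does not model phylogenetic correlation,
substitution processes, or insertion blocks. Passing recovery tests on this
generator therefore demonstrates correctness of the estimators and the
greedy search, not robustness to tree-structured confounding in real
alignments.

## Validation problem sizes

The planted-recovery check runs 100 replicates per noise level
(0, 0.05, 0.2) at 105 species × 50 columns with one planted triple,
requiring ≥95% top-rank recovery at 5% noise and a non-increasing recovery
rate in noise. The independent-columns null uses 1000 replicates of five
uniform 4-letter columns (SRMode below 0.05 in ≥95%). Property tests
(entropy invariances, NMI symmetry/range/relabeling, the SRMode bound,
nesting) run on randomized inputs with fixed seeds.

## Degenerate inputs and numerical choices

* Ragged alignments, empty files, and invalid characters are hard errors
  naming the offending row.
* An entirely-gap reference row cannot be mapped (error).
* All-gap columns: flagged, excluded from clustering and logos, reported.
* Entropy of a single-symbol column is exactly 0 (clamped against −0.0).
* NMI values are clipped to [0, 1] against floating-point drift.
* Thresholds: entropy scale [0, 0.25] inclusive; non-insertion (0, 100];
  cluster order 2–10.

## Limitations

* No phylogenetic correction: shared ancestry can inflate apparent
  covariation between columns; rankings on real alignments should be read
  with that in mind.
* Plug-in estimators are biased at low row counts; the joint-coverage guard
  mitigates the worst case (heavily gapped pairs) but alignment depths below
  ~50 rows will compress the dynamic range of NMI.
* The greedy extension explores one child per parent cluster; it is a fast
  hierarchy builder, not an exhaustive search over all k-subsets.
* Region annotation is configuration, not prediction: the bundled
  topoisomerase IIα preset (C-terminal domain 1175–1531, the two nuclear
  localization sequences, sumoylation/phosphorylation sites) is a starting
  point for that protein only.
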