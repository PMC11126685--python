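# Methods

`lichenscan` implements the inference chain used to ask how a binary
symbiotic lifestyle (lichen algal symbiont, LAS, vs non-symbiotic alga, NSA)
evolved across a chlorophyte species tree, and which gene families track it:
ancestral state reconstruction under a two-state Markov model, a per-family
enrichment scan and sparse discriminant analysis of an orthogroup count
matrix, cross-referencing with differential-expression calls, and a
horizontal-gene-transfer (HGT) evidence synthesis. A synthetic-data
generator with exact ground truth exercises every stage.

## Mk model and ancestral state reconstruction

The trait follows a continuous-time Markov chain on the rooted tree with
gain rate `q01` (NSA→LAS) and loss rate `q10` (LAS→NSA), per unit branch
length. ER constrains `q01 = q10`; ARD frees both. Transition probabilities
use the closed form

    P00(t) = (q10 + q01 e^{-(q01+q10)t}) / (q01 + q10),  P01 = 1 − P00,

and likewise for `P11`. Tip data are integrated by Felsenstein pruning;
polytomies are handled natively as products over children, and partial
likelihoods are rescaled per node so deep trees cannot underflow.
Zero-length branches are legal (identity transition); a state conflict
across a zero-length path yields log-likelihood −∞ rather than an error.

Rates are fitted by maximizing the log-likelihood over log-rates with
L-BFGS-B, bounds `[1e−8, 1e3]`, and three deterministic starts
(0.1, 1, 10 × the inverse tree height); the best of starts and optima is
kept, so the returned likelihood never falls below any starting point. ER
vs ARD selection reports ΔlogL, the likelihood-ratio statistic with a
1-df χ² p-value, and AIC; the richer model is retained when it improves the
log-likelihood beyond 1e−6, with ER as the tie-break.

Marginal posteriors combine the pruning (subtree) partials with an outside
pass propagating root-ward information; tip posteriors are point masses on
the observed states. Gains and losses are read off by thresholding the
posterior at 0.5 (a node exactly at threshold is flagged ambiguous and
inherits its parent's call): a gain is an edge 0→1, a loss 1→0.

**Root priors.** Three options: uniform (0.5, 0.5), stationary
(`q10/(q01+q10)`, `q01/(q01+q10)`), and a custom pair. The library default
is uniform. For gain/loss counting on symbiosis-like data, however, the
maximum-likelihood surface has a degenerate corner: as `q01 → 0` with a
uniform root prior, the data can always be explained as an ancestral
presence followed by losses only (every presence clade "survives", every
absence is a loss), and this Dollo-like corner frequently dominates the
likelihood when losses outnumber gains. The pipeline therefore supports
pinning the root to the non-symbiotic state (`root_prior="nsa"`, i.e.
π = (1, 0)), which is the biologically motivated choice whenever the tree
is rooted on a non-symbiotic outgroup — the configuration used for the
synthetic study. The stationary prior damps the same corner more softly.

## Orthogroup enrichment scan

The screen operates on a species × family matrix of non-negative gene
counts. Families observed in fewer than three species are removed first
(this drops species-specific and two-species families). Species are split
into `focal` (symbiotic) and `other`; each family is tested with a
two-sided Mann–Whitney–Wilcoxon test on its counts, zeros included — a
species lacking the family carries presence/absence signal. When the
number of group assignments `C(n+m, n)` is at most 200,000 the exact null
distribution is enumerated with mid-ranks for ties and the two-sided p is
the doubled smaller tail, capped at 1; larger designs use the
tie-corrected, continuity-corrected normal approximation (at the study-like
13 vs 23 split and above, the approximation is in effect). Significance
defaults to raw `p < 0.01` with no multiplicity correction — mirroring the
screen this package reproduces — with Benjamini–Hochberg adjustment
available (`adjust="BH"`, delegated to statsmodels). Direction is defined
by mean-rank comparison so it can never contradict the statistic. Constant
families after subsetting are dropped with a warning: they admit no test.

The same Wilcoxon machinery backs the genomic-feature comparison
(genome size, gene count, GC%, TE fraction), which reports group medians so
statements like "lower in the symbiotic group" are explicit.

## Sparse PLS-DA

X is the column-centered, unit-variance-scaled count matrix (sd with one
delta degree of freedom; zero-variance columns stay zero and always receive
zero loading so feature indices are stable). Y is a centered/scaled
two-column class-indicator block; a one-column ±1 coding is available and
selects the same component-1 support for two classes. Each component is
the dominant singular pair of `X_hᵀY` found by power iteration
(tol 1e−9, max 500 iterations, non-convergence is an error). At every
iteration the X-weight is soft-thresholded with the order-statistic λ (the
(keepX+1)-th largest absolute weight), ties broken by ascending feature
order and kept at a nominal magnitude, so that exactly `keepX` features
survive; the weight is then re-normalized. Scores are `X_h·w`; X is
deflated by regressing it on the score (regression mode — Y is not
deflated). Counts enter untransformed by default; `log1p` is an option.

Explained variance is reported two ways: the primary figure is the
fraction of `‖X‖_F²` captured by the (Gram–Schmidt-orthogonalized, in fit
order) component scores, computed against the undeflated scaled X; the
Y-variance analogue is exposed as an auxiliary output. On data of this
shape the X-variance fractions are small (a few percent): class-linked
families are a thin slice of total count variance, which is exactly why a
discriminant criterion is needed.

## Differential-expression cross-referencing

The package consumes per-gene statistics (log fold change and
FDR-adjusted p) from standard count-based DE tools; model fitting itself is
out of scope. `logFC` is treated as log2, so the 1.5 threshold is roughly
a 2.8-fold change. Calls are strict: up iff `fdr < 0.05` and
`logFC > 1.5`; down iff `fdr < 0.05` and `logFC < −1.5`; boundary values
are `none`. The low-count pre-filter removes genes whose summed reads fall
below 10 in *every* sample class; the stricter reading (≥10 in all
classes) is available via a flag, since the prose rule "fewer than 10 reads
across each class" admits both.

Family regulation is the aggregate of member-gene calls: `both` iff at
least one up and one down member, `none` iff no DE member. The final
triage walks the discriminant top-k list in rank order: families outside
the enrichment-significant set are `dropped_not_enriched` (a status added
here — the triage order implies the step), families with regulation `none`
are `dropped_no_expression`, families whose external phylogenetic flag is
`refuted` are `dropped_phylogeny`, `unresolved` flags are carried through
as a status, and the rest are `retained`. Phylogenetic flags are inputs
(from gene-tree curation or the HGT stage); absent flags default to
`supported`.

## HGT triage

Four lines of evidence, each deterministic and auditable:

- **Specificity.** Presence fractions (count ≥ 1) in focal vs other
  species, reported with numerators and denominators.
- **Event parsimony.** `transfers` = number of maximal present clades − 1:
  the donor lineage counts as the native origin, so a bacteria → fungi,
  bacteria → algae history (or a serial bacteria → fungi → algae chain)
  costs two events; counting the origin is an option. `dollo_losses` =
  number of maximal absent clades strictly inside the MRCA of the present
  tips — the cost of a single ancient origin under Dollo parsimony. The
  verdict compares the two, with ties allowed, and a Sankoff minimum-change
  count with configurable gain/loss costs is attached for sensitivity.
  Full DTL reconciliation is deliberately out of scope.
- **Gene-tree nesting.** The gene tree (tips `seqid|taxon_group`) is
  rooted on the outgroup MRCA when outgroup tips exist (otherwise analyzed
  as supplied, flagged unrooted). Maximal focal-only clades are located;
  the donor hypothesis is the majority taxon among the sister lineages of
  those clades. A majority belonging to the focal group itself or to a
  declared `vertical_taxa` set (e.g. other chlorophytes for an algal
  candidate) means vertical descent and yields donor `none`. Support
  values are carried but not used for gating by default.
- **Scaffold anchoring.** Up to 5 genes per side of the candidate, in
  start-coordinate order on its scaffold (GFF3 coordinates kept 1-based
  inclusive; strand ignored for ordering). `anchored` requires at least 2
  assigned neighbors on each existing side and a host fraction ≥ 0.6 among
  assigned neighbors; a lower fraction is `suspect` (contamination-like);
  fewer than two assigned neighbors total is `insufficient_context`. The
  window and thresholds are package decisions — the criterion they encode
  is qualitative ("anchored among host genes").

The pipeline's joint flag (`hgt_supported`) requires a non-vertical donor,
focal presence ≥ 0.5 and at least twice the other-group presence, an event
verdict not favoring losses, and non-suspect anchoring.

## Synthetic-data generator

The generator emulates the statistical structure of the study design, not
its sequences: a Yule (pure-birth, rate 1) tree scaled to height 1 with 141
tips; a planted trait history with 3 independent gains and 11 nested tip
losses (or alternatively a free Mk simulation); an orthogroup matrix of
2,000 background families (rate λ_f ~ Gamma(2, 1), counts iid
Poisson(λ_f)), 20 expanded families (Poisson mean × 4 in symbiotic
species), and 2 xenolog families present with probability 0.85 in symbiotic
and 0.2 in non-symbiotic species (count 1 + Poisson(0.3)) — echoing an
11/13 vs 5/23 retention pattern; DE tables where candidate-family genes are
differentially expressed with probability 0.8 (fair-coin direction,
|logFC| = 1.5 + Exp(1), fdr ~ U(0, 0.05)) against a 5% background rate
(logFC ~ N(0, 0.5), fdr ~ U(0, 1)); gene trees grafting the algal candidate
clade inside a bacterial clade (xenolog mode) or beside other chlorophytes
(vertical mode); and scaffold fixtures with host-like or contaminant-like
neighborhoods. One RNG stream drives each dataset in the fixed order
tree → trait → families → genes → fixtures, and all emitted text uses fixed
float formatting, so identical configurations give byte-identical files.

**Identifiability constraints on the planted history.** Marginal ML
reconstruction only recovers a planted event history when the pattern is
strongly phylogenetically clustered, so planted clades are chosen greedily
(largest first, 10–28 tips) under constraints that make each gain and loss
the likelihood-preferred reading: clades hang on long stem branches
(≥ 0.1, and longer than their parent's stem), have compact crowns (≤ 0.4),
and any two clades are separated by at least 15 intervening tips and 5
side-lineages on the connecting path; losses avoid sibling pairs, direct
children of clade roots, and very short terminal branches, and every
internal clade node keeps a majority of its tips present. When a given
tree cannot satisfy the strict constraints they are relaxed stepwise
(documented in `simulate._CLADE_LADDER`); if no placement exists at all,
the generator raises. Even under the strict conditions the marginal-ML
reading occasionally differs from the planted truth by a single event
(a gain shifted one node rootward, costing an extra loss) — the acceptance
suite requires exact recovery in at least 80% of replicates and reports the
measured fraction, rather than pretending the estimator is exact.

**What the generator does not emulate — and what passing therefore does
not show.** Counts are iid across species given the family law, with no
phylogenetic autocorrelation beyond the trait linkage (the screen under
test ignores phylogeny too; a Brownian-rate variant would be the natural
extension). DE statistics are drawn from the planted truth rather than
fitted from reads, so DEG-stage tests validate thresholding and
bookkeeping, not a DE model. Gene trees are constructed topologies, not
inferred from evolved sequences, so nesting tests validate the
classification rule, not phylogenetic inference. Results on real data
additionally depend on orthogroup quality, expression noise, and gene-tree
uncertainty, none of which are represented here.

## Numerical and engineering choices

- Optimizer tolerances `ftol 1e−12 / gtol 1e−10`; likelihood comparisons
  use a 1e−6 nesting tolerance.
- Exact-vs-approximate Wilcoxon switch at `C(n+m, n) ≤ 200,000` keeps the
  worst exact case around a tenth of a second while guaranteeing exactness
  at small group sizes.
- Deterministic tie-breaks throughout: feature order in sPLS-DA selection
  and contributor ranking, parent-inheritance for threshold-exact ASR
  calls, `sort_keys` + fixed float rounding (10 decimals) in all JSON.
- Pipeline reports contain no timestamps, so re-runs with identical inputs
  are byte-identical.
- Newick I/O is backed by dendropy with validation layered on top
  (duplicate tips, default branch lengths with a warning); writing uses the
  package's own fixed-format serializer.

## Known limitations

- Binary traits only; no hidden-rate or multi-state models, no stochastic
  character mapping. Event counts from thresholded marginal posteriors are
  a point summary — they carry no uncertainty interval.
- The uniform-prior ML degeneracy described above means gain/loss counts
  on loss-heavy data should be interpreted with a deliberate root prior.
- The enrichment scan's raw-p default reproduces the screen it mirrors;
  for stand-alone use BH adjustment is recommended.
- sPLS-DA keepX/ncomp are fixed inputs; cross-validated tuning is out of
  scope.
- The anchoring check orders genes by start coordinate only and does not
  model nested or overlapping genes.
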