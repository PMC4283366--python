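# Methods

## Scope and model

`caridelim` implements a single-locus (mitochondrial 16S) delimitation
workflow for a pair of morphologically cryptic shrimp lineages plus their
relatives: site-pattern statistics, pairwise divergences, lineage-level
divergence summaries, strict-clock dating, and a block-wise
diagnostic-character screen for categorical morphology. Phylogenetic tree
inference proper (Bayesian, likelihood, parsimony) is deliberately out of
scope: lineage membership is taken from specimen metadata, exactly as species
assignments accompany museum material, and the package's own UPGMA + tree-cut
path is offered only as a clearly labelled unsupervised fallback, not as a
stand-in for model-based phylogenetics.

## Sequence handling

Sequences are read from pre-aligned FASTA (the aligner is an upstream choice;
MAFFT defaults were used for the original 16S set this workflow targets).
Columns are filtered by *complete deletion*: a column is dropped when any
sequence carries `-` (gap), `?` (missing) or an IUPAC letter outside ACGT
(ambiguous, including N). The three exclusion reasons are recorded per column
with priority gap > missing > ambiguous; the symbol conventions are a package
choice, since datasets in the wild differ in whether unsequenced overhangs
are coded `-` or `?`. Pairwise deletion is available in the distance layer
for sensitivity analysis; on a filtered alignment the two modes coincide,
which the tests exploit as an invariant.

Site classification follows the standard parsimony bookkeeping: a column is
variable iff ≥ 2 states occur, parsimony-informative iff ≥ 2 states each
occur in ≥ 2 sequences, otherwise singleton-variable.

## Distances

Distances are stored as proportions end to end; multiplication by 100 happens
only when rendering reports. Corrections:

- JC: `d = −(3/4)·ln(1 − 4p/3)`, defined for p < 0.75;
- K2P: `d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q)` with P + Q = p,
  defined while both logarithm arguments stay positive.

Values at or beyond the saturation bound raise rather than return infinity.
K2P is the default reporting model with JC always computed alongside: neither
is privileged by the data at these divergence depths (the dated results agree
to < 0.1 Ma on the default scenario), so both are reported wherever dating is.

Lineage summaries are exact min/mean/max over unordered sequence pairs
(unweighted arithmetic means); intra cells for singleton groups are flagged
undefined rather than zero. Both per-pair values and the cell summaries are
exposed, since barcode-gap plots are drawn both ways in practice.

## Strict-clock dating

Under a strict clock at rate *r* (substitutions/site/Myr per lineage), the
corrected divergence between lineages that split *t* Ma ago is `d = 2rt`.
Calibration inverts the same identity on a dated sister pair
(`r = d_cal / 2t_cal`); the default rate, 0.0083 subs/site/Myr, is the
published neotropical palaemonid 16S rate anchored on the ~3 Ma transisthmian
split and is treated as an input constant (its underlying calibration
divergence was never published; `calibrate_rate(0.0498, 3.0)` reproduces it
and serves as the worked example). The group-level divergence is the
unweighted mean of cross-pair corrected distances — ranges are reported
separately, but a point estimate needs a defined statistic.

Uncertainty is a *site bootstrap*: alignment columns are resampled with
replacement, the mean corrected cross-lineage distance and `t = d/(2r)` are
recomputed per replicate, and the 2.5/97.5 percentiles form the interval.
This quantifies site-sampling variance only. It is not a Bayesian credible
interval: calibration error, rate variation across lineages and genealogical
stochasticity are all outside it, and every report labels it accordingly.
Replicates that resample their way past the correction's saturation bound are
dropped and counted; more than 10% dropped aborts the estimate. Replicates
are vectorised as multinomial column counts, so 1000 replicates cost two
small matrix products.

The clock assumption itself is screened with Tajima's one-degree-of-freedom
relative-rate test on (ingroup A, ingroup B, outgroup): the counts of sites
where only A, respectively only B, differs from the outgroup are compared
with a χ² statistic `(m1 − m2)²/(m1 + m2)`. This is a deliberately
lightweight check, not a likelihood-ratio clock test.

## Diagnostic-character screening

The screen looks for categorical characters separating two molecularly
delimited clades, driven throughout by *constancy* — the fraction of a
clade's scored specimens showing the clade's candidate (modal) state,
computed over known states only. Three stages:

1. **Initial screen** on molecular-voucher specimens: a character is a
   candidate iff the two clades' modal states differ and constancy is
   strictly above the threshold (default 0.80) in *both* clades. Requiring
   both sides is a design choice (a diagnostic character must be reliable on
   each side); a modal-state tie within a clade makes the character
   non-diagnosable for the comparison and it is skipped with a trace entry.
2. **Block validation** on the remaining specimens from voucher lots, in
   shuffled blocks (default 10 per clade; the shuffle seed is recorded since
   the historical block order of any real screen is unrecoverable). After
   each block the *cumulative* constancy — initial specimens plus all blocks
   so far — is recomputed against the fixed modal states; a character is
   discarded at the first block where either clade drops strictly below
   threshold, and never revisited. Cumulative rather than per-block constancy
   drives the decision: per-block constancy on 10 specimens is too noisy to
   support an irreversible discard.
3. **Final check** on hold-out lots containing no molecular voucher. The
   hold-out blocks continue the same running tally ("additional blocks" of
   one step-by-step evaluation) rather than restarting it; the trace still
   shows per-block cumulative values so a hold-out collapse is visible.

Juveniles are excluded by default (diagnostic characters in this group are
reliable only in adults); `adults_only=False` exists for sensitivity
analysis. The strict (`>` not `≥`) threshold and the per-clade (not pooled)
constancy are both surfaced as parameters, since either convention is
defensible; the defaults are documented here and used everywhere.

## Synthetic data

The sequence generator evolves a uniform-random root sequence down a fixed
four-tip species tree — carteri vs (ivonicus, yuna) splitting at t₁ = 10 Ma,
ivonicus vs yuna at t₂ = 2.6 Ma, outgroup at 25 Ma — at r = 0.0083
subs/site/Myr over 435 sites, the dimensions of the filtered 16S matrix this
workflow targets. t₂ = 2.6 Ma is back-computed from the observed ~4.3%
ivonicus–yuna divergence via t = d/(2r); the 25 Ma outgroup age is arbitrary
but keeps the deepest path below 16S saturation at the default rate.
Within-lineage variation is modelled as star-shaped terminal branches: each
lineage's samples radiate from a lineage ancestor 1 Ma deep (giving intra
p-distances of roughly 0–4%, matching the shallow within-lineage variation
such datasets show), so cross-lineage sample pairs coalesce exactly at the
split ages and the dating stage has a well-defined truth. Substitutions are
per-site Poisson counts per branch with multiple-hit overwriting, so observed
p saturates exactly as the JC expectation
`E[p] = (3/4)(1 − e^(−8rt/3))` predicts; the truth record stores these
per-pair expectations for use as oracles. A K2P mode adds a
transition/transversion bias κ. No indels, no rate heterogeneity across
sites, no relaxed clock, no within-lineage coalescent genealogy: passing
tests therefore demonstrate correctness of the estimators under the model's
own assumptions, not robustness to alignment error or rate variation in real
16S data. The column-filter path is exercised with handcrafted gapped
fixtures instead.

The morphology generator draws, per clade, 80 specimens over 8 lots
(round-robin), reserving one lot per clade as hold-out; 15% of specimens are
juveniles and about half of the non-hold-out adults are flagged molecular
vouchers, giving initial-screen pools of ~30 per clade — sized like the large
museum series such revisions rest on, so that a character with true constancy
0.95 is almost always carried into validation, while the downstream block and
hold-out stages do the discriminating. Character kinds: *diagnostic*
(clade-specific modal state drawn with probability c), *overlapping*
(identical distribution in both clades — the null), *ontogenetic*
(diagnostic in adults, juveniles flipped toward the opposite clade's state
with probability 0.8, emulating characters that only work in adults).

## Numerical and degenerate-case choices

- UPGMA ties are broken by the lexicographically smallest member-id pair and
  node height is half the joining distance, making trees deterministic and
  leaf-to-leaf path lengths equal to matrix distances; scipy's average
  linkage is the independent reference in tests.
- Filtering that removes every column raises; an empty alignment is never
  returned. Zero comparable columns for a pair under pairwise deletion raises
  naming the pair.
- The bootstrap interval is clamped to contain the full-data point estimate
  (relevant only in pathological short-alignment cases).
- The relative-rate test with zero informative sites is reported as
  undefined, not as p = 1.
- All percentile intervals use the 2.5/97.5 convention; all RNG is
  `numpy.random.default_rng` seeded explicitly, and every CLI output embeds
  its seeds and a config hash.

## Problem sizes

The default test and acceptance runs use the study-scale conditions: 435
sites, 4 sequences per ingroup lineage, 1000 bootstrap replicates; replicated
experiments use 30 datasets (dating means), 100 (interval coverage,
screen operating characteristics) or 200 (clock recovery, screen acceptance
checks), and 500 (relative-rate null calibration). These sizes give Monte
Carlo standard errors comfortably inside the asserted bands.

## Known limitations

- Single locus, strict clock, point calibration: the dating interval
  understates total uncertainty by construction.
- The UPGMA fallback assumes clock-like distances; for non-ultrametric data
  use the supervised path.
- The screen treats specimens as exchangeable within clade; lot-level
  correlation (shared preservation, collector, ontogeny) is only addressed by
  the hold-out stage, not modelled.
- The simulator's uniform base frequencies and site-homogeneous rates are
  idealisations of real 16S evolution.
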