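# caridelim

Integrative lineage delimitation for cryptic freshwater shrimp, built around
the mitochondrial 16S rRNA fragment. The motivating problem: Amazonian
palaemonid shrimp of the *Palaemon carteri* complex look nearly identical but
fall into two deeply divergent molecular lineages — "carteri" and
"ivonicus/yuna" — whose status as species needs corroboration from sequence
divergence, divergence time and diagnostic morphology together. `caridelim`
packages that whole workflow as a tested library, a CLI and a set of
reproducible analysis scripts, with a synthetic-data generator so everything
runs offline.

Audience: systematists and molecular ecologists doing DNA-barcoding-style
species delimitation on small single-locus datasets, who want the arithmetic
(distances, site counts, clock dating, character screening) to be explicit,
auditable and reproducible.

## What it computes

- **Site-pattern statistics.** After complete-deletion filtering of
  gap/missing/ambiguous columns, each column is classified as constant,
  singleton-variable or parsimony-informative (≥ 2 states each in ≥ 2
  sequences).
- **Divergences.** Uncorrected p-distance `p = mismatches / sites` under
  complete or pairwise deletion, with Jukes–Cantor
  `d = −(3/4)·ln(1 − 4p/3)` and Kimura two-parameter
  `d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q)` corrections
  (P, Q = transition, transversion proportions).
- **Lineage summaries.** Given a partition of sequences into lineages
  (metadata labels, or an UPGMA tree cut as an unsupervised fallback), the
  min/mean/max of intra- and inter-lineage distances — the barcode-gap table.
- **Strict-clock dating.** With a per-lineage rate *r* (substitutions/site/Myr),
  two lineages split *t* Ma ago accumulate corrected divergence `d = 2rt`, so
  `t̂ = d/(2r)`. The default rate 0.0083 subs/site/Myr is the neotropical
  palaemonid 16S rate anchored on a 3 Ma transisthmian sister-species split.
  Uncertainty comes from a site bootstrap (resampling alignment columns), and
  a Tajima relative-rate test sanity-checks the clock assumption.
- **Diagnostic-character screening.** The block-wise "optimized comparison"
  screen for categorical morphology: candidate characters must separate the
  clades with strictly more than 80% constancy on the molecular-voucher
  specimens, then survive cumulative re-evaluation in shuffled blocks of 10
  specimens per clade, and finally hold up on hold-out lots never used in the
  molecular work. Every decision is logged in an audit trace.
- **Synthetic data.** A strict-clock sequence simulator (per-site Poisson
  substitutions with multiple-hit overwriting on a three-lineage-plus-outgroup
  tree) and a morphology generator with controllable per-character constancy,
  ontogenetic noise and lot structure.

## Worked example

```bash
python analysis/01_simulate.py --seed 1     # synthetic study dataset
python analysis/02_align_stats.py
python analysis/03_distances.py
python analysis/04_dating.py
python analysis/05_morphoscreen.py
```

prints (seed 1):

```
435 input columns, 0 excluded -> 435 aligned positions; 186 variable, of which 75 (40%) parsimony-informative
lineage divergence summary (p-distance, %):
  intra carteri: 1.6-2.5 (mean 2.1)
  intra ivonicus_yuna: 0.9-3.9 (mean 2.6)
  inter carteri vs ivonicus_yuna: 15.9-17.7 (mean 16.8)
JC: divergence carteri vs ivonicus_yuna = 11.5 Ma (site-bootstrap 95% 9.1-14.0 Ma)
clock (Tajima relative-rate, carteri_1 vs ivonicus_1): not rejected (P = 0.18)
3 diagnostic character(s) confirmed for carteri vs ivonicus_yuna
```

Reading: within-lineage 16S variation is shallow (< 4%), the two focal
lineages are separated by a wide gap (~16% for this random replicate), and at
0.0083 subs/site/Myr that gap corresponds to a split roughly 10 Ma ago (the
site-bootstrap interval quantifies site-sampling noise around the estimate
for one simulated dataset; the generating truth is 10 Ma). Three of the four
simulated morphological characters carry true diagnostic signal and all three
survive the 80%/block-10 screen; the distribution-identical character is
rejected.

The same stages are exposed as a CLI (`caridelim simulate|align-stats|
distances|lineages|date|screen|run-all`); `run-all` chains them from one YAML
config and writes a manifest (input hashes, seeds, config hash) in every
output directory, so reruns are byte-identical.

To analyse real data instead, give `align-stats`/`distances`/`lineages`/`date`
a pre-aligned FASTA plus a metadata table with lineage labels — alignment
itself is an upstream step (the original 16S set was aligned with MAFFT
defaults; `scripts/fetch_accessions.py` documents the one-time GenBank
download and alignment for users with network access).

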