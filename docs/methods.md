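# Methods

## Study design emulated by the simulators

The expression generator reproduces the sampling layout of a diel
entrainment experiment in filamentous cyanobacteria: 12 time points in
triplicate on a 12 h light / 12 h dark cycle. Eight "core" time points form
two complete entrainment cycles (MidDark1/2, Pre-Dawn1/2, MidLight1/2,
Pre-Dusk1/2); Pre-Dawn0 and Pre-Dusk0 precede entrainment; Light24 and
Dark24 are 24-h constant-light/-dark perturbations. Phases: day =
Pre-Dusk, MidLight, Light24; night = Pre-Dawn, MidDark, Dark24.

### Expression model

Per-gene baselines are log-normal, `b_i ~ LogNormal(ln 3000, 1)`. The
location matches the deposited study's sequencing depth (~20M mapped reads
over a ~6,700-gene genome, i.e. on the order of 3,000 reads per gene); the
scale of 1 natural-log unit gives the 1–2 orders of magnitude of
between-gene spread typical of bacterial RNA-seq. Counts are negative
binomial with mean `mu` and variance `mu + alpha*mu^2`; the default
dispersion `alpha = 0.1` (CV ~ 0.32 at high expression) is typical of
biological replicates.

Signal classes, all multiplicative on the baseline:

* `light_pref` / `dark_pref` genes: mean multiplied by `2^effect_log2`
  (default 1, i.e. two-fold) in samples of the preferred phase. Defaults
  plant 300 + 300 of 3,000 genes.
* co-expression blocks: `mu_it = b_i * exp(loading * f(t))` for a shared
  latent profile `f`. The three smooth default blocks use +/-1 profiles at
  loading 0.7; for a +/-1 profile the expected within-module Pearson
  correlation is `sinh^2(l) / (sinh^2(l) + cosh(2l)*cv^2)`, which is ~0.7
  at `l = 0.7` and `cv^2 ~ 0.1` — the regime in which module detection is
  non-trivial but feasible. The fourth ("prophage-like") block spikes only
  at MidDark2 with loading 2 (e^2 ~ 7.4-fold), mimicking a prophage
  induction event.
* remaining genes are flat (`null`).

Replicates are i.i.d. draws: the real experiment amplified libraries with
10 vs 14 PCR cycles across replicates, a potential batch effect that is
deliberately not modelled (no batch term exists in the analysis either).
What passing recovery tests show is therefore sensitivity/FDR under clean
replicate noise; they say nothing about batch confounding, library-size
artefacts beyond a global scale factor, or rhythmic (harmonic) signal
shapes, none of which the generator produces.

### DGR pileup model

A template repeat (TR, default 120 nt with 30 adenines) is copied at one
or more variable-repeat (VR) offsets. At TR-adenine-aligned VR positions
the population carries one alternate base at frequency `mu_A` (default
0.05; optionally Beta-distributed per site); every position additionally
receives uniform sequencing error (`error_rate = 0.002` split over the
three non-template bases, the right order for Illumina after filtering).
Per-position depth is Poisson (default mean 100). The simulator emits
base-count pileups directly — read-level FASTQ simulation and alignment
are out of scope, so alignment artefacts (mapping bias, indel noise) are
not represented.

## Preprocessing

Upper-quartile normalization computes `UQ_s` as the 75th percentile
(linear interpolation) of each sample's **nonzero** values and rescales by
`m / UQ_s` with `m` the mean UQ across samples. This convention is
idempotent and scale-equivariant: rescaling one library changes all
normalized values by a single common factor only, and per-gene z-scores
are unaffected. The low-expression filter keeps a gene when at least one
time point's replicate-averaged expression is >= 10 (the boundary is
inclusive: "below 10 in all time points" is removed). It is applied after
normalization by default. Z-scores use the n−1 standard deviation;
constant genes map to all-zero rows.

## Diel statistics

The four-state ANOVA treats every core-cycle sample as an independent
observation (2 time points x 3 replicates = 6 per state; a
`collapse_replicates` flag averages replicates first, n = 2 per state).
p-values come from F(3, n−4); genes with zero total variance get F = 0,
p = 1. The orchestrating stage (`diel_gene_table`) runs the ANOVA on
`log2(normalized + 1)`: negative-binomial counts are strongly
heteroscedastic (variance grows with the squared mean, so for a planted
gene the preferred-phase groups carry four times the variance of the
other groups), and the log transform restores the roughly constant
per-observation variance the F test assumes — the standard practice
before linear modelling of RNA-seq counts. `log_scale=False` restores
raw-scale testing; `anova_four_state` itself never transforms. Reported
group means stay on the normalized-count scale.

BH adjustment is the exact step-up `q(i) = min_{j>=i} m*p(j)/j`, capped at
1, returned in input order; it is implemented directly (a few lines) so
its output is bit-identical to the canonical formula, and cross-checked
against `statsmodels` in the test suite.

Significant genes (q < 0.05) are clustered by complete-linkage Euclidean
distance on core-sample z-scores and cut into two clusters; a cluster is
"day" when its mean z over light samples exceeds its mean over dark
samples. If both clusters lean the same way the stronger lean keeps its
label and the other is flipped (with a warning), so both labels are always
used. Fold changes use pseudocount 1 (none is standard; 1 keeps zeros
finite without distorting counts at the depths simulated).

Consensus day/night sets union the ANOVA sets with genes of modules
assigned to light/dark time points; a gene claimed by both sides goes to
the side with the larger |mean z difference| and is reported.

## Co-expression networks

The network is unsigned, `a = |r|^beta` (a `signed` flag switches to
`((1+r)/2)^beta`). The soft power is the smallest candidate whose
connectivity distribution fits a scale-free law (R² >= 0.8 with negative
slope over 10 log-binned connectivity bins); when no candidate qualifies
— common for small synthetic designs — the WGCNA-conventional default
beta = 6 is used with a warning.

Topological overlap uses `TOM_ij = (l_ij + a_ij)/(min(k_i,k_j)+1−a_ij)`
with `l_ij = Σ_{u≠i,j} a_iu a_uj`, diagonal 1. Modules come from
average-linkage clustering of `1 − TOM` with a **static** height cut —
deterministic and fully specifiable, unlike dynamic tree cutting. The
default cut height is 0.97: TOM dissimilarities concentrate near 1 even
for strongly co-expressed genes (with within-module r ~ 0.7 and beta = 6,
within-module TOM is ~0.1–0.2, i.e. dissimilarity ~0.85, while unrelated
pairs sit at ~1.0), so the informative merge range lives just below 1 and
static cuts in WGCNA practice are likewise placed near the top of the
tree. Cutting at, say, 0.8 would leave every gene a singleton. Clusters
smaller than `min_size = 20` are unassigned; labels M1, M2, … follow
decreasing size for determinism.

Module eigengenes are the first right singular vector of the
row-centered module submatrix (unit norm), sign-aligned with the module
mean profile; variance explained is the leading squared singular value
fraction. Modules are assigned to the time point whose one-hot indicator
correlates most positively with the eigengene at p < 0.05, else left
unassigned.

MCC enumerates all maximal cliques of the thresholded graph (|value| >=
0.75 by default, mirroring the r >= 0.75 association convention) with
Bron–Kerbosch pivoting and scores `MCC(v) = Σ (|C|−1)!`. Isolated
vertices score 0; ties in the top-n ranking break by node id. A 2,000-node
guard refuses graphs where clique enumeration could blow up.

## Enrichment

Over-representation uses the exact upper-tail hypergeometric probability,
computed with integer arithmetic (`math.comb`), so small-universe values
are exact to the last bit. The universe is the set of genes passing the
expression filter. Sets are intersected with the universe; zero-overlap
sets are reported but untested. Tiers (≤0.001, ≤0.01, ≤0.05, ≤0.1, ns)
are assigned from the raw p-value; BH q across tested sets is reported
alongside, since whether the original analysis corrected across pathways
is unknown.

## DGR diversity

Per-site π uses the unbiased pairwise estimator
`π = Σ_{b<b'} n_b n_{b'} / C(n,2)` over A/C/G/T counts only (indels and
ambiguous bases excluded); sites with usable depth < `min_depth` (default
10) or n < 2 are masked. Adenine flags come from the TR sense strand
through the (optionally gapped) TR→VR alignment map; unmapped TR adenines
are excluded and counted. The adenine contrast is
`delta = mean(π | adenine) − mean(π | other)` with a permutation null
(shuffle flags over unmasked sites, default 10,000 permutations,
`perm_p = (1 + #{delta* ≥ delta})/(1 + n_perm)` — never exactly zero).
Coordinates are 0-based half-open throughout; pileup counts are
reference-forward.

## Pipeline and reproducibility

`run_pipeline` wires simulate → preprocess → diel statistics → network →
enrichment → DGR diversity, writing TSV/GMT/FASTA/BED outputs plus a JSON
manifest of SHA-256 checksums. Every stochastic stage derives its seed
from the single global seed keyed by the stage name (SHA-256 of the name
into a `SeedSequence` spawn key), so identical configuration + seed gives
byte-identical outputs and stages cannot silently perturb one another's
streams. The manifest deliberately carries no timestamps, so two
identical runs produce identical manifest bytes. The default end-to-end
simulation size is 600 genes — large enough for every stage (including
module detection and enrichment) to engage, small enough to run in
seconds.

## Numerical conventions

* Percentiles: linear interpolation between order statistics.
* Standard deviations: n−1 everywhere.
* Hierarchical clustering: SciPy's complete/average linkage; tie handling
  follows SciPy's deterministic nearest-neighbor-chain order.
* Constant genes: z-score rows of zeros, correlations set to 0 with a
  warning, F = 0 / p = 1.
* Permutation p-values use the +1 convention and are reproducible given
  the seed.

## Problem sizes used by the test suite and acceptance script

Exactness checks: 1,000 random p-vectors (BH), 50 random G(30, 0.2)
graphs (MCC), five 50-node networks (TOM), all hypergeometric tails for
N ≤ 12, 200 random count vectors (π). Simulation measurements: the
default 3,000-gene design for diel recovery; fifty 300-gene runs (four
50-gene modules + 100 null genes) for module recovery; 100 runs for DGR
power and 1,000 for null calibration (499–999 permutations each); a
600-gene end-to-end determinism run. These sizes keep the full suite and
the acceptance script at desk scale while leaving each measurement's
Monte Carlo error well inside its acceptance margin.

## Known limitations

* No batch, library-preparation, or rhythmic-waveform effects in the
  generator; recovery results bound performance only under its noise
  model.
* Static tree cutting can split large loose modules that dynamic cutting
  would keep together; cut height and minimum size are exposed.
* The scale-free fit rarely selects a power on small synthetic designs
  (the fallback beta = 6 is used); the scale-free fit is more meaningful at
  genome scale.
* MCC is exponential in the worst case; the node guard refuses graphs
  above 2,000 nodes rather than approximating.
* π at the error floor: with sequencing error e, monomorphic sites sit at
  π ≈ 2e rather than 0; the adenine contrast is a *relative* test and is
  calibrated under this floor, but absolute π values near 2e should not be
  read as biological diversity.
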