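# dielomics

Diel (24-h light/dark) transcriptome analysis for filamentous cyanobacteria,
built around the study design used for *Nostoc punctiforme*: 12 time points
sampled in triplicate across a 12 h light / 12 h dark regime — two core
entrainment cycles (MidDark, Pre-Dawn, MidLight, Pre-Dusk, each observed
twice), two early time points, and 24-h constant-light / constant-dark
perturbations.

The package is for computational biologists who want a tested, reproducible
re-implementation of that analysis stack, runnable end to end on synthetic
data with known ground truth:

1. **Preprocessing** — upper-quartile normalization (`f_s = m / UQ_s`, with
   `UQ_s` the 75th percentile of a sample's nonzero counts and `m` the mean
   UQ across samples), removal of genes with mean expression < 10 in every
   time point, per-gene z-scoring, and Spearman sample-correlation QC.
2. **Diel-variable expression** — per-gene one-way ANOVA of the four diel
   states (MidDark, Pre-Dawn, MidLight, Pre-Dusk) over the core cycles on
   log2(normalized + 1) values, Benjamini–Hochberg correction
   (`q(i) = min_{j≥i} m·p(j)/j`), partition of significant genes into
   "day" and "night" sets by complete-linkage Euclidean clustering of their
   z-scores, and per-contrast log2 fold changes
   `log2((x̄_A + 1)/(x̄_B + 1))`.
3. **Co-expression networks** — WGCNA-style unsigned adjacency
   `a_ij = |r_ij|^β` with β chosen by scale-free topology fit, topological
   overlap `TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, module
   detection by average-linkage clustering of `1 − TOM`, module eigengenes
   (first principal component across samples), module→time-point assignment
   by indicator correlation, and hub ranking by **maximal clique
   centrality**, `MCC(v) = Σ_{cliques C ∋ v} (|C|−1)!`, from an exact
   Bron–Kerbosch enumeration.
4. **Pathway over-representation** — exact upper-tail hypergeometric
   p-values `P(X ≥ k)` for day/night gene sets against a GMT collection,
   with the significance tiers ≤0.001 / ≤0.01 / ≤0.05 / ≤0.1.
5. **DGR adenine hypermutation** — for a diversity-generating retroelement,
   maps template-repeat (TR) adenines onto variable-repeat (VR) coordinates,
   computes per-site nucleotide diversity
   `π = Σ_{b<b'} n_b n_{b'} / C(n,2)` from a base-count pileup, and tests
   adenine-vs-other diversity enrichment with a label-permutation test.
6. **Synthetic data** — generators for diel count matrices (negative
   binomial over log-normal baselines, planted light/dark-preferential
   genes, co-expressed blocks including a dark-spiking prophage-like
   module) and DGR pileups (adenine-restricted alternate alleles plus
   sequencing error), each emitting ground truth for recovery testing.

## Worked example

```python
import dielomics as d

# simulate a 1,000-gene diel experiment (12 time points x 3 replicates)
X, truth = d.simulate_diel_counts(d.SimExprConfig(n_genes=1000, seed=42))

# normalize -> filter -> diel statistics
filt = d.filter_low_expression(d.upper_quartile_normalize(X))
table, dend = d.diel_gene_table(filt.matrix, alpha=0.05)
print((table.q < 0.05).sum(), (table.label == "day").sum(),
      (table.label == "night").sum())
# 337 155 182

# co-expression modules and their time points
Z = d.zscore_by_gene(filt.matrix)
C = d.pearson_matrix(Z)
tom = d.tom_from_adjacency(d.adjacency_from_correlation(C, 6))
ms = d.build_modules(Z, tom)
print(ms.tp_assignment.dropna().to_dict())
# {'M1': 'Light24', 'M2': 'MidDark2', 'M3': 'MidDark1', 'M4': 'Pre-Dawn2'}
```

337 of 1,000 genes vary significantly across the four diel states at
q < 0.05; the day/night partition splits them 155/182, and the planted
dark-spiking block is recovered as module M2 assigned to MidDark2 — the
behaviour expected of a prophage induction event. For the DGR stage:

```python
cfg = d.DgrSimConfig(tr_sequence=d.random_tr_sequence(120, 30, seed=42), seed=42)
locus, pileup, _ = d.simulate_dgr_pileup(cfg)
tr = d.pi_profile(pileup, locus.tr_interval, locus, region_name="TR")
vr = locus.vr_regions[0]
vrp = d.pi_profile(pileup, (vr.start, vr.end), locus, vr_name=vr.name)
print(d.compare_vr_tr(tr, [vrp], n_perm=10000, seed=0).round(5))
```

```
region  mean_pi  mean_pi_adenine  mean_pi_other  adenine_delta  adenine_perm_p
    TR  0.00294          0.00462        0.00238        0.00224         0.11059
   VR1  0.02756          0.09983        0.00347        0.09636         0.00010
```

The variable repeat shows elevated diversity confined to adenine-aligned
sites (mean π 0.0998 vs 0.0035 elsewhere; permutation p = 1e-4), while the
template repeat sits at the sequencing-error floor — the signature of
adenine-restricted DGR hypermutation.

A command-line umbrella mirrors the library:
`dielomics simulate-expression | simulate-dgr | preprocess | diel-test |
network | enrich | dgr-pi | run`.

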