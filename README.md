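# sclcnet

Analysis pipeline for paired blood-transcriptome studies of chemotherapy
resistance in small-cell lung cancer (SCLC), and for any similarly shaped
two-timepoint, two-group expression cohort.  It is aimed at
computational-biology practitioners who have a log2 expression matrix
(genes × samples), per-sample clinical annotations (patient, pre/post
treatment timepoint, primary vs acquired resistance, progression time), and
gene-set files — and who want the complete chain from normalization to hub
genes and survival association as reproducible, scriptable stages rather
than a collection of one-off notebooks.

## What it computes

* **Quantile normalization** — every sample mapped onto the common
  reference distribution (row means of column-sorted values), ties
  averaged.
* **Differential expression** — paired one-sample t on within-patient
  (post − pre) log2 differences, or pooled two-sample t between resistance
  groups at one timepoint; per-gene variances shrunk by an empirical-Bayes
  scaled-F prior (posterior s̃² = (d₀s₀² + d·s²)/(d₀+d), t on d+d₀ df,
  validated against the limma reference); a gene is a DEG when BH-adjusted
  p ≤ 0.05 and |log2FC| > 0.3.
* **Single-sample signature scores** — the rank-weighted running-sum
  statistic of ssGSEA (in-set weight (N−i+1)^α, α = 0.25) over
  user-supplied GMT signatures, with immune/stromal/microenvironment
  composites and exact-or-asymptotic rank tests between sample arms.
* **Co-expression network and hubs** — soft-thresholded Pearson adjacency
  |r|^β (β = 6) over a gene panel, edges filtered at weight > 0.01 then per
  gene to its top 30% (union semantics), minimum spanning forest under
  distance 1 − weight, hub = tree degree > 4.
* **Outcome association** — median-split Kaplan–Meier curves with the
  two-group log-rank test (explicit observed/expected event counts) on
  progression or survival time, and pathway association by rank test or
  Pearson correlation against per-sample pathway scores.
* **Synthetic cohorts** — a generator planting DE genes, hub-centred star
  modules and hazard-linked outcomes in a 17-patient paired design, with a
  ground-truth record for recovery scoring.

## Worked example

Run the whole pipeline on a synthetic cohort (2000 genes, 34 samples,
two planted 9-leaf modules at ρ = 0.9 inside a 100-gene panel, planted
DEGs, survival effect 1.0 per SD of hub expression):

```sh
$ sclcnet run-all --out demo --seed 7
pipeline complete: 25 files in demo
```

The hub report (`demo/hubs_primary.tsv`) recovers exactly the two planted
module hubs — their spanning-tree degrees are the module sizes, every
other panel gene stays at tree degree ≤ 4:

```
gene_id  degree  is_hub
G0010    9       True
G0000    8       True
G0001    2       False
```

The paired pre/post DEG table (`demo/deg_paired_pre_post.tsv`, sorted by
adjusted p) calls 5 genes, all planted, led by:

```
gene_id    log2fc    t_stat     adj_p  is_deg
G0210    1.555696  4.547582  0.010853    True
G0207   -1.486645 -4.345734  0.013881    True
G0205   -1.355942 -3.963665  0.029523    True
```

and `demo/survival_logrank.tsv` shows the hazard-linked hub (G0000, the
gene whose expression drives the simulated progression hazard) splitting
the 17 patients into arms with clearly different progression:

```
gene_id  outcome      chi_square  p_value   n_high  n_low
G0010    progression    0.077372  0.780891  8       9
G0000    progression   14.798601  0.000120  8       9
```

G0010 carries no survival effect and behaves as a null, while G0000's
median split yields log-rank χ² ≈ 14.8 (p ≈ 1.2 × 10⁻⁴).  Re-running with
the same seed reproduces every file byte-for-byte.

The same stages run individually (`simulate`, `normalize`, `dge`,
`scores`, `network`, `hubs`, `gsva`, `survival`) on real files; see
`sclcnet --help`.

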