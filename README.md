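# coregnet

Discovery of function-enriched coregulation between transcription
factors (TFs) and miRNA families from two-layer regulator–target
networks.

The pipeline:

1. **Pairs** — collapse mature miRNAs into families, intersect target
   sets, and enumerate TF–TF, TF–miRNA and miRNA–miRNA coregulation
   pairs that share at least `--min-shared` targets.
2. **Enrichment** — fingerprint each pair's shared targets over the
   level-2 biological-process GO terms (direct children of the BP root),
   score the fingerprint with a multivariate-hypergeometric
   log-likelihood, and calibrate it against a permutation null of
   same-size gene sets drawn from the background universe
   (`--permutations`, default 10,000), with pooled FDR control at
   `--fdr` (default 0.05).
3. **Linkages & networks** — per enriched pair, Fisher's exact test per
   level-2 term with step-down Benjamini–Liu correction (BH available);
   passing (pair, term) linkages form regulator multigraphs whose
   parallel edges are GO terms, summarised by links-per-pair,
   edge-types-per-regulator and largest-component statistics.
4. **Motifs** — build the upstream regulator–regulator network (TF
   targeting, predicted TF→miRNA edges, host-gene propagation,
   miRNA-family targeting of TF genes) and test five motif patterns
   (bidirectional/unidirectional FFLs, common upstream TF, common
   upstream TF+miRNA, upstream crosstalk) against `--resamples`
   same-size background pair sets (significance at `--motif-alpha`,
   default 0.001).
5. **Expression** — Pearson correlation of each pair's regulators in
   normal vs tumour samples, foreground (enriched) vs background (all
   other same-kind pairs), compared by two-sample Kolmogorov–Smirnov.

Real database snapshots are not bundled; a synthetic-data generator
produces complete input bundles with known planted ground truth
(term-coherent pairs, upstream motifs, condition-specific correlations)
for testing and calibration. File formats are documented in
[FORMATS.md](FORMATS.md).

## CLI

```sh
# generate a synthetic bundle (defaults: 2,000 genes, 20 TFs,
# 20 families, 10 planted pairs; override via a YAML config)
coregnet simulate --out-dir bundle/ --seed 1

# full pipeline
coregnet run --bundle bundle/ --out-dir results/ \
    --permutations 10000 --fdr 0.05 --min-shared 3 --seed 1

# individual stages (each runs its prerequisites; outputs match `run`)
coregnet enrich --bundle bundle/ --out-dir results/ --seed 1
```

Outputs: `pairs.tsv`, `enrichment.tsv`, `linkages.tsv`,
`network.graphml`/`.sif`, `network_stats.json`, `motifs.tsv`,
`correlation_values.tsv`, `correlation_summary.tsv`, plus a
deterministic `manifest.json` (input digests, seeds, counts).

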