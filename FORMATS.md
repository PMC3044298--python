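# File formats

All tab-separated files are UTF-8 with LF line endings; blank lines and
lines starting with `#` are ignored; the first data line is a header.
Identifiers are opaque, case-sensitive strings.

## Inputs

### `tf_targets.tsv` — regulator → target edge list
| column | meaning |
|---|---|
| `regulator_id` | regulator identifier (e.g. TF symbol) |
| `regulator_kind` | `TF` or `MIRNA_FAMILY` (case-insensitive) |
| `target_gene` | target gene identifier |

Duplicate rows are collapsed silently (count logged).

### `mirna_targets.tsv` — mature-miRNA → target edge list
Columns `mature_mirna`, `target_gene`. Collapsed into families via the
family map before analysis.

### `family_map.tsv`
Columns `mature_mirna`, `family`. miRNA-precursor names used in the host
map may also appear in the first column so host-gene regulation can be
propagated to families. Mature miRNAs absent from this map become
singleton families under their own name.

### `host_map.tsv`
Columns `precursor`, `host_gene`: a miRNA precursor embedded in a
protein-coding host gene (assumed to share its transcription unit).

### `tf_mir_edges.tsv`
Columns `source`, `dest`: predicted TF → miRNA-family regulation edges.

### `ontology.obo`
OBO 1.2. Only the `biological_process` namespace is used; `is_a` and
`relationship: part_of` edges are kept (separately); obsolete terms are
dropped.

### `annotations.tsv` / GAF
Two-column TSV `gene<TAB>term`, or GAF 2.x (rows with a `NOT` qualifier
are skipped; evidence codes are accepted by default, with an optional
exclusion list).

### `expression_matrix.tsv`
Rows = entities, columns = sample ids; first column `entity_id`. Missing
values use the `NA` token (configurable). `sample_meta.tsv` has columns
`sample_id`, `tissue`, `condition` (`normal`/`tumor`). Optional
`entity_kinds.tsv` has columns `entity_id`, `kind`
(`mRNA`/`mature_miRNA`).

## Outputs

### `pairs.tsv`
`reg_a`, `reg_b`, `pair_kind` (`TF_TF`/`TF_MIR`/`MIR_MIR`), `n_shared`,
`shared_targets` (pipe-joined, sorted). `reg_a < reg_b` lexicographically.

### `enrichment.tsv`
`reg_a`, `reg_b`, `pair_kind`, `n_shared`, `loglik` (natural log, ≤ 0),
`p_perm`, `q`, `enriched`.

### `linkages.tsv`
`reg_a`, `reg_b`, `pair_kind`, `term`, `term_name`, `p_fisher`, `q`,
`passed`.

### `network.graphml` / `network.sif`
Coregulation multigraph. GraphML keeps parallel edges with a `go_term`
edge attribute and a `kind` node attribute; SIF uses the GO term id as
the interaction type. `network_stats.json` reports, per pair-kind view
and for the union: `n_nodes`, `n_edges`, `links_per_pair`,
`edge_types_per_regulator`, `largest_component` (NaN markers for empty
networks).

### `motifs.tsv`
`motif_id`, `pair_kind`, `observed`, `fraction`, `null_mean`, `null_sd`,
`p_emp`, `significant`.

### `correlation_values.tsv` / `correlation_summary.tsv`
Per-pair Pearson r values (`pair_kind`, `condition`, `group`, `r`) and
per-(kind, condition) summaries (`ks_stat`, `ks_p`, counts).

### `manifest.json` / `timings.json`
Deterministic run manifest (config snapshot without output path, input
SHA-256 digests, per-stage seeds, record counts, tool version, failed
stage marker). Wall-clock timings live in `timings.json` so manifests are
byte-identical across repeated runs.

### `truth.json` (synthetic bundles)
Planted ground truth: `planted_pairs` (regulator pair + planted GO term),
`planted_motifs`, `planted_correlations` (per-pair normal/tumour rho),
regulator rosters.
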