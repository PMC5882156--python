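# tfcensus

Comparative analysis of DNA-binding transcription factors (TFs) in
prokaryotic genomes, built as a tested pipeline over per-genome
structural-domain assignment tables. It computes:

- **Family census** — abundance of 19 TF families per genome, z-normalized
  abundance profiles, Pearson correlation with genome size (in ORFs) and
  strong / intermediate / low correlation classes, percentage shares and the
  four published abundance groups.
- **Lifestyle stratification** — per-genome TF proportions by lifestyle
  (free-living, pathogen, extremophile, intracellular), the Kruskal–Wallis
  comparison, family-per-lifestyle occurrence rates and their UPGMA
  clustering (Manhattan distance, Newick dendrogram output).
- **Domain-architecture promiscuity** — companion-domain (CD) repertoires,
  the weighted architecture score WS = IAF × IV per family per genome,
  Sturges genome-size windows, coefficient-of-variation promiscuity classes
  and the directed CD-sharing matrix.
- **Enrichment** — one-tailed Fisher's exact test of DBD–CD association with
  Benjamini–Hochberg correction (enriched at adjusted p ≤ 1e-10 by default)
  and per-family unique-CD flags.
- **Synthetic data** — a deterministic generator that plants abundance–size
  correlations, lifestyle effects, CD-usage skew and explicit DBD–CD
  enrichments, with a machine-readable truth ledger, so the whole pipeline is
  testable without any downloads.

## Input formats

One tab-separated assignment file per genome, columns:
`genome_id  protein_id  model_id  position  e_value  model_description
family_e_value  family_id  coverage  pdb_ref`, with `position` as
`start-end` (1-based inclusive) and `NA` for missing optional fields.
Alongside the assignment files (either in the input directory or an
`assignments/` subdirectory) the pipeline expects `metadata.tsv`
(`genome_id  organism  n_orfs  lifestyle`) and `catalog.tsv`
(`family  model_id`, mapping each family to its DBD model identifiers).

Filtering follows the source protocol: family (DBD) hits are kept at family
E-value ≤ 1e-4 with ≥ 60% model coverage (skipped with a warning when the
table carries no coverage column), other structural-domain hits at
E-value ≤ 1e-3. Overlapping hits on a protein are resolved best-E-value
first when they overlap by more than half of the shorter hit.

## CLI

```sh
# generate a synthetic dataset (writes assignments/, metadata.tsv,
# catalog.tsv and the truth ledger truth.tsv)
tfcensus generate --config examples/generate.yaml --out data/

# sanity-check inputs without running anything
tfcensus validate --input-dir data/

# run every stage and write all tables + manifest.json
tfcensus all --input-dir data/ --out results/ [--figures]
```

`tfcensus abundance|lifestyle|promiscuity|enrich|report` run the same
pipeline and print the path of the corresponding output table. Key outputs
under `--out`: `family_report.tsv` (consolidated per-family summary:
totals, shares, per-genome means, distinct/enriched CD counts, Pearson R,
abundance group, CV and promiscuity class), `abundance_matrix.tsv`,
`ws_scores.tsv` (long) and `ws_scores_wide.tsv` (one WS column per family),
`enrichment.tsv`, `sharing_matrix.tsv`, `family_dendrogram.nwk` and
`manifest.json`. Every TSV carries a `#` header with the config hash;
reruns with the same configuration are byte-identical.

A generator configuration is plain YAML, e.g.

```yaml
n_genomes: 50
seed: 7
orf_range: [800, 6000]
default_family: {base_rate: 4.0, size_slope: 0.8}
families:
  LysR: {cd_pool_size: 12}
  Fur: {cd_concentration: 3.0, p_monodomain: 0.8}
planted_enrichments: [[LysR, CD0001]]
```

Omitting `families` uses the 19 canonical families with rates scaled from
the published census.

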