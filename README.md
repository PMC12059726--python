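# netgex

Connectome–transcriptome association analysis as a tested, reusable pipeline:

1. **synthdata** — fully seeded generators for atlas metadata, a two-group
   multi-site cohort of regional time series with planted between-network FC
   effects and site effects, multi-donor microarray-style tissue samples with
   spatially autocorrelated expression and planted target-coupled genes, and
   GMT gene-set collections with planted/decoy terms.
2. **connectome** — Fisher-z FC matrices, empirical-Bayes ComBat site
   harmonization with protected covariates, 7×7 network aggregation
   (SMN, VAN, VN, DAN, DMN, FPN, SC).
3. **expression** — microarray processing into a left-hemisphere
   region×gene matrix: intensity-based probe filtering (≥50% above
   background), one probe per gene by reference correlation, sample-to-region
   assignment within 10 mm, scaled-robust-sigmoid normalization within donor
   and structure class, within-region then cross-donor averaging.
4. **groupdiff** — inclusion filtering (FD > 0.2 mm, HAMD ≤ 7, quality < 4,
   missing scores), HAMA > 18 grouping, edge/network GLM contrasts with
   covariates, NBS correction via Freedman–Lane permutation of the maximum
   suprathreshold component size, per-region net t-values (row sums of the
   edge t matrix), propensity-score matching, and paired sign-flip NBS
   validation.
5. **plsassoc** — SIMPLS partial least squares of the net t-value map on
   regional gene expression, component selection by response variance,
   variogram-matched spatial surrogate permutation significance, bootstrap
   z-scored gene weights, |z| > 3 gene selection.
6. **enrich** — hypergeometric over-representation on GMT collections with
   BH-FDR.

## CLI

Every stage is a subcommand reading/writing plain-text artifacts in a run
directory, so any stage can be re-run or replaced with externally produced
inputs in the same layout:

```bash
netgex run-all --out runs/demo                 # defaults
netgex run-all --config cfg.yaml --seed 7 --out runs/demo
netgex net-t --config cfg.yaml --out runs/demo # re-run one stage
netgex validate-config --config cfg.yaml
```

Artifacts: `atlas.tsv`, `cohort.tsv` + per-subject `ts_*.tsv`, per-subject
`fc_*.tsv` / harmonized `fch_*.tsv`, `edge_t.tsv`/`edge_p.tsv`, `nbs.json`,
`network_t.tsv`/`network_p.tsv`, `net_t.tsv`, donor tables + `expression.tsv`,
`pls_summary.json`, `gene_weights.tsv`, `genes_pos.txt`/`genes_neg.txt`,
`gene_sets.gmt`, `enrichment.tsv`, and a `manifest.json` with the config
hash and seeds. Runs are byte-identical under fixed seeds.

Configuration is a single YAML file mirroring `netgex.config.PipelineConfig`;
all thresholds default to the study values (HAMA cut 18, FD 0.2 mm, edge
p 0.001, component α 0.05, 1000 permutations, 10 mm assignment distance,
|z| > 3, FDR 0.05).

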