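# assemblage

Community-assembly analysis for taxa-by-sample count tables (OTU tables):

- **Guild classification** — Levins niche breadth per OTU with a seeded
  permutation null; OTUs strictly above / below the 95% null band are
  generalists / specialists.
- **Neutral community model** — occurrence frequency vs. regional relative
  abundance under drift + immigration; fits `Nm`, derives a migration rate
  `m`, reports `R²` and Wilson 95% prediction bands, overall and per
  (group, guild) stratum.
- **Normalized stochasticity ratio (NST)** — observed pairwise dissimilarity
  (Ruzicka by default) against a richness-preserving null; values above 0.5
  read as stochastic-process dominance.
- **Co-occurrence networks** — Spearman correlations on the top-N most
  abundant taxa with BH-adjusted significance; average degree, density,
  mean shortest path, greedy modularity, positive-edge and
  generalist/specialist edge-type proportions.
- **Diversity** — Shannon (nats), Bray–Curtis PCoA, permutation ANOSIM.
- **Synthetic data** — seeded generators with planted ground truth: Moran
  neutral dynamics with known immigration rate, Gaussian niche filtering
  with planted wide/narrow-niche taxa, convex process mixing, and copula
  correlation injection. Every downstream stage is validated against these
  generators.

## CLI

The `assemblage` entry point exposes the full pipeline and each stage:

```sh
# full pipeline from one config (YAML or JSON)
assemblage run --config config.yaml

# stage-wise
assemblage simulate --config sim.yaml --seed 1 \
    --out-table t.tsv --out-metadata m.tsv --out-truth truth.json
assemblage classify-guilds --table t.tsv --metadata m.tsv \
    --perms 1000 --seed 1 --scheme taxon_shuffle --out guilds.tsv
assemblage ncm --table t.tsv --metadata m.tsv --out ncm.json
assemblage nst --table t.tsv --metadata m.tsv --metric ruzicka \
    --null proportional_fix --reps 1000 --seed 1 --out nst.json
assemblage network --table t.tsv --metadata m.tsv --top 300 --r 0.6 \
    --out-prefix net
assemblage diversity --table t.tsv --metadata m.tsv --seed 1 --out-prefix div
```

Example pipeline config:

```yaml
seed: 1
output_dir: out/
table_path: table.tsv        # or a `simulate:` block instead
metadata_path: metadata.tsv
niche: {n_perm: 1000, scheme: taxon_shuffle}
nst: {metric: ruzicka, null_algorithm: proportional_fix, n_reps: 1000}
network: {n_top: 300, r_threshold: 0.6, p_threshold: 0.05, scope_n: 100}
diversity: {n_perm: 999}
```

Input format: tab-separated count table (rows = OTUs, header = sample ids,
first column = OTU ids) plus a metadata TSV with columns
`sample_id` and `group`. All outputs are TSV/JSON (networks additionally as
GraphML).

## Notes on defaults

- Niche-breadth `P_ij` uses per-sample relative abundances normalized within
  each OTU. The default null (`taxon_shuffle`) permutes profile-to-taxon
  assignment and is a relative test against the community's breadth
  distribution; `row_shuffle` and `column_label_permute` are available as
  low-power sensitivity controls.
- NCM detection limit defaults to one read in an average library; the
  community size used for `m = Nm / N` defaults to the mean library size.
  Both are overridable (`--detection-limit`, `--community-size`).
- NST is taxonomic (no phylogeny): Ruzicka / Bray–Curtis / binary Jaccard.
- Network thresholds (|ρ| ≥ 0.6, BH-adjusted p < 0.05, prevalence ≥ 20%)
  follow common microbiome practice and are CLI-overridable.
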