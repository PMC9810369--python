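# hypercon

Functional-connectivity graph construction, hyperbolic disc embedding, and
edge-level anomaly detection against control cohorts — with a synthetic-data
generator that emulates the statistical structure of the inputs.

The pipeline:

1. **connectivity** — Pearson correlation matrices from node × timepoint
   series; binary graphs by absolute-value thresholding; threshold selection
   by scanning a grid (default 0.15–0.65, step 0.01) for windows where the
   largest connected component keeps ≥ 95% of nodes *and* the degree
   distribution passes a maximum-likelihood power-law fit with bootstrap
   goodness of fit; a group threshold that satisfies the most subjects.
2. **manifold_bench** — Riemannian (S)GD embedding of binary graphs into
   constant-curvature spaces (Euclidean, unit sphere, unit hyperboloid, any
   dimension) under a scaled-distortion loss; fidelity scored by average
   distortion and mean average precision (mAP).
3. **s1h2_embed** (`hypercon.s1h2`) — maximum-likelihood embedding onto the
   hyperbolic disc of the circle (S1) geometric model: clustering-matched
   inverse temperature, mean-field hidden degrees, spectral-initialized
   angular coordinates refined by per-node likelihood sweeps, and the
   change of variables to disc polar coordinates.
4. **anomaly_detect** — reproducibility via the coefficient of variation of
   the distance analog `exp((d - R̂)/2)` over repeated embeddings; per-edge
   control distributions with empirical 2.5% tail cuts; flagging of a test
   subject's abnormally long/short edges; region-pair aggregation.
5. **synthcohort** — block-correlated Gaussian series, circle-model networks
   with known ground truth, control cohorts, and topological anomaly
   injection for end-to-end detector-recovery experiments.
6. **cli_io** (`hypercon.io`, `hypercon.pipeline`, `hypercon.cli`) —
   plain-text readers/writers, a validated YAML pipeline configuration, and
   the umbrella CLI.

## CLI

```sh
hypercon simulate --n-nodes 200 --beta 2.5 --seed 1 --out g.edgelist
hypercon connect  --series ts.tsv --tau 0.40 --abs --out graph.edgelist
hypercon window   --series ts.tsv --grid 0.15:0.65:0.01 --out report.tsv
hypercon bench    --graph graph.edgelist --space H2 --epochs 1500 --report r.tsv
hypercon embed    --graph graph.edgelist --seed 7 --out disc.csv
hypercon align    --disc disc.csv --ref refs.txt --out aligned.csv
hypercon cv       --graph graph.edgelist --reps 100 --seed 11 --out cv.tsv
hypercon detect   --test disc.csv --controls controls_dir/ --tail 0.025 --out flags.tsv
hypercon run      --config run.yaml
```

Exit codes: 0 success, 2 validation error, 3 stage failure.  `hypercon run`
executes connect → embed → (optional cv) → detect from a YAML config and
writes every intermediate artifact plus a JSON run log (seeds, parameters,
artifact checksums) sufficient to reproduce all numeric outputs.

### Formats (all plain text)

- series: TSV, header `node<TAB>t0...`, one row per node;
- correlation matrices: square CSV with node labels on both axes;
- graphs: two-column whitespace edge lists of 0-based ids plus a sidecar
  `id<TAB>label` table;
- discs: `#`-prefixed metadata (beta, mu, r_hat, loglik) followed by CSV
  rows (node id, label, kappa, r, theta).

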