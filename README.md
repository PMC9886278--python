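# sarcopaint

Nanometre-precision mapping of protein epitopes relative to the
sarcomeric Z-disc, from DNA-PAINT single-molecule localization tables.

In striated muscle, giant elastic proteins (titin in vertebrates; its
*Drosophila* homologs Sallimus and Projectin in flight muscle) occupy
reproducible positions within each sarcomere. DNA-PAINT imaging of
nanobody-labelled epitopes resolves these positions as pairs of bands
flanking every Z-disc, but turning a cloud of millions of localizations
into "epitope X sits d nm from the Z-disc, 95% CI [a, b]" requires a
careful extraction chain. `sarcopaint` implements that chain for anyone
doing localization microscopy of periodic cytoskeletal structures:

1. **filter** localizations from simultaneous multi-emitter events using
   the (sx, sy) Gaussian-fit-width distribution (disc of radius 0.2 px
   around the mode);
2. **rotate** each picked myofibril onto the x-axis and **project** it
   into an axial histogram (bin = camera pixel, 130 nm);
3. **detect Z-discs** as the longest chain of profile peaks spaced one
   sarcomere (~3.5 µm ± 25%) apart;
4. **fit bands**: per Z-disc, a 13 nm histogram is smoothed (Gaussian,
   σ 25 nm) for rough peak finding, then every band is refined by a
   Gaussian + baseline least-squares fit on the raw counts — for an
   epitope with bands at ±d, the half separation of its left/right pair
   is its distance from the Z-disc;
5. **aggregate**: pooled means with bootstrap 95% CIs (1000 replicates,
   2.5/97.5% quantiles), per-sarcomere dual-epitope ordering counts,
   aligned composite profiles, and a separation-vs-sarcomere-length
   regression that justifies pooling.

A synthetic-data module (`sarcopaint.synthpaint`) generates localization
tables with known Z-disc lattices, epitope offsets, localization
precision (4–8 nm regime), background and multi-emitter contamination,
so every stage is verifiable without real data. See `docs/methods.md`
for the full model and its assumptions.

## Worked example

Simulate a myofibril with two epitopes at 50 and 98 nm from the Z-disc
(the Sallimus N-/C-terminal geometry), then run the pipeline on it:

```python
import yaml
import sarcopaint as sp
from sarcopaint.pipeline import PipelineConfig, run_pipeline

cfg = sp.SimConfig(n_sarcomeres=20, seed=12)
table, pick, truth = sp.simulate_myofibril(cfg)
sp.write_localizations("locs.hdf5", table)   # Picasso-style HDF5 + YAML
sp.write_picks("picks.yaml", [pick])

run = {
    "inputs": {"channels": [{"path": "locs.hdf5", "channel_label": "ch0"}],
               "picks": "picks.yaml"},
    "epitope_map": {"ch0": ["sls_nterm", "sls_cterm"]},  # inner -> outer
    "output_dir": "out",
    "seed": 1,
}
with open("run.yaml", "w") as fh:
    yaml.safe_dump(run, fh)
run_pipeline(PipelineConfig.from_yaml("run.yaml"))
```

The run logs `myofibril 0: 21 Z-discs, 40 measurements, 1 skipped` and
`out/summary.json` contains:

```json
{
  "epitopes": {
    "sls_nterm": {
      "mean_nm": 50.35957758786023,
      "ci_low_nm": 49.263950556375505,
      "ci_high_nm": 51.45791517083647,
      "n_replicates": 1000,
      "n_observations": 20,
      "seed": 1
    },
    "sls_cterm": {
      "mean_nm": 98.50045143442473,
      "ci_low_nm": 96.98467181473241,
      "ci_high_nm": 100.00437762181383,
      "n_replicates": 1000,
      "n_observations": 20,
      "seed": 2
    }
  },
  "pairs": {}
}
```

Both configured offsets (50 and 98 nm) are recovered within ~0.5 nm,
with ~2 nm-wide bootstrap confidence intervals from 20 sarcomeres.
`out/` also holds `bands.csv` (every fitted band), `measurements.csv`
(per-sarcomere half-distances) and a verbatim config echo.

The same is available from the shell:

```sh
sarcopaint simulate --out-dir sim --seed 12
sarcopaint run --config run.yaml
sarcopaint stats --measurements out/measurements.csv --pairs sls_nterm,sls_cterm
```

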