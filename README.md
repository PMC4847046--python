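# krigfuse

Geostatistical mapping from dual-instrument point assays: ordinary
kriging, ordinary co-kriging, variography with geometric anisotropy,
inter-instrument calibration fusion, and a synthetic survey generator
for benchmarking mapping strategies.

The package targets the common survey regime where a site has a handful
of accurate lab assays (ICP–AES-like, the *primary* instrument) and many
rapid field readings (PXRF-like, the *secondary* instrument) that are
noisier and positively biased but almost perfectly linearly correlated
with the lab values. Four mapping approaches are implemented and
compared on independent holdout points:

1. ordinary kriging of the sparse primary data;
2. ordinary kriging of the dense secondary data (left on its biased scale);
3. **calibration fusion** — regress primary on co-located secondary,
   transform the dense set, merge with primary preference, then ordinary
   kriging;
4. ordinary co-kriging (primary + secondary under a linear model of
   coregionalization).

A natural-log transform (lognormal kriging) is applied automatically when
the data are positively skewed, with `naive_exp` and Lagrange-corrected
`unbiased` back-transforms.

## Library quick start

```python
import krigfuse as kf

data = kf.generate_scenario(kf.ScenarioConfig(seed=1))
res = kf.run_approach(
    kf.ApproachConfig(3, grid=kf.GridSpec(0, 0, 10.0, 30, 24)),
    data["primary"], data["secondary"], data["validation"],
)
print(res.holdout.rmse, res.holdout.pearson_r)
```

Key modules:

- `krigfuse.types` — `SamplePoint` / `SampleSet` / `GridSpec` / `PredictionGrid`.
- `krigfuse.io` — CSV/TSV sample tables, Esri ASCII grids, YAML configs,
  plus `load_reference_samples()` (a bundled 23-sample lab assay table).
- `krigfuse.variography` — experimental/directional/cross variograms,
  Gaussian/spherical/exponential models with geometric anisotropy
  (practical-range convention, azimuths clockwise from north),
  weighted-least-squares fitting, LMC validity screen.
- `krigfuse.kriging` — OK / CK / lognormal OK at points and grids.
- `krigfuse.calibration` — trend-line calibration, secondary transform,
  primary-preference merging.
- `krigfuse.evaluation` — summary stats, skewness/correlation screens,
  leave-one-out cross-validation, holdout validation (ME, RMSE, Pearson R;
  ME = observed − predicted).
- `krigfuse.pipeline` — approach orchestration, ranking, replicate studies.
- `krigfuse.synthetic` — lognormal truth fields (hotspot trend + Gaussian
  random field via exact covariance factorization) and survey sampling.

## Command line

```sh
krigfuse simulate --config examples/scenario.yaml --out sim/
krigfuse calibrate --primary sim/primary.csv --secondary sim/secondary.csv --out cal.yaml
krigfuse fuse --primary sim/primary.csv --secondary sim/secondary.csv --cal cal.yaml --out fused.csv
krigfuse krige --samples fused.csv --variogram v.yaml --grid g.yaml --method ok-log --out map.asc
krigfuse evaluate --samples sim/secondary.csv --report report.json
krigfuse pipeline run --config examples/scenario.yaml --out run/
krigfuse pipeline compare run/
```

Every run writes a `manifest.json` (config hash, seed, version, outputs).

Variogram YAML follows the usual nugget/sill/range layout; `sill` is read
as the total sill by default, switchable with `sill_is_total: false`.
Anisotropic ranges are written `range: 70/35` with `direction: 115`
(degrees clockwise from north).

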