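# cardiodyn

Quantifies the contractile dynamics of beating cardiac tissue (e.g.
stem-cell-derived cardiomyocyte clusters) from bright-field video, combining
linear beat metrics with nonlinear (fractal) dimensional analysis:

1. **Motion tracking** (`cardiodyn.motiontrack`) — exhaustive block matching
   (sum of absolute differences) between consecutive frames produces
   per-frame displacement-vector fields, collapsed into a contraction-motion
   waveform (mean block speed, µm/s).
2. **Linear metrics** (`cardiodyn.linmetrics`) — peak detection and beat-cycle
   grouping yield beat rate, peak-to-peak interval, and contraction /
   relaxation velocities (mean ± sd).
3. **Nonlinear analysis** (`cardiodyn.nonlin`) —
   *capacity dimension* from the variogram log–log slope (`D = 2 − P/2`,
   recovering `2 − H` on fractional Brownian motion), and *correlation
   dimension* via Takens delay embedding and Grassberger–Procaccia pair
   counting on 32 log-spaced bins, with ACF-based delay selection
   (first lag at `C(0)/e`), false-nearest-neighbor embedding-dimension
   selection, automatic scaling-region fits, and plateau ("steady")
   extraction over embedding dimensions.
4. **Synthetic data** (`cardiodyn.synthdata`) — seeded generators for
   twin-peak beat waveforms (with missed-beat / spike / jitter aberrations),
   exact-covariance fractional Brownian motion (circulant embedding), a
   Lorenz reference trajectory, and rendered textured videos with known
   per-frame displacements.
5. **Pipeline** (`cardiodyn.pipeline`) — single-recording and batch
   orchestration with per-group mean ± sd summaries and bit-reproducible
   JSON reports.

## CLI

```sh
# video (multi-page TIFF or frame glob) -> waveform CSV
cardiodyn track --input stack.tif --fps 100 --um-per-px 0.65 \
    --block 16 --search 7 --out waveform.csv

# waveform CSV -> beat metrics JSON
cardiodyn metrics --waveform waveform.csv --out metrics.json

# waveform CSV -> nonlinear report (variogram, D_capacity, C_m(r), D_steady)
cardiodyn nonlin --waveform waveform.csv --tau auto --m-max 12 --out nonlin.json

# synthetic inputs with ground-truth sidecars
cardiodyn simulate waveform --seed 1 --out w.csv
cardiodyn simulate lorenz --seed 1 --out x.txt
cardiodyn simulate video --seed 1 --out v.tif

# batch over a manifest (path, sample_id, group [, fps, um_per_px])
cardiodyn run --manifest manifest.tsv --config config.json --out report/
```

Waveform CSVs have the header `time_s,speed_um_per_s`. Batch output is one
JSON report per sample plus `samples.tsv` / `summary.tsv` and the echoed
config.

## Conventions worth knowing

- Coordinates are (row, col) = (y, x), origin top-left; a displacement
  (dy, dx) is where a block of frame *k* lands in frame *k+1*.
- The waveform duplicates the first inter-frame speed so video and waveform
  have equal length.
- Degenerate inputs (constant waveforms, coincident embedded points) return
  flagged sentinel results instead of raising, so batches survive dead
  samples.
- Every stochastic generator takes an explicit seed and is bit-reproducible.
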