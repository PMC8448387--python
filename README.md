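# calwave

Quantification of evoked intercellular calcium waves in acute brain-slice
imaging, astrocyte co-label classification, 3-D astroglial morphometrics,
and two-group statistical reporting — with a synthetic-data generator that
plants ground-truth waves and cell morphologies so every stage of the
pipeline is verifiable without microscope data.

**Who it is for.** Slice physiologists and image analysts who evoke a
calcium wave by focal depolarization (e.g. in the cerebellar internal
granular layer), record it with a calcium indicator at ~1 Hz, and want
reproducible, scriptable versions of the standard measurements: ΔF/F
transient detection, concentric-ring recruitment counts, wave length and
speed, dye-based astrocyte co-labeling, 3DMorph-style skeleton metrics,
and Shapiro–Wilk-gated control-vs-treatment comparisons.

## The measurements

With F_b the pixelwise mean of the pre-stimulus frames,

- ΔF/F(t) = (F(t) − F_b)/F_b per ROI; a cell is **recruited** when ΔF/F
  stays ≥ k·SD(pre-stimulus ΔF/F) for ≥ `min_frames` consecutive frames
  after the stimulus (defaults k = 2.5, 3 frames);
- recruited cells are counted in half-open concentric rings
  [50k, 50(k+1)) µm around the stimulation site;
- **maximum length** = largest recruited-cell distance (µm);
  **speed** = max_length/(t₁ − t₀), t₀ the first post-stimulus
  activation, t₁ the activation at maximum length;
- transient **AUC** by the trapezoidal rule; amplitudes as peak ΔF (a.u.)
  and peak ΔF/F;
- **co-labeling**: Otsu mask of the second channel; an ROI is co-labeled
  when ≥ 50% of its pixels overlap the mask;
- **morphometrics**: volume = voxel count × voxel volume; medial-axis
  skeleton → branchpoints (degree ≥ 3 clusters), branches, branch length;
  soma density in 50 × 200 µm fields;
- **group comparison**: mean ± SEM, Shapiro–Wilk gate → Welch t test or
  Mann–Whitney U (two-sided), integer percent change vs control.

See `docs/methods.md` for the full model, defaults, and limitations.

## Worked example

```python
from calwave import SimulationConfig, build_report
from calwave.synthetic import simulate_movie, truth_frame
from calwave.pipeline import analyze_movie

cfg = SimulationConfig(seed=1)          # 200 frames @ 1 Hz, wave at 27.3 um/s
movie, truth = simulate_movie(cfg)
calls, metrics, colabel = analyze_movie(movie)
print(f"recruited {metrics.total_recruited} cells, per ring {metrics.cells_per_ring}")
print(f"max length {metrics.max_length:.1f} um, speed {metrics.speed:.1f} um/s")
print(f"planted recruited: {truth_frame(truth).recruited.sum()}")
```

prints

```
recruited 70 cells, per ring [4, 14, 29, 20, 3]
max length 222.4 um, speed 27.8 um/s
planted recruited: 70
```

i.e. the pipeline recovered all 70 planted recruited cells, their
ring distribution, and the planted propagation speed of 27.3 µm/s to
within 2%.  Two-group experiments go through
`calwave.synthetic.simulate_experiment` →
`calwave.pipeline.analyze_experiment` → `build_report`, which emits one
row per metric with group means ± SEM, the gated test used, p-value,
significance stars and integer percent change.

A CLI mirrors the library:

```
calwave simulate movie|stack|experiment --config cfg.yaml --seed 1 --out dir/
calwave quantify --movie dir/movie [--rois rois.csv] --out out/
calwave morph --stack dir/stack --out out/
calwave compare --metrics per_slice.csv --out report/
```

Movies and z-stacks travel as 16-bit multi-page TIFFs with JSON sidecars;
tables as CSV.

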