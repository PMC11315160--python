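# stisebs

Superpixel segmentation of dense spatial time series.

Long, high-resolution satellite index records (e.g. 20 years of 8-day
NDVI at 250 m) are routinely too large for regional environmental
analyses, forcing a fallback to coarser pixels and the subpixel
heterogeneity that comes with them. `stisebs` reduces the *spatial*
dimension instead: it groups pixels whose temporal profiles are similar
into contiguous **superpixels**, so each superpixel's mean series can
stand in for its pixels with minimal information loss. It is aimed at
remote-sensing and environmental researchers who need a tractable
spatial unit for time-series analysis without giving up resolution.

## Method

For a grid of I valid pixels over T periods the pipeline is:

1. **Clean** — NDVI = (NIR − Red)/(NIR + Red); values outside [−1, 1]
   removed; gaps filled by a centered exponentially weighted moving
   average (±3 periods, weights (1/2)^(|Δt|−1)); Savitzky–Golay
   smoothing (window 7, order 2, optional upper-envelope iterations).
2. **Reduce** — PCA on the centered series, keeping the smallest C
   components explaining ≥ 99 % of the variance (cap 200).
3. **Cluster** — seeded k-means on the component vectors (no spatial
   coordinates).
4. **Dissolve** — 4-connected same-cluster pixels become patches with
   mean feature vectors x_j.
5. **Regionalize** — the patch adjacency graph (Euclidean feature
   costs) is reduced to a minimum spanning tree (Prim) and pruned
   greedily, each cut minimizing the total within-tree deviation
   `SSD_k = (1/n_k) Σ_j ||x_j − x_k||²`, until k superpixels remain
   (SKATER).
6. **Assemble** — each superpixel's series is the mean over its member
   pixels.

The package also ships the full assessment suite (disassembly to
hypothetical HR pixels, cumulative Euclidean error, inhomogeneity δ,
isolation γ, land-cover agreement with OA/kappa/per-class MCC), two
baselines (coarse f×f blocks; e-SLIC = SLIC on the top-3 principal
components), and a seeded synthetic-scene generator with ground truth.
See `docs/methods.md` for the details and design choices.

## Worked example

```python
import stisebs as st

# a 64x64x92 seasonal scene: 6 Voronoi regions, noise sd 0.02, 2% gaps
grid, truth = st.generate_scene(st.default_scene(seed=7))

res = st.run_stisebs(grid, k_superpixels=6, k_clusters=6, seed=7,
                     preprocess=True, full=True)
print(res.pca.n_components, res.patches.n_patches, res.superpixels.k)
# -> 3 6 6        (3 components reach 99% variance; 6 patches; 6 superpixels)

print(st.score_recovery(res.labels, truth))
# -> {'ari': 1.0, 'boundary_recall': 1.0, 'achievable_accuracy': 1.0}

clean = res.preprocessed
lg_c, sp_c = st.coarse_pixel_baseline(clean, factor=4)     # 256 LR blocks
e_s, _ = st.euclidean_error(clean, st.broadcast_to_hr(res.labels, res.superpixels))
e_c, _ = st.euclidean_error(clean, st.broadcast_to_hr(lg_c, sp_c))
print(round(e_s, 1), round(e_c, 1))
# -> 461.5 857.9  (cumulative series error: 6 superpixels already beat 256 blocks)
```

The recovery scores mean the six superpixels coincide exactly with the
six true regions; the error pair shows that six well-chosen contiguous
segments represent the scene's series better than 256 arbitrary 4×4
blocks (46 % less cumulative deviation).

The same pipeline is available from the shell:

```sh
stisebs synth --height 64 --width 64 --periods 92 --seed 1 scene.tif truth.tif
stisebs run --input scene.tif --superpixels 50 --seed 42 --out out/
stisebs assess --truth scene.tif --segments out/superpixels.tif \
               --baseline coarse --factor 4 --out report.json
```

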