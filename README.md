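# qdepth

Quantifies how deep fluorescent nanoparticles (e.g. quantum dots) penetrate
past the apical membrane of an epithelial cell monolayer, from two-channel 3D
confocal z-stacks (membrane label + particle label).  It is written for
nanotoxicology and cell-biology groups who image particle exposure on
polarized monolayers (Caco-2-style transwell cultures) and want a number —
not a visual impression — for "are the particles inside the cells or just
sitting on them?".

## The measurement

For every stack the pipeline:

1. optionally deconvolves each channel (Richardson–Lucy against a theoretical
   Gaussian PSF),
2. smooths laterally — σ = 2 px on the particle channel, σ = 30 px on the
   membrane channel — with *no* axial filtering, and thins the membrane
   axially by subtracting a copy shifted 2 voxels toward the basal side,
   keeping a sharp band at the apical membrane edge,
3. segments both channels with a 256-bin Otsu threshold; keeps the single
   large membrane sheet (≥ 10⁵ voxels) and discards particle objects below
   450 voxels or dimmer than 5 % of the threshold-to-maximum intensity range;
   splits merged agglomerates with a marker-based watershed (σ = 0.1 µm),
4. extracts the apical membrane surface (apical-most membrane voxel per
   lateral column) and measures, for each particle object, the signed axial
   component of the vector from the 3D-nearest surface voxel to the object's
   intensity-weighted centre of mass — negative means below the membrane,
   inside the cell,
5. pools distances across stacks, histograms them and fits a Gaussian
   A·exp(−(x−x_c)²/2σ²).  The peak position **x_c** is the penetration depth;
   a population is called *penetrating* when x_c + 2·SE(x_c) < 0, otherwise
   *membrane-associated*.

A synthetic-scene generator renders monolayer stacks with exact ground truth
(membrane surface position, per-emitter signed offsets, agglomerate
membership, organelle diameters), so every stage is testable without any
microscopy data.

## Worked example

```python
from qdepth import (PipelineConfig, PreprocessParams, analyze_pair,
                    classify_penetration, monolayer_scene, pool_and_fit,
                    render_scene)

config = PipelineConfig(preprocess=PreprocessParams(deconvolve=False))
records = []
for s in range(6):
    spec = monolayer_scene(-1.3, shape=(128, 256, 256), seed=100 + s,
                           geometry_seed=200 + s)
    scene = render_scene(spec)
    recs, _, _ = analyze_pair(scene.membrane, scene.particles, config, f"s{s}")
    records.extend(recs)

fit = pool_and_fit(records, n_stacks=6)
print(fit.x_c, fit.x_c_se, classify_penetration(fit))
```

Running `python examples/02_measure_penetration_depth.py` (the same
computation for both exposure regimes) prints:

```
penetrated             true offset -1.3 µm -> x_c = -1.299 ± 0.001 µm (σ = 0.003 µm, n = 24) -> penetrating
membrane-associated    true offset +0.0 µm -> x_c = -0.000 ± 0.000 µm (σ = 0.002 µm, n = 24) -> membrane-associated
```

i.e. agglomerates placed 1.3 µm below the synthetic membrane are recovered at
x_c = −1.30 µm and flagged as penetrating, while agglomerates sitting on the
membrane come back at x_c ≈ 0 and are flagged membrane-associated.  The other
scripts in `examples/` demonstrate scene simulation, the histogram fit on raw
distances (including the normality screen rejecting a bimodal pool), and
organelle-diameter recovery (0.6 µm and 0.9 µm spheres measured at 0.69 µm
and 0.92 µm after deconvolution).

## Command line

```bash
qdepth simulate  --spec scene.yaml --out scene/        # synthetic scene + truth
qdepth analyze   --stacks stacks/ --config cfg.yaml --out report/
qdepth fixtures  --seed 7 --out fixtures/              # four canonical scenes
```

`analyze` writes per-object tables, the pooled record table, histogram CSV,
fit JSON, a plot, and the resolved configuration; re-running with the same
config and inputs reproduces every output byte for byte.

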