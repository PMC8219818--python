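# scenescale

Voxel-wise fMRI analysis of **object-scene scale consistency** — how the
brain responds when an object appears at an unusual size relative to its
surrounding scene — implemented as a fully tested pipeline over a
synthetic BOLD generator with known ground truth.

Humans searching a scene often miss objects rendered at anomalous sizes,
and scene-processing cortex (e.g. the transverse occipital sulcus) and
attention-related parietal regions respond *less* to mis-scaled objects.
This package reimplements the analysis chain used to establish that kind
of result and exercises every stage on simulated data, so the statistical
machinery — in particular the selection-matched permutation nulls — can
be validated against generators where the truth is known.

## What it computes

**Design.** 10 objects × 2 manipulations (object retinal size vs scene
field-of-view) × 6 scale-consistency levels (factor ladder 1, 1.6, 2.2,
2.8, 3.4, 4) = 120 images, each carrying ordinal levels for four
properties: scale consistency, retinal size, real-world size, FOV.  Per
scan, 120 stimulus + 20 task trials in 10 blocks, 10 s blanks, TR 0.7 s.

**Rank-1 FIR GLM.** Per voxel, the lag × condition FIR coefficient
matrix is constrained to rank one, B = h βᵀ: one HRF estimate h shared
across conditions and one amplitude β_k per condition, fitted by
alternating least squares.  The contrast of interest is
β(normal) − mean(β mis-scaled), tested with label permutations.

**Blank-baseline z-scoring and extraction.** Per scan and voxel,
z_n = (d_n − b̄)/s_b with b̄, s_b from the blank periods of the linearly
detrended series; per-event responses are read out at event onset plus
the voxel's HRF peak delay (fixed 7 TRs = 4.9 s for voxel selection,
per-voxel estimated delays for decoding and encoding).

**MVPA.** Linear SVM decoding of normal vs mis-scaled on the top-50
scene-responsive voxels, leave-one-run-out over the 5 scans, averaged
over the five level pairings; chance = 50%, null by randomizing training
labels only.

**Encoding model.** Per voxel, ridge regression of event responses on
the four normalized features (each in [−1, 1]) yields feature weights
w_f.  Responsiveness: mean w_f vs a shuffled-feature null (two-tailed).
Selectivity: among the top 30% of voxels by |w_scale|, the mean ratio
|w_scale| / Σ_f |w_f|; because ranking-then-averaging biases the ratio
above its chance value of 1/4, the null repeats the identical selection
inside every permutation.  Validation: leave-one-run-out predicted BOLD,
summarized per level × mis-scaling direction and tested with one-tailed
paired t-tests (BH-FDR).

## Worked example

```python
from scenescale.pipeline import PipelineConfig, build_design, \
    prepare_subject, simulate_subject
from scenescale import encoding, mvpa

images, _ = build_design()
cfg = PipelineConfig(n_subjects=1, n_voxels=40,
                     scenario="scale_negative", seed=2)
ana = prepare_subject(simulate_subject(images, cfg, 0), images, cfg)
res = mvpa.run_mvpa(ana.responses[:, ana.top_voxels.indices],
                    ana.events["scale_level"].to_numpy(),
                    ana.events["scan"].to_numpy())
print(res.pairing_pcs, res.mean_pc)
```

prints (level → percent correct):

```
{2: 63.5, 3: 81.0, 4: 92.0, 5: 99.0, 6: 100.0} 87.1
```

The generator gives every voxel a negative scale-consistency weight, so
decoding accuracy climbs from 63.5% for the mildest mis-scaling pairing
to 100% for the strongest, mean PC 87.1% against a training-label
permutation null of 50.0%.  The numbered scripts under `analysis/`
(design checks, simulation, GLM, MVPA, encoding, group validation) run
the same stages end to end and write their tables under `results/`; the
group validation script shows that 14 simulated subjects yield
significant normal > mis-scaled predicted responses in *both*
mis-scaling directions under scale-consistency tuning (t(13) ≈ 131,
p_FDR < .001) and in neither direction under a null generator.

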