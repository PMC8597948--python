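# probeloc

Localization of every electrode on a linear probe (Neuropixels-class) in a
standardized mouse-brain coordinate system, from histology plus
electrophysiology — and a groundtruth analysis that measures how accurate
that localization actually is.

## The problem

Long linear probes span many brain regions in a single insertion, so
interpreting the recorded activity requires knowing where each recording
site sits in a common reference space (the CCF — the standardized coordinate
frame of the Allen mouse brain atlas). Histology alone is not enough: the
dye-labeled track gives the trajectory, but the dye tip over- or
under-estimates the probe tip, the atlas is enlarged and nonuniformly
distorted relative to the in vivo brain, and a fixed inter-electrode pitch
of 20 μm turns small scale errors into large depth errors over a 3.84 mm
bank. The workflow implemented here combines:

1. **Landmark warping** — 3D thin-plate-spline transforms
   `f(x) = Ax + b + Σᵢ wᵢ‖x − cᵢ‖` fitted on manually placed point
   correspondences between the subject volume and the atlas template, with
   exact interpolation at the landmarks and composable transform chains
   (subject → CCF → in-skull MRI template).
2. **Track reconstruction** — an arc-length-parametrized polyline through
   manually annotated dye-centerline points (~20 points per penetration at
   ~0.2 mm spacing), projected between spaces.
3. **Electrode placement** — sites placed from the dye tip by the known
   geometry (Neuropixels 1.0: 960 sites, 3.84 mm tip bank), then *anchored*:
   sites with recognizable electrophysiological signatures (brain surface
   step in LFP power and spiking, quiet white-matter stretches,
   hippocampus/thalamus rate transition) are pinned to the corresponding
   atlas-boundary crossings on the track, and the sites in between are
   placed by piecewise-linear scaling, with nearest-segment extrapolation
   beyond the anchored range.
4. **Region assignment** — nearest-voxel lookup in the atlas annotation
   volume for every site.
5. **Groundtruth accuracy** — along each localized probe, the fluorescence
   of virally labeled axonal projections is compared with the
   photostimulation-evoked multiunit activity; both per-depth profiles are
   fitted with multi-term Gaussians `Σₖ Aₖ exp(−(x−μₖ)²/2σₖ²) + c`, peaks
   are matched greedily by nearest mean, and the per-penetration mean
   |Δpeak| (mm) is the localization error.

A fully synthetic phantom (layered toy atlas, known smooth deformation,
rendered dye track, region-dependent spiking with an out-of-brain segment,
fluorescent blobs with matched evoked responses) provides exact ground truth
for every step.

## Worked example

```python
import dataclasses
from probeloc import presets, run_study
from probeloc.workflow import make_study_cohort

# 17 penetrations pooled from a cohort of 4 phantom brains
spec = dataclasses.replace(presets()["realistic"], seed=23)
study = run_study(make_study_cohort(spec, n_brains=4))

res = study.summary("undistorted")      # anchored in the in-vivo-shaped space
print(f"accuracy {res.mean_mm:.3f} ± {res.sd_mm:.3f} mm "
      f"({res.n_penetrations} penetrations)")
res_s = study.summary("scaled")         # anchored directly in the enlarged atlas
print(f"atlas-direct {res_s.mean_mm:.3f} ± {res_s.sd_mm:.3f} mm")
print(f"tip bias: atlas {study.tip_audit_mm('scaled').mean():+.2f} mm, "
      f"undistorted {study.tip_audit_mm('undistorted').mean():+.2f} mm")
```

prints

```
accuracy 0.047 ± 0.025 mm (17 penetrations)
atlas-direct 0.049 ± 0.031 mm
tip bias: atlas +1.12 mm, undistorted +0.05 mm
```

Reading: under realistic manual-work noise (50 μm landmark jitter, 30 μm
anchor jitter, dye-tip smear), electrodes are localized to a few tens of
microns; anchoring directly in the enlarged atlas space is worse than in
the in-vivo-shaped template space; and the raw dye-tip depth overshoots the
micromanipulator reading by ~1.1 mm in the enlarged space (the enlargement
itself, at a ~3.25 mm mean insertion) but only ~0.05 mm in the undistorted
space (dye smear and track-reconstruction wiggle).

The same pipeline runs from the shell: `probeloc phantom` writes a bundle to
disk, `probeloc localize` produces a per-site CSV from track + anchor files,
and `probeloc groundtruth` emits the accuracy report for one penetration.

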