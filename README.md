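# orbitcut

Seed-driven graph-cut segmentation and volumetry of orbital soft tissue in
CT. From a handful of brush strokes marking extraocular muscle, intraorbital
fat and bone/dense structures on one or a few axial slices, `orbitcut`
labels every voxel of a 3-D orbital region of interest, reports per-tissue
volumes in cm³, and reconstructs triangle-mesh surfaces. It ships the full
validation battery used in orbital volumetry studies (Jaccard/Dice overlap,
two-way mixed-effects ICC, paired/independent t tests, percentage
difference) and a synthetic orbital-phantom generator with exact ground
truth, so the whole pipeline is testable without any scan data.

Intended users: researchers in ophthalmic / orbital imaging who need
reproducible soft-tissue volume measurements (e.g. muscle and fat changes
after enucleation or in thyroid eye disease), and anyone who wants a small,
fully scripted interactive-segmentation baseline.

## The method

Segmentation is posed as a multi-label energy minimisation over a graph of
voxels or watershed superpixels. For a labeling *L*:

```
E(L) = Σ_i |R_i| · D_i(L_i)  +  λ Σ_(i,j) w_ij · [L_i ≠ L_j]
```

* **Data term** — each tissue's intensity model is a set of k-means centers
  fitted to the seeded voxels' Hounsfield values;
  `D_i(l) = d_l / Σ_m d_m` with `d_l` the minimum |HU − center| distance
  (normalised to [0, 1]).
* **Smoothness term** — a contrast-sensitive Potts penalty
  `w_ij = 1 / (ε + (I_i − I_j)²)`: cheap to cut where intensity jumps,
  expensive inside homogeneous tissue.
* **Hard constraints** — seeded voxels are pinned with a large finite cost;
  air and the ROI corners are auto-seeded as background unless the user
  provides background strokes.
* **Minimisation** — alpha-expansion: one binary max-flow/min-cut per label
  per sweep (scipy's Dinic solver) until a full sweep no longer lowers the
  energy. The energy never increases and runs are bit-reproducible.

Volumes are pure voxel counts × voxel volume; surfaces are marching-cubes
isosurfaces of each tissue mask.

## Worked example

```python
import orbitcut as oc

# a synthetic orbit: bone shell, HA sphere, 3.8 cm^3 of muscle strips,
# 2.5 cm^3 of fat, CT-like noise (sigma = 15 HU)
spec = oc.PhantomSpec(noise_sigma=15.0, rng_seed=1)
vol, truth = oc.generate_phantom(spec)

# simulate the interactive user: 25 single-voxel strokes per tissue
seeds = oc.auto_seeds_from_truth(truth, per_label_count=25, rng_seed=2)

result = oc.segment(vol, seeds, oc.EnergyConfig())
report = oc.compute_volumes(result.labels, vol.spacing)
print(f"MV = {report.MV:.4f} cm^3  "
      f"({oc.percentage_difference(report.MV, 3.8):.2f}% vs truth)")
for lab in (1, 2, 3):
    name = truth.label_names[lab]
    print(f"dice[{name}] = {oc.dice(result.labels.mask(lab), truth.mask(lab)):.4f}")
```

prints

```
MV = 3.8310 cm^3  (0.82% vs truth)
dice[muscle] = 0.9733
dice[fat] = 0.9585
dice[bone] = 0.9995
```

i.e. the measured extraocular muscle volume is within 1% of the known
3.8 cm³ ground truth and every tissue overlaps its true extent with
Dice ≥ 0.95. With `noise_sigma=0` and `EnergyConfig(use_superpixels=False)`
the recovery is exact, voxel for voxel.

The same pipeline is available from the shell:

```
orbitcut phantom --out data/ --series default --seed 1
orbitcut segment --volume data/phantom_05_ct.nii.gz \
                 --auto-seeds-from data/phantom_05_truth.nii.gz --out run/
orbitcut evaluate --pred run/labels.nii.gz \
                  --truth data/phantom_05_truth.nii.gz --out run/
```

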