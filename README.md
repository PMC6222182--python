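# airwaynav

Virtual-bronchoscopy biopsy planning from chest CT, for interventional
pulmonology research and tool development. Given a CT volume and a lesion
point, `airwaynav` segments the airway lumen, encodes its centerline as a
rooted binary tree, finds the route from the trachea to the airway point
closest to the lesion, and translates that route into ordered,
human-readable quadrant instructions — one per bifurcation — exported as a
roadmap (JSON, numbered text, schematic image mosaic).

## Method in brief

- **Segmentation.** Lumens are dark tubes on CT. A multiscale
  second-derivative-of-Gaussian filter scores each voxel from the
  γ-normalized (γ=2) Hessian eigenvalues λ₁ ≤ λ₂ ≤ λ₃ of the smoothed
  volume: R = max(λ₂λ₃ − λ₁², 0) where λ₂, λ₃ > 0, maximized over scales.
  The mask is the trachea-seeded connected component of the thresholded
  response, united with HU region growing (< −950 HU) that secures the
  large proximal airways.
- **Tree.** The mask is thinned to a medial curve (distance-ordered
  homotopic thinning, 26/6 connectivity), condensed into a branch graph,
  pruned, and directed away from the trachea entry by depth-first search.
  Levels are bronchial generations (trachea = 0). The tree is stored as two
  matrices: binary node adjacency, and per-pair 3-D centerline segments
  p₁ᵈ … p_{k_d}ᵈ joining bifurcation points at consecutive levels.
- **Path.** A navigation path S₁, …, S_n connects the root to the
  centerline point closest to the lesion (exhaustive minimization with a
  deterministic tie-break; the final segment is truncated at the anchor and
  the residual lesion gap in mm is reported).
- **Instructions.** At each bifurcation p_{k_d}ᵈ a virtual camera sits 5 mm
  proximal on the path looking at the carina; each child segment projects
  into the image, which is split into quadrants I–IV (up-right, up-left,
  down-left, down-right) about the projected bifurcation point. A child is
  assigned the quadrant holding most of its points, and the pair of labels
  simplifies by dropping the shared word: I vs IV → "go up"/"go down",
  II vs I → "go left"/"go right", and so on. Bifurcations closer than 6 mm
  are flagged (their lumens superimpose in one view) and can optionally be
  merged into a single instruction.

No patient data is required anywhere: a phantom module rasterizes branching
tube trees with known centerlines and topology (HU-realistic lumen, wall,
parenchyma, optional noise), so the entire pipeline is testable offline.

## Worked example

The self-contained demo generates a 4-generation phantom on a 128³ grid,
plants a lesion near a random leaf, and runs the whole pipeline:

```
$ airwaynav demo --seed 7 --out demo_out
```

which prints the per-stage record and the roadmap:

```
"segment": { "voxels": 34604, "seed": [63, 64, 119] }
"tree":    { "skeleton_voxels": 270, "nodes": 16, "leaves": 8, "discarded_edges": 0 }
"plan":    { "segments": 4, "gap_mm": 1.556, "anchor_edge": [5, 10] }
"roadmap": { "instructions": 3 }

1. (level 1) go left
2. (level 2) go up
3. (level 3) go up
```

Reading: the segmented airway yielded a 16-node tree with 8 leaves (a
complete 4-generation binary tree). The lesion anchors mid-airway 1.56 mm
from the centerline, 4 segments from the trachea; the 3 instructions say
which lumen to enter at each of the 3 bifurcations en route — at the main
carina take the left lumen, then the upper lumen twice. `demo_out/` holds
the volume, ground truth, mask, tree, path, roadmap and provenance log; the
same stages are available piecewise as `airwaynav phantom | segment | tree |
plan | roadmap | run`.

Library use mirrors the CLI:

```python
import airwaynav as an

vol  = an.load_volume("ct.nii.gz")                  # or a DICOM directory
mask = an.segment_airways(vol)                      # seeded, thresholded lumen
skel = an.skeletonize(mask)
g    = an.build_skeleton_graph(skel, mask.affine)
g    = an.extend_leaf_tips(g, mask.mask, mask.affine)
g    = an.prune_spurs(g, 3.0, mask=mask.mask, affine=mask.affine)
tree = an.direct_from_root(g, an.world_from_voxel(vol, mask.seed))
path = an.plan_path(tree, lesion_xyz_mm)
rm   = an.encode_instructions(path, tree)
an.export_roadmap(rm, "out/", formats=("json", "txt", "png"))
```

See `docs/methods.md` for the model, parameter defaults, and limitations.

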