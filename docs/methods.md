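# Methods

`airwaynav` plans virtual-bronchoscopy biopsy routes: it segments the airway
lumen from a chest CT, reduces it to a rooted centerline tree, finds the
path from the trachea to a user-selected lesion, and renders that path as
ordered quadrant-based instructions ("go left", "go up-right", ...) at every
bifurcation. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic phantoms do and do not show.

## Coordinate conventions

All world coordinates are millimetres in the DICOM patient frame (LPS:
+x left, +y posterior, +z superior). NIfTI input (RAS) is converted on load
and back on save. Voxel indices are 0-based; an integer index addresses the
voxel centre. DICOM slices are ordered by `ImagePositionPatient` projected
on the slice normal, never by instance number, so renumbered series load
correctly.

## Airway segmentation

Airway lumens appear on CT as dark (air, about −1000 HU) tubes wrapped in a
brighter wall, embedded in parenchyma (about −850 HU). The lumen detector is
a multiscale second-derivative-of-Gaussian (Hessian) filter. At scale
σ (mm) the volume is smoothed, the Hessian is computed with derivatives
taken in millimetres (so anisotropic voxels are handled exactly), and
γ-normalized with γ = 2 (multiplied by σ²). With eigenvalues
λ₁ ≤ λ₂ ≤ λ₃, the dark-tube response is

    R_σ = max(λ₂·λ₃ − λ₁², 0)  where λ₂ > 0 and λ₃ > 0, else 0.

On a lumen axis the two cross-sectional curvatures are large and positive
and the axial one is near zero, so R is large; for bright tubes, plates, and
flat regions R is zero by construction (the polarity and constant-volume
tests assert exactly this). The multiresolution map takes the voxelwise
maximum of R_σ over a scale ladder (default {0.5, 1, 2, 4, 8} mm; scales
below half the voxel spacing are undersampled and rejected) and records the
argmax scale.

Two properties of the walled-lumen profile matter in practice:

- The response peaks near σ ≈ r/2, not σ ≈ r: at σ ≈ r the positive side
  lobes of the second-derivative kernel overlap the bright wall and the
  axial response crosses zero (verified on 1-D/2-D ring profiles). The
  argmax scale therefore tracks calibre proportionally (thicker lumen →
  larger argmax scale) rather than equalling the radius.
- The thin parenchyma shell just outside the bright wall also scores high
  on tubularity. Since a non-air voxel cannot be lumen, the thresholded
  candidate set is intersected with an HU air gate (default < −900 HU).

The binary mask is the 26-connected component containing the trachea seed of
`{response ≥ τ} ∪ {region grown from the seed over HU < −950}`. The HU
region growing secures the trachea and main bronchi, whose large calibre the
thin-tube filter is not tuned for; the growing front aborts when its
per-iteration voxel gain exceeds 4× the running median (the classic guard
against explosion into parenchyma through a wall defect). τ defaults to the
Otsu threshold of the nonzero response histogram and is overridable; raising
τ can only shrink the mask (monotonicity is tested). The trachea seed is
auto-detected as the centroid of the largest near-circular dark component
(mean cross-section 20–2000 mm²) in the most superior tenth of the slices.

For speed the eigenvalue evaluation inside `segment_airways` is restricted
to a 2-voxel dilation of the dark (< −900 HU) region; the response is
defined zero far from any lumen, so the thresholded set is unchanged. The
lower-level `tubularity_at_scale` / `appearance_map` evaluate the full grid
by default.

## Skeletonization and the airway tree

The mask is thinned to a 1-voxel-wide medial curve by distance-ordered
homotopic thinning (module `_thinning`): border voxels are deleted in order
of increasing Euclidean distance to the background, only if deletion
preserves topology (Malandain–Bertrand simple-point test for the
26-object/6-background connectivity pair) and the voxel is not a curve
endpoint. Deleting by distance keeps the survivors on the medial axis; the
endpoint test preserves branch tips. This thinning is implemented here
(numba-compiled) rather than taken from a library after the installed
3-D thinner proved unreliable on symmetric tubes.

The skeleton is condensed into a branch graph: maximal 26-connected clusters
of degree ≥ 3 voxels become branching nodes, degree-1 voxels become end
nodes, and the degree-2 chains between them become edges carrying ordered
world-mm polylines. Every skeleton voxel belongs to exactly one node cluster
or one chain (a conservation law the tests assert). A chain end touching
several clusters attaches so as to join two distinct nodes whenever
possible.

Two corrections follow, both consequences of thinning geometry:

- **Tip extension.** Homotopic thinning erodes a free tube end by roughly
  one lumen radius. Each leaf edge is marched onward along its end direction
  (averaged over its last 3 mm) in half-voxel steps until the mask distance
  transform starts descending — i.e. to the medial endpoint at the centre of
  the terminal cap — recovering the lost tip without overshooting into the
  rounded end.
- **Spur pruning.** Leaf edges shorter than 3 mm are removed iteratively,
  and nodes left with two incident edges are merged. When the mask is
  available the threshold additionally adapts to the junction's local lumen
  radius (max(3 mm, 1.5 × distance-to-boundary at the junction)), because
  thinning a junction bulge leaves medial spurs about one radius long —
  at an 8 mm trachea that is far beyond any fixed millimetre threshold.
  Pruning is idempotent and a zero threshold is the identity.

The pruned graph is directed away from the root — the node nearest the
detected trachea entry (ties: most superior) — by depth-first search with
children visited in descending edge-length order; DFS back edges (cycles,
rare thinning artifacts) are discarded and counted in the diagnostics.
Pass-through nodes with a single child are merged so every directed edge
advances exactly one bronchial generation: the root (trachea entry) is
level 0 and level(child) = level(parent) + 1 always. Nodes with more than
two children are kept and flagged `non_binary` rather than force-split,
since near-coincident bifurcations are a real, instruction-relevant
phenomenon (see close levels below). The tree is encoded as a symmetric
binary node-adjacency matrix plus a matrix of 3-D segments holding the
ordered centerline points joining each adjacent pair; encode → decode is the
identity.

## Path planning

The lesion is a world point. Its anchor is the global minimizer of the
Euclidean distance over all sampled polyline points of all edges —
point-to-sampled-polyline, not point-to-continuous-segment, which bounds the
error by half a voxel diagonal at skeleton sampling density. Ties break
deterministically: canonical (parent, child) edge order, then lowest point
index. The navigation path is the unique tree path from the root to the
anchor edge, with the final polyline truncated at the anchor (lesions rarely
coincide with the most distal point reached; the residual `gap_mm` is
reported). Each segment owns its distal junction: S_d runs from the
bifurcation it leaves to the bifurcation point at its own level d.

## Quadrant instructions

For each internal path bifurcation a pinhole camera is placed `setback_mm`
(default 5 mm, a bronchoscope approaching the carina) proximal to the
bifurcation point along S_d, looking at the bifurcation; the field of view
defaults to 120° (wide-angle, bronchoscope-like), though the quadrant logic
is fov-insensitive by construction. "Up" is the patient-superior axis
orthogonalized against the view, falling back to patient-anterior when the
view is within ~8° of vertical (|view·superior| > 0.99) — a reproducible
convention absent any scope-roll model. The centerline points of each child
segment (excluding the shared junction point, which projects onto the
principal point for every child) are perspective-projected; points behind
the camera or outside the view cone are dropped and counted.

The image splits into quadrants about the projected bifurcation point:
I = up-right (x ≥ 0, y ≥ 0), II = up-left, III = down-left, IV = down-right
(half-open boundaries; boundary points go right/up). Each child is assigned
the quadrant containing most of its points; ties go to the quadrant of the
most distal projected point — the direction the operator will actually
steer toward. The label pair then simplifies by dropping the shared word:
different vertical halves → "go up"/"go down"; same vertical but different
horizontal halves → "go right"/"go left"; diagonal pairs (I/III, II/IV) use
the vertical rule (a fixed precedence; the choice is conventional). Two
children in the same quadrant are split along the axis on which their mean
projected points differ more. Quadrant voting is exactly invariant to
positive rescaling of image coordinates; mirroring the scene across the
camera's vertical plane swaps left/right words, and rolling the camera 180°
maps every word to its diagonal opposite (all tested exactly).

**Close levels.** When the next path bifurcation lies within `close_mm`
(default 6 mm) of the current one, both carinae superimpose in one view and
three lumens appear — a known source of operator confusion. The step is
flagged `close_levels`; with `merge_close` enabled the two steps collapse
into a single instruction that names the full quadrant (e.g. "go
down-right") of the on-path grandchild as seen from the first camera.
Merging is off by default.

The roadmap (ordered instructions, per-bifurcation projection geometry,
anchor metadata) exports as machine-readable JSON (lossless round trip),
numbered plain text, and a schematic PNG mosaic — one panel per bifurcation
with the projected child points, the quadrant cross, and the chosen-direction
arrow. The mosaic is deliberately schematic, not an endoluminal rendering.

## Synthetic phantoms and what the tests show

No patient data ships with the package. The phantom module rasterizes
recursive binary tube trees with exact ground truth: straight branches, a
dark lumen (−1000 HU) in a bright wall (−100 HU, 1.5 mm) on parenchyma
background (−850 HU), optional Gaussian noise, deterministic per seed.
Default geometry is anatomically plausible at desk scale: trachea 40 mm
long, 8 mm radius; per generation length ×0.75, radius ×0.79, branching
±35° in planes that alternate between two split axes, with 3° angular
jitter in seeded experiments. The grid top-aligns the superior extent, as
in a chest scan. Options reproduce specific conditions: a shortened first
trachea child places a grandchild bifurcation within a configurable
distance (the three-lumen condition), and a camera-aligned variant
(`evaluation.camera_aligned_spec`) alternates branch planes between the
approaching camera's horizontal and vertical image axes, making the full
instruction sequence analytically predictable.

Phantoms emulate calibre cascade, branching topology, HU contrast, and
noise; they do not emulate curved branches, partial-volume blur at
sub-voxel walls, stenoses, breathing motion, mucus, or scanner artifacts.
Passing phantom tests therefore demonstrates the correctness of the
pipeline's geometry and logic — topology recovery, centerline accuracy,
instruction semantics — not clinical segmentation performance on patient
CT, where thresholds and scales would need tuning against real data.

Problem sizes used by the test suite and the acceptance script: topology
recovery runs 20 seeded phantoms (generations 2–5, 128³ voxels, ~1 mm
isotropic spacing, minimum branch radius ≥ 2 voxels, ~6 s each);
segmentation Dice uses generation-3 phantoms at 96³, noiseless and at
20 HU noise; oracle-equivalence checks use 1,000 random point clouds and
1,000 random lesions.

## Known limitations

- Sub-voxel airways (radius below ~2 voxels) are not reliably segmented;
  the Dice conditions are stated for branches of radius ≥ 2 voxels.
- The instruction "up" is an anatomical convention, not the scope's actual
  roll; integrating a roll model would only change the camera up vector.
- The anchor is geometric; instrument reachability (calibre vs. tool
  diameter) is not modelled.
- Trachea auto-detection assumes the scan includes the most superior airway
  extent; scans cropped below the carina need an explicit seed.
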