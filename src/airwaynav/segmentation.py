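"""Airway lumen segmentation by thresholded multiscale tubularity.

Airway lumens are dark (air, ~ -1000 HU) tubes ringed by brighter walls.
A per-scale tubularity response is built from the eigenvalues
``lam1 <= lam2 <= lam3`` of the gamma-normalized (gamma = 2) Hessian of the
Gaussian-smoothed volume:

    R = max(lam2 * lam3 - lam1**2, 0)   where lam2 > 0 and lam3 > 0, else 0

For a dark tube the two cross-sectional second derivatives are large and
positive (lam2, lam3) while the axial one (lam1) is near zero, so R peaks on
the lumen axis and vanishes for bright tubes (polarity) and flat regions.
Scales are combined by a voxelwise maximum (multiresolution, to cover both
main and distal calibres).  Derivatives are taken in millimetres, so
anisotropic voxels are handled correctly.

The final mask is the seeded connected component of the thresholded
response, united with a HU-based region growing (< -950 HU) from the trachea
seed that secures the large proximal airways the thin-tube filter is not
tuned for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "ResponseVolume",
    "AirwayMask",
    "SegmentationError",
    "TracheaNotFoundError",
    "tubularity_at_scale",
    "appearance_map",
    "detect_trachea_seed",
    "segment_airways",
    "dice",
    "DEFAULT_SCALES_MM",
]

DEFAULT_SCALES_MM = (0.5, 1.0, 2.0, 4.0, 8.0)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    pass


class TracheaNotFoundError(RuntimeError):
    pass


@dataclass
class ResponseVolume:
    """Tubularity response with the per-voxel scale that produced it."""

    values: np.ndarray    # >= 0, same shape as source
    scale_mm: np.ndarray  # argmax scale per voxel

    def __post_init__(self) -> None:
        if self.values.shape != self.scale_mm.shape:
            raise ValueError("values/scale_mm shape mismatch")
        if self.values.min() < 0:
            raise ValueError("response must be non-negative")


@dataclass
class AirwayMask:
    """Binary lumen mask: one 26-connected component containing the seed."""

    mask: np.ndarray
    seed: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.seed = tuple(int(s) for s in self.seed)
        if not self.mask[self.seed]:
            raise ValueError("seed not inside mask")
        _, n = ndimage.label(self.mask, structure=_CONN26)
        if n != 1:
            raise ValueError(f"mask has {n} components, expected 1")


# ---------------------------------------------------------------------------
# tubularity


def _hessian_mm(img: np.ndarray, spacing: np.ndarray, sigma_mm: float) -> list[np.ndarray]:
    """Upper-triangle Hessian components (xx, xy, xz, yy, yz, zz) in mm^-2,
    gamma=2 normalized (multiplied by sigma^2)."""
    sig_vox = sigma_mm / spacing
    comps = []
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            d = ndimage.gaussian_filter(img, sig_vox, order=order, mode="nearest")
            comps.append(d * (sigma_mm ** 2 / (spacing[a] * spacing[b])))
    return comps


def _response_from_hessian(comps: list[np.ndarray], roi: np.ndarray | None) -> np.ndarray:
    shape = comps[0].shape
    if roi is None:
        roi = np.ones(shape, dtype=bool)
    H = np.empty((int(roi.sum()), 3, 3), dtype=np.float32)
    xx, xy, xz, yy, yz, zz = (c[roi] for c in comps)
    H[:, 0, 0] = xx
    H[:, 0, 1] = H[:, 1, 0] = xy
    H[:, 0, 2] = H[:, 2, 0] = xz
    H[:, 1, 1] = yy
    H[:, 1, 2] = H[:, 2, 1] = yz
    H[:, 2, 2] = zz
    lam = np.linalg.eigvalsh(H)  # ascending: lam1 <= lam2 <= lam3
    l1, l2, l3 = lam[:, 0], lam[:, 1], lam[:, 2]
    r = np.where((l2 > 0) & (l3 > 0), np.maximum(l2 * l3 - l1 ** 2, 0.0), 0.0)
    out = np.zeros(shape, dtype=np.float32)
    out[roi] = r
    return out


def tubularity_at_scale(vol: CTVolume, sigma_mm: float,
                        roi: np.ndarray | None = None) -> ResponseVolume:
    """Single-scale dark-tube Hessian response (see module docstring).

    ``roi`` optionally limits eigenvalue evaluation to a voxel subset; the
    response is zero outside it.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if sigma_mm < 0.5 * vol.spacing.min():
        raise ValueError(
            f"sigma {sigma_mm} mm is below half the smallest spacing "
            f"({vol.spacing.min()} mm): kernel undersampled")
    img = vol.voxels.astype(np.float32)
    comps = _hessian_mm(img, vol.spacing, sigma_mm)
    values = _response_from_hessian(comps, roi)
    return ResponseVolume(values=values, scale_mm=np.full(vol.shape, sigma_mm, dtype=np.float32))


def appearance_map(vol: CTVolume, scales_mm,
                   roi: np.ndarray | None = None) -> ResponseVolume:
    """Voxelwise maximum tubularity across scales; records the argmax scale."""
    scales = list(scales_mm)
    if not scales:
        raise ValueError("at least one scale required")
    best = None
    for s in scales:
        r = tubularity_at_scale(vol, s, roi=roi)
        if best is None:
            best = r
        else:
            take = r.values > best.values
            best.values[take] = r.values[take]
            best.scale_mm[take] = s
    return best


# ---------------------------------------------------------------------------
# trachea seed


def _superior_axis(vol: CTVolume) -> tuple[int, int]:
    """(voxel axis most aligned with world superior, +1/-1 index direction)."""
    zrow = vol.affine[2, :3]
    axis = int(np.argmax(np.abs(zrow)))
    return axis, (1 if zrow[axis] > 0 else -1)


def detect_trachea_seed(vol: CTVolume, hu_threshold: float = -900.0,
                        area_range_mm2=(20.0, 2000.0),
                        min_circularity: float = 0.3) -> tuple[int, int, int]:
    """Locate a trachea seed voxel in the most superior tenth of the volume.

    Looks for the largest near-circular dark (< -900 HU) component over the
    top 10% of axial slices and returns a voxel inside it near its centroid.
    """
    axis, sign = _superior_axis(vol)
    n = vol.shape[axis]
    band = max(3, int(np.ceil(0.1 * n)))
    sl = [slice(None)] * 3
    sl[axis] = slice(n - band, n) if sign > 0 else slice(0, band)
    sub = vol.voxels[tuple(sl)]
    dark = sub < hu_threshold
    in_plane_axes = [a for a in range(3) if a != axis]
    vox_area = float(np.prod(vol.spacing[in_plane_axes]))

    labels, nlab = ndimage.label(dark, structure=_CONN26)
    best = None
    for lab in range(1, nlab + 1):
        comp = labels == lab
        nslices = len(np.unique(np.nonzero(comp)[axis]))
        area = comp.sum() / nslices * vox_area  # mean cross-sectional area
        if not (area_range_mm2[0] <= area <= area_range_mm2[1]):
            continue
        if _mid_slice_circularity(comp, axis) < min_circularity:
            continue
        if best is None or comp.sum() > best[1]:
            best = (lab, comp.sum())
    if best is None:
        raise TracheaNotFoundError("trachea not found")
    comp = labels == best[0]
    pts = np.argwhere(comp)
    centroid = pts.mean(axis=0)
    seed_local = pts[np.argmin(np.linalg.norm(pts - centroid, axis=1))]
    seed = list(seed_local)
    seed[axis] += (n - band) if sign > 0 else 0
    return tuple(int(s) for s in seed)


def _mid_slice_circularity(comp: np.ndarray, axis: int) -> float:
    """4*pi*A / P^2 of the component's middle occupied slice (1 = circle)."""
    from skimage import measure

    occupied = np.unique(np.nonzero(comp)[axis])
    mid = occupied[len(occupied) // 2]
    sl = [slice(None)] * 3
    sl[axis] = mid
    plane = comp[tuple(sl)]
    area = plane.sum()
    per = measure.perimeter(plane)
    if per == 0:
        return 1.0  # single-voxel cross-section
    return float(4 * np.pi * area / per ** 2)


# ---------------------------------------------------------------------------
# region growing and the full segmentation


def _region_grow(cand: np.ndarray, seed: tuple[int, int, int],
                 leak_factor: float = 4.0, warmup: int = 10) -> np.ndarray:
    """26-connected front growth of ``seed`` within ``cand``.

    A front whose per-iteration voxel gain exceeds ``leak_factor`` times the
    running median gain (after a warm-up) aborts further growth — the classic
    guard against explosion into lung parenchyma.
    """
    cur = np.zeros_like(cand)
    cur[seed] = True
    gains: list[int] = []
    while True:
        new = ndimage.binary_dilation(cur, structure=_CONN26, mask=cand)
        gain = int(new.sum() - cur.sum())
        if gain == 0:
            break
        if len(gains) >= warmup and gain > leak_factor * float(np.median(gains)):
            break
        cur = new
        gains.append(gain)
    return cur


def segment_airways(vol: CTVolume, scales_mm=DEFAULT_SCALES_MM,
                    tau: float | str = "auto",
                    seed: tuple[int, int, int] | None = None,
                    grow_from_seed: bool = True,
                    grow_hu: float = -950.0,
                    air_max_hu: float = -900.0) -> AirwayMask:
    """Segment the airway lumen as a single seeded connected component.

    The mask is the 26-connected component containing the trachea seed of
    ``{appearance_map >= tau}`` united with the region grown from the seed
    over voxels below ``grow_hu``.  ``tau="auto"`` uses the Otsu threshold of
    the nonzero response histogram.
    """
    if seed is None:
        seed = detect_trachea_seed(vol)
    seed = tuple(int(s) for s in seed)
    if not all(0 <= seed[a] < vol.shape[a] for a in range(3)):
        raise ValueError("seed outside volume")

    usable = [s for s in scales_mm if s >= 0.5 * vol.spacing.min()]
    if not usable:
        raise SegmentationError("segmentation failed: no scale resolvable at this spacing")
    if len(usable) < len(list(scales_mm)):
        import warnings
        warnings.warn(f"dropping {len(list(scales_mm)) - len(usable)} scale(s) "
                      f"below half the voxel spacing")

    # evaluate the (expensive) eigen-response only near dark voxels; the
    # response is defined zero far from any lumen anyway
    air = vol.voxels < air_max_hu
    roi = ndimage.binary_dilation(air, structure=_CONN26, iterations=2)
    amap = appearance_map(vol, usable, roi=roi)

    if tau == "auto":
        nz = amap.values[amap.values > 0]
        if nz.size < 2:
            raise SegmentationError("segmentation failed: empty response map")
        from skimage.filters import threshold_otsu
        tau = float(threshold_otsu(nz))
    if tau <= 0:
        raise ValueError("tau must be positive")

    # the lumen is air: a bright voxel can score high on tubularity (e.g.
    # the shell just outside a wall) but cannot be lumen
    cand = (amap.values >= tau) & air
    if grow_from_seed:
        grown = _region_grow(vol.voxels < grow_hu, seed)
        cand = cand | grown
    if not cand.any():
        raise SegmentationError(
            f"segmentation failed: thresholded set empty "
            f"(max response {float(amap.values.max()):.4g}, tau {tau:.4g})")
    labels, n = ndimage.label(cand, structure=_CONN26)
    if labels[seed] == 0:
        raise SegmentationError(
            f"segmentation failed: seed disconnected "
            f"(components {n}, max response {float(amap.values.max()):.4g})")
    mask = labels == labels[seed]
    return AirwayMask(mask=mask, seed=seed, affine=vol.affine)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
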