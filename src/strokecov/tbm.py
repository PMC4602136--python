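"""Tensor-based morphometry maps and synthetic datasets.

Local volume change between two time points is quantified by the Jacobian
determinant of the deformation mapping one image onto the other: det > 1
means expansion, det < 1 contraction.  The module also provides the standard
post-processing (modulation by a tissue segmentation, isotropic Gaussian
smoothing at a given FWHM) and a generator of synthetic subject maps with
known embedded covariance patterns, behavioral coupling and subgroup-specific
lesion masks — the ground truth against which the covariance decomposition is
validated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import DeformationField, VolumeMap

__all__ = [
    "TBMDatasetTruth",
    "jacobian_determinant",
    "modulate",
    "gaussian_smooth",
    "fwhm_to_sigma",
    "synth_tbm_dataset",
    "roi_gmv_change",
    "default_brain_mask",
    "make_smooth_patterns",
    "make_lesion_masks",
]

#: FWHM of a Gaussian = sigma * sqrt(8 ln 2)
_FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian sigma in voxels for a FWHM given in mm."""
    return fwhm_mm / _FWHM_PER_SIGMA / voxel_size_mm


def jacobian_determinant(field: DeformationField) -> VolumeMap:
    """Voxelwise determinant of the Jacobian of the mapping x -> x + u(x).

    Spatial gradients of the displacement are taken by central differences
    (one-sided at the borders) with the voxel size as spacing; the identity
    is added so a zero field yields determinant 1 everywhere.  Non-positive
    determinants (folding / non-invertible mapping) are counted and reported
    through a warning, not an exception.
    """
    if min(field.data.shape[:3]) < 2:
        raise ValueError("grid must be >= 2 voxels along each axis")
    h = field.voxel_size_mm
    J = np.empty(field.data.shape[:3] + (3, 3))
    for i in range(3):
        grads = np.gradient(field.data[..., i], h, axis=(0, 1, 2))
        for j in range(3):
            J[..., i, j] = grads[j]
        J[..., i, i] += 1.0
    det = np.linalg.det(J)
    n_bad = int((det <= 0).sum())
    if n_bad:
        warnings.warn(f"degenerate mapping: {n_bad} voxel(s) with determinant <= 0")
    return VolumeMap(det, field.voxel_size_mm, field.origin_mm, name="jacobian")


def modulate(jacobian: VolumeMap, segmentation: VolumeMap) -> VolumeMap:
    """Voxelwise product of a Jacobian map with a tissue segmentation."""
    jacobian.check_geometry(segmentation)
    return jacobian.with_data(jacobian.data * segmentation.data, name="modulated")


def gaussian_smooth(vmap: VolumeMap, fwhm_mm: float, mode: str = "reflect") -> VolumeMap:
    """Isotropic 3-D Gaussian smoothing at the given FWHM (mm).

    ``fwhm_mm = 0`` is the identity.  The default reflective boundary
    preserves the total sum to machine precision.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return vmap.with_data(vmap.data.copy())
    sigma = fwhm_to_sigma(fwhm_mm, vmap.voxel_size_mm)
    return vmap.with_data(gaussian_filter(np.asarray(vmap.data, dtype=float), sigma, mode=mode))


def roi_gmv_change(vmap: VolumeMap, roi: VolumeMap, mode: str = "change") -> float:
    """Mean volume change over a region of interest, as a signed fraction.

    ``mode="jacobian"`` treats the map as a raw Jacobian-modulated map and
    averages (value - 1); ``mode="change"`` averages the values directly.
    0.01 means +1% local volume gain.
    """
    vmap.check_geometry(roi)
    if mode not in ("jacobian", "change"):
        raise ValueError("mode must be 'jacobian' or 'change'")
    sel = roi.data > 0
    if not sel.any():
        raise ValueError("empty ROI")
    vals = vmap.data[sel]
    return float(np.mean(vals - 1.0 if mode == "jacobian" else vals))


@dataclass
class TBMDatasetTruth:
    """Ground truth of a synthetic TBM dataset.

    ``patterns`` are the spatial covariance patterns actually embedded in the
    delivered maps (pairwise orthonormal over the mask); ``loadings`` the
    subjects x patterns coefficient matrix; ``lesion_masks`` one binary
    :class:`VolumeMap` per subject; ``lesion_volumes_cc`` their volumes.
    """

    patterns: list[VolumeMap]
    loadings: np.ndarray
    noise_sd: float
    mask: VolumeMap
    lesion_masks: list[VolumeMap] | None = None
    lesion_volumes_cc: np.ndarray | None = None


def default_brain_mask(shape=(32, 32, 32), voxel_size_mm: float = 2.0) -> VolumeMap:
    """Spherical 'brain' mask filling ~85% of the grid radius."""
    shape = tuple(shape)
    center = (np.asarray(shape) - 1) / 2.0
    radius = 0.85 * min(shape) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return VolumeMap((r2 <= radius**2).astype(np.float32), voxel_size_mm, name="brain_mask")


def make_smooth_patterns(
    mask: VolumeMap,
    n_patterns: int,
    rng: np.random.Generator,
    fwhm_mm: float = 12.0,
) -> list[VolumeMap]:
    """Smooth, orthonormal (over the mask) spatial patterns.

    White noise is smoothed to the requested spatial scale, masked, and the
    resulting vectors orthonormalized; each is then rescaled to unit RMS over
    the mask so a loading of 1 contributes a per-voxel sd of ~1.
    """
    sel = mask.data > 0
    n_vox = int(sel.sum())
    if n_patterns >= n_vox:
        raise ValueError("more patterns than mask voxels")
    sigma = fwhm_to_sigma(fwhm_mm, mask.voxel_size_mm)
    vecs = np.empty((n_vox, n_patterns))
    for k in range(n_patterns):
        fld = gaussian_filter(rng.normal(size=mask.shape), sigma, mode="reflect")
        vecs[:, k] = fld[sel]
    q, _ = np.linalg.qr(vecs)
    q *= np.sqrt(n_vox)  # unit RMS columns, still pairwise orthogonal
    patterns = []
    for k in range(n_patterns):
        arr = np.zeros(mask.shape)
        arr[sel] = q[:, k]
        patterns.append(mask.with_data(arr, name=f"pattern_{k + 1}"))
    return patterns


def _correlated_loadings(
    n: int,
    targets: list[np.ndarray],
    strengths: list[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance loading vector with prescribed correlations to targets.

    Targets are orthonormalized first; the residual weight keeps total
    variance at 1, so each requested correlation is the population value.
    """
    if not targets:
        return rng.normal(size=n)
    for s in strengths:
        if not -1 < s < 1:
            raise ValueError(f"correlation strength {s} outside (-1, 1)")
    Z = np.column_stack([(t - np.mean(t)) / np.std(t) for t in targets])
    Q, _ = np.linalg.qr(Z)
    Q *= np.sqrt(n)  # unit-variance orthogonal columns
    w = np.asarray(strengths, dtype=float)
    tot = float(w @ w)
    if tot >= 1:
        raise ValueError("combined correlation strengths exceed 1")
    return Q @ w + np.sqrt(1 - tot) * rng.normal(size=n)


# Class-typical lesion centers (fractional grid coordinates) and median
# volumes in cc: the impaired subgroup carries the largest lesions.
_LESION_SPEC = {
    "fast": ((0.68, 0.40, 0.60), 7.8),
    "slow": ((0.62, 0.55, 0.62), 3.5),
    "impaired": ((0.66, 0.48, 0.55), 42.8),
}


def make_lesion_masks(
    mask: VolumeMap,
    classes: list[str],
    rng: np.random.Generator,
) -> tuple[list[VolumeMap], np.ndarray]:
    """Subgroup-specific spherical lesion masks inside the brain mask.

    Lesion volume is log-normal around the class-typical median; the center
    jitters by a couple of voxels around the class-typical site.
    """
    sel = mask.data > 0
    shape = np.asarray(mask.shape)
    vv = mask.voxel_volume_cc
    grids = np.ogrid[tuple(slice(0, s) for s in mask.shape)]
    masks, volumes = [], []
    for cls in classes:
        frac_center, median_cc = _LESION_SPEC[cls]
        vol_cc = float(median_cc * np.exp(rng.normal(0.0, 0.8)))
        center = shape * np.asarray(frac_center) + rng.normal(0, 1.0, size=3)
        radius_vox = (3.0 * vol_cc / vv / (4.0 * np.pi)) ** (1.0 / 3.0)
        r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        lesion = (r2 <= radius_vox**2) & sel
        masks.append(mask.with_data(lesion.astype(np.float32), name=f"lesion_{cls}"))
        volumes.append(float(lesion.sum()) * vv)
    return masks, np.asarray(volumes)


def synth_tbm_dataset(
    n_subjects: int,
    n_patterns: int = 3,
    seed: int = 0,
    mask: VolumeMap | None = None,
    noise_sd: float = 0.1,
    pattern_sds: np.ndarray | None = None,
    behavior: np.ndarray | None = None,
    behavior_corr: float = 0.0,
    behavior_pattern: int = 1,
    lesion_classes: list[str] | None = None,
    lesion_corr: float = 0.0,
    smooth_fwhm_mm: float = 12.0,
) -> tuple[list[VolumeMap], TBMDatasetTruth]:
    """Synthetic volume-change maps with embedded covariance patterns.

    Each subject map is ``1 + sum_k loading[s, k] * pattern_k + noise`` where
    the patterns are smooth and orthonormal over the brain mask and the noise
    is a smooth random field rescaled to sd ``noise_sd`` (both at
    ``smooth_fwhm_mm``, emulating the 12-mm kernel of the morphometry
    pipeline; the stored truth patterns are exactly the patterns embedded in
    the delivered maps).  The loading of ``behavior_pattern`` can be given a
    population correlation ``behavior_corr`` with a supplied behavioral
    vector and ``lesion_corr`` with log lesion volume.

    Returns the subject maps and the :class:`TBMDatasetTruth`.
    """
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    root = np.random.SeedSequence(seed)
    rng_pat, rng_load, rng_noise, rng_les = (np.random.default_rng(s) for s in root.spawn(4))
    if mask is None:
        mask = default_brain_mask()
    sel = mask.data > 0
    n_vox = int(sel.sum())
    patterns = make_smooth_patterns(mask, n_patterns, rng_pat, fwhm_mm=smooth_fwhm_mm)
    if pattern_sds is None:
        pattern_sds = 0.02 * np.ones(n_patterns)
    pattern_sds = np.asarray(pattern_sds, dtype=float)

    lesion_masks = lesion_volumes = None
    if lesion_classes is not None:
        lesion_masks, lesion_volumes = make_lesion_masks(mask, lesion_classes, rng_les)

    loadings = np.empty((n_subjects, n_patterns))
    for k in range(n_patterns):
        targets, strengths = [], []
        if k == behavior_pattern:
            if behavior is not None and behavior_corr != 0.0:
                targets.append(np.asarray(behavior, dtype=float))
                strengths.append(behavior_corr)
            if lesion_volumes is not None and lesion_corr != 0.0:
                targets.append(np.log(lesion_volumes))
                strengths.append(lesion_corr)
        loadings[:, k] = pattern_sds[k] * _correlated_loadings(n_subjects, targets, strengths, rng_load)

    P = np.stack([p.data[sel] for p in patterns], axis=1)  # voxels x patterns
    sigma = fwhm_to_sigma(smooth_fwhm_mm, mask.voxel_size_mm)
    maps = []
    for s in range(n_subjects):
        arr = np.ones(mask.shape)
        arr[sel] += P @ loadings[s]
        if noise_sd > 0:
            fld = gaussian_filter(rng_noise.normal(size=mask.shape), sigma, mode="reflect")
            fld /= fld[sel].std()
            arr[sel] += noise_sd * np.mean(pattern_sds) * fld[sel]
        maps.append(mask.with_data(arr, name=f"subject_{s + 1:02d}"))
    truth = TBMDatasetTruth(
        patterns=patterns,
        loadings=loadings,
        noise_sd=noise_sd,
        mask=mask,
        lesion_masks=lesion_masks,
        lesion_volumes_cc=lesion_volumes,
    )
    return maps, truth
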