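"""Voxelwise structural covariance decomposition (scaled-subprofile-style PCA).

The masked scans x voxels matrix is double centered — from every element the
row mean and the column mean are subtracted and the grand mean added back, so
the residual matrix has vanishing row, column and grand means — and then
factored by singular value decomposition.  Each component consists of an
*eigenimage* (unit-norm voxel pattern), a vector of per-scan *expression
coefficients* (unit-norm, hence bounded by [-1, 1]) and a singular value
whose square is proportional to the fraction of variance explained.

Note the classic scaled-subprofile model takes logarithms before centering;
here the volume-change values are centered directly, since they already live
on a ratio-around-1 scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stats import critical_r, pearson_r
from .volume import VolumeMap

__all__ = [
    "ResidualMatrix",
    "SSMDecomposition",
    "build_data_matrix",
    "double_center",
    "ssm_decompose",
    "component_expression",
    "select_networks",
    "backproject",
    "cumulative_variance_pct",
]


def cumulative_variance_pct(variance_pcts) -> float:
    """Cumulative explained variance of a set of components, in percent,
    rounded to one decimal as printed in selection reports."""
    return round(float(np.sum(np.asarray(variance_pcts, dtype=float))), 1)

_CENTER_TOL = 1e-10


@dataclass
class ResidualMatrix:
    """Double-centered scans x voxels matrix with its voxel bookkeeping."""

    matrix: np.ndarray
    voxel_indices: np.ndarray  # flat indices of in-mask voxels, raster order
    scan_ids: list[str]
    shape: tuple[int, int, int]
    voxel_size_mm: float
    origin_mm: tuple[float, float, float]

    def check_centered(self) -> None:
        R = self.matrix
        if (
            np.abs(R.mean()) > _CENTER_TOL
            or np.abs(R.mean(axis=0)).max() > _CENTER_TOL
            or np.abs(R.mean(axis=1)).max() > _CENTER_TOL
        ):
            raise ValueError("matrix is not double centered")


@dataclass
class SSMDecomposition:
    """SVD of a double-centered scans x voxels residual matrix.

    ``eigenimages`` is components x voxels with unit-norm rows;
    ``coefficients`` scans x components with unit-norm columns;
    ``singular_values`` descending; ``variance_fractions`` sum to 1 over the
    non-null components.
    """

    eigenimages: np.ndarray
    coefficients: np.ndarray
    singular_values: np.ndarray
    variance_fractions: np.ndarray
    voxel_indices: np.ndarray
    scan_ids: list[str]
    shape: tuple[int, int, int]
    voxel_size_mm: float
    origin_mm: tuple[float, float, float]

    @property
    def n_components(self) -> int:
        return self.singular_values.size


def build_data_matrix(maps: list[VolumeMap], mask: VolumeMap) -> tuple[np.ndarray, np.ndarray]:
    """Stack masked maps into a scans x voxels matrix.

    Returns the matrix and the flat in-mask voxel indices (fixed raster
    order) used for back-projection.
    """
    sel = np.asarray(mask.data) > 0
    if not sel.any():
        raise ValueError("empty mask")
    for m in maps:
        mask.check_geometry(m)
    voxel_indices = np.flatnonzero(sel)
    X = np.stack([np.asarray(m.data).reshape(-1)[voxel_indices] for m in maps])
    return X, voxel_indices


def double_center(matrix: np.ndarray) -> np.ndarray:
    """Remove row means and column means, adding back the grand mean.

    R_ij = X_ij - colmean_j - rowmean_i + grandmean.  Idempotent; the result
    has row, column and grand means all below 1e-10 in magnitude.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with >= 2 rows and >= 2 columns")
    return X - X.mean(axis=0, keepdims=True) - X.mean(axis=1, keepdims=True) + X.mean()


def residual_from_maps(maps: list[VolumeMap], mask: VolumeMap, scan_ids=None) -> ResidualMatrix:
    """Convenience: masked data matrix, double centered, with geometry."""
    X, voxel_indices = build_data_matrix(maps, mask)
    if scan_ids is None:
        scan_ids = [m.name or f"scan_{i + 1:02d}" for i, m in enumerate(maps)]
    return ResidualMatrix(
        matrix=double_center(X),
        voxel_indices=voxel_indices,
        scan_ids=list(scan_ids),
        shape=mask.shape,
        voxel_size_mm=mask.voxel_size_mm,
        origin_mm=mask.origin_mm,
    )


def ssm_decompose(residual: ResidualMatrix, sign_convention: str = "peak_positive") -> SSMDecomposition:
    """Thin SVD of the residual matrix into covariance components.

    Components are ordered by descending singular value; trailing numerically
    null components (double centering bounds the rank at min(scans, voxels)
    - 1) are dropped.  Variance fraction_i = sigma_i^2 / sum(sigma^2).  With
    the default sign convention each eigenimage's largest-magnitude voxel is
    positive, the coefficient column being flipped jointly;
    ``sign_convention="none"`` leaves the raw SVD signs.
    """
    residual.check_centered()
    try:
        U, s, Vt = np.linalg.svd(residual.matrix, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical pathology
        R = residual.matrix
        raise np.linalg.LinAlgError(
            f"SVD failed on {R.shape} matrix (finite: {np.isfinite(R).all()}, "
            f"fro-norm: {np.linalg.norm(R):.3g})"
        ) from exc
    tol = max(residual.matrix.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    if sign_convention == "peak_positive" and s.size:
        flip = np.sign(Vt[np.arange(s.size), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        Vt = Vt * flip[:, None]
        U = U * flip[None, :]
    elif sign_convention not in ("peak_positive", "none"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    total = float(np.sum(s**2))
    return SSMDecomposition(
        eigenimages=Vt,
        coefficients=U,
        singular_values=s,
        variance_fractions=s**2 / total if total > 0 else s,
        voxel_indices=residual.voxel_indices,
        scan_ids=residual.scan_ids,
        shape=residual.shape,
        voxel_size_mm=residual.voxel_size_mm,
        origin_mm=residual.origin_mm,
    )


def component_expression(decomp: SSMDecomposition, component: int) -> np.ndarray:
    """Unit-norm per-scan expression coefficients of one component.

    Because of the row centering the coefficients sum to ~0 across scans.
    """
    if not 0 <= component < decomp.n_components:
        raise IndexError(f"component {component} out of range [0, {decomp.n_components})")
    return decomp.coefficients[:, component]


def backproject(decomp: SSMDecomposition, component: int) -> VolumeMap:
    """Eigenimage of one component as a volume (zeros outside the mask)."""
    if not 0 <= component < decomp.n_components:
        raise IndexError(f"component {component} out of range [0, {decomp.n_components})")
    arr = np.zeros(int(np.prod(decomp.shape)))
    arr[decomp.voxel_indices] = decomp.eigenimages[component]
    return VolumeMap(
        arr.reshape(decomp.shape),
        decomp.voxel_size_mm,
        decomp.origin_mm,
        name=f"eigenimage_{component + 1}",
    )


def select_networks(
    decomp: SSMDecomposition,
    externals: dict[str, np.ndarray],
    alpha: float = 0.05,
    m: int = 8,
    components: list[int] | None = None,
) -> "pd.DataFrame":
    """Screen components against external variables by Pearson correlation.

    Every (component, variable) pair is correlated; a pair is significant
    when |r| exceeds the critical correlation at the Bonferroni-corrected
    per-comparison alpha (``alpha / m``, two-tailed, n - 2 df).  Returns a
    long-format report (component, variance %, variable, r, critical r,
    selected) mirroring a network-selection table; constant externals are
    flagged as undefined and never selected.
    """
    import pandas as pd

    n = decomp.coefficients.shape[0]
    if components is None:
        components = list(range(decomp.n_components))
    r_crit = critical_r(n, alpha / m, tails="two")
    rows = []
    for c in components:
        coeff = component_expression(decomp, c)
        for name, values in externals.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (n,):
                raise ValueError(f"external {name!r} must have one value per scan")
            if np.std(values) == 0:
                warnings.warn(f"external {name!r} is constant; correlation undefined")
                r = np.nan
            else:
                r = pearson_r(coeff, values)
            rows.append(
                {
                    "component": c + 1,
                    "variance_pct": 100 * decomp.variance_fractions[c],
                    "variable": name,
                    "r": r,
                    "critical_r": r_crit,
                    "significant": bool(np.abs(r) > r_crit) if np.isfinite(r) else False,
                }
            )
    report = pd.DataFrame(rows)
    report["component_selected"] = report.groupby("component")["significant"].transform("any")
    return report
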