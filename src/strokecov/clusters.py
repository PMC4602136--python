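"""Cluster delineation on eigenimages and lesion-overlap volumetrics.

An eigenimage is thresholded at the first and ninety-ninth percentile of its
in-mask voxel values (inclusive tails, linear-interpolation percentiles);
surviving voxels are grouped into connected components and components below
the extent threshold (32 voxels by default, the minimal resolution element
of the smoothed maps) are discarded.  Subgroup lesion-density maps — the
per-voxel fraction of lesioned patients, binarized at a strict >20% — are
then intersected with the clusters, yielding overlap volume in cc, percent
of the lesion map falling on the cluster and percent of the cluster
affected.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .volume import VolumeMap

__all__ = [
    "ClusterTable",
    "LesionDensityMap",
    "threshold_eigenimage",
    "connected_clusters",
    "lesion_density",
    "lesion_volume",
    "overlap_volumetrics",
    "overlap_percentages",
]

#: neighborhood spec (voxel neighbors) -> skimage connectivity order
_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterTable:
    """Supra-threshold clusters of one tail of an eigenimage.

    ``table`` has one row per cluster (label, sign, size_vox, volume_cc,
    peak mm coordinates, peak value), sorted by size descending;
    ``label_map`` assigns each voxel its cluster label (0 = background).
    """

    table: pd.DataFrame
    label_map: VolumeMap
    sign: str  # "positive" (low tail by convention) or "negative"
    connectivity: int
    k_min: int

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LesionDensityMap:
    """Per-voxel lesioned-subject fraction for one recovery subgroup."""

    density: VolumeMap  # values in [0, 1]
    thresholded: VolumeMap  # binary, strict > threshold
    subgroup: str
    threshold: float
    volume_cc: float  # volume of the thresholded map


def threshold_eigenimage(
    image: VolumeMap,
    mask: VolumeMap,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> tuple[VolumeMap, VolumeMap]:
    """Split an eigenimage into its extreme-percentile tails.

    Percentiles are computed over in-mask voxel values only (linear
    interpolation between order statistics); the low-tail map keeps voxels
    <= P(low_pct), the high-tail map voxels >= P(high_pct) — inclusive, so
    the percentile voxel itself survives.  A degenerate (constant) image
    yields two empty tails with a warning.
    """
    if not 0 < low_pct < high_pct < 100:
        raise ValueError("need 0 < low_pct < high_pct < 100")
    image.check_geometry(mask)
    sel = np.asarray(mask.data) > 0
    if not sel.any():
        raise ValueError("empty mask")
    vals = np.asarray(image.data)[sel]
    p_low, p_high = np.percentile(vals, [low_pct, high_pct])
    if p_low >= p_high:
        warnings.warn("degenerate (near-constant) image: returning empty tails")
        empty = np.zeros(image.shape, dtype=np.uint8)
        return image.with_data(empty, "low_tail"), image.with_data(empty.copy(), "high_tail")
    low = (np.asarray(image.data) <= p_low) & sel
    high = (np.asarray(image.data) >= p_high) & sel
    return (
        image.with_data(low.astype(np.uint8), "low_tail"),
        image.with_data(high.astype(np.uint8), "high_tail"),
    )


def connected_clusters(
    binary: VolumeMap,
    connectivity: int = 18,
    k_min: int = 32,
    values: VolumeMap | None = None,
    sign: str = "positive",
) -> ClusterTable:
    """Connected-component labeling with an extent threshold.

    ``connectivity`` counts voxel neighbors (6 face, 18 face+edge, 26
    face+edge+corner).  Components smaller than ``k_min`` voxels are
    discarded; survivors are relabeled 1..K by decreasing size.  If the
    source ``values`` image is supplied, each cluster's peak voxel (largest
    |value|) and peak value are reported; peak coordinates are in mm.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if values is not None:
        binary.check_geometry(values)
    arr = np.asarray(binary.data) > 0
    labels = cc_label(arr, connectivity=_CONNECTIVITY[connectivity])
    sizes = np.bincount(labels.reshape(-1))
    keep = [lab for lab in range(1, sizes.size) if sizes[lab] >= k_min]
    keep.sort(key=lambda lab: -sizes[lab])
    out_labels = np.zeros_like(labels)
    rows = []
    vv = binary.voxel_volume_cc
    for new, lab in enumerate(keep, start=1):
        sel = labels == lab
        out_labels[sel] = new
        size = int(sizes[lab])
        row = {
            "label": new,
            "sign": sign,
            "size_vox": size,
            "volume_cc": size * vv,
        }
        if values is not None:
            vals = np.asarray(values.data)
            idx = np.argwhere(sel)
            peak = idx[np.argmax(np.abs(vals[sel]))]
            peak_mm = binary.voxel_to_mm(peak)
            row.update(
                peak_x_mm=peak_mm[0],
                peak_y_mm=peak_mm[1],
                peak_z_mm=peak_mm[2],
                peak_value=float(vals[tuple(peak)]),
            )
        rows.append(row)
    cols = ["label", "sign", "size_vox", "volume_cc"] + (
        ["peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_value"] if values is not None else []
    )
    table = pd.DataFrame(rows, columns=cols)
    return ClusterTable(
        table=table,
        label_map=binary.with_data(out_labels, "cluster_labels"),
        sign=sign,
        connectivity=connectivity,
        k_min=k_min,
    )


def lesion_density(
    lesions: list[VolumeMap],
    threshold: float = 0.20,
    subgroup: str = "",
) -> LesionDensityMap:
    """Subgroup lesion-density map, binarized at a strict ``> threshold``."""
    if not lesions:
        raise ValueError("need at least one lesion mask")
    first = lesions[0]
    stack = []
    for les in lesions:
        first.check_geometry(les)
        stack.append(np.asarray(les.data) > 0)
    density = np.mean(stack, axis=0)
    thresholded = (density > threshold).astype(np.uint8)
    return LesionDensityMap(
        density=first.with_data(density, f"lesion_density_{subgroup}"),
        thresholded=first.with_data(thresholded, f"lesion_density_{subgroup}_thr"),
        subgroup=subgroup,
        threshold=threshold,
        volume_cc=float(thresholded.sum()) * first.voxel_volume_cc,
    )


def lesion_volume(lesion: VolumeMap) -> float:
    """Volume of a binary lesion mask in cc (voxel count x voxel volume)."""
    if not lesion.is_binary():
        raise ValueError("lesion mask must contain only 0/1 values")
    return float(np.asarray(lesion.data).sum()) * lesion.voxel_volume_cc


def overlap_percentages(overlap_cc: float, lesion_cc: float, cluster_cc: float):
    """Percent-of-lesion and percent-of-cluster for one overlap, one decimal.

    Zero-volume denominators yield NaN (reported as undefined).
    """
    pol = 100.0 * overlap_cc / lesion_cc if lesion_cc > 0 else np.nan
    poc = 100.0 * overlap_cc / cluster_cc if cluster_cc > 0 else np.nan
    return pol, poc


def overlap_volumetrics(
    clusters: ClusterTable | list[ClusterTable],
    density_maps: list[LesionDensityMap],
) -> pd.DataFrame:
    """Volumetric intersection of network clusters with subgroup lesion maps.

    One row per (subgroup, cluster): overlap volume in cc, percent of the
    thresholded lesion-density map lying on the cluster, and percent of the
    cluster affected by the lesion map.  Percentages are rounded to one
    decimal in the report; raw cc values are kept at full precision.
    """
    tables = clusters if isinstance(clusters, list) else [clusters]
    rows = []
    for dmap in density_maps:
        les = np.asarray(dmap.thresholded.data) > 0
        for ct in tables:
            ct.label_map.check_geometry(dmap.thresholded)
            vv = ct.label_map.voxel_volume_cc
            lab = np.asarray(ct.label_map.data)
            for _, cl in ct.table.iterrows():
                ov_vox = int(np.sum(les & (lab == cl["label"])))
                ov_cc = ov_vox * vv
                pol, poc = overlap_percentages(ov_cc, dmap.volume_cc, cl["volume_cc"])
                rows.append(
                    {
                        "subgroup": dmap.subgroup,
                        "lesion_map_cc": dmap.volume_cc,
                        "cluster": f"{cl['label']}{'+' if ct.sign == 'positive' else '-'}",
                        "cluster_cc": cl["volume_cc"],
                        "overlap_cc": ov_cc,
                        "pct_of_lesion": round(pol, 1) if np.isfinite(pol) else np.nan,
                        "pct_of_cluster": round(poc, 1) if np.isfinite(poc) else np.nan,
                    }
                )
    return pd.DataFrame(rows)
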