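"""Nuclear-fraction quantification of a transcription factor in 3D stacks.

The segmentation chain follows the standard confocal workflow for
nucleo-cytoplasmic partitioning of YAP/TAZ-class factors: median-filter the
nuclear-dye channel, threshold, refine by morphological opening, declump
touching nuclei by a seeded 3D watershed (seeds = regional maxima of the
physical distance transform, dilated in-plane), then assign cytoplasm to
the nearest nucleus within a maximum physical distance. Cells touching the
lateral image border or with small (< 147 um^3) or fragmented nuclei are
discarded. The per-cell statistic is

    f = (signal integrated over the nucleus) / (signal over the whole cell)

and each image is summarised by the mean f of its cells; groups of images
are compared with a two-sided unpaired t-test (image = statistical unit).

All spatial parameters are physical (micrometres) and converted to voxels
through each stack's geometry, so they transfer across magnifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import local_maxima
from skimage.segmentation import watershed


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel edge lengths in micrometres, (z, y, x) order."""

    z: float
    y: float
    x: float

    def __post_init__(self) -> None:
        if min(self.z, self.y, self.x) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def sampling(self) -> tuple[float, float, float]:
        return (self.z, self.y, self.x)

    @property
    def voxel_volume(self) -> float:
        return self.z * self.y * self.x

    def radii_to_voxels(self, radii_um: tuple[float, float, float]) -> tuple[int, int, int]:
        return tuple(int(round(r / v)) for r, v in zip(radii_um, self.sampling))


@dataclass(frozen=True)
class NucSegParams:
    # Defaults are the workflow's published physical radii.
    median_radius_um: tuple[float, float, float] = (0.6, 0.5, 0.5)  # (z, y, x)
    opening_radius_um: tuple[float, float, float] = (0.0, 0.7, 0.7)
    seed_dilation_um: tuple[float, float, float] = (0.0, 2.1, 2.1)  # in-plane only
    cytoplasm_distance_um: tuple[float, float, float] = (74.6, 17.7, 17.7)
    threshold: float | None = None  # absolute intensity; None -> Otsu
    min_nuclear_volume_um3: float = 147.0


@dataclass
class CellFractionRecord:
    cell: int
    nuclear_volume_um3: float
    cell_volume_um3: float
    nuclear_fluorescence: float
    cell_fluorescence: float
    nuclear_fraction: float
    excluded: str = ""  # "", "small", "border", "fragmented", "no_signal"


def _ellipsoid_footprint(radii_vox: tuple[int, int, int]) -> np.ndarray:
    rz, ry, rx = (max(int(r), 0) for r in radii_vox)
    zz, yy, xx = np.ogrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    return (
        (zz / max(rz, 1)) ** 2 + (yy / max(ry, 1)) ** 2 + (xx / max(rx, 1)) ** 2
    ) <= 1.0


def segment_nuclei(
    volume: np.ndarray,
    geometry: VoxelGeometry,
    params: NucSegParams = NucSegParams(),
) -> np.ndarray:
    """Label the nuclei of a 3D nuclear-dye volume, splitting touching ones.

    Median filter -> threshold -> 3D opening -> watershed declumping with
    seeds from the regional maxima of the anisotropic distance transform,
    dilated in-plane. Returns an int32 label volume (0 = background).
    """
    if volume.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    vol = volume.astype(float)
    med_size = tuple(2 * r + 1 for r in geometry.radii_to_voxels(params.median_radius_um))
    vol = ndi.median_filter(vol, size=med_size)
    if vol.max() == vol.min():
        return np.zeros(volume.shape, dtype=np.int32)
    thr = params.threshold if params.threshold is not None else float(threshold_otsu(vol))
    mask = vol > thr
    open_fp = _ellipsoid_footprint(geometry.radii_to_voxels(params.opening_radius_um))
    mask = ndi.binary_opening(mask, structure=open_fp)
    if not mask.any():
        return np.zeros(volume.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask, sampling=geometry.sampling)
    seeds = local_maxima(distance) & mask
    seed_fp = _ellipsoid_footprint(geometry.radii_to_voxels(params.seed_dilation_um))
    seeds = ndi.binary_dilation(seeds, structure=seed_fp) & mask
    markers = cc_label(seeds)
    if markers.max() == 0:
        return cc_label(mask).astype(np.int32)
    return watershed(-distance, markers=markers, mask=mask).astype(np.int32)


def assign_cytoplasm(
    nuclei_labels: np.ndarray,
    geometry: VoxelGeometry,
    max_distance_um: float,
) -> np.ndarray:
    """Grow each nucleus into its surrounding cytoplasm.

    Every voxel within ``max_distance_um`` (physical metric) of a nucleus
    is assigned to the nearest nucleus; equidistant voxels go to the lower
    label. With distance 0 the cells equal the nuclei.
    """
    labels = np.asarray(nuclei_labels)
    out = labels.astype(np.int32).copy()
    if labels.max() == 0 or max_distance_um <= 0:
        return out
    best = np.full(labels.shape, np.inf)
    assign = np.zeros(labels.shape, dtype=np.int32)
    for lab in np.unique(labels)[1:]:
        d = ndi.distance_transform_edt(labels != lab, sampling=geometry.sampling)
        closer = d < best  # strict: ties keep the earlier (lower) label
        best[closer] = d[closer]
        assign[closer] = lab
    within = best <= max_distance_um
    out[within] = assign[within]
    out[labels > 0] = labels[labels > 0]
    return out


def measure_cells(
    nuclei_labels: np.ndarray,
    cell_labels: np.ndarray,
    signal: np.ndarray,
    geometry: VoxelGeometry,
) -> list[CellFractionRecord]:
    """Integrate the signal channel over nucleus and cell for every label."""
    records = []
    for lab in np.unique(nuclei_labels)[1:]:
        nuc = nuclei_labels == lab
        cell = cell_labels == lab
        nuc_sum = float(signal[nuc].sum())
        cell_sum = float(signal[cell].sum())
        rec = CellFractionRecord(
            cell=int(lab),
            nuclear_volume_um3=float(nuc.sum()) * geometry.voxel_volume,
            cell_volume_um3=float(cell.sum()) * geometry.voxel_volume,
            nuclear_fluorescence=nuc_sum,
            cell_fluorescence=cell_sum,
            nuclear_fraction=nuc_sum / cell_sum if cell_sum > 0 else float("nan"),
        )
        if cell_sum <= 0:
            rec.excluded = "no_signal"
        records.append(rec)
    return records


def filter_cells(
    records: list[CellFractionRecord],
    nuclei_labels: np.ndarray,
    cell_labels: np.ndarray,
    min_nuclear_volume_um3: float = 147.0,
) -> list[CellFractionRecord]:
    """Apply the exclusion rules; returns all records, exclusions annotated.

    A cell is dropped when its region touches a lateral (y or x) image
    face, its nucleus is smaller than the volume cutoff, or the nucleus
    label splits into more than one connected component (fragmented).
    Stacks of an epithelial monolayer routinely clip cells at the axial
    faces, so the border rule uses lateral faces only.
    """
    border = np.zeros(cell_labels.shape, dtype=bool)
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    border_labels = set(np.unique(cell_labels[border])) - {0}
    for rec in records:
        if rec.excluded:
            continue
        if rec.cell in border_labels:
            rec.excluded = "border"
        elif rec.nuclear_volume_um3 < min_nuclear_volume_um3:
            rec.excluded = "small"
        elif cc_label(nuclei_labels == rec.cell).max() > 1:
            rec.excluded = "fragmented"
    return records


def quantify_stack(
    nuclei_channel: np.ndarray,
    signal_channel: np.ndarray,
    geometry: VoxelGeometry,
    params: NucSegParams = NucSegParams(),
) -> pd.DataFrame:
    """Run the full chain on one stack; one row per detected cell."""
    nuclei = segment_nuclei(nuclei_channel, geometry, params)
    cells = assign_cytoplasm(nuclei, geometry, float(min(params.cytoplasm_distance_um)))
    records = measure_cells(nuclei, cells, signal_channel, geometry)
    records = filter_cells(records, nuclei, cells, params.min_nuclear_volume_um3)
    return pd.DataFrame(
        [
            {
                "cell": r.cell,
                "nuclear_volume_um3": r.nuclear_volume_um3,
                "cell_volume_um3": r.cell_volume_um3,
                "nuclear_fluorescence": r.nuclear_fluorescence,
                "cell_fluorescence": r.cell_fluorescence,
                "nuclear_fraction": r.nuclear_fraction,
                "excluded": r.excluded,
            }
            for r in records
        ]
    )


def summarize_and_compare(
    records: pd.DataFrame,
    group_col: str = "group",
    image_col: str = "image",
    value_col: str = "nuclear_fraction",
) -> tuple[pd.DataFrame, float]:
    """Image-level means and a two-group unpaired t-test on those means.

    ``records`` holds per-cell rows (already filtered of exclusions) with
    image and group identifiers; each image contributes one mean. Exactly
    two groups are required for the test.
    """
    kept = records
    if "excluded" in records.columns:
        kept = records[records["excluded"] == ""]
    means = (
        kept.groupby([group_col, image_col])[value_col].mean().rename("image_mean").reset_index()
    )
    groups = means[group_col].unique()
    if len(groups) != 2:
        raise ValueError("need exactly two groups to compare")
    a = means.loc[means[group_col] == groups[0], "image_mean"]
    b = means.loc[means[group_col] == groups[1], "image_mean"]
    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if np.isnan(p):
        p = 1.0
    return means, p
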