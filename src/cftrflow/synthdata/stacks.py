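"""Synthetic 3D confocal stacks for nuclear-fraction quantification.

Each stack emulates a polarized epithelial monolayer imaged in two
channels: a nuclear dye and a signal channel (the transcription factor
whose nuclear fraction is measured). Cells are ellipsoids with ellipsoidal
nuclei; the signal channel distributes each cell's total fluorescence
between nucleus and cytoplasm so that the nuclear share equals a planted
per-cell fraction. Ground-truth label volumes accompany the images, and
violator cells — nuclei below the volume filter, cells clipped by the
lateral image border, clumped (touching) nucleus pairs — can be planted to
exercise the quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StackSimParams:
    shape: tuple[int, int, int] = (24, 160, 160)  # (z, y, x) voxels
    voxel_size_um: tuple[float, float, float] = (0.6, 0.5, 0.5)  # (z, y, x)
    n_cells: int = 8
    nuclear_fraction_true: float = 0.5
    fraction_noise_sd: float = 0.0
    nucleus_radius_um: tuple[float, float, float] = (2.7, 4.2, 4.2)
    cell_scale: float = 1.6  # cell ellipsoid radii = nucleus radii * scale (xy), capped in z
    total_fluorescence: float = 1.0e6
    clumping_rate: float = 0.0
    border_cell_rate: float = 0.0
    n_small_nuclei: int = 0
    small_radius_um: tuple[float, float, float] = (1.5, 2.0, 2.0)  # ~50 um^3 (< 147)
    border_margin_um: float = 5.0  # interior cells stay this far from lateral faces
    background: float = 20.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if not 0.0 <= self.nuclear_fraction_true <= 1.0:
            raise ValueError("nuclear_fraction_true must be in [0, 1]")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for r, v, n in zip(self.nucleus_radius_um, self.voxel_size_um, self.shape):
            if r / v * 2 >= n:
                raise ValueError("nucleus larger than image along one axis")


@dataclass
class ConfocalStack:
    """One simulated stack: channels, geometry and ground truth."""

    nuclei_channel: np.ndarray
    signal_channel: np.ndarray
    voxel_size_um: tuple[float, float, float]
    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    truth: pd.DataFrame  # cell, f_true, nuclear_volume_um3, small, border, clumped


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii_vox: tuple[float, float, float],
) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii_vox[0]) ** 2
        + ((yy - center[1]) / radii_vox[1]) ** 2
        + ((xx - center[2]) / radii_vox[2]) ** 2
    ) <= 1.0


def generate_confocal_stack(params: StackSimParams) -> ConfocalStack:
    """Render one two-channel stack with ground-truth labels.

    Cell centres are laid out on a jittered lateral grid with spacing
    derived from the cell radius, so regular cells never touch; planted
    violators override their placement (border cells sit on a lateral
    face, a clumped partner is placed within one nucleus radius of its
    neighbour).
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape
    vz, vy, vx = params.voxel_size_um
    nuc_r = (
        params.nucleus_radius_um[0] / vz,
        params.nucleus_radius_um[1] / vy,
        params.nucleus_radius_um[2] / vx,
    )
    cell_rxy = (nuc_r[1] * params.cell_scale, nuc_r[2] * params.cell_scale)
    cell_rz = min(nuc_r[0] * 1.3, (nz - 1) / 2 - 0.5)

    n = params.n_cells
    side = int(np.ceil(np.sqrt(n)))
    pitch_y, pitch_x = ny // side, nx // side
    if pitch_y < 2 * cell_rxy[0] or pitch_x < 2 * cell_rxy[1]:
        raise ValueError("cells do not fit the lateral field without overlap")

    small_ids = set(range(params.n_small_nuclei))
    n_border = int(round(params.border_cell_rate * n))
    border_ids = set(range(params.n_small_nuclei, params.n_small_nuclei + n_border))
    n_clump_pairs = int(round(params.clumping_rate * n / 2))

    # interior cells keep a lateral margin wide enough that downstream
    # cytoplasm growth (<= margin beyond the cell ellipsoid) cannot reach a
    # face; only planted border cells touch it.
    margin_y = cell_rxy[0] + params.border_margin_um / vy
    margin_x = cell_rxy[1] + params.border_margin_um / vx
    centers: list[tuple[float, float, float]] = []
    clumped: set[int] = set()
    for i in range(n):
        gy, gx = divmod(i, side)
        jitter_y = max(1, int(pitch_y / 2 - cell_rxy[0] - 1))
        jitter_x = max(1, int(pitch_x / 2 - cell_rxy[1] - 1))
        cy = gy * pitch_y + pitch_y // 2 + rng.integers(-jitter_y, jitter_y + 1)
        cx = gx * pitch_x + pitch_x // 2 + rng.integers(-jitter_x, jitter_x + 1)
        cy = float(np.clip(cy, margin_y, ny - 1 - margin_y))
        cx = float(np.clip(cx, margin_x, nx - 1 - margin_x))
        cz = nz / 2 + rng.uniform(-1, 1)
        if i in border_ids:
            cy = 0.0 if rng.random() < 0.5 else ny - 1.0  # nucleus clipped by the face
        centers.append((cz, cy, cx))
    # clumped pairs: pick from the regular cells and move one member of each
    # pair next to (overlapping) the other
    regular = [i for i in range(n) if i not in small_ids and i not in border_ids]
    for p in range(n_clump_pairs):
        if 2 * p + 1 >= len(regular):
            break
        a, b = regular[2 * p], regular[2 * p + 1]
        za, ya, xa = centers[a]
        xb = xa + 1.6 * nuc_r[2]
        if xb > nx - 1 - margin_x:
            xb = xa - 1.6 * nuc_r[2]
        centers[b] = (za, ya, xb)
        clumped.update((a, b))

    nuclei_labels = np.zeros(params.shape, dtype=np.int32)
    cell_labels = np.zeros(params.shape, dtype=np.int32)
    signal = np.zeros(params.shape, dtype=float)
    rows = []
    voxel_vol = vz * vy * vx
    for i, center in enumerate(centers):
        label = i + 1
        if i in small_ids:
            r_um = params.small_radius_um
            r_vox = (r_um[0] / vz, r_um[1] / vy, r_um[2] / vx)
        else:
            r_vox = nuc_r
        nuc = _ellipsoid_mask(params.shape, center, r_vox)
        cell = _ellipsoid_mask(params.shape, center, (cell_rz, *cell_rxy)) | nuc
        # later labels must not steal earlier voxels (clumped pairs overlap)
        nuc &= nuclei_labels == 0
        cell &= (cell_labels == 0) | (cell_labels == label)
        nuclei_labels[nuc] = label
        cell_labels[cell & (nuclei_labels == 0)] = label
        cell_labels[nuc] = label
        f_true = float(
            np.clip(
                params.nuclear_fraction_true
                + (rng.normal(0.0, params.fraction_noise_sd) if params.fraction_noise_sd else 0.0),
                0.0,
                1.0,
            )
        )
        nuc_vox = int(nuc.sum())
        cyt = cell & ~nuc
        cyt_vox = int(cyt.sum())
        if nuc_vox == 0:
            raise ValueError("nucleus fell entirely outside the image")
        signal[nuc] += params.total_fluorescence * f_true / nuc_vox
        if cyt_vox:
            signal[cyt] += params.total_fluorescence * (1.0 - f_true) / cyt_vox
        rows.append(
            {
                "cell": label,
                "f_true": f_true,
                "nuclear_volume_um3": nuc_vox * voxel_vol,
                "small": i in small_ids,
                "border": i in border_ids,
                "clumped": i in clumped,
            }
        )

    nuclei_channel = np.where(nuclei_labels > 0, 1000.0, 0.0) + params.background
    if params.noise_sd:
        nuclei_channel = nuclei_channel + rng.normal(0.0, params.noise_sd, params.shape)
    return ConfocalStack(
        nuclei_channel=np.clip(nuclei_channel, 0, None),
        signal_channel=signal,
        voxel_size_um=params.voxel_size_um,
        nuclei_labels=nuclei_labels,
        cell_labels=cell_labels,
        truth=pd.DataFrame(rows),
    )
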