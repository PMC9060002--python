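"""Synthetic siRNA traffic-screen plates with per-cell ground truth.

The simulated assay mirrors the dual-tag reporter readout: every cell
carries a total-CFTR fluorescence (the mCherry channel) and a
surface-CFTR fluorescence (the extracellular-tag channel), the latter being
a plasma-membrane fraction of the former. An siRNA treatment acts as a
multiplier on the surface fraction; the transfection-control wells (siCFTR)
instead knock the total signal down. Intensities carry multiplicative
lognormal noise with a configurable coefficient of variation so that
``noise_cv=0`` recovers the analytic values exactly.

Two granularities are provided: :func:`simulate_screen_cells` emits the
per-cell ground-truth table directly (fast, used for Monte-Carlo
calibration of the scoring stage), and :func:`generate_screen_plate`
renders the same cells as three-channel well images for the segmentation
stage, painting each cell as a disk whose pixel sum equals its true
integrated intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

SATURATION_VALUE = np.iinfo(np.uint16).max


@dataclass(frozen=True)
class Treatment:
    well: str
    label: str
    effect: float = 1.0  # multiplier on the surface fraction
    role: str = "sample"  # sample | NCtrl | siCFTR | positive

    def __post_init__(self) -> None:
        if self.effect <= 0:
            raise ValueError("effect multiplier must be positive")


@dataclass(frozen=True)
class ScreenSimParams:
    treatments: tuple[Treatment, ...]
    plate_rows: int = 8
    plate_cols: int = 12
    cells_per_well_mean: int = 200
    transfection_efficiency: float = 0.9  # knockdown depth in siCFTR wells
    pm_fraction_baseline: float = 0.25
    total_intensity_mean: float = 5000.0
    noise_cv: float = 0.1
    saturation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_well_mean <= 0:
            raise ValueError("cells_per_well_mean must be positive")
        for frac, name in [
            (self.transfection_efficiency, "transfection_efficiency"),
            (self.pm_fraction_baseline, "pm_fraction_baseline"),
            (self.saturation_rate, "saturation_rate"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        roles = {t.role for t in self.treatments}
        if "NCtrl" not in roles or "siCFTR" not in roles:
            raise ValueError("layout must include NCtrl and siCFTR wells")
        wells = [t.well for t in self.treatments]
        if len(wells) != len(set(wells)):
            raise ValueError("duplicate wells in layout")


def default_layout(
    n_samples: int = 60,
    n_nctrl: int = 8,
    n_sicftr: int = 2,
    effects: Sequence[float] | None = None,
) -> tuple[Treatment, ...]:
    """A 96-well layout: samples, NCtrl wells and siCFTR transfection controls."""
    wells = [f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(8) for c in range(12)]
    effects = list(effects) if effects is not None else [1.0] * n_samples
    if len(effects) != n_samples:
        raise ValueError("one effect per sample treatment required")
    out = []
    i = 0
    for j in range(n_nctrl):
        out.append(Treatment(well=wells[i], label="NCtrl", effect=1.0, role="NCtrl"))
        i += 1
    for j in range(n_sicftr):
        out.append(Treatment(well=wells[i], label="siCFTR", effect=1.0, role="siCFTR"))
        i += 1
    for j in range(n_samples):
        out.append(Treatment(well=wells[i], label=f"siRNA{j + 1:03d}", effect=effects[j]))
        i += 1
    return tuple(out)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative noise with the requested CV; exactly 1 at cv=0."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _well_rng(seed: int, well: str) -> np.random.Generator:
    # Per-well substream: independently reproducible regardless of iteration order.
    key = [ord(c) for c in well]
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def simulate_screen_cells(params: ScreenSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell ground truth and per-well true summaries for one plate.

    Returns ``(cells, wells)``; ``cells`` has one row per simulated cell
    with its true integrated total and surface fluorescence, ``wells`` the
    true median surface/total per well plus treatment metadata.
    """
    cell_rows, well_rows = [], []
    for t in params.treatments:
        rng = _well_rng(params.seed, t.well)
        n = max(1, int(rng.poisson(params.cells_per_well_mean)))
        total = params.total_intensity_mean * _lognormal_factor(rng, params.noise_cv, n)
        if t.role == "siCFTR":
            total = total * (1.0 - params.transfection_efficiency)
        frac = np.clip(
            params.pm_fraction_baseline * t.effect * _lognormal_factor(rng, params.noise_cv, n),
            0.0,
            1.0,
        )
        surface = total * frac
        saturated = rng.random(n) < params.saturation_rate
        cell_rows.append(
            pd.DataFrame(
                {
                    "well": t.well,
                    "cell": np.arange(n),
                    "treatment": t.label,
                    "role": t.role,
                    "true_total": total,
                    "true_surface": surface,
                    "saturated": saturated,
                }
            )
        )
        well_rows.append(
            {
                "well": t.well,
                "treatment": t.label,
                "role": t.role,
                "effect": t.effect,
                "n_cells": n,
                "true_median_surface": float(np.median(surface)),
                "true_median_total": float(np.median(total)),
            }
        )
    return pd.concat(cell_rows, ignore_index=True), pd.DataFrame(well_rows)


def render_well_images(
    cells: pd.DataFrame,
    image_shape: tuple[int, int] = (360, 360),
    cell_radius: int = 5,
    nucleus_radius: int = 2,
    background: float = 100.0,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Paint one well's cells as three uint16 channel images.

    Cells are laid out on a jittered grid of non-overlapping disks; the
    pixel sum of each disk equals the cell's true integrated intensity on
    top of a constant background. Cells flagged ``saturated`` get a third
    of their pixels clipped to the dtype maximum in the surface channel.
    """
    rng = rng or np.random.default_rng(0)
    n = len(cells)
    h, w = image_shape
    side = int(np.ceil(np.sqrt(n)))
    pitch_y, pitch_x = h // side, w // side
    if min(pitch_y, pitch_x) < 2 * cell_radius + 2:
        raise ValueError("too many cells for the requested image size")
    nuclei = np.full(image_shape, background, dtype=float)
    total = np.full(image_shape, background, dtype=float)
    surface = np.full(image_shape, background, dtype=float)

    def paint(img: np.ndarray, mask: np.ndarray, amount: float) -> None:
        # Integer-dithered fill: the painted pixels sum to round(amount),
        # so integrated intensities survive the uint16 quantisation exactly.
        idx = np.flatnonzero(mask.ravel())
        base, extra = divmod(int(round(amount)), len(idx))
        img.ravel()[idx] += base
        img.ravel()[idx[:extra]] += 1

    yy, xx = np.ogrid[:h, :w]
    jitter = min(pitch_y, pitch_x) // 2 - cell_radius - 1
    for i, row in enumerate(cells.itertuples()):
        gy, gx = divmod(i, side)
        cy = gy * pitch_y + pitch_y // 2 + rng.integers(-jitter, jitter + 1)
        cx = gx * pitch_x + pitch_x // 2 + rng.integers(-jitter, jitter + 1)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius**2
        core = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius**2
        nuclei[core] += 1000.0
        paint(total, disk, row.true_total)
        paint(surface, disk, row.true_surface)
        if row.saturated:
            idx = np.flatnonzero(disk.ravel())
            pick = rng.choice(idx, size=max(1, len(idx) // 3), replace=False)
            surface.ravel()[pick] = SATURATION_VALUE
    out = {}
    for name, img in [("nuclei", nuclei), ("total", total), ("surface", surface)]:
        out[name] = np.clip(np.round(img), 0, SATURATION_VALUE).astype(np.uint16)
    return out


def generate_screen_plate(
    params: ScreenSimParams,
    image_shape: tuple[int, int] = (360, 360),
    background: float = 100.0,
) -> tuple[dict[str, dict[str, np.ndarray]], pd.DataFrame, pd.DataFrame]:
    """Render a full plate: per-well channel images plus the ground truth.

    Deterministic for a fixed seed; each well draws from its own seeded
    substream so individual wells can be regenerated independently.
    """
    cells, wells = simulate_screen_cells(params)
    images: dict[str, dict[str, np.ndarray]] = {}
    for well, well_cells in cells.groupby("well", sort=False):
        rng = _well_rng(params.seed + 1_000_003, well)
        images[well] = render_well_images(
            well_cells, image_shape=image_shape, background=background, rng=rng
        )
    return images, cells, wells


def published_screen_emulation() -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, bool]]:
    """A deterministic screen-summary table with the study library's structure.

    Emulates the screen's published results table: 83 treatments (59 EMT
    siRNAs across 30 genes — two per gene for all but one — plus three
    assay controls and 21 two-siRNA combinations), each with an aggregate
    modified Z per cell line, the siRNA -> gene-target map and the
    complementary-evidence flags. The planted hit structure mirrors the
    study's library design: ten genes with two concordant enhancer
    siRNAs (four of them selective for the F508del line), four
    single-siRNA hits backed by complementary evidence, sixteen
    single-siRNA hits without corroboration, all combinations scoring as
    hits, and active transfection/positive controls. Anchor Z values
    (1.05/1.37 for the first concordant pair, 1.62 for the positive
    control) match the reporter assay's typical effect sizes.

    Returns ``(table, sirna_genes, evidence)`` with one table row per
    (treatment, cell line).
    """
    genes = [f"G{i:02d}" for i in range(1, 31)]
    rows: list[dict] = []
    sirna_genes: dict[str, list[str]] = {}
    evidence: dict[str, bool] = {}

    def add(treatment, targets, z_wt, z_f508, flag=False):
        sirna_genes[treatment] = targets
        evidence[treatment] = flag
        rows.append({"treatment": treatment, "cell_line": "wt", "z_mean": z_wt})
        rows.append({"treatment": treatment, "cell_line": "f508del", "z_mean": z_f508})

    # ten concordant enhancer pairs; the first four selective for F508del
    pair_z = [(1.05, 1.37), (1.21, 1.33), (1.15, 1.42), (1.08, 1.27)]
    for i, g in enumerate(genes[:4]):
        z1, z2 = pair_z[i]
        add(f"si{g} (1)", [g], 0.2, z1)
        add(f"si{g} (2)", [g], -0.1, z2)
    for g in genes[4:10]:
        add(f"si{g} (1)", [g], 1.3, 1.5)
        add(f"si{g} (2)", [g], 1.2, 1.4)
    # four single-siRNA hits rescued by complementary evidence
    for g in genes[10:14]:
        add(f"si{g} (1)", [g], 1.2, 1.6, flag=True)
        add(f"si{g} (2)", [g], 0.3, 0.5)
    # sixteen uncorroborated single-siRNA hits (wt line only)
    for g in genes[14:30]:
        add(f"si{g} (1)", [g], 1.4, 0.4)
    for g in genes[14:29]:
        add(f"si{g} (2)", [g], 0.2, -0.3)
    # assay controls: negative, transfection and positive
    add("NCtrl", ["NCTRL"], 0.0, 0.0)
    add("siCFTR", ["CFTR"], -1.8, -1.6)
    add("siCOPZ1", ["COPZ1"], 1.5, 1.62)
    # 21 two-siRNA combinations, each with a unique gene pair
    pairs = [(genes[i], genes[(i + 1) % 30]) for i in range(0, 21)]
    for a, b in pairs:
        add(f"si{a}+si{b}", sorted([a, b]), -1.3, -0.2)
    table = pd.DataFrame(rows)
    assert table["treatment"].nunique() == 83
    return table, sirna_genes, evidence


def simulate_screen_wells_table(
    params: ScreenSimParams,
    n_replicates: int = 3,
    cell_line: str = "f508del",
) -> pd.DataFrame:
    """Tidy multi-replicate well table ready for the scoring stage.

    Each replicate is a fresh plate (seed offset by the replicate index);
    the well statistic ``x`` is the true per-well median surface signal —
    i.e. what the quantification stage recovers on noise-free images.
    """
    frames = []
    for r in range(n_replicates):
        _, wells = simulate_screen_cells(replace(params, seed=params.seed + 7919 * (r + 1)))
        wells = wells.rename(columns={"true_median_surface": "x"})
        wells["replicate"] = r
        wells["cell_line"] = cell_line
        frames.append(wells[["treatment", "role", "cell_line", "replicate", "x", "effect"]])
    return pd.concat(frames, ignore_index=True)
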