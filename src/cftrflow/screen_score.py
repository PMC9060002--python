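"""Modified Z-scores, hit calling and hit classification for the traffic screen.

The screen's per-well statistic is a control-based Z: the well's median
surface-CFTR fluorescence is centred on the median of the negative-control
(NCtrl) wells of the same plate and scaled by their standard deviation.
Despite the conventional name "modified Z-score", the scaling is the sample
SD of the control wells, not the MAD; a MAD variant is available through
``robust=True`` for sensitivity analysis.

Treatments are called enhancers (Z > 1) or inhibitors (Z < -1) of CFTR
plasma-membrane traffic, strict inequalities. Hits are upgraded to high
confidence when at least two siRNAs (or siRNA combinations) targeting the
same gene set show the same direction of effect, or when a single hit is
corroborated by independent evidence on the target (e.g. differential
expression between the two cell lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

HIT_ENHANCER = "enhancer"
HIT_INHIBITOR = "inhibitor"
HIT_NONE = "none"


class DegenerateControlsError(ValueError):
    """Raised when the negative-control wells have zero spread."""


@dataclass
class ZScoreResult:
    treatment: str
    cell_line: str
    replicate_z: list[float]
    z_mean: float
    z_sem: float
    p_value: float
    hit_class: str = HIT_NONE
    confidence: str = "standard"
    genes: tuple[str, ...] = field(default_factory=tuple)


def modified_z(x: float, nctrl_medians: Sequence[float], robust: bool = False) -> float:
    """Control-based Z of one well median against its plate's NCtrl wells.

    Parameters
    ----------
    x : well median surface-CFTR fluorescence.
    nctrl_medians : medians of the plate's negative-control wells (>= 2).
    robust : scale by 1.4826*MAD instead of the sample SD.
    """
    ctrl = np.asarray(nctrl_medians, dtype=float)
    if ctrl.size < 2:
        raise ValueError("need at least two negative-control wells")
    center = float(np.median(ctrl))
    if robust:
        scale = 1.4826 * float(np.median(np.abs(ctrl - center)))
    else:
        scale = float(np.std(ctrl, ddof=1))
    if scale == 0:
        raise DegenerateControlsError("degenerate controls: zero spread among NCtrl wells")
    return (float(x) - center) / scale


def aggregate_and_test(
    treatment_z: Sequence[float],
    nctrl_z: Sequence[float],
    welch: bool = False,
) -> tuple[float, float, float]:
    """Average per-replicate Z and test against the control replicates.

    Returns ``(mean, sem, p)`` with SEM = sd/sqrt(n) and a two-sided
    unpaired t-test (pooled variance by default, Welch optional).
    """
    t = np.asarray(treatment_z, dtype=float)
    c = np.asarray(nctrl_z, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("need at least two replicates per group")
    mean = float(np.mean(t))
    sem = float(np.std(t, ddof=1) / np.sqrt(t.size))
    p = float(stats.ttest_ind(t, c, equal_var=not welch).pvalue)
    if np.isnan(p):  # identical constant groups
        p = 1.0
    return mean, sem, p


def call_hit(z_mean: float) -> str:
    """Strict-threshold hit class: enhancer iff Z > 1, inhibitor iff Z < -1."""
    if z_mean > 1:
        return HIT_ENHANCER
    if z_mean < -1:
        return HIT_INHIBITOR
    return HIT_NONE


def classify_confidence(
    results: Iterable[ZScoreResult],
    sirna_genes: Mapping[str, Sequence[str]],
    evidence: Mapping[str, bool] | None = None,
) -> list[ZScoreResult]:
    """Label each hit high-confidence or standard.

    High confidence requires, within one cell line, at least two
    same-direction hits whose treatments target the same gene set
    (single siRNAs and combinations alike, keyed by the set of target
    genes), or a single hit with its evidence flag set.
    """
    evidence = evidence or {}
    results = list(results)
    for r in results:
        if r.treatment not in sirna_genes:
            raise KeyError(f"treatment {r.treatment!r} has no gene mapping")
        r.genes = tuple(sorted(sirna_genes[r.treatment]))

    counts: dict[tuple[str, tuple[str, ...], str], int] = {}
    for r in results:
        if r.hit_class != HIT_NONE:
            key = (r.cell_line, r.genes, r.hit_class)
            counts[key] = counts.get(key, 0) + 1
    for r in results:
        if r.hit_class == HIT_NONE:
            r.confidence = "standard"
            continue
        concordant = counts[(r.cell_line, r.genes, r.hit_class)] >= 2
        flagged = bool(evidence.get(r.treatment, False))
        r.confidence = "high" if (concordant or flagged) else "standard"
    return results


def select_top_hits(results: Iterable[ZScoreResult]) -> list[str]:
    """Treatments that enhance traffic in F508del cells but are neutral in wt.

    The selective-rescue criterion of the screen: an enhancer call in the
    F508del-CFTR line together with class ``none`` in the wt line.
    """
    by_treatment: dict[str, dict[str, str]] = {}
    for r in results:
        by_treatment.setdefault(r.treatment, {})[r.cell_line] = r.hit_class
    return sorted(
        t
        for t, classes in by_treatment.items()
        if classes.get("f508del") == HIT_ENHANCER and classes.get("wt") == HIT_NONE
    )


def score_screen(
    wells: pd.DataFrame,
    robust: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Score a whole screen from a tidy well table.

    ``wells`` needs columns ``treatment, role, cell_line, replicate, x``
    (x = well median surface fluorescence). Z is computed per
    (cell_line, replicate) plate against that plate's NCtrl wells, averaged
    over replicates and tested against the NCtrl replicate Zs.
    """
    required = {"treatment", "role", "cell_line", "replicate", "x"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")

    rows = []
    for cell_line, line_df in wells.groupby("cell_line"):
        # per-plate Z for every well
        z_by_treatment: dict[str, list[float]] = {}
        nctrl_z: list[float] = []
        for _, plate in line_df.groupby("replicate"):
            ctrl = plate.loc[plate["role"] == "NCtrl", "x"].to_numpy()
            if ctrl.size < 2:
                raise ValueError("each plate needs >= 2 NCtrl wells")
            for _, w in plate.iterrows():
                z = modified_z(w["x"], ctrl, robust=robust)
                if w["role"] == "NCtrl":
                    nctrl_z.append(z)
                else:
                    z_by_treatment.setdefault(w["treatment"], []).append(z)
        for treatment, zs in z_by_treatment.items():
            mean, sem, p = aggregate_and_test(zs, nctrl_z, welch=welch)
            rows.append(
                {
                    "treatment": treatment,
                    "cell_line": cell_line,
                    "n_replicates": len(zs),
                    "z_mean": mean,
                    "z_sem": sem,
                    "p_value": p,
                    "hit_class": call_hit(mean),
                }
            )
    return pd.DataFrame(rows).sort_values(["cell_line", "treatment"]).reset_index(drop=True)
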