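"""Closed-form quantifications used in the validation experiments.

Western-blot processing efficiency C/(B+C), qPCR fold change by the
delta-delta-Ct method, and patch-clamp current density. Intensities and Ct
values are taken as inputs; densitometry and amplification-efficiency
modelling are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandQuant:
    """Densitometric intensities for one lane of a CFTR Western blot.

    Band B is the immature (core-glycosylated) form, band C the mature
    (fully glycosylated) form. ``loading_control`` and ``reference`` allow
    normalisation of the processing ratio across lanes/conditions.
    """

    band_b: float
    band_c: float
    loading_control: float = 1.0
    reference: float = 1.0

    def __post_init__(self) -> None:
        if self.band_b < 0 or self.band_c < 0:
            raise ValueError("band intensities must be non-negative")


@dataclass(frozen=True)
class CtQuad:
    """The four qPCR cycle-threshold values entering a delta-delta-Ct."""

    ct_target_sample: float
    ct_housekeeping_sample: float
    ct_target_control: float
    ct_housekeeping_control: float

    @property
    def ddct(self) -> float:
        return (self.ct_target_sample - self.ct_housekeeping_sample) - (
            self.ct_target_control - self.ct_housekeeping_control
        )


def processing_ratio(q: BandQuant, normalized: bool = False) -> float:
    """Fraction of mature CFTR, C/(B+C), in [0, 1].

    With ``normalized=True`` the ratio is divided by the loading control
    and by the reference-condition value (ratio-of-ratios; the order of the
    two divisions does not change the result).
    """
    total = q.band_b + q.band_c
    if total == 0:
        raise ValueError("B + C must be positive")
    ratio = q.band_c / total
    if not normalized:
        return ratio
    if q.loading_control <= 0 or q.reference <= 0:
        raise ValueError("loading control and reference must be positive")
    return ratio / q.loading_control / q.reference


def ddct_fold_change(q: CtQuad) -> float:
    """Fold change FC = 2**(-ddCt); 1.0 means no change versus control."""
    return float(2.0 ** (-q.ddct))


def current_density(current_pa: float, capacitance_pf: float) -> float:
    """Whole-cell current normalised to membrane area (pA/pF).

    Capacitance is proportional to membrane area, so the quotient removes
    cell-size differences. Sign of the current is preserved.
    """
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    return current_pa / capacitance_pf
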