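"""Force-balance validation: component sums, per-trial ratios, cohort stats.

Static equilibrium of a lying body demands that the mattress's vertical
support sum to body weight G while the horizontal (shear) components sum to
zero. Summing the per-cell vector forces therefore validates the whole
measurement chain: F_z/G should sit near 100%, and the lateral (x, mat
width) and axial (y, mat length) sums near 0% of G. The total scalar
pressure, by contrast, exceeds G on a deformed surface — each tilted cell
must push harder than its vertical share — which is why pressure mats alone
overestimate load by roughly 30%.

A published five-subject, two-posture validation cohort ships with the
module (:func:`reference_cohort`) so the ratio and cohort arithmetic can be
exercised against known printed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .forcefield import VectorForceField
from .pressure import PressureGrid


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed tables).

    numpy/python round half to even; force tables conventionally do not.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if x < 0 else 1.0
    )


@dataclass(frozen=True)
class TrialSummary:
    """One trial's force components and their body-weight ratios (percent).

    Ratios are stored unrounded; ``rounded()`` reports them to 2 decimals.
    """

    body_weight: float
    total_pressure: float
    F_x: float
    F_y: float
    F_z: float
    posture: str = ""
    subject: str = ""

    def __post_init__(self):
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")

    @property
    def total_pressure_ratio(self) -> float:
        return 100.0 * self.total_pressure / self.body_weight

    @property
    def vertical_ratio(self) -> float:
        return 100.0 * self.F_z / self.body_weight

    @property
    def lateral_ratio(self) -> float:
        return 100.0 * self.F_x / self.body_weight

    @property
    def axial_ratio(self) -> float:
        return 100.0 * self.F_y / self.body_weight

    def rounded(self) -> dict[str, float]:
        return {
            "total_pressure_ratio": round_half_away(self.total_pressure_ratio),
            "vertical_ratio": round_half_away(self.vertical_ratio),
            "lateral_ratio": round_half_away(self.lateral_ratio),
            "axial_ratio": round_half_away(self.axial_ratio),
        }


@dataclass(frozen=True)
class CohortSummary:
    """Mean and population SD of one ratio quantity across trials."""

    quantity: str
    mean: float
    sd: float
    n: int
    absolute: bool
    sd_mode: str = "population"

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


def sum_components(fld: VectorForceField) -> tuple[float, float, float]:
    """Componentwise sums (F_x, F_y, F_z) over all cells."""
    return fld.component_sums()


def total_pressure(grid: PressureGrid) -> float:
    """Sum of all scalar cell forces (N)."""
    if grid.units != "N":
        raise ValueError("grid must be in Newtons")
    return grid.total()


def trial_summary(
    fld: VectorForceField,
    body_weight: float,
    posture: str = "",
    subject: str = "",
) -> TrialSummary:
    """Summarize one trial's field against the subject's weight."""
    fx, fy, fz = fld.component_sums()
    return TrialSummary(
        body_weight=body_weight,
        total_pressure=float(fld.scalar_forces.sum()),
        F_x=fx,
        F_y=fy,
        F_z=fz,
        posture=posture,
        subject=subject,
    )


_QUANTITIES = {
    "total_pressure_ratio": lambda t: t.total_pressure_ratio,
    "vertical_ratio": lambda t: t.vertical_ratio,
    "lateral_ratio": lambda t: t.lateral_ratio,
    "axial_ratio": lambda t: t.axial_ratio,
}


def cohort_summary(
    trials: list[TrialSummary], quantity: str, absolute: bool = False
) -> CohortSummary:
    """Mean and population SD (divide by n) of a ratio across trials.

    Means are taken over the unrounded per-trial ratios; ``absolute=True``
    averages magnitudes, appropriate for shear components whose signs vary
    by trial.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials for a cohort summary")
    if quantity not in _QUANTITIES:
        raise KeyError(f"unknown quantity {quantity!r}")
    vals = np.array([_QUANTITIES[quantity](t) for t in trials])
    if absolute:
        vals = np.abs(vals)
    return CohortSummary(
        quantity=quantity,
        mean=float(vals.mean()),
        sd=float(vals.std()),  # ddof=0: population SD
        n=len(vals),
        absolute=absolute,
    )


def summaries_to_table(trials: list[TrialSummary]) -> pd.DataFrame:
    """Per-trial report table with ratios rounded to 2 decimals."""
    rows = []
    for t in trials:
        r = t.rounded()
        rows.append(
            {
                "posture": t.posture,
                "subject": t.subject,
                "body_weight_N": t.body_weight,
                "total_pressure_N": t.total_pressure,
                "total_pressure_pct_bw": r["total_pressure_ratio"],
                "vertical_N": t.F_z,
                "vertical_pct_bw": r["vertical_ratio"],
                "lateral_N": t.F_x,
                "lateral_pct_bw": r["lateral_ratio"],
                "axial_N": t.F_y,
                "axial_pct_bw": r["axial_ratio"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published validation cohort: five subjects, supine + lateral postures.
# Columns: posture, subject, body weight G (N), total scalar pressure (N),
# vertical F_z (N), lateral F_x (N), axial F_y (N).
_REFERENCE_ROWS = [
    ("supine", "1", 343.00, 460.66, 349.06, 8.76, -5.72),
    ("supine", "2", 450.80, 596.15, 428.79, 1.66, 4.46),
    ("supine", "3", 617.40, 814.46, 619.64, 12.78, -0.75),
    ("supine", "4", 676.20, 843.18, 655.41, -8.89, 8.55),
    ("supine", "5", 735.00, 892.29, 714.88, 2.08, 12.56),
    ("lateral", "1", 343.00, 445.74, 333.68, 1.32, -13.15),
    ("lateral", "2", 450.80, 576.34, 483.52, 3.87, -11.17),
    ("lateral", "3", 617.40, 872.18, 685.99, -25.50, -10.84),
    ("lateral", "4", 676.20, 837.21, 655.41, -8.89, 8.55),
    ("lateral", "5", 735.00, 1020.84, 607.53, -5.43, -49.22),
]


def reference_cohort() -> list[TrialSummary]:
    """The published five-subject validation cohort as trial summaries.

    Force components (N) measured per subject in supine and lateral
    positions; the derived body-weight ratios and cohort statistics
    are recomputed from these raw values, not copied.
    """
    return [
        TrialSummary(
            body_weight=g,
            total_pressure=tp,
            F_x=fx,
            F_y=fy,
            F_z=fz,
            posture=pos,
            subject=sub,
        )
        for pos, sub, g, tp, fz, fx, fy in _REFERENCE_ROWS
    ]
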