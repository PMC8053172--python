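"""Compartment volumetrics and longitudinal percent-change tables.

Volumes are voxel counts times the voxel volume, reported in mm³ (1 mm³ =
1 µl; human values are conventionally quoted in ml = 1000 mm³).  Follow-up
measurements are expressed as signed percent change from baseline, which
normalizes away inter-subject baseline differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contour_seg import BodyCompartments

__all__ = [
    "COMPARTMENTS",
    "Timepoint",
    "SubjectTimeline",
    "compartment_volumes",
    "axial_profile",
    "percent_change",
    "format_percent",
    "total_fat",
    "build_change_table",
    "plot_axial_profile",
]

COMPARTMENTS = ("scat", "vat", "ltw")
_CODES = {"scat": 1, "vat": 2, "ltw": 3, "excluded": 4}


def compartment_volumes(compartments: BodyCompartments) -> dict[str, float]:
    """Volumes in mm³ per compartment; excluded voxels are counted separately."""
    spacing = compartments.spacing
    if spacing is None or len(spacing) != 3 or min(spacing) <= 0:
        raise ValueError("valid (row, col, slice) voxel spacing is required")
    vox = spacing[0] * spacing[1] * spacing[2]
    labels = compartments.labels
    return {
        name: float(np.count_nonzero(labels == code) * vox) for name, code in _CODES.items()
    }


def axial_profile(compartments: BodyCompartments, reverse: bool = False) -> pd.DataFrame:
    """Per-slice compartment volumes (mm³), caudal→cranial (index 0 = caudal).

    ``reverse=True`` returns the craniocaudal ordering.  Column sums equal the
    total compartment volumes exactly.
    """
    spacing = compartments.spacing
    vox = spacing[0] * spacing[1] * spacing[2]
    labels = compartments.labels
    rows = {
        name: (labels == code).sum(axis=(1, 2)) * vox for name, code in _CODES.items()
    }
    df = pd.DataFrame(rows)
    df.index.name = "slice"
    if reverse:
        df = df.iloc[::-1].reset_index(drop=False)
        df = df.set_index("slice")
    return df


def percent_change(baseline: float, followup: float) -> float:
    """Signed percent change from baseline: 100·(followup − baseline)/baseline."""
    if not baseline > 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return 100.0 * (followup - baseline) / baseline


def format_percent(value: float, decimals: int = 0) -> str:
    """Render a percent change the way reports print it, e.g. ``-26%`` or ``-7.2%``."""
    sign = "+" if value > 0 else ""
    return f"{sign}{value:.{decimals}f}%"


def total_fat(volumes: dict[str, float]) -> float:
    """Total adipose volume VAT + SCAT (mm³)."""
    missing = [k for k in ("vat", "scat") if k not in volumes]
    if missing:
        raise KeyError(f"missing compartment(s): {missing}")
    return float(volumes["vat"] + volumes["scat"])


@dataclass
class Timepoint:
    label: str
    volumes_mm3: dict[str, float]
    body_weight: float | None = None  # kg (human) or g (mouse)
    bmi: float | None = None


@dataclass
class SubjectTimeline:
    """Per-subject longitudinal record; the first timepoint is the baseline."""

    subject_id: str
    species: str = "human"
    therapy: str | None = None
    response: str | None = None
    timepoints: list[Timepoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "human"):
            raise ValueError("species must be 'mouse' or 'human'")
        for tp in self.timepoints:
            for v in tp.volumes_mm3.values():
                if v < 0:
                    raise ValueError("volumes must be non-negative")

    @property
    def baseline(self) -> Timepoint:
        return self.timepoints[0]

    def changes(self) -> pd.DataFrame:
        """Percent change from baseline per compartment at each follow-up."""
        labels = [tp.label for tp in self.timepoints]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate timepoint labels for subject {self.subject_id}")
        if len(self.timepoints) < 2:
            raise ValueError("at least two timepoints are required for changes")
        rows = []
        base = self.baseline.volumes_mm3
        for tp in self.timepoints[1:]:
            row: dict[str, float | str | None] = {"timepoint": tp.label}
            for comp in COMPARTMENTS:
                b = base.get(comp)
                v = tp.volumes_mm3.get(comp)
                if b is None or v is None or not b > 0:
                    row[comp] = np.nan
                else:
                    row[comp] = percent_change(b, v)
            rows.append(row)
        return pd.DataFrame(rows).set_index("timepoint")


def build_change_table(timelines: list[SubjectTimeline]) -> pd.DataFrame:
    """Cohort change table: last-measurement percent change per compartment.

    Subjects whose baseline lacks a compartment get NaN there and are flagged
    in the ``incomplete`` column rather than dropped.
    """
    rows = []
    for tl in timelines:
        ch = tl.changes()
        last = ch.iloc[-1]
        row = {
            "subject": tl.subject_id,
            "species": tl.species,
            "therapy": tl.therapy,
            "response": tl.response,
        }
        for comp in COMPARTMENTS:
            row[f"{comp}_change_pct"] = float(last[comp])
        row["incomplete"] = bool(last[list(COMPARTMENTS)].isna().any())
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def plot_axial_profile(profile: pd.DataFrame, ax=None, unit: str = "µl"):
    """Plot the caudocranial compartment distribution (one line per compartment)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for comp in COMPARTMENTS:
        if comp in profile:
            ax.plot(profile.index, profile[comp], label=comp.upper())
    ax.set_xlabel("slice (caudal → cranial)")
    ax.set_ylabel(f"volume [{unit}]")
    ax.legend()
    return ax
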