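"""Per-run glycemic metrics and Control Variability Grid Analysis.

CVGA summarises a population of closed-loop runs by one point per run:
the per-run minimum blood glucose (x-axis, plotted reversed from 110
down to 50 mg/dl) against the per-run maximum (y-axis, 110 up to 400).
The plane is partitioned into a 3x3 grid of risk zones with boundaries
at minimum 90 and 70 and maximum 180 and 300:

    A       — min in [90, 110], max in [110, 180]  (tight control)
    Lower B — min in [70, 90),  max in [110, 180]
    Upper B — min in [90, 110], max in (180, 300]
    B       — min in [70, 90),  max in (180, 300]
    Lower C — min in [50, 70),  max in [110, 180]
    Upper C — min in [90, 110], max in (300, 400]
    Lower D — min in [50, 70),  max in (180, 300]
    Upper D — min in [70, 90),  max in (300, 400]
    E       — min in [50, 70),  max in (300, 400]  (erroneous control)

Values are clipped to the axes before classification; boundary ties go
to the lower-risk zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

__all__ = [
    "GlycemicMetrics",
    "CVGAPoint",
    "ZONES",
    "glycemic_metrics",
    "first_sustained_below",
    "time_to_basal",
    "cvga_point",
    "cvga_zone",
    "cvga_summary",
    "cvga_plot",
]

ZONES = ("A", "Lower B", "Upper B", "B", "Lower C", "Upper C", "Lower D", "Upper D", "E")

#: Zones counted as "B or better" in concentration summaries.
B_OR_BETTER = ("A", "Lower B", "Upper B", "B")


@dataclass(frozen=True)
class GlycemicMetrics:
    """Scalar summary of one closed-loop run."""

    min_bg: float
    max_bg: float
    t_below_180: float  # min; nan if never sustainedly below
    t_to_basal: float  # min; nan if basal never reached
    u_max: float
    hypo: bool  # any sample below 50 mg/dl
    time_in_range: float  # fraction of samples in [70, 180]


def first_sustained_below(
    t: np.ndarray, x: np.ndarray, threshold: float, hold: float = 10.0
) -> float:
    """First time ``x`` drops below ``threshold`` and stays below >= ``hold`` min."""
    below = x < threshold
    n = len(t)
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j == n or t[j - 1] - t[i] >= hold:
                return float(t[i])
            i = j
        else:
            i += 1
    return float("nan")


def time_to_basal(t: np.ndarray, x: np.ndarray, basal: float, band: float = 2.0) -> float:
    """Time of first attainment of the basal value.

    Returns the first crossing of ``basal``; if the trajectory never
    crosses it but enters the ±``band`` neighbourhood and stays there,
    the entry time of that final excursion-free stretch is returned.
    """
    dev = x - basal
    sign_change = np.where(np.diff(np.signbit(dev)) | (dev[1:] == 0))[0]
    if dev[0] == 0:
        return float(t[0])
    if len(sign_change):
        i = sign_change[0]
        # linear interpolation within the step
        d0, d1 = dev[i], dev[i + 1]
        if d1 == d0:
            return float(t[i + 1])
        frac = d0 / (d0 - d1)
        return float(t[i] + frac * (t[i + 1] - t[i]))
    inband = np.abs(dev) <= band
    if inband[-1]:
        out = np.where(~inband)[0]
        idx = out[-1] + 1 if len(out) else 0
        if idx < len(t):
            return float(t[idx])
    return float("nan")


def glycemic_metrics(traj, basal: float = 80.0, band: float = 2.0) -> GlycemicMetrics:
    """Summary metrics of a :class:`~aemglucose.simulate.Trajectory`."""
    t = np.asarray(traj.t, dtype=float)
    x1 = np.asarray(traj.glucose, dtype=float)
    if len(t) == 0:
        raise ValueError("empty trajectory")
    return GlycemicMetrics(
        min_bg=float(x1.min()),
        max_bg=float(x1.max()),
        t_below_180=first_sustained_below(t, x1, 180.0),
        t_to_basal=time_to_basal(t, x1, basal, band),
        u_max=float(np.asarray(traj.u).max()),
        hypo=bool((x1 < 50.0).any()),
        time_in_range=float(np.mean((x1 >= 70.0) & (x1 <= 180.0))),
    )


@dataclass(frozen=True)
class CVGAPoint:
    """One run's clipped (min BG, max BG) pair and its risk zone."""

    min_bg: float  # clipped to [50, 110]
    max_bg: float  # clipped to [110, 400]
    zone: str


def cvga_zone(min_bg: float, max_bg: float) -> str:
    """Risk zone of a (min, max) pair; inputs are clipped to the grid axes."""
    m = float(np.clip(min_bg, 50.0, 110.0))
    M = float(np.clip(max_bg, 110.0, 400.0))
    col = 0 if m >= 90.0 else (1 if m >= 70.0 else 2)
    row = 0 if M <= 180.0 else (1 if M <= 300.0 else 2)
    table = (
        ("A", "Lower B", "Lower C"),
        ("Upper B", "B", "Lower D"),
        ("Upper C", "Upper D", "E"),
    )
    return table[row][col]


def cvga_point(traj, window: tuple = (120.0, None)) -> CVGAPoint:
    """CVGA point of one run over an assessment window.

    The default window drops the first 120 min (controller start-up)
    and extends to the end of the run.
    """
    t = np.asarray(traj.t, dtype=float)
    lo = window[0] if window[0] is not None else t[0]
    hi = window[1] if window[1] is not None else t[-1]
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise ValueError("assessment window outside trajectory span")
    x1 = np.asarray(traj.glucose, dtype=float)[sel]
    m = float(np.clip(x1.min(), 50.0, 110.0))
    M = float(np.clip(x1.max(), 110.0, 400.0))
    return CVGAPoint(min_bg=m, max_bg=M, zone=cvga_zone(m, M))


def cvga_summary(points) -> dict:
    """Percentage of runs per zone (all zones reported, summing to 100)."""
    points = list(points)
    if not points:
        raise ValueError("no CVGA points")
    counts = Counter(p.zone for p in points)
    n = len(points)
    return {z: 100.0 * counts.get(z, 0) / n for z in ZONES}


def cvga_plot(points, ax=None):
    """Scatter the cohort on the standard grid (reversed min axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for v in (70.0, 90.0):
        ax.axvline(v, color="0.6", lw=0.8)
    for v in (180.0, 300.0):
        ax.axhline(v, color="0.6", lw=0.8)
    ax.scatter([p.min_bg for p in points], [p.max_bg for p in points], s=12, c="k")
    ax.set_xlim(110.0, 50.0)  # reversed axis
    ax.set_ylim(110.0, 400.0)
    ax.set_xlabel("minimum BG (mg/dl)")
    ax.set_ylabel("maximum BG (mg/dl)")
    labels = {
        ("A"): (100, 145),
        ("Lower B"): (80, 145),
        ("Lower C"): (60, 145),
        ("Upper B"): (100, 240),
        ("B"): (80, 240),
        ("Lower D"): (60, 240),
        ("Upper C"): (100, 350),
        ("Upper D"): (80, 350),
        ("E"): (60, 350),
    }
    for z, (x, y) in labels.items():
        ax.annotate(z, (x, y), color="0.4", ha="center", fontsize=9)
    return ax
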