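"""Turnover, fate classification, carryover/survival accounting, and
shaft-normalized spine-volume quantification.

Turnover rates follow the longitudinal-imaging convention: the generation
percentage over an interval is the number of spines present at the second
session but not the first, divided by the count present at the first
session, times 100; elimination mirrors it.  Over three sessions every spine
present at session 2 (plus those eliminated over the first interval) falls
into one of four fate patterns; the newly generated spines that persist to
session 3 are the *carryover* spines.

The volume stage quantifies spine size from a 3-D fluorescence stack: a
5-plane moving average along z approximates the summed spine fluorescence
near the diffraction limit, and the spine's peak is divided by the adjacent
dendrite shaft's peak to remove imaging-depth and expression differences.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SpineDataset

__all__ = [
    "FateLabel",
    "TurnoverResult",
    "generation_rate",
    "elimination_rate",
    "classify_fates",
    "carryover_fraction",
    "survival_rate",
    "zstack_moving_average",
    "normalized_spine_volume",
    "small_large_partition",
]


class FateLabel(enum.Enum):
    """Fate of a spine across three sessions (1 -> 2 -> 3)."""

    PRE_EXISTING_SURVIVED = "pre_existing_survived"   # (T, T, T)
    PRE_EXISTING_LOST = "pre_existing_lost"           # (T, T, F)
    GENERATED_SURVIVED = "generated_survived"         # (F, T, T)  carryover
    GENERATED_LOST = "generated_lost"                 # (F, T, F)
    ELIMINATED_EARLY = "eliminated_1_2"               # (T, F, *)  reported separately
    LATE_GENERATED = "generated_2_3"                  # (F, F, T)  not a fate class


@dataclass
class TurnoverResult:
    """Pooled and per-dendrite turnover percentages for one interval."""

    kind: str                       # "generation" | "elimination"
    interval: tuple[int, int]
    n_events: int
    n_baseline: int
    pooled_pct: float
    per_dendrite: pd.DataFrame     # columns: dendrite_id, n_events, n_baseline, pct
    undefined_dendrites: list[str]  # zero baseline; excluded from means

    @property
    def mean_dendrite_pct(self) -> float:
        vals = self.per_dendrite["pct"].dropna()
        return float(vals.mean()) if len(vals) else float("nan")


def _turnover(dataset: SpineDataset, interval: tuple[int, int], kind: str) -> TurnoverResult:
    s_a, s_b = interval
    if dataset.n_sessions and (s_b >= dataset.n_sessions or s_a < 0):
        raise ValueError(f"interval {interval} outside the {dataset.n_sessions} sessions")
    rows = []
    undefined = []
    n_events_total = 0
    n_base_total = 0
    for d in dataset.dendrites:
        spines = dataset.spines_on(d.dendrite_id)
        n_base = sum(s.present[s_a] for s in spines)
        if kind == "generation":
            n_ev = sum((not s.present[s_a]) and s.present[s_b] for s in spines)
        else:
            n_ev = sum(s.present[s_a] and (not s.present[s_b]) for s in spines)
        pct = 100.0 * n_ev / n_base if n_base else float("nan")
        if not n_base:
            undefined.append(d.dendrite_id)
        rows.append(
            {"dendrite_id": d.dendrite_id, "n_events": n_ev, "n_baseline": n_base, "pct": pct}
        )
        n_events_total += n_ev
        n_base_total += n_base
    pooled = 100.0 * n_events_total / n_base_total if n_base_total else float("nan")
    return TurnoverResult(
        kind=kind,
        interval=interval,
        n_events=n_events_total,
        n_baseline=n_base_total,
        pooled_pct=pooled,
        per_dendrite=pd.DataFrame(rows),
        undefined_dendrites=undefined,
    )


def generation_rate(dataset: SpineDataset, interval: tuple[int, int] = (0, 1)) -> TurnoverResult:
    """Percentage of spines present at ``s_b`` but not ``s_a``, relative to the
    count present at ``s_a`` (per dendrite and pooled)."""
    return _turnover(dataset, interval, "generation")


def elimination_rate(dataset: SpineDataset, interval: tuple[int, int] = (0, 1)) -> TurnoverResult:
    """Percentage of spines present at ``s_a`` but not ``s_b``, relative to the
    count present at ``s_a``."""
    return _turnover(dataset, interval, "elimination")


def classify_fates(dataset: SpineDataset) -> dict[str, FateLabel]:
    """Assign the three-session fate pattern to every spine.

    Requires exactly three sessions.  Spines absent throughout raise during
    validation, so every spine receives a label; the four fate classes
    partition the spines present at session 2 plus those eliminated over the
    first interval, while ``LATE_GENERATED`` covers (F, F, T).
    """
    if dataset.n_sessions != 3:
        raise ValueError("fate classification is defined for exactly 3 sessions")
    out: dict[str, FateLabel] = {}
    for s in dataset.spines:
        p1, p2, p3 = s.present
        if p1 and not p2:
            out[s.spine_id] = FateLabel.ELIMINATED_EARLY
        elif p1 and p2 and p3:
            out[s.spine_id] = FateLabel.PRE_EXISTING_SURVIVED
        elif p1 and p2:
            out[s.spine_id] = FateLabel.PRE_EXISTING_LOST
        elif p2 and p3:
            out[s.spine_id] = FateLabel.GENERATED_SURVIVED
        elif p2:
            out[s.spine_id] = FateLabel.GENERATED_LOST
        else:
            out[s.spine_id] = FateLabel.LATE_GENERATED
    return out


def carryover_fraction(
    dataset: SpineDataset,
    subset: str = "all",
    threshold_um: float = 3.0,
):
    """Fraction of carryover spines (newly generated, then surviving) among
    all spines present at session 1.

    ``subset`` restricts the numerator to ``clustered`` or ``non_clustered``
    generated spines (membership computed within-dendrite at
    ``threshold_um``); the denominator is always the pooled session-1 spine
    count.  Returns ``(fraction, n_carryover, n_total)``.
    """
    from .cluster_null import count_clustered_generated

    if subset not in ("all", "clustered", "non_clustered"):
        raise ValueError(f"unknown subset {subset!r}")
    fates = classify_fates(dataset)
    n_total = sum(s.present[0] for s in dataset.spines)
    if subset == "all":
        members = {sid for sid, f in fates.items() if f is FateLabel.GENERATED_SURVIVED}
    else:
        flags, _ = count_clustered_generated(dataset, (0, 1), threshold_um)
        want = subset == "clustered"
        members = {
            sid
            for sid, f in fates.items()
            if f is FateLabel.GENERATED_SURVIVED and flags.get(sid, False) == want
        }
    n_carry = len(members)
    fraction = n_carry / n_total if n_total else 0.0
    return fraction, n_carry, n_total


def survival_rate(dataset: SpineDataset, cohort: str = "newly_generated") -> float:
    """Percentage of session-2-present spines of a cohort still present at
    session 3.

    ``newly_generated``: 100*GS/(GS+GL); ``pre_existing``:
    100*survived/(survived+lost).  Raises on an empty cohort.
    """
    fates = classify_fates(dataset)
    counts = {f: 0 for f in FateLabel}
    for f in fates.values():
        counts[f] += 1
    if cohort == "newly_generated":
        num = counts[FateLabel.GENERATED_SURVIVED]
        den = num + counts[FateLabel.GENERATED_LOST]
    elif cohort == "pre_existing":
        num = counts[FateLabel.PRE_EXISTING_SURVIVED]
        den = num + counts[FateLabel.PRE_EXISTING_LOST]
    else:
        raise ValueError(f"unknown cohort {cohort!r}")
    if den == 0:
        raise ValueError(f"empty cohort {cohort!r}: survival rate undefined")
    return 100.0 * num / den


# ---------------------------------------------------------------------------
# Volume quantification


def zstack_moving_average(stack: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving average along z (axis 0) with a centered window.

    Edge planes use the truncated window (no padding intensity is invented).
    The output has the same shape as the input.
    """
    stack = np.asarray(stack, dtype=float)
    nz = stack.shape[0]
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > nz:
        raise ValueError(f"window {window} exceeds the {nz} planes")
    half = window // 2
    csum = np.cumsum(stack, axis=0)
    out = np.empty_like(stack)
    for z in range(nz):
        lo, hi = max(0, z - half), min(nz - 1, z + half)
        total = csum[hi] - (csum[lo - 1] if lo > 0 else 0)
        out[z] = total / (hi - lo + 1)
    return out


def _roi_slices(roi: dict) -> tuple[slice, slice, slice]:
    return (
        slice(roi["z0"], roi["z1"]),
        slice(roi["y0"], roi["y1"]),
        slice(roi["x0"], roi["x1"]),
    )


def normalized_spine_volume(
    stack: np.ndarray,
    spine_roi: dict,
    shaft_roi: dict,
    window: int = 5,
) -> float:
    """Shaft-normalized spine volume from a fluorescence z-stack.

    ROIs are ``{z0, z1, y0, y1, x0, x1}`` (0-based, half-open).  The statistic
    is the maximum of the z-moving-averaged stack over the spine ROI divided
    by the maximum over the shaft ROI — invariant to global intensity
    scaling.
    """
    sz, sy, sx = _roi_slices(spine_roi)
    hz, hy, hx = _roi_slices(shaft_roi)
    smoothed = zstack_moving_average(stack, window)
    spine_peak = float(np.max(smoothed[sz, sy, sx]))
    shaft_peak = float(np.max(smoothed[hz, hy, hx]))
    if shaft_peak <= 0 or not math.isfinite(shaft_peak):
        raise ValueError("degenerate shaft ROI: nonpositive peak intensity")
    return spine_peak / shaft_peak


def small_large_partition(volumes, v_threshold: float = 0.15):
    """Split volume indices into small (V <= threshold) and large (V > threshold).

    Ties at the threshold go to the small group.  Returns two index arrays.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size and not np.all(np.isfinite(volumes)):
        raise ValueError("volumes must be finite")
    idx = np.arange(volumes.size)
    small = idx[volumes <= v_threshold]
    large = idx[volumes > v_threshold]
    return small, large
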