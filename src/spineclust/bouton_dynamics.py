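"""Axonal bouton detection, cross-session identity matching, and
projection-stratified turnover.

Boutons are presynaptic varicosities that show up as bright swellings along
an axon's intensity profile.  The detection rule is a ratio test: a local
maximum is a bouton call iff its peak intensity is at least twice the
flanking axon-backbone intensity, estimated as the median of two windows on
either side of the peak (other candidate peaks excluded).  The rule is
scale-free, so detection is invariant to global intensity changes.

Across sessions, calls within 1 µm are treated as the same bouton (greedy
closest-first matching); unmatched calls in the later session are generated
boutons, unmatched calls in the earlier session eliminated ones.  This
threshold rule can overestimate turnover — a sub-threshold bouton that
brightens past 2x looks newly generated — which is a documented property of
the detection criterion, not of the matching.

Rates are reported both per unit axon length (events/µm over the interval)
and as percentages of the mean bouton density of the two sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "IntensityProfile",
    "BoutonCall",
    "detect_boutons",
    "match_boutons",
    "bouton_density",
    "bouton_rates",
    "stratify_by_projection",
]


@dataclass
class IntensityProfile:
    """Brightness sampled along an axon shaft."""

    axon_id: str
    positions_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions_um.shape != self.intensity.shape:
            raise ValueError("positions and intensity must have the same length")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class BoutonCall:
    position_um: float
    size_ratio: float


def detect_boutons(
    profile: IntensityProfile,
    backbone_window_um: float = 2.0,
    min_ratio: float = 2.0,
    exclusion_um: float = 1.0,
) -> list[BoutonCall]:
    """Call boutons on a profile with the two-fold flanking-backbone rule.

    Candidate peaks are local maxima with prominence above a quarter of the
    profile median (a relative floor, preserving scale invariance).  For each
    candidate the backbone is the median intensity over
    ``[p - 2w, p - w] U [p + w, p + 2w]`` excluding samples within
    ``exclusion_um`` of other candidates; a candidate becomes a call iff
    peak/backbone >= ``min_ratio``.
    """
    x, y = profile.positions_um, profile.intensity
    if x.size < 3:
        raise ValueError("profile needs at least 3 samples")
    scale = float(np.median(np.abs(y)))
    if scale <= 0:
        return []
    peaks, _ = find_peaks(y, prominence=0.25 * scale)
    if peaks.size == 0:
        return []
    w = backbone_window_um
    calls: list[BoutonCall] = []
    for p in peaks:
        px = x[p]
        in_flank = ((x >= px - 2 * w) & (x <= px - w)) | (
            (x >= px + w) & (x <= px + 2 * w)
        )
        others = peaks[peaks != p]
        if others.size:
            near_other = np.min(np.abs(x[:, None] - x[others][None, :]), axis=1) <= exclusion_um
            in_flank &= ~near_other
        backbone = float(np.median(y[in_flank])) if np.any(in_flank) else scale
        if backbone <= 0:
            continue
        ratio = float(y[p]) / backbone
        if ratio >= min_ratio:
            calls.append(BoutonCall(float(px), ratio))
    return calls


def match_boutons(
    session_a: list[BoutonCall],
    session_b: list[BoutonCall],
    tolerance_um: float = 1.0,
):
    """Greedy closest-first identity matching between two sessions.

    Returns ``(matched, generated, eliminated)``: matched is a list of
    (call_a, call_b) pairs with |delta| <= tolerance; unmatched calls in b
    are generated, unmatched in a eliminated.  Swapping the sessions swaps
    the generated and eliminated lists exactly.
    """
    pairs = sorted(
        (
            (abs(a.position_um - b.position_um), i, j)
            for i, a in enumerate(session_a)
            for j, b in enumerate(session_b)
            if abs(a.position_um - b.position_um) <= tolerance_um
        ),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((session_a[i], session_b[j]))
    generated = [b for j, b in enumerate(session_b) if j not in used_b]
    eliminated = [a for i, a in enumerate(session_a) if i not in used_a]
    return matched, generated, eliminated


def bouton_density(n_calls: int, axon_length_um: float) -> float:
    """Boutons per µm of axon."""
    if axon_length_um <= 0:
        raise ValueError("axon length must be positive")
    return n_calls / axon_length_um


def bouton_rates(
    session_a: list[BoutonCall],
    session_b: list[BoutonCall],
    axon_length_um: float,
    tolerance_um: float = 1.0,
) -> dict:
    """Generation/elimination over one interval, per length and as percent.

    Per-length rates divide the event counts by the axon length; percentage
    rates divide the per-length rates by the mean bouton density of the two
    sessions (x100).  A zero mean density leaves the percentages undefined
    (NaN, flagged).
    """
    matched, generated, eliminated = match_boutons(session_a, session_b, tolerance_um)
    per_len_gen = len(generated) / axon_length_um
    per_len_elim = len(eliminated) / axon_length_um
    mean_density = (
        bouton_density(len(session_a), axon_length_um)
        + bouton_density(len(session_b), axon_length_um)
    ) / 2
    if mean_density > 0:
        pct_gen = 100.0 * per_len_gen / mean_density
        pct_elim = 100.0 * per_len_elim / mean_density
        undefined = False
    else:
        pct_gen = pct_elim = float("nan")
        undefined = True
    return {
        "n_matched": len(matched),
        "n_generated": len(generated),
        "n_eliminated": len(eliminated),
        "per_length_generation": per_len_gen,
        "per_length_elimination": per_len_elim,
        "mean_density": mean_density,
        "pct_generation": pct_gen,
        "pct_elimination": pct_elim,
        "undefined": undefined,
    }


def stratify_by_projection(
    per_axon: pd.DataFrame,
    by: tuple[str, ...] = ("group", "projection"),
    value_columns: tuple[str, ...] = ("pct_generation", "pct_elimination"),
) -> pd.DataFrame:
    """Summarize per-axon rates by condition (mean ± s.e.m. and n).

    ``per_axon`` must carry the grouping columns plus the value columns.
    Empty strata simply do not appear; callers should check the returned
    index against the expected condition grid.
    """
    for col in (*by, *value_columns):
        if col not in per_axon.columns:
            raise ValueError(f"missing column {col!r}")
    g = per_axon.groupby(list(by))
    out = {}
    for col in value_columns:
        out[(col, "mean")] = g[col].mean()
        out[(col, "sem")] = g[col].sem()
        out[(col, "n")] = g[col].count()
    return pd.DataFrame(out)
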