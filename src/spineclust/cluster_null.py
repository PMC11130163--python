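"""Clustering-bias inference for 1-D synaptic event positions.

Newly generated (or eliminated) spines are points on linear branchlets.  To
ask whether they appear closer together than chance, the observed statistic
is the *clustering probability*: the fraction of consecutive-neighbour gaps
no larger than a distance threshold (3 µm by default), computed after
joining all branchlets end-to-end.  Because the join order is arbitrary, the
observed statistic is averaged over random concatenation orders (1000 by
default).  The null model redraws the same number of events uniformly — on
the concatenated pseudo-dendrite (``concatenated`` mode) or independently
per dendrite with each dendrite's own event count fixed (``per_dendrite``
mode) — and the empirical P-value is the fraction of Monte Carlo iterations
whose clustering probability is at least the observed value.

A threshold sweep locates the distance at which observed clustering exceeds
chance by the largest margin (the Youden-style optimal cut-off), and
crosstalk distances measure how close newly generated spines fall to the
nearest eliminated spine of the same interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core_io import SpineDataset

__all__ = [
    "EventSet",
    "ClusterTestResult",
    "events_from_dataset",
    "concatenate",
    "adjacent_gaps",
    "clustering_probability",
    "observed_clustering",
    "monte_carlo_null",
    "count_clustered_generated",
    "threshold_sweep",
    "crosstalk_distances",
]

DEFAULT_THRESHOLD_UM = 3.0


@dataclass
class EventSet:
    """Per-dendrite sorted positions of one event type over one interval."""

    event_type: str                      # "generated" | "eliminated"
    positions: dict[str, np.ndarray]     # dendrite_id -> sorted positions (µm)
    lengths: dict[str, float]            # dendrite_id -> branchlet length (µm)

    def __post_init__(self) -> None:
        for d_id, pos in self.positions.items():
            pos = np.sort(np.asarray(pos, dtype=float))
            if d_id not in self.lengths:
                raise ValueError(f"no length for dendrite {d_id!r}")
            if pos.size and (pos[0] < 0 or pos[-1] > self.lengths[d_id]):
                raise ValueError(f"event outside dendrite {d_id!r}")
            self.positions[d_id] = pos

    @property
    def n_events(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths.values()))

    @property
    def dendrite_ids(self) -> list[str]:
        return sorted(self.lengths)


@dataclass
class ClusterTestResult:
    """Outcome of the Monte Carlo clustering-bias test at one threshold."""

    threshold_um: float
    observed_prob: float
    observed_pair_count: int
    null_mean: float
    null_p50: float
    null_p95: float
    iterations: int
    empirical_p: float
    mode: str
    seed: int
    n_events: int
    total_length_um: float
    null_probs: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self, histogram_bins: int = 20) -> dict:
        out = {
            "threshold_um": self.threshold_um,
            "observed_prob": self.observed_prob,
            "observed_pair_count": self.observed_pair_count,
            "null_mean": self.null_mean,
            "null_p50": self.null_p50,
            "null_p95": self.null_p95,
            "iterations": self.iterations,
            "empirical_p": self.empirical_p,
            "mode": self.mode,
            "seed": self.seed,
            "n_events": self.n_events,
            "total_length_um": self.total_length_um,
        }
        if self.null_probs is not None:
            counts, edges = np.histogram(self.null_probs, bins=histogram_bins)
            out["null_histogram"] = {
                "counts": counts.tolist(),
                "edges": edges.tolist(),
            }
        return out


def events_from_dataset(
    dataset: SpineDataset, interval: tuple[int, int], event_type: str
) -> EventSet:
    """Extract generated or eliminated spine positions for one interval.

    ``interval`` is a pair of 0-based session indices ``(s_a, s_b)``; a
    generation event is absent at ``s_a`` and present at ``s_b``, an
    elimination event the reverse.
    """
    s_a, s_b = interval
    if event_type not in ("generated", "eliminated"):
        raise ValueError(f"unknown event type {event_type!r}")
    lengths = {d.dendrite_id: d.length_um for d in dataset.dendrites}
    positions: dict[str, list[float]] = {d_id: [] for d_id in lengths}
    for s in dataset.spines:
        if event_type == "generated":
            hit = not s.present[s_a] and s.present[s_b]
        else:
            hit = s.present[s_a] and not s.present[s_b]
        if hit:
            positions[s.dendrite_id].append(s.position_um)
    return EventSet(
        event_type,
        {d: np.asarray(p) for d, p in positions.items()},
        lengths,
    )


def concatenate(events: EventSet, order: list[str]) -> tuple[float, np.ndarray]:
    """Join dendrites end-to-end in ``order``; events shift by cumulative length.

    Returns ``(total_length, sorted offset positions)``.  The event multiset
    is preserved; only the offsets depend on the order.
    """
    if sorted(order) != events.dendrite_ids:
        raise ValueError("order must be a permutation of the dendrite ids")
    offset = 0.0
    out = []
    for d_id in order:
        out.append(events.positions[d_id] + offset)
        offset += events.lengths[d_id]
    pos = np.sort(np.concatenate(out)) if out else np.empty(0)
    return offset, pos


def adjacent_gaps(positions: np.ndarray) -> np.ndarray:
    """Distances between consecutive sorted positions (n - 1 gaps)."""
    positions = np.sort(np.asarray(positions, dtype=float))
    if positions.size < 2:
        return np.empty(0)
    return np.diff(positions)


def clustering_probability(gaps: np.ndarray, threshold_um: float) -> float:
    """Fraction of gaps within the threshold ("within" is inclusive).

    Empty gap lists yield 0 by convention.
    """
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size == 0:
        return 0.0
    return float(np.mean(gaps <= threshold_um))


def observed_clustering(
    events: EventSet,
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    n_permutations: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean clustering probability over random concatenation orders."""
    if events.n_events < 2:
        raise ValueError("need at least two events to form a gap")
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = events.dendrite_ids
    if len(ids) == 1:
        _, pos = concatenate(events, ids)
        return clustering_probability(adjacent_gaps(pos), threshold_um)
    total = 0.0
    ids_arr = np.asarray(ids, dtype=object)
    for _ in range(n_permutations):
        order = list(ids_arr[rng.permutation(len(ids))])
        _, pos = concatenate(events, order)
        total += clustering_probability(adjacent_gaps(pos), threshold_um)
    return total / n_permutations


def _null_concatenated(
    n: int, total_length: float, threshold_um: float, iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    draws = rng.uniform(0.0, total_length, size=(iterations, n))
    draws.sort(axis=1)
    gaps = np.diff(draws, axis=1)
    return np.mean(gaps <= threshold_um, axis=1)


def _null_per_dendrite(
    events: EventSet, threshold_um: float, iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    hits = np.zeros(iterations)
    n_gaps = 0
    for d_id in events.dendrite_ids:
        n = events.positions[d_id].size
        if n < 2:
            continue
        draws = rng.uniform(0.0, events.lengths[d_id], size=(iterations, n))
        draws.sort(axis=1)
        gaps = np.diff(draws, axis=1)
        hits += np.sum(gaps <= threshold_um, axis=1)
        n_gaps += n - 1
    if n_gaps == 0:
        return np.zeros(iterations)
    return hits / n_gaps


def monte_carlo_null(
    events: EventSet,
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    iterations: int = 100_000,
    mode: str = "concatenated",
    seed: int = 0,
    n_permutations: int = 1000,
    observed: float | None = None,
    keep_null: bool = True,
    midp: bool = False,
) -> ClusterTestResult:
    """Monte Carlo uniform-null test of clustering bias.

    The observed statistic (unless supplied) is the concatenation-averaged
    clustering probability in ``concatenated`` mode, or the pooled
    within-dendrite statistic in ``per_dendrite`` mode.  ``empirical_p`` is
    the plain fraction of iterations with null probability >= observed
    (resolution ``1/iterations``); set ``midp=False`` (default) for that
    convention or ``True`` for the (k+1)/(n+1) correction.

    The observed average and the null draws use independent child streams of
    ``seed``, so either half can be recomputed without perturbing the other.
    """
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    if mode not in ("concatenated", "per_dendrite"):
        raise ValueError(f"unknown mode {mode!r}")
    if events.n_events < 2:
        raise ValueError("need at least two events")
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_obs = np.random.default_rng(ss[0])
    rng_null = np.random.default_rng(ss[1])
    if observed is None:
        if mode == "concatenated":
            observed = observed_clustering(
                events, threshold_um, n_permutations=n_permutations, rng=rng_obs
            )
        else:
            pooled = np.concatenate(
                [adjacent_gaps(events.positions[d]) for d in events.dendrite_ids]
            )
            observed = clustering_probability(pooled, threshold_um)
    if mode == "concatenated":
        null = _null_concatenated(
            events.n_events, events.total_length, threshold_um, iterations, rng_null
        )
    else:
        null = _null_per_dendrite(events, threshold_um, iterations, rng_null)
    k = int(np.sum(null >= observed))
    p = (k + 1) / (iterations + 1) if midp else k / iterations
    return ClusterTestResult(
        threshold_um=threshold_um,
        observed_prob=float(observed),
        observed_pair_count=events.n_events - 1,
        null_mean=float(null.mean()),
        null_p50=float(np.percentile(null, 50)),
        null_p95=float(np.percentile(null, 95)),
        iterations=iterations,
        empirical_p=float(p),
        mode=mode,
        seed=seed,
        n_events=events.n_events,
        total_length_um=events.total_length,
        null_probs=null if keep_null else None,
    )


def count_clustered_generated(
    dataset: SpineDataset,
    interval: tuple[int, int],
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    event_type: str = "generated",
):
    """Flag event spines with a same-interval partner within the threshold.

    Clustering here is within-dendrite (no concatenation): an event spine is
    clustered iff another event spine of the same interval lies within
    ``threshold_um`` on the same dendrite.  Returns ``(flags, per_dendrite)``
    where ``flags`` maps spine_id -> bool and ``per_dendrite`` maps
    dendrite_id -> percentage of clustered event spines relative to the
    spines present at the interval's first session on that dendrite.
    """
    s_a, s_b = interval
    flags: dict[str, bool] = {}
    per_dendrite: dict[str, float] = {}
    by_dendrite: dict[str, list] = {d.dendrite_id: [] for d in dataset.dendrites}
    baseline: dict[str, int] = {d.dendrite_id: 0 for d in dataset.dendrites}
    for s in dataset.spines:
        if event_type == "generated":
            hit = not s.present[s_a] and s.present[s_b]
        else:
            hit = s.present[s_a] and not s.present[s_b]
        if hit:
            by_dendrite[s.dendrite_id].append(s)
        if s.present[s_a]:
            baseline[s.dendrite_id] += 1
    for d_id, group in by_dendrite.items():
        n_clustered = 0
        for s in group:
            clustered = any(
                o.spine_id != s.spine_id
                and abs(o.position_um - s.position_um) <= threshold_um
                for o in group
            )
            flags[s.spine_id] = clustered
            n_clustered += clustered
        per_dendrite[d_id] = (
            100.0 * n_clustered / baseline[d_id] if baseline[d_id] else float("nan")
        )
    return flags, per_dendrite


def threshold_sweep(
    events: EventSet,
    thresholds: list[float] = (3.0, 6.0, 9.0),
    iterations: int = 100_000,
    mode: str = "concatenated",
    seed: int = 0,
    n_permutations: int = 1000,
):
    """Run the clustering test at several thresholds and pick the optimal one.

    Returns ``(results, youden_threshold)``.  The optimal cut-off maximizes
    observed-minus-chance clustering probability (Youden-style separation of
    the observed and null distributions); ties break toward the smaller
    threshold.
    """
    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ValueError("need at least two thresholds to sweep")
    results = {}
    for t in sorted(thresholds):
        results[t] = monte_carlo_null(
            events,
            threshold_um=t,
            iterations=iterations,
            mode=mode,
            seed=seed,
            n_permutations=n_permutations,
            keep_null=False,
        )
    best = max(
        sorted(results),  # ascending: first max wins ties -> smaller threshold
        key=lambda t: results[t].observed_prob - results[t].null_mean,
    )
    return results, best


def crosstalk_distances(
    generated: EventSet, eliminated: EventSet
) -> dict[str, list[float | None]]:
    """Nearest eliminated-spine distance for each generated spine.

    Distances are within-dendrite; a dendrite with generated spines but no
    eliminated spines contributes ``None`` entries ("no partner").
    """
    out: dict[str, list[float | None]] = {}
    for d_id in generated.dendrite_ids:
        gen = generated.positions[d_id]
        elim = eliminated.positions.get(d_id, np.empty(0))
        dists: list[float | None] = []
        for g in gen:
            if elim.size == 0:
                dists.append(None)
            else:
                dists.append(float(np.min(np.abs(elim - g))))
        out[d_id] = dists
    return out


def exhaustive_observed_clustering(
    events: EventSet, threshold_um: float
) -> float:
    """Exact all-orders average of the concatenated clustering probability.

    Enumeration over all dendrite orderings; only feasible for a handful of
    dendrites (used as an oracle for :func:`observed_clustering`).
    """
    ids = events.dendrite_ids
    vals = []
    for order in itertools.permutations(ids):
        _, pos = concatenate(events, list(order))
        vals.append(clustering_probability(adjacent_gaps(pos), threshold_um))
    return float(np.mean(vals))
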