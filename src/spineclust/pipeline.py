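"""Pipeline orchestration: validation -> turnover -> fates -> clustering ->
carryover contingency tables, plus period-wise batch runs for multi-session
(time-course) datasets.

Every stochastic stage records its seed and iteration count in the report,
and the whole run is deterministic given the configuration.  Delegated
group-comparison statistics (rank tests, ANOVA) are deliberately not part of
the report; the report carries the per-dendrite vectors they would consume.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import __version__
from .cluster_null import (
    count_clustered_generated,
    events_from_dataset,
    monte_carlo_null,
    threshold_sweep,
)
from .core_io import SpineDataset, validate
from .spine_dynamics import (
    FateLabel,
    carryover_fraction,
    classify_fates,
    elimination_rate,
    generation_rate,
    survival_rate,
)
from .stats_concordance import fisher_exact_2x2, table_from_counts

__all__ = [
    "RunConfig",
    "run_spine_pipeline",
    "run_period_series",
    "compare_carryover",
]


@dataclass
class RunConfig:
    """Knobs of a full spine-pipeline run."""

    thresholds: tuple[float, ...] = (3.0, 6.0, 9.0)
    primary_threshold_um: float = 3.0
    iterations: int = 100_000
    n_permutations: int = 1000
    mode: str = "concatenated"
    seed: int = 0
    interval: tuple[int, int] = (0, 1)
    event_types: tuple[str, ...] = ("generated", "eliminated")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _clustering_stage(dataset, interval, config: RunConfig, seed: int) -> dict:
    out: dict = {}
    for event_type in config.event_types:
        events = events_from_dataset(dataset, interval, event_type)
        if events.n_events < 2:
            out[event_type] = {"skipped": f"fewer than 2 {event_type} events"}
            continue
        sweep, youden = threshold_sweep(
            events,
            thresholds=list(config.thresholds),
            iterations=config.iterations,
            mode=config.mode,
            seed=seed,
            n_permutations=config.n_permutations,
        )
        out[event_type] = {
            "per_threshold": {str(t): r.to_dict() for t, r in sweep.items()},
            "youden_threshold_um": youden,
        }
    return out


def run_spine_pipeline(dataset: SpineDataset, config: RunConfig | None = None) -> dict:
    """Execute the full three-session analysis and return a JSON-able report."""
    config = config or RunConfig()
    report: dict = {"version": __version__, "config": vars(config).copy()}
    report["config"]["thresholds"] = list(config.thresholds)
    report["config"]["event_types"] = list(config.event_types)
    report["config"]["interval"] = list(config.interval)

    vrep = validate(dataset)
    if not vrep.ok:
        raise PipelineError(
            f"validation: {len(vrep.violations)} violation(s); "
            f"first: {vrep.violations[0].message}"
        )
    if not dataset.spines:
        raise PipelineError("validation: dataset contains no spines")
    report["n_dendrites"] = len(dataset.dendrites)
    report["n_spines"] = len(dataset.spines)

    try:
        intervals = [(i, i + 1) for i in range(dataset.n_sessions - 1)]
        report["turnover"] = {}
        for iv in intervals:
            gen = generation_rate(dataset, iv)
            elim = elimination_rate(dataset, iv)
            report["turnover"][f"{iv[0]}-{iv[1]}"] = {
                "generation_pct": gen.pooled_pct,
                "elimination_pct": elim.pooled_pct,
                "n_generated": gen.n_events,
                "n_eliminated": elim.n_events,
                "n_baseline": gen.n_baseline,
            }
    except Exception as exc:  # pragma: no cover - defensive stage tagging
        raise PipelineError(f"turnover: {exc}") from exc

    if dataset.n_sessions == 3:
        try:
            fates = classify_fates(dataset)
            counts = {f.value: 0 for f in FateLabel}
            for f in fates.values():
                counts[f.value] += 1
            report["fates"] = counts
            report["survival"] = {
                "newly_generated_pct": _maybe(survival_rate, dataset, "newly_generated"),
                "pre_existing_pct": _maybe(survival_rate, dataset, "pre_existing"),
            }
            report["carryover"] = {}
            for subset in ("all", "clustered", "non_clustered"):
                frac, k, n = carryover_fraction(
                    dataset, subset, threshold_um=config.primary_threshold_um
                )
                report["carryover"][subset] = {
                    "fraction": frac,
                    "n_carryover": k,
                    "n_total": n,
                }
        except Exception as exc:
            raise PipelineError(f"fates: {exc}") from exc

    try:
        report["clustering"] = _clustering_stage(
            dataset, config.interval, config, config.seed
        )
        _, per_dendrite = count_clustered_generated(
            dataset, config.interval, config.primary_threshold_um
        )
        report["clustered_generated_pct_per_dendrite"] = per_dendrite
    except Exception as exc:
        raise PipelineError(f"clustering: {exc}") from exc

    return report


def compare_carryover(
    dataset_a: SpineDataset,
    dataset_b: SpineDataset,
    threshold_um: float = 3.0,
) -> dict:
    """Fisher exact comparison of carryover fractions between two groups.

    For each subset (all / clustered / non-clustered carryover spines) the
    2x2 table is (k, N - k) per group, where k is the subset's carryover
    count and N the group's pooled session-1 spine count; the two-sided
    exact P accompanies the counts and the between-group fold ratio of the
    fractions.
    """
    out: dict = {}
    for subset in ("all", "clustered", "non_clustered"):
        fa, ka, na = carryover_fraction(dataset_a, subset, threshold_um)
        fb, kb, nb = carryover_fraction(dataset_b, subset, threshold_um)
        table = table_from_counts(ka, na, kb, nb)
        out[subset] = {
            "counts": [ka, na, kb, nb],
            "fraction_a": fa,
            "fraction_b": fb,
            "fold_ratio_b_over_a": (fb / fa) if fa > 0 else None,
            "fisher_p": fisher_exact_2x2(table),
        }
    return out


def _maybe(fn, *args):
    try:
        return fn(*args)
    except ValueError:
        return None


def run_period_series(
    dataset: SpineDataset,
    periods: list[tuple[int, int]] | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Re-run the clustering test per consecutive-session period.

    For a (k+1)-session dataset the default periods are (0,1) ... (k-1,k) —
    the D0-3 / D3-6 / D6-9 layout when sessions are 3 days apart.  Each
    period is analyzed in isolation with its own child seed; the report
    carries a log10(empirical P) series per event type.
    """
    config = config or RunConfig()
    if periods is None:
        periods = [(i, i + 1) for i in range(dataset.n_sessions - 1)]
    for s_a, s_b in periods:
        if not 0 <= s_a < s_b < dataset.n_sessions:
            raise PipelineError(f"period ({s_a}, {s_b}) outside the sessions")
    report: dict = {"version": __version__, "periods": {}, "seed": config.seed}
    import math

    for idx, period in enumerate(periods):
        key = f"{period[0]}-{period[1]}"
        per = {}
        for event_type in config.event_types:
            events = events_from_dataset(dataset, period, event_type)
            if events.n_events < 2:
                per[event_type] = {"skipped": f"fewer than 2 {event_type} events"}
                continue
            result = monte_carlo_null(
                events,
                threshold_um=config.primary_threshold_um,
                iterations=config.iterations,
                mode=config.mode,
                seed=config.seed + idx,
                n_permutations=config.n_permutations,
                keep_null=False,
            )
            d = result.to_dict()
            d["log10_empirical_p"] = (
                math.log10(result.empirical_p) if result.empirical_p > 0 else None
            )
            per[event_type] = d
        report["periods"][key] = per
    return report
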