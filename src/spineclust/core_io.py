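"""Domain types, table readers/writers, and validation.

All spatial coordinates are 1-D arc length in micrometres, measured from the
proximal end of each branchlet, on the closed interval ``[0, L]``.  Presence
of a spine or bouton is a per-session boolean; a structure that temporarily
disappears and reappears is represented as e.g. ``(True, False, True)`` and
the re-gain counts as a new generation event downstream.

Tables are plain CSV (comma separated, UTF-8, mandatory header, booleans as
0/1).  A spine table carries one row per spine with columns
``spine_id, dendrite_id, position_um, present_s1 .. present_sk[, volume_norm]``
and a companion dendrite table carries
``dendrite_id, length_um, animal_id, group``.  Axon/bouton tables follow the
same pattern (see :func:`read_axon_table`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Dendrite",
    "SpineRecord",
    "SpineDataset",
    "Axon",
    "BoutonRecord",
    "AxonDataset",
    "ValidationReport",
    "Violation",
    "FormatError",
    "read_spine_table",
    "write_spine_table",
    "read_axon_table",
    "write_axon_table",
    "validate",
]

GROUPS = ("UE", "VPA")
PROJECTIONS = ("ipsilateral", "contralateral")


class FormatError(ValueError):
    """Raised when an input table is structurally unusable."""


@dataclass(frozen=True)
class Dendrite:
    """A single imaged dendritic branchlet."""

    dendrite_id: str
    length_um: float
    animal_id: str = ""
    group: str = "UE"


@dataclass(frozen=True)
class SpineRecord:
    """One spine tracked across imaging sessions.

    ``present`` holds one boolean per session (sessions are equally spaced;
    the default spacing is 3 days).  ``volume_norm`` is the dimensionless
    shaft-normalized spine volume, when measured.
    """

    spine_id: str
    dendrite_id: str
    position_um: float
    present: tuple[bool, ...]
    volume_norm: float | None = None


@dataclass
class SpineDataset:
    """Dendrites plus their longitudinally tracked spines."""

    dendrites: list[Dendrite]
    spines: list[SpineRecord]
    session_interval_days: int = 3

    @property
    def n_sessions(self) -> int:
        return len(self.spines[0].present) if self.spines else 0

    def dendrite_map(self) -> dict[str, Dendrite]:
        return {d.dendrite_id: d for d in self.dendrites}

    def spines_on(self, dendrite_id: str) -> list[SpineRecord]:
        return [s for s in self.spines if s.dendrite_id == dendrite_id]


@dataclass(frozen=True)
class Axon:
    """A single imaged axon segment with its projection label."""

    axon_id: str
    length_um: float
    animal_id: str = ""
    group: str = "UE"
    projection: str = "ipsilateral"


@dataclass(frozen=True)
class BoutonRecord:
    """One axonal bouton tracked across sessions.

    ``size_ratio`` is the peak intensity divided by the flanking axon
    backbone intensity; boutons admitted by detection satisfy
    ``size_ratio >= 2``.
    """

    bouton_id: str
    axon_id: str
    position_um: float
    present: tuple[bool, ...]
    size_ratio: float | None = None


@dataclass
class AxonDataset:
    axons: list[Axon]
    boutons: list[BoutonRecord]
    session_interval_days: int = 3

    @property
    def n_sessions(self) -> int:
        return len(self.boutons[0].present) if self.boutons else 0

    def axon_map(self) -> dict[str, Axon]:
        return {a.axon_id: a for a in self.axons}

    def boutons_on(self, axon_id: str) -> list[BoutonRecord]:
        return [b for b in self.boutons if b.axon_id == axon_id]


@dataclass(frozen=True)
class Violation:
    record_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok


# ---------------------------------------------------------------------------
# CSV I/O


def _present_columns(columns: Iterable[str]) -> list[str]:
    cols = [c for c in columns if re.fullmatch(r"present_s\d+", c)]
    return sorted(cols, key=lambda c: int(c.split("_s")[1]))


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"missing column {c!r} in {path}")


def read_spine_table(
    spine_path, dendrite_path, *, session_interval_days: int = 3
) -> SpineDataset:
    """Read a spine table and its companion dendrite table into a dataset.

    Raises :class:`FormatError` on missing columns and :class:`ValueError`
    (via :func:`validate`) if the resulting dataset breaks an invariant such
    as a spine referencing an unknown dendrite or an out-of-range position.
    """
    ddf = pd.read_csv(dendrite_path, dtype={"dendrite_id": str, "animal_id": str},
                      float_precision="round_trip")
    _require(ddf, ["dendrite_id", "length_um"], dendrite_path)
    sdf = pd.read_csv(spine_path, dtype={"spine_id": str, "dendrite_id": str},
                      float_precision="round_trip")
    _require(sdf, ["spine_id", "dendrite_id", "position_um"], spine_path)
    pcols = _present_columns(sdf.columns)
    if len(pcols) < 2:
        raise FormatError(
            f"need at least two present_s<k> columns in {spine_path}, found {pcols}"
        )
    dendrites = [
        Dendrite(
            dendrite_id=str(r.dendrite_id),
            length_um=float(r.length_um),
            animal_id=str(getattr(r, "animal_id", "")),
            group=str(getattr(r, "group", "UE")),
        )
        for r in ddf.itertuples(index=False)
    ]
    has_vol = "volume_norm" in sdf.columns
    spines = []
    for r in sdf.itertuples(index=False):
        vol = getattr(r, "volume_norm", None) if has_vol else None
        if vol is not None and pd.isna(vol):
            vol = None
        spines.append(
            SpineRecord(
                spine_id=str(r.spine_id),
                dendrite_id=str(r.dendrite_id),
                position_um=float(r.position_um),
                present=tuple(bool(int(getattr(r, c))) for c in pcols),
                volume_norm=None if vol is None else float(vol),
            )
        )
    ds = SpineDataset(dendrites, spines, session_interval_days=session_interval_days)
    report = validate(ds)
    if not report.ok:
        first = report.violations[0]
        raise ValueError(
            f"invalid spine dataset ({len(report.violations)} violation(s)); "
            f"first: {first.record_id}: {first.message}"
        )
    return ds


def write_spine_table(dataset: SpineDataset, spine_path, dendrite_path) -> None:
    """Write a dataset back to the two-CSV schema read by :func:`read_spine_table`."""
    pd.DataFrame(
        [
            {
                "dendrite_id": d.dendrite_id,
                "length_um": d.length_um,
                "animal_id": d.animal_id,
                "group": d.group,
            }
            for d in dataset.dendrites
        ]
    ).to_csv(dendrite_path, index=False)
    rows = []
    for s in dataset.spines:
        row = {
            "spine_id": s.spine_id,
            "dendrite_id": s.dendrite_id,
            "position_um": s.position_um,
        }
        for i, p in enumerate(s.present, start=1):
            row[f"present_s{i}"] = int(p)
        row["volume_norm"] = s.volume_norm
        rows.append(row)
    pd.DataFrame(rows).to_csv(spine_path, index=False)


def read_axon_table(
    bouton_path, axon_path, *, session_interval_days: int = 3
) -> AxonDataset:
    adf = pd.read_csv(axon_path, dtype={"axon_id": str, "animal_id": str},
                      float_precision="round_trip")
    _require(adf, ["axon_id", "length_um", "projection"], axon_path)
    bdf = pd.read_csv(bouton_path, dtype={"bouton_id": str, "axon_id": str},
                      float_precision="round_trip")
    _require(bdf, ["bouton_id", "axon_id", "position_um"], bouton_path)
    pcols = _present_columns(bdf.columns)
    if len(pcols) < 2:
        raise FormatError(
            f"need at least two present_s<k> columns in {bouton_path}, found {pcols}"
        )
    axons = [
        Axon(
            axon_id=str(r.axon_id),
            length_um=float(r.length_um),
            animal_id=str(getattr(r, "animal_id", "")),
            group=str(getattr(r, "group", "UE")),
            projection=str(r.projection),
        )
        for r in adf.itertuples(index=False)
    ]
    has_sr = "size_ratio" in bdf.columns
    boutons = []
    for r in bdf.itertuples(index=False):
        sr = getattr(r, "size_ratio", None) if has_sr else None
        if sr is not None and pd.isna(sr):
            sr = None
        boutons.append(
            BoutonRecord(
                bouton_id=str(r.bouton_id),
                axon_id=str(r.axon_id),
                position_um=float(r.position_um),
                present=tuple(bool(int(getattr(r, c))) for c in pcols),
                size_ratio=None if sr is None else float(sr),
            )
        )
    ds = AxonDataset(axons, boutons, session_interval_days=session_interval_days)
    report = validate(ds)
    if not report.ok:
        first = report.violations[0]
        raise ValueError(
            f"invalid axon dataset ({len(report.violations)} violation(s)); "
            f"first: {first.record_id}: {first.message}"
        )
    return ds


def write_axon_table(dataset: AxonDataset, bouton_path, axon_path) -> None:
    pd.DataFrame(
        [
            {
                "axon_id": a.axon_id,
                "length_um": a.length_um,
                "animal_id": a.animal_id,
                "group": a.group,
                "projection": a.projection,
            }
            for a in dataset.axons
        ]
    ).to_csv(axon_path, index=False)
    rows = []
    for b in dataset.boutons:
        row = {
            "bouton_id": b.bouton_id,
            "axon_id": b.axon_id,
            "position_um": b.position_um,
        }
        for i, p in enumerate(b.present, start=1):
            row[f"present_s{i}"] = int(p)
        row["size_ratio"] = b.size_ratio
        rows.append(row)
    pd.DataFrame(rows).to_csv(bouton_path, index=False)


# ---------------------------------------------------------------------------
# Validation


def validate(dataset: SpineDataset | AxonDataset) -> ValidationReport:
    """Check every type invariant; one violation per broken rule.

    The report is deterministic: violations are sorted by record id then rule.
    """
    if isinstance(dataset, SpineDataset):
        return _validate_generic(
            parents=dataset.dendrites,
            parent_id=lambda d: d.dendrite_id,
            parent_len=lambda d: d.length_um,
            children=dataset.spines,
            child_id=lambda s: s.spine_id,
            child_parent=lambda s: s.dendrite_id,
            child_pos=lambda s: s.position_um,
            child_present=lambda s: s.present,
            child_extra=_spine_extra,
            parent_kind="dendrite",
            child_kind="spine",
        )
    return _validate_generic(
        parents=dataset.axons,
        parent_id=lambda a: a.axon_id,
        parent_len=lambda a: a.length_um,
        children=dataset.boutons,
        child_id=lambda b: b.bouton_id,
        child_parent=lambda b: b.axon_id,
        child_pos=lambda b: b.position_um,
        child_present=lambda b: b.present,
        child_extra=_bouton_extra,
        parent_kind="axon",
        child_kind="bouton",
    )


def _spine_extra(s: SpineRecord) -> list[tuple[str, str]]:
    out = []
    if s.volume_norm is not None and s.volume_norm < 0:
        out.append(("volume_nonnegative", f"volume_norm {s.volume_norm} < 0"))
    return out


def _bouton_extra(b: BoutonRecord) -> list[tuple[str, str]]:
    out = []
    if b.size_ratio is not None and b.size_ratio < 2:
        # advisory: detection only admits >=2x peaks, so a smaller stored
        # ratio indicates an annotation inconsistency
        out.append(("size_ratio_two_fold", f"size_ratio {b.size_ratio} < 2"))
    return out


def _validate_generic(
    *,
    parents,
    parent_id,
    parent_len,
    children,
    child_id,
    child_parent,
    child_pos,
    child_present,
    child_extra,
    parent_kind,
    child_kind,
) -> ValidationReport:
    violations: list[Violation] = []
    seen_parents: dict[str, float] = {}
    for p in parents:
        pid = parent_id(p)
        if pid in seen_parents:
            violations.append(
                Violation(pid, f"{parent_kind}_id_unique", f"duplicate {parent_kind} id")
            )
        seen_parents[pid] = parent_len(p)
        if not parent_len(p) > 0:
            violations.append(
                Violation(pid, "length_positive", f"length_um {parent_len(p)} <= 0")
            )
    seen_children: set[str] = set()
    for c in children:
        cid = child_id(c)
        if cid in seen_children:
            violations.append(
                Violation(cid, f"{child_kind}_id_unique", f"duplicate {child_kind} id")
            )
        seen_children.add(cid)
        pid = child_parent(c)
        if pid not in seen_parents:
            violations.append(
                Violation(cid, "parent_exists", f"unknown {parent_kind} {pid!r}")
            )
        else:
            pos = child_pos(c)
            if not 0 <= pos <= seen_parents[pid]:
                violations.append(
                    Violation(
                        cid,
                        "position_in_range",
                        f"position out of range: {pos} not in [0, {seen_parents[pid]}]",
                    )
                )
        if not any(child_present(c)):
            violations.append(
                Violation(cid, "present_somewhere", "all presence flags are false")
            )
        violations.extend(Violation(cid, rule, msg) for rule, msg in child_extra(c))
    violations.sort(key=lambda v: (v.record_id, v.rule))
    return ValidationReport(violations)
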