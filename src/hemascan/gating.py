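"""Event gating and evoked-trait featurization.

Each blood sample yields one event cloud per analyzer channel; every event
records forward scatter (FSC), side scatter (SSC) and side fluorescence
(SFL).  Gates are axis-aligned boxes (lower inclusive, upper exclusive)
with priority ranks resolving overlaps.  For every donor x condition the
featurizer emits, per gate, the event count, the percentage of in-channel
events, and robust location/scale statistics (median, 1.4826xMAD robust
s.d., robust CV) along each optical axis, plus configured count ratios
such as NE2/NE4 (evoked neutrophils over total neutrophils).

Parameter names follow the grammar ``<CHANNEL>_<Condition>_<Gate>_<Stat>``
so that trait names are stable join keys across the QC, association and
scoring modules (e.g. ``WDF_Pam3CSK4_19h_NE2_Med_SFL``).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CHANNELS, INSTRUMENT_MAX, GateTemplate

AXES = ("FSC", "SSC", "SFL")
STAT_NAMES = (
    "Count",
    "Pct",
    "Med_FSC",
    "Med_SSC",
    "Med_SFL",
    "SD_FSC",
    "SD_SSC",
    "SD_SFL",
    "CV_FSC",
    "CV_SSC",
    "CV_SFL",
)

#: Gaussian-consistency constant: robust s.d. = 1.4826 x MAD.
MAD_SCALE = 1.4826

UNGATED = "ungated"


@dataclass
class EventTable:
    """Optical events for one donor, one condition, one channel."""

    donor: str
    condition: str
    channel: str
    events: np.ndarray  # N x 3, columns (FSC, SSC, SFL)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float).reshape(-1, 3)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.events.size and (
            not np.all(np.isfinite(self.events)) or np.any(self.events < 0)
        ):
            raise ValueError("event values must be finite and >= 0")

    @property
    def n(self) -> int:
        return self.events.shape[0]


@dataclass(frozen=True)
class GateDefinition:
    """Axis-aligned box gate; bounds are lower-inclusive, upper-exclusive."""

    name: str
    channel: str
    bounds: Mapping[str, tuple[float, float]]  # axis -> (lo, hi)
    priority: int

    def __post_init__(self) -> None:
        for axis, (lo, hi) in self.bounds.items():
            if axis not in AXES:
                raise ValueError(f"unknown axis {axis!r}")
            if not lo < hi:
                raise ValueError(f"gate {self.name}: bound {axis} has lower >= upper")


@dataclass(frozen=True)
class RatioDefinition:
    """A count ratio; numerator/denominator may sum several gates (e.g. the
    total-neutrophil denominator NE4 = NE1+NE2+NE3)."""

    name: str
    channel: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]


def default_gate_definitions(
    templates: Sequence[GateTemplate], half_width: float = 0.09 * INSTRUMENT_MAX
) -> list[GateDefinition]:
    """Boxes centred on the simulation gate anchors, priority by list order."""
    gates = []
    prio: dict[str, int] = {}
    for t in templates:
        rank = prio.get(t.channel, 0)
        prio[t.channel] = rank + 1
        bounds = {
            axis: (max(0.0, m - half_width), min(float(INSTRUMENT_MAX), m + half_width))
            for axis, m in zip(AXES, t.mean)
        }
        gates.append(GateDefinition(t.name, t.channel, bounds, rank))
    return gates


def default_ratio_definitions() -> list[RatioDefinition]:
    # NE4 (total neutrophils) is the union of the neutrophil gates.
    return [
        RatioDefinition("NE2/NE4", "WDF", ("NE2",), ("NE1", "NE2", "NE3")),
    ]


# ---------------------------------------------------------------------------
# I/O

# donor ids must not contain underscores; condition ids may (e.g. Pam3CSK4_19h)
_FILENAME_RE = re.compile(
    r"^(?P<donor>[^_]+)_(?P<condition>.+)_(?P<channel>WDF|WNR|RET|PLTF)$"
)


def write_events_csv(table: EventTable, directory: str) -> str:
    """Write one event table as ``<donor>_<condition>_<channel>.csv``."""
    path = os.path.join(
        directory, f"{table.donor}_{table.condition}_{table.channel}.csv"
    )
    pd.DataFrame(table.events, columns=list(AXES)).to_csv(path, index=False)
    return path


def read_events(
    path: str,
    fmt: str = "csv",
    donor: str | None = None,
    condition: str | None = None,
    channel: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> EventTable:
    """Read an event table from CSV.

    Donor, condition and channel default to the ``<donor>_<condition>_<channel>``
    filename pattern.  ``column_map`` renames instrument-specific column
    headers onto the canonical FSC/SSC/SFL axes.
    """
    if fmt.lower() not in ("csv",):
        raise ValueError(
            f"unsupported event format {fmt!r}; this build reads CSV event tables"
        )
    stem = os.path.splitext(os.path.basename(path))[0]
    m = _FILENAME_RE.match(stem)
    if m:
        donor = donor or m.group("donor")
        condition = condition or m.group("condition")
        channel = channel or m.group("channel")
    if donor is None or condition is None or channel is None:
        raise ValueError(
            "donor/condition/channel not given and not parseable from filename "
            f"{stem!r} (expected <donor>_<condition>_<channel>)"
        )
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [a for a in AXES if a not in df.columns]
    if missing:
        raise ValueError(
            f"channel columns {missing} not found in {path}; "
            f"available columns: {list(df.columns)}"
        )
    return EventTable(donor, condition, channel, df[list(AXES)].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Gating

def assign_gates(events: EventTable, gates: Sequence[GateDefinition]) -> np.ndarray:
    """Per-event gate label; the lowest priority rank wins on overlap.

    Events inside no gate are labelled ``"ungated"``.  Bounds are
    lower-inclusive / upper-exclusive so adjacent boxes tile without
    double counting.
    """
    relevant = sorted(
        (g for g in gates if g.channel == events.channel), key=lambda g: g.priority
    )
    ranks = [g.priority for g in relevant]
    if len(set(ranks)) != len(ranks):
        raise ValueError(f"duplicate gate priorities in channel {events.channel}")
    labels = np.full(events.n, UNGATED, dtype=object)
    unassigned = np.ones(events.n, dtype=bool)
    for g in relevant:
        inside = unassigned.copy()
        for axis, (lo, hi) in g.bounds.items():
            col = events.events[:, AXES.index(axis)]
            inside &= (col >= lo) & (col < hi)
        labels[inside] = g.name
        unassigned &= ~inside
    return labels


def robust_stats(values: np.ndarray) -> tuple[float, float, float]:
    """(median, robust s.d., robust CV%) of a vector.

    robust s.d. = 1.4826 x median(|x - median|); robust CV = 100 x
    robust s.d. / median, missing when the median is zero.  An empty
    vector yields three missing values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return (np.nan, np.nan, np.nan)
    if not np.all(np.isfinite(values)):
        raise ValueError("robust_stats requires finite values")
    med = float(np.median(values))
    sd = MAD_SCALE * float(np.median(np.abs(values - med)))
    cv = 100.0 * sd / med if med != 0 else np.nan
    return (med, sd, cv)


def derive_ratio(
    counts: Mapping[str, float],
    numerator: str | Sequence[str],
    denominator: str | Sequence[str],
) -> float:
    """Count ratio between (sums of) gates; missing when the denominator is 0."""
    num_gates = (numerator,) if isinstance(numerator, str) else tuple(numerator)
    den_gates = (denominator,) if isinstance(denominator, str) else tuple(denominator)
    for g in num_gates + den_gates:
        if g not in counts:
            raise KeyError(f"unknown gate {g!r}; counts has {sorted(counts)}")
    num = sum(counts[g] for g in num_gates)
    den = sum(counts[g] for g in den_gates)
    if den == 0:
        return np.nan
    return num / den


def featurize(
    tables: Iterable[EventTable],
    gates: Sequence[GateDefinition],
    ratios: Sequence[RatioDefinition] = (),
    min_count: int = 10,
) -> dict[str, float]:
    """Evoked-trait parameter vector for one donor x condition.

    Emits for every gate: Count, Pct of the in-channel event total, and the
    nine robust statistics over member events (statistics of gates with
    fewer than ``min_count`` events are reported missing, Count/Pct kept).
    Ratio parameters are computed from gate counts.  Channels absent from
    ``tables`` yield no parameters.
    """
    tables = list(tables)
    keys = {(t.donor, t.condition) for t in tables}
    if len(keys) > 1:
        raise ValueError(f"featurize got multiple (donor, condition) pairs: {keys}")
    seen_channels = [t.channel for t in tables]
    if len(set(seen_channels)) != len(seen_channels):
        raise ValueError("duplicate channel table for one (donor, condition)")

    row: dict[str, float] = {}
    counts_by_channel: dict[str, dict[str, int]] = {}
    condition = tables[0].condition if tables else ""
    for table in tables:
        labels = assign_gates(table, gates)
        chan_gates = [g for g in gates if g.channel == table.channel]
        counts: dict[str, int] = {}
        total = table.n
        for g in chan_gates:
            member = table.events[labels == g.name]
            count = member.shape[0]
            counts[g.name] = count
            prefix = f"{table.channel}_{table.condition}_{g.name}"
            row[f"{prefix}_Count"] = float(count)
            row[f"{prefix}_Pct"] = 100.0 * count / total if total else np.nan
            if count >= min_count:
                stats = [robust_stats(member[:, k]) for k in range(3)]
            else:
                stats = [(np.nan, np.nan, np.nan)] * 3
            for k, axis in enumerate(AXES):
                med, sd, cv = stats[k]
                row[f"{prefix}_Med_{axis}"] = med
                row[f"{prefix}_SD_{axis}"] = sd
                row[f"{prefix}_CV_{axis}"] = cv
        counts_by_channel[table.channel] = counts
    for r in ratios:
        if r.channel not in counts_by_channel:
            continue
        row[f"{r.channel}_{condition}_{r.name}"] = derive_ratio(
            counts_by_channel[r.channel], r.numerator, r.denominator
        )
    return row


def featurize_cohort(
    tables: Iterable[EventTable],
    gates: Sequence[GateDefinition],
    ratios: Sequence[RatioDefinition] = (),
    min_count: int = 10,
) -> pd.DataFrame:
    """Wide phenotype matrix (donors as index) across all conditions.

    Parameter names embed the condition, so one row per donor suffices.
    """
    by_key: dict[tuple[str, str], list[EventTable]] = {}
    for t in tables:
        by_key.setdefault((t.donor, t.condition), []).append(t)
    rows: dict[str, dict[str, float]] = {}
    for (donor, _cond), group in sorted(by_key.items()):
        rows.setdefault(donor, {}).update(featurize(group, gates, ratios, min_count))
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def phenotypes_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Long-format (donor, parameter, value) view of a wide phenotype matrix."""
    long = wide.reset_index(names="donor").melt(
        id_vars="donor", var_name="parameter", value_name="value"
    )
    return long.sort_values(["donor", "parameter"]).reset_index(drop=True)
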