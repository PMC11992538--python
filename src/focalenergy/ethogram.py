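"""Focal-animal ethogram: domain types, I/O, time budgets, and site summaries.

A focal sample is one continuous observation (~5 min) of a single bird,
scored into an exhaustive, mutually exclusive set of ten behavior
categories.  Behaviors partition the observed time: every second of the
sample belongs to exactly one bout, so per-behavior seconds sum to the
sample's total time and percentages sum to 100.

Three of the ten categories (diving, head-dipping, eye-submerging) are
foraging modes; prey-capture attempts resolve into the sample's
success/failure counts, and the per-sample environment record carries the
habitat covariates measured alongside the observation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIORS",
    "FORAGING",
    "Bout",
    "ForagingOutcome",
    "EnvironmentRecord",
    "FocalSample",
    "SiteSummary",
    "load_samples",
    "write_samples",
    "time_allocation",
    "behavior_frequency",
    "foraging_time",
    "sample_table",
    "summarize",
    "summary_frame",
]

#: The closed behavior vocabulary.  No operation accepts or emits any label
#: outside this set.
BEHAVIORS: tuple[str, ...] = (
    "resting",
    "running_on_water",
    "head_dipping",
    "diving",
    "flying",
    "eye_submerging",
    "swimming",
    "vigilance",
    "comfort",
    "feeding",
)

#: Foraging modes: underwater or surface prey search.
FORAGING: frozenset[str] = frozenset({"diving", "head_dipping", "eye_submerging"})

_TIME_TOL = 1e-6

#: Environment covariate CSV columns, in file order.
ENV_FIELDS: tuple[str, ...] = (
    "avg_fish_weight_g",
    "fish_biomass_g_m2",
    "temperature_C",
    "river_width_m",
    "water_depth_m",
    "water_velocity_m_s",
    "disturbance_number",
    "disturbance_duration_s",
    "disturbance_distance_m",
)


def _check_label(behavior: str, context: str = "") -> None:
    if behavior not in BEHAVIORS:
        where = f" ({context})" if context else ""
        raise ValueError(
            f"unknown behavior label {behavior!r}{where}; "
            f"expected one of {sorted(BEHAVIORS)}"
        )


@dataclass(frozen=True)
class Bout:
    """One uninterrupted run of a single behavior within a sample."""

    behavior: str
    duration: float  # seconds, strictly positive
    index: int  # ordinal position within the sample, 0-based

    def __post_init__(self) -> None:
        _check_label(self.behavior, f"bout index {self.index}")
        if not self.duration > 0:
            raise ValueError(
                f"bout duration must be > 0, got {self.duration} "
                f"({self.behavior}, index {self.index})"
            )


@dataclass(frozen=True)
class ForagingOutcome:
    """Prey-capture tally for one sample (SFF = success_count)."""

    success_count: int
    failure_count: int

    def __post_init__(self) -> None:
        if self.success_count < 0 or self.failure_count < 0:
            raise ValueError("foraging counts must be non-negative")


@dataclass(frozen=True)
class EnvironmentRecord:
    """Habitat covariates measured for one focal sample.

    Missing values (e.g. disturbance distance when no disturbance occurred)
    are NaN, never zero.
    """

    avg_fish_weight_g: float = math.nan
    fish_biomass_g_m2: float = math.nan
    temperature_C: float = math.nan
    river_width_m: float = math.nan
    water_depth_m: float = math.nan
    water_velocity_m_s: float = math.nan
    disturbance_number: float = math.nan
    disturbance_duration_s: float = math.nan
    disturbance_distance_m: float = math.nan

    def __post_init__(self) -> None:
        nonneg = (
            "avg_fish_weight_g",
            "fish_biomass_g_m2",
            "river_width_m",
            "water_depth_m",
            "water_velocity_m_s",
            "disturbance_number",
            "disturbance_duration_s",
        )
        for name in nonneg:
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        dn = self.disturbance_number
        if not math.isnan(dn) and dn != int(dn):
            raise ValueError(f"disturbance_number must be an integer, got {dn}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class FocalSample:
    """One focal-animal observation: bout sequence, foraging outcome, habitat."""

    sample_id: str
    site: str
    bouts: tuple[Bout, ...]
    outcome: ForagingOutcome
    environment: EnvironmentRecord
    total_time: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.bouts:
            raise ValueError(f"sample {self.sample_id!r} has no bouts")
        indices = [b.index for b in self.bouts]
        if sorted(indices) != list(range(len(self.bouts))):
            raise ValueError(
                f"sample {self.sample_id!r}: bout indices must be unique and "
                f"contiguous from 0, got {indices}"
            )
        total = float(sum(b.duration for b in self.bouts))
        if self.total_time is None:
            object.__setattr__(self, "total_time", total)
        elif abs(self.total_time - total) > _TIME_TOL:
            raise ValueError(
                f"sample {self.sample_id!r}: total_time {self.total_time} does "
                f"not equal sum of bout durations {total}"
            )
        if not self.total_time > 0:
            raise ValueError(f"sample {self.sample_id!r}: total_time must be > 0")
        n_forage = sum(1 for b in self.bouts if b.behavior in FORAGING)
        if self.outcome.success_count > n_forage:
            warnings.warn(
                f"sample {self.sample_id!r}: success_count "
                f"{self.outcome.success_count} exceeds foraging bout count "
                f"{n_forage}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SiteSummary:
    """Descriptive summary (n, mean, sample sd) of one variable in one group."""

    group: str
    variable: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("summary group must contain at least one sample")
        if not math.isnan(self.sd) and self.sd < 0:
            raise ValueError("sd must be >= 0")


# ---------------------------------------------------------------------------
# I/O: long-format bout CSV plus per-sample metadata CSV
# ---------------------------------------------------------------------------

def load_samples(
    samples_path: str | Path, meta_path: str | Path
) -> list[FocalSample]:
    """Read focal samples from ``samples.csv`` + ``sample_meta.csv``.

    ``samples.csv`` is long-format (one bout per row) with columns
    ``sample_id,site,bout_index,behavior,duration_s``; ``sample_meta.csv``
    carries the foraging outcome and environment covariates.  Empty strings
    are missing values.  Unknown behavior labels and non-positive durations
    are hard errors naming the offending row; missing covariates load as NaN.
    """
    # round_trip parsing keeps doubles bit-identical through write->read
    bouts_df = pd.read_csv(
        samples_path, dtype={"sample_id": str, "site": str},
        float_precision="round_trip",
    )
    meta_df = pd.read_csv(
        meta_path, dtype={"sample_id": str, "site": str},
        float_precision="round_trip",
    )

    for row in bouts_df.itertuples():
        if row.behavior not in BEHAVIORS:
            raise ValueError(
                f"{samples_path}: row {row.Index + 2}: unknown behavior label "
                f"{row.behavior!r}"
            )
        if not row.duration_s > 0:
            raise ValueError(
                f"{samples_path}: row {row.Index + 2}: non-positive duration "
                f"{row.duration_s}"
            )

    meta_df = meta_df.set_index("sample_id")
    samples: list[FocalSample] = []
    # groupby(sort=False) preserves first-appearance order of samples.
    for sid, grp in bouts_df.groupby("sample_id", sort=False):
        grp = grp.sort_values("bout_index")
        if sid not in meta_df.index:
            raise ValueError(f"sample {sid!r} has bouts but no metadata row")
        meta = meta_df.loc[sid]
        env = EnvironmentRecord(
            **{
                name: float(meta[name]) if not pd.isna(meta[name]) else math.nan
                for name in ENV_FIELDS
            }
        )
        outcome = ForagingOutcome(
            success_count=int(meta["success_count"]),
            failure_count=int(meta["failure_count"]),
        )
        bouts = tuple(
            Bout(behavior=r.behavior, duration=float(r.duration_s), index=i)
            for i, r in enumerate(grp.itertuples())
        )
        site = str(grp["site"].iloc[0])
        samples.append(
            FocalSample(
                sample_id=str(sid), site=site, bouts=bouts,
                outcome=outcome, environment=env,
            )
        )
    return samples


def write_samples(
    samples: Sequence[FocalSample],
    samples_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write samples to the two-CSV layout read by :func:`load_samples`.

    Numeric fields round-trip exactly (pandas ``repr`` precision preserves
    doubles bit-comparably).
    """
    bout_rows = [
        {
            "sample_id": s.sample_id,
            "site": s.site,
            "bout_index": b.index,
            "behavior": b.behavior,
            "duration_s": b.duration,
        }
        for s in samples
        for b in s.bouts
    ]
    meta_rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "site": s.site,
            "success_count": s.outcome.success_count,
            "failure_count": s.outcome.failure_count,
        }
        row.update(s.environment.as_dict())
        meta_rows.append(row)
    pd.DataFrame(bout_rows).to_csv(samples_path, index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# Time-budget operations
# ---------------------------------------------------------------------------

def time_allocation(sample: FocalSample) -> dict[str, tuple[float, float]]:
    """Seconds and percent of total time per behavior.

    Absent behaviors report ``(0.0, 0.0)``; seconds sum to ``total_time``
    and percents to 100.
    """
    seconds = dict.fromkeys(BEHAVIORS, 0.0)
    for b in sample.bouts:
        seconds[b.behavior] += b.duration
    return {
        lab: (sec, 100.0 * sec / sample.total_time)
        for lab, sec in seconds.items()
    }


def behavior_frequency(sample: FocalSample) -> dict[str, int]:
    """Bout counts per behavior (all ten labels, absent ones 0)."""
    counts = dict.fromkeys(BEHAVIORS, 0)
    for b in sample.bouts:
        counts[b.behavior] += 1
    return counts


def foraging_time(sample: FocalSample) -> float:
    """Total seconds spent in the three foraging modes."""
    return float(
        sum(b.duration for b in sample.bouts if b.behavior in FORAGING)
    )


# ---------------------------------------------------------------------------
# Descriptive summaries (per-sample wide table, then grouped mean ± sd)
# ---------------------------------------------------------------------------

def sample_table(samples: Sequence[FocalSample]) -> pd.DataFrame:
    """Wide per-sample table of every summarizable variable.

    Columns: ``time_<behavior>`` (s), ``pct_<behavior>`` (%),
    ``freq_<behavior>`` (bouts), ``total_time``, ``success_count``,
    ``failure_count``, ``foraging_time``, and the environment covariates.
    Percents are per-sample (behavior seconds / that sample's total time),
    so grouped means of ``pct_*`` are means of per-sample percentages.
    """
    rows = []
    for s in samples:
        alloc = time_allocation(s)
        freq = behavior_frequency(s)
        row: dict[str, object] = {"sample_id": s.sample_id, "site": s.site}
        for lab in BEHAVIORS:
            row[f"time_{lab}"] = alloc[lab][0]
            row[f"pct_{lab}"] = alloc[lab][1]
            row[f"freq_{lab}"] = freq[lab]
        row["total_time"] = s.total_time
        row["success_count"] = s.outcome.success_count
        row["failure_count"] = s.outcome.failure_count
        row["foraging_time"] = foraging_time(s)
        row.update(s.environment.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    samples: Sequence[FocalSample],
    variables: Iterable[str] | None = None,
    group_by: str = "site",
) -> list[SiteSummary]:
    """Mean ± sample sd (n−1) per variable per group, plus a pooled Total row.

    ``group_by``: ``"site"`` for per-site rows + Total, ``"all"`` for Total
    only.  Missing values are excluded pairwise (n is the count of non-missing
    contributions).  Single-observation groups report sd 0 with a warning;
    empty groups are dropped with a warning.
    """
    if not samples:
        raise ValueError("summarize requires at least one sample")
    table = sample_table(samples)
    if variables is None:
        variables = [
            c for c in table.columns
            if c not in ("sample_id", "site")
        ]
    variables = list(variables)
    for v in variables:
        if v not in table.columns:
            raise KeyError(f"unknown summary variable {v!r}")

    groups: list[tuple[str, pd.DataFrame]] = []
    if group_by == "site":
        groups.extend((site, grp) for site, grp in table.groupby("site", sort=False))
    elif group_by != "all":
        raise ValueError("group_by must be 'site' or 'all'")
    groups.append(("Total", table))

    out: list[SiteSummary] = []
    for label, grp in groups:
        if grp.empty:
            warnings.warn(f"group {label!r} is empty; dropped", stacklevel=2)
            continue
        for v in variables:
            col = pd.to_numeric(grp[v], errors="coerce").dropna()
            n = int(col.shape[0])
            if n == 0:
                warnings.warn(
                    f"group {label!r}: variable {v!r} has no observations",
                    stacklevel=2,
                )
                continue
            if n == 1:
                warnings.warn(
                    f"group {label!r}: single observation for {v!r}; sd "
                    "reported as 0",
                    stacklevel=2,
                )
                sd = 0.0
            else:
                sd = float(col.std(ddof=1))
            out.append(
                SiteSummary(group=label, variable=v, n=n,
                            mean=float(col.mean()), sd=sd)
            )
    return out


def summary_frame(summaries: Sequence[SiteSummary]) -> pd.DataFrame:
    """Tidy frame (group, variable, n, mean, sd) for ``summary.csv``."""
    return pd.DataFrame(
        [
            {"group": s.group, "variable": s.variable, "n": s.n,
             "mean": s.mean, "sd": s.sd}
            for s in summaries
        ]
    )
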