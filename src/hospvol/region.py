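"""Region description: hospitals, provincial demand, planning flags.

An :class:`AllocationInstance` bundles everything the strategic allocation
model needs: the hospital roster (capacities, last year's volumes and
observed outcomes, unit costs), provincial demand ``I_n``, the hospitality
thresholds ``delta_n`` that cap cross-province patient flows, the guideline
volume threshold ``T``, the regional budget, and the case-study planning
flags (capacity doubling, halved threshold outside the capital province,
forced opening of compliant hospitals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import ConfigurationError, InputError, MortalityCurve, performance_coefficient

__all__ = ["PlanningFlags", "AllocationInstance", "HOSPITAL_COLUMNS", "hospitals_frame"]

#: Required columns of a hospital table (x/y coordinates optional, synthetic only).
HOSPITAL_COLUMNS = (
    "id",
    "province",
    "capacity",
    "prev_volume",
    "prev_observed_rate",
    "unit_cost",
)


@dataclass(frozen=True)
class PlanningFlags:
    """Case-study planning switches.

    force_open_above_T:
        Hospitals that performed more than ``T`` interventions last year are
        forced to remain open (close the inexperienced, not the compliant).
    halve_threshold_outside_capital:
        The open-hospital lower bound drops to ``ceil(T/2)`` outside the
        capital province (small-hospital territories could otherwise not
        cover their own demand).
    capacity_from_prev_volume:
        Effective capacity is ``2 * prev_volume`` (strategic-level elasticity)
        instead of the recorded capacity column.
    """

    force_open_above_T: bool = False
    halve_threshold_outside_capital: bool = False
    capacity_from_prev_volume: bool = False


def hospitals_frame(records) -> pd.DataFrame:
    """Normalize a hospital table: validate columns, index by id, sort."""
    df = pd.DataFrame(records).copy()
    missing = [c for c in HOSPITAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"hospital table is missing column(s): {missing}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise InputError(f"duplicate hospital id(s): {dups}")
    df = df.set_index("id", drop=False).sort_index()
    for col in ("capacity", "prev_volume"):
        if (df[col] < 0).any():
            bad = df.index[df[col] < 0].tolist()
            raise InputError(f"negative {col} for hospital(s) {bad}")
    rates = df["prev_observed_rate"]
    bad = rates.notna() & ((rates < 0) | (rates > 1))
    if bad.any():
        raise InputError(f"prev_observed_rate outside [0, 1] for hospital(s) {df.index[bad].tolist()}")
    return df


@dataclass
class AllocationInstance:
    """A planning region: hospitals, demand, constraints, and the curve.

    ``hospitals`` is indexed by hospital id; a ``v`` column (performance
    coefficients) is derived from last year's volume and observed rate at
    construction if absent.
    """

    hospitals: pd.DataFrame
    demand: dict[str, int]
    T: int
    delta: Mapping[str, float] | float = 0.0
    budget: float | None = None
    capital_province: str | None = None
    flags: PlanningFlags = field(default_factory=PlanningFlags)
    curve: MortalityCurve = field(default_factory=MortalityCurve)

    def __post_init__(self) -> None:
        self.hospitals = hospitals_frame(self.hospitals)
        if self.T < 1:
            raise ConfigurationError(f"threshold T must be >= 1, got {self.T}")
        provinces = self.provinces
        unknown = set(self.hospitals["province"]) - set(provinces)
        if unknown:
            raise InputError(f"hospital province(s) {sorted(unknown)} missing from demand table")
        for n, d in self.demand.items():
            if d < 0:
                raise InputError(f"negative demand for province {n}")
        if np.isscalar(self.delta):
            self.delta = {n: float(self.delta) for n in provinces}
        else:
            self.delta = {n: float(self.delta.get(n, 0.0)) for n in provinces}
        for n, d in self.delta.items():
            if not 0.0 <= d <= 1.0:
                raise ConfigurationError(f"hospitality threshold for {n} must be in [0, 1], got {d}")
        if sum(self.demand.values()) <= 0:
            raise InputError("total regional demand must be positive")
        if "v" not in self.hospitals.columns:
            self.hospitals["v"] = [
                performance_coefficient(self.curve, int(r.prev_volume), r.prev_observed_rate)
                for r in self.hospitals.itertuples()
            ]

    # -- structural accessors -------------------------------------------------

    @property
    def provinces(self) -> list[str]:
        return sorted(self.demand.keys())

    def province_hospitals(self, province: str) -> pd.DataFrame:
        return self.hospitals[self.hospitals["province"] == province]

    def effective_bounds(self, hospital_id: str) -> tuple[int, int]:
        """Open-hospital volume bounds (lower, upper) for one hospital.

        Upper bound is the capacity (or ``2 * prev_volume`` under the
        capacity-doubling flag); lower bound is ``T``, halved (rounded up)
        outside the capital province when the halving flag is set.
        """
        row = self.hospitals.loc[hospital_id]
        if self.flags.capacity_from_prev_volume:
            upper = int(2 * row["prev_volume"])
        else:
            upper = int(row["capacity"])
        lower = self.T
        if (
            self.flags.halve_threshold_outside_capital
            and row["province"] != self.capital_province
        ):
            lower = math.ceil(self.T / 2)
        return lower, upper

    def is_forced_open(self, hospital_id: str) -> bool:
        """Whether the forced-open rule pins this hospital open."""
        if not self.flags.force_open_above_T:
            return False
        return int(self.hospitals.loc[hospital_id, "prev_volume"]) > self.T

    def allocatable_ids(self, province: str | None = None) -> list[str]:
        """Hospitals admissible to the allocation model.

        Hospitals whose effective capacity is below their applicable lower
        bound cannot host any feasible open volume and are dropped up front.
        """
        df = self.hospitals if province is None else self.province_hospitals(province)
        keep = []
        for hid in df.index:
            lo, up = self.effective_bounds(hid)
            if up >= lo:
                keep.append(hid)
        return keep

    def restrict_to(self, open_ids) -> "AllocationInstance":
        """Sub-instance where the given hospitals are forced open, others gone.

        Used by the integrated algorithm's skim phase: each candidate choice
        set is re-solved strategically with its openings pinned.
        """
        open_ids = sorted(open_ids)
        missing = [h for h in open_ids if h not in self.hospitals.index]
        if missing:
            raise InputError(f"unknown hospital id(s): {missing}")
        sub = replace(
            self,
            hospitals=self.hospitals.loc[open_ids].copy(),
            demand=dict(self.demand),
            delta=dict(self.delta),
        )
        sub._forced = set(open_ids)  # every listed hospital must stay open
        return sub


def forced_open_ids(instance: AllocationInstance, province: str | None = None) -> set[str]:
    """Hospitals pinned open, by the flag rule or an explicit restriction."""
    explicit = getattr(instance, "_forced", set())
    ids = instance.hospitals.index if province is None else instance.province_hospitals(province).index
    out = set()
    for hid in ids:
        if hid in explicit or instance.is_forced_open(hid):
            out.add(hid)
    return out
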