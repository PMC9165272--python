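"""Strategic allocation: minimize total expected deaths over a region.

The decision maker chooses which hospitals stay open (``f``) and how many
interventions each performs (``x``), minimizing

    sum_j x_j * m(x_j) + x_j * v_j * dev(x_j)

subject to: open hospitals operate between the guideline threshold and their
capacity; provincial totals respect the hospitality thresholds ``delta_n``
(cross-province patient flows); every patient is treated (conservation); and
an optional budget caps total cost.

The objective is nonlinear in ``x`` but ``x`` lives on a small bounded
integer domain, so it is handled exactly by tabulation: a dynamic program
over hospitals x cumulative volume when the model decomposes by province
(all ``delta_n = 0``, no budget), and otherwise a MILP in which each hospital
picks one volume level through binary indicators with precomputed costs
(solved with HiGHS through :func:`scipy.optimize.milp`, zero MIP gap).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from .curves import InputError, expected_deaths
from .region import AllocationInstance, forced_open_ids

__all__ = [
    "AllocationPlan",
    "solve_province",
    "solve_region",
    "verify_plan",
    "brute_force_allocate",
]


@dataclass
class AllocationPlan:
    """A strategic solution: open flags, integer volumes, objective value."""

    open: dict[str, bool]
    volumes: dict[str, int]
    objective: float
    status: str  # "optimal" | "infeasible"
    message: str = ""

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.volumes)
        return pd.DataFrame(
            {
                "hospital_id": ids,
                "open": [int(self.open[h]) for h in ids],
                "volume": [self.volumes[h] for h in ids],
            }
        )


def _infeasible(message: str) -> AllocationPlan:
    return AllocationPlan(open={}, volumes={}, objective=float("inf"), status="infeasible", message=message)


def _levels(instance: AllocationInstance, hid: str, cap_at: int) -> np.ndarray:
    """Admissible volume levels {0} u [lower, upper] for one hospital."""
    lo, up = instance.effective_bounds(hid)
    up = min(up, cap_at)
    forced = hid in forced_open_ids(instance)
    open_levels = np.arange(lo, up + 1, dtype=int) if up >= lo else np.empty(0, dtype=int)
    if forced:
        return open_levels
    return np.concatenate([np.zeros(1, dtype=int), open_levels])


def _level_costs(instance: AllocationInstance, hid: str, levels: np.ndarray) -> np.ndarray:
    v = float(instance.hospitals.loc[hid, "v"])
    return expected_deaths(instance.curve, levels.astype(float), v)


def _finish_plan(instance: AllocationInstance, volumes: dict[str, int]) -> AllocationPlan:
    """Fill closed hospitals, recompute the objective from the volumes."""
    full = {hid: int(volumes.get(hid, 0)) for hid in instance.hospitals.index}
    obj = 0.0
    for hid, x in full.items():
        if x > 0:
            obj += expected_deaths(instance.curve, float(x), float(instance.hospitals.loc[hid, "v"]))
    return AllocationPlan(
        open={h: x > 0 for h, x in full.items()},
        volumes=full,
        objective=obj,
        status="optimal",
    )


# ---------------------------------------------------------------------------
# province-wise dynamic program (exact, delta = 0)
# ---------------------------------------------------------------------------

def solve_province(instance: AllocationInstance, province: str) -> AllocationPlan:
    """Exact optimum for one province under zero hospitality threshold.

    Minimizes the sum of per-hospital expected deaths subject to the
    provincial conservation ``sum_j x_j = I_n`` and the open-volume bounds,
    by dynamic programming over hospitals x cumulative volume.  Ties are
    resolved deterministically: backtracking prefers the smallest admissible
    volume from the last hospital backwards, which concentrates demand on
    the earliest hospital ids.
    """
    if province not in instance.demand:
        raise InputError(f"unknown province {province!r}")
    demand = int(instance.demand[province])
    ids = instance.allocatable_ids(province)
    forced = forced_open_ids(instance, province)
    dropped_forced = forced - set(ids)
    if dropped_forced:
        return _infeasible(
            f"province {province}: forced-open hospital(s) {sorted(dropped_forced)} "
            "cannot reach their lower bound (volume-bounds constraint)"
        )
    if demand == 0 and not forced:
        return _finish_plan(instance, {hid: 0 for hid in instance.province_hospitals(province).index})

    dp = np.full(demand + 1, np.inf)
    dp[0] = 0.0
    back: list[np.ndarray] = []
    for hid in ids:
        levels = _levels(instance, hid, demand)
        if levels.size == 0:
            return _infeasible(
                f"province {province}: forced-open hospital {hid} needs more volume than the demand"
            )
        costs = _level_costs(instance, hid, levels)
        new_dp = np.full(demand + 1, np.inf)
        choice = np.full(demand + 1, -1, dtype=int)
        for lv, c in zip(levels, costs):
            cand = dp[: demand + 1 - lv] + c
            seg = new_dp[lv:]
            better = cand < seg  # strict: earlier (smaller) level wins ties
            seg[better] = cand[better]
            choice[lv:][better] = lv
        dp, back_j = new_dp, choice
        back.append(back_j)

    if not np.isfinite(dp[demand]):
        return _infeasible(
            f"province {province}: demand {demand} cannot be met by the admissible hospitals (volume bounds + conservation)"
        )
    volumes: dict[str, int] = {hid: 0 for hid in instance.province_hospitals(province).index}
    s = demand
    for hid, choice in zip(reversed(ids), reversed(back)):
        lv = int(choice[s])
        volumes[hid] = lv
        s -= lv
    assert s == 0
    return _finish_plan(instance, volumes)


# ---------------------------------------------------------------------------
# regional solve
# ---------------------------------------------------------------------------

def solve_region(instance: AllocationInstance, method: str = "auto") -> AllocationPlan:
    """Exact optimum for the whole region.

    With all hospitality thresholds at zero and no budget the model
    decomposes by province and the province DPs are concatenated; otherwise
    a volume-level MILP couples the provinces.  ``method`` can force
    ``"dp"`` (decomposition; requires the decomposable case) or ``"milp"``.
    """
    decomposable = all(d == 0.0 for d in instance.delta.values()) and instance.budget is None
    if method not in ("auto", "dp", "milp"):
        raise InputError(f"unknown method {method!r}")
    if method == "dp" and not decomposable:
        raise InputError("province-wise DP requires delta = 0 everywhere and no budget")
    if method == "milp" or (method == "auto" and not decomposable):
        return _solve_region_milp(instance)

    volumes: dict[str, int] = {}
    objective = 0.0
    for province in instance.provinces:
        sub = solve_province(instance, province)
        if not sub.is_optimal:
            return sub
        volumes.update({h: sub.volumes[h] for h in instance.province_hospitals(province).index})
        objective += sub.objective
    return _finish_plan(instance, volumes)


def _solve_region_milp(instance: AllocationInstance) -> AllocationPlan:
    total_demand = sum(instance.demand.values())
    ids = instance.allocatable_ids()
    forced = forced_open_ids(instance)
    dropped_forced = forced - set(ids)
    if dropped_forced:
        return _infeasible(
            f"forced-open hospital(s) {sorted(dropped_forced)} cannot reach their lower bound (volume-bounds constraint)"
        )

    # one binary per admissible (hospital, volume level)
    var_hosp: list[int] = []
    var_level: list[int] = []
    costs: list[float] = []
    hosp_slices: list[slice] = []
    for j, hid in enumerate(ids):
        prov = instance.hospitals.loc[hid, "province"]
        cap_at = int(np.floor(instance.demand[prov] * (1.0 + instance.delta[prov])))
        levels = _levels(instance, hid, min(cap_at, total_demand))
        if levels.size == 0:
            return _infeasible(f"forced-open hospital {hid} needs more volume than its province can host")
        start = len(var_level)
        var_hosp.extend([j] * levels.size)
        var_level.extend(levels.tolist())
        costs.extend(_level_costs(instance, hid, levels).tolist())
        hosp_slices.append(slice(start, len(var_level)))

    n_var = len(var_level)
    if n_var == 0:
        return _infeasible(_diagnose_infeasibility(instance, ids))
    lv = np.array(var_level, dtype=float)
    constraints = []

    pick_one = np.zeros((len(ids), n_var))
    for j, sl in enumerate(hosp_slices):
        pick_one[j, sl] = 1.0
    constraints.append(LinearConstraint(pick_one, 1.0, 1.0))

    provinces = instance.provinces
    delta_total = sum(instance.delta[n] * instance.demand[n] for n in provinces)
    prov_rows = np.zeros((len(provinces), n_var))
    prov_lb = np.empty(len(provinces))
    prov_ub = np.empty(len(provinces))
    for r, n in enumerate(provinces):
        in_prov = [j for j, hid in enumerate(ids) if instance.hospitals.loc[hid, "province"] == n]
        for j in in_prov:
            prov_rows[r, hosp_slices[j]] = lv[hosp_slices[j]]
        # provincial demand with hospitality thresholds, as stated:
        # I_n - sum_{n'!=n} delta_n' I_n' <= sum_j x_jn <= I_n + delta_n I_n
        prov_lb[r] = instance.demand[n] - (delta_total - instance.delta[n] * instance.demand[n])
        prov_ub[r] = instance.demand[n] + instance.delta[n] * instance.demand[n]
    constraints.append(LinearConstraint(prov_rows, prov_lb, prov_ub))

    constraints.append(LinearConstraint(lv[None, :], float(total_demand), float(total_demand)))

    if instance.budget is not None:
        unit = instance.hospitals.loc[[ids[j] for j in var_hosp], "unit_cost"].to_numpy(float)
        constraints.append(LinearConstraint((unit * lv)[None, :], -np.inf, float(instance.budget)))

    res = milp(
        c=np.array(costs),
        constraints=constraints,
        integrality=np.ones(n_var),
        bounds=Bounds(0.0, 1.0),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0 or res.x is None:
        return _infeasible(_diagnose_infeasibility(instance, ids))
    y = res.x > 0.5
    volumes = {hid: 0 for hid in instance.hospitals.index}
    for k in np.nonzero(y)[0]:
        volumes[ids[var_hosp[k]]] = int(var_level[k])
    return _finish_plan(instance, volumes)


def _diagnose_infeasibility(instance: AllocationInstance, ids: list[str]) -> str:
    """Name the first constraint family that obviously cannot hold."""
    uppers = {hid: instance.effective_bounds(hid)[1] for hid in ids}
    total_cap = sum(uppers.values())
    total_demand = sum(instance.demand.values())
    if total_cap < total_demand:
        return f"conservation: total capacity {total_cap} < total demand {total_demand}"
    delta_total = sum(instance.delta[n] * instance.demand[n] for n in instance.provinces)
    for n in instance.provinces:
        cap_n = sum(uppers[h] for h in ids if instance.hospitals.loc[h, "province"] == n)
        lb = instance.demand[n] - (delta_total - instance.delta[n] * instance.demand[n])
        if cap_n < lb:
            return f"province-demand: province {n} capacity {cap_n} below lower bound {lb:g}"
    if instance.budget is not None:
        return "budget: no feasible plan fits the available funding"
    return "infeasible (no single violated constraint family identified)"


# ---------------------------------------------------------------------------
# verification & brute-force oracle
# ---------------------------------------------------------------------------

def verify_plan(instance: AllocationInstance, plan: AllocationPlan, tol: float = 1e-9) -> list[str]:
    """Check a plan against every model constraint; empty list = feasible."""
    unknown = [h for h in plan.volumes if h not in instance.hospitals.index]
    if unknown:
        raise InputError(f"plan references unknown hospital(s): {unknown}")
    violations: list[str] = []
    forced = forced_open_ids(instance)
    for hid in instance.hospitals.index:
        x = plan.volumes.get(hid, 0)
        is_open = plan.open.get(hid, False)
        lo, up = instance.effective_bounds(hid)
        if is_open != (x > 0):
            violations.append(f"bounds[{hid}]: open flag {is_open} inconsistent with volume {x}")
        if is_open and not lo <= x <= up:
            violations.append(f"bounds[{hid}]: volume {x} outside [{lo}, {up}]")
        if hid in forced and not is_open:
            violations.append(f"bounds[{hid}]: forced-open hospital is closed")
    delta_total = sum(instance.delta[n] * instance.demand[n] for n in instance.provinces)
    for n in instance.provinces:
        tot = sum(plan.volumes.get(h, 0) for h in instance.province_hospitals(n).index)
        lb = instance.demand[n] - (delta_total - instance.delta[n] * instance.demand[n])
        ub = instance.demand[n] + instance.delta[n] * instance.demand[n]
        if tot < lb - tol or tot > ub + tol:
            violations.append(f"province-demand[{n}]: provincial total {tot} outside [{lb:g}, {ub:g}]")
    total = sum(plan.volumes.get(h, 0) for h in instance.hospitals.index)
    want = sum(instance.demand.values())
    if abs(total - want) > tol:
        violations.append(f"conservation: total volume {total} != total demand {want}")
    if instance.budget is not None:
        cost = sum(
            plan.volumes.get(h, 0) * instance.hospitals.loc[h, "unit_cost"]
            for h in instance.hospitals.index
        )
        if cost > instance.budget + tol:
            violations.append(f"budget: cost {cost:g} exceeds budget {instance.budget:g}")
    return violations


def brute_force_allocate(instance: AllocationInstance, max_nodes: int = 2_000_000) -> AllocationPlan:
    """Exhaustive-enumeration oracle for small instances.

    Enumerates every feasible integer volume vector province by province and
    returns the global optimum.  Guards against combinatorial blow-up and
    refuses instances whose enumeration tree exceeds ``max_nodes``.
    """
    total_demand = sum(instance.demand.values())
    per_prov: list[tuple[str, list[str], list[np.ndarray], list[np.ndarray]]] = []
    est = 0
    for n in instance.provinces:
        ids = instance.allocatable_ids(n)
        forced = forced_open_ids(instance, n)
        if forced - set(ids):
            return _infeasible(f"province {n}: forced-open hospital(s) cannot reach their lower bound")
        cap_at = int(np.floor(instance.demand[n] * (1.0 + instance.delta[n])))
        lvls = [_levels(instance, h, min(cap_at, total_demand)) for h in ids]
        csts = [_level_costs(instance, h, l) for h, l in zip(ids, lvls)]
        # provinces are enumerated independently, so the work is a sum of
        # per-province level products, not their product
        est += int(np.prod([max(l.size, 1) for l in lvls]))
        per_prov.append((n, ids, lvls, csts))
    if est > max_nodes:
        raise ValueError(f"instance too large for brute force (~{est} nodes > {max_nodes})")

    delta_total = sum(instance.delta[n] * instance.demand[n] for n in instance.provinces)
    prov_options: list[list[tuple[int, float, float, dict[str, int]]]] = []
    for n, ids, lvls, csts in per_prov:
        lb = instance.demand[n] - (delta_total - instance.delta[n] * instance.demand[n])
        ub = instance.demand[n] + instance.delta[n] * instance.demand[n]
        opts = []
        for combo in itertools.product(*[range(l.size) for l in lvls]):
            tot = sum(int(lvls[j][k]) for j, k in enumerate(combo))
            if tot < lb or tot > ub:
                continue
            cost = sum(float(csts[j][k]) for j, k in enumerate(combo))
            money = sum(
                int(lvls[j][k]) * float(instance.hospitals.loc[ids[j], "unit_cost"])
                for j, k in enumerate(combo)
            )
            opts.append((tot, cost, money, {ids[j]: int(lvls[j][k]) for j, k in enumerate(combo)}))
        if not opts:
            return _infeasible(f"province {n}: no feasible provincial volume vector (bounds + province demand)")
        prov_options.append(opts)
    combos = int(np.prod([len(o) for o in prov_options], dtype=float))
    if combos > max_nodes:
        raise ValueError(f"instance too large for brute force (~{combos} combinations > {max_nodes})")

    best_cost = np.inf
    best_vol: dict[str, int] | None = None

    def rec(i: int, tot: int, cost: float, money: float, vols: dict[str, int]) -> None:
        nonlocal best_cost, best_vol
        if cost >= best_cost:
            return
        if i == len(prov_options):
            if tot == total_demand and (instance.budget is None or money <= instance.budget + 1e-9):
                best_cost, best_vol = cost, dict(vols)
            return
        for ptot, pcost, pmoney, pvols in prov_options[i]:
            rec(i + 1, tot + ptot, cost + pcost, money + pmoney, {**vols, **pvols})

    rec(0, 0, 0.0, 0.0, {})
    if best_vol is None:
        return _infeasible("no feasible volume vector (exhaustive search)")
    return _finish_plan(instance, best_vol)
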