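"""The integrated three-phase planning algorithm.

The strategic model assumes patients obey the plan; the patient model shows
they do not.  The integrated algorithm lets the policy maker pick the
*choice set* (which hospitals stay open) whose *predicted* patient response
yields the lowest total mortality:

Phase 1 - enumerate admissible choice sets: per province, only hospitals
meeting the guideline threshold are eligible (default: capacity >= T), at
least ``r~_n`` of them (the fewest highest-capacity hospitals covering the
provincial demand) must be open, and each provincial subset must have enough
capacity for its demand.  The pre-filter count is the closed form
``N_cs = prod_n sum_{r=r~_n}^{H_n} C(H_n, r)``.

Phase 2 - evaluate each admissible set through the conditional-logit patient
model (quality = last year's volumes), compute the implied total mortality,
and keep the operational solutions in the three lowest integer mortality
groups, dropping the 2nd/3rd groups if they exceed the lowest by more than
theta percent.

Phase 3 - skim the candidates by a decision criterion: ``structural`` picks
the candidate whose operational volumes are closest (L1) to the strategic
solution of its own choice set; ``utility`` picks the candidate minimizing
the gap between past and predicted per-hospital performance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation import AllocationPlan, solve_region
from .choice import Coefficients, choice_probabilities, predict_volumes
from .curves import InputError, expected_deaths, total_mortality
from .region import AllocationInstance

__all__ = [
    "ChoiceSetEnumeration",
    "OperationalEvaluation",
    "IntegratedReport",
    "eligible_hospitals",
    "min_required_open",
    "count_choice_sets",
    "enumerate_choice_sets",
    "evaluate_choice_set",
    "select_candidates",
    "skim",
    "run_integrated",
    "expected_divergence",
]


def eligible_hospitals(
    hospitals: pd.DataFrame, T: int, criterion: str = "capacity"
) -> dict[str, list[str]]:
    """Per-province ids of hospitals meeting the guideline threshold.

    Default eligibility is ``capacity >= T``; ``criterion="prev_volume"``
    instead requires last year's volume to reach the threshold.
    """
    if criterion not in ("capacity", "prev_volume"):
        raise InputError(f"unknown eligibility criterion {criterion!r}")
    ok = hospitals[criterion] >= T
    out: dict[str, list[str]] = {}
    for prov in sorted(hospitals["province"].unique()):
        sel = hospitals[(hospitals["province"] == prov) & ok]
        out[prov] = sorted(sel.index)
    return out


def min_required_open(capacities: Sequence[float], demand: int) -> int:
    """Fewest highest-capacity hospitals whose joint capacity covers demand.

    With zero demand one hospital must still stay open (every province keeps
    at least one facility under zero hospitality thresholds).
    """
    caps = sorted(capacities, reverse=True)
    if not caps:
        raise InputError("province has no eligible hospital")
    if demand <= 0:
        return 1
    cum = 0.0
    for r, c in enumerate(caps, start=1):
        cum += c
        if cum >= demand:
            return r
    raise InputError(f"eligible capacity {cum:g} can never satisfy demand {demand}")


def count_choice_sets(H: Sequence[int], r_min: Sequence[int]) -> int:
    """Closed-form number of pre-filter choice sets (exact integers)."""
    if len(H) != len(r_min):
        raise InputError("H and r_min must have the same length")
    total = 1
    for h, r in zip(H, r_min):
        if not 1 <= r <= h:
            raise InputError(f"need 1 <= r_min <= H, got r_min={r}, H={h}")
        total *= sum(math.comb(h, k) for k in range(r, h + 1))
    return total


@dataclass
class ChoiceSetEnumeration:
    """Admissible open-hospital combinations, streamed lazily.

    ``provincial_sets`` holds, per province, the subsets (id tuples) passing
    both Phase-1 constraints; the regional sets are their cross product,
    iterated in lexicographic order.
    """

    provinces: list[str]
    eligible: dict[str, list[str]]
    H: dict[str, int]
    r_min: dict[str, int]
    provincial_sets: dict[str, list[tuple[str, ...]]]
    n_precount: int
    n_admissible: int

    def __iter__(self) -> Iterator[tuple[str, ...]]:
        pools = [self.provincial_sets[n] for n in self.provinces]
        for combo in itertools.product(*pools):
            yield tuple(sorted(itertools.chain.from_iterable(combo)))

    def materialize(self, max_sets: int = 100_000) -> list[tuple[str, ...]]:
        if self.n_admissible > max_sets:
            raise InputError(
                f"{self.n_admissible} admissible sets exceed the eager limit {max_sets}; iterate instead"
            )
        return list(self)


def enumerate_choice_sets(
    instance: AllocationInstance, eligibility: str = "capacity"
) -> ChoiceSetEnumeration:
    """Phase 1: build the admissible choice-set enumeration for a region."""
    elig = eligible_hospitals(instance.hospitals, instance.T, eligibility)
    provinces = instance.provinces
    H: dict[str, int] = {}
    r_min: dict[str, int] = {}
    prov_sets: dict[str, list[tuple[str, ...]]] = {}
    for n in provinces:
        ids = elig.get(n, [])
        if not ids:
            raise InputError(f"province {n} has no eligible hospital: no admissible choice set exists")
        caps = instance.hospitals.loc[ids, "capacity"]
        H[n] = len(ids)
        r_min[n] = min_required_open(caps.tolist(), int(instance.demand[n]))
        subsets = []
        for r in range(r_min[n], H[n] + 1):
            for combo in itertools.combinations(ids, r):
                if caps[list(combo)].sum() >= instance.demand[n]:
                    subsets.append(combo)
        prov_sets[n] = subsets
    n_precount = count_choice_sets([H[n] for n in provinces], [r_min[n] for n in provinces])
    n_admissible = int(np.prod([len(prov_sets[n]) for n in provinces], dtype=object))
    return ChoiceSetEnumeration(
        provinces=provinces,
        eligible=elig,
        H=H,
        r_min=r_min,
        provincial_sets=prov_sets,
        n_precount=n_precount,
        n_admissible=n_admissible,
    )


@dataclass
class OperationalEvaluation:
    """Patient response to one choice set: volumes, deaths, violations."""

    open_ids: tuple[str, ...]
    volumes: pd.Series
    total_deaths: float
    threshold_violations: list[str] = field(default_factory=list)
    capacity_violations: list[str] = field(default_factory=list)


def evaluate_choice_set(
    open_ids: Iterable[str],
    instance: AllocationInstance,
    coeffs: Coefficients,
    patients: pd.DataFrame,
    distances: pd.DataFrame,
    quality_volumes: pd.Series | None = None,
) -> OperationalEvaluation:
    """Phase 2 inner step: predict volumes and mortality for one choice set.

    Quality defaults to last year's volumes (the one-year information lag);
    passing ``quality_volumes`` substitutes e.g. the strategic plan's volumes
    (the full-information experiment).
    """
    open_ids = tuple(sorted(open_ids))
    quality = (
        instance.hospitals["prev_volume"].astype(float)
        if quality_volumes is None
        else quality_volumes.astype(float)
    )
    vols = predict_volumes(coeffs, patients, distances, quality, open_ids)
    deaths = total_mortality(vols, instance.hospitals, instance.curve)
    thr = [h for h in open_ids if vols[h] < instance.T]
    cap = [h for h in open_ids if vols[h] > instance.hospitals.loc[h, "capacity"]]
    return OperationalEvaluation(open_ids, vols, deaths, thr, cap)


def select_candidates(
    evaluations: Sequence[OperationalEvaluation], theta: float
) -> list[OperationalEvaluation]:
    """Phase 2 theta-rule on integer mortality groups.

    Mortalities are grouped by rounding to the nearest integer; every
    evaluation in the lowest group is kept, and the 2nd and 3rd lowest
    groups are kept iff their value does not exceed the lowest by more than
    theta percent.
    """
    if not evaluations:
        raise InputError("no operational evaluations to select from")
    if theta < 0:
        raise InputError("theta must be >= 0")
    rounded = np.array([round(e.total_deaths) for e in evaluations])
    values = np.unique(rounded)
    lowest = values[0]
    keep_values = {lowest}
    for v in values[1:3]:
        if v <= (1.0 + theta / 100.0) * lowest:
            keep_values.add(v)
    out = [e for e, r in zip(evaluations, rounded) if r in keep_values]
    return sorted(out, key=lambda e: (e.total_deaths, e.open_ids))


def skim(
    candidates: Sequence[OperationalEvaluation],
    criterion: str,
    instance: AllocationInstance,
) -> tuple[OperationalEvaluation, pd.DataFrame]:
    """Phase 3: pick the final (integrated) solution among the candidates.

    ``structural``: minimize the L1 distance between the candidate's
    operational volumes and the strategic solution of its own choice set
    (open hospitals pinned).  ``utility``: minimize the summed per-hospital
    gap |expected deaths at last year's volume - at the predicted volume|,
    a proxy for the past-vs-actual performance discrepancy patients face.
    Candidates whose strategic sub-solve is infeasible are excluded with a
    warning; ties break lexicographically on the choice set.
    """
    if not candidates:
        raise InputError("no candidates to skim")
    if criterion not in ("structural", "utility"):
        raise InputError(f"unknown skim criterion {criterion!r}")
    rows = []
    scored: list[tuple[float, OperationalEvaluation]] = []
    for cand in candidates:
        if criterion == "structural":
            plan = solve_region(instance.restrict_to(cand.open_ids))
            if not plan.is_optimal:
                warnings.warn(
                    f"candidate {cand.open_ids} excluded: strategic sub-solve infeasible ({plan.message})"
                )
                rows.append({"open_ids": cand.open_ids, "score": np.nan, "excluded": True})
                continue
            score = float(sum(abs(cand.volumes[h] - plan.volumes[h]) for h in cand.open_ids))
        else:
            score = 0.0
            for h in cand.open_ids:
                v = float(instance.hospitals.loc[h, "v"])
                past = expected_deaths(
                    instance.curve, float(instance.hospitals.loc[h, "prev_volume"]), v
                )
                now = expected_deaths(instance.curve, float(cand.volumes[h]), v)
                score += abs(past - now)
        rows.append({"open_ids": cand.open_ids, "score": score, "excluded": False})
        scored.append((score, cand))
    if not scored:
        raise InputError("all candidates excluded during the skim")
    scored.sort(key=lambda t: (t[0], t[1].open_ids))
    return scored[0][1], pd.DataFrame(rows)


def expected_divergence(
    probabilities: pd.DataFrame,
    patient_provinces: pd.Series,
    planned_sets: Mapping[str, Iterable[str]],
) -> float:
    """Expected fraction of patients choosing outside their planned set.

    Average over patients of the probability mass assigned to hospitals not
    in the planned set of the patient's own province.
    """
    planned = {n: set(h) for n, h in planned_sets.items()}
    total = 0.0
    for pid in probabilities.index:
        inside = planned.get(patient_provinces.loc[pid], set())
        out_cols = [c for c in probabilities.columns if c not in inside]
        total += float(probabilities.loc[pid, out_cols].sum())
    return total / len(probabilities) if len(probabilities) else 0.0


@dataclass
class IntegratedReport:
    """Full output of the integrated algorithm plus the comparison baselines."""

    theta: float
    criterion: str
    enumeration: ChoiceSetEnumeration
    n_evaluated: int
    min_operational_deaths: float
    candidates: list[OperationalEvaluation]
    integrated: OperationalEvaluation
    skim_scores: pd.DataFrame
    strategic_plan: AllocationPlan
    operational_of_strategic: OperationalEvaluation | None
    actual_deaths: float
    mortalities: dict[str, float]


def run_integrated(
    instance: AllocationInstance,
    coeffs: Coefficients,
    patients: pd.DataFrame,
    distances: pd.DataFrame,
    theta: float = 10.0,
    criterion: str = "structural",
    eligibility: str = "capacity",
    strict_threshold: bool = False,
    max_evaluations: int = 200_000,
) -> IntegratedReport:
    """Run Phases 1-3 and assemble the four-way mortality comparison.

    Besides the integrated solution, the report carries the pure strategic
    solution, the patient response to the strategic choice set (the
    operational solution), and the actual baseline mortality implied by last
    year's observed volumes.  ``strict_threshold=True`` disqualifies choice
    sets whose predicted volumes leave an open hospital below the threshold;
    by default such violations are only reported.
    """
    enumeration = enumerate_choice_sets(instance, eligibility)
    if enumeration.n_admissible == 0:
        raise InputError("no admissible choice set passes the Phase-1 constraints")
    if enumeration.n_admissible > max_evaluations:
        raise InputError(
            f"{enumeration.n_admissible} admissible sets exceed max_evaluations={max_evaluations}"
        )
    evaluations: list[OperationalEvaluation] = []
    for open_ids in enumeration:
        ev = evaluate_choice_set(open_ids, instance, coeffs, patients, distances)
        if strict_threshold and ev.threshold_violations:
            continue
        evaluations.append(ev)
    if not evaluations:
        raise InputError("every admissible choice set was disqualified by the strict threshold rule")
    min_deaths = min(e.total_deaths for e in evaluations)
    candidates = select_candidates(evaluations, theta)
    integrated, skim_scores = skim(candidates, criterion, instance)

    strategic_plan = solve_region(instance)
    operational_of_strategic = None
    if strategic_plan.is_optimal:
        strategic_open = tuple(sorted(h for h, o in strategic_plan.open.items() if o))
        if strategic_open:
            operational_of_strategic = evaluate_choice_set(
                strategic_open, instance, coeffs, patients, distances
            )
    actual_volumes = instance.hospitals["prev_volume"].astype(float)
    actual_deaths = total_mortality(actual_volumes, instance.hospitals, instance.curve)

    mortalities = {
        "actual": actual_deaths,
        "strategic": strategic_plan.objective if strategic_plan.is_optimal else float("nan"),
        "operational": (
            operational_of_strategic.total_deaths if operational_of_strategic else float("nan")
        ),
        "integrated": integrated.total_deaths,
    }
    return IntegratedReport(
        theta=theta,
        criterion=criterion,
        enumeration=enumeration,
        n_evaluated=len(evaluations),
        min_operational_deaths=min_deaths,
        candidates=candidates,
        integrated=integrated,
        skim_scores=skim_scores,
        strategic_plan=strategic_plan,
        operational_of_strategic=operational_of_strategic,
        actual_deaths=actual_deaths,
        mortalities=mortalities,
    )
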