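"""Synthetic regions: multi-province planning instances with no real data.

Real hospital discharge records are confidential, so every test and example
runs on synthetic regions that emulate the structural facts of a typical
north-Italian planning territory: about eight provinces, some fifty
hospitals with strongly right-skewed annual volumes (only a minority above
the guideline threshold of 50 colon resections/year), a decreasing
volume-mortality curve, and patients whose hospital choice trades distance
disutility against volume-as-quality attraction.

Two entry points matter: :func:`generate_region` draws a parametric region
from a seeded generator (fully deterministic per seed), and
:func:`piedmont_like_fixture` builds a fixed 8-province, 53-hospital,
1405-patient instance whose eligible-hospital counts and minimum-open
numbers match the combinatorial structure of the motivating territory
(H = 5,1,1,5,2,8,2,2 and r~ = 2,1,1,2,2,4,1,1 at T = 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .allocation import solve_province
from .choice import CHARACTERISTICS, Coefficients, simulate_choices
from .curves import ConfigurationError, MortalityCurve
from .region import AllocationInstance, PlanningFlags

__all__ = ["RegionConfig", "generate_region", "piedmont_like_fixture", "generate_choice_history"]

#: Default choice coefficients used by the generator: distance costs utility,
#: lagged volume adds it, and older patients are more distance-averse.
DEFAULT_COEFFS = Coefficients(
    beta_d=-0.10,
    beta_q=0.01,
    alpha_d=(-0.02, 0.0, 0.0, 0.0, 0.0),
    alpha_q=(0.0, 0.0, 0.0, 0.0, 0.0),
)


@dataclass(frozen=True)
class RegionConfig:
    """Generative model of a planning region; the seed fixes everything."""

    seed: int = 0
    hospitals_per_province: tuple[int, ...] = (9, 3, 3, 9, 5, 16, 4, 4)
    total_patients: int = 1405
    patients_per_province: tuple[int, ...] | None = None
    province_names: tuple[str, ...] | None = None
    T: int = 50
    box_km: float = 200.0
    cluster_km: float = 20.0
    # two-tier volume skew: a hub tier of ~frac_high of each province's
    # hospitals shares high_share of the provincial volume; the rest scatter
    # over many small performers (lognormal with shape volume_sigma)
    frac_high: float = 0.30
    high_share: float = 0.80
    high_sigma: float = 0.25
    volume_sigma: float = 1.1
    capacity_factor: tuple[float, float] = (1.3, 2.2)
    hub_topup: bool = True  # size the largest provincial hospital to cover demand
    curve: MortalityCurve = field(default_factory=MortalityCurve)
    true_coeffs: Coefficients = DEFAULT_COEFFS
    delta: float = 0.0
    budget: float | None = None
    flags: PlanningFlags = field(default_factory=PlanningFlags)

    @property
    def n_provinces(self) -> int:
        return len(self.hospitals_per_province)

    def names(self) -> tuple[str, ...]:
        if self.province_names is not None:
            if len(self.province_names) != self.n_provinces:
                raise ConfigurationError("province_names length must match hospitals_per_province")
            return self.province_names
        return tuple(f"P{i + 1}" for i in range(self.n_provinces))


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer split of ``total`` proportional to ``weights``, exact sum."""
    raw = total * weights / weights.sum()
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def _patient_frame(rng, province, count, center, spread_km):
    ids = [f"{province}_p{i:04d}" for i in range(count)]
    return pd.DataFrame(
        {
            "id": ids,
            "province": province,
            "age": rng.standard_normal(count).round(4),
            "sex": rng.binomial(1, 0.5, count),
            "rurality": rng.binomial(1, 0.3, count),
            "admission_type": rng.binomial(1, 0.35, count),
            "comorbidity": rng.binomial(1, 0.4, count),
            "x_coord": (center[0] + rng.uniform(-spread_km, spread_km, count)).round(3),
            "y_coord": (center[1] + rng.uniform(-spread_km, spread_km, count)).round(3),
        }
    ).set_index("id", drop=False)


def _distances(patients: pd.DataFrame, hospitals: pd.DataFrame) -> pd.DataFrame:
    D = cdist(
        patients[["x_coord", "y_coord"]].to_numpy(float),
        hospitals[["x_coord", "y_coord"]].to_numpy(float),
    )
    return pd.DataFrame(D.round(3), index=patients.index, columns=hospitals.index)


def generate_region(config: RegionConfig) -> tuple[AllocationInstance, pd.DataFrame, pd.DataFrame]:
    """Draw a region: (instance, patient table, patient x hospital distances).

    Hospital volumes are right-skewed (lognormal weights scaled to the
    provincial demand), capacities a modest multiple of the volume with the
    largest provincial hospital sized to cover provincial demand (the hub),
    observed past outcomes scatter inside the deviation band around the
    curve, and patients sit in provincial clusters with standardized-normal
    age and Bernoulli binary characteristics.  Impossible configurations
    (a province whose demand can never be met under the threshold) raise
    :class:`ConfigurationError` at generation time.
    """
    rng = np.random.default_rng(config.seed)
    names = config.names()
    if config.patients_per_province is not None:
        if len(config.patients_per_province) != config.n_provinces:
            raise ConfigurationError("patients_per_province length must match provinces")
        demand = np.asarray(config.patients_per_province, dtype=int)
    else:
        demand = _largest_remainder(
            config.total_patients, np.asarray(config.hospitals_per_province, dtype=float)
        )

    centers = {
        n: (rng.uniform(0.15, 0.85) * config.box_km, rng.uniform(0.15, 0.85) * config.box_km)
        for n in names
    }

    hosp_rows = []
    for n, J, I_n in zip(names, config.hospitals_per_province, demand):
        if J < 1:
            raise ConfigurationError(f"province {n} must have at least one hospital")
        n_high = min(J, max(1, round(config.frac_high * J)))
        high_total = int(round(config.high_share * I_n)) if J > n_high else int(I_n)
        w_high = rng.lognormal(mean=0.0, sigma=config.high_sigma, size=n_high)
        prev_high = _largest_remainder(high_total, w_high)
        if J > n_high:
            w_low = rng.lognormal(mean=0.0, sigma=config.volume_sigma, size=J - n_high)
            prev_low = _largest_remainder(int(I_n) - high_total, w_low)
        else:
            prev_low = np.empty(0, dtype=int)
        prev = np.sort(np.concatenate([prev_high, prev_low]))[::-1]
        caps = np.ceil(prev * rng.uniform(*config.capacity_factor, size=J)).astype(int)
        caps = np.maximum(caps, 5)
        if config.hub_topup:
            caps[0] = max(caps[0], int(I_n))
        for k in range(J):
            m = config.curve.rate(int(prev[k]))
            dev = config.curve.deviation(int(prev[k]))
            rate = float(np.clip(m + rng.uniform(-0.95, 0.95) * dev, 0.0, 1.0))
            hosp_rows.append(
                {
                    "id": f"{n}_h{k + 1:02d}",
                    "province": n,
                    "capacity": int(caps[k]),
                    "prev_volume": int(prev[k]),
                    "prev_observed_rate": round(rate, 5),
                    "unit_cost": round(float(np.clip(rng.normal(9000, 800), 1000, None)), 2),
                    "x_coord": round(centers[n][0] + rng.uniform(-config.cluster_km, config.cluster_km), 3),
                    "y_coord": round(centers[n][1] + rng.uniform(-config.cluster_km, config.cluster_km), 3),
                }
            )
    hospitals = pd.DataFrame(hosp_rows)

    instance = AllocationInstance(
        hospitals=hospitals,
        demand={n: int(d) for n, d in zip(names, demand)},
        T=config.T,
        delta=config.delta,
        budget=config.budget,
        capital_province=names[0],
        flags=config.flags,
        curve=config.curve,
    )

    # fail fast on impossible configurations: with zero hospitality threshold
    # each province must be individually servable under the volume bounds
    if all(d == 0.0 for d in instance.delta.values()) and instance.budget is None:
        for n in names:
            sub = solve_province(instance, n)
            if not sub.is_optimal:
                raise ConfigurationError(
                    f"generated region is infeasible in province {n}: {sub.message}"
                )

    patients = pd.concat(
        [
            _patient_frame(rng, n, int(I_n), centers[n], 1.5 * config.cluster_km)
            for n, I_n in zip(names, demand)
        ]
    )
    distances = _distances(patients, instance.hospitals)
    return instance, patients, distances


# ---------------------------------------------------------------------------
# fixed territory fixture
# ---------------------------------------------------------------------------

_FIXTURE_PROVINCES = ("AL", "AT", "BI", "CN", "NO", "TO", "VB", "VC")
_FIXTURE_J = (9, 3, 3, 9, 5, 16, 4, 4)  # hospitals per province, sum 53
_FIXTURE_DEMAND = (239, 79, 79, 239, 133, 424, 106, 106)  # 1405 patients
_FIXTURE_ELIGIBLE_CAPS = {
    "AL": [150, 120, 90, 70, 55],
    "AT": [110],
    "BI": [95],
    "CN": [160, 110, 80, 60, 55],
    "NO": [90, 70],
    "TO": [140, 130, 120, 110, 100, 90, 70, 60],
    "VB": [120, 60],
    "VC": [115, 55],
}
_FIXTURE_CENTERS = {
    "AL": (140.0, 60.0),
    "AT": (110.0, 70.0),
    "BI": (95.0, 140.0),
    "CN": (70.0, 30.0),
    "NO": (150.0, 120.0),
    "TO": (60.0, 90.0),
    "VB": (150.0, 170.0),
    "VC": (120.0, 120.0),
}


def piedmont_like_fixture(
    curve: MortalityCurve | None = None,
) -> tuple[AllocationInstance, pd.DataFrame, pd.DataFrame]:
    """Fixed 8-province instance mirroring the motivating territory's shape.

    53 hospitals and 1405 patients across provinces AL, AT, BI, CN, NO, TO,
    VB, VC; capacities are invented but constrained so that, at T = 50, the
    eligible-hospital counts are H = (5, 1, 1, 5, 2, 8, 2, 2) (26 eligible in
    total) and the minimum-open numbers are r~ = (2, 1, 1, 2, 2, 4, 1, 1).
    Entirely deterministic (internal fixed seed).  The instance carries the
    case-study planning flags: threshold halved outside the capital province
    TO, hospitals above the threshold last year forced open.
    """
    rng = np.random.default_rng(777)
    curve = curve or MortalityCurve()
    rows = []
    for n, J, I_n in zip(_FIXTURE_PROVINCES, _FIXTURE_J, _FIXTURE_DEMAND):
        caps = list(_FIXTURE_ELIGIBLE_CAPS[n])
        caps += sorted(rng.integers(10, 46, size=J - len(caps)).tolist(), reverse=True)
        caps = np.asarray(caps, dtype=int)
        w = caps.astype(float) ** 1.5
        prev = _largest_remainder(int(I_n), w)
        for k in range(J):
            m = curve.rate(int(prev[k]))
            dev = curve.deviation(int(prev[k]))
            rate = float(np.clip(m + rng.uniform(-0.95, 0.95) * dev, 0.0, 1.0))
            rows.append(
                {
                    "id": f"{n}_h{k + 1:02d}",
                    "province": n,
                    "capacity": int(caps[k]),
                    "prev_volume": int(prev[k]),
                    "prev_observed_rate": round(rate, 5),
                    "unit_cost": round(float(np.clip(rng.normal(9000, 800), 1000, None)), 2),
                    "x_coord": round(_FIXTURE_CENTERS[n][0] + rng.uniform(-18, 18), 3),
                    "y_coord": round(_FIXTURE_CENTERS[n][1] + rng.uniform(-18, 18), 3),
                }
            )
    hospitals = pd.DataFrame(rows)
    instance = AllocationInstance(
        hospitals=hospitals,
        demand=dict(zip(_FIXTURE_PROVINCES, _FIXTURE_DEMAND)),
        T=50,
        delta=0.0,
        budget=None,
        capital_province="TO",
        flags=PlanningFlags(force_open_above_T=True, halve_threshold_outside_capital=True),
        curve=curve,
    )
    patients = pd.concat(
        [
            _patient_frame(rng, n, int(I_n), _FIXTURE_CENTERS[n], 25.0)
            for n, I_n in zip(_FIXTURE_PROVINCES, _FIXTURE_DEMAND)
        ]
    )
    distances = _distances(patients, instance.hospitals)
    return instance, patients, distances


def generate_choice_history(
    instance: AllocationInstance,
    patients: pd.DataFrame,
    distances: pd.DataFrame,
    true_coeffs: Coefficients,
    n_years: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate several years of hospital choices in long format.

    Each year, every patient draws a hospital from the conditional logit
    with quality equal to the previous year's volumes; realized counts
    become next year's lagged volumes.  The output is one row per
    (year, patient, hospital) suitable for :func:`hospvol.choice.fit_coefficients`.
    """
    rng = np.random.default_rng(seed)
    hosp_ids = list(instance.hospitals.index)
    volumes = instance.hospitals["prev_volume"].astype(float)
    n_pat, n_hosp = len(patients), len(hosp_ids)
    frames = []
    for year in range(n_years):
        chosen = simulate_choices(true_coeffs, patients, distances, volumes, seed=rng)
        decision = np.repeat([f"y{year}:{pid}" for pid in patients.index], n_hosp)
        frame = pd.DataFrame(
            {
                "decision_id": decision,
                "hospital_id": np.tile(hosp_ids, n_pat),
                "chosen": (np.tile(hosp_ids, n_pat) == np.repeat(chosen.to_numpy(), n_hosp)).astype(int),
                "distance": distances.loc[patients.index, hosp_ids].to_numpy(float).ravel(),
                "lagged_volume": np.tile(volumes[hosp_ids].to_numpy(float), n_pat),
            }
        )
        for c in CHARACTERISTICS:
            frame[c] = np.repeat(patients[c].to_numpy(float), n_hosp)
        frames.append(frame)
        counts = chosen.value_counts()
        volumes = pd.Series(
            [float(counts.get(h, 0)) for h in hosp_ids], index=hosp_ids, dtype=float
        )
    if not frames:
        return pd.DataFrame(
            columns=["decision_id", "hospital_id", "chosen", "distance", "lagged_volume", *CHARACTERISTICS]
        )
    return pd.concat(frames, ignore_index=True)
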