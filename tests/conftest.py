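import numpy as np
import pandas as pd
import pytest

import hospvol as hv
from hospvol.choice import Coefficients


@pytest.fixture(scope="session")
def curve():
    return hv.MortalityCurve(form="exponential", m_floor=0.02, m_scale=0.08, decay=0.02, dev_fraction=0.3)


@pytest.fixture(scope="session")
def fixture_region():
    """The fixed 8-province, 53-hospital, 1405-patient territory."""
    return hv.piedmont_like_fixture()


@pytest.fixture(scope="session")
def small_region():
    """Reduced synthetic region: 3 provinces, 6 hospitals, 300 patients."""
    cfg = hv.RegionConfig(
        seed=11,
        hospitals_per_province=(2, 2, 2),
        total_patients=300,
        patients_per_province=(140, 100, 60),
        T=20,
    )
    return hv.generate_region(cfg)


@pytest.fixture(scope="session")
def base_coeffs():
    return Coefficients(beta_d=-0.10, beta_q=0.01)


def make_random_instance(rng, n_prov=2, max_hosp=3, max_demand=30, delta=0.0, budget=None):
    """Small random allocation instance for oracle-equivalence sweeps."""
    rows, demand = [], {}
    for n in range(n_prov):
        prov = f"P{n + 1}"
        demand[prov] = int(rng.integers(0, max_demand + 1))
        for j in range(int(rng.integers(1, max_hosp + 1))):
            rows.append(
                dict(
                    id=f"{prov}_h{j + 1}",
                    province=prov,
                    capacity=int(rng.integers(3, 25)),
                    prev_volume=int(rng.integers(0, 20)),
                    prev_observed_rate=float(np.clip(0.1 + 0.05 * rng.standard_normal(), 0, 1)),
                    unit_cost=float(rng.integers(50, 150)),
                )
            )
    curve = hv.MortalityCurve(m_floor=0.02, m_scale=0.15, decay=0.1, dev_fraction=0.3)
    return hv.AllocationInstance(
        hospitals=pd.DataFrame(rows),
        demand=demand,
        T=int(rng.integers(2, 6)),
        delta=delta,
        budget=budget,
        curve=curve,
    )
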