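"""Configuration, CSV input validation, and report writing.

All inputs are small administrative-style tables, so everything is plain
CSV plus one YAML config.  Loaders validate schemas and referential
integrity and raise :class:`~hospvol.curves.InputError` naming the offending
row/field; report writers emit tables from which every stored mortality
figure can be recomputed (each volume table carries the hospital's
performance coefficient ``v``, so the curve config plus the table determine
the expected deaths).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .choice import Coefficients
from .curves import InputError, MortalityCurve, expected_deaths
from .planner import IntegratedReport
from .region import HOSPITAL_COLUMNS, AllocationInstance, PlanningFlags

__all__ = [
    "load_config",
    "config_curve",
    "config_flags",
    "config_coefficients",
    "load_instance",
    "load_patients",
    "load_distances",
    "write_region",
    "write_plan",
    "write_report",
    "recompute_mortality",
]

logger = logging.getLogger("hospvol")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"config file {path} must contain a YAML mapping")
    return cfg


def config_curve(cfg: dict) -> MortalityCurve:
    return MortalityCurve(**cfg.get("curve", {}))


def config_flags(cfg: dict) -> PlanningFlags:
    return PlanningFlags(**cfg.get("flags", {}))


def config_coefficients(cfg: dict) -> Coefficients:
    c = cfg.get("coefficients")
    if c is None:
        raise InputError("config has no 'coefficients' section")
    return Coefficients(
        beta_d=float(c["beta_d"]),
        beta_q=float(c["beta_q"]),
        alpha_d=tuple(c.get("alpha_d", (0.0,) * 5)),
        alpha_q=tuple(c.get("alpha_q", (0.0,) * 5)),
    )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_instance(
    hospitals_csv,
    provinces_csv,
    cfg: dict,
    drop_below_threshold: bool = True,
) -> AllocationInstance:
    """Build a validated instance from the hospital and province tables.

    Hospitals whose effective capacity cannot reach their applicable lower
    bound are dropped with a logged warning (they could never host a
    feasible open volume).
    """
    hospitals = pd.read_csv(hospitals_csv)
    missing = [c for c in HOSPITAL_COLUMNS if c not in hospitals.columns]
    if missing:
        raise InputError(f"{hospitals_csv}: missing column(s) {missing}")
    provinces = pd.read_csv(provinces_csv)
    for col in ("province", "demand"):
        if col not in provinces.columns:
            raise InputError(f"{provinces_csv}: missing column {col!r}")
    demand = {str(r.province): int(r.demand) for r in provinces.itertuples()}
    if "delta" in provinces.columns:
        delta = {str(r.province): float(r.delta) for r in provinces.itertuples()}
    else:
        delta = float(cfg.get("delta", 0.0)) if np.isscalar(cfg.get("delta", 0.0)) else cfg.get("delta")
    instance = AllocationInstance(
        hospitals=hospitals,
        demand=demand,
        T=int(cfg.get("T", 50)),
        delta=delta,
        budget=cfg.get("budget"),
        capital_province=cfg.get("capital_province"),
        flags=config_flags(cfg),
        curve=config_curve(cfg),
    )
    if drop_below_threshold:
        keep = instance.allocatable_ids()
        dropped = sorted(set(instance.hospitals.index) - set(keep))
        if dropped:
            logger.warning(
                "dropping %d hospital(s) below the applicable volume lower bound: %s",
                len(dropped),
                dropped,
            )
            instance = AllocationInstance(
                hospitals=instance.hospitals.loc[keep].drop(columns=["v"]),
                demand=demand,
                T=instance.T,
                delta=dict(instance.delta),
                budget=instance.budget,
                capital_province=instance.capital_province,
                flags=instance.flags,
                curve=instance.curve,
            )
    return instance


def load_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["id", "province", "age", "sex", "rurality", "admission_type", "comorbidity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    if df["id"].duplicated().any():
        raise InputError(f"{path}: duplicate patient id(s)")
    return df.set_index("id", drop=False)


def load_distances(path, patients: pd.DataFrame, hospitals: pd.DataFrame) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    missing = [h for h in hospitals.index if h not in df.columns]
    if missing:
        raise InputError(f"{path}: distance matrix missing hospital column(s) {missing}")
    missing_p = [p for p in patients.index if p not in df.index]
    if missing_p:
        raise InputError(f"{path}: distance matrix missing patient row(s) {missing_p[:5]}...")
    if (df[list(hospitals.index)] < 0).any().any():
        raise InputError(f"{path}: negative distances")
    return df


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_region(out_dir, instance: AllocationInstance, patients: pd.DataFrame, distances: pd.DataFrame) -> None:
    """Emit the four CSVs every other command consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    instance.hospitals.drop(columns=["v"]).to_csv(out / "hospitals.csv", index=False)
    pd.DataFrame(
        {
            "province": instance.provinces,
            "demand": [instance.demand[n] for n in instance.provinces],
            "delta": [instance.delta[n] for n in instance.provinces],
        }
    ).to_csv(out / "provinces.csv", index=False)
    patients.to_csv(out / "patients.csv", index=False)
    distances.to_csv(out / "distances.csv")


def _volumes_table(volumes: pd.Series | dict, instance: AllocationInstance) -> pd.DataFrame:
    if isinstance(volumes, dict):
        volumes = pd.Series(volumes)
    ids = sorted(volumes.index)
    vols = volumes[ids].astype(float)
    v = instance.hospitals.loc[ids, "v"].astype(float)
    deaths = [expected_deaths(instance.curve, x, vv) for x, vv in zip(vols, v)]
    return pd.DataFrame(
        {"hospital_id": ids, "volume": vols.to_numpy(), "v": v.to_numpy(), "expected_deaths": deaths}
    )


def write_plan(path, plan, instance: AllocationInstance) -> None:
    """Strategic plan CSV: hospital_id, open, volume, expected_deaths."""
    tab = _volumes_table(plan.volumes, instance)
    tab.insert(1, "open", [int(plan.open[h]) for h in tab["hospital_id"]])
    tab.to_csv(path, index=False)


def recompute_mortality(volumes_table: pd.DataFrame, curve: MortalityCurve) -> float:
    """Total deaths recomputed from a stored volume table and the curve."""
    return float(
        sum(
            expected_deaths(curve, float(r.volume), float(r.v))
            for r in volumes_table.itertuples()
        )
    )


def write_report(out_dir, report: IntegratedReport, instance: AllocationInstance, cfg: dict, seed) -> None:
    """Write the integrated-run report directory.

    Contains per-phase counts, the candidate list, one volume table per
    solution (actual / strategic / operational / integrated) and a plain-text
    summary with the four-way mortality comparison.  Re-reading any volume
    table and recomputing mortality with the echoed curve config reproduces
    the stored figures.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enum = report.enumeration

    counts = {
        "provinces": enum.provinces,
        "H": enum.H,
        "r_min": enum.r_min,
        "n_choice_sets_closed_form": enum.n_precount,
        "n_admissible": enum.n_admissible,
        "n_evaluated": report.n_evaluated,
        "n_candidates": len(report.candidates),
        "seed": seed,
    }
    (out / "phase_counts.json").write_text(json.dumps(counts, indent=2, default=str))

    pd.DataFrame(
        [
            {
                "rank": i + 1,
                "open_ids": ";".join(c.open_ids),
                "total_deaths": c.total_deaths,
                "n_threshold_violations": len(c.threshold_violations),
                "n_capacity_violations": len(c.capacity_violations),
            }
            for i, c in enumerate(report.candidates)
        ]
    ).to_csv(out / "candidates.csv", index=False)

    tables = {
        "actual": instance.hospitals["prev_volume"].astype(float),
        "integrated": report.integrated.volumes,
    }
    if report.strategic_plan.is_optimal:
        tables["strategic"] = pd.Series(report.strategic_plan.volumes, dtype=float)
    if report.operational_of_strategic is not None:
        tables["operational"] = report.operational_of_strategic.volumes
    for name, vols in tables.items():
        _volumes_table(vols, instance).to_csv(out / f"volumes_{name}.csv", index=False)

    pd.DataFrame(
        {"solution": list(report.mortalities), "total_deaths": list(report.mortalities.values())}
    ).to_csv(out / "mortalities.csv", index=False)

    echo = dict(cfg)
    echo["seed"] = seed
    (out / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))

    lines = [
        "Integrated planning report",
        "==========================",
        f"theta = {report.theta}%, skim criterion = {report.criterion}",
        "",
        "Phase 1: "
        f"H = {enum.H}, r_min = {enum.r_min}; "
        f"{enum.n_precount} choice sets by the closed form, {enum.n_admissible} admissible",
        f"Phase 2: {report.n_evaluated} operational solutions evaluated; "
        f"minimum mortality {report.min_operational_deaths:.3f}; "
        f"{len(report.candidates)} candidate(s) pass the theta rule",
        f"Phase 3: integrated choice set = {', '.join(report.integrated.open_ids)}",
        "",
        "Total expected deaths:",
    ]
    for name in ("actual", "strategic", "operational", "integrated"):
        val = report.mortalities.get(name, float("nan"))
        lines.append(f"  {name:<12} {val:.3f}")
    if not report.candidates:
        lines.append("No integrated solution: candidate list is empty.")
    thr = report.integrated.threshold_violations
    lines.append("")
    lines.append(
        f"Threshold violations in the integrated solution: {', '.join(thr) if thr else 'none'}"
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
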