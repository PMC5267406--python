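"""Synthetic ICU cohort generator.

No patient-level data exist for the cohort this package analyses, so the
generator produces reproducible synthetic cohorts carrying the structure
the pipeline assumes: a latent severity-of-illness variable drives all
organ physiology through monotone clipped linear/log-linear links with
Gaussian noise, mortality follows a logistic model in baseline severity
with the intercept calibrated by root-finding to a target death rate, and
severity drifts apart after 48 h — downward in eventual survivors, upward
in non-survivors.  Decoy patients (low-risk monitoring admissions, deaths
within 24 h, one patient lost to follow-up) are injected so the
eligibility filter has work to do.

The generative model (per patient i, observation time t):

    z0_i ~ Normal(0, 1)                                (baseline severity)
    P(death_i) = expit(alpha + beta * z0_i),  alpha solved so that
                 mean_i P(death_i) = target mortality
    outcome_i ~ Bernoulli(P(death_i))
    z48_i = z0_i + drift(outcome_i) + Normal(0, 0.5)
    z_i(t) = z_window + Normal(0, 0.15) per observation

Organ links (values clipped to physiologic ranges; eta = per-obs latent):

    SpO2        = 96 - 6*eta - 3*max(eta - 1.2, 0)^2 + N(0, 2)     [40, 100]
    oxygen      = room air (eta < -1.2), nasal cannula with flow
                  3 + 2.5*(eta + 1.2) L/min (-1.2 <= eta < 0), else
                  ventilator with FiO2 0.45 + 0.25*eta              [0.25, 1]
    PaO2        = SpO2-consistent: 27 + 1.3*(SpO2 - 57) + N(0, 8)   [30, 500]
    platelets   = 230 - 45*eta + N(0, 42)                           [5, 800]
    bilirubin   = exp(-0.80 + 0.70*eta + N(0, 0.42))                [0.1, 40]
    MAP         = 86 - 8*eta + N(0, 8)                              [30, 180]
    GCS         = round(10 - 2.8*eta + N(0, 2.2))                   [3, 15]
    creatinine  = exp(-0.05 + 0.55*eta + N(0, 0.32))                [0.2, 20]
    urine       = 1500*exp(-0.45*eta) + N(0, 250)                   [0, 8000]
    vasopressor: P(any) = expit(-2.9 + 1.2*eta); norepinephrine 70%
                 (dose 0.05*exp(0.8*eta + N(0, 0.5))), dopamine 25%
                 (dose 4*exp(0.5*eta + N(0, 0.5))), dobutamine 5%

Coefficients were calibrated once against the published cohort moments
(mortality 46.6%, admission total mSOFA mean ~6.5 SD ~3.7, the per-organ
admission means) and are a smoke check, not an exact reproduction target.
PaO2 is blanked with probability 0.9 by default, emulating the near-total
absence of blood-gas data that motivates the SpO2 modification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .pipeline import ADMISSION_SOURCES

#: observation timestamps (hours) falling in the T0 and T48 scoring windows
T0_TIMES = (0.0, 8.0, 16.0)
T48_TIMES = (28.0, 38.0, 48.0)

_OBS_COLUMNS = [
    "patient_id", "timestamp_h", "spo2", "pao2", "oxygen_device",
    "oxygen_flow", "fio2", "map", "gcs", "platelets", "bilirubin",
    "creatinine", "urine_output", "dopamine", "dobutamine", "norepinephrine",
]


def _default_missingness() -> dict[str, float]:
    return {"pao2": 0.9, "spo2": 0.03, "map": 0.03, "gcs": 0.03, "urine_output": 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``n_patients`` counts eligible (analyzable) patients; decoys destined
    for exclusion are generated on top, at ``low_risk_fraction`` and
    ``early_death_fraction`` of the eligible count, plus one
    outcome-unknown patient in cohorts of 50 or more.
    """

    n_patients: int = 118
    target_mortality: float = 0.466
    severity_effect: float = 0.9     # log-odds of death per unit baseline severity
    survivor_drift: float = -0.60    # mean latent change by 48 h, survivors
    nonsurvivor_drift: float = 0.25  # mean latent change by 48 h, non-survivors
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    low_risk_fraction: float = 0.36
    early_death_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("target_mortality", "low_risk_fraction", "early_death_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for param, p in self.missingness.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"missingness[{param!r}] must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: the two pipeline input tables plus ground truth."""

    patients: pd.DataFrame
    observations: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "patients": outdir / "patients.csv",
            "observations": outdir / "observations.csv",
            "ground_truth": outdir / "ground_truth.csv",
        }
        self.patients.to_csv(paths["patients"], index=False)
        self.observations.to_csv(paths["observations"], index=False)
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


def calibrate_intercept(z0: np.ndarray, beta: float, target: float) -> float:
    """Solve expit-mean(alpha + beta z0) = target for alpha by root-finding."""
    if not (0.0 < target < 1.0):
        raise ValueError(
            f"target mortality must lie strictly in (0, 1) for a finite intercept, got {target}")

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + beta * z0))) - target

    return float(optimize.brentq(gap, -40.0, 40.0, xtol=1e-10))


def _physiology_row(eta: float, rng: np.random.Generator) -> dict[str, object]:
    spo2 = float(np.clip(96 - 6 * eta - 3 * max(eta - 1.2, 0.0) ** 2 + rng.normal(0, 2), 40, 100))
    if eta < -1.2:
        device, flow, fio2 = "room_air", None, None
    elif eta < 0.0:
        device = "nasal_cannula"
        flow = float(np.clip(3 + 2.5 * (eta + 1.2) + rng.normal(0, 0.5), 0.5, 10))
        fio2 = None
    else:
        device = "ventilator"
        flow = None
        fio2 = float(np.clip(0.45 + 0.25 * eta + rng.normal(0, 0.05), 0.25, 1.0))
    pao2 = float(np.clip(27 + 1.3 * (spo2 - 57) + rng.normal(0, 8), 30, 500))
    row: dict[str, object] = {
        "spo2": round(spo2, 1),
        "pao2": round(pao2, 1),
        "oxygen_device": device,
        "oxygen_flow": round(flow, 1) if flow is not None else None,
        "fio2": round(fio2, 2) if fio2 is not None else None,
        "map": round(float(np.clip(86 - 8 * eta + rng.normal(0, 8), 30, 180)), 1),
        "gcs": int(np.clip(round(10 - 2.8 * eta + rng.normal(0, 2.2)), 3, 15)),
        "platelets": round(float(np.clip(230 - 45 * eta + rng.normal(0, 42), 5, 800)), 1),
        "bilirubin": round(float(np.clip(math.exp(-0.80 + 0.70 * eta + rng.normal(0, 0.42)), 0.1, 40)), 2),
        "creatinine": round(float(np.clip(math.exp(-0.05 + 0.55 * eta + rng.normal(0, 0.32)), 0.2, 20)), 2),
        "urine_output": round(float(np.clip(1500 * math.exp(-0.45 * eta) + rng.normal(0, 250), 0, 8000)), 0),
        "dopamine": None,
        "dobutamine": None,
        "norepinephrine": None,
    }
    if rng.random() < expit(-2.9 + 1.2 * eta):
        drug = rng.choice(["norepinephrine", "dopamine", "dobutamine"], p=[0.70, 0.25, 0.05])
        if drug == "norepinephrine":
            dose = np.clip(0.05 * math.exp(0.8 * eta + rng.normal(0, 0.5)), 0.01, 3.0)
        elif drug == "dopamine":
            dose = np.clip(4 * math.exp(0.5 * eta + rng.normal(0, 0.5)), 0.5, 40.0)
        else:
            dose = np.clip(5 * math.exp(0.3 * eta + rng.normal(0, 0.5)), 0.5, 40.0)
        row[drug] = round(float(dose), 3)
    return row


def _demographics(pid: str, rng: np.random.Generator) -> dict[str, object]:
    return {
        "patient_id": pid,
        "age": round(float(np.clip(rng.normal(37, 17), 13.5, 95)), 1),
        "sex": "male" if rng.random() < 0.58 else "female",
        "admission_source": str(rng.choice(ADMISSION_SOURCES)),
        "admission_type": "medical" if rng.random() < 0.34 else "surgical",
    }


def _observation_rows(pid: str, z0: float, z48: float, rng: np.random.Generator) -> list[dict[str, object]]:
    rows = []
    for times, z in ((T0_TIMES, z0), (T48_TIMES, z48)):
        for t in times:
            eta = z + rng.normal(0, 0.15)
            row = {"patient_id": pid, "timestamp_h": t}
            row.update(_physiology_row(eta, rng))
            rows.append(row)
    return rows


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one reproducible synthetic cohort under ``config``.

    Returns the patients table, the long-format observations table and a
    ground-truth table (latent severities, true death probability, decoy
    flag) kept in a separate file that the pipeline never reads.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    z0 = rng.standard_normal(n)
    alpha = calibrate_intercept(z0, config.severity_effect, config.target_mortality)
    p_death = expit(alpha + config.severity_effect * z0)
    outcome = rng.random(n) < p_death
    drift = np.where(outcome, config.nonsurvivor_drift, config.survivor_drift)
    z48 = z0 + drift + rng.normal(0, 0.5, n)

    patients, observations, truth = [], [], []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        demo = _demographics(pid, rng)
        obs_rows = _observation_rows(pid, z0[i], z48[i], rng)
        vaso_used = any(r[d] is not None for r in obs_rows
                        for d in ("dopamine", "dobutamine", "norepinephrine"))
        los = float(np.clip(rng.lognormal(mean=1.8, sigma=0.8), 1.05, 90))
        if outcome[i]:
            los = min(los, float(np.clip(rng.lognormal(mean=1.6, sigma=0.8), 1.05, 90)))
        demo.update(
            mechanically_ventilated=int(any(r["oxygen_device"] == "ventilator" for r in obs_rows)),
            vasopressor_used=int(vaso_used),
            low_risk_monitoring=0,
            icu_los_days=round(los, 2),
            outcome="died" if outcome[i] else "survived",
        )
        patients.append(demo)
        observations.extend(obs_rows)
        truth.append({
            "patient_id": pid, "z0": z0[i], "z48": z48[i],
            "p_death": p_death[i], "outcome": int(outcome[i]), "decoy": "",
        })

    # eligibility decoys: excluded by the filter, never analyzed
    n_low = int(round(n * config.low_risk_fraction))
    n_early = int(round(n * config.early_death_fraction))
    n_noout = 1 if n >= 50 else 0
    decoys = [("low_risk", -1.0, "survived", (0.2, 0.9), 1)] * n_low \
        + [("early_death", 1.8, "died", (0.05, 0.9), 0)] * n_early \
        + [("no_outcome", 0.0, "none", (2.0, 10.0), 0)] * n_noout
    for j, (kind, z_decoy, out, los_range, low_flag) in enumerate(decoys):
        pid = f"D{j + 1:04d}"
        demo = _demographics(pid, rng)
        los = float(rng.uniform(*los_range))
        zd = z_decoy + rng.normal(0, 0.3)
        obs_rows = _observation_rows(pid, zd, zd, rng)
        if kind == "early_death":  # dead before 24 h: no T48 observations
            obs_rows = [r for r in obs_rows if r["timestamp_h"] < 24]
        demo.update(
            mechanically_ventilated=int(any(r["oxygen_device"] == "ventilator" for r in obs_rows)),
            vasopressor_used=int(any(r[d] is not None for r in obs_rows
                                     for d in ("dopamine", "dobutamine", "norepinephrine"))),
            low_risk_monitoring=low_flag,
            icu_los_days=round(los, 2),
            outcome=out,
        )
        patients.append(demo)
        observations.extend(obs_rows)
        truth.append({"patient_id": pid, "z0": zd, "z48": zd,
                      "p_death": float("nan"), "outcome": int(out == "died"), "decoy": kind})

    obs_df = pd.DataFrame(observations, columns=_OBS_COLUMNS)
    obs_df = inject_missingness(obs_df, config.missingness, seed=int(rng.integers(2**31)))
    return Cohort(
        patients=pd.DataFrame(patients),
        observations=obs_df,
        ground_truth=pd.DataFrame(truth),
        config=config,
    )


def inject_missingness(
    observations: pd.DataFrame,
    missingness: dict[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Independently blank each parameter value with its configured
    probability; realized per-parameter rates go to the frame's attrs."""
    rng = np.random.default_rng(seed)
    out = observations.copy()
    realized: dict[str, float] = {}
    for column, p in missingness.items():
        if column not in out.columns:
            raise ValueError(f"unknown observation column {column!r}")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"missingness[{column!r}] must lie in [0, 1], got {p}")
        present = out[column].notna()
        blank = rng.random(len(out)) < p
        out.loc[blank, column] = np.nan
        n_present = int(present.sum())
        realized[column] = float((blank & present).sum() / n_present) if n_present else float("nan")
    out.attrs["realized_missingness"] = realized
    return out
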