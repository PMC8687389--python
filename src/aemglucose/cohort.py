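"""Virtual patient populations for robustness evaluation.

Inter-patient variability is modelled by independent uniform draws of
each rate constant from its physiological range; intra-patient
variability by sinusoidal modulation within the run.  So that the total
parametric excursion stays inside the population ranges (a 30% band
around the nominal subject), each patient's modulation amplitude is
clipped per parameter to the distance from the drawn base value to the
nearer range endpoint.

Per-patient randomness (parameter draw, modulation phases, meal
schedule) derives from the master seed through per-index spawn keys, so
enlarging a cohort never reshuffles earlier patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import NOMINAL_PATIENT, ParamRanges, PatientParams, TABLE_RANGES
from .simulate import MODULATED, ParamModulation, run_scenario_2

__all__ = [
    "VirtualPatient",
    "sample_patient",
    "generate_cohort",
    "named_patients",
    "run_cohort",
    "cohort_manifest",
]


@dataclass(frozen=True)
class VirtualPatient:
    """One sampled subject plus the randomness needed to re-run it."""

    id: int
    params: PatientParams
    phases: dict = field(default_factory=dict)
    meal_seed: int = 0

    def modulation(self, clip_to: ParamRanges | None = TABLE_RANGES) -> ParamModulation:
        """Sinusoidal modulation; amplitudes clipped to the population ranges."""
        if clip_to is None:
            return ParamModulation(amplitude=0.30, phases=self.phases)
        amps = {}
        for name in MODULATED:
            lo, hi = getattr(clip_to, name)
            v = getattr(self.params, name)
            amps[name] = max(0.0, min(v - lo, hi - v))
        return ParamModulation(amplitude=0.30, phases=self.phases, amplitudes=amps)


def _patient_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def sample_patient(
    rng: np.random.Generator,
    ranges: ParamRanges = TABLE_RANGES,
    id: int = 0,
    meal_seed: int = 0,
) -> VirtualPatient:
    """Draw one subject: modulated parameters uniform in range, c1 pinned."""
    kw = {}
    for name in MODULATED:
        lo, hi = getattr(ranges, name)
        kw[name] = float(rng.uniform(lo, hi))
    params = NOMINAL_PATIENT.replace(**kw)
    phases = {n: float(rng.uniform(0.0, 2.0 * math.pi)) for n in MODULATED}
    return VirtualPatient(id=id, params=params, phases=phases, meal_seed=meal_seed)


def generate_cohort(
    n: int, seed: int, ranges: ParamRanges = TABLE_RANGES
) -> list[VirtualPatient]:
    """``n`` independent virtual subjects, reproducible under ``seed``."""
    if n < 0:
        raise ValueError("cohort size must be >= 0")
    cohort = []
    for i in range(n):
        rng = _patient_rng(seed, i)
        meal_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(sample_patient(rng, ranges, id=i, meal_seed=meal_seed))
    return cohort


def named_patients(ranges: ParamRanges = TABLE_RANGES) -> dict:
    """The nominal / maximum / minimum showcase triple.

    All rate constants sit at the range midpoint, upper corner, or
    lower corner simultaneously; note that the corner subjects keep the
    nominal insulin sensitivity ratio ``c3/c2``.
    """
    out = {}
    for label, pick in (
        ("nominal", lambda lo, hi: 0.5 * (lo + hi)),
        ("maximum", lambda lo, hi: hi),
        ("minimum", lambda lo, hi: lo),
    ):
        kw = {n: pick(*getattr(ranges, n)) for n in MODULATED}
        out[label] = NOMINAL_PATIENT.replace(**kw)
    return out


def run_cohort(
    cohort: list[VirtualPatient],
    K: np.ndarray | None = None,
    L: np.ndarray | None = None,
    days: int = 3,
    modulate: bool = True,
    ranges: ParamRanges = TABLE_RANGES,
    progress: bool = False,
    **cfg_kw,
):
    """Scenario-II run per patient; per-patient failures are collected.

    Returns ``(results, failures)`` where ``results`` is a list of
    ``(patient, Trajectory)`` and ``failures`` a list of
    ``(patient, exception)``.
    """
    results, failures = [], []
    it = cohort
    if progress:
        try:
            from tqdm import tqdm

            it = tqdm(cohort, desc="cohort")
        except ImportError:
            pass
    for patient in it:
        try:
            mod = patient.modulation(ranges) if modulate else ParamModulation.none()
            traj = run_scenario_2(
                params=patient.params,
                K=K,
                L=L,
                seed=np.random.default_rng(patient.meal_seed),
                mod=mod,
                days=days,
                **cfg_kw,
            )
            results.append((patient, traj))
        except Exception as exc:  # noqa: BLE001 - batch driver collects failures
            failures.append((patient, exc))
    return results, failures


def cohort_manifest(cohort: list[VirtualPatient]) -> pd.DataFrame:
    """Tabular description of a cohort (one row per subject)."""
    rows = []
    for p in cohort:
        row = {"id": p.id, "meal_seed": p.meal_seed}
        row.update({n: getattr(p.params, n) for n in MODULATED})
        row.update({f"phase_{n}": p.phases.get(n, 0.0) for n in MODULATED})
        rows.append(row)
    return pd.DataFrame(rows)
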