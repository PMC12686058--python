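"""Seeded synthetic patients with known ground truth.

Every downstream stage (fitting, DOE, surrogate, UQ, validation) is testable
against cohorts generated here: each patient carries true model inputs drawn
around the nominal epistemic values, an imaged diastolic geometry, the true
loaded diameter/stress recomputed through the membrane simulator, and
CTA-like triplicate diameter measurements with Normal scanner noise
(sd 0.625 mm, the scanner's through-plane voxel size treated as one standard
deviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .doe import INPUT_NAMES, InputBounds
from .materials import OgdenParams, StressStrainCurve, is_valid_material, ogden_stress
from .vessel import ModelInputs, SimResult, ToyCoefficients, VesselGeometry, simulate_patient

__all__ = [
    "SyntheticPatient",
    "ComparatorMeasurement",
    "make_cohort",
    "synth_biaxial_curves",
    "measure_comparator",
    "DEFAULT_SCANNER_SD",
]

#: CTA scanner diameter uncertainty (mm), one standard deviation.
DEFAULT_SCANNER_SD = 0.625


@dataclass(frozen=True)
class SyntheticPatient:
    id: str
    true_inputs: ModelInputs
    geom: VesselGeometry
    true_diameter: float  # mm, loaded diameter at peak systole
    true_stress: float  # MPa

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "true_inputs": {n: getattr(self.true_inputs, n) for n in INPUT_NAMES},
            "geom": {
                "diastolic_diameter": self.geom.diastolic_diameter,
                "R0": self.geom.R0,
                "lambda_z": self.geom.lambda_z,
                "convention": self.geom.convention,
            },
            "true_diameter": self.true_diameter,
            "true_stress": self.true_stress,
        }


@dataclass(frozen=True)
class ComparatorMeasurement:
    """Triplicate CTA-like diameter measurement."""

    replicates: tuple[float, float, float]
    mean: float
    sd_assumed: float

    def __post_init__(self) -> None:
        if len(self.replicates) != 3:
            raise ValueError("exactly three replicates expected")
        if self.sd_assumed <= 0:
            raise ValueError("sd_assumed must be positive")


def _draw_inputs(bounds: InputBounds, rng: np.random.Generator) -> np.ndarray:
    """One truncated-Normal draw per input, centered at the nominal with
    sd = (UB - LB) / 4, truncated to [LB, UB]."""
    lb, ub, nom = bounds.lb, bounds.ub, bounds.nominal
    sd = (ub - lb) / 4.0
    a = (lb - nom) / sd
    b = (ub - nom) / sd
    return truncnorm.rvs(a, b, loc=nom, scale=sd, random_state=rng)


def make_cohort(
    n: int,
    bounds: InputBounds | None = None,
    diastolic_diameter_range: tuple[float, float] = (42.0, 55.0),
    seed: int = 0,
    coeffs: ToyCoefficients = ToyCoefficients(),
    lambda_z: float = 1.0,
    convention: str = "lumen",
    max_tries: int = 200,
) -> list[SyntheticPatient]:
    """Generate ``n`` synthetic patients, deterministic under ``seed``.

    True inputs are redrawn until the material passes the ground-state
    validity screen and the membrane solve converges; the imaged diastolic
    mid-wall diameter is drawn uniformly from ``diastolic_diameter_range``
    (the cohort's aneurysm size range).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo_d, hi_d = diastolic_diameter_range
    if not 0 < lo_d < hi_d:
        raise ValueError("invalid diastolic diameter range")
    bounds = bounds or InputBounds.reference()
    rng = np.random.default_rng(seed)
    patients: list[SyntheticPatient] = []
    for i in range(n):
        d_dias = float(rng.uniform(lo_d, hi_d))
        geom = VesselGeometry(
            diastolic_diameter=d_dias, lambda_z=lambda_z, convention=convention
        )
        sol: SimResult | None = None
        x: ModelInputs | None = None
        for _ in range(max_tries):
            vals = _draw_inputs(bounds, rng)
            params = OgdenParams(vals[0], vals[1], vals[2], vals[3])
            if not is_valid_material(params, "ground_state").valid:
                continue
            try:
                x = ModelInputs.from_array(vals)
            except ValueError:
                continue
            cand = simulate_patient(geom, x, coeffs)
            if cand.converged:
                sol = cand
                break
        if sol is None or x is None:
            raise RuntimeError(
                f"could not generate a convergent patient after {max_tries} draws"
            )
        patients.append(
            SyntheticPatient(
                id=f"SYN-{i + 1:02d}",
                true_inputs=x,
                geom=geom,
                true_diameter=sol.diameter,
                true_stress=sol.stress,
            )
        )
    return patients


def synth_biaxial_curves(
    params: OgdenParams,
    n_points: int = 20,
    lam_max: float = 1.3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[StressStrainCurve, StressStrainCurve]:
    """Equibiaxial stress–stretch curves for the circumferential and
    longitudinal directions (identical kinematics under isotropy), with
    i.i.d. Normal stress noise of ``noise_sd`` MPa."""
    if lam_max <= 1:
        raise ValueError("lam_max must exceed 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not is_valid_material(params, "ground_state").valid:
        raise ValueError("material must be ground-state valid")
    rng = np.random.default_rng(seed)
    lam = np.linspace(1.0, lam_max, n_points)
    clean = ogden_stress(params, lam, "equibiaxial")
    curves = []
    for _ in range(2):
        noisy = clean + rng.normal(0.0, noise_sd, size=n_points) if noise_sd else clean
        curves.append(StressStrainCurve(lam, np.asarray(noisy), "equibiaxial"))
    return curves[0], curves[1]


def measure_comparator(
    patient: SyntheticPatient,
    sd: float = DEFAULT_SCANNER_SD,
    seed: int = 0,
) -> ComparatorMeasurement:
    """Triplicate Normal(true diameter, sd) CTA-like measurement."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    reps = rng.normal(patient.true_diameter, sd, size=3)
    return ComparatorMeasurement(
        replicates=tuple(float(r) for r in reps),
        mean=float(np.mean(reps)),
        sd_assumed=float(sd),
    )
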