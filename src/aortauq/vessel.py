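"""Thin-walled membrane model of the pressurized ascending aorta.

This module is the physics stand-in for the patient-specific finite-element
solve: a quasi-static, incompressible Ogden membrane cylinder inflated by the
peak of a scaled physiological pressure waveform.  Equilibrium of a thin
membrane with unloaded mid-wall radius R0, unloaded thickness s0 and
prescribed axial stretch lambda_z reads

    P = sigma_theta(l) * s0 / (l**2 * lambda_z * R0),      l = lambda_theta,

with the circumferential Cauchy stress from the Ogden law under traction-free
radial stress,

    sigma_theta(l) = sum_i (2 mu_i / a_i) (l**a_i - (l * lambda_z)**(-a_i)).

The loaded lumen (inner) diameter is 2*l*R0 - s0/(l*lambda_z), matching what
CTA lumen segmentation measures; the mid-wall convention is available as an
option.  The unloaded radius can either be given directly or recovered from
an imaged diastolic diameter (the membrane analog of recovering the
zero-pressure configuration from diastolic imaging before simulating the
cardiac cycle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .materials import OgdenParams, is_valid_material
from .units import MMHG_TO_KPA, MMHG_TO_MPA

__all__ = [
    "ModelInputs",
    "VesselGeometry",
    "PressureWaveform",
    "SimResult",
    "ToyCoefficients",
    "INPUT_COLUMNS",
    "RESULT_COLUMNS",
    "default_pulse_template",
    "scale_waveform",
    "inflate_membrane",
    "calibrate_unloaded_radius",
    "simulate_patient",
    "simulate_plan",
    "laplace_stress",
]

#: canonical column order of the CSV interchange format.
INPUT_COLUMNS = ["mu1", "a1", "mu2", "a2", "s", "HR", "Psys", "Pdias", "V"]
RESULT_COLUMNS = INPUT_COLUMNS + ["diameter", "stress", "converged"]


@dataclass(frozen=True)
class ModelInputs:
    """One point of the 9-D epistemic input space.

    mu1, mu2 (MPa) and a1, a2 (-) are the Ogden material parameters, s the
    wall thickness (mm), HR heart rate (bpm), Psys/Pdias systolic/diastolic
    pressure (mmHg), V transaortic flow velocity (m/s).
    """

    mu1: float
    a1: float
    mu2: float
    a2: float
    s: float
    HR: float
    Psys: float
    Pdias: float
    V: float

    def __post_init__(self) -> None:
        if not self.Psys > self.Pdias > 0:
            raise ValueError(f"need Psys > Pdias > 0, got {self.Psys}, {self.Pdias}")
        if self.HR <= 0:
            raise ValueError("HR must be positive")
        if self.s <= 0:
            raise ValueError("thickness s must be positive")
        if self.V < 0:
            raise ValueError("V must be non-negative")

    @property
    def ogden(self) -> OgdenParams:
        return OgdenParams(self.mu1, self.a1, self.mu2, self.a2)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in INPUT_COLUMNS])

    @classmethod
    def from_array(cls, row) -> "ModelInputs":
        return cls(**dict(zip(INPUT_COLUMNS, map(float, row))))


@dataclass(frozen=True)
class VesselGeometry:
    """Vessel geometry specification.

    Exactly one of ``R0`` (unloaded mid-wall radius, mm) or
    ``diastolic_diameter`` (imaged mid-wall diameter at diastolic pressure,
    mm) must be given.  In the anchored mode the unloaded radius is solved
    per material so the membrane reproduces the imaged diastolic state, as
    the FE workflow recovers the zero-pressure configuration from diastolic
    imaging.  ``convention`` selects the reported loaded diameter: the lumen
    (inner) diameter measured by CTA segmentation, or the mid-wall diameter.
    """

    R0: float | None = None
    diastolic_diameter: float | None = None
    lambda_z: float = 1.0
    convention: Literal["lumen", "midwall"] = "lumen"

    def __post_init__(self) -> None:
        if (self.R0 is None) == (self.diastolic_diameter is None):
            raise ValueError("give exactly one of R0 or diastolic_diameter")
        if self.R0 is not None and self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.diastolic_diameter is not None and self.diastolic_diameter <= 0:
            raise ValueError("diastolic_diameter must be positive")
        if self.lambda_z <= 0:
            raise ValueError("lambda_z must be positive")
        if self.convention not in ("lumen", "midwall"):
            raise ValueError(f"unknown diameter convention {self.convention!r}")


@dataclass(frozen=True)
class PressureWaveform:
    """One cardiac cycle of pressure samples (s, mmHg)."""

    times: np.ndarray
    pressures: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    @property
    def peak(self) -> float:
        return float(np.max(self.pressures))


@dataclass(frozen=True)
class SimResult:
    """Loaded-state outputs at peak systole."""

    diameter: float  # mm, per the geometry's diameter convention
    stress: float  # MPa, max principal (circumferential) Cauchy stress
    converged: bool
    residual: float  # MPa, |lhs - rhs| of the equilibrium equation
    lambda_theta: float = float("nan")
    R0: float = float("nan")  # unloaded mid-wall radius actually used (mm)


@dataclass(frozen=True)
class ToyCoefficients:
    """Synthetic hemodynamic coupling of HR and V into the structural load.

    The FE study never states how flow velocity and heart rate enter the
    structural model; these coefficients are an explicit package construct.
    Defaults are small so that HR and V sensitivities stay marginal:

        P_eff = Psys*(1 + c_V*(V - V_nom)/V_nom)
                + c_HR*((HR - HR_nom)/HR_nom)*(Psys - Pdias)
    """

    c_V: float = 0.02
    c_HR: float = 0.01
    V_nom: float = 1.3
    HR_nom: float = 70.0

    def effective_pressure(self, x: ModelInputs) -> float:
        return x.Psys * (1.0 + self.c_V * (x.V - self.V_nom) / self.V_nom) + (
            self.c_HR * ((x.HR - self.HR_nom) / self.HR_nom) * (x.Psys - x.Pdias)
        )


# ---------------------------------------------------------------------------
# Pressure waveform
# ---------------------------------------------------------------------------


def default_pulse_template(tau, peak_frac: float = 0.3, decay: float = 4.0):
    """Normalized pulse shape on [0, 1]: half-sine upstroke peaking at
    ``peak_frac``, exponential diastolic decay reaching 0 at tau = 1."""
    tau = np.asarray(tau, dtype=float)
    up = np.sin(0.5 * np.pi * np.clip(tau, 0, None) / peak_frac) ** 2
    down_raw = np.exp(-decay * (tau - peak_frac))
    floor = math.exp(-decay * (1.0 - peak_frac))
    down = (down_raw - floor) / (1.0 - floor)
    out = np.where(tau <= peak_frac, up, down)
    return out if out.ndim else float(out)


def scale_waveform(
    Psys: float,
    Pdias: float,
    HR: float,
    n_steps: int = 200,
    template: Callable[[np.ndarray], np.ndarray] = default_pulse_template,
) -> PressureWaveform:
    """Scale the normalized template to the pulse (Pdias .. Psys) and the
    cycle duration 60/HR, sampled at ``n_steps + 1`` uniform times."""
    if not Psys > Pdias:
        raise ValueError(f"need Psys > Pdias, got {Psys} <= {Pdias}")
    if HR <= 0:
        raise ValueError("HR must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    duration = 60.0 / HR
    t = np.linspace(0.0, duration, n_steps + 1)
    p = Pdias + (Psys - Pdias) * np.asarray(template(t / duration), dtype=float)
    return PressureWaveform(times=t, pressures=p)


# ---------------------------------------------------------------------------
# Membrane inflation
# ---------------------------------------------------------------------------


def _sigma_theta(params: OgdenParams, lam, lambda_z: float):
    """Circumferential Cauchy stress of the biaxial membrane state
    (lam, lambda_z, 1/(lam*lambda_z)) with traction-free radial stress."""
    lam = np.asarray(lam, dtype=float)
    out = np.zeros_like(lam)
    for mu, a in ((params.mu1, params.alpha1), (params.mu2, params.alpha2)):
        if mu != 0.0:
            out = out + (2.0 * mu / a) * (lam**a - (lam * lambda_z) ** (-a))
    return out if out.ndim else float(out)


def inflate_membrane(
    params: OgdenParams,
    R0: float,
    s0: float,
    P_mmHg: float,
    lambda_z: float = 1.0,
    lam_max: float = 3.0,
    tol: float = 1e-10,
    _grid_n: int = 601,
) -> SimResult:
    """Quasi-static inflation of the membrane cylinder at pressure ``P_mmHg``.

    Solves the equilibrium equation for lambda_theta by a grid scan for the
    first sign change followed by bracketed root refinement.  A missing
    bracket (limit-point instability or over-distension beyond ``lam_max``,
    the membrane analog of an exploded explicit-FE run) yields a flagged
    non-converged result rather than an exception.  The returned diameter is
    the mid-wall diameter 2*lambda_theta*R0.
    """
    if P_mmHg < 0:
        raise ValueError("pressure must be non-negative")
    if R0 <= 0 or s0 <= 0:
        raise ValueError("R0 and s0 must be positive")
    validity = is_valid_material(params, "ground_state")
    if not validity.valid:
        raise ValueError(
            "material not ground-state valid: " + ", ".join(validity.violated)
        )
    P = P_mmHg * MMHG_TO_MPA

    if P == 0.0 and lambda_z == 1.0:
        return SimResult(
            diameter=2.0 * R0, stress=0.0, converged=True, residual=0.0,
            lambda_theta=1.0, R0=R0,
        )

    def g(lam: float) -> float:
        return _sigma_theta(params, lam, lambda_z) * s0 / (lam**2 * lambda_z * R0) - P

    lam_lo = 0.5 if lambda_z != 1.0 else 1.0
    grid = np.linspace(lam_lo, lam_max, _grid_n)
    vals = np.array([g(x) for x in grid])
    sign = np.sign(vals)
    crossings = np.where(sign[:-1] * sign[1:] <= 0)[0]
    crossings = crossings[np.isfinite(vals[crossings]) & np.isfinite(vals[crossings + 1])]
    if crossings.size == 0:
        return SimResult(
            diameter=float("nan"), stress=float("nan"), converged=False,
            residual=float("inf"), lambda_theta=float("nan"), R0=R0,
        )
    i = int(crossings[0])
    if vals[i] == 0.0:
        lam = float(grid[i])
    else:
        # brentq tolerance on the stretch is kept three decades below the
        # residual tolerance so the equilibrium residual (in MPa) lands below
        # ``tol`` even for very stiff materials.
        xtol = max(tol * 1e-3, 1e-15)
        lam = brentq(g, grid[i], grid[i + 1], xtol=xtol, rtol=8.9e-16)
    stress = _sigma_theta(params, lam, lambda_z)
    residual = abs(g(lam))
    return SimResult(
        diameter=2.0 * lam * R0,
        stress=float(stress),
        converged=bool(residual < tol),
        residual=float(residual),
        lambda_theta=float(lam),
        R0=R0,
    )


def calibrate_unloaded_radius(
    params: OgdenParams,
    s0: float,
    Pdias_mmHg: float,
    diastolic_diameter: float,
    lambda_z: float = 1.0,
    lam_max: float = 3.0,
) -> float | None:
    """Unloaded mid-wall radius R0 such that inflation at diastolic pressure
    reproduces the imaged mid-wall diameter.  Returns ``None`` when no such
    radius exists for this material (flagged simulation failure)."""
    target = diastolic_diameter

    def mismatch(R0: float) -> float:
        sol = inflate_membrane(params, R0, s0, Pdias_mmHg, lambda_z, lam_max)
        if not sol.converged:
            return float("nan")
        return sol.diameter - target

    lo = 0.35 * target / 2.0
    hi = 0.9999 * target / 2.0
    f_lo, f_hi = mismatch(lo), mismatch(hi)
    if not (np.isfinite(f_lo) and np.isfinite(f_hi)) or f_lo * f_hi > 0:
        return None
    return float(brentq(mismatch, lo, hi, xtol=1e-10))


def _reported_diameter(sol: SimResult, geom: VesselGeometry, s0: float) -> float:
    if geom.convention == "midwall":
        return sol.diameter
    # lumen diameter: subtract the current (deformed) wall thickness,
    # t = s0 / (lambda_theta * lambda_z) by incompressibility.
    t_cur = s0 / (sol.lambda_theta * geom.lambda_z)
    return sol.diameter - t_cur


def simulate_patient(
    geom: VesselGeometry,
    x: ModelInputs,
    coeffs: ToyCoefficients = ToyCoefficients(),
    waveform_steps: int | None = None,
    tol: float = 1e-10,
    lam_max: float = 3.0,
) -> SimResult:
    """Map one 9-D input row to peak-systolic diameter and wall stress.

    The effective peak pressure folds the (synthetic, documented) HR and V
    couplings into the systolic pressure; when ``waveform_steps`` is given
    the peak is taken from the discretely sampled scaled waveform instead of
    the exact pulse maximum, which is what the discretization-convergence
    study varies.
    """
    P_eff = coeffs.effective_pressure(x)
    if waveform_steps is not None:
        wf = scale_waveform(P_eff, x.Pdias, x.HR, n_steps=waveform_steps)
        P_peak = wf.peak
    else:
        P_peak = P_eff

    if geom.diastolic_diameter is not None:
        R0 = calibrate_unloaded_radius(
            x.ogden, x.s, x.Pdias, geom.diastolic_diameter, geom.lambda_z, lam_max
        )
        if R0 is None:
            return SimResult(
                diameter=float("nan"), stress=float("nan"), converged=False,
                residual=float("inf"),
            )
    else:
        R0 = geom.R0

    sol = inflate_membrane(x.ogden, R0, x.s, P_peak, geom.lambda_z, lam_max, tol)
    if not sol.converged:
        return sol
    return replace(sol, diameter=_reported_diameter(sol, geom, x.s))


def simulate_plan(
    plan: pd.DataFrame,
    geom: VesselGeometry,
    coeffs: ToyCoefficients = ToyCoefficients(),
    drop_failed: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`simulate_patient` over every row of an input table.

    Returns the CSV interchange table (input columns + diameter + stress +
    converged).  Failed rows are dropped by default, mirroring how failed FE
    runs are excluded from surrogate training.
    """
    missing = [c for c in INPUT_COLUMNS if c not in plan.columns]
    if missing:
        raise ValueError(f"plan is missing input columns {missing}")
    records = []
    for _, row in plan[INPUT_COLUMNS].iterrows():
        rec = dict(row)
        try:
            x = ModelInputs.from_array(row.to_numpy())
            sol = simulate_patient(geom, x, coeffs, **kwargs)
            rec.update(diameter=sol.diameter, stress=sol.stress, converged=sol.converged)
        except ValueError:
            # physically inconsistent sampled combination (e.g. Pdias >=
            # Psys, possible under the overlapping published pressure
            # bounds): flagged failed run, mirroring failed FE simulations
            rec.update(diameter=float("nan"), stress=float("nan"), converged=False)
        records.append(rec)
    out = pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)
    if drop_failed:
        out = out[out["converged"]].reset_index(drop=True)
    return out


def laplace_stress(
    P_mmHg: float,
    r: float,
    t: float,
    mode: Literal["paper_formula", "cylinder_hoop"] = "cylinder_hoop",
) -> float:
    """Thin-wall analytic stress benchmark (kPa).

    ``cylinder_hoop`` is P*r/t, the closed-cylinder circumferential stress
    matching the implemented membrane geometry; ``paper_formula`` is the
    spherical-cap style P*r/(2t).  P in mmHg, r and t in mm.
    """
    if P_mmHg < 0:
        raise ValueError("pressure must be non-negative")
    if r <= 0 or t <= 0:
        raise ValueError("r and t must be positive")
    P_kpa = P_mmHg * MMHG_TO_KPA
    if mode == "paper_formula":
        return P_kpa * r / (2.0 * t)
    if mode == "cylinder_hoop":
        return P_kpa * r / t
    raise ValueError(f"unknown mode {mode!r}")
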