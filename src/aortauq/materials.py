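"""Second-order Ogden hyperelasticity for aneurysmal aortic tissue.

The wall is modelled as an incompressible isotropic Ogden solid with two
terms,

    W(l1, l2, l3) = sum_i (2 mu_i / alpha_i**2) (l1**a_i + l2**a_i + l3**a_i - 3),

the convention used by the major commercial FE solvers, so fitted (mu_i,
alpha_i) pairs are directly interpretable as solver inputs.  Incompressibility
(l1*l2*l3 = 1) is enforced exactly; principal Cauchy stress differences are

    sigma_j - sigma_k = sum_i (2 mu_i / alpha_i) (l_j**a_i - l_k**a_i).

The ground-state shear modulus is mu0 = mu1 + mu2.  Fitted parameter sets are
screened with a validity predicate before use: negative mu0 means negative
initial stiffness and an unstable membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "OgdenParams",
    "StressStrainCurve",
    "MaterialValidity",
    "ogden_stress",
    "strain_energy",
    "is_valid_material",
    "OgdenModel",
    "OgdenFitResults",
    "fit_ogden",
]

Protocol = Literal["equibiaxial", "uniaxial"]
ValidityMode = Literal["ground_state", "strict_hill"]

# Smallest |alpha| tolerated inside stress formulas (the 2 mu/alpha terms are
# singular at alpha = 0).
_ALPHA_FLOOR = 1e-8


@dataclass(frozen=True)
class OgdenParams:
    """Two-term Ogden parameter set (mu in MPa, alpha dimensionless)."""

    mu1: float
    alpha1: float
    mu2: float
    alpha2: float

    def __post_init__(self) -> None:
        vals = (self.mu1, self.alpha1, self.mu2, self.alpha2)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"Ogden parameters must be finite, got {vals}")
        if abs(self.alpha1) < _ALPHA_FLOOR or abs(self.alpha2) < _ALPHA_FLOOR:
            raise ValueError("alpha1 and alpha2 must be nonzero")

    @property
    def mu0(self) -> float:
        """Ground-state shear modulus mu1 + mu2 (MPa)."""
        return self.mu1 + self.mu2

    def as_array(self) -> np.ndarray:
        return np.array([self.mu1, self.alpha1, self.mu2, self.alpha2])


@dataclass(frozen=True)
class StressStrainCurve:
    """One loading protocol's stress–stretch record.

    ``stretches`` are principal stretches (>= 1, strictly increasing) and
    ``stresses`` the corresponding Cauchy stresses in MPa.
    """

    stretches: np.ndarray
    stresses: np.ndarray
    protocol: Protocol = "equibiaxial"

    def __post_init__(self) -> None:
        lam = np.asarray(self.stretches, dtype=float)
        sig = np.asarray(self.stresses, dtype=float)
        if lam.shape != sig.shape or lam.ndim != 1:
            raise ValueError("stretches and stresses must be 1-D and equal length")
        if lam.size and lam[0] < 1.0 - 1e-12:
            raise ValueError("first stretch must be >= 1")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("stretches must be strictly increasing")
        if not np.all(np.isfinite(sig)):
            raise ValueError("stresses must be finite")
        object.__setattr__(self, "stretches", lam)
        object.__setattr__(self, "stresses", sig)
        if self.protocol not in ("equibiaxial", "uniaxial"):
            raise ValueError(f"unknown protocol {self.protocol!r}")

    def __len__(self) -> int:
        return self.stretches.size


def _terms(params: OgdenParams):
    return ((params.mu1, params.alpha1), (params.mu2, params.alpha2))


def ogden_stress(params: OgdenParams, stretch, protocol: Protocol = "equibiaxial"):
    """Cauchy stress (MPa) at principal stretch ``stretch``.

    Equibiaxial: l1 = l2 = lam, l3 = lam**-2 and a traction-free thickness
    direction give sigma = sum_i (2 mu_i/a_i)(lam**a_i - lam**(-2 a_i)).
    Uniaxial: l1 = lam, l2 = l3 = lam**-1/2 give
    sigma = sum_i (2 mu_i/a_i)(lam**a_i - lam**(-a_i/2)).
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    if protocol == "equibiaxial":
        lateral_exp = -2.0
    elif protocol == "uniaxial":
        lateral_exp = -0.5
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    out = np.zeros_like(lam, dtype=float)
    for mu, a in _terms(params):
        if mu != 0.0:
            out = out + (2.0 * mu / a) * (lam**a - lam ** (lateral_exp * a))
    return out if out.ndim else float(out)


def strain_energy(params: OgdenParams, l1, l2, l3):
    """Strain-energy density W (MPa) at principal stretches (l1, l2, l3)."""
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    w = np.zeros(np.broadcast(l1, l2, l3).shape, dtype=float)
    for mu, a in _terms(params):
        w = w + (2.0 * mu / a**2) * (l1**a + l2**a + l3**a - 3.0)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class MaterialValidity:
    valid: bool
    violated: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.valid


def is_valid_material(params: OgdenParams, mode: ValidityMode = "ground_state") -> MaterialValidity:
    """Validity screen for fitted Ogden parameters.

    ``ground_state``: mu1 + mu2 > 0 (positive initial shear stiffness).  The
    nominal aneurysmal parameter set passes this but fails the per-term
    condition, so this is the default.
    ``strict_hill``: additionally requires mu1*alpha1 > 0 and mu2*alpha2 > 0
    (per-term monotone stability).
    """
    violated: list[str] = []
    if not params.mu0 > 0:
        violated.append("mu1 + mu2 > 0")
    if mode == "strict_hill":
        if not params.mu1 * params.alpha1 > 0:
            violated.append("mu1*alpha1 > 0")
        if not params.mu2 * params.alpha2 > 0:
            violated.append("mu2*alpha2 > 0")
    elif mode != "ground_state":
        raise ValueError(f"unknown validity mode {mode!r}")
    return MaterialValidity(valid=not violated, violated=tuple(violated))


# ---------------------------------------------------------------------------
# Biaxial-curve fitting
# ---------------------------------------------------------------------------


@dataclass
class OgdenFitResults:
    """Result of :meth:`OgdenModel.fit`."""

    params: OgdenParams
    rmse: float
    residuals: np.ndarray
    converged: bool
    n_points: int
    n_starts: int
    validity: MaterialValidity
    cost_trace: tuple[float, ...] = field(default_factory=tuple)

    def predict(self, curve: StressStrainCurve) -> np.ndarray:
        return ogden_stress(self.params, curve.stretches, curve.protocol)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Ogden (2nd order) fit",
            "=" * 42,
            f"  mu1    {p.mu1: .6g} MPa",
            f"  alpha1 {p.alpha1: .6g}",
            f"  mu2    {p.mu2: .6g} MPa",
            f"  alpha2 {p.alpha2: .6g}",
            f"  mu0    {p.mu0: .6g} MPa (ground-state shear modulus)",
            f"  RMSE   {self.rmse:.3e} MPa over {self.n_points} points",
            f"  converged: {self.converged}   valid: {self.validity.valid}",
        ]
        if self.validity.violated:
            lines.append("  violated: " + ", ".join(self.validity.violated))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {
                "mu1": self.params.mu1,
                "alpha1": self.params.alpha1,
                "mu2": self.params.mu2,
                "alpha2": self.params.alpha2,
                "mu0": self.params.mu0,
            },
            "rmse_mpa": self.rmse,
            "n_points": self.n_points,
            "converged": self.converged,
            "valid": self.validity.valid,
            "violated": list(self.validity.violated),
        }


class OgdenModel:
    """Nonlinear least-squares fit of the two-term Ogden model to
    stress–stretch curves.

    Circumferential and longitudinal records are fitted jointly (isotropy
    assumption); each curve contributes its own protocol kinematics.  Fitting
    uses trust-region least squares with a seeded multi-start around the
    initial guess and box bounds on the parameters.
    """

    #: default parameter box (mu1, alpha1, mu2, alpha2); spans the epistemic
    #: ranges reported for aneurysmal tissue with margin.
    DEFAULT_BOUNDS = (
        np.array([-50.0, -120.0, -50.0, -120.0]),
        np.array([50.0, 120.0, 50.0, 120.0]),
    )

    def __init__(self, curves: StressStrainCurve | Iterable[StressStrainCurve]):
        if isinstance(curves, StressStrainCurve):
            curves = [curves]
        self.curves: list[StressStrainCurve] = list(curves)
        if not self.curves:
            raise ValueError("at least one curve required")
        self.n_points = sum(len(c) for c in self.curves)
        if self.n_points < 6:
            raise ValueError(
                f"need >= 6 data points to fit 4 parameters, got {self.n_points}"
            )

    def _residual(self, theta: np.ndarray) -> np.ndarray:
        mu1, a1, mu2, a2 = theta
        a1 = math.copysign(max(abs(a1), _ALPHA_FLOOR), a1 if a1 != 0 else 1.0)
        a2 = math.copysign(max(abs(a2), _ALPHA_FLOOR), a2 if a2 != 0 else 1.0)
        res = []
        for c in self.curves:
            lam = c.stretches
            lat = -2.0 if c.protocol == "equibiaxial" else -0.5
            model = (2.0 * mu1 / a1) * (lam**a1 - lam ** (lat * a1)) + (
                2.0 * mu2 / a2
            ) * (lam**a2 - lam ** (lat * a2))
            res.append(model - c.stresses)
        return np.concatenate(res)

    def fit(
        self,
        init: OgdenParams | Sequence[float] | None = None,
        mode: ValidityMode = "ground_state",
        n_starts: int = 10,
        seed: int = 0,
        bounds: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> OgdenFitResults:
        """Fit and return the best validity-respecting parameter set.

        ``init`` seeds the multi-start cloud; when omitted a generic
        soft-tissue guess is used.  A result is flagged non-converged when no
        start both terminates successfully and satisfies the validity mode.
        """
        if init is None:
            theta0 = np.array([1.0, 8.0, -0.1, 10.0])
        elif isinstance(init, OgdenParams):
            theta0 = init.as_array()
        else:
            theta0 = np.asarray(init, dtype=float)
        lo, hi = bounds if bounds is not None else self.DEFAULT_BOUNDS
        theta0 = np.clip(theta0, lo, hi)

        rng = np.random.default_rng(seed)
        starts = [theta0]
        for _ in range(max(0, n_starts - 1)):
            jitter = rng.normal(0.0, 0.15, size=4)
            starts.append(np.clip(theta0 * (1.0 + jitter) + 0.01 * jitter, lo, hi))

        best = None
        cost_trace = []
        for th in starts:
            try:
                sol = least_squares(
                    self._residual, th, bounds=(lo, hi), method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            cost_trace.append(float(sol.cost))
            cand = OgdenParams(*_floor_alphas(sol.x))
            if not is_valid_material(cand, mode).valid:
                continue
            if sol.status < 0:
                continue
            # status 0 (iteration cap) is kept as a candidate: with the very
            # tight tolerances above the returned point is typically at the
            # optimum anyway, and a worse candidate never wins on cost.
            if best is None or sol.cost < best[0]:
                best = (sol.cost, cand)

        if best is None:
            # Flagged, not silent: return the raw best start without validity.
            params = OgdenParams(*_floor_alphas(starts[0]))
            res = self._residual(params.as_array())
            return OgdenFitResults(
                params=params,
                rmse=float(np.sqrt(np.mean(res**2))),
                residuals=res,
                converged=False,
                n_points=self.n_points,
                n_starts=len(starts),
                validity=is_valid_material(params, mode),
                cost_trace=tuple(cost_trace),
            )

        params = best[1]
        res = self._residual(params.as_array())
        return OgdenFitResults(
            params=params,
            rmse=float(np.sqrt(np.mean(res**2))),
            residuals=res,
            converged=True,
            n_points=self.n_points,
            n_starts=len(starts),
            validity=is_valid_material(params, mode),
            cost_trace=tuple(cost_trace),
        )


def _floor_alphas(theta: np.ndarray) -> np.ndarray:
    out = np.array(theta, dtype=float)
    for i in (1, 3):
        if abs(out[i]) < _ALPHA_FLOOR:
            out[i] = _ALPHA_FLOOR
    return out


def fit_ogden(
    curves: StressStrainCurve | Iterable[StressStrainCurve],
    init: OgdenParams | Sequence[float] | None = None,
    **kwargs,
) -> OgdenFitResults:
    """Functional wrapper around :class:`OgdenModel`."""
    return OgdenModel(curves).fit(init=init, **kwargs)
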