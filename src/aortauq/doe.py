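"""Design of experiments over the 9-D epistemic input space.

``InputBounds`` is the registry of nominal value, lower bound and upper
bound for each model input (material parameters, wall thickness and
hemodynamics); the bundled reference table is the published epistemic range
for aneurysmal ascending-aorta modelling, with bounds at +/- 2 standard
deviations of the underlying clinical/ex-vivo data.  ``lhs_plan`` draws the
simulation plan by Latin hypercube sampling — 7 samples per variable, hence
9 x 7 = 63 runs by default — and ``filter_plan`` removes rows whose material
parameters fail the validity screen before they reach the simulator.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .materials import OgdenParams, is_valid_material
from .vessel import INPUT_COLUMNS, ModelInputs

__all__ = ["INPUT_NAMES", "InputBounds", "DOEPlan", "lhs_plan", "filter_plan"]

INPUT_NAMES = tuple(INPUT_COLUMNS)

#: reference epistemic ranges: name -> (nominal, LB, UB).
#: mu1/mu2 in MPa, a1/a2 dimensionless, s in mm, HR in bpm, pressures in
#: mmHg, V in m/s.
_REFERENCE = {
    "mu1": (5.0, -0.01, 20.0),
    "a1": (7.3, -29.4, 45.1),
    "mu2": (-0.4, -2.9, 0.10),
    "a2": (18.8, -98.8, 14.6),
    "s": (2.0, 1.2, 2.9),
    "HR": (70.0, 51.0, 100.0),
    "Psys": (120.0, 95.0, 180.0),
    "Pdias": (80.0, 60.0, 101.0),
    "V": (1.3, 0.8, 4.0),
}


@dataclass(frozen=True)
class InputBounds:
    """Nominal/LB/UB per input; defines every sampling range.

    Bounds are canonicalized to [min(LB, UB), max(LB, UB)] on construction;
    a nominal value outside its canonical range raises a warning, not an
    error (the reference table itself contains one such row, a2).
    """

    table: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        missing = [n for n in INPUT_NAMES if n not in self.table]
        extra = [n for n in self.table if n not in INPUT_NAMES]
        if missing or extra:
            raise ValueError(
                f"bounds must cover exactly {list(INPUT_NAMES)}; "
                f"missing {missing}, unexpected {extra}"
            )
        canon: dict[str, tuple[float, float, float]] = {}
        for name in INPUT_NAMES:
            nominal, lb, ub = (float(v) for v in self.table[name])
            lo, hi = min(lb, ub), max(lb, ub)
            if lo == hi:
                raise ValueError(f"input {name!r} has zero-width bounds [{lo}, {hi}]")
            if not lo <= nominal <= hi:
                warnings.warn(
                    f"nominal value of {name!r} ({nominal}) lies outside its "
                    f"bounds [{lo}, {hi}]; bounds kept as printed",
                    stacklevel=2,
                )
            canon[name] = (nominal, lo, hi)
        object.__setattr__(self, "table", canon)

    @classmethod
    def reference(cls) -> "InputBounds":
        """The bundled reference epistemic ranges."""
        return cls(dict(_REFERENCE))

    # -- array views -------------------------------------------------------
    @property
    def lb(self) -> np.ndarray:
        return np.array([self.table[n][1] for n in INPUT_NAMES])

    @property
    def ub(self) -> np.ndarray:
        return np.array([self.table[n][2] for n in INPUT_NAMES])

    @property
    def nominal(self) -> np.ndarray:
        return np.array([self.table[n][0] for n in INPUT_NAMES])

    def nominal_inputs(self) -> ModelInputs:
        return ModelInputs.from_array(self.nominal)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.table[n] for n in INPUT_NAMES],
            index=list(INPUT_NAMES),
            columns=["nominal", "lb", "ub"],
        )

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {n: {"nominal": v[0], "lb": v[1], "ub": v[2]} for n, v in self.table.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InputBounds":
        raw = yaml.safe_load(Path(path).read_text())
        return cls._from_mapping(raw)

    @classmethod
    def from_json(cls, path: str | Path) -> "InputBounds":
        return cls._from_mapping(json.loads(Path(path).read_text()))

    @classmethod
    def _from_mapping(cls, raw: dict) -> "InputBounds":
        table = {}
        for name, v in raw.items():
            if isinstance(v, dict):
                table[name] = (v["nominal"], v["lb"], v["ub"])
            else:
                table[name] = tuple(v)
        return cls(table)


@dataclass
class DOEPlan:
    """A simulation plan: one row of model inputs per run, plus provenance."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self):
        for _, row in self.frame.iterrows():
            yield ModelInputs.from_array(row[list(INPUT_NAMES)].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: dict | None = None) -> "DOEPlan":
        return cls(pd.read_csv(path), provenance or {"method": "external"})


def lhs_plan(
    bounds: InputBounds,
    samples_per_variable: int = 7,
    seed: int | None = None,
    optimization: str | None = None,
) -> DOEPlan:
    """Latin hypercube plan with n = 9 * samples_per_variable rows.

    Per column, exactly one point falls in each of the n equal-width strata
    of [LB, UB].  ``optimization`` is passed to scipy's sampler (e.g.
    ``"random-cd"`` for a discrepancy-optimized plan); the default is plain
    random pairing.
    """
    if samples_per_variable < 1:
        raise ValueError("samples_per_variable must be >= 1")
    d = len(INPUT_NAMES)
    n = d * samples_per_variable
    sampler = qmc.LatinHypercube(d=d, seed=seed, optimization=optimization)
    unit = sampler.random(n)
    scaled = qmc.scale(unit, bounds.lb, bounds.ub)
    frame = pd.DataFrame(scaled, columns=list(INPUT_NAMES))
    return DOEPlan(
        frame=frame,
        provenance={
            "method": "lhs" if optimization is None else f"lhs-{optimization}",
            "seed": seed,
            "samples_per_variable": samples_per_variable,
            "n_requested": n,
            "n_valid": n,
        },
    )


def filter_plan(plan: DOEPlan, mode: str = "ground_state") -> tuple[DOEPlan, list[dict]]:
    """Drop plan rows whose material parameters fail the validity screen.

    Returns the surviving plan (row order preserved) and a log of dropped
    rows with the violated conditions.  Raises when nothing survives.
    """
    if len(plan) == 0:
        raise ValueError("plan is empty")
    keep = []
    dropped: list[dict] = []
    for idx, row in plan.frame.iterrows():
        params = OgdenParams(row["mu1"], row["a1"], row["mu2"], row["a2"])
        verdict = is_valid_material(params, mode)
        if verdict.valid:
            keep.append(idx)
        else:
            dropped.append({"index": int(idx), "violated": list(verdict.violated)})
    if not keep:
        raise ValueError(
            "all plan rows removed by the material validity screen; "
            "consider mode='ground_state' or wider bounds"
        )
    out = DOEPlan(
        frame=plan.frame.loc[keep].reset_index(drop=True),
        provenance={**plan.provenance, "n_valid": len(keep), "validity_mode": mode},
    )
    return out, dropped
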