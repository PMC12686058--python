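"""End-to-end credibility pipeline: DOE -> simulate -> surrogate -> UQ ->
validation -> verification -> report.

`CredibilityStudy` is the top-level model object: constructed from a
configuration plus either synthetic patients or an externally produced
simulation table, its :meth:`~CredibilityStudy.fit` runs every stage and
returns a :class:`CredibilityReport` carrying, per patient, the surrogate
LOO metrics for the diameter and stress outputs, the total-effect
sensitivity tables with association signs, the CDF area-metric validation
against the comparator, the wall-stress density summary and the
verification cases.  Everything is deterministic under the configured
seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    DEFAULT_SCANNER_SD,
    ComparatorMeasurement,
    SyntheticPatient,
    make_cohort,
    measure_comparator,
)
from .doe import INPUT_NAMES, DOEPlan, InputBounds, filter_plan, lhs_plan
from .surrogate import GPSurrogate
from .uq import (
    area_metric,
    association_signs,
    density_mode,
    prob_leq,
    sobol_sample,
    total_effect_indices,
)
from .verification import code_verification, convergence_study
from .vessel import RESULT_COLUMNS, ToyCoefficients, VesselGeometry, simulate_plan

__all__ = [
    "PipelineConfig",
    "CredibilityStudy",
    "CredibilityReport",
    "circumcircle_diameter",
    "write_report",
]


def circumcircle_diameter(p1, p2, p3) -> float:
    """Diameter of the circle through three 3-D points (mm).

    This is how the loaded aneurysm diameter is extracted from a simulated
    wall: three points at the mid-height define a circumference, whose
    diameter is D = a*b*c / (2 * triangle area).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = float(np.linalg.norm(p2 - p3))
    b = float(np.linalg.norm(p1 - p3))
    c = float(np.linalg.norm(p1 - p2))
    cross = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * float(np.linalg.norm(cross))
    scale = max(a, b, c)
    if scale == 0.0 or area < 1e-12 * scale**2:
        raise ValueError("points are collinear (or coincident); no unique circle")
    return a * b * c / (2.0 * area)


@dataclass
class PipelineConfig:
    """All knobs of one credibility run; every seed is explicit."""

    bounds: InputBounds = field(default_factory=InputBounds.reference)
    n_patients: int = 1
    samples_per_variable: int = 7
    qmc_n: int = 10_000
    sensitivity_base_n: int = 1024
    area_threshold_percent: float = 5.0
    comparator_sd: float = DEFAULT_SCANNER_SD
    validity_mode: str = "ground_state"
    coeffs: ToyCoefficients = field(default_factory=ToyCoefficients)
    diastolic_diameter_range: tuple[float, float] = (42.0, 55.0)
    gp_n_starts: int = 5
    seeds: dict = field(
        default_factory=lambda: {
            "cohort": 10,
            "lhs": 20,
            "gp": 30,
            "qmc": 40,
            "sensitivity": 50,
            "comparator": 60,
        }
    )

    def __post_init__(self) -> None:
        if self.area_threshold_percent <= 0:
            raise ValueError("area threshold must be positive")
        required = {"cohort", "lhs", "gp", "qmc", "sensitivity", "comparator"}
        missing = required - set(self.seeds)
        if missing:
            raise ValueError(f"seeds missing for {sorted(missing)}")

    def to_dict(self) -> dict:
        return {
            "bounds": {n: list(v) for n, v in self.bounds.table.items()},
            "n_patients": self.n_patients,
            "samples_per_variable": self.samples_per_variable,
            "qmc_n": self.qmc_n,
            "sensitivity_base_n": self.sensitivity_base_n,
            "area_threshold_percent": self.area_threshold_percent,
            "comparator_sd": self.comparator_sd,
            "validity_mode": self.validity_mode,
            "coeffs": asdict(self.coeffs),
            "diastolic_diameter_range": list(self.diastolic_diameter_range),
            "gp_n_starts": self.gp_n_starts,
            "seeds": dict(self.seeds),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "bounds" in kwargs:
            kwargs["bounds"] = InputBounds._from_mapping(kwargs["bounds"])
        if "coeffs" in kwargs:
            kwargs["coeffs"] = ToyCoefficients(**kwargs["coeffs"])
        if "diastolic_diameter_range" in kwargs:
            kwargs["diastolic_diameter_range"] = tuple(kwargs["diastolic_diameter_range"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PatientReport:
    patient_id: str
    comparator: dict
    n_plan: int
    n_valid: int
    n_converged: int
    loo_diameter: dict
    loo_stress: dict
    sensitivity_diameter: dict
    sensitivity_stress: dict
    validation: dict
    stress_uq: dict
    prob_leq_comparator_mean: float
    diameter_sample_summary: dict
    # raw per-patient artifacts kept for plot-data export (not serialized)
    _tables: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if not k.startswith("_")}
        return d


@dataclass
class CredibilityReport:
    """Source of truth for one pipeline run."""

    config: dict
    config_hash: str
    patients: list[PatientReport]
    verification: dict
    stages_failed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "config_hash": self.config_hash,
            "patients": [p.to_dict() for p in self.patients],
            "verification": self.verification,
            "stages_failed": self.stages_failed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> dict:
        """Reload the serialized report (as plain dict; JSON is the source
        of truth)."""
        return json.loads(Path(path).read_text())

    def summary(self) -> str:
        lines = [
            "Credibility report",
            "==================",
            f"config hash: {self.config_hash}",
            "",
        ]
        for p in self.patients:
            v = p.validation
            verdict = "PASS" if v["passed"] else "FAIL"
            lines += [
                f"Patient {p.patient_id}",
                f"  simulation plan: {p.n_plan} rows, {p.n_valid} material-valid, "
                f"{p.n_converged} converged",
                f"  diameter surrogate LOO: RMSE {p.loo_diameter['loo_rmse']:.3f} mm, "
                f"R^2 {p.loo_diameter['r2']:.3f}, MRE {p.loo_diameter['mre_percent']:.2f}%",
                f"  stress surrogate LOO: RMSE {p.loo_stress['loo_rmse']:.4f} MPa, "
                f"R^2 {p.loo_stress['r2']:.3f}, MRE {p.loo_stress['mre_percent']:.2f}%",
                f"  top diameter driver: {p.sensitivity_diameter['ranking'][0]} "
                f"({p.sensitivity_diameter['tei_percent'][p.sensitivity_diameter['ranking'][0]]:.1f}%)",
                f"  top stress drivers: "
                + ", ".join(p.sensitivity_stress["ranking"][:2]),
                f"  area metric: {v['area_mm']:.3f} mm = {v['area_percent']:.2f}% "
                f"(threshold {v['threshold_percent']:.0f}%) -> {verdict}",
                f"  wall-stress mode: {p.stress_uq['mode']:.3f} MPa "
                f"[95% {p.stress_uq['interval95'][0]:.3f}, {p.stress_uq['interval95'][1]:.3f}]",
                "",
            ]
        if self.verification:
            cv = self.verification.get("code_verification", {})
            if cv:
                lines.append(
                    f"Code verification: numeric {cv['numeric_kpa']:.2f} kPa vs "
                    f"hoop {cv['analytic_hoop_kpa']:.2f} kPa, RE {cv['re_percent']:.3f}% "
                    f"-> {'PASS' if cv['passed'] else 'FAIL'}"
                )
            for case in self.verification.get("convergence", []):
                status = "PASS" if case["passed"] else "not met"
                lines.append(
                    f"Convergence ({case['factor']}): selected level "
                    f"{case['selected_level']} ({status}, criterion "
                    f"{case['criterion_percent']:.0f}%)"
                )
        if self.stages_failed:
            lines.append("")
            for stage, cause in self.stages_failed.items():
                lines.append(f"STAGE FAILED: {stage}: {cause}")
        return "\n".join(lines)


class CredibilityStudy:
    """Credibility-assessment model over a cohort (or external FE results).

    Parameters
    ----------
    config : PipelineConfig
    patients : optional list of SyntheticPatient
        When omitted, ``config.n_patients`` synthetic patients are generated
        under the cohort seed.
    external_results : optional DataFrame
        A pre-computed simulation table (interchange schema) replacing the
        DOE + simulate stages; requires ``external_comparator``.
    external_comparator : optional (mean_mm, sd_mm)
    """

    def __init__(
        self,
        config: PipelineConfig | None = None,
        patients: list[SyntheticPatient] | None = None,
        external_results: pd.DataFrame | None = None,
        external_comparator: tuple[float, float] | None = None,
        verbose: bool = False,
    ):
        self.config = config or PipelineConfig()
        self.patients = patients
        self.external_results = external_results
        self.external_comparator = external_comparator
        self.verbose = verbose
        if external_results is not None:
            missing = [c for c in RESULT_COLUMNS if c not in external_results.columns]
            if missing:
                raise ValueError(f"external results missing columns {missing}")
            if external_comparator is None:
                raise ValueError("external results require external_comparator=(mean, sd)")

    def _log(self, stage: str, t0: float, **info) -> None:
        if self.verbose:
            kv = " ".join(f"{k}={v}" for k, v in info.items())
            print(f"[{stage}] elapsed={time.perf_counter() - t0:.2f}s {kv}")

    # -- per-patient stages -------------------------------------------------
    def _training_table(self, patient: SyntheticPatient | None, seed_offset: int):
        cfg = self.config
        if self.external_results is not None:
            table = self.external_results[self.external_results["converged"]]
            return table.reset_index(drop=True), len(table), len(table)
        plan = lhs_plan(
            cfg.bounds, cfg.samples_per_variable, seed=cfg.seeds["lhs"] + seed_offset
        )
        filtered, _dropped = filter_plan(plan, cfg.validity_mode)
        table = simulate_plan(filtered.frame, patient.geom, cfg.coeffs)
        return table, len(plan), len(filtered)

    def _run_patient(self, patient: SyntheticPatient | None, idx: int) -> PatientReport:
        cfg = self.config
        t0 = time.perf_counter()
        table, n_plan, n_valid = self._training_table(patient, idx)
        self._log("simulate", t0, n=len(table))
        if len(table) < 10:
            raise RuntimeError(
                f"only {len(table)} converged simulations; cannot train surrogate"
            )

        X = table[list(INPUT_NAMES)]
        sur_d = GPSurrogate(X, table["diameter"], "diameter").fit(
            seed=cfg.seeds["gp"] + idx, n_starts=cfg.gp_n_starts
        )
        sur_s = GPSurrogate(X, table["stress"], "stress").fit(
            seed=cfg.seeds["gp"] + idx, n_starts=cfg.gp_n_starts
        )
        loo_d, _ = sur_d.loo()
        loo_s, _ = sur_s.loo()
        self._log("surrogate", t0, loo_rmse_d=f"{loo_d.loo_rmse:.4f}")

        # quasi-Monte Carlo propagation
        qmc_X = sobol_sample(cfg.bounds, cfg.qmc_n, seed=cfg.seeds["qmc"] + idx)
        diam_sample = sur_d.predict(qmc_X)
        stress_sample = sur_s.predict(qmc_X)

        # sensitivity
        sens_d = total_effect_indices(
            lambda A: sur_d.predict(A), cfg.bounds,
            base_n=cfg.sensitivity_base_n, seed=cfg.seeds["sensitivity"] + idx,
        )
        sens_d.signs = association_signs(qmc_X, diam_sample)
        sens_s = total_effect_indices(
            lambda A: sur_s.predict(A), cfg.bounds,
            base_n=cfg.sensitivity_base_n, seed=cfg.seeds["sensitivity"] + idx,
        )
        sens_s.signs = association_signs(qmc_X, stress_sample)
        self._log("sensitivity", t0, top=sens_d.ranking[0])

        # comparator + validation
        if self.external_comparator is not None:
            comp_mean, comp_sd = self.external_comparator
            comparator = {"mean_mm": comp_mean, "sd_mm": comp_sd, "replicates": None}
        else:
            meas = measure_comparator(
                patient, sd=cfg.comparator_sd, seed=cfg.seeds["comparator"] + idx
            )
            comp_mean, comp_sd = meas.mean, meas.sd_assumed
            comparator = {
                "mean_mm": meas.mean,
                "sd_mm": meas.sd_assumed,
                "replicates": list(meas.replicates),
            }
        validation = area_metric(
            diam_sample, comp_mean, comp_sd, threshold=cfg.area_threshold_percent
        )
        stress_uq = density_mode(stress_sample)
        self._log("validation", t0, area_pct=f"{validation.area_percent:.2f}")

        pid = patient.id if patient is not None else "EXTERNAL"
        return PatientReport(
            patient_id=pid,
            comparator=comparator,
            n_plan=n_plan,
            n_valid=n_valid,
            n_converged=len(table),
            loo_diameter=loo_d.to_dict(),
            loo_stress=loo_s.to_dict(),
            sensitivity_diameter=sens_d.to_dict(),
            sensitivity_stress=sens_s.to_dict(),
            validation=validation.to_dict(),
            stress_uq=stress_uq.to_dict(),
            prob_leq_comparator_mean=prob_leq(diam_sample, comp_mean),
            diameter_sample_summary={
                "mean": float(np.mean(diam_sample)),
                "sd": float(np.std(diam_sample)),
                "min": float(np.min(diam_sample)),
                "max": float(np.max(diam_sample)),
            },
            _tables={
                "training": table,
                "diameter_sample": np.asarray(diam_sample),
                "stress_sample": np.asarray(stress_sample),
                "sens_diameter": sens_d.as_frame(),
                "sens_stress": sens_s.as_frame(),
            },
        )

    def _run_verification(self, patient: SyntheticPatient | None) -> dict:
        cfg = self.config
        if patient is None:
            geom = VesselGeometry(diastolic_diameter=float(np.mean(cfg.diastolic_diameter_range)))
            inputs = cfg.bounds.nominal_inputs()
        else:
            geom = patient.geom
            inputs = patient.true_inputs
        cases = [
            convergence_study("waveform_steps", [16, 64, 256], geom, inputs, cfg.coeffs),
            convergence_study("solver_tol", [1e-4, 1e-6, 1e-8], geom, inputs, cfg.coeffs),
        ]
        cv = code_verification()
        return {
            "convergence": [c.to_dict() for c in cases],
            "code_verification": cv.to_dict(),
            "coefficients": asdict(cfg.coeffs),
        }

    # -- orchestration ------------------------------------------------------
    def fit(self) -> CredibilityReport:
        cfg = self.config
        stages_failed: dict[str, str] = {}
        if self.external_results is not None:
            cohort: list[SyntheticPatient | None] = [None]
        elif self.patients is not None:
            cohort = list(self.patients)
        else:
            cohort = make_cohort(
                cfg.n_patients,
                cfg.bounds,
                cfg.diastolic_diameter_range,
                seed=cfg.seeds["cohort"],
                coeffs=cfg.coeffs,
            )

        reports: list[PatientReport] = []
        for i, patient in enumerate(cohort):
            try:
                reports.append(self._run_patient(patient, i))
            except Exception as exc:  # stage isolation: report, do not hide
                pid = patient.id if patient is not None else "EXTERNAL"
                stages_failed[f"patient:{pid}"] = str(exc)

        try:
            verification = self._run_verification(
                cohort[0] if cohort and cohort[0] is not None else None
            )
        except Exception as exc:
            verification = {}
            stages_failed["verification"] = str(exc)

        report = CredibilityReport(
            config=cfg.to_dict(),
            config_hash=cfg.config_hash(),
            patients=reports,
            verification=verification,
            stages_failed=stages_failed,
        )
        if stages_failed:
            # keep the report, but make failures visible to callers
            report.stages_failed = stages_failed
        return report


def write_report(report: CredibilityReport, out_dir: str | Path) -> dict[str, Path]:
    """Persist the report: JSON source of truth, CSV tables for each
    patient (training data, sensitivity Pareto data, CDF plot data) and a
    markdown summary.  Returns the mapping of artifact name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    json_path = out / "report.json"
    report.to_json(json_path)
    paths["report"] = json_path

    for p in report.patients:
        tag = p.patient_id.lower().replace(" ", "_")
        tables = p._tables
        if tables:
            tr = out / f"{tag}_training.csv"
            tables["training"].to_csv(tr, index=False)
            paths[f"{tag}_training"] = tr
            for key in ("sens_diameter", "sens_stress"):
                sp = out / f"{tag}_{key}.csv"
                tables[key].to_csv(sp, index=False)
                paths[f"{tag}_{key}"] = sp
            # CDF plot data: sorted model sample with empirical CDF levels
            diam = np.sort(tables["diameter_sample"])
            cdf = pd.DataFrame(
                {
                    "diameter_mm": diam,
                    "model_cdf": np.arange(1, diam.size + 1) / diam.size,
                }
            )
            cp = out / f"{tag}_cdf.csv"
            cdf.to_csv(cp, index=False)
            paths[f"{tag}_cdf"] = cp

    md = out / "summary.md"
    md.write_text(_markdown_summary(report))
    paths["summary"] = md
    return paths


def _markdown_summary(report: CredibilityReport) -> str:
    lines = ["# Credibility summary", "", f"Config hash: `{report.config_hash}`", ""]
    for p in report.patients:
        v = p.validation
        verdict = "**PASS**" if v["passed"] else "**FAIL**"
        lines += [
            f"## Patient {p.patient_id}",
            "",
            f"- Area metric: {v['area_mm']:.3f} mm ({v['area_percent']:.2f}% of "
            f"comparator mean) vs threshold {v['threshold_percent']:.0f}% -> {verdict}",
            f"- Diameter surrogate LOO RMSE {p.loo_diameter['loo_rmse']:.3f} mm, "
            f"R^2 {p.loo_diameter['r2']:.3f}, MRE {p.loo_diameter['mre_percent']:.2f}%",
            f"- Stress surrogate LOO RMSE {p.loo_stress['loo_rmse']:.4f} MPa, "
            f"R^2 {p.loo_stress['r2']:.3f}, MRE {p.loo_stress['mre_percent']:.2f}%",
            f"- Most influential input (diameter): {p.sensitivity_diameter['ranking'][0]}",
            f"- Wall-stress mode: {p.stress_uq['mode']:.3f} MPa",
            "",
        ]
    if report.verification:
        cv = report.verification.get("code_verification")
        lines.append("## Verification")
        lines.append("")
        if cv:
            lines.append(
                f"- Code verification RE {cv['re_percent']:.3f}% "
                f"({'PASS' if cv['passed'] else 'FAIL'}, criterion 1%)"
            )
        for case in report.verification.get("convergence", []):
            lines.append(
                f"- {case['factor']}: selected level {case['selected_level']} "
                f"({'PASS' if case['passed'] else 'not met'})"
            )
    else:
        lines.append("## Verification")
        lines.append("")
        lines.append("- not run")
    if report.stages_failed:
        lines += ["", "## Failed stages", ""]
        for stage, cause in report.stages_failed.items():
            lines.append(f"- {stage}: {cause}")
    lines.append("")
    return "\n".join(lines)
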