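"""End-to-end analysis pipeline and report plumbing.

:func:`run_abfe` composes the building blocks in the standard order —
parse → (optional) decorrelation → every requested estimator →
diagnostics — and returns a machine-readable :class:`Report`.  A single
estimator failing is recorded in the report rather than aborting the
run; only zero parseable inputs or all estimators failing is fatal.
Absolute binding free energies are then differences of per-leg results
(:func:`combine_legs`), e.g. the solvation leg in water minus the
solvation leg in the binding site.

Reports serialize to a versioned JSON document (``alchest-report/1``,
schema in ``docs/report-schema.json``); floats are written with
shortest-round-trip precision so re-loading is value-exact.
"""

from __future__ import annotations

import glob as globmod
import json
import logging
import math
import time as timemod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .datamodel import GradientTable, concat_tables
from .diagnostics import (
    ConvergenceSeries,
    EquilibrationSummary,
    OverlapMatrix,
    forward_backward_convergence,
    fractional_equilibration,
    overlap_matrix,
    ti_curvature_profile,
)
from .estimators import BAR, MBAR, TI, FreeEnergyResult, GaussianQuadratureTI
from .exceptions import WorkflowError
from .parsers import parse_csv, parse_xvg_dhdl, parse_xvg_u_nk
from .preprocessing import decorrelate

logger = logging.getLogger(__name__)

__all__ = ["WorkflowConfig", "Report", "run_abfe", "combine_legs",
           "write_report", "load_report", "validate_report_dict"]

REPORT_SCHEMA = "alchest-report/1"

ALL_ESTIMATORS = ("TI", "TI-GQ", "BAR", "MBAR")

#: preference order when a single endpoint number is requested
_ENDPOINT_PREFERENCE = ("MBAR", "BAR", "TI", "TI-GQ")


@dataclass(frozen=True)
class WorkflowConfig:
    """Configuration of the end-to-end pipeline."""

    inputs: tuple[str, ...]
    format: str = "csv"
    estimators: tuple[str, ...] = ("TI", "BAR", "MBAR")
    temperature_override: Optional[float] = None
    decorrelate: bool = True
    series_policy: Optional[str] = None
    n_fractions: int = 10
    equilibration_threshold: float = 0.3
    gauss_points: Optional[int] = None
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "estimators", tuple(self.estimators))
        if self.format not in ("csv", "xvg"):
            raise ValueError(f"unknown input format {self.format!r}")
        if not self.estimators:
            raise ValueError("at least one estimator is required")
        for name in self.estimators:
            if name not in ALL_ESTIMATORS:
                raise ValueError(
                    f"unknown estimator {name!r}; expected subset of "
                    f"{ALL_ESTIMATORS}"
                )
        if not self.inputs:
            raise ValueError("at least one input path or glob is required")


@dataclass
class Report:
    """Structured outcome of one workflow run."""

    config: dict
    results: dict[str, FreeEnergyResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    decorrelation: dict = field(default_factory=dict)
    overlap: Optional[OverlapMatrix] = None
    convergence: Optional[ConvergenceSeries] = None
    equilibration: dict[str, EquilibrationSummary] = field(default_factory=dict)
    ti_curvature: Optional[dict] = None
    provenance: dict = field(default_factory=dict)

    def endpoint(self, estimator: Optional[str] = None) -> tuple[float, float]:
        """Endpoint Δf ± error, from *estimator* or the preferred one."""
        if estimator is None:
            for name in _ENDPOINT_PREFERENCE:
                if name in self.results:
                    estimator = name
                    break
            else:
                raise WorkflowError("report holds no successful estimate")
        if estimator not in self.results:
            raise WorkflowError(f"no result for estimator {estimator!r}")
        return self.results[estimator].endpoint()

    @property
    def energy_unit(self) -> str:
        for result in self.results.values():
            return result.metadata.energy_unit
        raise WorkflowError("report holds no successful estimate")

    def to_dict(self) -> dict:
        doc: dict = {"schema": REPORT_SCHEMA, "config": self.config}
        estimators = {}
        for name, result in self.results.items():
            value, error = result.endpoint()
            estimators[name] = {
                "states": [
                    {"names": list(s.names), "values": list(s.values)}
                    for s in result.states
                ],
                "delta_f": result.delta_f.tolist(),
                "d_delta_f": result.d_delta_f.tolist(),
                "endpoint_delta_f": value,
                "endpoint_error": error,
                "units": result.metadata.energy_unit,
                "temperature": result.metadata.temperature,
            }
        doc["estimators"] = estimators
        if self.failures:
            doc["failures"] = dict(self.failures)
        if self.decorrelation:
            doc["decorrelation"] = {
                kind: [
                    {
                        "window": list(lam.values),
                        "t0": rep.t0,
                        "g": rep.g,
                        "n_effective": rep.n_effective,
                        "n_kept": rep.n_kept,
                    }
                    for lam, rep in reports.items()
                ]
                for kind, reports in self.decorrelation.items()
            }
        if self.overlap is not None:
            doc["overlap"] = {
                "states": [list(s.values) for s in self.overlap.states],
                "matrix": self.overlap.O.tolist(),
            }
        if self.convergence is not None:
            doc["convergence"] = {
                "fractions": list(self.convergence.fractions),
                "forward_df": list(self.convergence.forward_df),
                "forward_err": list(self.convergence.forward_err),
                "backward_df": list(self.convergence.backward_df),
                "backward_err": list(self.convergence.backward_err),
            }
        if self.equilibration:
            doc["equilibration"] = {
                kind: {
                    "threshold": summary.threshold,
                    "windows": [
                        {
                            "window": list(w.state.values),
                            "fraction_equilibration": w.fraction_equilibration,
                            "flagged": w.flagged,
                            "error": w.error,
                        }
                        for w in summary.windows
                    ],
                }
                for kind, summary in self.equilibration.items()
            }
        if self.ti_curvature is not None:
            doc["ti_curvature"] = {
                "second_differences": [
                    float(v) for v in self.ti_curvature["second_differences"]
                ],
                "mean_curvature": self.ti_curvature["mean_curvature"],
            }
        doc["provenance"] = self.provenance
        return doc


def _expand_inputs(config: WorkflowConfig) -> list[str]:
    files: list[str] = []
    for pattern in config.inputs:
        p = Path(pattern)
        if p.exists():
            files.append(str(p))
        else:
            files.extend(sorted(globmod.glob(pattern)))
    # de-duplicate preserving order
    seen: set[str] = set()
    out = []
    for f in files:
        if f not in seen:
            seen.add(f)
            out.append(f)
    return out


def _parse_inputs(config: WorkflowConfig, files: Sequence[str]):
    dhdl_tables, unk_tables = [], []
    for path in files:
        if config.format == "csv":
            table = parse_csv(path)
            if isinstance(table, GradientTable):
                dhdl_tables.append(table)
            else:
                unk_tables.append(table)
        else:
            parsed_any = False
            try:
                dhdl_tables.append(
                    parse_xvg_dhdl(path, config.temperature_override)
                )
                parsed_any = True
            except Exception as exc:  # file may hold only u_nk columns
                logger.debug("no dH/dl data in %s: %s", path, exc)
            try:
                unk_tables.append(
                    parse_xvg_u_nk(path, config.temperature_override)
                )
                parsed_any = True
            except Exception as exc:
                logger.debug("no u_nk data in %s: %s", path, exc)
            if not parsed_any:
                raise WorkflowError(f"{path}: neither dH/dl nor u_nk parseable")
    dhdl = concat_tables(dhdl_tables) if dhdl_tables else None
    u_nk = concat_tables(unk_tables) if unk_tables else None
    return dhdl, u_nk


def run_abfe(config: WorkflowConfig) -> Report:
    """Execute parse → decorrelate → estimate → diagnose.

    Estimator failures are isolated: each failure is recorded under the
    report's ``failures`` with its message, and the workflow only raises
    if *every* requested estimator failed (or no input parsed).
    """
    t_start = timemod.time()
    files = _expand_inputs(config)
    if not files:
        raise WorkflowError(
            f"no input files matched {list(config.inputs)!r}"
        )
    logger.info("parsing %d input file(s)", len(files))
    dhdl, u_nk = _parse_inputs(config, files)
    if dhdl is None and u_nk is None:
        raise WorkflowError("no parseable free-energy data in the inputs")

    report = Report(config=_config_echo(config))
    report.provenance = {
        "alchest_version": __version__,
        "n_input_files": len(files),
        "started_unix_time": t_start,
    }

    # diagnostics that only need the raw tables
    for kind, table in (("dhdl", dhdl), ("u_nk", u_nk)):
        if table is not None:
            report.equilibration[kind] = fractional_equilibration(
                table, threshold=config.equilibration_threshold,
                series_policy=config.series_policy,
            )

    if config.decorrelate:
        if dhdl is not None:
            dhdl, reports = decorrelate(dhdl, config.series_policy)
            report.decorrelation["dhdl"] = reports
            logger.info("decorrelated dhdl: %s rows kept", len(dhdl))
        if u_nk is not None:
            u_nk, reports = decorrelate(u_nk, config.series_policy)
            report.decorrelation["u_nk"] = reports
            logger.info("decorrelated u_nk: %s rows kept", len(u_nk))

    needs = {"TI": dhdl, "TI-GQ": dhdl, "BAR": u_nk, "MBAR": u_nk}
    fitted: dict[str, object] = {}
    for name in config.estimators:
        table = needs[name]
        if table is None:
            report.failures[name] = (
                "required table kind not present in the inputs"
            )
            continue
        try:
            est = _make_estimator(name, config)
            est.fit(table)
            fitted[name] = est
            report.results[name] = est.result_
            value, error = est.result_.endpoint()
            logger.info("%s: endpoint delta_f = %.6f +/- %.6f kT",
                        name, value, error)
        except Exception as exc:
            logger.warning("%s failed: %s", name, exc)
            report.failures[name] = str(exc)
    if not report.results:
        raise WorkflowError(
            f"all estimators failed: {report.failures}"
        )

    if "MBAR" in fitted:
        report.overlap = overlap_matrix(fitted["MBAR"].weights_)
    if "TI" in fitted:
        try:
            report.ti_curvature = ti_curvature_profile(fitted["TI"])
        except ValueError as exc:
            logger.debug("curvature profile unavailable: %s", exc)
    conv_name = next(
        (n for n in ("MBAR", "BAR", "TI") if n in report.results), None
    )
    if conv_name is not None:
        conv_table = needs[conv_name]
        try:
            report.convergence = forward_backward_convergence(
                conv_table, conv_name, config.n_fractions
            )
        except Exception as exc:
            logger.warning("convergence analysis failed: %s", exc)
    report.provenance["elapsed_seconds"] = timemod.time() - t_start
    return report


def _make_estimator(name: str, config: WorkflowConfig):
    if name == "TI":
        return TI()
    if name == "TI-GQ":
        return GaussianQuadratureTI(n_points=config.gauss_points)
    if name == "BAR":
        return BAR()
    if name == "MBAR":
        return MBAR()
    raise ValueError(name)


def _config_echo(config: WorkflowConfig) -> dict:
    return {
        "inputs": list(config.inputs),
        "format": config.format,
        "estimators": list(config.estimators),
        "temperature_override": config.temperature_override,
        "decorrelate": config.decorrelate,
        "series_policy": config.series_policy,
        "n_fractions": config.n_fractions,
        "equilibration_threshold": config.equilibration_threshold,
        "gauss_points": config.gauss_points,
    }


def combine_legs(
    leg_reports: Sequence[tuple[Report, int]],
    estimator: Optional[str] = None,
) -> tuple[float, float]:
    """Signed sum of per-leg endpoint Δf with quadrature-added errors.

    Legs are independent simulations, so errors add in quadrature.  For
    an absolute binding free energy, pass the water leg with sign +1 and
    the binding-site leg with sign −1 (or vice versa, matching your sign
    convention).
    """
    if not leg_reports:
        raise ValueError("combine_legs needs at least one leg")
    units = {report.energy_unit for report, _ in leg_reports}
    if len(units) != 1:
        raise WorkflowError(f"legs use mixed energy units: {sorted(units)}")
    total = 0.0
    var = 0.0
    for report, sign in leg_reports:
        if sign not in (+1, -1):
            raise ValueError(f"leg sign must be +1 or -1, got {sign}")
        value, error = report.endpoint(estimator)
        total += sign * value
        var += error * error
    return total, math.sqrt(var)


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

def write_report(report: Report, path) -> None:
    """Serialize a report to versioned JSON (``alchest-report/1``)."""
    doc = report.to_dict()
    validate_report_dict(doc)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_report(path) -> dict:
    """Load a report document written by :func:`write_report`."""
    doc = json.loads(Path(path).read_text())
    validate_report_dict(doc)
    return doc


def validate_report_dict(doc: dict) -> None:
    """Structural validation against the ``alchest-report/1`` schema."""
    if not isinstance(doc, dict) or doc.get("schema") != REPORT_SCHEMA:
        raise WorkflowError(
            f"not an {REPORT_SCHEMA} document: schema={doc.get('schema')!r}"
        )
    if "estimators" not in doc or not isinstance(doc["estimators"], dict):
        raise WorkflowError("report must contain an 'estimators' mapping")
    for name, entry in doc["estimators"].items():
        for key in ("states", "delta_f", "d_delta_f", "endpoint_delta_f",
                    "endpoint_error", "units"):
            if key not in entry:
                raise WorkflowError(f"estimator {name!r} missing key {key!r}")
        k = len(entry["states"])
        df = np.asarray(entry["delta_f"], dtype=float)
        if df.shape != (k, k):
            raise WorkflowError(
                f"estimator {name!r}: delta_f shape {df.shape} != ({k}, {k})"
            )
        if abs(entry["endpoint_delta_f"] - df[0, -1]) > 1e-12:
            raise WorkflowError(
                f"estimator {name!r}: endpoint does not equal delta_f[0, -1]"
            )
    if "overlap" in doc:
        o = np.asarray(doc["overlap"]["matrix"], dtype=float)
        if o.ndim != 2 or o.shape[0] != o.shape[1]:
            raise WorkflowError("overlap matrix must be square")
    if "config" not in doc:
        raise WorkflowError("report must echo its config")
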