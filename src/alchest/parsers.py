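"""Readers and writers for raw free-energy data files.

Two on-disk formats are supported:

* **GROMACS-style XVG** (Grace) files holding per-window time series of
  Hamiltonian gradients dH/dλ and/or reduced-potential differences
  ΔH to other λ-states.  Energies are assumed to be in kJ/mol (the
  GROMACS convention, overridable) and are converted to kT on ingestion
  using the temperature found in the subtitle (``T = <x> (K)``) or an
  explicit override.

* The **alchest CSV dialect**, a plain-text portable format with a
  ``#alchest <kind> v1`` header line, ``#meta key=value`` metadata lines
  and ordinary comma-separated numeric rows.  See ``docs/formats.md``
  for the grammar.  :func:`write_csv` emits 17-significant-digit
  decimals so that :func:`parse_csv` is a lossless inverse.

All parsed tables come out in kT regardless of the source unit.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    EnergyMetadata,
    GradientTable,
    LambdaVector,
    ReducedPotentialTable,
    convert_energy,
)
from .exceptions import FormatError, MetadataError, ValidationError

__all__ = ["parse_xvg_dhdl", "parse_xvg_u_nk", "parse_csv", "write_csv"]

# Grace in-string escapes: "\xl\f{}" renders λ, "\xD\f{}" renders Δ, and
# \s…\N / \S…\N switch sub/superscript.  We strip them before matching.
_GRACE_ESCAPE_RE = re.compile(r"\\x[^\\]*\\f\{\}|\\[sSnN]")

#: gradient legends, e.g. "dH/d\xl\f{} fep-lambda = 0.2500" after escape
#: stripping becomes "dH/d fep-lambda = 0.2500"
_DHDL_LEGEND_RE = re.compile(
    r"dH/d\S*\s+(?P<name>[A-Za-z0-9_\-]+)\s*=\s*(?P<value>[-+0-9.eE]+)"
)

#: ΔH legends, e.g. "\xD\f{}H \xl\f{} to 0.0000" or "… to (0.00, 0.50)"
_DELTAH_LEGEND_RE = re.compile(r"\bto\s+(?P<target>\([^)]*\)|[-+0-9.eE]+)\s*$")

_SUBTITLE_T_RE = re.compile(r"\bT\s*=\s*(?P<t>[-+0-9.eE]+)\s*\(K\)")
_SUBTITLE_LAMBDA_RE = re.compile(
    r"(?P<name>[A-Za-z][A-Za-z0-9_\-]*)\s*=\s*(?P<value>[-+]?[0-9.][0-9.eE+-]*)"
)

_FLOAT_FMT = "{:.17g}"


def _fmt(x: float) -> str:
    return _FLOAT_FMT.format(float(x))


# ---------------------------------------------------------------------------
# XVG
# ---------------------------------------------------------------------------

class _Xvg:
    """Parsed skeleton of a Grace XVG document."""

    def __init__(self, path):
        self.path = Path(path)
        self.subtitle = ""
        self.legends: list[str] = []
        self.rows: list[list[float]] = []
        legend_idx: list[int] = []
        with open(self.path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith("@"):
                    self._meta_line(line, legend_idx)
                    continue
                fields = line.split()
                try:
                    values = [float(f) for f in fields]
                except ValueError as exc:
                    raise FormatError(
                        f"{self.path}:{lineno}: non-numeric data line {line!r}"
                    ) from exc
                if self.rows and len(values) != len(self.rows[0]):
                    raise FormatError(
                        f"{self.path}:{lineno}: ragged row with {len(values)} "
                        f"fields, expected {len(self.rows[0])}"
                    )
                self.rows.append(values)
        # legends must be dense s0..s(n-1); order by index
        if legend_idx and sorted(legend_idx) != list(range(len(legend_idx))):
            raise FormatError(
                f"{self.path}: non-contiguous legend indices {sorted(legend_idx)}"
            )
        if self.rows and self.legends:
            if len(self.rows[0]) != 1 + len(self.legends):
                raise FormatError(
                    f"{self.path}: {len(self.rows[0])} data columns but "
                    f"{len(self.legends)} legends (+1 time expected)"
                )

    def _meta_line(self, line: str, legend_idx: list[int]) -> None:
        m = re.match(r'@\s*subtitle\s+"(?P<s>.*)"', line)
        if m:
            self.subtitle = m.group("s")
            return
        m = re.match(r'@\s*s(?P<i>\d+)\s+legend\s+"(?P<s>.*)"', line)
        if m:
            i = int(m.group("i"))
            legend_idx.append(i)
            if i < len(self.legends):
                self.legends[i] = m.group("s")
            else:
                self.legends.extend([""] * (i + 1 - len(self.legends)))
                self.legends[i] = m.group("s")

    def stripped_legends(self) -> list[str]:
        return [_GRACE_ESCAPE_RE.sub("", s) for s in self.legends]

    def temperature(self, override: Optional[float]) -> float:
        if override is not None:
            return float(override)
        m = _SUBTITLE_T_RE.search(_GRACE_ESCAPE_RE.sub("", self.subtitle))
        if m is None:
            raise MetadataError(
                f"{self.path}: no temperature in subtitle and no override given"
            )
        return float(m.group("t"))

    def data(self) -> np.ndarray:
        if not self.rows:
            raise FormatError(f"{self.path}: no data rows")
        return np.asarray(self.rows, dtype=float)


def _dhdl_legends(xvg: _Xvg) -> list[tuple[int, str, float]]:
    """(column index, component name, window λ value) per gradient legend."""
    out = []
    for i, legend in enumerate(xvg.stripped_legends()):
        m = _DHDL_LEGEND_RE.search(legend)
        if m:
            out.append((i + 1, m.group("name"), float(m.group("value"))))
    return out


def _sampling_state(xvg: _Xvg) -> LambdaVector:
    """Window λ-vector, from the dH/dλ legends or the subtitle."""
    dhdl = _dhdl_legends(xvg)
    if dhdl:
        return LambdaVector(
            tuple(name for _, name, _ in dhdl),
            tuple(value for _, _, value in dhdl),
        )
    sub = _GRACE_ESCAPE_RE.sub("", xvg.subtitle)
    pairs = [
        (m.group("name"), float(m.group("value")))
        for m in _SUBTITLE_LAMBDA_RE.finditer(sub)
        if m.group("name") != "T"
    ]
    if not pairs:
        raise MetadataError(
            f"{xvg.path}: cannot determine the sampling lambda state "
            "(no dH/dl legends and no 'name = value' pairs in the subtitle)"
        )
    return LambdaVector(tuple(n for n, _ in pairs), tuple(v for _, v in pairs))


def _kt_factor(temperature: float, source_unit: str) -> float:
    """Division factor taking source-unit energies to kT."""
    meta = EnergyMetadata(temperature, source_unit)
    return meta.to_kj_per_mol() / EnergyMetadata(temperature, "kT").to_kj_per_mol()


def parse_xvg_dhdl(
    path,
    temperature_override: Optional[float] = None,
    source_unit: str = "kJ/mol",
) -> GradientTable:
    """Read one window's dH/dλ time series from a GROMACS-style XVG file.

    Legends matching the ``dH/d… <component> = <λ>`` pattern become the
    gradient columns (one per λ-component); the window λ-vector is taken
    from the legend values.  Energies are converted from *source_unit*
    (kJ/mol by default) to kT using the subtitle temperature unless
    *temperature_override* is given.
    """
    xvg = _Xvg(path)
    dhdl = _dhdl_legends(xvg)
    if not dhdl:
        raise FormatError(f"{path}: no dH/dlambda legends found")
    temperature = xvg.temperature(temperature_override)
    arr = xvg.data()
    lam = LambdaVector(
        tuple(n for _, n, _ in dhdl), tuple(v for _, _, v in dhdl)
    )
    factor = _kt_factor(temperature, source_unit)
    time = arr[:, 0]
    index = pd.MultiIndex.from_arrays(
        [time] + [np.full(len(time), v) for v in lam.values],
        names=["time", *lam.names],
    )
    frame = pd.DataFrame(
        {name: arr[:, col] * factor for col, name, _ in dhdl}, index=index
    )
    return GradientTable(frame, EnergyMetadata(temperature, "kT"))


def parse_xvg_u_nk(
    path,
    temperature_override: Optional[float] = None,
    source_unit: str = "kJ/mol",
) -> ReducedPotentialTable:
    """Read one window's reduced-potential differences from an XVG file.

    Legends ending in ``to <λ>`` (or ``to (λ1, λ2, …)``) identify the
    evaluated target states; the sampling state comes from the dH/dλ
    legends or the subtitle.  Values are converted to kT.
    """
    xvg = _Xvg(path)
    sampling = _sampling_state(xvg)
    names = sampling.names
    targets: list[tuple[int, tuple[float, ...]]] = []
    for i, legend in enumerate(xvg.stripped_legends()):
        m = _DELTAH_LEGEND_RE.search(legend)
        if m is None:
            continue
        raw = m.group("target")
        if raw.startswith("("):
            vals = tuple(float(v) for v in raw.strip("()").split(","))
        else:
            vals = (float(raw),)
        if len(vals) != len(names):
            raise FormatError(
                f"{path}: target state {raw!r} has {len(vals)} components, "
                f"expected {len(names)} ({names})"
            )
        targets.append((i + 1, vals))
    if not targets:
        raise FormatError(f"{path}: no 'to <lambda>' legends found")
    seen: set[tuple[float, ...]] = set()
    for _, vals in targets:
        if vals in seen:
            raise FormatError(f"{path}: duplicate target-state legend for {vals}")
        seen.add(vals)
    for _, vals in targets:
        LambdaVector(names, vals)  # raises ValidationError outside [0, 1]
    temperature = xvg.temperature(temperature_override)
    arr = xvg.data()
    factor = _kt_factor(temperature, source_unit)
    time = arr[:, 0]
    index = pd.MultiIndex.from_arrays(
        [time] + [np.full(len(time), v) for v in sampling.values],
        names=["time", *names],
    )
    frame = pd.DataFrame(
        {vals: arr[:, col] * factor for col, vals in targets}, index=index
    )
    frame.columns = pd.Index(list(frame.columns), tupleize_cols=False)
    return ReducedPotentialTable(frame, EnergyMetadata(temperature, "kT"))


# ---------------------------------------------------------------------------
# alchest CSV dialect
# ---------------------------------------------------------------------------

def _state_label(values: tuple[float, ...]) -> str:
    return "u(" + "|".join(_fmt(v) for v in values) + ")"


_STATE_LABEL_RE = re.compile(r"^u\((?P<vals>[^)]*)\)$")


def write_csv(table, path) -> None:
    """Write a table in the alchest CSV dialect (see ``docs/formats.md``).

    Numbers are emitted with 17 significant digits so the round trip
    through :func:`parse_csv` is exact for IEEE doubles.
    """
    is_dhdl = isinstance(table, GradientTable)
    kind = "dhdl" if is_dhdl else "u_nk"
    names = table.lambda_names
    lines = [f"#alchest {kind} v1"]
    lines.append(f"#meta temperature={_fmt(table.metadata.temperature)}")
    lines.append(f"#meta energy_unit={table.metadata.energy_unit}")
    lines.append("#meta lambda_names=" + ",".join(names))
    if is_dhdl:
        header = ["time", *names] + [f"dHdl_{n}" for n in names]
    else:
        header = ["time", *names] + [
            _state_label(col) for col in table.data.columns
        ]
    lines.append(",".join(header))
    index_arrays = [
        table.data.index.get_level_values(i) for i in range(table.data.index.nlevels)
    ]
    values = table.data.to_numpy(dtype=float)
    for r in range(len(table.data)):
        key = [_fmt(a[r]) for a in index_arrays]
        row = [_fmt(v) for v in values[r]]
        lines.append(",".join(key + row))
    Path(path).write_text("\n".join(lines) + "\n")


def parse_csv(path):
    """Read an alchest CSV dialect file into the matching table kind.

    The ``#alchest <kind> v1`` header selects the table type; values in
    units other than kT are converted to kT on read using the ``#meta``
    temperature.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text or not text[0].startswith("#alchest"):
        raise FormatError(f"{path}: missing '#alchest <kind> v1' header line")
    head = text[0].split()
    if len(head) != 3 or head[2] != "v1" or head[1] not in ("dhdl", "u_nk"):
        raise FormatError(f"{path}: bad header line {text[0]!r}")
    kind = head[1]
    meta: dict[str, str] = {}
    body_start = 1
    for i, line in enumerate(text[1:], start=1):
        if line.startswith("#meta"):
            try:
                key, value = line[len("#meta"):].strip().split("=", 1)
            except ValueError as exc:
                raise FormatError(f"{path}:{i + 1}: bad meta line {line!r}") from exc
            meta[key.strip()] = value.strip()
        elif line.startswith("#"):
            continue
        else:
            body_start = i
            break
    else:
        body_start = len(text)
    if "temperature" not in meta:
        raise MetadataError(f"{path}: missing '#meta temperature=' line")
    temperature = float(meta["temperature"])
    unit = meta.get("energy_unit", "kT")
    names = tuple(n for n in meta.get("lambda_names", "").split(",") if n)
    if not names:
        raise MetadataError(f"{path}: missing '#meta lambda_names=' line")

    body = [ln for ln in text[body_start:] if ln and not ln.startswith("#")]
    if not body:
        raise FormatError(f"{path}: missing column header row")
    header = [h.strip() for h in body[0].split(",")]
    expected_prefix = ["time", *names]
    if header[: len(expected_prefix)] != expected_prefix:
        raise FormatError(
            f"{path}: header must start with {expected_prefix}, got {header}"
        )
    value_cols = header[len(expected_prefix):]
    if kind == "dhdl":
        expected = [f"dHdl_{n}" for n in names]
        if value_cols != expected:
            raise FormatError(
                f"{path}: dhdl value columns must be {expected}, got {value_cols}"
            )
        out_cols: list = list(names)
    else:
        out_cols = []
        for label in value_cols:
            m = _STATE_LABEL_RE.match(label)
            if m is None:
                raise FormatError(
                    f"{path}: u_nk value column {label!r} is not a 'u(...)' "
                    "state label"
                )
            vals = tuple(float(v) for v in m.group("vals").split("|"))
            if len(vals) != len(names):
                raise FormatError(
                    f"{path}: state label {label!r} has {len(vals)} components, "
                    f"expected {len(names)}"
                )
            out_cols.append(vals)
    rows = []
    for lineno, line in enumerate(body[1:], start=1):
        fields = line.split(",")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: row {lineno} has {len(fields)} fields, "
                f"expected {len(header)}"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric row {lineno}: {line!r}") from exc
    arr = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(header)), dtype=float)
    )
    index = pd.MultiIndex.from_arrays(
        [arr[:, i] for i in range(len(expected_prefix))],
        names=["time", *names],
    )
    frame = pd.DataFrame(
        arr[:, len(expected_prefix):], index=index, columns=out_cols
    )
    if kind == "u_nk":
        frame.columns = pd.Index(out_cols, tupleize_cols=False)
    metadata = EnergyMetadata(temperature, unit)
    table = (
        GradientTable(frame, metadata)
        if kind == "dhdl"
        else ReducedPotentialTable(frame, metadata)
    )
    if unit != "kT":
        table = convert_energy(table, "kT")
    return table
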