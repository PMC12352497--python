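"""Standard tabular data structures for alchemical free-energy data.

Alchemical free-energy calculations stratify a transformation between two
physical end states into a series of λ-windows, each simulated at a fixed
value of the coupling-parameter vector λ = (λ1, …, λN).  Every simulation
engine writes its own raw format; this module defines the two canonical
in-memory tables everything downstream consumes:

* :class:`GradientTable` — samples of the Hamiltonian gradient ∂H/∂λ per
  window (the TI integrand), one numeric column per λ-component;
* :class:`ReducedPotentialTable` — samples of the reduced potential u of
  each configuration evaluated under *every* λ-state (the FEP/BAR/MBAR
  input), one numeric column per evaluated state.

Both are thin wrappers around a :class:`pandas.DataFrame` with a
``(time, λ-components…)`` row MultiIndex, carrying an
:class:`EnergyMetadata` record (temperature and energy unit) that is
propagated unchanged through every operation in the library.  The
canonical internal unit is kT; parsers convert on ingestion and
:func:`convert_energy` moves tables between kT, kJ/mol and kcal/mol for
input/output purposes only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    IncompatibleTablesError,
    MetadataError,
    UnitError,
    ValidationError,
)

__all__ = [
    "BOLTZMANN_CONSTANT",
    "AVOGADRO_CONSTANT",
    "KCAL_TO_KJ",
    "ENERGY_UNITS",
    "LambdaVector",
    "EnergyMetadata",
    "GradientTable",
    "ReducedPotentialTable",
    "StateCounts",
    "kt_to_kj_per_mol",
    "convert_energy",
    "concat_tables",
    "state_counts",
]

#: Boltzmann constant in J/K (exact, SI definition).
BOLTZMANN_CONSTANT = 1.380649e-23

#: Avogadro constant in 1/mol (exact, SI definition).
AVOGADRO_CONSTANT = 6.02214076e23

#: Thermochemical calorie: 1 kcal = 4.184 kJ exactly.
KCAL_TO_KJ = 4.184

#: The three supported energy unit tags.
ENERGY_UNITS = ("kT", "kJ/mol", "kcal/mol")


def kt_to_kj_per_mol(temperature: float) -> float:
    """Return the value of 1 kT in kJ/mol at the given temperature.

    Computed as k·N_A·T/1000 with the exact SI constants; ≈2.494 kJ/mol
    at 300 K.
    """
    return BOLTZMANN_CONSTANT * AVOGADRO_CONSTANT * temperature / 1000.0


@dataclass(frozen=True)
class LambdaVector:
    """An ordered, named coupling-parameter vector λ = (λ1, …, λN).

    Component names identify what each coordinate couples (e.g.
    ``fep-lambda``, ``coul-lambda``); matching between tables is by name,
    never by position.  All values live in [0, 1]; (0,…,0) is the initial
    and (1,…,1) the final physical state.
    """

    names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)
        if len(names) != len(values):
            raise ValidationError(
                f"lambda vector has {len(names)} names but {len(values)} values"
            )
        if len(names) == 0:
            raise ValidationError("lambda vector needs at least one component")
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate lambda component names: {names}")
        for name, value in zip(names, values):
            if not math.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"lambda component {name!r} = {value} outside [0, 1]"
                )

    @property
    def n_components(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[float]:
        return iter(self.values)

    def sort_key(self) -> tuple[float, ...]:
        """Lexicographic ordering key over component values."""
        return self.values

    def __str__(self) -> str:
        inner = ", ".join(f"{n}={v:g}" for n, v in zip(self.names, self.values))
        return f"λ({inner})"


@dataclass(frozen=True)
class EnergyMetadata:
    """Temperature and energy-unit tag attached to every table.

    ``temperature`` is in Kelvin and must be finite and positive;
    ``energy_unit`` is one of ``kT``, ``kJ/mol``, ``kcal/mol``.
    """

    temperature: float
    energy_unit: str = "kT"

    def __post_init__(self) -> None:
        t = float(self.temperature)
        object.__setattr__(self, "temperature", t)
        if not math.isfinite(t) or t <= 0:
            raise MetadataError(f"temperature must be finite and > 0, got {t}")
        if self.energy_unit not in ENERGY_UNITS:
            raise UnitError(
                f"unknown energy unit {self.energy_unit!r}; "
                f"expected one of {ENERGY_UNITS}"
            )

    def to_kj_per_mol(self) -> float:
        """Value of 1 of this unit in kJ/mol at this temperature."""
        return _unit_in_kj_per_mol(self.energy_unit, self.temperature)


def _unit_in_kj_per_mol(unit: str, temperature: float) -> float:
    if unit == "kT":
        return kt_to_kj_per_mol(temperature)
    if unit == "kJ/mol":
        return 1.0
    if unit == "kcal/mol":
        return KCAL_TO_KJ
    raise UnitError(f"unknown energy unit {unit!r}; expected one of {ENERGY_UNITS}")


def _check_row_index(df: pd.DataFrame, kind: str) -> None:
    """Validate the (time, λ…) MultiIndex shared by both table kinds."""
    if not isinstance(df.index, pd.MultiIndex) or df.index.nlevels < 2:
        raise ValidationError(
            f"{kind} requires a (time, lambda…) MultiIndex, got {df.index!r}"
        )
    if df.index.names[0] != "time":
        raise ValidationError(
            f"{kind} row index must start with 'time', got {df.index.names}"
        )
    if any(name is None for name in df.index.names[1:]):
        raise ValidationError("lambda index levels must be named")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(
            f"duplicate (time, state) row {dup!r}: looks like concatenated "
            "restarts; deduplicate explicitly before building the table"
        )
    # time strictly increasing within each window (vectorized groupby-diff)
    if len(df):
        times = pd.Series(
            df.index.get_level_values(0).to_numpy(dtype=float), index=df.index
        )
        diffs = times.groupby(
            level=list(range(1, df.index.nlevels)), sort=False
        ).diff()
        bad = diffs[diffs.notna() & (diffs <= 0)]
        if len(bad):
            raise ValidationError(
                f"time not strictly increasing within window at row "
                f"{bad.index[0]!r}"
            )


class _BaseTable:
    """Shared machinery of GradientTable / ReducedPotentialTable."""

    _kind = "table"

    def __init__(self, data: pd.DataFrame, metadata: EnergyMetadata):
        if not isinstance(metadata, EnergyMetadata):
            raise MetadataError(f"metadata must be EnergyMetadata, got {metadata!r}")
        self.data = data
        self.metadata = metadata
        self._validate()

    # -- interface ---------------------------------------------------------
    @property
    def lambda_names(self) -> tuple[str, ...]:
        """Names of the λ-components, taken from the row index levels."""
        return tuple(self.data.index.names[1:])

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def sampling_states(self) -> list[LambdaVector]:
        """Distinct λ-windows, in order of first appearance."""
        names = self.lambda_names
        tuples = list(
            zip(*[self.data.index.get_level_values(i)
                  for i in range(1, self.data.index.nlevels)])
        )
        out: list[LambdaVector] = []
        seen = set()
        for t in tuples:
            if t not in seen:
                seen.add(t)
                out.append(LambdaVector(names, t))
        return out

    def windows(self) -> list[tuple[LambdaVector, pd.DataFrame]]:
        """Per-window views: ``(lambda, frame indexed by time)`` pairs.

        Window order is order of first appearance; rows within a window
        keep their original (time-sorted) order.
        """
        out = []
        for lam in self.sampling_states():
            mask = np.ones(len(self.data), dtype=bool)
            for level, value in zip(range(1, self.data.index.nlevels), lam.values):
                mask &= self.data.index.get_level_values(level) == value
            sub = self.data.loc[mask]
            sub = sub.droplevel(list(range(1, self.data.index.nlevels)))
            out.append((lam, sub))
        return out

    def _replace(self, data: pd.DataFrame, metadata: EnergyMetadata | None = None):
        return type(self)(data, metadata or self.metadata)

    def _validate(self) -> None:
        raise NotImplementedError

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"<{type(self).__name__}: {self.n_rows} rows, "
            f"{len(self.sampling_states())} windows, "
            f"unit={self.metadata.energy_unit}, T={self.metadata.temperature} K>"
        )


class GradientTable(_BaseTable):
    """Long-format ∂H/∂λ samples, one column per λ-component.

    Rows are keyed by ``(time, λ-components…)``; each numeric column holds
    the gradient with respect to one named λ-component, in the table's
    energy unit.  This is the input of the TI estimator family.
    """

    _kind = "GradientTable"

    def _validate(self) -> None:
        _check_row_index(self.data, self._kind)
        expected = set(self.lambda_names)
        got = set(map(str, self.data.columns))
        if got != expected:
            raise ValidationError(
                f"{self._kind} columns {sorted(got)} must match the lambda "
                f"components {sorted(expected)} (one gradient per component)"
            )
        if len(self.data) and self.data.isna().any().any():
            raise ValidationError(f"{self._kind} contains missing values")
        # keep column order aligned with index level order
        self.data = self.data.loc[:, list(self.lambda_names)]


class ReducedPotentialTable(_BaseTable):
    """Reduced potentials u of every sample evaluated at every λ-state.

    Rows are keyed by ``(time, sampling-state λ…)``; columns are the
    evaluated λ-states (tuples of component values, aligned with the
    index's component names).  Column states must form a superset of the
    sampling states.  Values may be reduced potentials or differences
    relative to the sampling state — estimators are invariant to per-row
    additive constants, so both conventions are accepted as-is.
    """

    _kind = "ReducedPotentialTable"

    def _validate(self) -> None:
        _check_row_index(self.data, self._kind)
        names = self.lambda_names
        cols = []
        for col in self.data.columns:
            tup = col if isinstance(col, tuple) else (col,)
            if len(tup) != len(names):
                raise ValidationError(
                    f"column state {col!r} has {len(tup)} components; "
                    f"expected {len(names)} ({names})"
                )
            cols.append(tuple(float(v) for v in tup))
        if len(set(cols)) != len(cols):
            raise ValidationError(f"duplicate column states in {cols}")
        for tup in cols:
            LambdaVector(names, tup)  # range check
        sampled = {lam.values for lam in self.sampling_states()}
        missing = sampled - set(cols)
        if missing:
            raise ValidationError(
                f"sampling states {sorted(missing)} missing from evaluated "
                "columns: column states must be a superset of sampling states"
            )
        if len(self.data) and self.data.isna().any().any():
            raise ValidationError(f"{self._kind} contains missing values")
        self.data.columns = pd.Index(cols, tupleize_cols=False)

    def states(self) -> list[LambdaVector]:
        """Evaluated λ-states in column order."""
        names = self.lambda_names
        return [LambdaVector(names, col) for col in self.data.columns]


@dataclass(frozen=True)
class StateCounts:
    """Per-state sample counts N_k, in column-state order."""

    N_k: tuple[int, ...]

    def __post_init__(self) -> None:
        nk = tuple(int(n) for n in self.N_k)
        object.__setattr__(self, "N_k", nk)
        if any(n < 0 for n in nk):
            raise ValidationError(f"negative sample count in {nk}")

    @property
    def N_total(self) -> int:
        return sum(self.N_k)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def convert_energy(table, target_unit: str):
    """Rescale a table to another energy unit.

    The conversion factor between units is exact at the table's
    temperature (1 kT = k·N_A·T/1000 kJ/mol; 1 kcal = 4.184 kJ).  The
    returned table carries updated metadata; temperature is unchanged.
    A no-op conversion returns a value-identical copy.
    """
    if target_unit not in ENERGY_UNITS:
        raise UnitError(
            f"unknown energy unit {target_unit!r}; expected one of {ENERGY_UNITS}"
        )
    meta = table.metadata
    if meta.energy_unit == target_unit:
        return table._replace(table.data.copy())
    factor = (
        _unit_in_kj_per_mol(meta.energy_unit, meta.temperature)
        / _unit_in_kj_per_mol(target_unit, meta.temperature)
    )
    new_meta = EnergyMetadata(meta.temperature, target_unit)
    return table._replace(table.data * factor, new_meta)


def concat_tables(tables: Sequence[_BaseTable]):
    """Stack same-kind tables row-wise, preserving window order.

    All tables must agree on energy unit, temperature (to 1e-6 K) and
    column set; metadata is propagated unchanged.  Overlapping
    ``(time, state)`` keys across tables are rejected by table
    validation (they signal concatenated restarts).
    """
    if not tables:
        raise ValueError("concat_tables needs at least one table")
    first = tables[0]
    kind = type(first)
    for i, t in enumerate(tables[1:], start=1):
        if type(t) is not kind:
            raise IncompatibleTablesError(
                f"table {i} is {type(t).__name__}, expected {kind.__name__}"
            )
        if t.metadata.energy_unit != first.metadata.energy_unit:
            raise IncompatibleTablesError(
                f"table {i} unit {t.metadata.energy_unit!r} != "
                f"{first.metadata.energy_unit!r}"
            )
        if abs(t.metadata.temperature - first.metadata.temperature) > 1e-6:
            raise IncompatibleTablesError(
                f"table {i} temperature {t.metadata.temperature} K != "
                f"{first.metadata.temperature} K"
            )
        if set(t.data.columns) != set(first.data.columns):
            raise IncompatibleTablesError(
                f"table {i} columns {list(t.data.columns)} != "
                f"{list(first.data.columns)}"
            )
        if t.lambda_names != first.lambda_names:
            raise IncompatibleTablesError(
                f"table {i} lambda components {t.lambda_names} != "
                f"{first.lambda_names}"
            )
    if len(tables) == 1:
        return first._replace(first.data.copy())
    frames = [tables[0].data] + [
        t.data.loc[:, list(tables[0].data.columns)] for t in tables[1:]
    ]
    data = pd.concat(frames, axis=0)
    return first._replace(data)


def state_counts(u_nk: ReducedPotentialTable) -> StateCounts:
    """Count samples drawn from each column state.

    ``N_k[i]`` is the number of rows whose sampling state equals the
    *i*-th evaluated column state; states never sampled get 0.
    """
    cols = list(u_nk.data.columns)
    counts = dict.fromkeys(cols, 0)
    if len(u_nk.data):
        tuples = zip(*[u_nk.data.index.get_level_values(i)
                       for i in range(1, u_nk.data.index.nlevels)])
        for tup in tuples:
            key = tuple(float(v) for v in tup)
            counts[key] += 1
    return StateCounts(tuple(counts[c] for c in cols))
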