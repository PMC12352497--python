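"""Data model: λ-vectors, metadata, unit conversion, concatenation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alchest.datamodel import (
    AVOGADRO_CONSTANT,
    BOLTZMANN_CONSTANT,
    EnergyMetadata,
    GradientTable,
    LambdaVector,
    concat_tables,
    convert_energy,
    kt_to_kj_per_mol,
    state_counts,
)
from alchest.exceptions import (
    IncompatibleTablesError,
    MetadataError,
    UnitError,
    ValidationError,
)

from conftest import make_dhdl, make_unk


class TestLambdaVector:
    def test_rejects_out_of_range_and_duplicates(self):
        with pytest.raises(ValidationError):
            LambdaVector(("a",), (1.5,))
        with pytest.raises(ValidationError):
            LambdaVector(("a",), (-0.1,))
        with pytest.raises(ValidationError):
            LambdaVector(("a", "a"), (0.1, 0.2))

    def test_sort_key_orders_lexicographically(self):
        vs = [LambdaVector(("a", "b"), v) for v in
              [(0.5, 0.0), (0.0, 1.0), (0.0, 0.5)]]
        ordered = sorted(vs, key=lambda v: v.sort_key())
        assert [v.values for v in ordered] == [
            (0.0, 0.5), (0.0, 1.0), (0.5, 0.0)
        ]


class TestEnergyMetadata:
    @pytest.mark.parametrize("temperature", [0.0, -10.0, float("nan"),
                                             float("inf")])
    def test_rejects_bad_temperature(self, temperature):
        with pytest.raises(MetadataError):
            EnergyMetadata(temperature)

    def test_rejects_unknown_unit(self):
        with pytest.raises(UnitError):
            EnergyMetadata(300.0, "hartree")


class TestConvertEnergy:
    def test_kt_to_kj_per_mol_value(self, small_dhdl):
        # 1 kT at 300 K is k·N_A·300/1000 kJ/mol
        expected = BOLTZMANN_CONSTANT * AVOGADRO_CONSTANT * 300.0 / 1000.0
        out = convert_energy(small_dhdl, "kJ/mol")
        np.testing.assert_allclose(
            out.data.to_numpy(), expected, rtol=1e-14
        )
        assert out.metadata.energy_unit == "kJ/mol"
        assert out.metadata.temperature == 300.0
        assert math.isclose(expected, 2.494339, rel_tol=1e-6)

    def test_identity_conversion(self, small_dhdl):
        out = convert_energy(small_dhdl, "kT")
        pd.testing.assert_frame_equal(out.data, small_dhdl.data)

    def test_round_trip_through_kcal(self, small_dhdl):
        back = convert_energy(
            convert_energy(small_dhdl, "kcal/mol"), "kT"
        )
        np.testing.assert_allclose(
            back.data.to_numpy(), small_dhdl.data.to_numpy(), rtol=1e-12
        )

    @given(t=st.floats(1.0, 2000.0),
           u1=st.sampled_from(["kT", "kJ/mol", "kcal/mol"]),
           u2=st.sampled_from(["kT", "kJ/mol", "kcal/mol"]))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_conversion_composes(self, t, u1, u2):
        table = make_dhdl([np.linspace(-2, 3, 6)] * 2, [0.0, 1.0],
                          temperature=t)
        via = convert_energy(convert_energy(table, u1), u2)
        direct = convert_energy(table, u2)
        np.testing.assert_allclose(
            via.data.to_numpy(), direct.data.to_numpy(), rtol=1e-12
        )

    def test_unknown_target_unit(self, small_dhdl):
        with pytest.raises(UnitError):
            convert_energy(small_dhdl, "eV")


class TestTableValidation:
    def test_duplicate_time_state_rows_rejected(self):
        idx = pd.MultiIndex.from_arrays(
            [[0.0, 0.0], [0.5, 0.5]], names=["time", "fep-lambda"]
        )
        frame = pd.DataFrame({"fep-lambda": [1.0, 2.0]}, index=idx)
        with pytest.raises(ValidationError, match="duplicate|increasing"):
            GradientTable(frame, EnergyMetadata(300.0))

    def test_decreasing_time_rejected(self):
        idx = pd.MultiIndex.from_arrays(
            [[1.0, 0.0], [0.5, 0.5]], names=["time", "fep-lambda"]
        )
        frame = pd.DataFrame({"fep-lambda": [1.0, 2.0]}, index=idx)
        with pytest.raises(ValidationError, match="increasing"):
            GradientTable(frame, EnergyMetadata(300.0))

    def test_u_nk_columns_must_cover_sampling_states(self):
        from alchest.datamodel import ReducedPotentialTable

        idx = pd.MultiIndex.from_arrays(
            [[0.0, 1.0, 0.0, 1.0], [0.0, 0.0, 1.0, 1.0]],
            names=["time", "fep-lambda"],
        )
        frame = pd.DataFrame(np.zeros((4, 1)), index=idx)
        frame.columns = pd.Index([(0.0,)], tupleize_cols=False)
        with pytest.raises(ValidationError, match="superset"):
            ReducedPotentialTable(frame, EnergyMetadata(300.0))

    def test_missing_values_rejected(self):
        vals = np.ones((5, 1))
        vals[2] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            make_dhdl([vals, np.ones((5, 1))], [0.0, 1.0])


class TestConcat:
    def test_singleton_concat_is_identity(self, small_dhdl):
        out = concat_tables([small_dhdl])
        pd.testing.assert_frame_equal(out.data, small_dhdl.data)

    def test_two_windows_stack(self):
        a = make_dhdl([np.ones(100)], [0.0])
        b = make_dhdl([np.full(100, 2.0)], [1.0])
        out = concat_tables([a, b])
        assert len(out) == 200
        assert [lam.values for lam in out.sampling_states()] == [(0.0,), (1.0,)]

    def test_mixed_units_rejected(self, small_dhdl):
        other = convert_energy(small_dhdl, "kJ/mol")
        with pytest.raises(IncompatibleTablesError, match="unit"):
            concat_tables([small_dhdl, other])

    def test_mismatched_temperature_rejected(self):
        a = make_dhdl([np.ones(5)], [0.0], temperature=300.0)
        b = make_dhdl([np.ones(5)], [1.0], temperature=310.0)
        with pytest.raises(IncompatibleTablesError, match="temperature"):
            concat_tables([a, b])

    def test_concat_split_round_trip(self):
        a = make_dhdl([np.arange(7.0)], [0.0])
        b = make_dhdl([np.arange(5.0) + 10], [1.0])
        out = concat_tables([a, b])
        windows = out.windows()
        np.testing.assert_array_equal(
            windows[0][1].to_numpy(), a.windows()[0][1].to_numpy()
        )
        np.testing.assert_array_equal(
            windows[1][1].to_numpy(), b.windows()[0][1].to_numpy()
        )


class TestStateCounts:
    def test_counts_per_state(self, rng):
        u = rng.normal(size=(150, 3))
        table = make_unk(u, [0] * 50 + [1] * 50 + [2] * 50, [0.0, 0.5, 1.0])
        counts = state_counts(table)
        assert counts.N_k == (50, 50, 50)
        assert counts.N_total == 150

    def test_unsampled_state_counts_zero(self, rng):
        u = rng.normal(size=(40, 3))
        table = make_unk(u, [0] * 20 + [2] * 20, [0.0, 0.5, 1.0])
        assert state_counts(table).N_k == (20, 0, 20)

    def test_empty_table_all_zero(self):
        table = make_unk(np.empty((0, 2)), np.empty(0, dtype=int),
                         [0.0, 1.0])
        counts = state_counts(table)
        assert counts.N_k == (0, 0)
        assert counts.N_total == 0


def test_metadata_propagates_through_pipeline(rng):
    """One table threaded through slice → decorrelate → estimate keeps
    its temperature and unit at every stage."""
    from alchest.estimators import MBAR
    from alchest.preprocessing import decorrelate, slice_table

    from conftest import harmonic_unk

    table = harmonic_unk(rng, [1.0, 2.0, 4.0], 400)
    meta = table.metadata
    sliced = slice_table(table, step=2)
    assert sliced.metadata == meta
    decorr, _ = decorrelate(sliced)
    assert decorr.metadata == meta
    est = MBAR().fit(decorr)
    assert est.result_.metadata == meta
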