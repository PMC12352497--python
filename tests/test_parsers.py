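"""Parsers: XVG ingestion and the alchest CSV dialect round trip."""

import numpy as np
import pytest

from alchest.datamodel import GradientTable, ReducedPotentialTable, convert_energy
from alchest.exceptions import FormatError, MetadataError, ValidationError
from alchest.parsers import parse_csv, parse_xvg_dhdl, parse_xvg_u_nk, write_csv
from alchest.testsystems import HarmonicSpec, sample, write_fixtures

from conftest import make_dhdl, make_unk


@pytest.fixture(scope="module")
def harmonic_tables():
    spec = HarmonicSpec(lambdas=(0.0, 0.5, 1.0), n_samples=20, seed=9)
    return spec, sample(spec)


@pytest.fixture()
def xvg_dir(tmp_path, harmonic_tables):
    spec, _ = harmonic_tables
    write_fixtures(spec, tmp_path, "xvg")
    return tmp_path


class TestCsvRoundTrip:
    @pytest.mark.parametrize("kind", ["dhdl", "u_nk"])
    def test_round_trip_exact(self, tmp_path, harmonic_tables, kind):
        _, (dhdl, unk) = harmonic_tables
        table = dhdl if kind == "dhdl" else unk
        path = tmp_path / f"{kind}.csv"
        write_csv(table, path)
        back = parse_csv(path)
        assert type(back) is type(table)
        np.testing.assert_allclose(
            back.data.to_numpy(), table.data.to_numpy(), rtol=1e-12
        )
        assert list(back.data.columns) == list(table.data.columns)
        assert back.metadata == table.metadata

    def test_round_trip_bit_stable(self, tmp_path, rng):
        """write → parse → write reproduces the file byte-for-byte."""
        table = make_dhdl([rng.normal(size=500), rng.normal(size=500)],
                          [0.0, 1.0])
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_csv(table, p1)
        write_csv(parse_csv(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_non_kt_units_converted_on_read(self, tmp_path, small_dhdl):
        in_kj = convert_energy(small_dhdl, "kJ/mol")
        path = tmp_path / "kj.csv"
        write_csv(in_kj, path)
        back = parse_csv(path)
        assert back.metadata.energy_unit == "kT"
        np.testing.assert_allclose(
            back.data.to_numpy(), small_dhdl.data.to_numpy(), rtol=1e-12
        )

    def test_empty_table_round_trip(self, tmp_path, small_dhdl):
        from alchest.preprocessing import slice_table

        empty = slice_table(small_dhdl, lower=1e9)
        path = tmp_path / "empty.csv"
        write_csv(empty, path)
        back = parse_csv(path)
        assert len(back) == 0
        assert isinstance(back, GradientTable)

    def test_missing_temperature_is_metadata_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("#alchest dhdl v1\n#meta lambda_names=l\n"
                        "time,l,dHdl_l\n")
        with pytest.raises(MetadataError):
            parse_csv(path)

    def test_unknown_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("#alchest potato v1\n")
        with pytest.raises(FormatError):
            parse_csv(path)

    def test_kind_schema_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "#alchest u_nk v1\n#meta temperature=300\n"
            "#meta lambda_names=l\ntime,l,dHdl_l\n0,0,1\n"
        )
        with pytest.raises(FormatError):
            parse_csv(path)


class TestXvg:
    def test_dhdl_matches_generating_table(self, xvg_dir, harmonic_tables):
        _, (dhdl, _) = harmonic_tables
        tables = [parse_xvg_dhdl(p) for p in sorted(xvg_dir.glob("*.xvg"))]
        from alchest.datamodel import concat_tables

        merged = concat_tables(tables)
        np.testing.assert_allclose(
            merged.data.to_numpy(), dhdl.data.to_numpy(), rtol=1e-12
        )
        assert merged.metadata.energy_unit == "kT"

    def test_u_nk_matches_generating_table(self, xvg_dir, harmonic_tables):
        _, (_, unk) = harmonic_tables
        tables = [parse_xvg_u_nk(p) for p in sorted(xvg_dir.glob("*.xvg"))]
        from alchest.datamodel import concat_tables

        merged = concat_tables(tables)
        assert list(merged.data.columns) == list(unk.data.columns)
        np.testing.assert_allclose(
            merged.data.to_numpy(), unk.data.to_numpy(), rtol=1e-12
        )

    def test_comments_and_metadata_order_ignored(self, xvg_dir):
        path = sorted(xvg_dir.glob("*.xvg"))[0]
        reference = parse_xvg_dhdl(path)
        lines = path.read_text().splitlines()
        meta = [l for l in lines if l.startswith("@")]
        data = [l for l in lines if not l.startswith(("@", "#"))]
        # reverse the metadata block and sprinkle comments into the data
        shuffled = meta[::-1] + ["# a comment"] + data[:5] + \
            ["# another comment"] + data[5:]
        p2 = path.parent / "shuffled.xvg"
        p2.write_text("\n".join(shuffled) + "\n")
        again = parse_xvg_dhdl(p2)
        np.testing.assert_array_equal(
            again.data.to_numpy(), reference.data.to_numpy()
        )

    def test_empty_data_section_is_format_error(self, xvg_dir):
        path = sorted(xvg_dir.glob("*.xvg"))[0]
        lines = [l for l in path.read_text().splitlines()
                 if l.startswith(("@", "#"))]
        p2 = path.parent / "empty.xvg"
        p2.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="no data"):
            parse_xvg_dhdl(p2)

    def test_ragged_rows_error_names_line(self, xvg_dir):
        path = sorted(xvg_dir.glob("*.xvg"))[0]
        lines = path.read_text().splitlines()
        first_data = next(i for i, l in enumerate(lines)
                          if not l.startswith(("@", "#")))
        lines.insert(first_data + 1, "0.5 1.0")
        p2 = path.parent / "ragged.xvg"
        p2.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match=str(first_data + 2)):
            parse_xvg_dhdl(p2)

    def test_non_numeric_garbage_is_hard_error(self, xvg_dir):
        path = sorted(xvg_dir.glob("*.xvg"))[0]
        p2 = path.parent / "garbage.xvg"
        p2.write_text(path.read_text() + "hello world\n")
        with pytest.raises(FormatError, match="non-numeric"):
            parse_xvg_dhdl(p2)

    def test_duplicate_target_legend_rejected(self, xvg_dir):
        path = sorted(xvg_dir.glob("*.xvg"))[0]
        text = path.read_text()
        # duplicate the first ΔH legend under a fresh legend index
        dup = next(l for l in text.splitlines() if " to " in l)
        n_legends = sum(1 for l in text.splitlines() if "legend" in l)
        lines = text.splitlines()
        insert_at = max(i for i, l in enumerate(lines) if "legend" in l) + 1
        lines.insert(insert_at, dup.replace(
            dup.split()[1], f"s{n_legends}"
        ))
        p2 = path.parent / "dup.xvg"
        p2.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError):
            parse_xvg_u_nk(p2)

    def test_missing_temperature_needs_override(self, xvg_dir):
        path = sorted(xvg_dir.glob("*.xvg"))[0]
        lines = [l for l in path.read_text().splitlines()
                 if "subtitle" not in l]
        p2 = path.parent / "no_t.xvg"
        p2.write_text("\n".join(lines) + "\n")
        with pytest.raises(MetadataError):
            parse_xvg_dhdl(p2)
        table = parse_xvg_dhdl(p2, temperature_override=300.0)
        assert table.metadata.temperature == 300.0

    def test_no_dhdl_columns_is_format_error(self, tmp_path):
        p = tmp_path / "plain.xvg"
        p.write_text('@ subtitle "T = 300 (K)"\n0.0 1.0\n')
        with pytest.raises(FormatError, match="dH/dlambda"):
            parse_xvg_dhdl(p)
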