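import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.cp_io import (
    CpMatrix,
    collapse_replicates,
    estimate_efficiency,
    read_cp_table,
    read_efficiency_table,
    read_group_map,
    to_relative_quantities,
    write_cp_table,
)
from refstab.errors import (
    FitError,
    FormatError,
    MissingDataError,
    ParameterError,
    ValidationError,
)

from conftest import make_cp


WIDE = "gene\ts1\ts2\nA\t20.0\t21.0\nB\t25.0\t26.0\nC\t30.0\t29.0\n"

LONG = (
    "sample\tgene\treplicate\tcp\n"
    "s1\tA\t1\t20.0\n"
    "s1\tA\t2\t20.4\n"
    "s1\tB\t1\t25.0\n"
    "s1\tB\t2\t25.2\n"
    "s2\tA\t1\t21.0\n"
    "s2\tA\t2\t21.2\n"
    "s2\tB\t1\t26.0\n"
    "s2\tB\t2\t26.4\n"
)


class TestReadCpTable:
    def test_wide_preserves_order_and_values(self):
        cp = read_cp_table(io.StringIO(WIDE), layout="wide")
        assert cp.genes == ["A", "B", "C"]
        assert cp.samples == ["s1", "s2"]
        assert cp.values.to_numpy().tolist() == [
            [20.0, 21.0],
            [25.0, 26.0],
            [30.0, 29.0],
        ]
        assert cp.replicate_map is None

    def test_long_populates_replicate_map(self):
        cp = read_cp_table(io.StringIO(LONG), layout="long")
        assert cp.replicate_map is not None
        assert cp.replicate_map["s1.1"] == ("s1", 1)
        assert cp.replicate_map["s2.2"] == ("s2", 2)
        assert cp.values.at["A", "s1.2"] == 20.4

    def test_out_of_range_cp_names_cell(self):
        text = WIDE.replace("21.0", "47.2")
        with pytest.raises(ValidationError) as exc:
            read_cp_table(io.StringIO(text), layout="wide")
        assert "A" in str(exc.value) and "s2" in str(exc.value)

    def test_non_numeric_cp_names_cell(self):
        text = WIDE.replace("25.0", "n/a")
        with pytest.raises(ValidationError, match="s1"):
            read_cp_table(io.StringIO(text), layout="wide")

    def test_duplicate_gene_is_format_error(self):
        text = WIDE.replace("B\t", "A\t")
        with pytest.raises(FormatError):
            read_cp_table(io.StringIO(text), layout="wide")

    def test_duplicate_long_triple_is_format_error(self):
        text = LONG + "s2\tB\t2\t26.5\n"
        with pytest.raises(FormatError):
            read_cp_table(io.StringIO(text), layout="long")

    def test_unknown_layout(self):
        with pytest.raises(FormatError):
            read_cp_table(io.StringIO(WIDE), layout="tall")


class TestRoundTrip:
    def test_wide_round_trip_bit_identical(self, tmp_path, rng):
        cp = make_cp(rng.uniform(10, 40, size=(4, 5)))
        path = tmp_path / "cp.tsv"
        write_cp_table(cp, path, layout="wide")
        back = read_cp_table(path, layout="wide")
        assert back.genes == cp.genes
        assert back.samples == cp.samples
        assert np.array_equal(back.values.to_numpy(), cp.values.to_numpy())

    def test_long_round_trip(self, tmp_path):
        cp = read_cp_table(io.StringIO(LONG), layout="long")
        path = tmp_path / "cp_long.tsv"
        write_cp_table(cp, path, layout="long")
        back = read_cp_table(path, layout="long")
        assert np.array_equal(back.values.to_numpy(), cp.values.to_numpy())
        assert back.replicate_map == cp.replicate_map


class TestValidation:
    def test_groups_must_cover_samples(self):
        with pytest.raises(ValidationError):
            make_cp([[20.0, 21.0]], groups={"s1": "a"})

    def test_cp_bounds(self):
        with pytest.raises(ValidationError):
            make_cp([[20.0, 45.0]])
        with pytest.raises(ValidationError):
            make_cp([[0.0, 20.0]])


class TestCollapseReplicates:
    def _with_reps(self, rows):
        return make_cp(
            rows,
            samples=["b1.1", "b1.2", "b1.3"][: len(rows[0])],
            replicate_map={
                f"b1.{i}": ("b1", i) for i in range(1, len(rows[0]) + 1)
            },
        )

    def test_constant_replicates(self):
        cp = self._with_reps([[20.0, 20.0, 20.0]])
        assert collapse_replicates(cp).values.at["g1", "b1"] == 20.0

    def test_symmetric_replicates(self):
        cp = self._with_reps([[19.8, 20.0, 20.2]])
        assert collapse_replicates(cp).values.at["g1", "b1"] == pytest.approx(20.0)

    def test_two_replicates_mean(self):
        cp = self._with_reps([[18.0, 19.0]])
        # arithmetic mean by hand: (18 + 19) / 2
        assert collapse_replicates(cp).values.at["g1", "b1"] == 18.5

    def test_requires_replicate_map(self, small_cp):
        with pytest.raises(MissingDataError):
            collapse_replicates(small_cp)

    def test_groups_carried_over(self):
        cp = make_cp(
            [[20.0, 20.5, 25.0, 25.5]],
            samples=["a.1", "a.2", "b.1", "b.2"],
            replicate_map={
                "a.1": ("a", 1), "a.2": ("a", 2),
                "b.1": ("b", 1), "b.2": ("b", 2),
            },
            groups={"a.1": "x", "a.2": "x", "b.1": "y", "b.2": "y"},
        )
        out = collapse_replicates(cp)
        assert out.groups == {"a": "x", "b": "y"}


class TestRelativeQuantities:
    def test_calibrator_identity(self, small_cp):
        q = to_relative_quantities(small_cp)
        # the sample holding each gene's minimum Cp must have Q = 1
        assert np.allclose(q.q_values.max(axis=1), 1.0)

    def test_dcp_one_e_two(self):
        q = to_relative_quantities(make_cp([[20.0, 21.0]]), efficiencies=2.0)
        assert q.q_values.at["g1", "s2"] == 0.5

    def test_dcp_two_e_191(self):
        q = to_relative_quantities(make_cp([[20.0, 22.0]]), efficiencies=1.91)
        assert q.q_values.at["g1", "s2"] == pytest.approx(
            0.2741152928921905, rel=1e-12
        )

    def test_per_gene_efficiencies(self):
        cp = make_cp([[20.0, 21.0], [20.0, 21.0]])
        q = to_relative_quantities(cp, {"g1": 2.0, "g2": 1.9})
        assert q.q_values.at["g1", "s2"] == 0.5
        assert q.q_values.at["g2", "s2"] == pytest.approx(1.9**-1)

    @pytest.mark.parametrize("bad", [0.9, 1.0, 2.3, -1.0, float("nan")])
    def test_bad_efficiency(self, bad, small_cp):
        with pytest.raises(ParameterError):
            to_relative_quantities(small_cp, bad)

    def test_missing_gene_efficiency(self, small_cp):
        with pytest.raises(ParameterError):
            to_relative_quantities(small_cp, {"g1": 2.0})

    def test_log2_difference_identity(self, rng):
        # for E = 2: log2(Q[g,s]/Q[g,t]) == Cp[g,t] - Cp[g,s] exactly
        cp = make_cp(rng.uniform(15, 35, size=(3, 4)))
        q = to_relative_quantities(cp, 2.0)
        diffs = np.log2(q.q_values.iloc[:, 0] / q.q_values.iloc[:, 2])
        expected = cp.values.iloc[:, 2] - cp.values.iloc[:, 0]
        assert np.allclose(diffs, expected, atol=1e-12)


class TestEstimateEfficiency:
    def test_perfect_doubling(self):
        slope = -3.321928094887362  # -1 / log10(2)
        pts = [(c, 30.0 + slope * math.log10(c)) for c in (0.01, 0.1, 1.0, 10.0)]
        est = estimate_efficiency(pts, gene="X")
        assert est.efficiency == pytest.approx(2.000, abs=5e-4)
        assert est.r_squared == pytest.approx(1.0)

    def test_exact_linear_recovery(self):
        pts = [(c, 30.0 - 3.5 * math.log10(c)) for c in (0.01, 0.1, 1.0, 10.0)]
        est = estimate_efficiency(pts)
        assert est.slope == pytest.approx(-3.5, rel=1e-12)
        assert est.efficiency == pytest.approx(1.93069772888325, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert est.n_points == 4
        assert not est.warnings

    def test_two_points_is_fit_error(self):
        with pytest.raises(FitError):
            estimate_efficiency([(1.0, 30.0), (10.0, 26.7)])

    def test_zero_concentration_variance(self):
        with pytest.raises(FitError):
            estimate_efficiency([(1.0, 30.0), (1.0, 30.1), (1.0, 29.9)])

    def test_positive_slope_warns(self):
        pts = [(c, 30.0 + 3.5 * math.log10(c)) for c in (0.01, 0.1, 1.0, 10.0)]
        est = estimate_efficiency(pts)
        assert any("slope" in w for w in est.warnings)

    @settings(max_examples=50, deadline=None)
    @given(
        slope=st.floats(min_value=-4.0, max_value=-3.0),
        intercept=st.floats(min_value=20.0, max_value=35.0),
    )
    def test_noiseless_series_recovers_slope(self, slope, intercept):
        pts = [
            (c, intercept + slope * math.log10(c)) for c in (0.01, 0.1, 1.0, 10.0)
        ]
        est = estimate_efficiency(pts)
        assert abs(est.slope - slope) <= 1e-9 * abs(slope)


class TestAuxTables:
    def test_group_map(self):
        groups = read_group_map(io.StringIO("sample\tgroup\ns1\tHOS\ns2\tU2OS\n"))
        assert groups == {"s1": "HOS", "s2": "U2OS"}

    def test_group_map_duplicate(self):
        with pytest.raises(FormatError):
            read_group_map(io.StringIO("sample\tgroup\ns1\ta\ns1\tb\n"))

    def test_efficiency_table(self):
        effs = read_efficiency_table(io.StringIO("gene\tefficiency\nA\t1.91\nB\t2.0\n"))
        assert effs == {"A": 1.91, "B": 2.0}

    def test_efficiency_table_out_of_range(self):
        with pytest.raises(ParameterError):
            read_efficiency_table(io.StringIO("gene\tefficiency\nA\t2.5\n"))
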