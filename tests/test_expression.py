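from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chillseq.expression import (CountTable, QpcrRecord,
                                 build_profile, call_de, call_de_table,
                                 compute_cpm, flag_expressed,
                                 qpcr_relative_expression,
                                 upper_quartile_normalize)


def _table(raw: dict, totals: dict) -> CountTable:
    return CountTable(counts=pd.DataFrame(raw), totals=pd.Series(totals))


def _profile_from_cpm(cpm_a: float, cpm_b: float) -> CountTable:
    """Two-library table where gene g1 has the requested CPM values
    (depth 1e6 makes counts equal CPM); filler genes stabilize UQ."""
    return _table(
        {"A": [cpm_a, 50, 80, 120], "B": [cpm_b, 50, 80, 120]},
        {"A": 1e6, "B": 1e6},
    )


class TestCpm:
    def test_ten_reads_per_million(self):
        t = _table({"L": [10.0]}, {"L": 1_000_000})
        assert compute_cpm(t).at[0, "L"] == 10.0

    def test_linear_scaling(self):
        t = _table({"L": [5.0]}, {"L": 250_000})
        assert compute_cpm(t).at[0, "L"] == 20.0

    def test_column_sum_identity(self, rng):
        raw = rng.integers(0, 500, size=(50, 3)).astype(float)
        t = _table({f"L{i}": raw[:, i] for i in range(3)},
                   {f"L{i}": 2e6 for i in range(3)})
        cpm = compute_cpm(t)
        for i in range(3):
            assert np.isclose(cpm[f"L{i}"].sum(), 1e6 * raw[:, i].sum() / 2e6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            _table({"L": [1.0]}, {"L": 0})


class TestExpressedFlag:
    def test_threshold_is_inclusive(self):
        cpm = pd.DataFrame({"L": [9.99, 10.0, 0.0]})
        flags = flag_expressed(cpm)
        assert list(flags["L"]) == [False, True, False]

    def test_non_expressed_effective_level_is_zero(self):
        t = _table({"A": [9.0, 50, 80, 120], "B": [50.0, 50, 80, 120]},
                   {"A": 1e6, "B": 1e6})
        prof = build_profile(t)
        assert prof.effective_expression().at[0, "A"] == 0.0
        assert prof.effective_expression().at[0, "B"] > 0.0

    def test_all_zero_library_is_an_error(self):
        t = _table({"A": [0.0, 0.0], "B": [5.0, 5.0]}, {"A": 1e6, "B": 1e6})
        with pytest.raises(ValueError):
            build_profile(t)


class TestUpperQuartile:
    def test_identical_libraries_are_unchanged(self):
        t = _table({"A": [2.0, 4, 8, 100], "B": [2.0, 4, 8, 100]},
                   {"A": 1e6, "B": 1e6})
        norm, uq = upper_quartile_normalize(t)
        assert uq["A"] == uq["B"]
        assert np.allclose(norm.values, t.counts.values)

    def test_rescaled_library_is_invariant(self):
        base = {"A": [2.0, 4, 8, 100], "B": [3.0, 7, 20, 50]}
        t1 = _table(base, {"A": 1e6, "B": 1e6})
        t2 = _table({"A": [v * 3 for v in base["A"]], "B": base["B"]},
                    {"A": 1e6, "B": 1e6})
        n1, _ = upper_quartile_normalize(t1)
        n2, _ = upper_quartile_normalize(t2)
        # A's normalized values do not depend on A's global scale; note the
        # geometric-mean rescaling shifts both columns by the same constant
        ratio = n2["A"].values / n1["A"].values
        assert np.allclose(ratio, ratio[0])
        assert np.allclose(n2["A"] / n2["B"], n1["A"] / n1["B"])

    def test_percentile_rule_by_hand(self):
        # nonzero counts (2, 4, 8, 100): 75th percentile by linear
        # interpolation = 8 + 0.25 * (100 - 8) = 31
        t = _table({"A": [2.0, 4, 8, 100, 0]}, {"A": 1e6})
        _, uq = upper_quartile_normalize(t)
        assert uq["A"] == pytest.approx(31.0)

    def test_zeros_excluded_from_quartile(self):
        with_zeros = _table({"A": [2.0, 4, 8, 100, 0, 0, 0]}, {"A": 1e6})
        without = _table({"A": [2.0, 4, 8, 100]}, {"A": 1e6})
        assert upper_quartile_normalize(with_zeros)[1]["A"] == \
            upper_quartile_normalize(without)[1]["A"]


class TestCallDe:
    def test_fourfold_exactly_is_de(self):
        # identical filler counts pin both UQ factors to 900, so the
        # gene's normalized values are exactly 100 vs 400 (ratio 4.0)
        t = _table({"A": [100.0, 50, 800, 900, 1200],
                    "B": [400.0, 50, 800, 900, 1200]},
                   {"A": 1e6, "B": 1e6})
        prof = build_profile(t)
        assert prof.uq_factors["A"] == prof.uq_factors["B"] == 900.0
        call = call_de(0, ("B", "A"), prof)
        assert call.status == "up" and call.criterion == "fold"
        assert call.fold_change == pytest.approx(4.0)

    def test_on_off_boundaries(self):
        prof = build_profile(_profile_from_cpm(9.0, 41.0))
        call = call_de(0, ("A", "B"), prof)
        assert call.status == "down" and call.criterion == "on_off"
        prof2 = build_profile(_profile_from_cpm(9.0, 39.0))
        assert call_de(0, ("A", "B"), prof2).status == "not_de"
        # CPM exactly 40 is not over-expressed (strictly greater required)
        prof3 = build_profile(_profile_from_cpm(9.0, 40.0))
        assert call_de(0, ("A", "B"), prof3).status == "not_de"

    def test_expressed_in_neither_is_never_de(self):
        prof = build_profile(_profile_from_cpm(1.0, 9.0))
        assert call_de(0, ("A", "B"), prof).status == "not_de"

    def test_antisymmetry_and_exclusive_direction(self, rng):
        raw = rng.integers(0, 2000, size=(60, 2)).astype(float)
        raw[:5] = [[100, 50], [50, 100], [9, 41], [41, 9], [0, 0]]
        t = _table({"A": raw[:, 0], "B": raw[:, 1]}, {"A": 1e6, "B": 1e6})
        prof = build_profile(t)
        ab = call_de_table(prof, ("A", "B"))
        ba = call_de_table(prof, ("B", "A"))
        flip = {"up": "down", "down": "up", "not_de": "not_de"}
        assert list(ba["status"]) == [flip[s] for s in ab["status"]]
        assert list(ba["criterion"]) == list(ab["criterion"])

    def test_vectorized_calls_match_scalar(self, rng):
        raw = rng.integers(0, 3000, size=(40, 2)).astype(float)
        t = _table({"A": raw[:, 0], "B": raw[:, 1]}, {"A": 1e6, "B": 1e6})
        prof = build_profile(t)
        table = call_de_table(prof, ("A", "B"))
        for gene in prof.cpm.index:
            one = call_de(gene, ("A", "B"), prof)
            assert one.status == table.at[gene, "status"]
            assert one.criterion == table.at[gene, "criterion"]

    def test_de_status_invariant_under_library_rescaling(self, rng):
        raw = rng.integers(1, 3000, size=(50, 2)).astype(float)
        t1 = _table({"A": raw[:, 0], "B": raw[:, 1]}, {"A": 1e6, "B": 1e6})
        # scale library A's raw counts and its mapped total together: CPM
        # (hence expressed flags) and UQ-normalized ratios both survive
        t2 = _table({"A": raw[:, 0] * 5, "B": raw[:, 1]},
                    {"A": 5e6, "B": 1e6})
        c1 = call_de_table(build_profile(t1), ("A", "B"))
        c2 = call_de_table(build_profile(t2), ("A", "B"))
        assert list(c1["status"]) == list(c2["status"])


class TestQpcr:
    def test_no_change_is_one(self):
        rec = QpcrRecord(20, 15, 22, 17)  # ddCt = 0
        assert qpcr_relative_expression(rec) == 1.0

    def test_one_cycle_halves(self):
        rec = QpcrRecord(21, 15, 22, 17)  # ddCt = +1
        assert qpcr_relative_expression(rec) == 0.5

    def test_ntc_rule(self):
        rec = QpcrRecord(35, 15, 22, 17, ct_ntc=34)
        assert qpcr_relative_expression(rec) == "not expressed"
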