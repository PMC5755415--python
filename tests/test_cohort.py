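"""Cohort ingestion, filtering, prevalence and internal standardization."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import cariesmap as cm
from cariesmap.cohort import PrevalenceUndefinedError, records_from_rows

from conftest import make_children


class TestReadWrite:
    def test_well_formed_file_round_trips(self, tmp_path, rng):
        n = 500
        df = make_children(n, cases=50)
        df["age"] = rng.integers(3, 7, size=n)
        df["dmfs"] = np.where(df["dmfs"] > 0, rng.integers(1, 12, size=n), 0)
        path = tmp_path / "children.csv"
        cm.write_children(df, path)
        back = cm.read_children(path)
        pd.testing.assert_frame_equal(back, df.reset_index(drop=True))

    def test_three_row_file(self, tmp_path):
        path = tmp_path / "c.csv"
        cm.write_children(make_children(3), path)
        assert len(cm.read_children(path)) == 3

    def test_negative_dmfs_rejected_with_log(self, tmp_path, caplog):
        df = make_children(3)
        df.loc[1, "dmfs"] = -2
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with caplog.at_level(logging.WARNING):
            back = cm.read_children(path)
        assert len(back) == 2
        assert any("rejected" in r.message for r in caplog.records)

    def test_unparseable_age_rejected(self, tmp_path):
        df = make_children(4).astype({"age": object})
        df.loc[2, "age"] = "four"
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        assert len(cm.read_children(path)) == 3

    def test_missing_column_is_hard_error(self, tmp_path):
        df = make_children(3).drop(columns=["parish_id"])
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="parish_id"):
            cm.read_children(path)


class TestFilter:
    def test_domestic_split_reproduces_study_counts(self):
        total = pd.concat(
            [make_children(10583), make_children(344, birth_class="foreign_born")],
            ignore_index=True,
        )
        assert len(total) == 10927
        dom = cm.filter_cohort(total, birth_class="domestic")
        assert len(dom) == 10583

    def test_empty_input(self):
        empty = make_children(0)
        assert len(cm.filter_cohort(empty, year=2010)) == 0

    def test_age_band_excludes_all(self):
        df = make_children(10, age=12)
        assert len(cm.filter_cohort(df, age_min=3, age_max=6)) == 0

    def test_invalid_age_range(self):
        with pytest.raises(ValueError):
            cm.filter_cohort(make_children(3), age_min=6, age_max=3)

    def test_idempotent_and_commutative(self, small_cohort):
        f = cm.filter_cohort
        once = f(small_cohort, age_min=3, age_max=5)
        assert once.equals(f(once, age_min=3, age_max=5))
        ab = f(f(small_cohort, birth_class="domestic"), age_min=4, age_max=6)
        ba = f(f(small_cohort, age_min=4, age_max=6), birth_class="domestic")
        assert ab.equals(ba)

    def test_order_preserved(self, small_cohort):
        sub = cm.filter_cohort(small_cohort, age_min=3, age_max=6)
        assert list(sub.index) == sorted(sub.index)


class TestPrevalence:
    def test_exact_fraction(self):
        p = cm.prevalence(make_children(344, cases=11))
        assert (p.cases, p.n) == (11, 344)
        assert p.percent == 3.2  # 11/344 = 3.1977% -> half-up

    def test_all_sound(self):
        assert cm.prevalence(make_children(50)).percent == 0.0

    def test_empty_is_error(self):
        with pytest.raises(PrevalenceUndefinedError):
            cm.prevalence(make_children(0))

    def test_binomial_sampling_close_to_true_rate(self):
        rng = np.random.default_rng(106)
        n = 10_000
        df = make_children(n)
        df["dmfs"] = (rng.random(n) < 0.106) * 2
        assert abs(cm.prevalence(df).percent - 10.6) <= 1.0

    @given(st.integers(1, 200), st.integers(1, 200), st.integers(0, 200), st.integers(0, 200))
    def test_pooled_prevalence_between_subgroups(self, na, nb, ca, cb):
        ca, cb = min(ca, na), min(cb, nb)
        a, b = make_children(na, cases=ca), make_children(nb, cases=cb)
        pa, pb = cm.prevalence(a).proportion, cm.prevalence(b).proportion
        pooled = cm.prevalence(pd.concat([a, b], ignore_index=True)).proportion
        assert min(pa, pb) - 1e-12 <= pooled <= max(pa, pb) + 1e-12


class TestPrevalenceRatio:
    def test_printed_prevalences_give_fourfold_ratio(self):
        # 45.2% vs 10.6% ~ "around four times higher"
        a = make_children(1000, cases=452)
        b = make_children(1000, cases=106)
        r = cm.prevalence_ratio(a, b)
        assert r.ratio == pytest.approx(4.264, abs=0.01)

    def test_identical_groups(self):
        g = make_children(100, cases=36)
        r = cm.prevalence_ratio(g, g)
        assert r.ratio == 1.0
        assert r.p_value == pytest.approx(1.0)

    def test_chi_square_matches_closed_form(self):
        # 2x2 table (36/100 vs 11/100): X2 = N(ad-bc)^2 / (r1 r2 c1 c2)
        a, b = make_children(100, cases=36), make_children(100, cases=11)
        chi2_hand = 200 * (36 * 89 - 64 * 11) ** 2 / (100 * 100 * 47 * 153)
        assert chi2_hand == pytest.approx(17.3828, abs=1e-4)
        r = cm.prevalence_ratio(a, b)
        assert r.p_value == pytest.approx(stats.chi2.sf(chi2_hand, 1), rel=1e-9)

    def test_zero_denominator_flags_infinite(self):
        r = cm.prevalence_ratio(make_children(50, cases=5), make_children(50, cases=0))
        assert r.infinite and np.isinf(r.ratio)


class TestExpectedCounts:
    def test_single_parish_identity(self):
        counts = cm.expected_counts(make_children(80, cases=8))
        assert len(counts) == 1
        assert counts.loc[0, "expected"] == pytest.approx(counts.loc[0, "observed"])
        assert counts.loc[0, "smr"] == pytest.approx(1.0)

    def test_two_parish_symmetry(self):
        # equal size, equal sex mix, cases 4 and 0 -> E = 2 and 2
        df = pd.concat(
            [make_children(40, cases=4, parish="A"), make_children(40, cases=0, parish="B")],
            ignore_index=True,
        )
        counts = cm.expected_counts(df).set_index("parish_id")
        assert counts.loc["A", "expected"] == pytest.approx(2.0)
        assert counts.loc["B", "expected"] == pytest.approx(2.0)
        assert counts.loc["A", "smr"] == pytest.approx(2.0)
        assert counts.loc["B", "smr"] == pytest.approx(0.0)

    def test_matches_per_child_brute_force(self, rng):
        # 5 parishes, unequal sex mixes: E_i = sum over children of r_{sex}
        frames = []
        for i, (n, cases) in enumerate([(30, 3), (55, 9), (70, 2), (25, 6), (90, 10)]):
            df = make_children(n, cases=cases, parish=f"P{i}")
            df["sex"] = np.where(rng.random(n) < 0.3 + 0.1 * i, "M", "F")
            frames.append(df)
        pop = pd.concat(frames, ignore_index=True)
        rates = {
            s: (g["dmfs"] > 0).mean() for s, g in pop.groupby("sex")
        }
        expected_oracle = (
            pop.assign(r=pop["sex"].map(rates)).groupby("parish_id")["r"].sum()
        )
        counts = cm.expected_counts(pop).set_index("parish_id")
        for p in expected_oracle.index:
            assert counts.loc[p, "expected"] == pytest.approx(expected_oracle[p])

    def test_internal_standardization_conserves_totals(self, small_cohort):
        counts = cm.expected_counts(cm.filter_cohort(small_cohort, birth_class="domestic"))
        assert counts["expected"].sum() == pytest.approx(counts["observed"].sum(), rel=1e-9)
        assert (counts["observed"] <= counts["n_children"]).all()

    def test_missing_stratum_named(self):
        with pytest.raises(ValueError, match="X"):
            cm.expected_counts(make_children(20, cases=2), sex_levels=["M", "F", "X"])


def test_records_from_rows_validates():
    recs = records_from_rows(
        [
            dict(child_id="a", exam_year=2010, age=4, sex="F", parish_id="P1",
                 birth_class="domestic", dmfs=0),
            dict(child_id="b", exam_year=2010, age=25, sex="F", parish_id="P1",
                 birth_class="domestic", dmfs=0),  # age out of range
        ]
    )
    assert len(recs) == 1
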