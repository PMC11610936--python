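"""Normalization, fold-change, calling, region aggregation, and the two
condition-comparison statistics, checked against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

import tracterm as tt
from tracterm.differential import (
    ConcordanceResult,
    body_downstream_fc_correlation,
    call_stabilized_ends,
    end_position_concordance,
    filter_calls_to_regions,
    log2_ratio_track,
    normalize_cpm,
    region_rpkm,
    region_signal,
    select_flank_stabilized_tus,
    tu_regions,
)
from tracterm.io import EndProfile, TUAnnotation

from conftest import make_profile


class TestNormalization:
    def test_cpm_unit_definition(self):
        prof = make_profile(size=2_000_000, plus={10: 5, 20: 999_995})
        cpm = normalize_cpm(prof)
        assert cpm[("chrS", "+")][10] == pytest.approx(5.0)

    def test_region_rpkm_formula(self):
        prof = make_profile(size=1_100_000, plus={i: 1 for i in range(100)},
                            minus={500: 999_900})
        assert region_rpkm(prof, "chrS", "+", 0, 1000) == pytest.approx(100.0)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="zero library"):
            normalize_cpm(make_profile())


class TestLog2Ratio:
    def test_identical_samples_give_zero(self):
        a = make_profile(plus={10: 4, 50: 9}, sample_id="a")
        b = make_profile(plus={10: 4, 50: 9}, sample_id="b")
        fc = log2_ratio_track(a, b)
        arr = fc.array("chrS", "+")
        assert np.allclose(arr[[10, 50]], 0.0)
        assert np.isnan(arr[11])  # uncovered positions undefined

    def test_closed_form_value(self):
        # cpm_t = 3, cpm_c = 0 at one position, pc = 1 -> log2(4/1) = 2
        t = make_profile(size=2_000_000, plus={10: 3, 999: 999_997},
                         sample_id="t")
        c = make_profile(size=2_000_000, plus={999: 1_000_000}, sample_id="c")
        fc = log2_ratio_track(t, c, pseudocount=1.0)
        assert fc.array("chrS", "+")[10] == pytest.approx(2.0)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(0)
        pos = rng.choice(1000, 50, replace=False)
        t = make_profile(plus={int(p): int(rng.integers(1, 30)) for p in pos[:30]},
                         sample_id="t")
        c = make_profile(plus={int(p): int(rng.integers(1, 30)) for p in pos[20:]},
                         sample_id="c")
        ab = log2_ratio_track(t, c).array("chrS", "+")
        ba = log2_ratio_track(c, t).array("chrS", "+")
        covered = ~np.isnan(ab)
        np.testing.assert_allclose(ab[covered], -ba[covered], atol=1e-12)

    def test_mismatched_epap_pairing_rejected(self):
        t = make_profile(epap=True, plus={1: 1})
        c = make_profile(epap=False, plus={1: 1})
        with pytest.raises(ValueError, match="EPAP"):
            log2_ratio_track(t, c)

    def test_library_scaling_invariance(self):
        """Scaling both libraries by the same factor leaves CPM log2fc unchanged."""
        t = make_profile(plus={10: 8, 20: 2}, sample_id="t")
        c = make_profile(plus={10: 1, 20: 2}, sample_id="c")
        t3 = make_profile(plus={10: 24, 20: 6}, sample_id="t3")
        c3 = make_profile(plus={10: 3, 20: 6}, sample_id="c3")
        a = log2_ratio_track(t, c).array("chrS", "+")
        b = log2_ratio_track(t3, c3).array("chrS", "+")
        np.testing.assert_allclose(a[[10, 20]], b[[10, 20]])


class TestCalling:
    def test_identical_samples_give_empty_set(self):
        a = make_profile(plus={10: 4}, sample_id="a")
        b = make_profile(plus={10: 4}, sample_id="b")
        assert len(call_stabilized_ends(a, b)) == 0

    def test_arithmetic_example_called(self):
        # equal library sizes of 1e6 make count == CPM; log2(9/2) ~ 2.17 >= 1
        t = make_profile(size=1_000_001, plus={10: 8, 20: 999_992},
                         sample_id="t")
        c = make_profile(size=1_000_001, plus={10: 1, 20: 999_999},
                         sample_id="c")
        calls = call_stabilized_ends(t, c, min_log2=1.0)
        hit = calls.calls[calls.calls.pos == 10]
        assert len(hit) == 1
        assert hit.log2fc.iloc[0] == pytest.approx(np.log2(9 / 2), rel=1e-6)

    def test_planted_positions_recovered_exactly(self):
        """10 stabilized + 10 unchanged positions -> exactly the 10 planted."""
        planted = {100 + 7 * i: 40 for i in range(10)}
        unchanged = {500 + 11 * i: 40 for i in range(10)}
        t = make_profile(size=2000, plus={**planted, **unchanged}, sample_id="t")
        c = make_profile(size=2000,
                         plus={**{p: 5 for p in planted}, **unchanged},
                         sample_id="c")
        calls = call_stabilized_ends(t, c, min_log2=1.0)
        # brute-force per-position oracle
        lib_t, lib_c = t.library_size, c.library_size
        expected = sorted(
            p for p in {**planted, **unchanged}
            if np.log2((t.array("chrS", "+")[p] * 1e6 / lib_t + 1)
                       / (c.array("chrS", "+")[p] * 1e6 / lib_c + 1)) >= 1.0
        )
        assert sorted(calls.calls.pos) == expected == sorted(planted)

    def test_negative_min_log2_rejected(self):
        t = make_profile(plus={1: 1}, sample_id="t")
        c = make_profile(plus={1: 1}, sample_id="c")
        with pytest.raises(ValueError):
            call_stabilized_ends(t, c, min_log2=-1)


class TestRegionSignal:
    @pytest.fixture()
    def three_tu_fixture(self):
        tus = [
            TUAnnotation("tuA", "chrS", 100, 300, "+", "mono_nc", 1),
            TUAnnotation("tuB", "chrS", 600, 800, "-", "mono_nc", 1),
            TUAnnotation("tuC", "chrS", 1200, 1400, "+", "short_coding", 2),
        ]
        t = make_profile(
            size=2000, sample_id="t",
            plus={150: 10, 310: 20, 1250: 4},  # tuA body+down, tuC body
            minus={700: 6, 580: 8},            # tuB body + downstream(left)
        )
        c = make_profile(
            size=2000, sample_id="c",
            plus={150: 10, 310: 5, 1250: 4},
            minus={700: 6, 580: 2},
        )
        return tus, t, c

    def test_hand_summed_values(self, three_tu_fixture):
        tus, t, c = three_tu_fixture
        table = region_signal(t, c, tus, downstream_window=50).table
        row_a = table[table.tu_id == "tuA"].iloc[0]
        assert (row_a.body_raw_t, row_a.down_raw_t) == (10, 20)
        row_b = table[table.tu_id == "tuB"].iloc[0]
        # minus-strand downstream window is [start-50, start) in ref coords
        assert (row_b.body_raw_t, row_b.down_raw_t) == (6, 8)
        row_c = table[table.tu_id == "tuC"].iloc[0]
        assert (row_c.body_raw_t, row_c.down_raw_t) == (4, 0)

    def test_counts_inside_body_leave_downstream_zero(self, three_tu_fixture):
        tus, t, c = three_tu_fixture
        table = region_signal(t, c, [tus[2]], downstream_window=100).table
        assert table.down_raw_t.iloc[0] == 0

    def test_nonpositive_window_rejected(self, three_tu_fixture):
        tus, t, c = three_tu_fixture
        with pytest.raises(ValueError):
            region_signal(t, c, tus, downstream_window=0)


class TestTUSelection:
    def _table(self, rows):
        from tracterm.differential import RegionSignalTable
        return RegionSignalTable(pd.DataFrame(rows), 3000, 1.0)

    def test_flank_only_selected(self):
        rows = (
            [dict(tu_id=f"flank{i}", body_log2=0.1, down_log2=2.0)
             for i in range(5)]
            + [dict(tu_id=f"both{i}", body_log2=2.0, down_log2=2.0)
               for i in range(5)]
            + [dict(tu_id=f"none{i}", body_log2=0.0, down_log2=0.0)
               for i in range(5)]
        )
        got = select_flank_stabilized_tus(self._table(rows), 1.5, 0.5)
        assert got == [f"flank{i}" for i in range(5)]

    def test_infinite_flank_threshold_selects_nothing(self):
        rows = [dict(tu_id="a", body_log2=0.0, down_log2=5.0)]
        assert select_flank_stabilized_tus(self._table(rows),
                                           float("inf"), 0.5) == []

    def test_permissive_thresholds_select_any_positive_flank(self):
        rows = [dict(tu_id="a", body_log2=9.0, down_log2=0.4),
                dict(tu_id="b", body_log2=9.0, down_log2=-0.1)]
        got = select_flank_stabilized_tus(self._table(rows), 0.0, float("inf"))
        assert got == ["a"]


def _calls_from_positions(positions, strand="+", chrom="chrS"):
    from tracterm.differential import EndCallSet
    df = pd.DataFrame(
        dict(chrom=chrom, pos=sorted(positions), strand=strand,
             treat_count=1, ctrl_count=0, log2fc=2.0)
    )
    return EndCallSet(df, 1.0, 1, 1.0)


class TestConcordance:
    def test_self_comparison_is_100(self):
        a = _calls_from_positions([5, 10, 999])
        res = end_position_concordance(a, a)
        assert res.symmetric == 100.0

    def test_disjoint_sets_give_zero(self):
        a = _calls_from_positions([5, 10])
        b = _calls_from_positions([100, 200])
        assert end_position_concordance(a, b, tolerance=5).symmetric == 0.0

    def test_tolerance_window(self):
        a = _calls_from_positions([100])
        b = _calls_from_positions([104])
        assert end_position_concordance(a, b, tolerance=5).symmetric == 100.0
        assert end_position_concordance(a, b, tolerance=3).symmetric == 0.0

    def test_strand_mismatch_never_matches(self):
        a = _calls_from_positions([100], strand="+")
        b = _calls_from_positions([100], strand="-")
        assert end_position_concordance(a, b).symmetric == 0.0

    def test_random_sets_match_analytic_expectation(self):
        """E[%] = 100*(1-(1-11/1e6)^100) ~ 0.1099 for 100 vs 100 points, tol 5."""
        rng = np.random.default_rng(12345)
        n_rep = 400
        vals = []
        for _ in range(n_rep):
            a = _calls_from_positions(
                rng.choice(10**6, 100, replace=False).tolist())
            b = _calls_from_positions(
                rng.choice(10**6, 100, replace=False).tolist())
            vals.append(end_position_concordance(a, b, tolerance=5).a_in_b)
        mean = float(np.mean(vals))
        expected = 100 * (1 - (1 - 11 / 1e6) ** 100)
        se = float(np.std(vals, ddof=1) / np.sqrt(n_rep))
        assert abs(mean - expected) < 4 * se + 1e-9


class TestBodyDownstreamCorrelation:
    def _table(self, body, down):
        from tracterm.differential import RegionSignalTable
        return RegionSignalTable(
            pd.DataFrame(dict(tu_id=[f"t{i}" for i in range(len(body))],
                              body_log2=body, down_log2=down)),
            3000, 1.0,
        )

    def test_perfect_positive_and_negative(self):
        body = [0.1, 0.5, 1.0, 2.0]
        assert body_downstream_fc_correlation(
            self._table(body, body)) == pytest.approx(1.0)
        assert body_downstream_fc_correlation(
            self._table(body, [-b for b in body])) == pytest.approx(-1.0)

    def test_too_few_tus_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            body_downstream_fc_correlation(self._table([1, 2], [1, 2]))

    def test_uniform_flux_increase_gives_high_correlation(self, default_bundle):
        """dINT raises occupancy over snRNA bodies and downstream regions
        together (a flux change, not a termination defect)."""
        from tracterm.io import load_manifest, read_annotation

        ss = load_manifest(default_bundle / "manifest.yaml")
        tus = read_annotation(ss.annotation_path)
        short = [tu for tu in tus if tu.biotype in ("snRNA_like", "rdh_like",
                                                    "mono_nc")]
        t = ss["dINT.as.noEPAP"].profile
        c = ss["CTRL.as.noEPAP"].profile
        table = region_signal(t, c, short, downstream_window=1000)
        r = body_downstream_fc_correlation(table)
        assert r > 0.5


class TestCallRegionFiltering:
    def test_region_and_strand_filter(self):
        calls = _calls_from_positions([10, 50, 90])
        sub = filter_calls_to_regions(calls, [("chrS", 40, 60, "+")])
        assert sub.calls.pos.tolist() == [50]
        sub2 = filter_calls_to_regions(calls, [("chrS", 40, 60, "-")])
        assert len(sub2) == 0

    def test_tu_regions_span_strand_aware(self):
        minus = TUAnnotation("b", "c", 1000, 2000, "-", "mono_nc", 1)
        ((chrom, s, e, strand),) = tu_regions([minus], "span", 300)
        assert (s, e) == (700, 2000) and strand == "-"


class TestLastDetectedPosition:
    def test_most_three_prime_position_above_floor(self):
        from tracterm.differential import last_detected_position

        prof = make_profile(size=20000, sample_id="p",
                            plus={i: 50 for i in range(1000, 1200)})
        tu = TUAnnotation("a", "chrS", 1000, 1100, "+", "mono_nc", 1)
        pos = last_detected_position(prof, tu, max_downstream=5000,
                                     floor_cpm=0.1)
        # smoothing extends detection ~half a window past the last covered base
        assert 1190 <= pos <= 1210

    def test_none_when_everything_below_floor(self):
        from tracterm.differential import last_detected_position

        prof = make_profile(size=20000, sample_id="p", plus={1: 1, 19999: 10**6})
        tu = TUAnnotation("a", "chrS", 1000, 1100, "+", "mono_nc", 1)
        assert last_detected_position(prof, tu, floor_cpm=5.0) is None
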