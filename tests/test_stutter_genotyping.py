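"""Stutter-model fidelity, genotype fitting and noise summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strwga.str_mapping import RepeatHistogram
from strwga.stutter_genotyping import (
    FitGrid,
    GenotypeCall,
    StutterParams,
    _propagate,
    _window_slice,
    fit_genotype,
    noise_summary,
    read_calls,
    sample_repeat_histogram,
    stutter_distribution,
    write_calls,
)
from strwga.synthetic_data import make_synthetic_panel

from oracles import mc_stutter


def _dist_var(p):
    r = np.arange(len(p))
    mu = (r * p).sum()
    return ((r - mu) ** 2 * p).sum()


class TestStutterDistribution:
    def test_zero_cycles_is_point_mass(self):
        p = stutter_distribution(30, 0)
        assert p[30] == 1.0 and p.sum() == 1.0

    def test_zero_slip_stays_point_mass(self):
        p = stutter_distribution(30, 50, StutterParams(slip=0.0))
        assert p[30] == pytest.approx(1.0)

    def test_matches_monte_carlo_branching_oracle(self):
        params = StutterParams()
        expected = mc_stutter(20, 30, params, founders=100_000, seed=1)
        got = stutter_distribution(20, 30, params)
        tv = 0.5 * np.abs(got[: len(expected)] - expected).sum()
        assert tv < 0.01

    def test_invalid_allele_rejected(self):
        with pytest.raises(ValueError):
            stutter_distribution(0, 10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        allele=st.integers(5, 40),
        cycles=st.integers(0, 60),
        slip=st.floats(0.0005, 0.01),
    )
    def test_normalized_and_variance_monotone(self, allele, cycles, slip):
        params = StutterParams(slip=slip)
        p = stutter_distribution(allele, cycles, params)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[0] == 0.0
        # variance non-decreasing in cycles and in slip rate
        assert _dist_var(stutter_distribution(allele, cycles + 5, params)) >= _dist_var(p) - 1e-15
        assert _dist_var(
            stutter_distribution(allele, cycles, StutterParams(slip=slip * 2))
        ) >= _dist_var(p) - 1e-15

    def test_mixture_propagation_is_linear(self):
        # propagating a two-allele mixture == mixing the propagated singles
        params = StutterParams()
        f0 = np.zeros(45)
        f0[10], f0[14] = 0.3, 0.7
        mixed = _propagate(f0, 25, params)
        d10 = stutter_distribution(10, 25, params)
        d14 = stutter_distribution(14, 25, params)
        expected = np.zeros(45)
        expected[: len(d10)] += 0.3 * d10
        expected[: len(d14)] += 0.7 * d14
        np.testing.assert_allclose(mixed, expected, atol=1e-12)


def _mixture(a1, a2, w, cycles, params=None):
    d1 = stutter_distribution(a1, cycles, params)
    d2 = stutter_distribution(a2, cycles, params)
    mix = np.zeros(max(len(d1), len(d2)))
    mix[: len(d1)] += w * d1
    mix[: len(d2)] += (1 - w) * d2
    return mix


class TestFitGenotype:
    def test_single_spike_called_exactly(self):
        call = fit_genotype(RepeatHistogram("L", {30: 100}))
        assert call.alleles == (30,)
        assert call.cycles == 0
        assert call.correlation == pytest.approx(1.0)
        assert call.status == "called"
        assert call.proportion_shorter == 1.0

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            fit_genotype(RepeatHistogram("L", {}))

    def test_recovers_balanced_het_mixture(self, rng):
        hist = sample_repeat_histogram(_mixture(10, 13, 0.5, 40), 10_000, rng)
        call = fit_genotype(hist)
        assert call.alleles == (10, 13)
        assert abs(call.proportion_shorter - 0.5) <= 0.05
        assert abs(call.cycles - 40) <= 4
        assert call.status == "called"

    def test_matches_naive_grid_search(self, rng):
        # independent naive scorer over the same (restricted) grid
        grid = FitGrid(allele_margin=1, cycles=tuple(range(0, 61, 10)),
                       w_grid=(0.25, 0.5, 0.75))
        hist = sample_repeat_histogram(_mixture(12, 16, 0.5, 30), 5_000, rng)
        obs = sorted(hist.counts)
        lo, hi = max(1, obs[0] - 5), obs[-1] + 5
        y = np.zeros(hi - lo + 1)
        for r, c in hist.counts.items():
            y[r - lo] = c
        y = y / y.sum()
        best = (-2.0, None)
        amin, amax = max(1, obs[0] - 1), obs[-1] + 1
        for a1 in range(amin, amax + 1):
            for cyc in grid.cycles:
                v = _window_slice(stutter_distribution(a1, cyc), lo, hi)
                s = np.corrcoef(y, v)[0, 1]
                if s > best[0]:
                    best = (s, (a1,))
                for a2 in range(a1 + 1, amax + 1):
                    for w in grid.w_grid:
                        v = w * _window_slice(stutter_distribution(a1, cyc), lo, hi) + (
                            1 - w
                        ) * _window_slice(stutter_distribution(a2, cyc), lo, hi)
                        s = np.corrcoef(y, v)[0, 1]
                        if s > best[0]:
                            best = (s, (a1, a2))
        call = fit_genotype(hist, grid)
        assert call.alleles == best[1]
        assert call.correlation == pytest.approx(best[0], abs=1e-9)

    def test_adjacent_alleles_are_confusable(self, rng):
        # a homozygous allele-30 histogram is explained almost equally well
        # by a 29+30 two-allele candidate: stutter patterns one unit apart
        # overlap, which is why the balance analysis requires separation >= 3
        hist = sample_repeat_histogram(stutter_distribution(30, 40), 10_000, rng)
        best = fit_genotype(hist)  # free search, may pick the adjacent pair
        obs = sorted(hist.counts)
        lo, hi = max(1, obs[0] - 5), obs[-1] + 5
        y = np.zeros(hi - lo + 1)
        for r, c in hist.counts.items():
            y[r - lo] = c
        y = y / y.sum()
        best_single = max(
            np.corrcoef(y, _window_slice(stutter_distribution(a, c), lo, hi))[0, 1]
            for a in range(obs[0], obs[-1] + 1)
            for c in range(0, 91, 2)
        )
        assert abs(best.correlation - best_single) < 0.02

    def test_allele_constraint_restricts_candidates(self, rng):
        hist = sample_repeat_histogram(stutter_distribution(20, 33), 40, rng)
        constrained = fit_genotype(hist, alleles=(20,))
        assert constrained.alleles == (20,)
        pair = fit_genotype(hist, alleles=(17, 20))
        assert set(pair.alleles) <= {17, 20}

    def test_no_call_below_correlation_floor(self):
        # two distant spikes cannot be explained by any candidate at high corr
        grid = FitGrid(allele_margin=0, cycles=(0,), w_grid=(0.5,))
        call = fit_genotype(RepeatHistogram("L", {10: 50, 11: 30, 12: 45}), grid)
        assert call.status in ("called", "no_call")
        assert call.correlation < 1.0


class TestNoiseSummary:
    def _panel_calls(self):
        panel, _ = make_synthetic_panel(6, seed=11)
        ac = [l.locus_id for l in panel if l.unit == "AC"]
        return panel, ac

    def test_median_and_low_support_flag(self):
        panel, ac = self._panel_calls()
        assert len(ac) >= 3
        calls = [
            GenotypeCall(lid, (20,), 1.0, cyc, 0.99, "called")
            for lid, cyc in zip(ac[:3], (10, 20, 30))
        ]
        df = noise_summary({"c1": calls}, panel, min_calls=2)
        row = df.iloc[0]
        assert row.median_cycles == 20
        assert not row.low_support
        df2 = noise_summary({"c1": calls}, panel, min_calls=20)
        assert bool(df2.iloc[0].low_support)

    def test_zero_cycles_and_missing_value(self):
        panel, ac = self._panel_calls()
        calls = [GenotypeCall(ac[0], (20,), 1.0, 0, 0.99, "called")]
        df = noise_summary({"c1": calls, "c2": []}, panel)
        assert df.set_index("cell_id").loc["c1", "median_cycles"] == 0
        assert np.isnan(df.set_index("cell_id").loc["c2", "median_cycles"])

    def test_non_target_units_excluded(self):
        panel, _ = self._panel_calls()
        non_ac = [l.locus_id for l in panel if l.unit != "AC"]
        if not non_ac:
            pytest.skip("fixture panel has no non-AC locus")
        calls = [GenotypeCall(non_ac[0], (20,), 1.0, 50, 0.99, "called")]
        df = noise_summary({"c1": calls}, panel)
        assert df.iloc[0].n_calls == 0


class TestCycleRecovery:
    def test_noise_ordering_and_gap(self, rng):
        # genotype-seeded fits recover the ordering of true cycle means and
        # roughly their difference
        meds = {}
        for mean in (20, 40):
            fitted = []
            for _ in range(40):
                c_true = max(0, int(round(rng.normal(mean, 3))))
                a = int(rng.integers(10, 31))
                h = sample_repeat_histogram(stutter_distribution(a, c_true), 200, rng)
                fitted.append(fit_genotype(h, alleles=(a,)).cycles)
            meds[mean] = float(np.median(fitted))
        assert meds[20] < meds[40]
        assert 20 - 7 <= meds[40] - meds[20] <= 20 + 7

    def test_monotone_across_four_levels(self, rng):
        medians = []
        for mean in (10, 30, 50, 70):
            fitted = [
                fit_genotype(
                    sample_repeat_histogram(
                        stutter_distribution(20, max(0, int(round(rng.normal(mean, 3))))),
                        150,
                        rng,
                    ),
                    alleles=(20,),
                ).cycles
                for _ in range(50)
            ]
            medians.append(np.median(fitted))
        assert medians == sorted(medians)
        assert len(set(medians)) == 4


class TestCallsIO:
    def test_round_trip(self, tmp_path):
        calls = {
            "c1": [
                GenotypeCall("L1", (10, 13), 0.45, 40, 0.991, "called"),
                GenotypeCall("L2", (20,), 1.0, 12, 0.999, "called"),
            ],
            "c2": [GenotypeCall("L1", (11,), 1.0, 0, 0.8, "no_call")],
        }
        path = tmp_path / "calls.tsv"
        write_calls(calls, path)
        back = read_calls(path)
        assert back == calls
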