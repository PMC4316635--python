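"""Rates, SEs, spectra, ratio tests, expected-ratio calculations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mutline import (SPECTRUM_CLASSES, conditional_spectrum,
                     compare_region_spectra, expected_coding_intergenic_ratio,
                     expected_ns_ratio, goodness_of_fit_1df,
                     odds_ratio_logit_test, poisson_rate_ci, pooled_se,
                     substitution_class, substitution_rate, ts_tv_ratio)

BASES = "ACGT"

# printed six-class counts of the mutator MA experiment
CLASS_COUNTS = {"AT->GC": 14886, "GC->AT": 15445, "AT->TA": 95,
                "AT->CG": 90, "GC->TA": 414, "GC->CG": 176}


class TestSubstitutionRate:
    def test_zero_calls(self):
        est = substitution_rate(0, 1000.0, 100.0, 5)
        assert est.rate == 0.0 and est.se == 0.0

    def test_calls_frame_per_line_accounting(self):
        calls = pd.DataFrame({"line_id": ["a"] * 3 + ["b"],
                              "ref": ["A"] * 4, "alt": ["G"] * 4})
        est = substitution_rate(calls, 100.0, 10.0, line_ids=["a", "b"])
        assert est.mutation_count == 4
        assert est.rate == pytest.approx(4 / (2 * 100 * 10))
        np.testing.assert_allclose(est.per_line_rates,
                                   [3 / 1000, 1 / 1000])

    def test_rate_times_exposure_recovers_count(self, rng):
        counts = rng.integers(0, 50, size=8)
        est = substitution_rate(counts, 5000.0, 120.0, 8)
        assert est.rate * est.exposure == pytest.approx(counts.sum())

    def test_invariant_to_line_relabeling(self, rng):
        counts = rng.integers(0, 50, size=8).astype(float)
        a = substitution_rate(counts, 5000.0, 120.0, 8)
        b = substitution_rate(counts[::-1].copy(), 5000.0, 120.0, 8)
        assert a.rate == b.rate and a.se == b.se

    def test_estimator_consistency_on_simulated_truth(self):
        """Mean of the estimate over seeded runs lies within 2 pooled SEs."""
        from mutline import SimulationConfig, generate_genome, simulate_ma
        mu, T, L, N = 2e-6, 1000.0, 50_000, 5
        rates, se = [], None
        for seed in range(20):
            cfg = SimulationConfig(genome_length=L, n_lines=N, seed=seed,
                                   base_sub_rate=mu, generations=T,
                                   indel_rate=0.0, topology_amplitude=0.0,
                                   context_multipliers=np.ones(64))
            g, ann = generate_genome(cfg)
            truth = simulate_ma(g, ann, cfg)
            est = substitution_rate(truth.substitutions, float(L), T,
                                    line_ids=cfg.line_ids())
            rates.append(est.rate)
            se = est.se
        # mean over 20 runs: its SE is pooled SE / sqrt(20); 2 pooled SEs is
        # a generous envelope for the run-mean
        assert abs(np.mean(rates) - mu) < 2 * se


class TestPooledSE:
    def test_zero_rates(self):
        assert pooled_se([0.0, 0.0], [100.0, 100.0]) == 0.0

    def test_matches_parametric_bootstrap(self, rng):
        N, exposure, u = 10, 1e7, 1e-5
        formula = pooled_se(np.full(N, u), np.full(N, exposure))
        boots = rng.poisson(u * exposure, size=(4000, N)).sum(axis=1) / \
            (N * exposure)
        assert abs(formula - boots.std()) / boots.std() < 0.2


class TestSpectrum:
    def test_printed_counts_give_gc_at_fraction(self):
        spec = conditional_spectrum(CLASS_COUNTS, 0.6071,
                                    0.9870 * 5_720_000, 45, 5240.0)
        assert spec.table.loc["GC->AT", "fraction"] == pytest.approx(
            0.496, abs=1e-3)
        assert spec.total == 31106

    def test_single_class(self):
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        counts["AT->GC"] = 10
        spec = conditional_spectrum(counts, 0.5, 1000.0, 2, 10.0)
        assert spec.table.loc["AT->GC", "fraction"] == 1.0

    def test_rates_times_exposures_resum_to_counts(self):
        spec = conditional_spectrum(CLASS_COUNTS, 0.6071, 1e6, 45, 5240.0)
        for cls in SPECTRUM_CLASSES:
            frac = (1 - 0.6071) if cls.startswith("AT") else 0.6071
            exposure = 1e6 * frac * 45 * 5240.0
            assert spec.table.loc[cls, "rate"] * exposure == pytest.approx(
                CLASS_COUNTS[cls])

    def test_class_mapping(self):
        assert substitution_class("G", "A") == "GC->AT"
        assert substitution_class("C", "T") == "GC->AT"
        assert substitution_class("A", "G") == "AT->GC"
        assert substitution_class("A", "T") == "AT->TA"
        assert substitution_class("G", "C") == "GC->CG"
        assert substitution_class("G", "T") == "GC->TA"

    def test_simulated_ts_tv_within_multinomial_interval(self):
        from mutline import SimulationConfig, generate_genome, simulate_ma
        cfg = SimulationConfig(genome_length=200_000, n_lines=10, seed=17,
                               base_sub_rate=2e-6, indel_rate=0.0,
                               topology_amplitude=0.0,
                               context_multipliers=np.ones(64))
        g, ann = generate_genome(cfg)
        truth = simulate_ma(g, ann, cfg)
        ratio, ts, tv = ts_tv_ratio(truth.substitutions)
        n = ts + tv
        p = 39.14 / 40.14
        lo, hi = sps.binom.interval(0.95, n, p)
        assert lo <= ts <= hi


class TestTsTv:
    def test_printed_counts(self):
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        counts.update({"AT->GC": 14886, "GC->AT": 15445, "AT->TA": 95,
                       "AT->CG": 90, "GC->TA": 414, "GC->CG": 176})
        ratio, ts, tv = ts_tv_ratio(counts)
        assert (ts, tv) == (30331, 775)
        assert ratio == pytest.approx(39.14, abs=5e-3)

    def test_equal_counts(self):
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        counts.update({"AT->GC": 3, "GC->AT": 3, "AT->TA": 2, "GC->TA": 4})
        assert ts_tv_ratio(counts)[0] == 1.0

    def test_zero_transversions_signaled(self):
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        counts["AT->GC"] = 5
        with pytest.raises(ZeroDivisionError):
            ts_tv_ratio(counts)

    def test_random_spectra_match_direct_quotient(self, rng):
        for _ in range(200):
            counts = {c: int(k) for c, k in
                      zip(SPECTRUM_CLASSES, rng.integers(0, 500, 6))}
            ts = counts["AT->GC"] + counts["GC->AT"]
            tv = sum(v for c, v in counts.items()
                     if c not in ("AT->GC", "GC->AT"))
            if tv == 0:
                continue
            assert ts_tv_ratio(counts)[0] == ts / tv


class TestOddsRatioLogit:
    def test_symmetric_inputs(self):
        res = odds_ratio_logit_test(50, 50, 1000, 1000)
        assert res.ln_or == 0.0
        assert res.one_sided_p == pytest.approx(0.5)

    def test_zero_cell_signaled(self):
        with pytest.raises(ValueError):
            odds_ratio_logit_test(0, 50, 1000, 1000)

    def test_se_matches_multinomial_bootstrap(self, rng):
        pi1, pi2, n1, n2 = 30, 20, 1000, 1000
        res = odds_ratio_logit_test(pi1, pi2, n1, n2)
        b1 = rng.binomial(n1, pi1 / n1, size=5000)
        b2 = rng.binomial(n2, pi2 / n2, size=5000)
        ok = (b1 > 0) & (b2 > 0) & (b1 < n1) & (b2 < n2)
        lnors = np.log((b1[ok] / n1) / (b2[ok] / n2))
        assert abs(res.se_ln_or - lnors.std()) / lnors.std() < 0.1

    def test_directional_alternatives(self):
        res_less = odds_ratio_logit_test(30, 60, 1000, 1000,
                                         alternative="less")
        res_greater = odds_ratio_logit_test(30, 60, 1000, 1000,
                                            alternative="greater")
        assert res_less.one_sided_p < 0.05 < res_greater.one_sided_p
        assert res_less.one_sided_p + res_greater.one_sided_p == \
            pytest.approx(1.0)


def _brute_ns_enumeration(usage, rates):
    """Direct enumeration of all 576 codon changes via Biopython."""
    from Bio.Seq import Seq
    w_non = w_syn = 0.0
    for codon, freq in usage.items():
        aa = str(Seq(codon).translate(table=11))
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1:]
                w = freq * rates[substitution_class(codon[pos], alt)]
                if str(Seq(mutant).translate(table=11)) == aa:
                    w_syn += w
                else:
                    w_non += w
    return w_non / w_syn


class TestExpectedNSRatio:
    CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]

    def test_uniform_matches_genetic_code_constant(self):
        usage = {c: 1 / 64 for c in self.CODONS}
        rates = dict.fromkeys(SPECTRUM_CLASSES, 1.0)
        assert expected_ns_ratio(usage, rates) == pytest.approx(
            _brute_ns_enumeration(usage, rates), rel=1e-12)

    def test_single_codon_usage(self):
        usage = {"GGC": 1.0}
        rates = dict.fromkeys(SPECTRUM_CLASSES, 1.0)
        got = expected_ns_ratio(usage, rates)
        # GGC (Gly): 3rd-position changes are synonymous (GGx all Gly),
        # all 1st/2nd-position changes are nonsynonymous -> 6:3
        assert got == pytest.approx(2.0)

    def test_random_usage_and_spectrum_match_enumeration(self, rng):
        freqs = rng.dirichlet(np.ones(64))
        usage = dict(zip(self.CODONS, freqs))
        rates = {c: float(r) for c, r in
                 zip(SPECTRUM_CLASSES, rng.uniform(0.1, 5.0, 6))}
        assert expected_ns_ratio(usage, rates) == pytest.approx(
            _brute_ns_enumeration(usage, rates), rel=1e-12)

    def test_degenerate_spectrum_signaled(self):
        usage = {c: 1 / 64 for c in self.CODONS}
        with pytest.raises(ValueError):
            expected_ns_ratio(usage, dict.fromkeys(SPECTRUM_CLASSES, 0.0))


class TestGoodnessOfFit:
    def test_exact_expectation(self):
        chi2, p = goodness_of_fit_1df(60, 40, 1.5)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        chi2, p = goodness_of_fit_1df(60, 40, 1.0)
        assert chi2 == pytest.approx(4.0)

    def test_matches_monte_carlo_p(self, rng):
        a, b = 320, 280
        chi2_obs, p = goodness_of_fit_1df(a, b, 1.0)
        n = a + b
        draws = rng.binomial(n, 0.5, size=100_000)
        stat = (draws - n / 2) ** 2 / (n / 2) + \
            ((n - draws) - n / 2) ** 2 / (n / 2)
        p_mc = (stat >= chi2_obs - 1e-9).mean()
        assert abs(p - p_mc) < 0.02


class TestPoissonCI:
    def test_zero_count_lower_bound(self):
        lo, hi = poisson_rate_ci(0, 10.0)
        assert lo == 0.0 and hi > 0

    def test_matches_cdf_inversion_oracle(self):
        from scipy.optimize import brentq
        k, level = 10, 0.95
        lo, hi = poisson_rate_ci(k, 1.0, level)
        alpha = 1 - level
        lo_oracle = brentq(lambda lam: sps.poisson.sf(k - 1, lam) - alpha / 2,
                           1e-9, 100)
        hi_oracle = brentq(lambda lam: sps.poisson.cdf(k, lam) - alpha / 2,
                           1e-9, 100)
        assert lo == pytest.approx(lo_oracle, rel=1e-6)
        assert hi == pytest.approx(hi_oracle, rel=1e-6)

    def test_width_shrinks_with_count(self):
        widths = []
        for k in (5, 50, 500):
            lo, hi = poisson_rate_ci(k, float(k))   # fixed rate 1
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestRegionSpectra:
    def _calls(self, rng, rates_by_region, n_sites, T=100.0, N=5):
        rows = []
        for region, rate in rates_by_region.items():
            for cls in SPECTRUM_CLASSES:
                frac = 0.4 if cls.startswith("AT") else 0.6
                k = rng.poisson(rate * n_sites * frac * N * T)
                ref, alt = {"AT->GC": "AG", "GC->AT": "GA", "AT->TA": "AT",
                            "AT->CG": "AC", "GC->TA": "GT",
                            "GC->CG": "GC"}[cls]
                rows += [[region, ref, alt]] * k
        return pd.DataFrame(rows, columns=["region", "ref", "alt"])

    def test_equal_rates_all_cis_overlap(self, rng):
        calls = self._calls(rng, {"coding": 1e-5, "intergenic": 1e-5,
                                  "prophage": 1e-5}, 10_000)
        meta = {r: {"sites": 10_000, "gc": 0.6} for r in
                ("coding", "intergenic", "prophage")}
        _, overlap = compare_region_spectra(calls, meta, 5, 100.0)
        assert overlap["ci_overlap"].all()

    def test_halved_rate_detected(self, rng):
        calls = self._calls(rng, {"coding": 6.6e-5, "prophage": 3.3e-5},
                            50_000)
        meta = {r: {"sites": 50_000, "gc": 0.6} for r in
                ("coding", "prophage")}
        _, overlap = compare_region_spectra(calls, meta, 5, 100.0)
        ts = overlap.query("`class` in ('AT->GC', 'GC->AT')")
        assert not ts["ci_overlap"].any()

    def test_zero_mutation_region_overlaps_zero_lower_bounds(self):
        calls = pd.DataFrame(columns=["region", "ref", "alt"])
        meta = {"coding": {"sites": 1000, "gc": 0.5},
                "prophage": {"sites": 1000, "gc": 0.5}}
        _, overlap = compare_region_spectra(calls, meta, 5, 100.0)
        assert overlap["ci_overlap"].all()

    def test_zero_exposure_signaled(self):
        calls = pd.DataFrame(columns=["region", "ref", "alt"])
        with pytest.raises(ValueError):
            compare_region_spectra(calls, {"x": {"sites": 0, "gc": 0.5}},
                                   5, 100.0)


class TestCodingIntergenicRatio:
    @pytest.mark.parametrize("frac,expected", [
        (0.9153, 10.80), (0.5, 1.0), (0.75, 3.0),
    ])
    def test_examples(self, frac, expected):
        assert expected_coding_intergenic_ratio(frac) == pytest.approx(
            expected, abs=0.01)

    def test_boundaries_signaled(self):
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                expected_coding_intergenic_ratio(frac)
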