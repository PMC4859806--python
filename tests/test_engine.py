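"""Thermodynamic engine: configurations, weights, expression prediction.

The independent oracle here (`naive_predict`) enumerates configurations
with itertools and evaluates the weight and activity algebra from its
written definition, sharing no code with either package path.
"""

import itertools
import math

import numpy as np
import pytest

from enhancergram import schemes
from enhancergram.engine import (
    Configuration, GradientSet, N_POINTS, TFGradient, configuration_weight,
    predict_expression, predict_expression_fast, valid_configurations,
)
from enhancergram.motifs import BindingSite, SiteMap
from enhancergram.schemes import get_model

from conftest import random_sitemap, random_theta

SCALING_TF = {"Dorsal": "Dorsal", "Twist": "Twist", "bHLH": "Twist", "Snail": "Snail"}


def naive_predict(sitemap, theta, gradients, spec):
    """Brute-force oracle: explicit sum over subsets via itertools."""
    sites = sitemap.sites
    m = len(sites)
    overlaps = sitemap.overlap_pairs
    out = np.zeros(N_POINTS)
    for x in range(N_POINTS):
        conc = {tf: gradients.conc(tf)[x] for tf in ("Dorsal", "Twist", "Snail")}
        num = den = 0.0
        for r in range(m + 1):
            for comb in itertools.combinations(range(m), r):
                if any((i, j) in overlaps for i in comb for j in comb if i < j):
                    continue
                bound = sorted(comb)
                W = 1.0
                for i in bound:
                    s = sites[i]
                    W *= (theta[spec.slot(f"scale_{SCALING_TF[s.tf]}")]
                          * s.affinity * conc[SCALING_TF[s.tf]])
                for i, j in zip(bound[:-1], bound[1:]):
                    d = math.floor(abs(sites[i].center - sites[j].center) + 0.5)
                    cls = schemes.pair_class(sites[i].tf, sites[j].tf)
                    W *= spec.coop_factors(theta, np.array([float(d)]),
                                           np.array([cls]))[0]
                inactive = 1.0
                for pos, i in enumerate(bound):
                    if sites[i].tf == "Snail":
                        continue
                    survive = 1.0
                    for nb in ([bound[pos - 1]] if pos > 0 else []) + \
                              ([bound[pos + 1]] if pos + 1 < len(bound) else []):
                        if sites[nb].tf == "Snail":
                            d = math.floor(abs(sites[i].center - sites[nb].center) + 0.5)
                            qc = schemes.quench_class(sites[i].tf, sites[nb].tf)
                            f = spec.quench_fractions(theta, np.array([float(d)]),
                                                      np.array([qc]))[0]
                            survive *= 1.0 - f
                    inactive *= 1.0 - survive
                num += W * (1.0 - inactive)
                den += W
        out[x] = num / den
    return out


def make_map(entries, length=318):
    sites = [BindingSite(tf, start, start + L, "+", 5.0, aff, name=f"{tf}{k}")
             for k, (tf, start, L, aff) in enumerate(entries)]
    return SiteMap("toy", length, sites)


class TestConfigurations:
    def test_three_independent_sites_give_eight_states(self):
        sm = make_map([("Dorsal", 0, 10, 0.9), ("Twist", 50, 10, 0.9),
                       ("Snail", 100, 10, 0.9)])
        assert len(list(valid_configurations(sm))) == 8

    def test_two_overlapping_sites_give_three_states(self):
        sm = make_map([("Twist", 0, 10, 0.9), ("Snail", 5, 10, 0.9)])
        configs = {tuple(sorted(c.bound)) for c in valid_configurations(sm)}
        assert configs == {(), (0,), (1,)}

    def test_twelve_sites_with_one_overlap_pair(self):
        entries = [("Dorsal", i * 25, 10, 0.9) for i in range(11)]
        entries.append(("Snail", 255, 10, 0.9))  # overlaps the 11th site
        sm = make_map(entries)
        assert len(sm.overlap_pairs) == 2  # one pair, stored symmetrically
        n = sum(1 for _ in valid_configurations(sm))
        assert n == 2 ** 12 - 2 ** 10

    def test_cap_refuses_large_maps(self):
        sm = make_map([("Dorsal", i * 13, 10, 0.5) for i in range(23)], length=400)
        with pytest.raises(ValueError, match="cap"):
            list(valid_configurations(sm))


class TestConfigurationWeight:
    def test_empty_configuration_has_unit_weight(self, c5q5):
        sm = make_map([("Dorsal", 0, 10, 0.9)])
        w = configuration_weight(Configuration(frozenset()), np.ones(c5q5.n_params),
                                 {"Dorsal": 0.5}, sm, c5q5)
        assert w == 1.0

    def test_single_site_weight(self, c5q5):
        sm = make_map([("Dorsal", 0, 10, 0.8)])
        th = np.full(c5q5.n_params, 0.5)
        th[c5q5.slot("scale_Dorsal")] = 3.0
        w = configuration_weight(Configuration(frozenset({0})), th,
                                 {"Dorsal": 0.5}, sm, c5q5)
        assert w == pytest.approx(3.0 * 0.8 * 0.5)

    def test_two_cooperating_dorsal_sites(self, c5q5):
        # 40 bp apart: bin c1 of the 1-50 bp scheme applies
        sm = make_map([("Dorsal", 0, 10, 0.8), ("Dorsal", 40, 10, 0.6)])
        th = np.full(c5q5.n_params, 0.5)
        th[c5q5.slot("scale_Dorsal")] = 3.0
        th[c5q5.slot("coop_homo_bin1")] = 5.0
        w = configuration_weight(Configuration(frozenset({0, 1})), th,
                                 {"Dorsal": 0.5}, sm, c5q5)
        assert w == pytest.approx((3.0 * 0.8 * 0.5) * (3.0 * 0.6 * 0.5) * 5.0)

    def test_negative_parameter_rejected(self, c5q5):
        sm = make_map([("Dorsal", 0, 10, 0.8)])
        th = np.full(c5q5.n_params, -1.0)
        with pytest.raises(ValueError):
            configuration_weight(Configuration(frozenset({0})), th,
                                 {"Dorsal": 0.5}, sm, c5q5)


class TestPredictExpression:
    def test_zero_scaling_gives_zero_profile(self, gradients, wildtype_map, c5q5):
        th = np.full(c5q5.n_params, 0.5)
        for name in ("scale_Dorsal", "scale_Twist"):
            th[c5q5.slot(name)] = 0.0
        prof = predict_expression(wildtype_map, th, gradients, c5q5)
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_empty_sitemap_gives_zero_profile(self, gradients, c5q5):
        sm = SiteMap("empty", 318, [])
        prof = predict_expression(sm, np.full(c5q5.n_params, 0.5), gradients, c5q5)
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_quenching_irrelevant_where_snail_is_absent(self, gradients, c5q5):
        """At DV points 10-17 the printed Snail gradient is zero, so the
        repressor never binds and quench parameters cannot matter."""
        sm = make_map([("Dorsal", 0, 11, 0.9), ("Snail", 30, 10, 0.9),
                       ("Twist", 60, 10, 0.8)])
        th0 = np.full(c5q5.n_params, 0.7)
        th1 = th0.copy()
        for i, k in enumerate(c5q5.slot_kinds):
            th0[i] = 0.0 if k == "quench_fraction" else th0[i]
            th1[i] = 1.0 if k == "quench_fraction" else th1[i]
        p0 = predict_expression(sm, th0, gradients, c5q5).values
        p1 = predict_expression(sm, th1, gradients, c5q5).values
        np.testing.assert_allclose(p0[9:], p1[9:], atol=1e-12)
        assert not np.allclose(p0[:5], p1[:5])

    def test_two_activator_one_repressor_closed_form(self, gradients, c5q5):
        """Hand-expanded 6-term ensemble for activator-repressor-activator."""
        sm = make_map([("Dorsal", 0, 10, 0.8), ("Snail", 20, 10, 0.9),
                       ("Twist", 40, 10, 0.7)])
        th = np.full(c5q5.n_params, 0.5)
        sD, sT, sS = 2.0, 3.0, 4.0
        c1 = 1.7
        fq = 0.6
        th[c5q5.slot("scale_Dorsal")] = sD
        th[c5q5.slot("scale_Twist")] = sT
        th[c5q5.slot("scale_Snail")] = sS
        th[c5q5.slot("coop_DT_bin1")] = c1
        for name in ("quench_SD_bin1", "quench_ST_bin1"):
            th[c5q5.slot(name)] = fq
        got = predict_expression(sm, th, gradients, c5q5).values
        fast = predict_expression_fast(sm, th, gradients, c5q5).values
        for x in range(N_POINTS):
            a = sD * 0.8 * gradients.conc("Dorsal")[x]
            t = sT * 0.7 * gradients.conc("Twist")[x]
            r = sS * 0.9 * gradients.conc("Snail")[x]
            # configurations: {}, {a}, {t}, {r}, {a,t}, {a,r}, {t,r}, {a,t,r}
            # centers 5, 25, 45: a-t distance 40 -> DT bin1; a-r, t-r d=20
            den = 1 + a + t + r + a * t * c1 + a * r + t * r + a * r * t
            num = (a + t + a * t * c1
                   + a * r * (1 - fq) + t * r * (1 - fq)
                   + a * r * t * (1 - (fq) * (fq)))
            # in {a,r,t} both activators flank the repressor: each survives
            # with (1-fq); active unless both quenched
            num_art = a * r * t * (1 - fq * fq)
            num = (a + t + a * t * c1 + a * r * (1 - fq) + t * r * (1 - fq)
                   + num_art)
            assert got[x] == pytest.approx(num / den, abs=1e-12)
            assert fast[x] == pytest.approx(num / den, abs=1e-12)

    def test_single_site_closed_form(self, gradients, c5q5):
        sm = make_map([("Twist", 10, 10, 0.6)])
        th = np.full(c5q5.n_params, 0.5)
        th[c5q5.slot("scale_Twist")] = 2.5
        fast = predict_expression_fast(sm, th, gradients, c5q5).values
        w = 2.5 * 0.6 * gradients.conc("Twist")
        np.testing.assert_allclose(fast, w / (1 + w), atol=1e-12)

    def test_missing_gradient_raises(self, c5q5):
        sm = make_map([("Dorsal", 0, 10, 0.9)])
        partial = GradientSet({"Twist": TFGradient("Twist", np.zeros(17))})
        with pytest.raises(KeyError):
            predict_expression(sm, np.full(c5q5.n_params, 0.5), partial, c5q5)


class TestOracleEquivalence:
    def test_both_paths_match_naive_enumeration(self, gradients, all_models):
        rng = np.random.default_rng(8)
        for _ in range(25):
            spec = all_models[int(rng.integers(0, 120))]
            sm = random_sitemap(rng, int(rng.integers(1, 7)))
            th = random_theta(rng, spec)
            expected = naive_predict(sm, th, gradients, spec)
            enum = predict_expression(sm, th, gradients, spec).values
            fast = predict_expression_fast(sm, th, gradients, spec).values
            np.testing.assert_allclose(enum, expected, atol=1e-12)
            np.testing.assert_allclose(fast, expected, atol=1e-12)

    def test_fast_path_handles_thirty_sites(self, gradients, c5q5):
        rng = np.random.default_rng(9)
        sm = random_sitemap(rng, 30, length=900)
        th = random_theta(rng, c5q5)
        vals = predict_expression_fast(sm, th, gradients, c5q5).values
        assert np.all((vals >= 0) & (vals <= 1))


class TestInvariants:
    def test_profiles_bounded_for_random_parameters(self, gradients, all_models):
        rng = np.random.default_rng(10)
        for _ in range(40):
            spec = all_models[int(rng.integers(0, 120))]
            sm = random_sitemap(rng, int(rng.integers(1, 10)))
            th = random_theta(rng, spec)
            vals = predict_expression_fast(sm, th, gradients, spec).values
            assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_long_range_continuous_cooperativity_breaks_monotonicity(
            self, gradients):
        """Documented limitation: the continuous cooperativity forms decay to
        zero at long range, i.e. they penalize distant adjacently bound
        pairs (effective anti-cooperativity).  In that regime deleting an
        activator or adding a repressor CAN increase expression, so the
        monotone-role property is asserted only for genuinely cooperative
        (binned, factor >= 1) schemes elsewhere."""
        from conftest import random_theta

        rng = np.random.default_rng(7)
        spec_pool = [get_model(f"C3Q{j}") for j in range(2, 9)]
        found = 0.0
        for _ in range(300):
            spec = spec_pool[int(rng.integers(0, len(spec_pool)))]
            sm = random_sitemap(rng, int(rng.integers(3, 9)), allow_overlap=False)
            th = random_theta(rng, spec, coop_low=1.0, monotone_quench=True)
            base = predict_expression_fast(sm, th, gradients, spec).values
            for site in sm.sites:
                if site.tf == "Snail":
                    continue
                alt = predict_expression_fast(sm.without([site.name]), th,
                                              gradients, spec).values
                found = max(found, float((alt - base).max()))
            if found > 1e-3:
                break
        assert found > 1e-3

    def test_neutral_repressor_cancels_exactly(self, gradients, c5q5):
        """With all quench fractions zero, a non-overlapping, non-cooperating
        Snail site cancels between numerator and denominator."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            sm = random_sitemap(rng, int(rng.integers(1, 8)), allow_overlap=False)
            th = random_theta(rng, c5q5)
            for i, k in enumerate(c5q5.slot_kinds):
                if k == "quench_fraction":
                    th[i] = 0.0
            # SS cooperativity neutralized so the new Snail site cannot
            # interact with existing ones
            th[c5q5.slot("coop_homo_bin1")] = 1.0
            th[c5q5.slot("coop_homo_bin2")] = 1.0
            has_snail = any(s.tf == "Snail" for s in sm.sites)
            base = predict_expression_fast(sm, th, gradients, c5q5).values
            start = sm.length + 10
            extra = BindingSite("Snail", start, start + 10, "+", 5.0, 0.9, name="neuS")
            sm2 = SiteMap(sm.sequence_id, start + 30, sm.sites + [extra])
            with2 = predict_expression_fast(sm2, th, gradients, c5q5).values
            np.testing.assert_allclose(with2, base, atol=1e-12)
            if has_snail:
                # homotypic coop at 1 keeps cancellation exact even between
                # adjacent Snail sites
                pass
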