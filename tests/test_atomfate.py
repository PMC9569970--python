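"""Atom-fate forward model and PPP-fraction estimators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ppptrace as pt
from ppptrace.exceptions import InsufficientReplicatesError, InvalidInputError


def weights_by_pattern(isotopomers):
    return {iso.labeled_positions: iso.weight for iso in isotopomers}


class TestForwardIsotopomers:
    def test_pure_glycolysis_stoichiometry(self, pure_tracer):
        w = weights_by_pattern(pt.forward_isotopomers(0.0, pure_tracer))
        assert w == {
            frozenset({2, 3}): pytest.approx(1.0),
            frozenset(): pytest.approx(1.0),
        }

    def test_pure_ppp_stoichiometry_per_three_glucose(self, pure_tracer):
        w = weights_by_pattern(pt.forward_isotopomers(1.0, pure_tracer))
        per3 = {k: 3 * v for k, v in w.items()}
        assert per3[frozenset({1, 3})] == pytest.approx(1.0)
        assert per3[frozenset({3})] == pytest.approx(1.0)
        assert per3[frozenset()] == pytest.approx(3.0)
        # five molecules carrying three labeled carbons in total
        assert sum(per3.values()) == pytest.approx(5.0)
        assert sum(len(k) * v for k, v in per3.items()) == pytest.approx(3.0)

    def test_zero_purity_yields_only_unlabeled(self):
        tracer = pt.TracerSpec(purity=0.0)
        w = weights_by_pattern(pt.forward_isotopomers(0.0, tracer))
        assert set(w) == {frozenset()}
        assert w[frozenset()] == pytest.approx(2.0)

    @given(p=st.floats(min_value=0.0, max_value=1.0))
    def test_mass_balance_for_any_partition(self, p, pure_tracer):
        isos = pt.forward_isotopomers(p, pure_tracer)
        total_molecules = sum(i.weight for i in isos)
        total_labels = sum(i.weight * i.label_count for i in isos)
        # glycolysis: 2 lactate / 2 labels per glucose; PPP: 5/3 lactate,
        # 1 label per glucose
        assert total_molecules == pytest.approx(2 * (1 - p) + 5 * p / 3)
        assert total_labels == pytest.approx(2 * (1 - p) + p)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            pt.forward_isotopomers(1.2)
        with pytest.raises(InvalidInputError):
            pt.forward_isotopomers(-0.1)

    def test_requires_c1_c2_tracer(self):
        with pytest.raises(InvalidInputError):
            pt.forward_isotopomers(0.5, pt.TracerSpec(labeled_positions=frozenset({1, 6})))


class TestExpectedMid:
    def test_pure_ppp_full_ion(self, lactate_full_ion, pure_tracer):
        # 5 PPP lactates per 3 glucose: 3 unlabeled, 1 m+1, 1 m+2
        mid = pt.expected_mid(1.0, lactate_full_ion, pure_tracer)
        np.testing.assert_allclose(mid.fractions, [0.6, 0.2, 0.2, 0.0], atol=1e-12)

    def test_pure_glycolysis_fragment(self, lactate_fragment, pure_tracer):
        mid = pt.expected_mid(0.0, lactate_fragment, pure_tracer)
        np.testing.assert_allclose(mid.fractions, [0.5, 0.0, 0.5], atol=1e-12)

    def test_half_ppp_fragment_mixture(self, lactate_fragment, pure_tracer):
        mid = pt.expected_mid(0.5, lactate_fragment, pure_tracer)
        np.testing.assert_allclose(mid.fractions, [6 / 11, 2 / 11, 3 / 11], atol=1e-12)

    @given(p=st.floats(min_value=0.0, max_value=1.0))
    def test_closed_forms_match_positional_composition(
        self, p, lactate_fragment, lactate_full_ion, pure_tracer
    ):
        frag = pt.expected_mid(p, lactate_fragment, pure_tracer).as_array()
        np.testing.assert_allclose(
            frag, np.array([3.0, 2 * p, 3 - 3 * p]) / (6 - p), atol=1e-12
        )
        full = pt.expected_mid(p, lactate_full_ion, pure_tracer).as_array()
        np.testing.assert_allclose(
            full[:3], np.array([3.0, p, 3 - 2 * p]) / (6 - p), atol=1e-12
        )
        assert full[3] == pytest.approx(0.0, abs=1e-12)

    def test_fragment_m1_monotone_increasing_m2_decreasing(self, lactate_fragment):
        grid = np.linspace(0.0, 1.0, 21)
        mids = np.array([pt.expected_mid(p, lactate_fragment).fractions for p in grid])
        assert np.all(np.diff(mids[:, 1]) > 0)
        assert np.all(np.diff(mids[:, 2]) < 0)

    def test_pyruvate_shares_lactate_labeling(self, lactate_full_ion, pyruvate_full_ion):
        for p in (0.1, 0.5, 0.9):
            np.testing.assert_allclose(
                pt.expected_mid(p, pyruvate_full_ion).fractions,
                pt.expected_mid(p, lactate_full_ion).fractions,
                atol=1e-12,
            )


class TestRatioEstimator:
    def test_inverts_half_ppp_fragment(self, lactate_fragment):
        mid = pt.MID((6 / 11, 2 / 11, 3 / 11), "lactate", "lactate_117")
        assert pt.estimate_fppp_ratio(mid, lactate_fragment).f_ppp == pytest.approx(0.5)

    def test_no_m1_means_no_ppp(self, lactate_fragment):
        mid = pt.MID((0.5, 0.0, 0.5), "lactate", "lactate_117")
        assert pt.estimate_fppp_ratio(mid, lactate_fragment).f_ppp == 0.0

    def test_inverts_pure_ppp_full_ion(self, lactate_full_ion):
        mid = pt.MID((0.6, 0.2, 0.2, 0.0), "lactate", "lactate_full")
        assert pt.estimate_fppp_ratio(mid, lactate_full_ion).f_ppp == pytest.approx(1.0)

    def test_roundtrip_on_dense_grid(self, lactate_fragment, lactate_full_ion):
        for frag in (lactate_fragment, lactate_full_ion):
            for p in np.arange(0.01, 1.0, 0.01):
                est = pt.estimate_fppp_ratio(pt.expected_mid(p, frag), frag)
                assert abs(est.f_ppp - p) < 1e-9

    def test_degenerate_flags(self, lactate_fragment):
        only_m1 = pt.MID((0.7, 0.3, 0.0), "lactate", "lactate_117")
        res = pt.estimate_fppp_ratio(only_m1, lactate_fragment)
        assert res.f_ppp == 1.0 and res.degenerate
        no_label = pt.MID((1.0, 0.0, 0.0), "lactate", "lactate_117")
        res = pt.estimate_fppp_ratio(no_label, lactate_fragment)
        assert res.f_ppp == 0.0 and res.degenerate

    def test_partition_derived_quantities(self):
        part = pt.FluxPartition(0.5)
        assert part.f_glycolysis == 0.5
        assert part.triose_yield_share == pytest.approx(5 * 0.5 / 5.5)


class TestLeastSquaresEstimator:
    def test_agrees_with_ratio_on_noiseless_input(self, lactate_fragment):
        mid = pt.expected_mid(0.5, lactate_fragment)
        est = pt.estimate_fppp_lsq([mid], lactate_fragment)
        assert abs(est.f_ppp - 0.5) < 1e-6

    def test_exact_model_recovery_from_replicates(self, lactate_fragment):
        mids = [pt.expected_mid(0.2, lactate_fragment)] * 4
        assert pt.estimate_fppp_lsq(mids, lactate_fragment).f_ppp == pytest.approx(
            0.2, abs=1e-6
        )

    def test_grid_roundtrip(self, lactate_fragment, lactate_full_ion):
        for frag in (lactate_fragment, lactate_full_ion):
            for p in np.arange(0.1, 1.0, 0.1):
                est = pt.estimate_fppp_lsq([pt.expected_mid(p, frag)], frag)
                assert abs(est.f_ppp - p) < 1e-6

    def test_objective_unimodal_on_grid(self, lactate_fragment):
        # squared deviation from the truth decreases toward p0 from both sides
        target = pt.expected_mid(0.4, lactate_fragment).as_array()
        grid = np.linspace(0, 1, 101)
        obj = [
            float(np.sum((pt.expected_mid(p, lactate_fragment).as_array() - target) ** 2))
            for p in grid
        ]
        k = int(np.argmin(obj))
        assert np.all(np.diff(obj[: k + 1]) <= 1e-15)
        assert np.all(np.diff(obj[k:]) >= -1e-15)

    def test_empty_input_rejected(self, lactate_fragment):
        with pytest.raises(InvalidInputError):
            pt.estimate_fppp_lsq([], lactate_fragment)


class TestBootstrap:
    def test_identical_replicates_collapse_interval(self, lactate_fragment):
        mids = [pt.expected_mid(0.3, lactate_fragment)] * 5
        res = pt.bootstrap_ci(mids, lactate_fragment, n_boot=200, seed=7)
        assert res.ci_low == pytest.approx(res.f_ppp, abs=1e-9)
        assert res.ci_high == pytest.approx(res.f_ppp, abs=1e-9)

    def test_seeded_determinism(self, lactate_fragment):
        rng = np.random.default_rng(5)
        mids = []
        for _ in range(6):
            noisy = pt.expected_mid(0.5, lactate_fragment).as_array() * rng.lognormal(
                0, 0.05, 3
            )
            mids.append(pt.normalize_intensities(noisy, "lactate", "lactate_117"))
        a = pt.bootstrap_ci(mids, lactate_fragment, n_boot=300, seed=11)
        b = pt.bootstrap_ci(mids, lactate_fragment, n_boot=300, seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_coverage_under_replicate_noise(self, lactate_fragment):
        # The nominal-95% percentile interval from only six replicates
        # undercovers somewhat (true coverage ~86% here, a known
        # small-sample property of percentile bootstraps); assert coverage
        # consistent with that behavior rather than the nominal level.
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            mids = []
            for _ in range(6):
                noisy = pt.expected_mid(0.5, lactate_fragment).as_array() * rng.lognormal(
                    0, 0.05, 3
                )
                mids.append(pt.normalize_intensities(noisy, "lactate", "lactate_117"))
            res = pt.bootstrap_ci(mids, lactate_fragment, n_boot=1000, seed=rep)
            if res.ci_low <= 0.5 <= res.ci_high:
                hits += 1
        assert hits >= 78

    def test_requires_two_replicates(self, lactate_fragment):
        with pytest.raises(InsufficientReplicatesError):
            pt.bootstrap_ci([pt.expected_mid(0.5, lactate_fragment)], lactate_fragment)
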