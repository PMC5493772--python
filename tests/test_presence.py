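"""Background mixture fitting, presence calling, roster comparison."""

import numpy as np
import pandas as pd
import pytest

import ykofit as yk
from ykofit._types import MixtureFit, PresenceCall
from ykofit.presence import NoSeparationWarning, fit_background_mixture


def two_component_sample(seed=0, n_present=4000, n_absent=800):
    rng = np.random.default_rng(seed)
    return np.concatenate(
        [rng.normal(10.0, 0.8, n_present), rng.normal(6.5, 0.7, n_absent)]
    )


class TestFitBackgroundMixture:
    def test_parameter_recovery(self):
        fit = fit_background_mixture(two_component_sample(seed=1))
        assert fit.means[1] == pytest.approx(10.0, abs=0.1)
        assert fit.means[0] == pytest.approx(6.5, abs=0.1)
        assert fit.weights[1] == pytest.approx(4000 / 4800, abs=0.02)
        assert fit.converged

    def test_agrees_with_sklearn_em(self):
        """Independent oracle: scikit-learn's GaussianMixture on the same data."""
        from sklearn.mixture import GaussianMixture

        x = two_component_sample(seed=2)
        fit = fit_background_mixture(x)
        gm = GaussianMixture(2, tol=1e-8, max_iter=1000, random_state=0).fit(x[:, None])
        means = np.sort(gm.means_.ravel())
        assert fit.means == pytest.approx(means, abs=0.02)

    def test_loglik_monotone_nondecreasing(self):
        fit = fit_background_mixture(two_component_sample(seed=3))
        assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_single_component_warns_no_separation(self):
        rng = np.random.default_rng(4)
        with pytest.warns(NoSeparationWarning):
            fit = fit_background_mixture(rng.normal(10.0, 0.8, 2000))
        assert not fit.separated

    def test_identical_values_degenerate(self):
        with pytest.raises(yk.DegenerateInputError):
            fit_background_mixture(np.full(100, 5.0))

    def test_posterior_midpoint_is_half(self):
        fit = MixtureFit(
            weights=np.array([0.5, 0.5]), means=np.array([6.5, 10.0]),
            sds=np.array([0.7, 0.7]), loglik_trace=np.array([0.0]),
            converged=True, separated=True, n=100,
        )
        assert fit.posterior(8.25) == pytest.approx(0.5, abs=1e-12)

    def test_posterior_normalization_and_monotonicity(self):
        fit = fit_background_mixture(two_component_sample(seed=5))
        x = np.linspace(4, 13, 200)
        p = fit.posterior(x)
        assert np.all((p >= 0) & (p <= 1))
        # complementary posterior sums to one
        comp = MixtureFit(fit.weights[::-1].copy(), fit.means[::-1].copy(),
                          fit.sds[::-1].copy(), fit.loglik_trace, True, True, fit.n)
        assert p + comp.posterior(x) == pytest.approx(np.ones_like(x))
        assert np.all(np.diff(p) >= -1e-12)


class TestTagAndStrainCalls:
    def _fit(self):
        return fit_background_mixture(two_component_sample(seed=6))

    def test_threshold_is_strict(self):
        vals = pd.DataFrame({"c1": [8.25]}, index=["t_up"])
        # craft symmetric fit: posterior exactly 0.5 -> absent
        sym = MixtureFit(np.array([0.5, 0.5]), np.array([6.5, 10.0]),
                         np.array([0.7, 0.7]), np.array([0.0]), True, True, 100)
        calls, post = yk.call_tag_presence({"c1": sym}, vals)
        assert post.loc["t_up", "c1"] == pytest.approx(0.5, abs=1e-12)
        assert not calls.loc["t_up", "c1"]

    def test_tag_must_pass_all_control_replicates(self):
        sym = MixtureFit(np.array([0.5, 0.5]), np.array([6.5, 10.0]),
                         np.array([0.7, 0.7]), np.array([0.0]), True, True, 100)
        # posterior 0.51-ish in two controls, low in the third
        vals = pd.DataFrame({"c1": [8.30], "c2": [8.30], "c3": [7.0]}, index=["s1_up"])
        calls, _ = yk.call_tag_presence({c: sym for c in vals.columns}, vals)
        lib = pd.DataFrame({"strain_id": ["s1"], "uptag_seq": ["A" * 20],
                            "downtag_seq": ["C" * 20]})
        # restrict to the single tag actually on the array
        call = yk.call_strain_presence(calls, calls * 0.0, lib)
        assert not call.present["s1"]

    def test_strain_needs_all_tags(self):
        lib = pd.DataFrame({"strain_id": ["s1"], "uptag_seq": ["A" * 20],
                            "downtag_seq": ["C" * 20]})
        calls = pd.DataFrame({"c1": [True, False]}, index=["s1_up", "s1_dn"])
        call = yk.call_strain_presence(calls, calls * 0.0, lib)
        assert not call.present["s1"]
        calls = pd.DataFrame({"c1": [True, True]}, index=["s1_up", "s1_dn"])
        assert yk.call_strain_presence(calls, calls * 0.0, lib).present["s1"]

    def test_strain_with_no_tags_absent_and_logged(self):
        lib = pd.DataFrame({"strain_id": ["s1", "s2"],
                            "uptag_seq": ["A" * 20, "G" * 20],
                            "downtag_seq": ["C" * 20, "T" * 20]})
        calls = pd.DataFrame({"c1": [True, True]}, index=["s1_up", "s1_dn"])
        call = yk.call_strain_presence(calls, calls * 0.0, lib)
        assert not call.present["s2"]
        assert call.no_tag_strains == ["s2"]

    def test_planted_dropout_recovery(self, small_truth, small_library, noisy_screen):
        mat = yk.summarize_to_tags(noisy_screen.features, noisy_screen.matrix.manifest)
        call = yk.call_presence(mat, small_library, "YKO", "SC")
        present = small_truth.present_by_collection["YKO"]
        absent = set(small_truth.strains) - present
        recall = np.mean([not call.present[s] for s in absent])
        acc = np.mean([call.present[s] == (s in present) for s in small_truth.strains])
        assert recall >= 0.98
        assert acc >= 0.98

    def test_raising_threshold_never_adds_present_strains(self, small_library, noisy_screen):
        mat = yk.summarize_to_tags(noisy_screen.features, noisy_screen.matrix.manifest)
        lo = yk.call_presence(mat, small_library, "YKO", "SC", threshold=0.5)
        hi = yk.call_presence(mat, small_library, "YKO", "SC", threshold=0.9)
        assert hi.present_strains <= lo.present_strains


def _call(collection, strains):
    return PresenceCall(
        collection=collection, media="SC",
        present=pd.Series({s: s in strains for s in {"1", "2", "3"}}),
        tag_posteriors=pd.DataFrame(), threshold=0.5,
    )


class TestRosters:
    def test_identical_calls_fill_triple_region(self):
        calls = {c: _call(c, {"1", "2", "3"}) for c in "ABC"}
        venn = yk.compare_rosters(calls)
        assert venn.count("A", "B", "C") == 3
        assert sum(venn.regions.values()) == len(venn.universe) == 3

    def test_hand_enumerated_regions(self):
        calls = {"A": _call("A", {"1", "2"}), "B": _call("B", {"2", "3"}),
                 "C": _call("C", {"2"})}
        venn = yk.compare_rosters(calls)
        assert len(venn.universe) == 3
        assert venn.count("A", "B", "C") == 1
        assert venn.count("A") == 1
        assert venn.count("B") == 1
        assert venn.count("A", "B") == 0
        assert venn.region_strains[(True, True, True)] == {"2"}

    def test_region_counts_sum_to_universe(self):
        calls = {"A": _call("A", {"1", "2"}), "B": _call("B", {"2", "3"})}
        venn = yk.compare_rosters(calls)
        assert sum(venn.regions.values()) == len(venn.universe)

    def test_single_collection_rejected(self):
        with pytest.raises(yk.InputError):
            yk.compare_rosters({"A": _call("A", {"1"})})

    def test_missing_strain_report_hand_count(self):
        # 10-strain universe, 4 missing from B, annotation of 5 with 3 missing
        universe = {f"g{i}" for i in range(10)}
        present_b = {"g0", "g1", "g2", "g3", "g4", "g5"}
        call_a = PresenceCall("A", "SC", pd.Series({g: True for g in universe}),
                              pd.DataFrame(), 0.5)
        call_b = PresenceCall("B", "SC", pd.Series({g: g in present_b for g in universe}),
                              pd.DataFrame(), 0.5)
        venn = yk.compare_rosters({"A": call_a, "B": call_b})
        ann = ["g0", "g5", "g6", "g7", "g8"]  # 3 of these are missing from B
        rep = yk.missing_strain_report(venn, {"A": call_a, "B": call_b}, ann).set_index("collection")
        assert rep.loc["B", "n_missing"] == 4
        assert rep.loc["B", "frac_annotation_missing"] == pytest.approx(0.6)
        assert rep.loc["A", "n_missing"] == 0

    def test_empty_annotation_list_gives_nan(self):
        call_a = _call("A", {"1", "2"})
        call_b = _call("B", {"2"})
        venn = yk.compare_rosters({"A": call_a, "B": call_b})
        rep = yk.missing_strain_report(venn, {"A": call_a, "B": call_b}, [])
        assert rep["frac_annotation_missing"].isna().all()

    def test_annotation_equals_universe_fraction(self):
        call_a = _call("A", {"1", "2", "3"})
        call_b = _call("B", {"2"})
        venn = yk.compare_rosters({"A": call_a, "B": call_b})
        rep = yk.missing_strain_report(
            venn, {"A": call_a, "B": call_b}, sorted(venn.universe)
        ).set_index("collection")
        assert rep.loc["B", "frac_annotation_missing"] == pytest.approx(2 / 3)
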