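"""Normalization, best-tag selection, batch correction, FD scores, significance."""

import numpy as np
import pandas as pd
import pytest

import ykofit as yk
from ykofit._types import TagIntensityMatrix
from ykofit.fitness import compute_significance


def _matrix(values: dict, manifest: pd.DataFrame, index) -> TagIntensityMatrix:
    return TagIntensityMatrix(
        values=pd.DataFrame(values, index=index),
        manifest=manifest.set_index("array_id", drop=False),
    )


@pytest.fixture()
def lib2():
    return pd.DataFrame(
        {"strain_id": ["s1", "s2"],
         "uptag_seq": ["A" * 20, "G" * 20],
         "downtag_seq": ["C" * 20, "T" * 20]}
    )


@pytest.fixture()
def manifest4():
    return pd.DataFrame(
        {"array_id": ["c1", "c2", "t1", "t2"],
         "collection": "YKO", "media": "SC",
         "condition": ["control", "control", "condA", "condA"],
         "batch": "b1", "replicate": [1, 2, 1, 2],
         "role": ["control", "control", "treatment", "treatment"]}
    )


class TestNormalize:
    def test_identical_arrays_unchanged(self, lib2, manifest4):
        vals = {a: [10.0, 8.0, 9.0, 7.0] for a in ["c1", "c2", "t1", "t2"]}
        mat = _matrix(vals, manifest4, ["s1_up", "s1_dn", "s2_up", "s2_dn"])
        out, shifts = yk.normalize_by_tag_class_median(mat, lib2)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_uniform_uptag_offset_removed(self, lib2, manifest4):
        base = {"c1": [10.0, 8.0, 9.0, 7.0], "c2": [10.0, 8.0, 9.0, 7.0],
                "t1": [10.0, 8.0, 9.0, 7.0], "t2": [10.0, 8.0, 9.0, 7.0]}
        mat = _matrix(base, manifest4, ["s1_up", "s1_dn", "s2_up", "s2_dn"])
        mat.values.loc[["s1_up", "s2_up"], "c1"] += 1.0  # uptags on c1 shifted +1
        out, shifts = yk.normalize_by_tag_class_median(mat, lib2)
        assert out.values.loc["s1_up", "c1"] == pytest.approx(10.0)
        assert out.values.loc["s2_up", "c1"] == pytest.approx(9.0)
        # downtags untouched
        assert out.values.loc["s1_dn", "c1"] == pytest.approx(8.0)
        up_shift = shifts.query("array_id == 'c1' and tag_class == 'uptag'")["shift"]
        assert up_shift.iloc[0] == pytest.approx(-1.0)

    def test_idempotent(self, lib2, manifest4):
        rng = np.random.default_rng(0)
        vals = {a: rng.normal(9, 1, 4) for a in ["c1", "c2", "t1", "t2"]}
        mat = _matrix(vals, manifest4, ["s1_up", "s1_dn", "s2_up", "s2_dn"])
        once, _ = yk.normalize_by_tag_class_median(mat, lib2)
        twice, _ = yk.normalize_by_tag_class_median(once, lib2)
        pd.testing.assert_frame_equal(once.values, twice.values, atol=1e-12)

    def test_single_array_set_warns_identity(self, lib2):
        manifest = pd.DataFrame(
            {"array_id": ["c1"], "collection": "YKO", "media": "SC",
             "condition": ["control"], "batch": "b1", "replicate": [1],
             "role": ["control"]}
        )
        mat = _matrix({"c1": [10.0, 8.0, 9.0, 7.0]}, manifest,
                      ["s1_up", "s1_dn", "s2_up", "s2_dn"])
        with pytest.warns(UserWarning, match="single array"):
            out, _ = yk.normalize_by_tag_class_median(mat, lib2)
        pd.testing.assert_frame_equal(out.values, mat.values)


class TestSelectBestTag:
    def test_lower_cv_wins(self, lib2, manifest4):
        # s1 uptag noisy across controls, downtag steady -> downtag chosen
        vals = {"c1": [10.0, 8.0, 9.0, 7.0], "c2": [11.0, 8.0, 9.0, 7.0],
                "t1": [10.5, 8.0, 9.0, 7.0], "t2": [10.5, 8.0, 9.0, 7.0]}
        mat = _matrix(vals, manifest4, ["s1_up", "s1_dn", "s2_up", "s2_dn"])
        best, collapsed = yk.select_best_tag(mat, lib2)
        choice = best.set_index("strain_id")["tag_class"]
        assert choice["s1"] == "downtag"
        assert list(collapsed.values.loc["s1"]) == [8.0, 8.0, 8.0, 8.0]

    def test_exact_tie_prefers_uptag(self, lib2, manifest4):
        vals = {a: [10.0, 10.0, 9.0, 9.0] for a in ["c1", "c2", "t1", "t2"]}
        mat = _matrix(vals, manifest4, ["s1_up", "s1_dn", "s2_up", "s2_dn"])
        best, _ = yk.select_best_tag(mat, lib2)
        assert (best["tag_class"] == "uptag").all()

    def test_needs_two_control_replicates(self, lib2):
        manifest = pd.DataFrame(
            {"array_id": ["c1", "t1"], "collection": "YKO", "media": "SC",
             "condition": ["control", "condA"], "batch": "b1", "replicate": [1, 1],
             "role": ["control", "treatment"]}
        )
        mat = _matrix({"c1": [1.0] * 4, "t1": [1.0] * 4}, manifest,
                      ["s1_up", "s1_dn", "s2_up", "s2_dn"])
        with pytest.raises(yk.InputError, match="control replicates"):
            yk.select_best_tag(mat, lib2)

    def test_noiseless_collapse_matches_generating_means(
        self, small_truth, small_library, noiseless_screen
    ):
        best, collapsed = yk.select_best_tag(noiseless_screen.matrix, small_library)
        # every collapsed value must equal one of the strain's two tag values
        v = noiseless_screen.matrix.values
        for s in list(collapsed.values.index)[:25]:
            col = "YKO_SC_ctrl_1"
            assert collapsed.values.loc[s, col] in (
                v.loc[s + "_up", col], v.loc[s + "_dn", col]
            )


class TestBatchCorrect:
    def _mat(self, batches, values):
        arrays = [f"a{i}" for i in range(len(batches))]
        manifest = pd.DataFrame(
            {"array_id": arrays, "collection": "YKO", "media": "SC",
             "condition": "control", "batch": batches,
             "replicate": range(len(batches)), "role": "control"}
        )
        return _matrix(dict(zip(arrays, np.asarray(values).T)), manifest,
                       [f"s{i}" for i in range(np.asarray(values).shape[0])])

    def test_single_batch_identity(self):
        mat = self._mat(["b1"] * 4, np.random.default_rng(1).normal(9, 1, (5, 4)))
        out = yk.batch_correct(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_two_batch_offset_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(9, 1, (6, 4))
        shifted = np.hstack([base[:, :2], base[:, 2:] + 2.0])
        mat = self._mat(["b1", "b1", "b2", "b2"], shifted)
        out = yk.batch_correct(mat)
        means = {
            b: out.values.loc[:, mat.manifest.index[mat.manifest["batch"] == b]].mean(axis=1)
            for b in ("b1", "b2")
        }
        assert np.allclose(means["b1"], means["b2"], atol=1e-9)

    def test_pooled_mean_preserved(self):
        rng = np.random.default_rng(3)
        vals = np.hstack([rng.normal(9, 1, (5, 2)), rng.normal(11, 1, (5, 2))])
        mat = self._mat(["b1", "b1", "b2", "b2"], vals)
        out = yk.batch_correct(mat)
        assert np.allclose(out.values.mean(axis=1), mat.values.mean(axis=1), atol=1e-9)

    def test_singleton_batch_warns_location_only(self):
        vals = np.random.default_rng(4).normal(9, 1, (5, 3))
        mat = self._mat(["b1", "b1", "b2"], vals)
        with pytest.warns(UserWarning, match="one array"):
            yk.batch_correct(mat)


class TestFDScores:
    def test_treatment_equals_controls_gives_zero(self, manifest4):
        vals = {a: [10.0, 8.0] for a in ["c1", "c2", "t1", "t2"]}
        mat = _matrix(vals, manifest4, ["s1", "s2"])
        table = yk.compute_fd_scores(mat)
        assert (table.fd_median["condA"] == 0).all()

    def test_planted_defect_noiseless(self, small_truth, small_library, noiseless_screen):
        best, collapsed = yk.select_best_tag(
            noiseless_screen.matrix, small_library,
            strains=small_truth.present_by_collection["YKO"],
        )
        table = yk.compute_fd_scores(collapsed)
        for (strain, cond), d in small_truth.fitness_coeff.items():
            assert table.fd_median.loc[strain, cond] == pytest.approx(
                small_truth.generations * d, abs=1e-9
            )

    def test_fd_linearity_in_treatment_shift(self, manifest4):
        vals = {"c1": [10.0, 8.0], "c2": [10.0, 8.0],
                "t1": [9.0, 8.0], "t2": [9.5, 8.0]}
        mat = _matrix(vals, manifest4, ["s1", "s2"])
        base = yk.compute_fd_scores(mat).fd["condA"]
        mat2 = mat.copy()
        mat2.values[["t1", "t2"]] += 0.7
        shifted = yk.compute_fd_scores(mat2).fd["condA"]
        assert np.allclose(shifted.to_numpy(), base.to_numpy() - 0.7)

    def test_control_self_comparison_median_zero(self):
        # odd control count: FD of a control array against the control median
        manifest = pd.DataFrame(
            {"array_id": ["c1", "c2", "c3", "t1"], "collection": "YKO",
             "media": "SC", "condition": ["control"] * 3 + ["condA"],
             "batch": "b1", "replicate": [1, 2, 3, 1],
             "role": ["control"] * 3 + ["treatment"]}
        )
        rng = np.random.default_rng(5)
        vals = rng.normal(9, 1, (20, 4))
        mat = _matrix(dict(zip(["c1", "c2", "c3", "t1"], vals.T)), manifest,
                      [f"s{i}" for i in range(20)])
        ctrl_med = mat.values[["c1", "c2", "c3"]].median(axis=1)
        fds = pd.concat([(ctrl_med - mat.values[c]) for c in ("c1", "c2", "c3")], axis=1)
        assert (fds.median(axis=1) == 0).all()


class TestSignificance:
    def test_all_zero_fd_gives_p_one(self):
        fd = {"c": pd.DataFrame(np.zeros((5, 3)), index=[f"s{i}" for i in range(5)])}
        p, q, t = compute_significance(fd, method="t")
        assert (p["c"] == 1.0).all()
        assert (q["c"] == 1.0).all()

    def test_hand_computed_t_statistic(self):
        fd = {"c": pd.DataFrame([[2.0, 2.1, 1.9], [0.0, 0.1, -0.1]], index=["s1", "s2"])}
        p, q, t = compute_significance(fd, method="t")
        assert t.loc["s1", "c"] == pytest.approx(2.0 / (0.1 / np.sqrt(3)), rel=1e-9)
        assert t.loc["s1", "c"] == pytest.approx(34.64, abs=0.01)

    def test_q_matches_hand_computed_step_up(self):
        rng = np.random.default_rng(9)
        fd = {"c": pd.DataFrame(rng.normal(0.5, 0.4, (8, 3)),
                                index=[f"s{i}" for i in range(8)])}
        p, q, _ = compute_significance(fd, method="t")
        # hand BH: sort p, q_(i) = min_{j>=i} p_(j) * m / j
        ps = p["c"].sort_values()
        m = len(ps)
        raw = ps.to_numpy() * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(raw[::-1])[::-1]
        assert np.allclose(q["c"].loc[ps.index].to_numpy(), np.minimum(hand, 1.0))

    def test_zero_variance_nonzero_mean_smallest_p(self):
        fd = {"c": pd.DataFrame([[1.0, 1.0, 1.0]], index=["s1"])}
        p, q, t = compute_significance(fd, method="t")
        assert p.loc["s1", "c"] == np.finfo(float).tiny

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(6)
        fd = {"c": pd.DataFrame(rng.normal(0, 1, (50, 3)),
                                index=[f"s{i}" for i in range(50)])}
        p, q, _ = compute_significance(fd, method="t")
        order = p["c"].sort_values().index
        assert q.loc[order, "c"].is_monotonic_increasing

    def test_q_respects_step_up_bound(self):
        rng = np.random.default_rng(7)
        fd = {"c": pd.DataFrame(rng.normal(0, 1, (30, 3)),
                                index=[f"s{i}" for i in range(30)])}
        p, q, _ = compute_significance(fd, method="t")
        ps = p["c"].sort_values()
        m = len(ps)
        bound = ps.to_numpy() * m / np.arange(1, m + 1)
        qs = q["c"].loc[ps.index].to_numpy()
        # step-up: q never exceeds p*m/rank and never drops below the raw p
        assert np.all(qs <= bound + 1e-12)
        assert np.all(qs >= ps.to_numpy() - 1e-12)

    def test_robust_z_flags_outlier_strains(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 0.1, (200, 3))
        X[:5] += 2.0
        fd = {"c": pd.DataFrame(X, index=[f"s{i}" for i in range(200)])}
        p, q, z = compute_significance(fd, method="robust_z")
        assert (q["c"].iloc[:5] < 0.05).all()
        assert (q["c"].iloc[5:] > 0.05).mean() > 0.95

    def test_fewer_than_two_replicates_rejected(self):
        fd = {"c": pd.DataFrame([[1.0]], index=["s1"])}
        with pytest.raises(yk.InputError):
            compute_significance(fd)
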