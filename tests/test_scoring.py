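"""Ellipsoid fitting, Escore, cell classification and sensitivity sweeps."""

import numpy as np
import pytest
from scipy.stats import chi2

from escore import scoring as sc
from escore import training as tr
from escore.multifreq import compute_delta_sv
from tests.conftest import make_set
from tests.test_training import delta_grid, planted_library


def simple_model(mu=None, sigma=None, threshold=25.0):
    mu = np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]]) if mu is None else mu
    sigma = np.ones_like(mu) if sigma is None else sigma
    return sc.EchoClassModel(mu=mu, sigma=sigma, threshold=threshold)


class TestFitEllipsoids:
    def test_identical_triplets_floor_sigma(self):
        ets = [tr.EchoType(f"e{i}", [[0, 0]], [1.0, 2.0, 3.0], "r") for i in range(5)]
        lib = tr.EchoTypeLibrary(ets, labels=np.array([1] * 4 + [2]))
        model = sc.fit_ellipsoids(lib)
        np.testing.assert_allclose(model.mu[0], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(model.sigma, sc.SIGMA_FLOOR_DB)

    def test_two_point_statistics(self):
        ets = [
            tr.EchoType("a", [[0, 0]], [0.0, 0.0, 0.0], "r"),
            tr.EchoType("b", [[0, 1]], [2.0, 0.0, 0.0], "r"),
            tr.EchoType("c", [[1, 0]], [9.0, 9.0, 9.0], "r"),
        ]
        lib = tr.EchoTypeLibrary(ets, labels=np.array([1, 1, 2]))
        model = sc.fit_ellipsoids(lib)
        assert model.mu[0, 0] == 1.0
        np.testing.assert_allclose(model.sigma[0, 0], np.sqrt(2.0))

    def test_against_independent_statistics(self):
        lib, truth = planted_library(
            [(-5, 0, 2), (4, -3, 1)], n_per_class=40, seed=7
        )
        labelled = tr.hierarchical_classify(lib, 2)
        model = sc.fit_ellipsoids(labelled)
        x = lib.mean_triplets
        for i, c in enumerate((1, 2)):
            sub = x[labelled.labels == c]
            np.testing.assert_allclose(model.mu[i], sub.mean(axis=0), atol=1e-12)
            np.testing.assert_allclose(
                model.sigma[i], sub.std(axis=0, ddof=1), atol=1e-12
            )


class TestEscore:
    def test_centroid_scores_zero(self):
        m = simple_model()
        assert sc.escore([0.0, 0.0, 0.0], 1, m) == 0.0

    def test_two_sigma_on_each_axis_is_12(self):
        m = simple_model(sigma=np.full((2, 3), 0.5))
        assert sc.escore([1.0, 1.0, 1.0], 1, m) == pytest.approx(12.0)

    def test_three_sigma_on_each_axis_is_27(self):
        m = simple_model()
        assert sc.escore([3.0, 3.0, 3.0], 1, m) == pytest.approx(27.0)

    def test_chi_square_coverage(self):
        rng = np.random.default_rng(0)
        mu = np.array([[1.0, -2.0, 0.5]])
        sigma = np.array([[0.8, 1.3, 0.6]])
        model = sc.EchoClassModel(mu=mu, sigma=sigma)
        x = rng.normal(mu[0], sigma[0], size=(100_000, 3))
        s = sc.escore_matrix(x, model)[:, 0]
        for q in (2.366, 7.815, 25.0):
            assert abs((s < q).mean() - chi2.cdf(q, df=3)) < 0.01


class TestClassifyCells:
    def test_centroid_grid_perfect(self):
        m = simple_model()
        d = np.array([[[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]]])
        out = sc.classify_cells(delta_grid(d), m)
        np.testing.assert_array_equal(out.labels, [[1, 2]])
        np.testing.assert_array_equal(out.min_escore, [[0.0, 0.0]])

    def test_boundary_score_unclassified(self):
        m = simple_model(threshold=12.0)
        d = np.array([[[2.0, 2.0, 2.0]]])  # Escore exactly 12
        out = sc.classify_cells(delta_grid(d), m)
        assert out.labels[0, 0] == sc.UNCLASSIFIED

    def test_missing_propagates(self):
        m = simple_model()
        d = np.full((1, 2, 3), np.nan)
        d[0, 1] = [0.0, 0.0, 0.0]
        out = sc.classify_cells(delta_grid(d), m)
        assert out.labels[0, 0] == sc.MISSING_LABEL
        assert np.isnan(out.min_escore[0, 0])
        assert out.labels[0, 1] == 1

    def test_tie_breaks_to_lowest_class(self):
        mu = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        m = simple_model(mu=mu)
        out = sc.classify_cells(delta_grid([[[1.0, 0.0, 0.0]]]), m)
        assert out.labels[0, 0] == 1

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(3):
            k = int(rng.integers(2, 6))
            mu = rng.normal(0, 5, (k, 3))
            sigma = rng.uniform(0.3, 2.0, (k, 3))
            thr = float(rng.uniform(5, 40))
            model = sc.EchoClassModel(mu=mu, sigma=sigma, threshold=thr)
            cells = rng.normal(0, 6, (50, 40, 3))
            out = sc.classify_cells(delta_grid(cells), model)
            for i in range(50):
                for j in range(40):
                    scores = [
                        sum(
                            ((cells[i, j, a] - mu[c, a]) / sigma[c, a]) ** 2
                            for a in range(3)
                        )
                        for c in range(k)
                    ]
                    best = int(np.argmin(scores))
                    expect = best + 1 if scores[best] < thr else sc.UNCLASSIFIED
                    assert out.labels[i, j] == expect
                    assert out.min_escore[i, j] == pytest.approx(min(scores))

    def test_translation_invariance_via_delta(self):
        rng = np.random.default_rng(3)
        sv = {f: rng.uniform(-90, -60, (4, 6)) for f in (18.0, 38.0, 70.0, 120.0)}
        m = simple_model(mu=rng.normal(0, 3, (3, 3)), sigma=np.ones((3, 3)))
        base = sc.classify_cells(compute_delta_sv(make_set(sv)), m)
        shifted = sc.classify_cells(
            compute_delta_sv(make_set({f: v + 11.7 for f, v in sv.items()})), m
        )
        np.testing.assert_array_equal(base.labels, shifted.labels)
        np.testing.assert_allclose(base.min_escore, shifted.min_escore)


class TestSensitivitySweep:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        m = simple_model(
            mu=np.array([[0.0, 0.0, 0.0], [8.0, 8.0, 8.0]]),
            sigma=np.ones((2, 3)),
        )
        truth = rng.integers(1, 3, size=(10, 10))
        cells = m.mu[truth - 1] + rng.normal(0, 1.0, (10, 10, 3))
        return delta_grid(cells), truth, m

    def test_threshold_zero_all_unclassified(self):
        g, truth, m = self._setup()
        tab = sc.sensitivity_sweep(g, truth, m, thresholds=[0.0])
        allrows = tab[tab.echo_class == "all"]
        assert (allrows.pct_not == 100.0).all()

    def test_huge_threshold_none_unclassified(self):
        g, truth, m = self._setup()
        tab = sc.sensitivity_sweep(g, truth, m, thresholds=[1e9])
        assert (tab.pct_not == 0.0).all()

    def test_not_classified_monotone_in_threshold(self):
        g, truth, m = self._setup(seed=5)
        tab = sc.sensitivity_sweep(g, truth, m, thresholds=np.linspace(0, 60, 40))
        allrows = tab[tab.echo_class == "all"].sort_values("threshold")
        assert (np.diff(allrows.pct_not) <= 1e-9).all()

    def test_shares_sum_to_100(self):
        g, truth, m = self._setup(seed=2)
        tab = sc.sensitivity_sweep(g, truth, m)
        total = tab.pct_well + tab.pct_mis + tab.pct_not
        np.testing.assert_allclose(total, 100.0, atol=1e-9)
        assert 25.0 in set(tab.threshold)  # default sweep includes 25

    def test_empty_truth_rejected(self):
        g, truth, m = self._setup()
        with pytest.raises(ValueError, match="truth"):
            sc.sensitivity_sweep(g, np.zeros_like(truth), m)


class TestPerClassEchograms:
    def test_single_class_identity_over_window(self):
        rng = np.random.default_rng(1)
        sv = {f: rng.uniform(-90, -60, (3, 180)) for f in (18.0, 38.0, 70.0, 120.0)}
        eset = make_set(sv)  # 1.5 m bins to 270 m
        labels = np.ones((3, 180), dtype=int)
        classified = sc.ClassifiedGrid(
            ping_times=eset.ping_times,
            depth_edges=eset.depth_edges,
            labels=labels,
            min_escore=np.zeros((3, 180)),
        )
        grams = sc.per_class_echograms(classified, eset, 38.0)
        assert list(grams) == [1]
        window = (eset.depth_edges[:-1] >= 15.0) & (eset.depth_edges[:-1] < 250.0)
        np.testing.assert_array_equal(grams[1].sv, sv[38.0][:, window])

    def test_partition_conserves_sa(self):
        from escore.echogrid import sv_to_nasc

        rng = np.random.default_rng(2)
        sv = {f: rng.uniform(-90, -60, (4, 180)) for f in (18.0, 38.0, 70.0, 120.0)}
        eset = make_set(sv)
        labels = rng.choice([sc.UNCLASSIFIED, 1, 2, 3], size=(4, 180))
        classified = sc.ClassifiedGrid(
            ping_times=eset.ping_times,
            depth_edges=eset.depth_edges,
            labels=labels,
            min_escore=np.zeros((4, 180)),
        )
        grams = sc.per_class_echograms(classified, eset, 38.0)
        total = sum(sv_to_nasc(g, 15.0, 250.0) for g in grams.values())
        window = (eset.depth_edges[:-1] >= 15.0) & (eset.depth_edges[:-1] < 250.0)
        ref = sc.per_class_echograms(
            sc.ClassifiedGrid(
                ping_times=eset.ping_times,
                depth_edges=eset.depth_edges,
                labels=np.ones((4, 180), int),
                min_escore=np.zeros((4, 180)),
            ),
            eset,
            38.0,
        )[1]
        np.testing.assert_allclose(total, sv_to_nasc(ref, 15.0, 250.0), rtol=1e-12)

    def test_mask_oracle_on_random_grid(self):
        rng = np.random.default_rng(4)
        sv = {38.0: rng.uniform(-90, -60, (3, 40))}
        eset = make_set(sv)
        labels = rng.choice([sc.UNCLASSIFIED, 1, 2], size=(3, 40))
        classified = sc.ClassifiedGrid(
            ping_times=eset.ping_times,
            depth_edges=eset.depth_edges,
            labels=labels,
            min_escore=np.zeros((3, 40)),
        )
        grams = sc.per_class_echograms(classified, eset, 38.0, 15.0, 250.0)
        window = (eset.depth_edges[:-1] >= 15.0) & (eset.depth_edges[:-1] < 250.0)
        for c, g in grams.items():
            expect = np.where(labels == c, sv[38.0], np.nan)[:, window]
            np.testing.assert_array_equal(g.sv, expect)


class TestModelJson:
    def test_roundtrip(self, tmp_path):
        m = simple_model(
            mu=np.array([[1.5, -2.0, 3.0], [0.0, 1.0, -1.0]]),
            sigma=np.array([[0.5, 1.0, 2.0], [1.0, 1.0, 1.0]]),
            threshold=20.0,
        )
        m.dominant_khz = {1: 38.0, 2: 18.0}
        p = tmp_path / "model.json"
        m.to_json(p)
        back = sc.EchoClassModel.from_json(p)
        np.testing.assert_allclose(back.mu, m.mu)
        np.testing.assert_allclose(back.sigma, m.sigma)
        assert back.threshold == 20.0
        assert back.dominant_khz == {1: 38.0, 2: 18.0}
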