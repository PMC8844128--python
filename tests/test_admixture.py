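"""Admixture EM: likelihood correctness, monotonicity, optimum recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize

from beeadmix import simulate
from beeadmix.admixture import (
    LabelingError,
    admixture_loglik,
    em_step,
    fit_admixture,
    label_clusters,
    summarize_population_ancestry,
)
from beeadmix.gl_io import GenotypeLikelihoodDataset, _maf_em_all, _site_loglik


def make_ds(gl, depth=None):
    gl = np.asarray(gl, dtype=float)
    m, n, _ = gl.shape
    return GenotypeLikelihoodDataset(
        site_ids=np.array([f"chr1_{j+1}" for j in range(m)], dtype=object),
        major=np.zeros(m, dtype=np.int8),
        minor=np.ones(m, dtype=np.int8),
        gl=gl,
        depth=depth,
        base_counts=None,
        block_id=np.zeros(m, dtype=int),
        pos=np.arange(1, m + 1),
    )


def loglik_by_hand(ds, q, f):
    """Triple-loop reference implementation of the admixture likelihood."""
    total = 0.0
    inf = ds.informative()
    for i in range(ds.n_individuals):
        for j in range(ds.n_sites):
            if not inf[j, i]:
                continue
            h = sum(q[i, k] * f[k, j] for k in range(q.shape[1]))
            h = min(max(h, 1e-6), 1 - 1e-6)
            s = (ds.gl[j, i, 0] * (1 - h) ** 2
                 + ds.gl[j, i, 1] * 2 * h * (1 - h)
                 + ds.gl[j, i, 2] * h * h)
            total += np.log(s)
    return total


@pytest.fixture
def toy_ds(rng):
    gl = rng.random((2, 2, 3))
    gl /= gl.max(axis=2, keepdims=True)
    return make_ds(gl)


class TestLoglik:
    def test_matches_hand_computation(self, toy_ds, rng):
        q = rng.dirichlet(np.ones(2), size=2)
        f = rng.uniform(0.1, 0.9, size=(2, 2))
        assert admixture_loglik(toy_ds, q, f) == pytest.approx(
            loglik_by_hand(toy_ds, q, f), abs=1e-10
        )

    def test_k1_reduces_to_single_population_likelihood(self, small_study):
        ds = small_study.ds.take_sites(np.arange(50))
        p = np.random.default_rng(0).uniform(0.1, 0.9, size=50)
        ll = admixture_loglik(ds, np.ones((ds.n_individuals, 1)), p[None, :])
        ll_direct = _site_loglik(ds.gl, ds.informative(), p).sum()
        assert ll == pytest.approx(ll_direct, rel=1e-10)

    def test_invariant_under_cluster_relabeling(self, toy_ds, rng):
        q = rng.dirichlet(np.ones(3), size=2)
        f = rng.uniform(0.1, 0.9, size=(3, 2))
        perm = [2, 0, 1]
        assert admixture_loglik(toy_ds, q, f) == pytest.approx(
            admixture_loglik(toy_ds, q[:, perm], f[perm]), abs=1e-12
        )

    def test_shape_mismatch_raises(self, toy_ds):
        with pytest.raises(ValueError):
            admixture_loglik(toy_ds, np.ones((2, 2)) / 2, np.full((3, 2), 0.5))


class TestEMStep:
    def test_loglik_never_decreases_over_50_steps(self, rng):
        cfg = simulate.SimulationConfig(seed=21, n_sites=80)
        panel = simulate.simulate_source_frequencies(cfg, k=2)
        q_true = rng.dirichlet(np.ones(2), size=6)
        gm = simulate.simulate_admixed_genotypes(
            panel, simulate.TrueAncestry(q_true), 21
        )
        ds = simulate.simulate_genotype_likelihoods(gm, cfg)
        q = rng.dirichlet(np.ones(2), size=6)
        f = rng.uniform(0.05, 0.95, size=(2, 80))
        prev = admixture_loglik(ds, q, f)
        for _ in range(50):
            q, f = em_step(ds, q, f)
            cur = admixture_loglik(ds, q, f)
            assert cur >= prev - 1e-8
            prev = cur

    def test_degenerate_single_cluster_is_a_fixed_point(self):
        cfg = simulate.SimulationConfig(seed=22, n_sites=400)
        panel = simulate.simulate_source_frequencies(cfg, k=2, fst=(0.2, 0.2))
        panel.freqs[1] = panel.freqs[0]  # identical clusters
        gm = simulate.simulate_admixed_genotypes(
            panel, simulate.TrueAncestry(np.tile([1.0, 0.0], (8, 1))), 22
        )
        ds = simulate.simulate_genotype_likelihoods(gm, cfg)
        q = np.tile([1.0 - 1e-4, 1e-4], (8, 1))
        q_new, _ = em_step(ds, q, panel.freqs)
        assert np.abs(q_new - q).max() < 1e-3


class TestFit:
    def test_em_reaches_the_numeric_optimum_on_a_tiny_instance(self):
        # 3 individuals x 6 sites, K=2, identifiable by construction:
        # pure, pure, and 50/50 individuals at maximally diverged sites
        f1 = np.array([0.98, 0.02, 0.98, 0.02, 0.98, 0.02])
        gl = np.zeros((6, 3, 3))
        g_by_ind = [np.where(f1 > 0.5, 2, 0), np.where(f1 > 0.5, 0, 2),
                    np.ones(6, dtype=int)]
        for i, g in enumerate(g_by_ind):
            for j in range(6):
                triplet = np.full(3, 1e-6)
                triplet[g[j]] = 1.0
                gl[j, i] = triplet
        ds = make_ds(gl)
        model = fit_admixture(ds, k=2, n_restarts=20, tol=1e-12,
                              max_iter=5000, seed=0, search_iters=None)

        def neg_ll(x):
            q1 = x[:3]
            q = np.stack([q1, 1 - q1], axis=1)
            f = x[3:].reshape(2, 6)
            return -admixture_loglik(ds, q, f)

        best = None
        rng = np.random.default_rng(0)
        for _ in range(30):
            x0 = np.concatenate([rng.random(3), rng.random(12)])
            res = minimize(neg_ll, x0, method="SLSQP",
                           bounds=[(0, 1)] * 15,
                           options={"maxiter": 500, "ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        q_opt = np.stack([best.x[:3], 1 - best.x[:3]], axis=1)
        assert model.loglik == pytest.approx(-best.fun, abs=1e-3)
        # align the label permutation before comparing Q
        delta = min(
            np.abs(model.Q - q_opt).max(),
            np.abs(model.Q[:, ::-1] - q_opt).max(),
        )
        assert delta < 1e-3

    def test_k1_recovers_per_site_maf(self, small_study):
        ds = small_study.ds.take_sites(np.arange(300))
        model = fit_admixture(ds, k=1, n_restarts=1, seed=0, tol=1e-10,
                              max_iter=3000)
        assert np.allclose(model.Q, 1.0)
        p_em, _ = _maf_em_all(ds.gl, ds.informative())
        assert np.abs(model.F[0] - p_em).max() < 1e-3

    def test_two_population_recovery(self):
        # two source populations plus admixed individuals; the pure members
        # anchor the cluster frequencies, making Q identifiable
        cfg = simulate.SimulationConfig(seed=23, n_sites=2000)
        panel = simulate.simulate_source_frequencies(cfg, k=2, fst=0.2)
        q_true = np.vstack([
            np.tile([1.0, 0.0], (8, 1)),
            np.tile([0.0, 1.0], (8, 1)),
            np.tile([0.5, 0.5], (4, 1)),
        ])
        gm = simulate.simulate_admixed_genotypes(
            panel, simulate.TrueAncestry(q_true), 23
        )
        ds = simulate.simulate_genotype_likelihoods(gm, cfg)
        model = fit_admixture(ds, k=2, n_restarts=4, seed=23)
        rmse = min(
            np.sqrt(np.mean((model.Q - q_true) ** 2)),
            np.sqrt(np.mean((model.Q[:, ::-1] - q_true) ** 2)),
        )
        assert rmse < 0.02

    def test_same_seed_identical_model(self, small_study):
        ds = small_study.ds.take_sites(np.arange(150))
        kwargs = dict(k=2, n_restarts=3, seed=7, max_iter=200, search_iters=30)
        m1 = fit_admixture(ds, **kwargs)
        m2 = fit_admixture(ds, **kwargs)
        assert m1.loglik == m2.loglik
        assert np.array_equal(m1.Q, m2.Q)

    def test_invalid_inputs(self, small_study):
        ds = small_study.ds.take_sites(np.arange(10))
        with pytest.raises(ValueError):
            fit_admixture(ds, k=ds.n_individuals + 1)
        with pytest.raises(ValueError):
            fit_admixture(ds.take_sites(np.array([], dtype=int)), k=2)


class TestLabeling:
    def test_reference_panels_map_bijectively(self, small_study, labeled_model):
        assert labeled_model.cluster_labels == ["A", "C", "M", "O"]
        info = small_study.sample_info
        for lab in "AMCO":
            idx = np.flatnonzero(
                (info["role"].values == "reference") & (info["population"].values == lab)
            )
            k = labeled_model.cluster_labels.index(lab)
            assert labeled_model.Q[idx, k].mean() > 0.9

    def test_shuffled_clusters_get_same_labels(self, small_study, labeled_model):
        from dataclasses import replace

        perm = [2, 0, 3, 1]
        shuffled = replace(
            labeled_model, Q=labeled_model.Q[:, perm], F=labeled_model.F[perm],
            cluster_labels=None,
        )
        info = small_study.sample_info
        ref_map = {i: r.population for i, r in info.iterrows() if r.role == "reference"}
        relabeled = label_clusters(shuffled, ref_map)
        assert relabeled.cluster_labels == labeled_model.cluster_labels
        assert np.allclose(relabeled.Q, labeled_model.Q)

    def test_unsupported_lineage_raises(self, labeled_model):
        from dataclasses import replace

        model = replace(labeled_model, cluster_labels=None)
        # references that all sit in one cluster cannot support two lineages
        bad_refs = {0: "A", 1: "A", 2: "X", 3: "X"}
        with pytest.raises(LabelingError):
            label_clusters(model, bad_refs)


class TestSummaries:
    def test_identical_individuals_have_zero_se(self, labeled_model):
        from dataclasses import replace

        q = np.tile(labeled_model.Q[:1], (labeled_model.Q.shape[0], 1))
        model = replace(labeled_model, Q=q)
        out = summarize_population_ancestry(model, {"pop": np.arange(4)})
        assert all(out[f"se_{lab}"].iloc[0] == 0 for lab in model.cluster_labels)

    def test_means_sum_to_hundred(self, small_study, labeled_model):
        info = small_study.sample_info
        pops = {"panama": np.flatnonzero(info["role"].values == "admixed")}
        out = summarize_population_ancestry(labeled_model, pops)
        total = sum(out[f"mean_{lab}"].iloc[0] for lab in labeled_model.cluster_labels)
        assert total == pytest.approx(100.0, abs=1e-4)

    def test_empty_population_raises(self, labeled_model):
        with pytest.raises(ValueError):
            summarize_population_ancestry(labeled_model, {"none": np.array([], int)})
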