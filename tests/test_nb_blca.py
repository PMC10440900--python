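import itertools

import numpy as np
import pytest

from nbblca.data_model import BinaryDataset, PriorConfig, RunConfig
from nbblca.fixtures import sample_from_model
from nbblca.naive_bayes import nb_fit, nb_predict_proba
from nbblca.nb_blca import (
    LatentLayout,
    NBBLCAModel,
    class_posterior_given_latents,
    fit_em,
    fit_gibbs,
    information_criteria,
    loglik,
    model_from_json,
    model_to_json,
    predict_proba,
)


def toy_model(q1_c1=0.9, q1_c2=0.1, theta=((0.9,), (0.1,))):
    layout = LatentLayout.single(len(theta[0]), 2)
    return NBBLCAModel(
        np.array([0.5, 0.5]),
        (np.array([[q1_c1, 1 - q1_c1], [q1_c2, 1 - q1_c2]]),),
        (np.asarray(theta),),
        layout,
        ("c1", "c2"),
    )


def random_model(rng, K=2, G=(2, 3), sizes=(2, 3), C=2):
    layout = LatentLayout.from_sizes(list(sizes), list(G))
    q_c = rng.dirichlet(np.ones(C))
    qs = tuple(rng.dirichlet(np.ones(g), size=C) for g in G)
    ths = tuple(rng.uniform(0.05, 0.95, (g, s)) for g, s in zip(G, sizes))
    return NBBLCAModel(q_c, qs, ths, layout, tuple(f"c{i}" for i in range(C)))


class TestLayout:
    def test_partition_enforced(self):
        with pytest.raises(ValueError):
            LatentLayout(((0, 1), (1, 2)), (2, 2))

    def test_single_covers_all(self):
        lay = LatentLayout.single(5, 3)
        assert lay.blocks == (tuple(range(5)),)
        assert lay.M == 5 and lay.K == 1


class TestClassPosterior:
    def test_uninformative_latent_returns_prior(self):
        m = toy_model(q1_c1=0.7, q1_c2=0.7)
        assert class_posterior_given_latents(m, [0]) == pytest.approx([0.5, 0.5])

    def test_hand_bayes(self):
        m = toy_model(q1_c1=0.9, q1_c2=0.1)
        assert class_posterior_given_latents(m, [0]) == pytest.approx([0.9, 0.1])

    def test_normalized_for_random_models(self, rng):
        for _ in range(5):
            m = random_model(rng)
            profile = [rng.integers(0, g) for g in m.layout.levels]
            assert class_posterior_given_latents(m, profile).sum() == pytest.approx(1.0)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            class_posterior_given_latents(toy_model(), [5])


class TestPredict:
    def test_identical_theta_rows_return_prior(self, rng):
        """Identical item profiles across levels carry no class information:
        marginalisation collapses exactly to the class prior; hard assignment
        does too once the latent-given-class table is uninformative."""
        m = toy_model(theta=((0.4, 0.6), (0.4, 0.6)))
        X = rng.integers(0, 2, (6, 2))
        assert predict_proba(m, X, mode="marginalize") == pytest.approx(
            np.tile([0.5, 0.5], (6, 1))
        )
        flat = toy_model(q1_c1=0.7, q1_c2=0.7, theta=((0.4, 0.6), (0.4, 0.6)))
        assert predict_proba(flat, X, mode="hard") == pytest.approx(
            np.tile([0.5, 0.5], (6, 1))
        )

    def test_single_attribute_explicit_two_term_sum(self):
        m = toy_model()
        # P(x=1|c) = q(l1|c)*0.9 + q(l2|c)*0.1
        lik = {"c1": 0.9 * 0.9 + 0.1 * 0.1, "c2": 0.1 * 0.9 + 0.9 * 0.1}
        want = np.array([lik["c1"], lik["c2"]]) * 0.5
        want /= want.sum()
        assert predict_proba(m, [[1]])[0] == pytest.approx(want, abs=1e-12)

    def test_marginalize_equals_enumeration_oracle(self, rng):
        """Brute force: sum q(c) prod_k q_k(l_k|c) P(x_k | theta_l_k) over all
        latent profiles, for K=3 blocks with up to 3 levels."""
        m = random_model(rng, K=3, G=(2, 3, 2), sizes=(2, 2, 1))
        X = rng.integers(0, 2, (10, 5))
        got = predict_proba(m, X, mode="marginalize")
        for i, x in enumerate(X):
            post = np.zeros(m.n_classes)
            for c in range(m.n_classes):
                total = 0.0
                for profile in itertools.product(*(range(g) for g in m.layout.levels)):
                    term = m.q_c[c]
                    for k, l in enumerate(profile):
                        term *= m.q_given_c[k][c, l]
                        th = m.thetas[k][l]
                        xb = x[list(m.layout.blocks[k])]
                        term *= np.prod(th**xb * (1 - th) ** (1 - xb))
                    total += term
                post[c] = total
            assert got[i] == pytest.approx(post / post.sum(), abs=1e-10)

    def test_reduces_to_nb_with_degenerate_identity_latents(self, rng):
        """One latent per attribute, G_k=2, theta the identity mapping:
        the latent equals the attribute and the model is ordinary NB."""
        X = rng.integers(0, 2, (60, 3))
        y = np.where(rng.random(60) < 0.5, "a", "b")
        train = BinaryDataset(X=X, y=y)
        nb = nb_fit(train, smoothing=0)
        layout = LatentLayout.from_sizes([1, 1, 1], [2, 2, 2])
        qs = tuple(
            np.vstack([[1 - nb.cond_prob[c, k], nb.cond_prob[c, k]] for c in range(2)])
            for k in range(3)
        )
        ths = tuple(np.array([[0.0], [1.0]]) for _ in range(3))
        m = NBBLCAModel(nb.class_prior, qs, ths, layout, train.class_labels)
        assert predict_proba(m, X) == pytest.approx(nb_predict_proba(nb, X), abs=1e-9)

    def test_collapsed_latent_returns_class_prior(self, rng):
        X = rng.integers(0, 2, (40, 4))
        y = np.where(rng.random(40) < 0.3, "a", "b")
        train = BinaryDataset(X=X, y=y)
        model = fit_em(train, LatentLayout.single(4, 1), run=RunConfig(seed=0, n_restarts=1))
        proba = predict_proba(model, X)
        assert np.allclose(proba, proba[0])
        assert proba[0] == pytest.approx(model.q_c, abs=1e-9)


@pytest.fixture(scope="module")
def recovery_setup():
    rng = np.random.default_rng(314)
    layout = LatentLayout.single(10, 2)
    true = NBBLCAModel(
        np.array([0.4, 0.6]),
        (np.array([[0.85, 0.15], [0.2, 0.8]]),),
        (np.vstack([np.full(10, 0.85), np.full(10, 0.15)]),),
        layout,
        ("0", "1"),
    )
    data = sample_from_model(true, 5000, rng)
    return true, data, layout


def _aligned(model, true):
    th, q = model.thetas[0], model.q_given_c[0]
    if abs(th[0].mean() - true.thetas[0][0].mean()) > abs(th[1].mean() - true.thetas[0][0].mean()):
        th, q = th[::-1], q[:, ::-1]
    return th, q


class TestFitEM:
    def test_generative_truth_recovery(self, recovery_setup):
        true, data, layout = recovery_setup
        model = fit_em(data, layout, run=RunConfig(seed=5, n_restarts=10))
        th, q = _aligned(model, true)
        assert np.abs(th - true.thetas[0]).max() < 0.05
        assert np.abs(q - true.q_given_c[0]).max() < 0.05

    def test_two_stage_variant_also_recovers(self, recovery_setup):
        true, data, layout = recovery_setup
        model = fit_em(data, layout, run=RunConfig(seed=5, n_restarts=5), method="two_stage")
        th, q = _aligned(model, true)
        assert np.abs(th - true.thetas[0]).max() < 0.05
        assert np.abs(q - true.q_given_c[0]).max() < 0.05

    def test_objective_monotone(self, recovery_setup):
        """Each EM sweep cannot decrease the joint log posterior."""
        from nbblca.nb_blca import _default_priors, _em_objective

        true, data, layout = recovery_setup
        priors = _default_priors(layout)
        vals = []
        for iters in (1, 2, 4, 8, 16):
            m = fit_em(data, layout, run=RunConfig(seed=9, n_restarts=1, max_iter=iters))
            vals.append(_em_objective(m, data, priors, data.y_indices()))
        assert all(b >= a - 1e-8 * abs(a) for a, b in zip(vals, vals[1:]))

    def test_missing_class_rejected(self, rng):
        ds = BinaryDataset(
            X=rng.integers(0, 2, (10, 2)), y=np.array(["a"] * 10), class_labels=("a", "b")
        )
        with pytest.raises(ValueError):
            fit_em(ds, LatentLayout.single(2, 2))


class TestFitGibbs:
    def test_generative_truth_recovery(self, recovery_setup):
        true, data, layout = recovery_setup
        run = RunConfig(seed=6, gibbs_iters=1200, burn_in=400, thin=2)
        pm, chain = fit_gibbs(data, layout, run=run)
        th, q = _aligned(pm, true)
        assert np.abs(th - true.thetas[0]).max() < 0.05
        assert np.abs(q - true.q_given_c[0]).max() < 0.05
        assert chain.n_draws == 400

    def test_conjugate_conditionals_match_closed_form(self, rng):
        """Freezing the latent assignment, the theta draw distribution is the
        closed-form Beta posterior and the q draw the Dirichlet posterior."""
        n, a, b = 60, 1.0, 1.0
        x = rng.integers(0, 2, n).astype(float)
        z = rng.integers(0, 2, n)
        ones = x[z == 0].sum()
        n0 = (z == 0).sum()
        draws = rng.beta(ones + a, n0 - ones + b, size=20_000)
        assert draws.mean() == pytest.approx((ones + a) / (n0 + a + b), abs=0.01)
        counts = np.bincount(z, minlength=2)
        dirichlet = rng.dirichlet(counts + 1.0, size=20_000)
        assert dirichlet.mean(axis=0) == pytest.approx((counts + 1) / (n + 2), abs=0.01)

    def test_two_chains_converge_to_same_q(self, recovery_setup):
        true, data, layout = recovery_setup
        pms = []
        for seed in (21, 22):
            run = RunConfig(seed=seed, gibbs_iters=600, burn_in=200, thin=2)
            pm, _ = fit_gibbs(data, layout, run=run)
            pms.append(_aligned(pm, true)[1])
        assert np.abs(pms[0] - pms[1]).max() < 0.05


class TestInformationCriteria:
    def test_parameter_count_hand_example(self):
        m = toy_model(theta=((0.9, 0.8, 0.7), (0.1, 0.2, 0.3)))
        # K=1, G=2, M=3, |C|=2: (1*2) + (2*3) + 1 = 9
        assert m.n_parameters() == 9

    def test_aic_bic_algebra(self, recovery_setup):
        true, data, _ = recovery_setup
        out = information_criteria(true, data)
        p, N = out["p"], data.n
        assert out["AIC"] - out["BIC"] == pytest.approx(p * (2 - np.log(N)))

    def test_dic_pd_nonnegative_on_well_behaved_chain(self, recovery_setup):
        true, data, layout = recovery_setup
        run = RunConfig(seed=17, gibbs_iters=400, burn_in=100, thin=2)
        pm, chain = fit_gibbs(data, layout, run=run)
        out = information_criteria(pm, data, chain)
        assert out["p_D"] >= 0
        assert out["DIC"] == pytest.approx(out["p_D"] + (out["DIC"] - out["p_D"]))


def test_model_json_round_trip(rng):
    m = random_model(rng)
    back = model_from_json(model_to_json(m))
    assert back.q_c == pytest.approx(m.q_c)
    for a, b in zip(back.thetas, m.thetas):
        assert a == pytest.approx(b)
    assert back.layout == m.layout
    data = sample_from_model(m, 50, rng)
    assert loglik(back, data) == pytest.approx(loglik(m, data))
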