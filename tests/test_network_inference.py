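import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisnet import network_inference as ni


def test_znormalize_2x2_antisymmetric():
    Z = ni.znormalize(np.array([[0.0, 1.0], [1.0, 0.0]]))
    # row and column z-scores are +-1; combined pattern is antisymmetric
    expected = np.array([[-np.sqrt(2), np.sqrt(2)], [np.sqrt(2), -np.sqrt(2)]])
    np.testing.assert_allclose(Z, expected)


def test_znormalize_overall_mean_zero():
    rng = np.random.default_rng(0)
    Z = ni.znormalize(rng.random((6, 9)))
    assert abs(Z.mean()) < 1e-10


def test_znormalize_constant_matrix_errors():
    with pytest.raises(ValueError):
        ni.znormalize(np.ones((3, 3)))


def test_znormalize_zero_variance_row_falls_back():
    X = np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 4.0]])
    Z = ni.znormalize(X)
    assert np.all(np.isfinite(Z))


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1.0, 0.0], [1.0, 0.0], 1.0),  # identical unit vectors
        ([1.0, 0.0], [0.0, 1.0], 0.0),  # orthogonal
        ([1.0, 1.0], [1.0, 1.0], np.sqrt(2)),  # 2/sqrt(2+2-2)
    ],
)
def test_tanimoto_hand_values(x, y, expected):
    T = ni.tanimoto(np.array([x]), np.array(y)[:, None])
    assert abs(T[0, 0] - expected) < 1e-12


def test_tanimoto_zero_vectors_defined_as_zero():
    T = ni.tanimoto(np.zeros((1, 3)), np.zeros((3, 1)))
    assert T[0, 0] == 0.0


def test_tanimoto_shape_mismatch():
    with pytest.raises(ValueError):
        ni.tanimoto(np.ones((2, 3)), np.ones((4, 2)))


def test_panda_deterministic_and_converges():
    rng = np.random.default_rng(1)
    prior = (rng.random((5, 12)) < 0.4).astype(float)
    prior[0, 0] = 1
    expr = rng.normal(size=(12, 20))
    C = np.corrcoef(expr)
    state1 = ni.panda(prior, None, C, return_state=True)
    state2 = ni.panda(prior, None, C, return_state=True)
    assert state1.converged
    np.testing.assert_array_equal(state1.W, state2.W)
    # mean |dW| shrinks over the final stretch
    assert state1.hamming[-1] < state1.hamming[0]


def test_panda_block_prior_recovers_block_structure():
    """Planted 2-block prior plus matching co-expression: within-block
    weights exceed between-block weights at convergence."""
    rng = np.random.default_rng(2)
    n_tf, n_gene = 6, 20
    prior = np.zeros((n_tf, n_gene))
    prior[:3, :10] = 1.0
    prior[3:, 10:] = 1.0
    latent = np.zeros((n_gene, 30))
    f1, f2 = rng.normal(size=30), rng.normal(size=30)
    latent[:10] = f1
    latent[10:] = f2
    expr = latent + 0.3 * rng.normal(size=(n_gene, 30))
    C = np.corrcoef(expr)
    W = ni.panda(prior, None, C)
    within = np.concatenate([W[:3, :10].ravel(), W[3:, 10:].ravel()])
    between = np.concatenate([W[:3, 10:].ravel(), W[3:, :10].ravel()])
    assert within.mean() > between.mean()


def test_panda_rejects_asymmetric_coexpression():
    prior = np.ones((2, 3))
    C = np.array([[1.0, 0.5, 0.1], [0.2, 1.0, 0.3], [0.1, 0.3, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        ni.panda(prior, None, C)


def test_lioness_toy_matches_direct_formula():
    """N=3: EW_s must equal N*(W_all - W_-s) + W_-s with the leave-one-out
    networks recomputed independently."""
    import warnings

    rng = np.random.default_rng(3)
    prior = np.array([[1.0, 0.0, 1.0, 1.0], [1.0, 1.0, 0.0, 1.0]])
    expr = pd.DataFrame(
        rng.normal(size=(4, 3)),
        index=[f"g{i}" for i in range(4)],
        columns=["s1", "s2", "s3"],
    )
    from cisnet.expression_prep import coexpression

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nets = ni.lioness(prior, expr, tf_ids=["t1", "t2"])
        W_all = ni.panda(prior, None, coexpression(expr).to_numpy())
        for net in nets:
            rest = expr.drop(columns=[net.sample_id])
            W_rest = ni.panda(
                prior, None, coexpression(rest, min_samples=2).to_numpy()
            )
            expected = 3 * (W_all - W_rest) + W_rest
            np.testing.assert_allclose(net.EW.to_numpy(), expected, atol=1e-12)
            # prior-zero entries forced to zero on the softplus scale
            assert net.logEW.to_numpy()[0, 1] == 0.0


def test_lioness_sample_order_equivariance():
    rng = np.random.default_rng(4)
    prior = (rng.random((3, 5)) < 0.6).astype(float)
    prior[0, 0] = 1
    expr = pd.DataFrame(
        rng.normal(size=(5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=["s1", "s2", "s3", "s4"],
    )
    nets = {n.sample_id: n for n in ni.lioness(prior, expr)}
    permuted = expr[["s3", "s1", "s4", "s2"]]
    nets_p = {n.sample_id: n for n in ni.lioness(prior, permuted)}
    for s in expr.columns:
        np.testing.assert_allclose(
            nets[s].EW.to_numpy(), nets_p[s].EW.to_numpy(), atol=1e-12
        )


def test_lioness_requires_three_samples():
    prior = np.ones((2, 2))
    expr = pd.DataFrame(np.ones((2, 2)), columns=["s1", "s2"])
    with pytest.raises(ValueError):
        ni.lioness(prior, expr)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.lists(
        # below ~ -700, exp underflows and the float64 softplus rounds to 0
        st.floats(min_value=-700.0, max_value=1e3, allow_nan=False),
        min_size=1,
        max_size=30,
    )
)
def test_softplus_positive_and_order_preserving(values):
    x = np.array(values)
    y = ni.softplus_transform(x)
    assert np.all(y > 0)
    assert np.all(y >= x)  # softplus dominates the identity
    order = np.argsort(x, kind="stable")
    assert np.all(np.diff(y[order]) >= 0)


def test_softplus_monotone_positive():
    rng = np.random.default_rng(5)
    x = np.sort(rng.normal(scale=10, size=1000))
    y = ni.softplus_transform(x)
    assert np.all(y > 0)
    assert np.all(np.diff(y) > 0)
    # overflow-safe far tail
    assert ni.softplus_transform(np.array([1000.0]))[0] == 1000.0
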