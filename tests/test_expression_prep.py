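import numpy as np
import pandas as pd
import pytest

from cisnet import expression_prep as ep
from cisnet.genomic_io import ExpressionMatrix


def _expr(values, tissues, batches=None, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    idx = pd.Index(samples)
    batches = batches or ["b1"] * len(samples)
    return ExpressionMatrix(
        df, pd.Series(tissues, index=idx), pd.Series(batches, index=idx)
    )


def test_filter_expressed_rules():
    expr = _expr(
        [
            [5, 2, 1, 0, 0, 0],  # 3 samples >=1 in tissue A -> kept
            [1, 1, 0, 0, 1, 0],  # only 2 per tissue -> dropped
            [0, 0, 0, 2, 3, 4],  # kept via tissue B
        ],
        ["A", "A", "A", "B", "B", "B"],
    )
    out = ep.filter_expressed(expr, min_samples=3, min_count=1)
    assert list(out.values.index) == ["g0", "g2"]


def test_filter_warns_on_small_tissue():
    expr = _expr([[1, 1, 1]], ["A", "A", "B"])
    with pytest.warns(UserWarning, match="cannot qualify"):
        ep.filter_expressed(expr, min_samples=3)


def _plain_quantile_normalize(X):
    order = np.argsort(X, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=0)
    ref = sorted_vals.mean(axis=1)
    out = np.empty_like(X)
    for s in range(X.shape[1]):
        out[order[:, s], s] = ref
    return out


@pytest.mark.parametrize("tissues", [["A"] * 4, ["A", "A", "B", "B"]])
def test_qsmooth_reduces_to_quantile_normalization(tissues):
    """Single group, or groups drawn from one distribution (SSB ~ 0):
    qsmooth equals plain quantile normalization."""
    rng = np.random.default_rng(0)
    base = np.sort(rng.random(50) * 10)
    # same distribution in every sample: permuted copies
    X = np.stack([rng.permutation(base) for _ in range(4)], axis=1)
    expr = _expr(X, tissues)
    out = ep.qsmooth_normalize(expr).values.to_numpy()
    np.testing.assert_allclose(out, _plain_quantile_normalize(X), atol=1e-9)


def test_qsmooth_preserves_within_sample_ranks():
    rng = np.random.default_rng(1)
    X = rng.random((200, 6)) * np.array([1, 1, 1, 5, 5, 5])  # disjoint scales
    expr = _expr(X, ["A", "A", "A", "B", "B", "B"])
    out = ep.qsmooth_normalize(expr).values.to_numpy()
    for s in range(6):
        orig = np.argsort(X[:, s], kind="stable")
        assert np.all(np.diff(out[orig, s]) >= -1e-12)


def test_qsmooth_two_groups_disjoint_support_keeps_group_medians_apart():
    rng = np.random.default_rng(2)
    a = rng.random((100, 2))
    b = rng.random((100, 2)) + 10
    expr = _expr(np.hstack([a, b]), ["A", "A", "B", "B"])
    out = ep.qsmooth_normalize(expr).values.to_numpy()
    assert np.median(out[:, 2:]) > np.median(out[:, :2])


def test_remove_batch_recovers_planted_shift():
    rng = np.random.default_rng(3)
    tissues = ["A", "A", "A", "A", "B", "B", "B", "B"]
    batches = ["p", "q", "p", "q", "p", "q", "p", "q"]
    # noise-free gene profiles: the planted +2 shift is removed exactly
    X = np.tile(rng.normal(5, 1, size=(40, 1)), (1, 8))
    X[:, 4:] += 1.5  # a genuine tissue effect, which must be preserved
    shifted = X.copy()
    shifted[:, np.array(batches) == "q"] += 2.0
    expr = _expr(shifted, tissues, batches)
    out = ep.remove_batch(expr).values.to_numpy()
    np.testing.assert_allclose(out, X, atol=1e-8)
    # with noise, re-fitting the corrected data finds zero batch effect
    noisy = shifted + rng.normal(0, 0.3, size=shifted.shape)
    out_n = ep.remove_batch(_expr(noisy, tissues, batches)).values.to_numpy()
    T = np.stack([(np.array(tissues) == t).astype(float) for t in ("A", "B")], axis=1)
    B = (np.array(batches) == "q").astype(float)[:, None]
    design = np.hstack([T, B])
    coef, *_ = np.linalg.lstsq(design, out_n.T, rcond=None)
    np.testing.assert_allclose(coef[2], 0.0, atol=1e-8)


def test_remove_batch_idempotent_and_identity_cases():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 6))
    expr = _expr(X, ["A"] * 3 + ["B"] * 3, ["p", "q", "p", "q", "p", "q"])
    once = ep.remove_batch(expr)
    twice = ep.remove_batch(once)
    np.testing.assert_allclose(
        once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10
    )
    single = _expr(X, ["A"] * 3 + ["B"] * 3, ["p"] * 6)
    np.testing.assert_array_equal(
        ep.remove_batch(single).values.to_numpy(), X
    )


def test_remove_batch_confounded_design_errors():
    expr = _expr(
        np.ones((5, 4)), ["A", "A", "B", "B"], ["p", "p", "q", "q"]
    )
    with pytest.raises(ValueError, match="confounded"):
        ep.remove_batch(expr)


def test_coexpression_properties():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(4, 10))
    X[1] = X[0]  # duplicate
    X[2] = -X[0]  # negation
    X[3] = 7.0  # constant
    expr = _expr(X, ["A"] * 10)
    C = ep.coexpression(expr).to_numpy()
    assert abs(C[0, 1] - 1.0) < 1e-12
    assert abs(C[0, 2] + 1.0) < 1e-12
    assert C[3, 0] == 0.0 and C[3, 3] == 1.0
    np.testing.assert_allclose(C, C.T)
    assert np.all(C >= -1) and np.all(C <= 1)


def test_coexpression_requires_three_samples():
    expr = _expr(np.ones((3, 2)), ["A", "A"])
    with pytest.raises(ValueError):
        ep.coexpression(expr)
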