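"""Cross-entropy and MMD estimators against closed forms and kernel sums."""

import numpy as np
import pytest

import tianet as tn
from tianet._autograd import Tensor
from tianet.losses import LossConfig, mmd_squared, mmd_squared_graph


def _kernel(x, y, cfg, sigma_sq):
    if cfg.kernel == "linear":
        return float(x @ y)
    if cfg.kernel == "polynomial":
        return float((x @ y + 1) ** cfg.poly_degree)
    return float(np.exp(-((x - y) @ (x - y)) / (2 * sigma_sq)))


def _mmd_double_sum(ms, mt, cfg, sigma_sq=1.0):
    ns, nt = len(ms), len(mt)
    total = 0.0
    for a in ms:
        for b in ms:
            total += _kernel(a, b, cfg, sigma_sq) / ns**2
    for a in mt:
        for b in mt:
            total += _kernel(a, b, cfg, sigma_sq) / nt**2
    for a in ms:
        for b in mt:
            total -= 2 * _kernel(a, b, cfg, sigma_sq) / (ns * nt)
    return total


class TestCrossEntropy:
    def test_uniform_logits_give_log_k(self):
        for k in (2, 3, 7):
            logits = np.zeros((4, k))
            assert abs(tn.cross_entropy(logits, np.zeros(4, dtype=int)) - np.log(k)) < 1e-12

    def test_large_margin_drives_loss_to_zero(self):
        labels = np.array([0, 1])
        prev = np.inf
        for margin in (1.0, 10.0, 50.0):
            logits = np.array([[margin, 0.0], [0.0, margin]])
            loss = tn.cross_entropy(logits, labels)
            assert loss < prev
            prev = loss
        assert prev < 1e-20

    def test_random_logits_match_softmax_log_sum_oracle(self, rng):
        logits = rng.normal(size=(4, 3))
        labels = rng.integers(0, 3, 4)
        expected = 0.0
        for i in range(4):
            p = np.exp(logits[i]) / np.exp(logits[i]).sum()
            expected -= np.log(p[labels[i]]) / 4
        assert abs(tn.cross_entropy(logits, labels) - expected) < 1e-10


class TestMMD:
    def test_identical_batches_give_zero(self, rng):
        x = rng.normal(size=(6, 4))
        for kernel in ("linear", "gaussian_rbf", "polynomial"):
            cfg = LossConfig(kernel=kernel, bandwidth=1.0 if kernel == "gaussian_rbf"
                             else "median-heuristic")
            assert abs(mmd_squared(x, x.copy(), cfg)) <= 1e-12

    def test_linear_kernel_single_samples_is_squared_distance(self, rng):
        x, y = rng.normal(size=3), rng.normal(size=3)
        cfg = LossConfig(kernel="linear")
        assert abs(mmd_squared(x[None], y[None], cfg) - ((x - y) @ (x - y))) < 1e-12

    def test_linear_kernel_equals_mean_embedding_distance(self, rng):
        ms, mt = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        cfg = LossConfig(kernel="linear")
        d = ms.mean(0) - mt.mean(0)
        assert abs(mmd_squared(ms, mt, cfg) - d @ d) < 1e-12

    @pytest.mark.parametrize("kernel", ["linear", "gaussian_rbf", "polynomial"])
    def test_matches_explicit_double_sum(self, kernel, rng):
        ms, mt = rng.normal(size=(4, 3)), rng.normal(size=(6, 3))
        cfg = LossConfig(kernel=kernel, bandwidth=1.7 if kernel == "gaussian_rbf"
                         else "median-heuristic")
        expected = _mmd_double_sum(ms, mt, cfg, sigma_sq=1.7**2)
        assert abs(mmd_squared(ms, mt, cfg) - expected) < 1e-10

    def test_symmetric_in_batches(self, rng):
        ms, mt = rng.normal(size=(4, 2)), rng.normal(size=(5, 2))
        cfg = LossConfig()
        assert abs(mmd_squared(ms, mt, cfg) - mmd_squared(mt, ms, cfg)) < 1e-12

    def test_linear_kernel_quadratic_scaling(self, rng):
        ms, mt = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        cfg = LossConfig(kernel="linear")
        base = mmd_squared(ms, mt, cfg)
        assert abs(mmd_squared(3 * ms, 3 * mt, cfg) - 9 * base) < 1e-9

    def test_gaussian_bounded_by_four(self, rng):
        for _ in range(20):
            ms = rng.normal(size=(rng.integers(1, 8), 4)) * 10
            mt = rng.normal(size=(rng.integers(1, 8), 4)) * 10
            v = mmd_squared(ms, mt, LossConfig())
            assert -1e-12 <= v <= 4.0

    def test_unbiased_estimator_zero_mean_under_null(self, rng):
        """U-statistic averages near 0 when both batches share a distribution."""
        vals = [
            mmd_squared(rng.normal(size=(20, 2)), rng.normal(size=(20, 2)),
                        LossConfig(kernel="linear", unbiased=True))
            for _ in range(200)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mmd_squared(np.zeros((0, 3)), np.zeros((2, 3)), LossConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(lambda_disc=-1.0)
        with pytest.raises(ValueError):
            LossConfig(bandwidth=-2.0)
        with pytest.raises(ValueError):
            LossConfig(kernel="laplace")


class TestCombinedLoss:
    class _ToyModel:
        """Linear two-head model exposing the forward_joint contract."""

        def __init__(self, rng):
            self.W = Tensor(rng.normal(size=(6, 3)), requires_grad=True)
            self.A = Tensor(rng.normal(size=(6, 4)), requires_grad=True)

        def forward_joint(self, xs, xt, training=False, rng=None):
            ls = Tensor(xs) @ self.W
            lt = Tensor(xt) @ self.W
            vs = (Tensor(xs) @ self.A).sigmoid()
            vt = (Tensor(xt) @ self.A).sigmoid()
            return ls, lt, vs, vt

    def test_lambda_zero_is_sum_of_cross_entropies(self, rng):
        model = self._ToyModel(rng)
        xs, xt = rng.normal(size=(5, 6)), rng.normal(size=(4, 6))
        ys, yt = rng.integers(0, 3, 5), rng.integers(0, 3, 4)
        loss, comps = tn.combined_loss((xs, ys), (xt, yt), model,
                                       LossConfig(lambda_disc=0.0))
        assert comps["mmd"] == 0.0
        assert abs(comps["loss"] - comps["ce_s"] - comps["ce_t"]) < 1e-12

    def test_identical_batches_have_negligible_discrepancy(self, rng):
        model = self._ToyModel(rng)
        x = rng.normal(size=(4, 6))
        y = rng.integers(0, 3, 4)
        _, comps = tn.combined_loss((x, y), (x.copy(), y.copy()), model,
                                    LossConfig())
        assert comps["mmd"] <= 1e-12

    def test_components_recompose_to_total(self, rng):
        model = self._ToyModel(rng)
        xs, xt = rng.normal(size=(5, 6)), rng.normal(size=(4, 6))
        ys, yt = rng.integers(0, 3, 5), rng.integers(0, 3, 4)
        cfg = LossConfig(lambda_disc=2.5)
        loss, comps = tn.combined_loss((xs, ys), (xt, yt), model, cfg)
        lhs = comps["ce_s"] + comps["ce_t"] + 2.5 * comps["mmd"]
        assert abs(comps["loss"] - lhs) < 1e-10
        # independently recompute each part with the public oracles
        ls, lt, vs, vt = model.forward_joint(xs, xt)
        assert abs(comps["ce_s"] - tn.cross_entropy(ls.data, ys)) < 1e-10
        assert abs(comps["ce_t"] - tn.cross_entropy(lt.data, yt)) < 1e-10
        assert abs(comps["mmd"] - mmd_squared(vs.data, vt.data, cfg)) < 1e-10

    def test_discrepancy_contributes_to_gradient(self, rng):
        """With differing distributions and lambda>0, the attention-path
        parameters receive a gradient contribution from the MMD term."""
        xs = rng.normal(size=(5, 6)) + 2.0
        xt = rng.normal(size=(4, 6)) - 2.0
        ys, yt = rng.integers(0, 3, 5), rng.integers(0, 3, 4)

        grads = {}
        for lam in (0.0, 5.0):
            model = self._ToyModel(np.random.default_rng(7))
            loss, _ = tn.combined_loss((xs, ys), (xt, yt), model,
                                       LossConfig(lambda_disc=lam, kernel="linear"))
            loss.backward()
            grads[lam] = model.A.grad.copy() if model.A.grad is not None else 0.0
        assert np.any(grads[0.0] != grads[5.0])
        assert np.abs(grads[5.0]).max() > 0


def test_graph_mmd_matches_numpy_mmd(rng):
    ms, mt = rng.normal(size=(5, 3)), rng.normal(size=(6, 3))
    cfg = LossConfig()
    g = mmd_squared_graph(Tensor(ms), Tensor(mt), cfg)
    assert abs(float(g.data) - mmd_squared(ms, mt, cfg)) < 1e-12
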