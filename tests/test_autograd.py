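"""Gradient correctness of the autodiff core against central differences."""

import numpy as np
import pytest

from msrunet.autograd import Tensor, concat, default_dtype, layer_norm, no_grad, softmax
from msrunet.nn import Conv2d, DepthwiseConv2d, LayerNorm, Linear, trunc_normal

from conftest import numeric_grad


def _check_grad(make_output, x_data, tol=1e-5):
    """Compare analytic grad of sum(f(x) * w) against central differences."""
    rng = np.random.default_rng(0)
    x = Tensor(x_data.copy(), requires_grad=True)
    out = make_output(x)
    w = rng.normal(size=out.shape)
    (out * Tensor(w)).sum().backward()

    def scalar():
        return float((make_output(Tensor(x.data)).data * w).sum())

    num = numeric_grad(scalar, x.data)
    assert np.allclose(x.grad, num, rtol=1e-4, atol=tol)


@pytest.mark.parametrize(
    "fn",
    [
        lambda x: x.exp(),
        lambda x: (x + 3.0).log(),
        lambda x: x.tanh(),
        lambda x: x.gelu(),
        lambda x: x.relu(),
        lambda x: (x * x).sum(axis=0, keepdims=True),
        lambda x: x.mean(axis=1),
        lambda x: x.max(axis=0),
        lambda x: x.reshape(6, 2),
        lambda x: x.transpose((1, 0)),
        lambda x: x[1:3, ::2],
        lambda x: x.pad(((1, 2), (0, 1))),
        lambda x: softmax(x, axis=-1),
        lambda x: x / (x * x + 1.0),
        lambda x: x**3,
    ],
    ids=["exp", "log", "tanh", "gelu", "relu", "sum", "mean", "max", "reshape",
         "transpose", "slice", "pad", "softmax", "div", "pow"],
)
def test_elementwise_and_shape_op_gradients(fn):
    rng = np.random.default_rng(3)
    _check_grad(fn, rng.normal(size=(3, 4)))


def test_matmul_gradients_batched():
    rng = np.random.default_rng(4)
    b = Tensor(rng.normal(size=(2, 4, 5)), requires_grad=True)

    def f(x):
        return x @ b

    _check_grad(f, rng.normal(size=(2, 3, 4)))


def test_broadcast_add_unbroadcasts_gradient():
    a = Tensor(np.ones((2, 3)), requires_grad=True)
    bias = Tensor(np.ones(3), requires_grad=True)
    ((a + bias) * 2.0).sum().backward()
    assert a.grad.shape == (2, 3)
    assert bias.grad.shape == (3,)
    assert np.allclose(bias.grad, [4.0, 4.0, 4.0])  # summed over the batch axis


def test_shared_gradient_buffers_accumulate_correctly():
    # y = x + x routes the same upstream array to both parents; the result
    # must be 2x, not a silently aliased 1x
    x = Tensor(np.arange(3.0), requires_grad=True)
    (x + x).sum().backward()
    assert np.allclose(x.grad, [2.0, 2.0, 2.0])


def test_concat_round_trip_gradient():
    x = Tensor(np.arange(6.0).reshape(2, 3), requires_grad=True)
    y = Tensor(np.ones((2, 2)), requires_grad=True)
    c = concat([x, y], axis=1)
    (c * c).sum().backward()
    assert np.allclose(x.grad, 2 * x.data)
    assert np.allclose(y.grad, 2 * y.data)


def test_max_ties_route_gradient_to_first_occurrence():
    x = Tensor(np.array([[1.0, 1.0, 0.0]]), requires_grad=True)
    x.max(axis=1).sum().backward()
    assert np.allclose(x.grad, [[1.0, 0.0, 0.0]])


def test_no_grad_suppresses_graph():
    x = Tensor(np.ones(3), requires_grad=True)
    with no_grad():
        y = x * 2.0
    assert not y.requires_grad


def test_softmax_rows_sum_to_one():
    rng = np.random.default_rng(5)
    y = softmax(Tensor(rng.normal(scale=10.0, size=(8, 11))), axis=-1)
    assert np.allclose(y.data.sum(axis=-1), 1.0, atol=1e-6)


def test_layer_norm_matches_reference_and_gradients():
    rng = np.random.default_rng(6)
    x_data = rng.normal(size=(4, 7))
    gamma = Tensor(rng.normal(size=7) + 1.0, requires_grad=True)
    beta = Tensor(rng.normal(size=7), requires_grad=True)

    out = layer_norm(Tensor(x_data), gamma, beta)
    mu = x_data.mean(-1, keepdims=True)
    sd = np.sqrt(x_data.var(-1, keepdims=True) + 1e-6)
    ref = (x_data - mu) / sd * gamma.data + beta.data
    assert np.allclose(out.data, ref, atol=1e-10)

    def f(x):
        return layer_norm(x, gamma, beta)

    _check_grad(f, x_data)


@pytest.mark.parametrize(
    "layer_factory,cin",
    [
        (lambda rng: Conv2d(3, 5, kernel=3, stride=2, padding=1, rng=rng), 3),
        (lambda rng: Conv2d(2, 4, kernel=7, stride=4, padding=3, rng=rng), 2),
        (lambda rng: DepthwiseConv2d(3, rng=rng), 3),
    ],
    ids=["conv3s2", "conv7s4", "depthwise"],
)
def test_convolution_gradients(layer_factory, cin):
    rng = np.random.default_rng(7)
    layer = layer_factory(rng)
    x_data = rng.normal(size=(2, 9, 8, cin))
    x = Tensor(x_data, requires_grad=True)
    out = layer(x)
    w = rng.normal(size=out.shape)
    (out * Tensor(w)).sum().backward()

    for tensor in [x] + layer.parameters():
        def scalar():
            return float((layer(Tensor(x.data)).data * w).sum())

        num = numeric_grad(scalar, tensor.data)
        assert np.allclose(tensor.grad, num, rtol=1e-4, atol=1e-6)


def test_conv2d_matches_scipy_correlation():
    from scipy.signal import correlate2d

    rng = np.random.default_rng(8)
    conv = Conv2d(1, 1, kernel=3, stride=1, padding=1, rng=rng)
    x = rng.normal(size=(1, 6, 6, 1))
    out = conv(Tensor(x)).data[0, :, :, 0]
    ref = correlate2d(x[0, :, :, 0], conv.weight.data[:, :, 0, 0], mode="same")
    assert np.allclose(out, ref + conv.bias.data[0], atol=1e-10)


def test_default_dtype_context():
    with default_dtype("float32"):
        t = Tensor(np.zeros(3))
        assert t.data.dtype == np.float32
    assert Tensor(np.zeros(3)).data.dtype == np.float64


def test_trunc_normal_bounded():
    x = trunc_normal((1000,), std=0.02, rng=np.random.default_rng(0))
    assert np.abs(x).max() <= 0.04 + 1e-12
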