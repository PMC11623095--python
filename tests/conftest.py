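import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    g = np.zeros_like(x, dtype=float)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        f1 = f()
        flat[i] = orig - eps
        f0 = f()
        flat[i] = orig
        gf[i] = (f1 - f0) / (2 * eps)
    return g


def dense_attention(x, h):
    """Brute-force single-head softmax self-attention over flattened tokens.

    Independent oracle: plain loops over queries/keys, no shared code with
    the package's attention path.
    """
    tokens = x.reshape(-1, x.shape[-1])
    n, c = tokens.shape
    out = np.zeros_like(tokens)
    for q in range(n):
        scores = np.array(
            [float(tokens[q] @ tokens[k]) / np.sqrt(h) for k in range(n)]
        )
        w = np.exp(scores - scores.max())
        w = w / w.sum()
        for k in range(n):
            out[q] += w[k] * tokens[k]
    return out.reshape(x.shape)
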