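"""Plain-numpy building blocks for the 1-D convolutional classifier.

Everything operates on channels-last arrays: a batch of windows is
``(n, L, C)`` with L window positions and C features per position.  Conv1d is
implemented as im2col + matmul with 'same' zero padding; training uses Adam
with softmax cross-entropy.  All randomness flows through an explicit
``numpy.random.Generator``, so training is reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# primitive layers


def im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """(n, L, C) -> (n, L, kernel*C) patch matrix with 'same' zero padding."""
    n, L, C = x.shape
    half = kernel // 2
    xp = np.pad(x, ((0, 0), (half, half), (0, 0)))
    cols = np.empty((n, L, kernel, C))
    for i in range(kernel):
        cols[:, :, i, :] = xp[:, i : i + L, :]
    return cols.reshape(n, L, kernel * C)


def conv_forward(x, W, b, kernel):
    cols = im2col(x, kernel)
    y = cols @ W + b
    return y, (cols, x.shape)


def conv_backward(dy, cache, W, kernel):
    cols, x_shape = cache
    n, L, C = x_shape
    dy2 = dy.reshape(n * L, -1)
    dW = cols.reshape(n * L, -1).T @ dy2
    db = dy2.sum(axis=0)
    dcols = (dy2 @ W.T).reshape(n, L, kernel, C)
    half = kernel // 2
    dxp = np.zeros((n, L + 2 * half, C))
    for i in range(kernel):
        dxp[:, i : i + L, :] += dcols[:, :, i, :]
    dx = dxp[:, half : half + L, :]
    return dx, dW, db


def maxpool_forward(x, size=2):
    n, L, C = x.shape
    Lo = L // size
    xr = x[:, : Lo * size].reshape(n, Lo, size, C)
    idx = xr.argmax(axis=2)
    return xr.max(axis=2), (idx, x.shape, size)


def maxpool_backward(dy, cache):
    idx, x_shape, size = cache
    n, L, C = x_shape
    Lo = dy.shape[1]
    dxr = np.zeros((n, Lo, size, C))
    np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros(x_shape)
    dx[:, : Lo * size] = dxr.reshape(n, Lo * size, C)
    return dx


def relu(x):
    return np.maximum(x, 0.0)


def dropout_mask(rng: np.random.Generator, shape, rate: float):
    if rate <= 0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the network: conv0 -> [conv,conv,+skip,pool] x2 -> conv5,conv6 -> dense x2 -> softmax

CONV_NAMES = [f"conv{i}" for i in range(7)]


def init_params(
    rng: np.random.Generator,
    n_channels: int,
    window: int,
    filters: int,
    kernel: int,
    dense_units: int,
    n_pg: int,
) -> dict[str, np.ndarray]:
    """He-initialised weights for the fixed architecture."""
    params: dict[str, np.ndarray] = {}

    def he(fan_in, shape):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    in_ch = n_channels
    for name in CONV_NAMES:
        params[f"{name}_W"] = he(kernel * in_ch, (kernel * in_ch, filters))
        params[f"{name}_b"] = np.zeros(filters)
        in_ch = filters
    L_flat = (window // 2 // 2) * filters  # two stride-2 max pools
    params["dense1_W"] = he(L_flat + n_pg, (L_flat + n_pg, dense_units))
    params["dense1_b"] = np.zeros(dense_units)
    params["dense2_W"] = he(dense_units, (dense_units, dense_units))
    params["dense2_b"] = np.zeros(dense_units)
    params["out_W"] = he(dense_units, (dense_units, 2))
    params["out_b"] = np.zeros(2)
    return params


def forward(params, X, kernel, pg=None, dropout_rate=0.0, rng=None):
    """Forward pass; returns class probabilities and caches for backprop.

    ``X`` is (n, L, C); ``pg`` an optional (n, n_pg) side input concatenated
    before the dense layers.  Dropout is applied only when ``rng`` is given
    (training mode).
    """
    cache: dict = {}

    def conv(name, x, act=True):
        y, c = conv_forward(x, params[f"{name}_W"], params[f"{name}_b"], kernel)
        cache[name] = c
        if act:
            cache[f"{name}_pre"] = y
            return relu(y)
        return y

    a0 = conv("conv0", X)
    # residual block 1
    a1 = conv("conv1", a0)
    z2 = conv("conv2", a1, act=False)
    s1 = z2 + a0
    cache["s1_pre"] = s1
    r1 = relu(s1)
    p1, cache["pool1"] = maxpool_forward(r1)
    # residual block 2
    a3 = conv("conv3", p1)
    z4 = conv("conv4", a3, act=False)
    s2 = z4 + p1
    cache["s2_pre"] = s2
    r2 = relu(s2)
    p2, cache["pool2"] = maxpool_forward(r2)
    a5 = conv("conv5", p2)
    a6 = conv("conv6", a5)
    flat = a6.reshape(a6.shape[0], -1)
    if pg is not None:
        flat = np.concatenate([flat, pg], axis=1)
    cache["flat_shape"] = a6.shape
    cache["n_pg"] = 0 if pg is None else pg.shape[1]
    cache["flat"] = flat

    h1_pre = flat @ params["dense1_W"] + params["dense1_b"]
    h1 = relu(h1_pre)
    m1 = dropout_mask(rng, h1.shape, dropout_rate) if rng is not None else None
    if m1 is not None:
        h1 = h1 * m1
    h2_pre = h1 @ params["dense2_W"] + params["dense2_b"]
    h2 = relu(h2_pre)
    m2 = dropout_mask(rng, h2.shape, dropout_rate) if rng is not None else None
    if m2 is not None:
        h2 = h2 * m2
    logits = h2 @ params["out_W"] + params["out_b"]
    probs = softmax(logits)
    cache.update(h1_pre=h1_pre, h1=h1, m1=m1, h2_pre=h2_pre, h2=h2, m2=m2)
    return probs, cache


def backward(params, cache, probs, y, kernel):
    """Gradients of mean softmax cross-entropy w.r.t. every parameter."""
    n = probs.shape[0]
    grads: dict[str, np.ndarray] = {}
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    grads["out_W"] = cache["h2"].T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dh2 = dlogits @ params["out_W"].T
    if cache["m2"] is not None:
        dh2 = dh2 * cache["m2"]
    dh2 = dh2 * (cache["h2_pre"] > 0)
    grads["dense2_W"] = cache["h1"].T @ dh2
    grads["dense2_b"] = dh2.sum(axis=0)
    dh1 = dh2 @ params["dense2_W"].T
    if cache["m1"] is not None:
        dh1 = dh1 * cache["m1"]
    dh1 = dh1 * (cache["h1_pre"] > 0)
    grads["dense1_W"] = cache["flat"].T @ dh1
    grads["dense1_b"] = dh1.sum(axis=0)
    dflat = dh1 @ params["dense1_W"].T
    n_pg = cache["n_pg"]
    if n_pg:
        dflat = dflat[:, :-n_pg]
    da6 = dflat.reshape(cache["flat_shape"])

    def conv_back(name, dy, act=True):
        if act:
            dy = dy * (cache[f"{name}_pre"] > 0)
        dx, dW, db = conv_backward(dy, cache[name], params[f"{name}_W"], kernel)
        grads[f"{name}_W"] = dW
        grads[f"{name}_b"] = db
        return dx

    da5 = conv_back("conv6", da6)
    dp2 = conv_back("conv5", da5)
    dr2 = maxpool_backward(dp2, cache["pool2"])
    ds2 = dr2 * (cache["s2_pre"] > 0)
    da3 = conv_back("conv4", ds2, act=False)
    dp1 = conv_back("conv3", da3) + ds2  # skip connection
    dr1 = maxpool_backward(dp1, cache["pool1"])
    ds1 = dr1 * (cache["s1_pre"] > 0)
    da1 = conv_back("conv2", ds1, act=False)
    da0 = conv_back("conv1", da1) + ds1  # skip connection
    conv_back("conv0", da0)
    return grads


def cross_entropy(probs, y):
    n = len(y)
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
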