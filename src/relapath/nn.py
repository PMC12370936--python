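"""Minimal CPU convolutional encoder with hand-written backprop.

The encoder maps a grayscale image (replicated to 3 identical channels) to a
single scalar.  Architecture: conv(16, k2) - ReLU - conv(32, k2) - ReLU -
maxpool(4) - conv(32, k3) - ReLU - maxpool(6) - linear(flat -> 1), all conv
padding 1.  At the native 224x224 input the flattened pre-linear activation
is 2592-dimensional.

Implementation notes
--------------------
Convolutions use a "shift-and-GEMM" scheme: activations live in a
channels-last, zero-padded buffer whose rows are flattened, so each of the
k*k kernel taps corresponds to a *contiguous* slice of the flat buffer and
the whole convolution is k*k sgemm calls with no im2col copy.  Output rows
contain (k-1) garbage columns at the end of every image row; those columns
are never read (pooling/repacking index only the valid region) and their
gradient entries are kept at exactly zero so that merged-batch GEMMs remain
correct.  Elementwise stages (bias+ReLU+repack, bias+ReLU+maxpool and their
adjoints) are fused numba kernels.  Everything is float32.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F32 = np.float32

__all__ = ["ConvEncoder", "encoder_geometry"]


def encoder_geometry(side: int) -> dict:
    """Spatial sizes of every stage for a `side` x `side` input.

    Raises ValueError when the input is too small for the final 6x6 pool.
    """
    h1 = side + 1          # conv k2, pad 1
    h2 = h1 + 1            # conv k2, pad 1
    p2 = h2 // 4           # maxpool k4 (floor)
    h3 = p2                # conv k3, pad 1
    p3 = h3 // 6           # maxpool k6 (floor)
    if p3 < 1:
        raise ValueError(f"input side {side} too small for the pooling stack")
    return {"side": side, "h1": h1, "h2": h2, "p2": p2, "h3": h3, "p3": p3,
            "flat": 32 * p3 * p3}


# ---------------------------------------------------------------------------
# fused elementwise kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _relu_repack(y, b, xout, B, S, wp, h, w):
    # xout[n, i+1, j+1, c] = relu(y[n*S + i*wp + j, c] + b[c])
    C = y.shape[1]
    for n in range(B):
        base = n * S
        for i in range(h):
            row = base + i * wp
            for j in range(w):
                idx = row + j
                for c in range(C):
                    v = y[idx, c] + b[c]
                    xout[n, i + 1, j + 1, c] = v if v > 0.0 else 0.0


@njit(cache=True)
def _relu_pool_pack(y, b, B, S, wp, k, po, xout, off, amax):
    # max-pool (k, stride k) over relu(y + b); result written to
    # xout[n, p+off, q+off, c]; amax holds the flat row index of the winning
    # tap in y (or -1 when the window is entirely non-positive).
    C = y.shape[1]
    for n in range(B):
        base = n * S
        for p in range(po):
            for q in range(po):
                for c in range(C):
                    best = F32(0.0)
                    bi = -1
                    for a in range(k):
                        row = base + (p * k + a) * wp + q * k
                        for t in range(k):
                            v = y[row + t, c] + b[c]
                            if v > best:
                                best = v
                                bi = row + t
                    xout[n, p + off, q + off, c] = best
                    amax[n, p, q, c] = bi


@njit(cache=True)
def _pool_bwd(dp, amax, dy):
    B, po, qo, C = dp.shape
    for n in range(B):
        for p in range(po):
            for q in range(qo):
                for c in range(C):
                    i = amax[n, p, q, c]
                    if i >= 0:
                        dy[i, c] += dp[n, p, q, c]


@njit(cache=True)
def _relu_unpack(dx, x, dy, B, S, wp, h, w):
    # adjoint of _relu_repack: dy[n*S + i*wp + j, c] = dx[n,i+1,j+1,c] * (x>0)
    C = dy.shape[1]
    for n in range(B):
        base = n * S
        for i in range(h):
            row = base + i * wp
            for j in range(w):
                idx = row + j
                for c in range(C):
                    if x[n, i + 1, j + 1, c] > 0.0:
                        dy[idx, c] = dx[n, i + 1, j + 1, c]
                    else:
                        dy[idx, c] = 0.0


@njit(cache=True)
def _pack_images(img, xout, B, s):
    # grayscale image replicated onto 3 identical channels, into the padded
    # interior of the first-layer buffer
    for n in range(B):
        for i in range(s):
            for j in range(s):
                v = img[n, i, j]
                for c in range(3):
                    xout[n, i + 1, j + 1, c] = v


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

class _Layer:
    """Geometry bookkeeping for one shift-GEMM conv layer."""

    def __init__(self, k: int, cin: int, cout: int, hin: int):
        self.k, self.cin, self.cout = k, cin, cout
        self.hp = hin + 2                  # padded extent
        self.wp = self.hp
        self.hout = self.hp - k + 1        # valid output extent
        self.wout = self.wp - k + 1
        self.rows = self.hp + k            # extra zero rows absorb tap overrun
        self.S = self.rows * self.wp       # per-sample stride of flat buffers
        self.offsets = [di * self.wp + dj for di in range(k) for dj in range(k)]
        self.omax = self.offsets[-1]


class ConvEncoder:
    """Scalar-output convolutional encoder Z_w with explicit backprop."""

    def __init__(self, side: int = 224, rng: np.random.Generator | None = None):
        self.side = side
        g = encoder_geometry(side)
        self.geom = g
        self.l1 = _Layer(2, 3, 16, side)
        self.l2 = _Layer(2, 16, 32, g["h1"])
        self.l3 = _Layer(3, 32, 32, g["p2"])
        self.flat = g["flat"]
        self.params: dict[str, np.ndarray] = {}
        if rng is not None:
            self.init_params(rng)
        self._ws: dict[int, dict] = {}

    # -- parameters --------------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> None:
        """Uniform +-1/sqrt(fan_in) for every weight and bias."""

        def u(shape, fan_in):
            b = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-b, b, size=shape).astype(F32)

        for name, lay in (("1", self.l1), ("2", self.l2), ("3", self.l3)):
            fan = lay.cin * lay.k * lay.k
            self.params["W" + name] = u((lay.k * lay.k, lay.cin, lay.cout), fan)
            self.params["b" + name] = u((lay.cout,), fan)
        self.params["Wf"] = u((self.flat, 1), self.flat)
        self.params["bf"] = u((1,), self.flat)

    def release_workspaces(self) -> None:
        """Drop cached batch workspaces (a few hundred MB per batch size)."""
        self._ws.clear()

    def copy(self) -> "ConvEncoder":
        other = ConvEncoder(self.side)
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other

    # -- workspaces --------------------------------------------------------

    def _workspace(self, B: int) -> dict:
        ws = self._ws.get(B)
        if ws is None:
            l1, l2, l3 = self.l1, self.l2, self.l3
            p3 = self.geom["p3"]
            ws = {
                "X1": np.zeros((B, l1.rows, l1.wp, 3), F32),
                "Y1": np.empty((B * l1.S, 16), F32),
                "X2": np.zeros((B, l2.rows, l2.wp, 16), F32),
                "Y2": np.empty((B * l2.S, 32), F32),
                "X3": np.zeros((B, l3.rows, l3.wp, 32), F32),
                "Y3": np.empty((B * l3.S, 32), F32),
                "P3": np.empty((B, p3, p3, 32), F32),
                "am2": np.empty((B, self.geom["p2"], self.geom["p2"], 32), np.int32),
                "am3": np.empty((B, p3, p3, 32), np.int32),
                "tmp1": np.empty((B * l1.S - l1.omax, 16), F32),
                "tmp2": np.empty((B * l2.S - l2.omax, 32), F32),
                "tmp3": np.empty((B * l3.S - l3.omax, 32), F32),
                "dxt2": np.empty((B * l2.S - l2.omax, 16), F32),
                "dxt3": np.empty((B * l3.S - l3.omax, 32), F32),
                "dY1": np.zeros((B * l1.S, 16), F32),
                "dY2": np.zeros((B * l2.S, 32), F32),
                "dY3": np.zeros((B * l3.S, 32), F32),
                "dX2": np.empty((B, l2.rows, l2.wp, 16), F32),
                "dX3": np.empty((B, l3.rows, l3.wp, 32), F32),
                "dP2": np.empty((B, self.geom["p2"], self.geom["p2"], 32), F32),
            }
            self._ws[B] = ws
        return ws

    # -- conv primitives ---------------------------------------------------

    @staticmethod
    def _conv(xbuf, W, lay: _Layer, y, tmp, B):
        xf = xbuf.reshape(B * lay.S, lay.cin)
        L = B * lay.S - lay.omax
        np.matmul(xf[lay.offsets[0]:lay.offsets[0] + L], W[0], out=y[:L])
        for s in range(1, len(lay.offsets)):
            o = lay.offsets[s]
            np.matmul(xf[o:o + L], W[s], out=tmp)
            y[:L] += tmp

    @staticmethod
    def _conv_bwd(xbuf, dy, W, lay: _Layer, B, dxbuf=None, dxtmp=None):
        xf = xbuf.reshape(B * lay.S, lay.cin)
        L = B * lay.S - lay.omax
        dW = np.empty_like(W)
        for s, o in enumerate(lay.offsets):
            np.matmul(xf[o:o + L].T, dy[:L], out=dW[s])
        db = dy[:L].sum(axis=0)
        if dxbuf is not None:
            dxf = dxbuf.reshape(B * lay.S, lay.cin)
            dxf[:] = 0.0
            for s, o in enumerate(lay.offsets):
                np.matmul(dy[:L], W[s].T, out=dxtmp)
                dxf[o:o + L] += dxtmp
        return dW, db

    # -- forward / backward ------------------------------------------------

    def _forward(self, images: np.ndarray, ws: dict) -> np.ndarray:
        B = images.shape[0]
        l1, l2, l3 = self.l1, self.l2, self.l3
        g = self.geom
        p = self.params
        _pack_images(images, ws["X1"], B, self.side)
        self._conv(ws["X1"], p["W1"], l1, ws["Y1"], ws["tmp1"], B)
        _relu_repack(ws["Y1"], p["b1"], ws["X2"], B, l1.S, l1.wp,
                     l1.hout, l1.wout)
        self._conv(ws["X2"], p["W2"], l2, ws["Y2"], ws["tmp2"], B)
        _relu_pool_pack(ws["Y2"], p["b2"], B, l2.S, l2.wp, 4, g["p2"],
                        ws["X3"], 1, ws["am2"])
        self._conv(ws["X3"], p["W3"], l3, ws["Y3"], ws["tmp3"], B)
        _relu_pool_pack(ws["Y3"], p["b3"], B, l3.S, l3.wp, 6, g["p3"],
                        ws["P3"], 0, ws["am3"])
        z = ws["P3"].reshape(B, self.flat) @ p["Wf"] + p["bf"]
        return z[:, 0].astype(np.float64)

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Encode a batch of grayscale images (B, side, side) -> (B,)."""
        images = np.ascontiguousarray(images, dtype=F32)
        self._last_B = images.shape[0]
        return self._forward(images, self._workspace(images.shape[0]))

    def backward_from_last(self, dz: np.ndarray) -> dict:
        """Gradients of sum(dz * z) w.r.t. parameters, reusing the buffers of
        the most recent ``forward`` call (no weight update in between)."""
        B = self._last_B
        ws = self._workspace(B)
        p = self.params
        l1, l2, l3 = self.l1, self.l2, self.l3
        grads = {}
        dzc = np.ascontiguousarray(dz, dtype=F32).reshape(B, 1)
        p3flat = ws["P3"].reshape(B, self.flat)
        grads["Wf"] = p3flat.T @ dzc
        grads["bf"] = dzc.sum(axis=0)
        dP3 = (dzc @ p["Wf"].T).reshape(ws["P3"].shape)
        dY3 = ws["dY3"]
        dY3.fill(0.0)  # garbage rows/cols must stay exactly zero
        _pool_bwd(dP3, ws["am3"], dY3)
        grads["W3"], grads["b3"] = self._conv_bwd(
            ws["X3"], dY3, p["W3"], l3, B, ws["dX3"], ws["dxt3"])
        dP2 = ws["dP2"]
        np.copyto(dP2, ws["dX3"][:, 1:1 + self.geom["p2"],
                                 1:1 + self.geom["p2"], :])
        dY2 = ws["dY2"]
        dY2.fill(0.0)
        _pool_bwd(dP2, ws["am2"], dY2)
        grads["W2"], grads["b2"] = self._conv_bwd(
            ws["X2"], dY2, p["W2"], l2, B, ws["dX2"], ws["dxt2"])
        dY1 = ws["dY1"]
        _relu_unpack(ws["dX2"], ws["X2"], dY1, B, l1.S, l1.wp,
                     l1.hout, l1.wout)
        grads["W1"], grads["b1"] = self._conv_bwd(
            ws["X1"], dY1, p["W1"], l1, B)
        return grads

    def forward_backward(self, images: np.ndarray, dz: np.ndarray):
        """Forward pass plus gradients of sum(dz * z) w.r.t. all parameters."""
        z = self.forward(images)
        return z, self.backward_from_last(dz)

    def sgd_step(self, grads: dict, lr: float) -> None:
        for k, g in grads.items():
            self.params[k] -= F32(lr) * g.reshape(self.params[k].shape)
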