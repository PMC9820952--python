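"""Minimal reverse-mode engine for 3-D convolutional networks on NumPy.

Feature grids are stored channels-last, ``(batch, z, y, x, channel)`` in
float32.  3x3x3 convolutions are evaluated as 27 shifted GEMMs (one BLAS
``sgemm`` per kernel tap against a contiguous slice of the padded input),
which is the fastest layout for the small channel counts used here.

The engine is a tape: every differentiable op appends a closure to a
:class:`Tape`; ``Tape.backward`` runs them in reverse, accumulating
gradients on :class:`Node` activations and :class:`Parameter` leaves.
Passing ``tape=None`` runs the same forward math without recording
(inference mode).  Everything is deterministic given the inputs.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Parameter:
    """A learnable leaf tensor with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = None

    def add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=F32).copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None


class Node:
    """An activation tensor on the tape."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = None

    def add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=F32).copy()
        else:
            self.grad += g

    @property
    def shape(self):
        return self.value.shape


class Tape:
    """Records backward closures in execution order."""

    def __init__(self):
        self._backs: list = []

    def append(self, fn) -> None:
        self._backs.append(fn)

    def backward(self, seeds: list[tuple[Node, np.ndarray]]) -> None:
        """Seed output gradients, then run all recorded closures in reverse."""
        for node, g in seeds:
            node.add_grad(g)
        for fn in reversed(self._backs):
            fn()
        self._backs.clear()


# ---------------------------------------------------------------------------
# convolution


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))


def _tap_offsets(H: int, W: int, d: int):
    """Flattened-index offsets of the 27 kernel taps on a padded grid."""
    return [
        (i, j, k, d * ((i - 1) * H * W + (j - 1) * W + (k - 1)))
        for i in range(3)
        for j in range(3)
        for k in range(3)
    ]


def conv3d(tape: Tape | None, x: Node, w: Parameter, b: Parameter, dilation: int = 1) -> Node:
    """3x3x3 convolution, stride 1, 'same' zero padding, optional dilation.

    ``w`` has shape (3, 3, 3, C_in, C_out); ``b`` has shape (C_out,).
    Each kernel tap is one BLAS GEMM against a flat row-shifted view of the
    zero-padded input; padded border rows absorb the wrap-around and are
    cropped, so no gather copies are needed.
    """
    d = int(dilation)
    if d >= max(x.value.shape[1:4]):
        # every non-center tap reaches outside the grid (zero padding):
        # the conv degenerates to a per-voxel linear map through w[1,1,1]
        return _center_tap_conv(tape, x, w, b)
    xp = _pad_spatial(x.value, d)
    B, D, H, W, C = xp.shape
    O = w.value.shape[-1]
    R = B * D * H * W
    xf = xp.reshape(R, C)
    taps = _tap_offsets(H, W, d)
    acc = np.empty((R, O), dtype=F32)
    acc[:] = b.value
    for i, j, k, off in taps:
        if off >= 0:
            acc[: R - off] += xf[off:] @ w.value[i, j, k]
        else:
            acc[-off:] += xf[: R + off] @ w.value[i, j, k]
    out = Node(acc.reshape(B, D, H, W, O)[:, d:-d, d:-d, d:-d, :])

    if tape is not None:

        def back():
            gp = np.zeros((B, D, H, W, O), dtype=F32)
            gp[:, d:-d, d:-d, d:-d, :] = out.grad
            gf = gp.reshape(R, O)
            b.add_grad(out.grad.sum(axis=(0, 1, 2, 3)))
            dw = np.empty_like(w.value)
            dxf = np.zeros((R, C), dtype=F32)
            for i, j, k, off in taps:
                if off >= 0:
                    dw[i, j, k] = xf[off:].T @ gf[: R - off]
                    dxf[off:] += gf[: R - off] @ w.value[i, j, k].T
                else:
                    dw[i, j, k] = xf[: R + off].T @ gf[-off:]
                    dxf[: R + off] += gf[-off:] @ w.value[i, j, k].T
            w.add_grad(dw)
            x.add_grad(dxf.reshape(B, D, H, W, C)[:, d:-d, d:-d, d:-d, :])

        tape.append(back)
    return out


def _center_tap_conv(tape: Tape | None, x: Node, w: Parameter, b: Parameter) -> Node:
    C = x.value.shape[-1]
    xf = x.value.reshape(-1, C)
    out = Node((xf @ w.value[1, 1, 1] + b.value).reshape(
        x.value.shape[:-1] + (w.value.shape[-1],)
    ))

    if tape is not None:

        def back():
            gf = out.grad.reshape(-1, w.value.shape[-1])
            dw = np.zeros_like(w.value)
            dw[1, 1, 1] = xf.T @ gf
            w.add_grad(dw)
            b.add_grad(gf.sum(axis=0))
            x.add_grad((gf @ w.value[1, 1, 1].T).reshape(x.value.shape))

        tape.append(back)
    return out


def channel_linear(tape: Tape | None, x: Node, w: Parameter, b: Parameter) -> Node:
    """1x1x1 convolution: per-voxel linear map over channels."""
    C = x.value.shape[-1]
    xf = x.value.reshape(-1, C)
    out = Node((xf @ w.value + b.value).reshape(x.value.shape[:-1] + (w.value.shape[-1],)))

    if tape is not None:

        def back():
            gf = out.grad.reshape(-1, w.value.shape[-1])
            w.add_grad(xf.T @ gf)
            b.add_grad(gf.sum(axis=0))
            x.add_grad((gf @ w.value.T).reshape(x.value.shape))

        tape.append(back)
    return out


# ---------------------------------------------------------------------------
# pointwise / normalization


def leaky_relu(tape: Tape | None, x: Node, slope: float = 0.01) -> Node:
    fac = np.where(x.value < 0, F32(slope), F32(1.0))
    out = Node(x.value * fac)

    if tape is not None:

        def back():
            x.add_grad(out.grad * fac)

        tape.append(back)
    return out


def instance_norm(
    tape: Tape | None, x: Node, gamma: Parameter, beta: Parameter, eps: float = 1e-5
) -> Node:
    """Normalize each (sample, channel) over its spatial extent; affine scale."""
    ax = (1, 2, 3)
    mu = x.value.mean(axis=ax, keepdims=True)
    var = x.value.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.value - mu) * inv
    out = Node(gamma.value * xhat + beta.value)

    if tape is not None:

        def back():
            g = out.grad
            gamma.add_grad((g * xhat).sum(axis=(0, 1, 2, 3)))
            beta.add_grad(g.sum(axis=(0, 1, 2, 3)))
            gh = g * gamma.value
            m1 = gh.mean(axis=ax, keepdims=True)
            m2 = (gh * xhat).mean(axis=ax, keepdims=True)
            x.add_grad((gh - m1 - xhat * m2) * inv)

        tape.append(back)
    return out


# ---------------------------------------------------------------------------
# resolution changes


def max_pool2(tape: Tape | None, x: Node) -> Node:
    """2x max-pooling along all spatial axes; sizes must be even."""
    B, D, H, W, C = x.value.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"max_pool2 requires even spatial sizes, got {(D, H, W)}")
    r = (
        x.value.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        .transpose(0, 1, 3, 5, 7, 2, 4, 6)
        .reshape(B, D // 2, H // 2, W // 2, C, 8)
    )
    idx = r.argmax(axis=-1)
    out = Node(np.take_along_axis(r, idx[..., None], axis=-1)[..., 0])

    if tape is not None:

        def back():
            dr = np.zeros((B, D // 2, H // 2, W // 2, C, 8), dtype=F32)
            np.put_along_axis(dr, idx[..., None], out.grad[..., None], axis=-1)
            dx = (
                dr.reshape(B, D // 2, H // 2, W // 2, C, 2, 2, 2)
                .transpose(0, 1, 5, 2, 6, 3, 7, 4)
                .reshape(B, D, H, W, C)
            )
            x.add_grad(dx)

        tape.append(back)
    return out


def _up1(arr: np.ndarray, axis: int) -> np.ndarray:
    """Linear 2x upsampling along one axis (half-voxel aligned, edge clamped)."""
    a = np.moveaxis(arr, axis, 0)
    n = a.shape[0]
    p = np.concatenate([a[:1], a, a[-1:]], axis=0)
    even = F32(0.25) * p[:n] + F32(0.75) * p[1 : n + 1]
    odd = F32(0.75) * p[1 : n + 1] + F32(0.25) * p[2 : n + 2]
    out = np.empty((2 * n,) + a.shape[1:], dtype=F32)
    out[0::2] = even
    out[1::2] = odd
    return np.moveaxis(out, 0, axis)


def _up1_T(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_up1`."""
    ga = np.moveaxis(g, axis, 0)
    n = ga.shape[0] // 2
    ge, go = ga[0::2], ga[1::2]
    dp = np.zeros((n + 2,) + ga.shape[1:], dtype=F32)
    dp[:n] += F32(0.25) * ge
    dp[1 : n + 1] += F32(0.75) * ge + F32(0.75) * go
    dp[2 : n + 2] += F32(0.25) * go
    dx = dp[1 : n + 1].copy()
    dx[0] += dp[0]
    dx[-1] += dp[n + 1]
    return np.moveaxis(dx, 0, axis)


def upsample2(tape: Tape | None, x: Node) -> Node:
    """Trilinear 2x upsampling of all spatial axes (separable linear filter)."""
    y = x.value
    for axis in (1, 2, 3):
        y = _up1(y, axis)
    out = Node(y)

    if tape is not None:

        def back():
            g = out.grad
            for axis in (3, 2, 1):
                g = _up1_T(g, axis)
            x.add_grad(g)

        tape.append(back)
    return out


def upsample2_n(tape: Tape | None, x: Node, times: int) -> Node:
    for _ in range(times):
        x = upsample2(tape, x)
    return x


# ---------------------------------------------------------------------------
# structural ops


def concat(tape: Tape | None, xs: list[Node]) -> Node:
    splits = np.cumsum([x.value.shape[-1] for x in xs])[:-1]
    out = Node(np.concatenate([x.value for x in xs], axis=-1))

    if tape is not None:

        def back():
            for x, g in zip(xs, np.split(out.grad, splits, axis=-1)):
                x.add_grad(g)

        tape.append(back)
    return out


def add(tape: Tape | None, a: Node, b: Node) -> Node:
    out = Node(a.value + b.value)

    if tape is not None:

        def back():
            a.add_grad(out.grad)
            b.add_grad(out.grad)

        tape.append(back)
    return out


# ---------------------------------------------------------------------------
# output-side math (plain arrays; gradients seeded through Tape.backward)


def softmax_channels(scores: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the trailing channel axis."""
    s = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(s, dtype=np.float64)
    return (e / e.sum(axis=-1, keepdims=True)).astype(F32)
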