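"""Minimal neural-network primitives for sequence autoencoding.

Everything here is plain numpy with hand-derived gradients: a GRU layer with
backpropagation through time, a bidirectional GRU encoder whose final states
form the latent vector, a teacher-forced GRU decoder, a fully connected
classifier head, and an Adam optimizer.  Sequences are stored padded to a
common length with a frame-validity mask; masked steps copy the hidden state
through unchanged, so padding never influences latents, reconstructions or
gradients.

Gate equations follow the standard GRU cell (Cho et al. convention, with the
reset gate applied inside the candidate's recurrent term):

    r_t = sigmoid(W_xr x_t + b_xr + W_hr h_{t-1} + b_hr)
    z_t = sigmoid(W_xz x_t + b_xz + W_hz h_{t-1} + b_hz)
    n_t = tanh(W_xn x_t + b_xn + r_t * (W_hn h_{t-1} + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

All floating point work is float64; with a fixed seed every run is bit
reproducible on one device.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Linear",
    "GRULayer",
    "BiGRUEncoder",
    "GRUDecoder",
    "ClassifierHead",
    "Adam",
    "masked_mse",
    "masked_mse_grad",
    "softmax",
    "reverse_valid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Parameter:
    """A weight array paired with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Linear:
    """Affine map y = x W + b for 2-D or 3-D (batch, time, feat) inputs."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self, prefix: str) -> dict[str, Parameter]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class GRULayer:
    """One unidirectional GRU layer over a padded batch with frame mask."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        self.n_in = n_in
        self.n_hidden = n_hidden
        bound = 1.0 / np.sqrt(n_hidden)
        self.Wx = Parameter(rng.uniform(-bound, bound, size=(n_in, 3 * n_hidden)))
        self.Wh = Parameter(rng.uniform(-bound, bound, size=(n_hidden, 3 * n_hidden)))
        self.bx = Parameter(np.zeros(3 * n_hidden))
        self.bh = Parameter(np.zeros(3 * n_hidden))
        self._cache: list | None = None

    def params(self, prefix: str) -> dict[str, Parameter]:
        return {
            f"{prefix}.Wx": self.Wx,
            f"{prefix}.Wh": self.Wh,
            f"{prefix}.bx": self.bx,
            f"{prefix}.bh": self.bh,
        }

    def forward(
        self, x: np.ndarray, mask: np.ndarray, h0: np.ndarray | None = None
    ) -> np.ndarray:
        """Run the layer; returns hidden states (B, T, H).

        ``mask`` is (B, T) with 1 for real frames; masked steps leave the
        hidden state untouched, so ``hs[:, -1]`` is the state at each
        sequence's true final frame when padding sits at the end.
        """
        B, T, _ = x.shape
        H = self.n_hidden
        h = np.zeros((B, H)) if h0 is None else h0
        hs = np.empty((B, T, H))
        cache = []
        Wx, Wh = self.Wx.value, self.Wh.value
        bx, bh = self.bx.value, self.bh.value
        for t in range(T):
            xt = x[:, t]
            gx = xt @ Wx + bx
            gh = h @ Wh + bh
            r = sigmoid(gx[:, :H] + gh[:, :H])
            z = sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
            ghn = gh[:, 2 * H :]
            n = np.tanh(gx[:, 2 * H :] + r * ghn)
            h_cand = (1.0 - z) * n + z * h
            m = mask[:, t][:, None]
            h_new = m * h_cand + (1.0 - m) * h
            cache.append((xt, h, r, z, n, ghn, m))
            h = h_new
            hs[:, t] = h
        self._cache = cache
        return hs

    def backward(
        self, dhs: np.ndarray, dh_last: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """BPTT given per-step upstream grads and an optional extra gradient
        on the final state.  Returns (dx, dh0)."""
        cache = self._cache
        B, T, H = dhs.shape
        Wx, Wh = self.Wx.value, self.Wh.value
        dx = np.empty((B, T, self.n_in))
        carry = np.zeros((B, H)) if dh_last is None else dh_last.copy()
        for t in range(T - 1, -1, -1):
            xt, h_prev, r, z, n, ghn, m = cache[t]
            dh = dhs[:, t] + carry
            dh_cand = m * dh
            dh_prev = (1.0 - m) * dh
            dn = dh_cand * (1.0 - z)
            dz = dh_cand * (h_prev - n)
            dh_prev += dh_cand * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * ghn
            dghn = dn_pre * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            dgx = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            dgh = np.concatenate([dr_pre, dz_pre, dghn], axis=1)
            dx[:, t] = dgx @ Wx.T
            self.Wx.grad += xt.T @ dgx
            self.bx.grad += dgx.sum(axis=0)
            self.Wh.grad += h_prev.T @ dgh
            self.bh.grad += dgh.sum(axis=0)
            dh_prev += dgh @ Wh.T
            carry = dh_prev
        return dx, carry


def reverse_valid(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its valid length, keeping padding at
    the end.  Works for (B, T) masks and (B, T, F) arrays alike."""
    out = x.copy()
    for i, L in enumerate(lengths):
        out[i, :L] = x[i, :L][::-1]
    return out


class BiGRUEncoder:
    """Stack of bidirectional GRU layers + linear projection to the latent.

    The latent vector of a segment is the concatenation of the final hidden
    states of the forward and backward directions of the top layer, linearly
    mapped to the requested latent dimension.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        n_in: int,
        n_hidden: int,
        latent_dim: int,
        n_layers: int = 1,
    ):
        self.n_layers = n_layers
        self.fwd: list[GRULayer] = []
        self.bwd: list[GRULayer] = []
        d = n_in
        for _ in range(n_layers):
            self.fwd.append(GRULayer(rng, d, n_hidden))
            self.bwd.append(GRULayer(rng, d, n_hidden))
            d = 2 * n_hidden
        self.proj = Linear(rng, 2 * n_hidden, latent_dim)
        self._shapes: tuple | None = None

    def params(self, prefix: str = "enc") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for i, (f, b) in enumerate(zip(self.fwd, self.bwd)):
            out.update(f.params(f"{prefix}.l{i}.fwd"))
            out.update(b.params(f"{prefix}.l{i}.bwd"))
        out.update(self.proj.params(f"{prefix}.proj"))
        return out

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Encode (B, T, F) + mask -> latent (B, m)."""
        lengths = mask.sum(axis=1).astype(int)
        mask_r = reverse_valid(mask, lengths)  # identical for 0/1 runs, kept for clarity
        inp = x
        hs_f = hs_b_rev = None
        for f, b in zip(self.fwd, self.bwd):
            hs_f = f.forward(inp, mask)
            hs_b_rev = b.forward(reverse_valid(inp, lengths), mask_r)
            hs_b = reverse_valid(hs_b_rev, lengths)
            inp = np.concatenate([hs_f, hs_b], axis=2)
        final = np.concatenate([hs_f[:, -1], hs_b_rev[:, -1]], axis=1)
        self._lengths = lengths
        self._T = x.shape[1]
        return self.proj.forward(final)

    def backward(self, dlatent: np.ndarray) -> np.ndarray:
        """Backprop dL/dlatent to dL/dx (returned)."""
        H = self.fwd[0].n_hidden
        dfinal = self.proj.backward(dlatent)
        dhf_last, dhb_last = dfinal[:, :H], dfinal[:, H:]
        lengths, T = self._lengths, self._T
        B = dlatent.shape[0]
        # per-step grads flowing into the top layer (none besides finals)
        dhs_f = np.zeros((B, T, H))
        dhs_b_rev = np.zeros((B, T, H))
        dx_total = None
        for li in range(self.n_layers - 1, -1, -1):
            dx_f, _ = self.fwd[li].backward(dhs_f, dhf_last)
            dx_b_rev, _ = self.bwd[li].backward(dhs_b_rev, dhb_last)
            dx = dx_f + reverse_valid(dx_b_rev, lengths)
            if li == 0:
                dx_total = dx
            else:
                dhs_f = dx[:, :, :H]
                dhs_b_rev = reverse_valid(dx[:, :, H:], lengths)
                dhf_last = np.zeros((B, H))
                dhb_last = np.zeros((B, H))
        return dx_total


class GRUDecoder:
    """Unidirectional GRU decoder conditioned on the latent vector.

    The latent initializes the first layer's hidden state through a tanh
    affine map.  Step inputs are supplied by the caller: all zeros for
    input-free (fixed-state) decoding, or the previous true frame for
    teacher forcing (``teacher_inputs``).  ``forward_free`` runs the
    decoder on its own outputs for inference under teacher conditioning.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        n_out: int,
        n_hidden: int,
        latent_dim: int,
        n_layers: int = 1,
    ):
        self.n_hidden = n_hidden
        self.init_lin = Linear(rng, latent_dim, n_hidden)
        self.layers = [
            GRULayer(rng, n_out if i == 0 else n_hidden, n_hidden)
            for i in range(n_layers)
        ]
        self.out_lin = Linear(rng, n_hidden, n_out)
        self._h0_pre: np.ndarray | None = None

    def params(self, prefix: str = "dec") -> dict[str, Parameter]:
        out = self.init_lin.params(f"{prefix}.init")
        for i, l in enumerate(self.layers):
            out.update(l.params(f"{prefix}.l{i}"))
        out.update(self.out_lin.params(f"{prefix}.out"))
        return out

    def _h0(self, latent: np.ndarray) -> np.ndarray:
        self._h0_pre = self.init_lin.forward(latent)
        return np.tanh(self._h0_pre)

    @staticmethod
    def teacher_inputs(target: np.ndarray) -> np.ndarray:
        dec_in = np.zeros_like(target)
        dec_in[:, 1:] = target[:, :-1]
        return dec_in

    def forward_cond(
        self, latent: np.ndarray, inputs: np.ndarray, mask: np.ndarray
    ) -> np.ndarray:
        """Decode conditioned on the latent with explicit step inputs.

        ``inputs`` is (B, T, F): zeros for input-free (fixed-state) decoding,
        or the shifted target for teacher forcing.
        """
        h = self._h0(latent)
        hs = inputs
        for i, layer in enumerate(self.layers):
            hs = layer.forward(hs, mask, h0=h if i == 0 else None)
        return self.out_lin.forward(hs)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backprop through the teacher-forced pass; returns dL/dlatent."""
        dhs = self.out_lin.backward(dy)
        dh0 = None
        for i in range(len(self.layers) - 1, -1, -1):
            dhs, dh0 = self.layers[i].backward(dhs)
        # dh0 belongs to layer 0 (the only latent-initialized layer)
        dpre = dh0 * (1.0 - np.tanh(self._h0_pre) ** 2)
        return self.init_lin.backward(dpre)

    def forward_free(self, latent: np.ndarray, T: int) -> np.ndarray:
        """Free-running (autoregressive) decode for ``T`` steps."""
        B = latent.shape[0]
        F = self.out_lin.W.value.shape[1]
        h_states = [np.tanh(self.init_lin.forward(latent))] + [
            np.zeros((B, self.n_hidden)) for _ in self.layers[1:]
        ]
        y = np.zeros((B, F))
        out = np.empty((B, T, F))
        ones = np.ones((B, 1))
        for t in range(T):
            inp = y
            for i, layer in enumerate(self.layers):
                hs = layer.forward(inp[:, None, :], ones, h0=h_states[i])
                h_states[i] = hs[:, 0]
                inp = h_states[i]
            y = self.out_lin.forward(h_states[-1])
            out[:, t] = y
        return out


class ClassifierHead:
    """Fully connected softmax classifier over latent vectors."""

    def __init__(
        self,
        rng: np.random.Generator,
        latent_dim: int,
        n_classes: int,
        hidden: tuple[int, ...] = (128,),
    ):
        self.hidden = tuple(hidden)
        self.linears: list[Linear] = []
        d = latent_dim
        for h in self.hidden:
            self.linears.append(Linear(rng, d, h))
            d = h
        self.linears.append(Linear(rng, d, n_classes))
        self._relu_in: list[np.ndarray] = []

    def params(self, prefix: str = "cls") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for i, l in enumerate(self.linears):
            out.update(l.params(f"{prefix}.fc{i}"))
        return out

    def forward(self, latent: np.ndarray) -> np.ndarray:
        """Latents -> class probabilities (rows sum to 1)."""
        a = latent
        self._relu_in = []
        for l in self.linears[:-1]:
            a = l.forward(a)
            self._relu_in.append(a)
            a = np.maximum(a, 0.0)
        self._logits = self.linears[-1].forward(a)
        return softmax(self._logits)

    def backward_ce(
        self, probs: np.ndarray, labels: np.ndarray, weight: float = 1.0
    ) -> np.ndarray:
        """Gradient of mean cross-entropy over the given rows.

        ``probs`` are the rows of the last ``forward`` corresponding to
        labeled samples; returns dL/dlatent for those rows.
        """
        n = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits *= weight / n
        da = self.linears[-1].backward(dlogits)
        for l, pre in zip(reversed(self.linears[:-1]), reversed(self._relu_in)):
            da = da * (pre > 0)
            da = l.backward(da)
        return da


def masked_mse(y: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over valid frames and all features.

    ``mask`` is (B, T); the mean is taken over mask.sum() * F entries so
    padded frames contribute nothing.
    """
    diff = (y - target) * mask[:, :, None]
    denom = mask.sum() * y.shape[2]
    return float((diff**2).sum() / denom)


def masked_mse_grad(y: np.ndarray, target: np.ndarray, mask: np.ndarray) -> np.ndarray:
    denom = mask.sum() * y.shape[2]
    return 2.0 * (y - target) * mask[:, :, None] / denom


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(
        self,
        params: dict[str, Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        grad_clip: float | None = 5.0,
    ):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        if self.grad_clip is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params.values())
            )
            if total > self.grad_clip:
                scale = self.grad_clip / (total + 1e-12)
                for p in self.params.values():
                    p.grad *= scale
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p.value -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
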