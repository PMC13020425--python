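"""Hand-written CNN-LSTM network core (NumPy, CPU).

Architecture: token embedding -> [same-padded 1-D convolution + ReLU +
non-overlapping max-pool] x B -> length-masked LSTM (final valid hidden
state) -> dense ReLU (+ optional dropout) -> scalar logit.

The LSTM is masked by each sequence's true length so that a prediction
depends only on the real residues, never on trailing padding; this also
lets training batches be cropped to the longest sequence present.

All forward/backward passes are written out explicitly so that the gradient
of the logit with respect to the last convolutional activation map is
available for Grad-CAM.  Gradients are verified against finite differences
in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

_F = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy; returns (mean loss, dL/dlogit)."""
    z = logits.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / len(z)
    return float(loss.mean()), dz.astype(_F)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F)


class Adam:
    """Standard Adam optimiser over a parameter dict."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= (self.lr * (self.m[k] / b1t)
                          / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(_F)


class CNNLSTM:
    """The network itself: parameters plus explicit forward/backward."""

    def __init__(
        self,
        vocab_size: int,
        pad_index: int,
        embedding_dim: int,
        conv_filters: tuple[int, ...],
        kernel_size: int,
        pool_size: int,
        lstm_units: int,
        dense_units: int,
        dropout: float,
        rng: np.random.Generator,
        lstm_pooling: str = "last",
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding convolution)")
        if lstm_pooling not in ("mean", "last"):
            raise ValueError("lstm_pooling must be 'mean' or 'last'")
        self.lstm_pooling = lstm_pooling
        self.pad_index = pad_index
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.conv_filters = tuple(conv_filters)
        self.dropout = float(dropout)
        H, D = lstm_units, dense_units
        p: dict[str, np.ndarray] = {}
        p["emb"] = (rng.standard_normal((vocab_size, embedding_dim)) * 0.05).astype(_F)
        p["emb"][pad_index] = 0.0  # PAD embeds to zero and is never updated
        c_in = embedding_dim
        for i, c_out in enumerate(self.conv_filters):
            p[f"convW{i}"] = _glorot(rng, kernel_size * c_in, c_out,
                                     (kernel_size * c_in, c_out))
            p[f"convb{i}"] = np.zeros(c_out, dtype=_F)
            c_in = c_out
        p["Wx"] = _glorot(rng, c_in, 4 * H, (c_in, 4 * H))
        p["Wh"] = _glorot(rng, H, 4 * H, (H, 4 * H))
        p["lstm_b"] = np.zeros(4 * H, dtype=_F)
        p["lstm_b"][H:2 * H] = 1.0  # forget-gate bias init
        p["fc1W"] = _glorot(rng, H, D, (H, D))
        p["fc1b"] = np.zeros(D, dtype=_F)
        p["fc2W"] = _glorot(rng, D, 1, (D, 1))
        p["fc2b"] = np.zeros(1, dtype=_F)
        self.params = p
        self.lstm_units = H

    # ---------------------------------------------------------------- forward

    def n_frames(self, lengths: np.ndarray) -> np.ndarray:
        """Valid LSTM time steps for each sequence length."""
        f = np.asarray(lengths)
        for _ in self.conv_filters:
            f = -(-f // self.pool_size)
        return f

    def conv_frames(self, lengths: np.ndarray) -> np.ndarray:
        """Valid positions of the *last* conv layer for each length."""
        f = np.asarray(lengths)
        for _ in self.conv_filters[:-1]:
            f = -(-f // self.pool_size)
        return f

    def forward(
        self,
        tokens: np.ndarray,
        lengths: np.ndarray,
        train: bool = False,
        drop_rng: np.random.Generator | None = None,
        need_cache: bool = True,
    ) -> tuple[np.ndarray, dict]:
        """Return (logits (B,), cache) for a batch of token matrices (B, T).

        ``need_cache=False`` skips everything backward() would need
        (cheaper pure inference); the returned cache is then partial.
        """
        p = self.params
        K, P = self.kernel_size, self.pool_size
        half = K // 2
        X = p["emb"][tokens]  # (B, T, E)
        cache: dict = {"tokens": tokens, "lengths": np.asarray(lengths)}
        convs = []
        for i in range(len(self.conv_filters)):
            B, T, Cin = X.shape
            Xp = np.zeros((B, T + 2 * half, Cin), dtype=_F)
            Xp[:, half:half + T] = X
            win = np.lib.stride_tricks.sliding_window_view(Xp, K, axis=1)
            col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
                B * T, K * Cin)
            Z = (col @ p[f"convW{i}"] + p[f"convb{i}"]).reshape(
                B, T, -1)
            A = np.maximum(Z, 0.0)
            Tpad = -(-T // P) * P
            Ap = np.zeros((B, Tpad, A.shape[2]), dtype=_F)
            Ap[:, :T] = A
            Ar = Ap.reshape(B, Tpad // P, P, -1)
            if need_cache:
                arg = Ar.argmax(axis=2)
                pooled = np.take_along_axis(
                    Ar, arg[:, :, None, :], axis=2)[:, :, 0, :]
                convs.append({"col": col, "relu_mask": Z > 0, "arg": arg,
                              "T": T,
                              "A_last": A if i == len(self.conv_filters) - 1
                              else None})
            else:
                pooled = Ar.max(axis=2)
            X = pooled
        cache["convs"] = convs

        # masked LSTM over X (B, Tf, C)
        B, Tf, C = X.shape
        H = self.lstm_units
        frames = self.n_frames(cache["lengths"])
        h = np.zeros((B, H), dtype=_F)
        c = np.zeros((B, H), dtype=_F)
        h_sum = np.zeros((B, H), dtype=_F)
        steps = []
        for t in range(Tf):
            m = (t < frames).astype(_F)[:, None]
            a = X[:, t, :] @ p["Wx"] + h @ p["Wh"] + p["lstm_b"]
            i_g = sigmoid(a[:, :H])
            f_g = sigmoid(a[:, H:2 * H])
            g_g = np.tanh(a[:, 2 * H:3 * H])
            o_g = sigmoid(a[:, 3 * H:])
            c_cand = f_g * c + i_g * g_g
            tanh_c = np.tanh(c_cand)
            h_cand = o_g * tanh_c
            if need_cache:
                steps.append({"m": m, "i": i_g, "f": f_g, "g": g_g, "o": o_g,
                              "c_prev": c, "h_prev": h, "tanh_c": tanh_c})
            c = m * c_cand + (1 - m) * c
            h = m * h_cand + (1 - m) * h
            if self.lstm_pooling == "mean":
                h_sum += m * h
        cache["lstm_in"] = X
        cache["steps"] = steps
        cache["frames"] = frames
        if self.lstm_pooling == "mean":
            h = h_sum / frames[:, None].astype(_F)

        z1 = h @ p["fc1W"] + p["fc1b"]
        a1 = np.maximum(z1, 0.0)
        if train and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            mask = (drop_rng.random(a1.shape) < keep).astype(_F) / keep
            a1 = a1 * mask
            cache["drop_mask"] = mask
        logits = (a1 @ p["fc2W"] + p["fc2b"]).ravel()
        cache["h_final"] = h
        cache["z1"] = z1
        cache["a1"] = a1
        return logits, cache

    # --------------------------------------------------------------- backward

    def backward(
        self,
        cache: dict,
        dlogits: np.ndarray,
        want_param_grads: bool = True,
        want_conv_grad: bool = False,
    ) -> tuple[dict, np.ndarray | None]:
        """Backpropagate dL/dlogit; optionally stop-grad targets.

        Returns ``(grads, dA_last_conv)`` where ``dA_last_conv`` is the
        gradient with respect to the post-ReLU activations of the last conv
        layer (before its pool) when requested.
        """
        p = self.params
        K, P = self.kernel_size, self.pool_size
        half = K // 2
        H = self.lstm_units
        g: dict[str, np.ndarray] = {}
        dlog = dlogits[:, None].astype(_F)

        a1 = cache["a1"]
        if want_param_grads:
            g["fc2W"] = a1.T @ dlog
            g["fc2b"] = dlog.sum(axis=0)
        da1 = dlog @ p["fc2W"].T
        if "drop_mask" in cache:
            da1 = da1 * cache["drop_mask"]
        dz1 = da1 * (cache["z1"] > 0)
        if want_param_grads:
            g["fc1W"] = cache["h_final"].T @ dz1
            g["fc1b"] = dz1.sum(axis=0)
        dh = dz1 @ p["fc1W"].T

        X = cache["lstm_in"]
        B, Tf, C = X.shape
        dX = np.zeros_like(X)
        dc = np.zeros((B, H), dtype=_F)
        dWx = np.zeros_like(p["Wx"])
        dWh = np.zeros_like(p["Wh"])
        db = np.zeros_like(p["lstm_b"])
        if self.lstm_pooling == "mean":
            # dense head consumed the masked time-average of hidden states
            dh_pool = dh / cache["frames"][:, None].astype(_F)
            dh = np.zeros_like(dh_pool)
        for t in range(Tf - 1, -1, -1):
            s = cache["steps"][t]
            m = s["m"]
            if self.lstm_pooling == "mean":
                dh = dh + m * dh_pool
            dh_cand = dh * m
            dh_prev_direct = dh * (1 - m)
            dc_direct = dc * (1 - m)
            do = dh_cand * s["tanh_c"]
            dc_cand = dc * m + dh_cand * s["o"] * (1 - s["tanh_c"] ** 2)
            df = dc_cand * s["c_prev"]
            di = dc_cand * s["g"]
            dg = dc_cand * s["i"]
            dc = dc_cand * s["f"] + dc_direct
            da = np.concatenate(
                [di * s["i"] * (1 - s["i"]),
                 df * s["f"] * (1 - s["f"]),
                 dg * (1 - s["g"] ** 2),
                 do * s["o"] * (1 - s["o"])], axis=1)
            dX[:, t, :] = da @ p["Wx"].T
            if want_param_grads:
                dWx += X[:, t, :].T @ da
                dWh += s["h_prev"].T @ da
                db += da.sum(axis=0)
            dh = da @ p["Wh"].T + dh_prev_direct
        if want_param_grads:
            g["Wx"], g["Wh"], g["lstm_b"] = dWx, dWh, db

        # back through conv blocks (reverse order)
        dA_last_conv = None
        dpooled = dX
        for i in range(len(self.conv_filters) - 1, -1, -1):
            blk = cache["convs"][i]
            T = blk["T"]
            B = dpooled.shape[0]
            Cout = dpooled.shape[2]
            Tpad = -(-T // P) * P
            dAp = np.zeros((B, Tpad // P, P, Cout), dtype=_F)
            np.put_along_axis(dAp, blk["arg"][:, :, None, :],
                              dpooled[:, :, None, :], axis=2)
            dA = dAp.reshape(B, Tpad, Cout)[:, :T, :]
            if i == len(self.conv_filters) - 1 and want_conv_grad:
                dA_last_conv = dA.copy()
                if not want_param_grads:
                    break
            dZ = dA * blk["relu_mask"]
            dZ2 = dZ.reshape(B * T, Cout)
            if want_param_grads:
                g[f"convW{i}"] = blk["col"].T @ dZ2
                g[f"convb{i}"] = dZ2.sum(axis=0)
            if i == 0 and not want_param_grads:
                break  # embedding grads not needed
            dcol = (dZ2 @ p[f"convW{i}"].T).reshape(B, T, K, -1)
            Cin = dcol.shape[3]
            dXp = np.zeros((B, T + 2 * half, Cin), dtype=_F)
            for k in range(K):
                dXp[:, k:k + T, :] += dcol[:, :, k, :]
            dpooled = dXp[:, half:half + T, :]

        if want_param_grads:
            dX0 = dpooled  # (B, T0, E) gradient w.r.t. embedded input
            demb = np.zeros_like(p["emb"])
            np.add.at(demb, cache["tokens"].ravel(),
                      dX0.reshape(-1, dX0.shape[2]))
            demb[self.pad_index] = 0.0
            g["emb"] = demb
        return g, dA_last_conv

    # --------------------------------------------------------------- helpers

    def conv_activations_and_gradient(
        self, tokens: np.ndarray, lengths: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Last-conv activations, d(logit)/d(activations), and logits.

        Evaluation mode; used by Grad-CAM.  Shapes: activations and gradient
        are (B, T_conv, C); logits (B,).
        """
        logits, cache = self.forward(tokens, lengths, train=False)
        A = cache["convs"][-1]["A_last"]
        _, dA = self.backward(cache, np.ones_like(logits),
                              want_param_grads=False, want_conv_grad=True)
        return A, dA, logits
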