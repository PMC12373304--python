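"""GRU-D autoencoder: decay-to-mean imputation, recurrent encoder, GRU decoder.

The encoder is a GRU-D cell: every missing input cell is imputed as a
learned blend of the last observed value and the feature's empirical mean,

    x_hat = m * x + (1 - m) * (gamma * x_last + (1 - gamma) * x_mean)
    gamma = exp(-max(0, w_gamma * delta + b_gamma))

where ``delta`` is the (scaled) time since the feature was last observed.
As delta grows, gamma shrinks and the imputed value decays from the
carry-forward value toward the mean. The input-decay weights are diagonal
(one independent decay per feature); an optional hidden-state decay
``h' = exp(-max(0, W_gh delta + b_gh)) * h`` follows the original GRU-D
design. The final hidden state ``h_T`` is the dense period embedding. A
plain GRU decoder, initialized with ``h_T`` and driven by zero inputs,
unrolls T steps through a linear readout to reconstruct the post-imputation
inputs; the training loss is the sum of squared differences between the
reconstruction and those (by default gradient-detached) targets.

Everything is NumPy; gradients are derived by hand (reverse-mode through the
unrolled recurrence) and are checked against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

from aomphen.errors import ContractError


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def decay_weight(delta, w_gamma, b_gamma):
    """gamma = exp(-max(0, w*delta + b)), elementwise; gamma in (0, 1]."""
    delta = np.asarray(delta, dtype=float)
    if (delta < 0).any():
        raise ContractError("delta must be non-negative")
    return np.exp(-np.maximum(0.0, w_gamma * delta + b_gamma))


def impute_input(x, m, x_last, x_mean, gamma):
    """Observed passthrough; otherwise decay from carry-forward toward mean."""
    x, m = np.asarray(x, dtype=float), np.asarray(m, dtype=float)
    return m * x + (1.0 - m) * (gamma * np.asarray(x_last, dtype=float) + (1.0 - gamma) * np.asarray(x_mean, dtype=float))


def init_grud_params(
    n_features: int, hidden: int, seed: int, *, hidden_decay: bool = True
) -> dict[str, np.ndarray]:
    """Initialize parameters. Input-decay weights start small and positive so
    the rectifier in gamma is active and decay weights receive gradient."""
    rng = np.random.default_rng(seed)
    D, H = n_features, hidden
    if H < 1 or D < 1:
        raise ContractError("hidden size and feature count must be >= 1")
    k = 1.0 / np.sqrt(H)

    def u(shape):
        return rng.uniform(-k, k, size=shape)

    params = {
        "w_gx": np.full(D, 0.05),
        "b_gx": np.zeros(D),
        # encoder gates over [x_hat, mask, hidden]
        "Wz": u((D, H)), "Vz": u((D, H)), "Uz": u((H, H)), "bz": np.zeros(H),
        "Wr": u((D, H)), "Vr": u((D, H)), "Ur": u((H, H)), "br": np.zeros(H),
        "Wc": u((D, H)), "Vc": u((D, H)), "Uc": u((H, H)), "bc": np.zeros(H),
        # decoder GRU (zero inputs) + linear readout
        "Az": u((H, H)), "az": np.zeros(H),
        "Ar": u((H, H)), "ar": np.zeros(H),
        "Ac": u((H, H)), "ac": np.zeros(H),
        "Wo": u((H, D)) * np.sqrt(H) / np.sqrt(D), "bo": np.zeros(D),
    }
    if hidden_decay:
        params["W_gh"] = rng.uniform(0.0, 0.05, size=(H, D))
        params["b_gh"] = np.zeros(H)
    return params


def grud_forward(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    M: np.ndarray,
    Delta: np.ndarray,
    XL: np.ndarray,
    x_mean: np.ndarray,
    *,
    return_cache: bool = False,
):
    """Run the encoder and decoder over a batch.

    Parameters are the dict from :func:`init_grud_params`; ``X, M, Delta,
    XL`` have shape (N, T, D) and ``x_mean`` shape (D,). Returns
    ``(h_T, x_hat, x_bar)`` — embedding (N, H), post-imputation inputs and
    reconstruction (N, T, D) — plus a cache when requested.
    """
    N, T, D = X.shape
    H = params["Uz"].shape[0]
    if params["Wz"].shape[0] != D:
        raise ContractError(
            f"model expects {params['Wz'].shape[0]} feature channels, tensor has {D}"
        )
    hidden_decay = "W_gh" in params
    h = np.zeros((N, H))
    enc_steps = []
    xhat_all = np.empty((N, T, D))
    for t in range(T):
        x, m, d, xl = X[:, t], M[:, t], Delta[:, t], XL[:, t]
        u_in = d * params["w_gx"] + params["b_gx"]
        gx = np.exp(-np.maximum(0.0, u_in))
        xhat = m * x + (1.0 - m) * (gx * xl + (1.0 - gx) * x_mean)
        xhat_all[:, t] = xhat
        if hidden_decay:
            s = d @ params["W_gh"].T + params["b_gh"]
            gh = np.exp(-np.maximum(0.0, s))
            hp = gh * h
        else:
            s, gh, hp = None, None, h
        z = _sigmoid(xhat @ params["Wz"] + m @ params["Vz"] + hp @ params["Uz"] + params["bz"])
        r = _sigmoid(xhat @ params["Wr"] + m @ params["Vr"] + hp @ params["Ur"] + params["br"])
        c = np.tanh(xhat @ params["Wc"] + m @ params["Vc"] + (r * hp) @ params["Uc"] + params["bc"])
        h_new = (1.0 - z) * hp + z * c
        enc_steps.append(dict(x=x, m=m, d=d, xl=xl, u_in=u_in, gx=gx, xhat=xhat,
                              s=s, gh=gh, hp=hp, h_prev=h, z=z, r=r, c=c))
        h = h_new
    h_T = h

    g = h_T
    dec_steps = []
    xbar = np.empty((N, T, D))
    for t in range(T):
        z = _sigmoid(g @ params["Az"] + params["az"])
        r = _sigmoid(g @ params["Ar"] + params["ar"])
        c = np.tanh((r * g) @ params["Ac"] + params["ac"])
        g_new = (1.0 - z) * g + z * c
        xbar[:, t] = g_new @ params["Wo"] + params["bo"]
        dec_steps.append(dict(g_prev=g, z=z, r=r, c=c, g=g_new))
        g = g_new

    if return_cache:
        cache = dict(enc=enc_steps, dec=dec_steps, h_T=h_T, xhat=xhat_all, xbar=xbar,
                     x_mean=x_mean, hidden_decay=hidden_decay, shape=(N, T, D, H))
        return h_T, xhat_all, xbar, cache
    return h_T, xhat_all, xbar


def reconstruction_loss(x_bar: np.ndarray, x_hat: np.ndarray) -> float:
    """Sum over samples, steps and features of squared differences."""
    if x_bar.shape != x_hat.shape:
        raise ContractError("reconstruction and target shapes must match")
    return float(np.sum((x_hat - x_bar) ** 2))


def grud_backward(
    params: dict[str, np.ndarray],
    cache: dict,
    *,
    detach_targets: bool = True,
) -> dict[str, np.ndarray]:
    """Gradients of the summed squared reconstruction loss w.r.t. all params.

    With ``detach_targets`` (default) the post-imputation targets are
    treated as constants; otherwise the loss also backpropagates into the
    imputation pathway through the target side, which opens the shortcut of
    moving the targets toward the reconstruction.
    """
    N, T, D, H = cache["shape"]
    xhat, xbar = cache["xhat"], cache["xbar"]
    hidden_decay = cache["hidden_decay"]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    diff = xbar - xhat  # (N, T, D)

    # ---- decoder backward
    dg_next = np.zeros((N, H))
    for t in range(T - 1, -1, -1):
        step = cache["dec"][t]
        dxbar = 2.0 * diff[:, t]
        grads["Wo"] += step["g"].T @ dxbar
        grads["bo"] += dxbar.sum(axis=0)
        dg = dg_next + dxbar @ params["Wo"].T
        z, r, c, gp = step["z"], step["r"], step["c"], step["g_prev"]
        dz = dg * (c - gp)
        dc = dg * z
        dgp = dg * (1.0 - z)
        da_c = dc * (1.0 - c ** 2)
        grads["Ac"] += (r * gp).T @ da_c
        grads["ac"] += da_c.sum(axis=0)
        drg = da_c @ params["Ac"].T
        dr = drg * gp
        dgp += drg * r
        da_r = dr * r * (1.0 - r)
        grads["Ar"] += gp.T @ da_r
        grads["ar"] += da_r.sum(axis=0)
        dgp += da_r @ params["Ar"].T
        da_z = dz * z * (1.0 - z)
        grads["Az"] += gp.T @ da_z
        grads["az"] += da_z.sum(axis=0)
        dgp += da_z @ params["Az"].T
        dg_next = dgp

    # ---- encoder backward, seeded by dL/dh_T from the decoder's initial state
    dh = dg_next
    for t in range(T - 1, -1, -1):
        step = cache["enc"][t]
        z, r, c, hp = step["z"], step["r"], step["c"], step["hp"]
        m, d, xl, gx = step["m"], step["d"], step["xl"], step["gx"]
        dz = dh * (c - hp)
        dc = dh * z
        dhp = dh * (1.0 - z)
        da_c = dc * (1.0 - c ** 2)
        grads["Wc"] += step["xhat"].T @ da_c
        grads["Vc"] += m.T @ da_c
        grads["Uc"] += (r * hp).T @ da_c
        grads["bc"] += da_c.sum(axis=0)
        drhp = da_c @ params["Uc"].T
        dr = drhp * hp
        dhp += drhp * r
        da_r = dr * r * (1.0 - r)
        grads["Wr"] += step["xhat"].T @ da_r
        grads["Vr"] += m.T @ da_r
        grads["Ur"] += hp.T @ da_r
        grads["br"] += da_r.sum(axis=0)
        dhp += da_r @ params["Ur"].T
        da_z = dz * z * (1.0 - z)
        grads["Wz"] += step["xhat"].T @ da_z
        grads["Vz"] += m.T @ da_z
        grads["Uz"] += hp.T @ da_z
        grads["bz"] += da_z.sum(axis=0)
        dhp += da_z @ params["Uz"].T

        dxhat = da_z @ params["Wz"].T + da_r @ params["Wr"].T + da_c @ params["Wc"].T
        if not detach_targets:
            dxhat = dxhat - 2.0 * diff[:, t]  # dL/dxhat from the loss itself
        dgx = dxhat * (1.0 - m) * (xl - cache["x_mean"])
        du = -dgx * gx * (step["u_in"] > 0)
        grads["w_gx"] += (du * d).sum(axis=0)
        grads["b_gx"] += du.sum(axis=0)

        if hidden_decay:
            gh, h_prev = step["gh"], step["h_prev"]
            dgh = dhp * h_prev
            dh = dhp * gh
            ds = -dgh * gh * (step["s"] > 0)
            grads["W_gh"] += ds.T @ d
            grads["b_gh"] += ds.sum(axis=0)
        else:
            dh = dhp
    return grads


def encode(params: dict[str, np.ndarray], X, M, Delta, XL, x_mean) -> np.ndarray:
    """Embedding h_T for a batch of tensors (deterministic given params)."""
    h_T, _, _ = grud_forward(params, X, M, Delta, XL, x_mean)
    return h_T


def decode(h_T: np.ndarray, params: dict[str, np.ndarray], T: int = 13) -> np.ndarray:
    """Unroll the GRU decoder from h_T with zero inputs; (N, T, D) readout."""
    g = h_T
    N = h_T.shape[0]
    D = params["Wo"].shape[1]
    xbar = np.empty((N, T, D))
    for t in range(T):
        z = _sigmoid(g @ params["Az"] + params["az"])
        r = _sigmoid(g @ params["Ar"] + params["ar"])
        c = np.tanh((r * g) @ params["Ac"] + params["ac"])
        g = (1.0 - z) * g + z * c
        xbar[:, t] = g @ params["Wo"] + params["bo"]
    return xbar
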