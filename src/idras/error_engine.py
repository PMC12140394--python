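"""The learned functions: combination g, one-step prediction filter F and
the filtering error ℰ.

``c^k = g(z^k; θ)`` is the scalar candidate regulated quantity.  The filter
``ĉ^k = F(c^{k-T:k-1}; Θ)`` predicts the next value of that series through a
latent-state model: an encoder maps the length-T history to a latent state,
a deterministic drift advances the state over one sampling interval, and a
decoder emits the prediction.  The filtering error is

    e^k = c^k − ĉ^k = ℰ(z^{k-T:k}; Ω),        Ω = [θ, Θ].

With ``static_mode`` the filter is identically zero and the error reduces to
``e^k = c^k`` — the static fixed-set-point problem.

All three maps are differentiable end-to-end; batched evaluation runs the
same code path on plain arrays (inference) or autodiff tensors (training).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .nn import MLP

__all__ = [
    "CombinationParams",
    "FilterParams",
    "ModelState",
    "combination_apply",
    "filter_predict",
    "filtering_error",
    "batch_filtering_errors",
    "paired_filtering_errors",
    "batch_gauge_stats",
    "init_model",
]


@dataclass
class CombinationParams:
    """θ — the trainable combination g: ℝⁿ → ℝ."""

    net: MLP

    @property
    def n_channels(self) -> int:
        return self.net.n_in


@dataclass
class FilterParams:
    """Θ = [φ, ω, δ] — encoder, latent drift and decoder of the filter."""

    encoder: MLP      # ℝ^T -> ℝ^{b_y}
    drift: MLP        # ℝ^{b_y} -> ℝ^{b_y}
    decoder: MLP      # ℝ^{b_y} -> ℝ (linear)
    integrator: str = "euler"   # "euler" | "rk4", fixed step over dt
    n_substeps: int = 1

    @property
    def T(self) -> int:
        return self.encoder.n_in

    @property
    def b_y(self) -> int:
        return self.encoder.n_out


@dataclass
class ModelState:
    """Ω — the full parameter state plus normalization constants.

    ``z_mean``/``z_std`` standardize the observables once per fit;
    ``c_mean``/``c_std`` fix the output gauge of g (g is identifiable only
    up to affine transformations, so the reported c is standardized).
    """

    theta: CombinationParams
    Theta: FilterParams
    dt: float
    static_mode: bool = False
    z_mean: np.ndarray = field(default_factory=lambda: np.zeros(1))
    z_std: np.ndarray = field(default_factory=lambda: np.ones(1))
    c_mean: float = 0.0
    c_std: float = 1.0

    @property
    def T(self) -> int:
        return self.Theta.T

    def parameters(self) -> list[np.ndarray]:
        ps = self.theta.net.params()
        if not self.static_mode:
            ps = ps + (self.Theta.encoder.params() + self.Theta.drift.params()
                       + self.Theta.decoder.params())
        return ps

    def tensor_parameters(self) -> list[Tensor]:
        return [Tensor(p, requires_grad=True) for p in self.parameters()]

    # -- persistence ---------------------------------------------------------
    def save(self, archive_path: str, config_path: str) -> None:
        """Write parameters (npz) and a JSON sidecar config."""
        arrays = {}
        for name, net in self._nets().items():
            for i, (w, b) in enumerate(zip(net.weights, net.biases)):
                arrays[f"{name}_w{i}"] = w
                arrays[f"{name}_b{i}"] = b
        arrays["z_mean"] = self.z_mean
        arrays["z_std"] = self.z_std
        np.savez_compressed(archive_path, **arrays)
        cfg = {
            "n_channels": self.theta.n_channels,
            "T": self.T,
            "b_y": self.Theta.b_y,
            "g_hidden": list(self.theta.net.sizes[1:-1]),
            "enc_hidden": list(self.Theta.encoder.sizes[1:-1]),
            "drift_hidden": list(self.Theta.drift.sizes[1:-1]),
            "dt": self.dt,
            "static_mode": self.static_mode,
            "integrator": self.Theta.integrator,
            "n_substeps": self.Theta.n_substeps,
            "c_mean": self.c_mean,
            "c_std": self.c_std,
        }
        with open(config_path, "w", encoding="utf-8") as fh:
            json.dump(cfg, fh, indent=2)

    @classmethod
    def load(cls, archive_path: str, config_path: str) -> "ModelState":
        with open(config_path, encoding="utf-8") as fh:
            cfg = json.load(fh)
        state = init_model(
            n_channels=cfg["n_channels"], T=cfg["T"], b_y=cfg["b_y"],
            g_hidden=tuple(cfg["g_hidden"]), enc_hidden=tuple(cfg["enc_hidden"]),
            drift_hidden=tuple(cfg["drift_hidden"]), dt=cfg["dt"],
            static_mode=cfg["static_mode"], integrator=cfg["integrator"],
            n_substeps=cfg["n_substeps"], rng=np.random.default_rng(0),
        )
        with np.load(archive_path) as npz:
            for name, net in state._nets().items():
                for i in range(len(net.weights)):
                    net.weights[i][...] = npz[f"{name}_w{i}"]
                    net.biases[i][...] = npz[f"{name}_b{i}"]
            state.z_mean = npz["z_mean"]
            state.z_std = npz["z_std"]
        state.c_mean = cfg["c_mean"]
        state.c_std = cfg["c_std"]
        return state

    def _nets(self) -> dict[str, MLP]:
        return {
            "g": self.theta.net,
            "enc": self.Theta.encoder,
            "drift": self.Theta.drift,
            "dec": self.Theta.decoder,
        }


def init_model(n_channels: int, T: int, b_y: int = 3,
               g_hidden: tuple[int, ...] = (32, 32),
               enc_hidden: tuple[int, ...] = (32, 32),
               drift_hidden: tuple[int, ...] = (32,),
               dt: float = 1.0, static_mode: bool = False,
               integrator: str = "euler", n_substeps: int = 1,
               rng: np.random.Generator | None = None) -> ModelState:
    """Fresh Ω with the default desk-scale architecture."""
    rng = rng or np.random.default_rng()
    theta = CombinationParams(MLP(n_channels, g_hidden, 1, rng))
    Theta = FilterParams(
        encoder=MLP(T, enc_hidden, b_y, rng),
        drift=MLP(b_y, drift_hidden, b_y, rng),
        decoder=MLP(b_y, (), 1, rng),
        integrator=integrator,
        n_substeps=n_substeps,
    )
    return ModelState(theta=theta, Theta=Theta, dt=dt, static_mode=static_mode,
                      z_mean=np.zeros(n_channels), z_std=np.ones(n_channels))


# ---------------------------------------------------------------------------
# Forward passes (shared numpy / autodiff code path)
# ---------------------------------------------------------------------------

def _g_forward(z2d, theta: CombinationParams, params=None, z_mean=0.0, z_std=1.0):
    return theta.net.forward((z2d - z_mean) / z_std, params)


def _advance_latent(y, drift: MLP, dt: float, params=None):
    """Integrate dy/dt = w(y) over one sampling interval with fixed steps."""
    h = dt / drift_substeps(drift)
    for _ in range(drift_substeps(drift)):
        if drift._integrator == "rk4":
            k1 = drift.forward(y, params)
            k2 = drift.forward(y + (h / 2) * k1, params)
            k3 = drift.forward(y + (h / 2) * k2, params)
            k4 = drift.forward(y + h * k3, params)
            y = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            y = y + h * drift.forward(y, params)
    return y


def drift_substeps(drift: MLP) -> int:
    return getattr(drift, "_n_substeps", 1)


def _filter_forward(c_hist, Theta: FilterParams, dt: float,
                    enc_p=None, drift_p=None, dec_p=None):
    """ĉ for a batch of standardized histories, shape (B, T) -> (B,)."""
    y = Theta.encoder.forward(c_hist, enc_p)
    Theta.drift._integrator = Theta.integrator
    Theta.drift._n_substeps = Theta.n_substeps
    y = _advance_latent(y, Theta.drift, dt, drift_p)
    return Theta.decoder.forward(y, dec_p)[:, 0]


def _split_params(omega: ModelState, params):
    """Split the flat tensor-parameter list into per-network lists."""
    if params is None:
        return None, None, None, None
    n_g = len(omega.theta.net.params())
    g_p = params[:n_g]
    rest = params[n_g:]
    if omega.static_mode:
        return g_p, None, None, None
    n_e = len(omega.Theta.encoder.params())
    n_w = len(omega.Theta.drift.params())
    return g_p, rest[:n_e], rest[n_e : n_e + n_w], rest[n_e + n_w :]


def _errors_from_c(c_all, omega: ModelState, enc_p=None, drift_p=None, dec_p=None):
    """e^k from a (B, T+1) array/tensor of (already gauged) c values."""
    T = omega.T
    c_k = c_all[:, T]
    if omega.static_mode:
        return c_k
    c_hat = _filter_forward(c_all[:, :T], omega.Theta, omega.dt,
                            enc_p, drift_p, dec_p)
    return c_k - c_hat


def paired_filtering_errors(data_windows, surrogate_windows, omega: ModelState,
                            params=None):
    """Filtering errors of a data batch and a surrogate batch under one Ω,
    with the combination's output gauge fixed *in-graph* on the data batch
    (zero mean, unit variance over all its samples).

    This is the quantity the adversarial loss is built from: the gauge is
    part of the computation, so gradients see it, and the surrogate errors
    are measured in exactly the data batch's gauge.  Returns ``(e_data,
    e_surrogate)``.
    """
    data_windows = np.asarray(data_windows, dtype=np.float64)
    surrogate_windows = np.asarray(surrogate_windows, dtype=np.float64)
    B, Tp1, n = data_windows.shape
    C = surrogate_windows.shape[0]
    g_p, enc_p, drift_p, dec_p = _split_params(omega, params)
    cd = _g_forward(data_windows.reshape(B * Tp1, n), omega.theta, g_p,
                    omega.z_mean, omega.z_std)
    cs = _g_forward(surrogate_windows.reshape(C * Tp1, n), omega.theta, g_p,
                    omega.z_mean, omega.z_std)
    mu = cd.mean()
    sd = (((cd - mu) ** 2).mean() + 1e-12) ** 0.5
    cd = ((cd - mu) / sd).reshape(B, Tp1)
    cs = ((cs - mu) / sd).reshape(C, Tp1)
    return (_errors_from_c(cd, omega, enc_p, drift_p, dec_p),
            _errors_from_c(cs, omega, enc_p, drift_p, dec_p))


def batch_gauge_stats(omega: ModelState, windows) -> tuple[float, float]:
    """Mean/std of raw g over every sample of the given windows — the
    constants that reproduce the batch gauge at inference time."""
    windows = np.asarray(windows, dtype=np.float64)
    B, Tp1, n = windows.shape
    c = _g_forward(windows.reshape(B * Tp1, n), omega.theta,
                   z_mean=omega.z_mean, z_std=omega.z_std)[:, 0]
    return float(np.mean(c)), float(max(np.std(c), 1e-8))


def batch_filtering_errors(windows, omega: ModelState, params=None,
                           c_stats: tuple[float, float] | None = None):
    """Filtering errors for a batch of windows, shape (B, T+1, n) -> (B,).

    ``params`` is the flat tensor parameter list (``omega.tensor_parameters``
    order) for autodiff; ``c_stats=(mean, std)`` fixes the output gauge of g
    (defaults to the state's stored gauge).  The history c's are recomputed
    from the current θ on every call, so gradients couple θ and Θ end to end.
    """
    windows = np.asarray(windows, dtype=np.float64)
    B, Tp1, n = windows.shape
    T = omega.T
    if Tp1 != T + 1:
        raise ValueError(f"window length {Tp1} does not match T+1={T + 1}")
    if n != omega.theta.n_channels:
        raise ValueError(
            f"window has {n} channels, combination expects {omega.theta.n_channels}"
        )
    g_p, enc_p, drift_p, dec_p = _split_params(omega, params)
    if c_stats is None:
        c_stats = (omega.c_mean, omega.c_std)
    mu, sd = c_stats
    if omega.static_mode:
        # e^k = c^k exactly: evaluate g on the final samples alone, with the
        # same expression order as combination_apply (bit-identical results)
        c_tail = _g_forward(windows[:, T, :], omega.theta, g_p,
                            omega.z_mean, omega.z_std)[:, 0]
        return (c_tail - mu) / sd
    c_all = _g_forward(windows.reshape(B * Tp1, n), omega.theta, g_p,
                       omega.z_mean, omega.z_std)
    c_all = (c_all.reshape(B, Tp1) - mu) * (1.0 / sd)
    return _errors_from_c(c_all, omega, enc_p, drift_p, dec_p)


# ---------------------------------------------------------------------------
# Convenience operations (single inputs or batches, numpy only)
# ---------------------------------------------------------------------------

def combination_apply(z, theta: CombinationParams | ModelState):
    """c = g(z; θ) for one n-vector or a batch (B, n)."""
    omega = theta if isinstance(theta, ModelState) else None
    if omega is not None:
        theta = omega.theta
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    z2d = z[None, :] if single else z
    if z2d.shape[1] != theta.n_channels:
        raise ValueError(
            f"input has {z2d.shape[1]} channels, expected {theta.n_channels}"
        )
    if omega is not None:
        c = _g_forward(z2d, theta, None, omega.z_mean, omega.z_std)[:, 0]
        c = (c - omega.c_mean) / omega.c_std
    else:
        c = _g_forward(z2d, theta)[:, 0]
    return float(c[0]) if single else c


def filter_predict(c_hist, Theta: FilterParams | ModelState, dt: float):
    """ĉ = F(c^{k-T:k-1}; Θ) for one length-T history or a batch (B, T).

    Passing a :class:`ModelState` in ``static_mode`` yields exactly 0
    (the filter is switched off — the static fixed-set-point reduction).
    """
    c_hist = np.asarray(c_hist, dtype=np.float64)
    single = c_hist.ndim == 1
    if isinstance(Theta, ModelState):
        omega = Theta
        Theta = omega.Theta
        if omega.static_mode:
            return 0.0 if single else np.zeros(c_hist.shape[0])
    h2d = c_hist[None, :] if single else c_hist
    if h2d.shape[1] != Theta.T:
        raise ValueError(f"history length {h2d.shape[1]}, filter expects {Theta.T}")
    out = _filter_forward(h2d, Theta, dt)
    return float(out[0]) if single else out


def filtering_error(window, omega: ModelState, dt: float | None = None):
    """e = ℰ(z^{k-T:k}; Ω) for one (T+1, n) window or a batch (B, T+1, n)."""
    window = np.asarray(window, dtype=np.float64)
    single = window.ndim == 2
    w3d = window[None, ...] if single else window
    if dt is not None and dt != omega.dt:
        omega = ModelState(**{**omega.__dict__, "dt": dt})
    e = batch_filtering_errors(w3d, omega)
    return float(e[0]) if single else e
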