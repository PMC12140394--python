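"""The combination player and the alternating adversarial fitting loop.

Each outer iteration the shuffle player rebuilds a constrained surrogate
ensemble under the current parameters Ω (so the variance ratio re-enters at
≈ 1), then the combination player runs a few epochs of gradient descent on

    ratio(Ω) = var(data filtering errors) / var(surrogate filtering errors)

with the surrogate *windows* frozen (Ω still appears in their errors).  The
loop stops when the ratio stops improving.  A final ratio near 1 means the
temporal order of the data carries no predictable structure beyond the
marginal — no dynamic regulation was found.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .datamodel import TimeSeriesSet, build_windows
from .error_engine import (
    ModelState,
    batch_gauge_stats,
    init_model,
    paired_filtering_errors,
)
from .nn import Adam
from .shuffle_player import (
    make_unconstrained_surrogates,
    resample_surrogates,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "variance_ratio",
    "combination_step",
    "idras_fit",
    "iras_fit",
    "sweep_history_length",
]


@dataclass
class FitConfig:
    """Hyper-parameters of a fit; defaults are desk-scale."""

    T: int = 4
    b_y: int = 3
    g_hidden: tuple[int, ...] = (32, 32)
    enc_hidden: tuple[int, ...] = (32, 32)
    drift_hidden: tuple[int, ...] = (32,)
    outer_iters: int = 200
    inner_epochs: int = 20
    lr: float = 1e-3
    batch_size: int | None = None        # None -> full batch
    n_bins: int = 100
    tol: float = 1e-3                    # relative ratio improvement
    patience: int = 5
    seed: int = 0
    static_mode: bool = False
    surrogate_factor: int = 4
    integrator: str = "euler"
    n_substeps: int = 1
    detach_denominator: bool = False     # ablation: drop Ω-gradient of the denominator
    no_regulation_ratio: float = 0.9
    log: callable = None                 # optional per-iteration callback

    def __post_init__(self):
        if self.T < 1 or self.b_y < 1 or self.outer_iters < 1 \
                or self.inner_epochs < 0 or self.lr < 0:
            raise ValueError("all FitConfig sizes must be positive")
        if not (0.0 < self.tol < 1.0):
            raise ValueError(f"tolerance must lie in (0,1), got {self.tol}")


@dataclass
class FitResult:
    """Output of a fit: Ω*, the per-iteration trace and the learned series."""

    state: ModelState
    trace: list[dict] = field(default_factory=list)
    c: list[np.ndarray] = field(default_factory=list)
    c_hat: list[np.ndarray] = field(default_factory=list)
    converged: bool = False
    status: str = ""

    @property
    def final_ratio(self) -> float:
        return self.trace[-1]["ratio"] if self.trace else float("nan")

    @property
    def best_ratio(self) -> float:
        return min(t["ratio"] for t in self.trace) if self.trace else float("nan")


def variance_ratio(data_errors, surrogate_errors) -> float:
    """var(data errors) / var(surrogate errors), population (ddof=0) variances."""
    d = np.asarray(data_errors, dtype=np.float64).ravel()
    s = np.asarray(surrogate_errors, dtype=np.float64).ravel()
    if d.size < 2 or s.size < 2:
        raise ValueError("need at least 2 errors in each collection")
    denom = np.var(s)
    if denom == 0.0:
        raise ZeroDivisionError(
            "surrogate filtering errors have zero variance (degenerate denominator)"
        )
    return float(np.var(d) / denom)


def combination_step(omega: ModelState, data_windows: np.ndarray,
                     surrogate_windows: np.ndarray, config: FitConfig,
                     optimizer: Adam | None = None) -> tuple[float, float]:
    """Run ``inner_epochs`` of gradient descent on the empirical variance
    ratio with the surrogate ensemble frozen.  Updates Ω in place and
    returns (ratio at entry, ratio after the step) on the training batch.

    The output gauge of g (zero mean, unit variance over the data batch) is
    recomputed inside every forward pass, so it tracks θ through training.
    """
    opt = optimizer or Adam(omega.parameters(), lr=config.lr)

    def ratio_now() -> float:
        e_d, e_s = paired_filtering_errors(data_windows, surrogate_windows, omega)
        return variance_ratio(e_d, e_s)

    ratio_entry = ratio_now()
    for _ in range(config.inner_epochs):
        params = omega.tensor_parameters()
        e_d, e_s = paired_filtering_errors(data_windows, surrogate_windows,
                                           omega, params=params)
        if config.detach_denominator:
            loss = e_d.var() * (1.0 / float(e_s.var().data))
        else:
            loss = e_d.var() / e_s.var()
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite variance ratio {loss.data} during the "
                f"combination step (entry ratio {ratio_entry:.4g})"
            )
        loss.backward()
        opt.step([p.grad for p in params])
    return ratio_entry, ratio_now()


def _learned_series(omega: ModelState, ts: TimeSeriesSet
                    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Final c^k and ĉ^k per input series (ĉ is NaN for the first T samples)."""
    T = omega.T
    cs, chats = [], []
    for _, arr in ts.series:
        N = arr.shape[0]
        from .error_engine import _g_forward, _filter_forward

        c = (_g_forward(arr, omega.theta, z_mean=omega.z_mean,
                        z_std=omega.z_std)[:, 0] - omega.c_mean) / omega.c_std
        chat = np.full(N, np.nan)
        if not omega.static_mode and N > T:
            hist = np.stack([c[k - T : k] for k in range(T, N)])
            chat[T:] = _filter_forward(hist, omega.Theta, omega.dt)
        cs.append(c)
        chats.append(chat)
    return cs, chats


def idras_fit(ts: TimeSeriesSet, config: FitConfig) -> FitResult:
    """Alternate the shuffle player and the combination player until the
    variance ratio stops improving; all series are processed jointly into a
    single Ω*."""
    ss = np.random.SeedSequence(config.seed)
    init_rng, surr_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    we = build_windows(ts, config.T)
    omega = init_model(
        n_channels=ts.n_channels, T=config.T, b_y=config.b_y,
        g_hidden=config.g_hidden, enc_hidden=config.enc_hidden,
        drift_hidden=config.drift_hidden, dt=ts.dt,
        static_mode=config.static_mode, integrator=config.integrator,
        n_substeps=config.n_substeps, rng=init_rng,
    )
    pooled = ts.pooled_samples()
    omega.z_mean = pooled.mean(axis=0)
    omega.z_std = np.maximum(pooled.std(axis=0), 1e-8)

    opt = Adam(omega.parameters(), lr=config.lr)
    trace: list[dict] = []
    best = np.inf
    stall = 0
    for it in range(config.outer_iters):
        se = make_unconstrained_surrogates(
            we, ts, count=config.surrogate_factor * len(we), rng=surr_rng,
            channel_shuffle=config.static_mode,
        )
        sec = resample_surrogates(se, omega, we.windows, surr_rng,
                                  n_bins=config.n_bins)
        e_d, e_s = paired_filtering_errors(we.windows, sec.windows, omega)
        ks = sps.ks_2samp(e_d, e_s)
        ratio_entry = variance_ratio(e_d, e_s)
        _, ratio = combination_step(omega, we.windows, sec.windows, config,
                                    optimizer=opt)
        rec = {"iteration": it, "ratio_entry": ratio_entry, "ratio": ratio,
               "ks_stat": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}
        trace.append(rec)
        if config.log is not None:
            config.log(rec)
        improvement = (best - ratio) / best if np.isfinite(best) else 1.0
        best = min(best, ratio)
        stall = stall + 1 if improvement < config.tol else 0
        if stall >= config.patience:
            break

    omega.c_mean, omega.c_std = batch_gauge_stats(omega, we.windows)
    c, c_hat = _learned_series(omega, ts)
    best_ratio = min(t["ratio"] for t in trace)
    converged = best_ratio <= config.no_regulation_ratio
    status = (
        f"converged: best variance ratio {best_ratio:.4f}" if converged else
        f"no regulation found: best variance ratio {best_ratio:.4f} > "
        f"{config.no_regulation_ratio} (temporal order adds no predictability)"
    )
    return FitResult(state=omega, trace=trace, c=c, c_hat=c_hat,
                     converged=converged, status=status)


def iras_fit(ts: TimeSeriesSet, config: FitConfig) -> FitResult:
    """The static reduction: F ≡ 0 (e^k = c^k) with channel-shuffled
    surrogate tails — searches for a combination regulated about a fixed
    set-point."""
    return idras_fit(ts, replace(config, static_mode=True))


def sweep_history_length(ts: TimeSeriesSet, config: FitConfig,
                         T_values: list[int]) -> dict[int, FitResult]:
    """Refit for each T; pick the smallest T past which the best ratio stops
    improving (the system's effective memory time)."""
    return {T: idras_fit(ts, replace(config, T=T)) for T in T_values}
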