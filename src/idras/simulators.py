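"""Ground-truth generative models used to validate the identification loop.

Three generators with a known regulated combination:

* a kinetic gene-expression circuit in which the summed concentration of two
  proteins, P + S, is held by fast negative feedback near a set-point that
  follows a slowly oscillating transcription rate K(t);
* bacterial growth-division lineages in which cells grow exponentially and
  divide when their size crosses a slowly drifting Ornstein-Uhlenbeck
  threshold u(t) — a "sizer" with a dynamic threshold;
* a two-objective toy with two disjoint channel groups, each carrying an
  independent regulated combination tracking its own slow sinusoid.

All numeric defaults are this package's own documented choices of a
realistic regime: kinetic rates of order 1/min with the environmental
modulation 100x slower and strong feedback; threshold fluctuations much
slower than a cell cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import TimeSeriesSet

__all__ = [
    "KineticParams",
    "CellCycleParams",
    "TwoObjectiveParams",
    "LineageRecord",
    "kinetic_rate_K",
    "kinetic_setpoint",
    "simulate_kinetic",
    "ou_step",
    "simulate_lineages",
    "lineages_to_timeseries",
    "simulate_two_objectives",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# Kinetic gene-expression circuit
#   dM = (K(t) − f·(P+S) − γ_M·M) dt
#   dP = (k_P·M − γ_P·P) dt + η_P dW_P
#   dS = (k_S·M − γ_S·S) dt + η_S dW_S
#   K(t) = K0·(1 + 0.5·cos(2πt/τ_K + φ_K))
# Strong feedback f holds P+S near  c*(t) = K(t) / (f + γ_M·γ_P·γ_S/(k_P·γ_S + k_S·γ_P)).
# ---------------------------------------------------------------------------

@dataclass
class KineticParams:
    """Rates in 1/min, concentrations in arbitrary units, time in minutes."""

    K0: float = 50.0
    tau_K: float = 100.0        # environmental modulation period, 100x kinetics
    phi_K: float = 0.0
    f: float = 10.0             # feedback strength (strong-feedback regime)
    gamma_M: float = 1.0
    gamma_P: float = 1.0
    gamma_S: float = 1.0
    k_P: float = 1.0
    k_S: float = 1.0
    eta_P: float = 0.2
    eta_S: float = 0.2
    t_s: float = 1.0            # observation sampling interval
    sim_dt: float = 0.01        # Euler-Maruyama step
    duration: float = 500.0     # per-series simulated time (after burn-in)
    burn_in: float = 20.0
    n_series: int = 20
    phase_random: bool = True   # random φ_K per series (stationary marginal)
    initial_state: tuple[float, float, float] | None = None  # None -> steady state

    def __post_init__(self):
        rates = (self.f, self.gamma_M, self.gamma_P, self.gamma_S,
                 self.k_P, self.k_S, self.eta_P, self.eta_S)
        if any(r < 0 for r in rates) or self.tau_K <= 0:
            raise ValueError("rates must be >= 0 and tau_K > 0")
        if not (0 < self.sim_dt < self.t_s):
            raise ValueError("need 0 < sim_dt < t_s")

    def has_timescale_separation(self) -> bool:
        """Strong feedback with modulation much slower than the kinetics."""
        fastest = max(self.gamma_M, self.gamma_P, self.gamma_S)
        return self.tau_K >= 20.0 / fastest and self.f >= 5.0 * fastest


def kinetic_rate_K(t, params: KineticParams, phase: float | None = None):
    """Oscillating transcription rate, range [0.5·K0, 1.5·K0]."""
    phi = params.phi_K if phase is None else phase
    return params.K0 * (1.0 + 0.5 * np.cos(2.0 * np.pi * np.asarray(t) / params.tau_K + phi))


def _setpoint_denominator(p: KineticParams) -> float:
    denom = p.f + (p.gamma_M * p.gamma_P * p.gamma_S
                   / (p.k_P * p.gamma_S + p.k_S * p.gamma_P))
    if denom <= 0:
        raise ValueError("set-point denominator must be positive")
    return denom


def kinetic_setpoint(t, params: KineticParams, phase: float | None = None):
    """The reference level c*(t) that P+S tracks; linear in K(t)."""
    return kinetic_rate_K(t, params, phase) / _setpoint_denominator(params)


def _kinetic_steady_state(K: float, p: KineticParams) -> tuple[float, float, float]:
    """Noiseless fixed point of the kinetics at a frozen transcription rate K."""
    cs = K / _setpoint_denominator(p)
    M = (K - p.f * cs) / p.gamma_M
    return M, p.k_P * M / p.gamma_P, p.k_S * M / p.gamma_S


def simulate_kinetic(params: KineticParams, rng: np.random.Generator
                     ) -> tuple[TimeSeriesSet, list[np.ndarray]]:
    """Euler–Maruyama simulation; observations are [P, S] every ``t_s``.

    Returns the observed series and, per series, the ground-truth set-point
    track c*(t) at the same instants.  Concentrations are clipped at zero.
    """
    p = params
    n_sub = int(round(p.t_s / p.sim_dt))
    n_obs = int(round(p.duration / p.t_s))
    n_burn = int(round(p.burn_in / p.sim_dt))
    sqdt = math.sqrt(p.sim_dt)
    series, truths = [], []
    for m in range(p.n_series):
        phase = rng.uniform(0.0, 2.0 * np.pi) if p.phase_random else p.phi_K
        if p.initial_state is None:
            M, P, S = _kinetic_steady_state(float(kinetic_rate_K(0.0, p, phase)), p)
        else:
            M, P, S = p.initial_state
        t = -p.burn_in
        obs = np.empty((n_obs, 2))
        truth = np.empty(n_obs)
        # burn-in then recorded stretch, one EM step at a time
        n_total = n_burn + n_obs * n_sub
        noise = rng.standard_normal(size=(n_total, 2))
        j = 0
        for i in range(n_total):
            K = p.K0 * (1.0 + 0.5 * math.cos(2.0 * math.pi * t / p.tau_K + phase))
            dM = (K - p.f * (P + S) - p.gamma_M * M) * p.sim_dt
            dP = (p.k_P * M - p.gamma_P * P) * p.sim_dt + p.eta_P * sqdt * noise[i, 0]
            dS = (p.k_S * M - p.gamma_S * S) * p.sim_dt + p.eta_S * sqdt * noise[i, 1]
            M = max(M + dM, 0.0)
            P = max(P + dP, 0.0)
            S = max(S + dS, 0.0)
            if not (math.isfinite(M) and math.isfinite(P) and math.isfinite(S)):
                raise FloatingPointError(
                    f"kinetic simulation diverged at t={t:.3f}; use a smaller sim_dt"
                )
            t += p.sim_dt
            if i >= n_burn and (i - n_burn + 1) % n_sub == 0:
                obs[j] = (P, S)
                truth[j] = kinetic_setpoint(t, p, phase)
                j += 1
        series.append((f"series_{m}", obs))
        truths.append(truth)
    return TimeSeriesSet(series, dt=p.t_s, channel_names=["P", "S"]), truths


# ---------------------------------------------------------------------------
# Bacterial growth-division lineages with an OU division threshold
#   du = (μ_u − u)/τ_u dt + sqrt(2σ_u²/τ_u) dW
#   x(t) = x_b·e^{α(t−t_b)},  divide at the first t with x(t) = u(t)
#   x_b^k = η^k · x_d^{k−1},  α^k ~ Gamma,  η^k ~ N(0.5, σ_η²)
# ---------------------------------------------------------------------------

@dataclass
class CellCycleParams:
    """Times in units of the mean growth rate (ᾱ = γ_shape·γ_scale = 1 by default)."""

    mu_u: float = 1.0
    sigma_u: float = 0.15
    tau_u: float = 6.93          # default: ≈ 10 mean cycle times (slow threshold)
    gamma_shape: float = 25.0
    gamma_scale: float = 0.04    # mean growth rate 1, CV 20%
    sigma_eta: float = 0.02
    fixed_alpha: float | None = None   # override the Gamma draw (diagnostics)
    n_cycles: int = 100
    n_lineages: int = 30
    grid_dt: float | None = None  # threshold grid; None -> min(τ_u/1000, T̄/100)
    max_cycle_factor: float = 50.0

    def __post_init__(self):
        if self.mu_u <= 0 or self.sigma_u < 0 or self.tau_u <= 0:
            raise ValueError("need mu_u > 0, sigma_u >= 0, tau_u > 0")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("Gamma parameters must be positive")
        if not (0 <= self.sigma_eta < 0.25):
            raise ValueError("sigma_eta must lie in [0, 0.25)")

    @property
    def mean_alpha(self) -> float:
        return self.gamma_shape * self.gamma_scale

    @property
    def mean_cycle(self) -> float:
        """T̄ = log(2)/ᾱ — the doubling time of the average cell."""
        return math.log(2.0) / self.mean_alpha


@dataclass
class LineageRecord:
    """Per-cycle quantities of one lineage (arrays of length n_cycles)."""

    x_b: np.ndarray
    alpha: np.ndarray
    T: np.ndarray
    x_d: np.ndarray
    u_at_division: np.ndarray

    def __len__(self) -> int:
        return self.x_b.shape[0]


def ou_step(u, dt: float, mu_u: float, sigma_u: float, tau_u: float,
            rng: np.random.Generator):
    """Exact conditional OU update over a step of length ``dt``:

    mean μ_u + (u − μ_u)·e^{−dt/τ_u}, variance σ_u²·(1 − e^{−2dt/τ_u}).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return u
    decay = math.exp(-dt / tau_u)
    sd = sigma_u * math.sqrt(1.0 - decay * decay)
    noise = rng.standard_normal(np.shape(u)) if np.ndim(u) else rng.standard_normal()
    return mu_u + (u - mu_u) * decay + sd * noise


def simulate_lineages(params: CellCycleParams, rng: np.random.Generator,
                      return_tracks: bool = False):
    """Simulate growth-division lineages against an OU threshold.

    The threshold is advanced with the exact OU transition on a fine grid;
    the division time is the first grid crossing of the exponential size
    curve, refined by bisection against the linearly interpolated threshold
    (relative tolerance 1e-8).  The threshold is reflected at 0 (it must
    stay positive), a deviation from the unbounded OU that never triggers
    in the default regime.

    Returns a list of :class:`LineageRecord`; with ``return_tracks`` also a
    list of (t_grid, u_grid, x_grid) arrays for plotting.
    """
    p = params
    h = p.grid_dt if p.grid_dt is not None else min(p.tau_u / 1000.0,
                                                    p.mean_cycle / 100.0)
    decay = math.exp(-h / p.tau_u)
    sd = p.sigma_u * math.sqrt(1.0 - decay * decay)
    t_max = p.max_cycle_factor * p.mean_cycle
    records, tracks = [], []
    for _ in range(p.n_lineages):
        xd_prev = p.mu_u + p.sigma_u * rng.standard_normal()
        u = p.mu_u + p.sigma_u * rng.standard_normal()
        xb_arr = np.empty(p.n_cycles)
        al_arr = np.empty(p.n_cycles)
        T_arr = np.empty(p.n_cycles)
        xd_arr = np.empty(p.n_cycles)
        ud_arr = np.empty(p.n_cycles)
        tr_t, tr_u, tr_x = [], [], []
        t_abs = 0.0
        for k in range(p.n_cycles):
            alpha = (p.fixed_alpha if p.fixed_alpha is not None
                     else rng.gamma(p.gamma_shape, p.gamma_scale))
            eta = 0.5 + p.sigma_eta * rng.standard_normal()
            x_b = eta * xd_prev
            # march the threshold until the size curve crosses it
            tau = 0.0  # time since birth
            u_prev, t_prev = u, 0.0
            x_now = x_b
            while x_now < u:
                u_prev, t_prev = u, tau
                u = p.mu_u + (u - p.mu_u) * decay + sd * rng.standard_normal()
                if u < 0.0:
                    u = -u
                tau += h
                x_now = x_b * math.exp(alpha * tau)
                if return_tracks:
                    tr_t.append(t_abs + tau)
                    tr_u.append(u)
                    tr_x.append(x_now)
                if tau > t_max:
                    raise RuntimeError(
                        f"no threshold crossing within {p.max_cycle_factor} mean "
                        "cycles; parameterization is pathological"
                    )
            # bisection: exponential size vs linearly interpolated threshold
            lo, hi = t_prev, tau
            while hi - lo > 1e-8 * max(hi, h):
                mid = 0.5 * (lo + hi)
                w = (mid - t_prev) / (tau - t_prev) if tau > t_prev else 1.0
                u_mid = u_prev + w * (u - u_prev)
                if x_b * math.exp(alpha * mid) >= u_mid:
                    hi = mid
                else:
                    lo = mid
            T = 0.5 * (lo + hi)
            x_d = x_b * math.exp(alpha * T)
            w = (T - t_prev) / (tau - t_prev) if tau > t_prev else 1.0
            u_div = u_prev + w * (u - u_prev)
            xb_arr[k], al_arr[k], T_arr[k] = x_b, alpha, T
            xd_arr[k], ud_arr[k] = x_d, u_div
            xd_prev = x_d
            t_abs += T
            # continue the threshold from its value at the division instant
            u = u_div
        records.append(LineageRecord(xb_arr, al_arr, T_arr, xd_arr, ud_arr))
        if return_tracks:
            tracks.append((np.array(tr_t), np.array(tr_u), np.array(tr_x)))
    return (records, tracks) if return_tracks else records


def lineages_to_timeseries(records: list[LineageRecord]) -> TimeSeriesSet:
    """Observables z^k = [x_b^k, α^k, T^k], one sample per cycle (dt = 1 cycle)."""
    series = [
        (f"lineage_{i}", np.column_stack([r.x_b, r.alpha, r.T]))
        for i, r in enumerate(records)
    ]
    return TimeSeriesSet(series, dt=1.0, channel_names=["x_b", "alpha", "T"])


# ---------------------------------------------------------------------------
# Two-objective toy: two disjoint channel groups, each a linear combination
# tracking its own independent slow sinusoid with compensating noise.
# ---------------------------------------------------------------------------

@dataclass
class TwoObjectiveParams:
    n_series: int = 12
    n_steps: int = 400
    dt: float = 1.0
    tau_1: float = 60.0
    tau_2: float = 85.0          # incommensurate with tau_1
    amplitude: float = 1.0
    comp_noise: float = 1.0      # anti-correlated within-group noise
    obs_noise_1: float = 0.05    # group-1 channel noise (tight regulation)
    obs_noise_2: float = 0.15    # group-2 channel noise (looser regulation)


def simulate_two_objectives(params: TwoObjectiveParams, rng: np.random.Generator
                            ) -> tuple[TimeSeriesSet, list[np.ndarray], list[np.ndarray]]:
    """Four channels: z1+z2 tracks sinusoid 1, z3+z4 tracks sinusoid 2.

    Within each group a large iid compensating term cancels in the sum, so
    only the group's sum is predictable.  The two objectives are
    uncorrelated by construction (independent phases, incommensurate
    periods) and are regulated with different tightness: equally regulated
    twin objectives would make every mixture of the two exactly as
    predictable as either one — a degenerate flat optimum no identification
    method could resolve — whereas generic systems hold different
    quantities to different precision."""
    p = params
    t = np.arange(p.n_steps) * p.dt
    series, truth1, truth2 = [], [], []
    for m in range(p.n_series):
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        s1 = p.amplitude * np.sin(2 * np.pi * t / p.tau_1 + ph1)
        s2 = p.amplitude * np.sin(2 * np.pi * t / p.tau_2 + ph2)
        v1 = p.comp_noise * rng.standard_normal(p.n_steps)
        v2 = p.comp_noise * rng.standard_normal(p.n_steps)
        z = np.column_stack([
            0.5 * s1 + v1, 0.5 * s1 - v1,
            0.5 * s2 + v2, 0.5 * s2 - v2,
        ])
        z[:, :2] += p.obs_noise_1 * rng.standard_normal((p.n_steps, 2))
        z[:, 2:] += p.obs_noise_2 * rng.standard_normal((p.n_steps, 2))
        series.append((f"series_{m}", z))
        truth1.append(s1)
        truth2.append(s2)
    ts = TimeSeriesSet(series, dt=p.dt, channel_names=["z1", "z2", "z3", "z4"])
    return ts, truth1, truth2


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _lineage_quarter_tau() -> float:
    """τ_u solving 1 − e^{−2T̄/τ_u} = 0.25 for the default mean cycle."""
    Tbar = math.log(2.0)  # mean_alpha = 1 in the default parameterization
    return 2.0 * Tbar / math.log(4.0 / 3.0)


PRESETS = {
    # strong feedback, modulation 100x slower than the kinetics
    "kinetic": KineticParams(),
    # slow threshold: τ_u = 10 mean cycle times
    "lineage": CellCycleParams(tau_u=10.0 * math.log(2.0)),
    # threshold speed chosen so the one-step prediction floor is exactly 0.25
    "lineage_quarter": CellCycleParams(tau_u=_lineage_quarter_tau()),
    "two_objective": TwoObjectiveParams(),
}
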