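"""Metrics scoring a fitted combination against a known control objective.

The learned combination is identifiable only up to an affine gauge, so
correlations are reported after sign alignment; prediction quality is the
normalized mean-square error var(c − ĉ)/var(c).  For the lineage data the
three candidate division rules (sizer, adder, timer) provide reference
indicator series, and the Ornstein-Uhlenbeck threshold gives an analytic
one-step prediction floor 1 − e^{−2·T̄/τ_u} against which any trained
filter can be judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .simulators import LineageRecord

__all__ = [
    "EvalReport",
    "pearson_aligned",
    "nmse",
    "reference_indicators",
    "expected_ou_nmse",
    "mean_cycle",
    "sizer_residual",
    "lineage_truth",
    "evaluate_fit",
]


def pearson_aligned(c_star, c) -> float:
    """Pearson correlation after sign alignment (i.e. |ρ|).

    Accepts flat arrays or lists of per-series arrays; multiple series are
    standardized per series and pooled before correlating.
    """
    c_star, c = _pool(c_star), _pool(c)
    if c_star.size != c.size:
        raise ValueError(f"length mismatch: {c_star.size} vs {c.size}")
    if c_star.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(c_star) == 0 or np.std(c) == 0:
        raise ValueError("correlation undefined for a constant input")
    rho = sps.pearsonr(c_star, c).statistic
    return abs(float(rho))


def _pool(x) -> np.ndarray:
    """Standardize per series and concatenate; flat input passes through."""
    if isinstance(x, (list, tuple)) and len(x) and np.ndim(x[0]) >= 1:
        parts = []
        for arr in x:
            arr = np.asarray(arr, dtype=np.float64).ravel()
            sd = np.std(arr)
            parts.append((arr - arr.mean()) / (sd if sd > 0 else 1.0))
        return np.concatenate(parts)
    return np.asarray(x, dtype=np.float64).ravel()


def nmse(c, c_hat) -> float:
    """var(c − ĉ)/var(c); 0 is perfect, 1 no better than the mean.

    NaN entries of ĉ (e.g. the first T samples of a series, which have no
    full history) are dropped pairwise.  Lists of per-series arrays are
    pooled after per-series standardization of c (ĉ transformed with the
    same constants).
    """
    if isinstance(c, (list, tuple)) and len(c) and np.ndim(c[0]) >= 1:
        cs, hs = [], []
        for a, b in zip(c, c_hat):
            a = np.asarray(a, dtype=np.float64).ravel()
            b = np.asarray(b, dtype=np.float64).ravel()
            mu, sd = a.mean(), np.std(a)
            sd = sd if sd > 0 else 1.0
            cs.append((a - mu) / sd)
            hs.append((b - mu) / sd)
        c, c_hat = np.concatenate(cs), np.concatenate(hs)
    c = np.asarray(c, dtype=np.float64).ravel()
    c_hat = np.asarray(c_hat, dtype=np.float64).ravel()
    if c.size != c_hat.size:
        raise ValueError(f"length mismatch: {c.size} vs {c_hat.size}")
    keep = ~np.isnan(c_hat) & ~np.isnan(c)
    c, c_hat = c[keep], c_hat[keep]
    if c.size < 2:
        raise ValueError("need at least 2 samples")
    vc = np.var(c)
    if vc == 0:
        raise ValueError("var(c) is zero; NMSE undefined")
    return float(np.var(c - c_hat) / vc)


def reference_indicators(rec: LineageRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sizer, adder, timer) indicator series of one lineage:

    sizer  x_b·e^{αT}  (size at division),
    adder  x_b·(e^{αT} − 1)  (added size),
    timer  T  (cycle duration).
    """
    growth = np.exp(rec.alpha * rec.T)
    return rec.x_b * growth, rec.x_b * (growth - 1.0), rec.T.copy()


def expected_ou_nmse(T_bar: float, tau_u: float) -> float:
    """Analytic one-step NMSE floor 1 − e^{−2·T̄/τ_u} for predicting the
    division size when division triggers on an OU threshold of timescale τ_u."""
    if tau_u <= 0 or T_bar < 0:
        raise ValueError("need tau_u > 0 and T_bar >= 0")
    return 1.0 - math.exp(-2.0 * T_bar / tau_u)


def mean_cycle(gamma_shape: float, gamma_scale: float) -> float:
    """T̄ = log(2)/ᾱ with ᾱ = γ_shape·γ_scale (Gamma mean growth rate)."""
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValueError("Gamma parameters must be positive")
    return math.log(2.0) / (gamma_shape * gamma_scale)


def sizer_residual(rec: LineageRecord) -> np.ndarray:
    """The static mixture x_b·e^{αT} − 2·x_b.

    In the slow-threshold regime the threshold is nearly frozen within one
    cycle, so division size ≈ threshold ≈ 2·birth size and this mixture of
    sizer indicator and birth size hovers near zero — the combination a
    fixed-set-point search gravitates to."""
    growth = np.exp(rec.alpha * rec.T)
    return rec.x_b * growth - 2.0 * rec.x_b


@dataclass
class EvalReport:
    """Sign-aligned correlation and prediction NMSE of a fit, with optional
    per-series breakdown and division-rule indicator correlations."""

    rho_signed: float
    nmse: float | None = None
    per_series_rho: list[float] = field(default_factory=list)
    indicator_rho: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rho_signed": self.rho_signed,
            "nmse": self.nmse,
            "per_series_rho": self.per_series_rho,
            "indicator_rho": self.indicator_rho,
        }


def lineage_truth(records: list[LineageRecord]) -> dict[str, list[np.ndarray]]:
    """Ground-truth indicator tracks per lineage, keyed by rule name."""
    out: dict[str, list[np.ndarray]] = {"sizer": [], "adder": [], "timer": []}
    for r in records:
        s, a, t = reference_indicators(r)
        out["sizer"].append(s)
        out["adder"].append(a)
        out["timer"].append(t)
    return out


def evaluate_fit(c: list[np.ndarray], truth: list[np.ndarray],
                 c_hat: list[np.ndarray] | None = None,
                 indicators: dict[str, list[np.ndarray]] | None = None,
                 ) -> EvalReport:
    """Score learned per-series c against a ground-truth track (pooled after
    per-series standardization), optionally adding the filter NMSE and
    correlations against division-rule indicator tracks."""
    per = []
    for a, b in zip(truth, c):
        try:
            per.append(pearson_aligned(a, b))
        except ValueError:
            per.append(float("nan"))
    report = EvalReport(rho_signed=pearson_aligned(truth, c), per_series_rho=per)
    if c_hat is not None:
        report.nmse = nmse(c, c_hat)
    if indicators:
        report.indicator_rho = {
            name: pearson_aligned(tracks, c) for name, tracks in indicators.items()
        }
    return report
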