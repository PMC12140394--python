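"""The adversarial shuffle player: surrogate ensembles and ζ-resampling.

An *unconstrained* surrogate window keeps a genuine length-T data history
but replaces the final sample with one drawn from the pooled marginal of
all observations — destroying exactly the temporal link the filter exploits.
Raw surrogates can contain physically implausible jumps that would let the
combination player win by detecting data constraints rather than regulation;
the ζ-resampling step reweights and resamples the surrogates so that the
distribution of their filtering errors matches the data's, using the ratio
of shared-bin histogram densities

    ζ(e) = f_data(e) / f_surr(e)      (0 where f_surr vanishes),

after which the surrogate ensemble is a proper null: identical error
statistics, broken temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import TimeSeriesSet, WindowEnsemble
from .error_engine import ModelState, paired_filtering_errors

__all__ = [
    "SurrogateEnsemble",
    "make_unconstrained_surrogates",
    "estimate_error_density",
    "zeta_weights",
    "resample_by_errors",
    "resample_surrogates",
    "DegenerateZetaError",
]


class DegenerateZetaError(RuntimeError):
    """All ζ weights vanished: data and surrogate error supports are disjoint."""


@dataclass
class SurrogateEnsemble:
    """Prefix + detached-tail windows, optionally ζ-resampled.

    ``windows[j, :T]`` is a verbatim data-window prefix (source recorded in
    ``prefix_source``); ``windows[j, T]`` is a verbatim data sample drawn
    from the pooled marginal (``tail_source`` indexes the pooled sample
    array).  ``constrained`` is False for the raw ensemble f_z̄ and True
    after ζ-resampling (f_z̃).
    """

    windows: np.ndarray            # (C, T+1, n)
    T: int
    prefix_source: np.ndarray      # (C,) index into the data WindowEnsemble
    tail_source: np.ndarray        # (C,) index into pooled samples
    constrained: bool = False
    weights: np.ndarray | None = None

    def __len__(self) -> int:
        return self.windows.shape[0]


def make_unconstrained_surrogates(we: WindowEnsemble, ts: TimeSeriesSet,
                                  count: int, rng: np.random.Generator,
                                  channel_shuffle: bool = False) -> SurrogateEnsemble:
    """Draw ``count`` surrogates: a uniform data-window prefix of length T
    followed by an independent draw from the pooled sample marginal.

    With ``channel_shuffle`` the tail's channels are drawn independently
    from their per-channel pooled marginals, additionally destroying the
    cross-channel covariation of the final sample.  This is the null used
    by the static (fixed-set-point) reduction, where the temporal detachment
    alone leaves the error distribution untouched.
    """
    count = int(count)
    if count < 1:
        raise ValueError("surrogate count must be >= 1")
    if len(we) == 0:
        raise ValueError("empty window ensemble")
    pooled = ts.pooled_samples()
    prefix_idx = rng.integers(0, len(we), size=count)
    windows = we.windows[prefix_idx].copy()
    if channel_shuffle:
        tail_idx = rng.integers(0, pooled.shape[0], size=(count, pooled.shape[1]))
        windows[:, we.T, :] = pooled[tail_idx, np.arange(pooled.shape[1])[None, :]]
        tail_source = tail_idx[:, 0]
    else:
        tail_idx = rng.integers(0, pooled.shape[0], size=count)
        windows[:, we.T, :] = pooled[tail_idx]
        tail_source = tail_idx
    return SurrogateEnsemble(
        windows=windows, T=we.T,
        prefix_source=prefix_idx, tail_source=tail_source,
    )


def estimate_error_density(errors, bins: np.ndarray) -> np.ndarray:
    """Per-bin probability masses of a scalar error sample on shared edges.

    Values outside the edges are clipped into the end bins so that masses
    always sum to 1.
    """
    errors = np.asarray(errors, dtype=np.float64).ravel()
    if errors.size == 0:
        raise ValueError("empty error sample")
    bins = np.asarray(bins, dtype=np.float64)
    if bins.size < 3:
        raise ValueError("need at least 2 bins (3 edges)")
    clipped = np.clip(errors, bins[0], bins[-1])
    counts, _ = np.histogram(clipped, bins=bins)
    return counts / errors.size


def shared_bins(data_errors, surr_errors, n_bins: int = 50) -> np.ndarray:
    """Equal-width edges spanning the union range of both error samples."""
    lo = min(np.min(data_errors), np.min(surr_errors))
    hi = max(np.max(data_errors), np.max(surr_errors))
    if hi <= lo:  # all errors identical
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def zeta_weights(data_errors, surr_errors, bins: np.ndarray) -> np.ndarray:
    """ζ evaluated at each surrogate error via shared-bin histogram densities.

    Surrogates in bins with zero data mass get weight 0 (they would reward a
    constraint-detector solution); bins with zero surrogate mass contribute
    nothing by construction.
    """
    p = estimate_error_density(data_errors, bins)
    q = estimate_error_density(surr_errors, bins)
    zeta = np.zeros_like(p)
    nz = q > 0
    zeta[nz] = p[nz] / q[nz]
    which = np.clip(np.digitize(np.clip(surr_errors, bins[0], bins[-1]),
                                bins[1:-1]), 0, len(p) - 1)
    return zeta[which]


def resample_by_errors(se: SurrogateEnsemble, data_errors, surr_errors,
                       bins: np.ndarray, rng: np.random.Generator,
                       out_size: int) -> SurrogateEnsemble:
    """ζ-weight the ensemble and importance-resample it with replacement."""
    w = zeta_weights(data_errors, surr_errors, bins)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise DegenerateZetaError(
            "all ζ weights are zero: data and surrogate filtering-error "
            "supports do not overlap; widen the histogram bins or "
            "re-initialize the model"
        )
    w = w / total
    pick = rng.choice(len(se), size=int(out_size), replace=True, p=w)
    return SurrogateEnsemble(
        windows=se.windows[pick], T=se.T,
        prefix_source=se.prefix_source[pick],
        tail_source=se.tail_source[pick],
        constrained=True, weights=w,
    )


def resample_surrogates(se: SurrogateEnsemble, omega: ModelState,
                        data_windows: np.ndarray, rng: np.random.Generator,
                        n_bins: int = 100,
                        out_size: int | None = None) -> SurrogateEnsemble:
    """Constrain a raw surrogate ensemble under the current model Ω.

    Filtering errors of data windows and surrogates are computed under Ω,
    shared histogram bins are laid over their union range, each surrogate is
    ζ-weighted, and the ensemble is multinomially resampled (with
    replacement) down to the data-window count so numerator and denominator
    of the variance ratio rest on comparable sample sizes.
    """
    if se.constrained:
        raise ValueError("ensemble is already constrained")
    data_errors, surr_errors = paired_filtering_errors(data_windows, se.windows,
                                                       omega)
    bins = shared_bins(data_errors, surr_errors, n_bins)
    if out_size is None:
        out_size = data_windows.shape[0]
    return resample_by_errors(se, data_errors, surr_errors, bins, rng, out_size)
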