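"""Containers, windowing and file I/O for regularly sampled multivariate series.

A :class:`TimeSeriesSet` holds one or more series observed at a common
sampling interval ``dt``; :func:`build_windows` extracts every full
length-(T+1) history window, the empirical ensemble the fitting loop
consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesSet",
    "WindowEnsemble",
    "build_windows",
    "read_timeseries",
    "write_timeseries",
]


class TimeSeriesError(ValueError):
    """Malformed time-series input."""


@dataclass
class TimeSeriesSet:
    """A set of regularly sampled multivariate time series.

    Parameters
    ----------
    series
        List of ``(series_id, samples)`` pairs; ``samples`` is an
        ``(N_m, n)`` float array. All series share the channel count ``n``
        and the sampling interval ``dt``.
    dt
        Sampling interval in the data's time units.
    channel_names
        ``n`` channel labels.
    """

    series: list[tuple[str, np.ndarray]]
    dt: float
    channel_names: list[str]

    def __post_init__(self):
        if not self.series:
            raise TimeSeriesError("no series found")
        if self.dt <= 0:
            raise TimeSeriesError(f"dt must be positive, got {self.dt}")
        n = len(self.channel_names)
        clean = []
        for sid, arr in self.series:
            arr = np.asarray(arr, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[1] != n:
                raise TimeSeriesError(
                    f"series {sid!r}: expected shape (N, {n}), got {arr.shape}"
                )
            if arr.shape[0] < 1:
                raise TimeSeriesError(f"series {sid!r} is empty")
            clean.append((str(sid), arr))
        self.series = clean

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_series(self) -> int:
        return len(self.series)

    def lengths(self) -> list[int]:
        return [arr.shape[0] for _, arr in self.series]

    def pooled_samples(self) -> np.ndarray:
        """All samples of all series stacked, shape (sum N_m, n)."""
        return np.concatenate([arr for _, arr in self.series], axis=0)


@dataclass
class WindowEnsemble:
    """Every full length-(T+1) window of a :class:`TimeSeriesSet`.

    ``windows[j]`` is ``[z^{k-T}, ..., z^k]`` taken entirely inside series
    ``series_index[j]``, ending at sample index ``end_index[j]`` (0-based).
    """

    windows: np.ndarray          # (W, T+1, n)
    series_index: np.ndarray     # (W,) int
    end_index: np.ndarray        # (W,) int
    T: int
    series_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.windows.shape[0]


def build_windows(ts: TimeSeriesSet, T: int) -> WindowEnsemble:
    """Enumerate all full history windows, series by series, in time order.

    The first ``T`` samples of each series yield no window (a full history
    is required); a series of length ``N_m`` contributes ``max(0, N_m - T)``
    windows.
    """
    T = int(T)
    if T < 1:
        raise ValueError(f"history length T must be >= 1, got {T}")
    wins, sidx, kidx = [], [], []
    for m, (_, arr) in enumerate(ts.series):
        N = arr.shape[0]
        for k in range(T, N):
            wins.append(arr[k - T : k + 1])
            sidx.append(m)
            kidx.append(k)
    if not wins:
        raise TimeSeriesError(
            f"no usable windows: T={T} but the longest series has only "
            f"{max(ts.lengths())} samples (need at least T+1)"
        )
    return WindowEnsemble(
        windows=np.stack(wins),
        series_index=np.asarray(sidx, dtype=np.intp),
        end_index=np.asarray(kidx, dtype=np.intp),
        T=T,
        series_ids=[sid for sid, _ in ts.series],
    )


# ---------------------------------------------------------------------------
# File I/O.  Two formats:
#   "csv"  — long/columnar text: series_id, time_index, <channel...>
#   "npz"  — compressed array container: one (N_m, n) array per series plus
#            a JSON metadata record (dt, channel names, series order)
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "npz"):
            raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'npz')")
        return fmt
    return "npz" if str(path).endswith(".npz") else "csv"


def write_timeseries(ts: TimeSeriesSet, path: str, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frames = []
        for sid, arr in ts.series:
            df = pd.DataFrame(arr, columns=ts.channel_names)
            df.insert(0, "time_index", np.arange(arr.shape[0]))
            df.insert(0, "series_id", sid)
            frames.append(df)
        out = pd.concat(frames, axis=0)
        # %.17g round-trips float64 exactly
        out.to_csv(path, index=False, float_format="%.17g")
        with open(path, "a", encoding="utf-8") as fh:
            fh.write(f"# dt={ts.dt!r}\n")
    else:
        meta = {
            "dt": ts.dt,
            "channel_names": list(ts.channel_names),
            "series_order": [sid for sid, _ in ts.series],
        }
        arrays = {f"series_{i}": arr for i, (_, arr) in enumerate(ts.series)}
        np.savez_compressed(path, __meta__=np.bytes_(json.dumps(meta)), **arrays)


def read_timeseries(path: str, format: str | None = None,
                    dt: float | None = None) -> TimeSeriesSet:
    """Read a :class:`TimeSeriesSet` written by :func:`write_timeseries`.

    For CSV input the sampling interval is taken from the trailing
    ``# dt=`` comment; an explicit ``dt`` argument overrides it.
    """
    fmt = _infer_format(path, format)
    if fmt == "npz":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            series = [
                (sid, npz[f"series_{i}"])
                for i, sid in enumerate(meta["series_order"])
            ]
        return TimeSeriesSet(series, dt or meta["dt"], meta["channel_names"])

    file_dt = None
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("# dt="):
            file_dt = float(ln.split("=", 1)[1])
        elif ln.strip():
            body.append(ln)
    if len(body) <= 1:
        raise TimeSeriesError(f"{path}: no series found")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), float_precision="round_trip")
    required = {"series_id", "time_index"}
    if not required.issubset(df.columns):
        raise TimeSeriesError(f"{path}: missing columns {required - set(df.columns)}")
    channels = [c for c in df.columns if c not in required]
    if not channels:
        raise TimeSeriesError(f"{path}: no channel columns")
    if df[channels].isna().any().any():
        row = int(df[df[channels].isna().any(axis=1)].index[0]) + 2  # 1-based + header
        raise TimeSeriesError(f"{path}: missing channel value at row {row}")
    series = []
    for sid, grp in df.groupby("series_id", sort=False):
        tix = grp["time_index"].to_numpy()
        if np.any(np.diff(tix) <= 0):
            bad = int(grp.index[np.argmax(np.diff(tix) <= 0) + 1]) + 2
            raise TimeSeriesError(
                f"{path}: time_index not strictly increasing for series "
                f"{sid!r} at row {bad}"
            )
        series.append((str(sid), grp[channels].to_numpy(dtype=np.float64)))
    if dt is None and file_dt is None:
        dt = 1.0
    return TimeSeriesSet(series, dt if dt is not None else file_dt, channels)
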