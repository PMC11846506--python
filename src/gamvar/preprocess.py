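"""Data containers and preprocessing for community count time series.

Raw inputs are long-format monthly capture counts (one row per species and
trapping session; skipped sessions appear as blanks, not dropped rows) and a
monthly covariate table (minimum temperature, NDVI).  Preprocessing aligns
everything on a regular monthly grid, filters rarely observed species,
builds the 12-month trailing moving average of NDVI, z-scores covariates on
a training window, and assembles the distributed-lag matrices for the
temperature smooth (lags 0..6 by default, so the covariate table must carry
at least a 6-month lead-in before the count window; in practice a full year
of lead-in is used so the moving average is defined everywhere too).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTimeSeries",
    "LagDesign",
    "aggregate_monthly",
    "moving_average",
    "zscore",
    "filter_species",
    "build_lag_design",
    "prepare_covariates",
    "read_counts",
    "write_counts",
    "read_covariates",
    "write_covariates",
]


@dataclass
class CommunityTimeSeries:
    """Species-by-time integer counts on a regular monthly grid.

    ``mask[i, t]`` is True where species ``i`` was observed at month ``t``;
    missing trapping sessions are masked, never dropped, so ``time_index``
    always increases in unit steps.
    """

    counts: np.ndarray
    mask: np.ndarray
    species_ids: list[str]
    time_index: np.ndarray = None
    dates: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, dtype=bool)
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=bool))
        if self.counts.shape != self.mask.shape:
            raise ValueError("counts and mask must have the same shape")
        self.species_ids = list(self.species_ids)
        if len(self.species_ids) != self.counts.shape[0]:
            raise ValueError("species_ids length must match count rows")
        if self.time_index is None:
            self.time_index = np.arange(self.counts.shape[1])
        self.time_index = np.asarray(self.time_index, dtype=int)
        if np.any(np.diff(self.time_index) != 1):
            raise ValueError("time_index must increase in unit steps")
        obs = self.counts[self.mask]
        if obs.size and np.any(obs < 0):
            raise ValueError("observed counts must be non-negative")

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_times(self) -> int:
        return self.counts.shape[1]

    def subset_times(self, stop: int) -> "CommunityTimeSeries":
        """First ``stop`` timepoints (used by expanding-window CV)."""
        return CommunityTimeSeries(
            counts=self.counts[:, :stop].copy(),
            mask=self.mask[:, :stop].copy(),
            species_ids=self.species_ids,
            time_index=self.time_index[:stop].copy(),
            dates=None if self.dates is None else self.dates[:stop],
        )


@dataclass
class LagDesign:
    """Per-timepoint lagged covariate values and matching lag indices.

    ``value_matrix[t, l]`` is the covariate at time ``t - l`` and
    ``lag_matrix`` repeats ``(0, 1, ..., L)`` on every row.
    """

    value_matrix: np.ndarray
    lag_matrix: np.ndarray = None

    def __post_init__(self) -> None:
        self.value_matrix = np.atleast_2d(np.asarray(self.value_matrix, dtype=float))
        if self.lag_matrix is None:
            T, L1 = self.value_matrix.shape
            self.lag_matrix = np.tile(np.arange(L1, dtype=float), (T, 1))
        self.lag_matrix = np.atleast_2d(np.asarray(self.lag_matrix, dtype=float))
        if self.lag_matrix.shape != self.value_matrix.shape:
            raise ValueError("value_matrix and lag_matrix must share a shape")

    @property
    def max_lag(self) -> int:
        return self.value_matrix.shape[1] - 1


def aggregate_monthly(daily: pd.Series) -> pd.Series:
    """Collapse a dated daily series to calendar-month means.

    Months inside the span with no data come out as NaN (absence of
    sampling is not a zero).
    """
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise ValueError("daily series must carry calendar dates")
    return daily.resample("MS").mean()


def moving_average(x, window: int = 12) -> np.ndarray:
    """Trailing moving average inclusive of the current month.

    ``out[t] = mean(x[t - window + 1 .. t])``; the first ``window - 1``
    entries are NaN (undefined).
    """
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError(
            f"window ({window}) exceeds series length ({x.size})"
        )
    out = np.full(x.size, np.nan)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out[window - 1:] = (csum[window:] - csum[:-window]) / window
    return out


def zscore(x, reference: slice | np.ndarray | None = None) -> np.ndarray:
    """Standardize using mean and sample (n-1) sd of the reference window.

    Passing the training window as ``reference`` keeps test-period values on
    training moments (no leakage).
    """
    x = np.asarray(x, dtype=float)
    ref = x if reference is None else x[reference]
    ref = ref[np.isfinite(ref)]
    if ref.size < 2:
        raise ValueError("reference window needs at least two finite values")
    sd = ref.std(ddof=1)
    if sd <= 0:
        raise ValueError("reference window has zero variance")
    return (x - ref.mean()) / sd


def filter_species(
    raw: CommunityTimeSeries, min_presence: float = 0.10
) -> CommunityTimeSeries:
    """Drop species seen (count > 0) in fewer than ``min_presence`` of
    observed sessions; the boundary case (exactly at threshold) is kept.
    """
    keep = []
    for i in range(raw.n_species):
        obs = raw.mask[i]
        n_obs = int(obs.sum())
        if n_obs == 0:
            continue
        presence = float((raw.counts[i][obs] > 0).sum()) / n_obs
        if presence >= min_presence:
            keep.append(i)
    if not keep:
        raise ValueError("species filter removed every species")
    return CommunityTimeSeries(
        counts=raw.counts[keep],
        mask=raw.mask[keep],
        species_ids=[raw.species_ids[i] for i in keep],
        time_index=raw.time_index,
        dates=raw.dates,
    )


def build_lag_design(x, max_lag: int = 6, start: int | None = None) -> LagDesign:
    """Lag matrix for the distributed-lag smooth.

    ``x`` is the full covariate series including lead-in; the count window
    starts at index ``start`` (default ``max_lag``).  Row ``t`` of the value
    matrix is ``(x[s+t], x[s+t-1], ..., x[s+t-max_lag])``.
    """
    x = np.asarray(x, dtype=float)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    s = max_lag if start is None else int(start)
    if s < max_lag:
        raise ValueError(
            f"insufficient lead-in: need {max_lag} months before the count "
            f"window, got {s}"
        )
    T = x.size - s
    if T <= 0:
        raise ValueError("count window is empty")
    value = np.empty((T, max_lag + 1))
    for l in range(max_lag + 1):
        value[:, l] = x[s - l : s - l + T]
    return LagDesign(value_matrix=value)


def prepare_covariates(
    cov: pd.DataFrame,
    count_start: int,
    train_stop: int | None = None,
    ma_window: int = 12,
) -> pd.DataFrame:
    """Derive model covariates from a raw (time_index, mintemp, ndvi) table.

    ``count_start`` is the row index where the count window begins (rows
    before it are lead-in); ``train_stop`` bounds the reference window used
    for z-scoring (count rows ``count_start .. count_start + train_stop``),
    defaulting to the full count window.  Adds ``ndvi_ma12`` (z-scored
    trailing moving average) and ``mintemp_z``.
    """
    cov = cov.copy().reset_index(drop=True)
    if count_start < ma_window:
        raise ValueError(
            f"need >= {ma_window} months of covariate lead-in before the "
            f"count window, got {count_start}"
        )
    ma = moving_average(cov["ndvi"].to_numpy(), window=ma_window)
    n = len(cov)
    stop = n if train_stop is None else count_start + train_stop
    ref = np.zeros(n, dtype=bool)
    ref[count_start:stop] = True
    cov["ndvi_ma12"] = zscore(ma, reference=ref & np.isfinite(ma))
    cov["mintemp_z"] = zscore(cov["mintemp"].to_numpy(), reference=ref)
    return cov


# ---------------------------------------------------------------------------
# delimited text round-trip


def write_counts(cts: CommunityTimeSeries, path) -> None:
    rows = []
    for t in range(cts.n_times):
        date = "" if cts.dates is None else cts.dates[t].strftime("%Y-%m-%d")
        for i, sp in enumerate(cts.species_ids):
            val = str(int(cts.counts[i, t])) if cts.mask[i, t] else ""
            rows.append((int(cts.time_index[t]), date, sp, val))
    df = pd.DataFrame(rows, columns=["time_index", "date", "species", "count"])
    df.to_csv(path, index=False)


def read_counts(path) -> CommunityTimeSeries:
    df = pd.read_csv(path, dtype={"species": str}, keep_default_na=True)
    species = list(dict.fromkeys(df["species"]))
    times = np.sort(df["time_index"].unique())
    t0 = times[0]
    T = times[-1] - t0 + 1
    counts = np.zeros((len(species), T), dtype=int)
    mask = np.zeros((len(species), T), dtype=bool)
    sp_idx = {s: i for i, s in enumerate(species)}
    for _, row in df.iterrows():
        i, t = sp_idx[row["species"]], int(row["time_index"]) - t0
        if pd.notna(row["count"]):
            counts[i, t] = int(row["count"])
            mask[i, t] = True
    dates = None
    if "date" in df.columns and df["date"].notna().any():
        date_map = df.dropna(subset=["date"]).drop_duplicates("time_index")
        if len(date_map) == T:
            dates = pd.DatetimeIndex(
                pd.to_datetime(date_map.sort_values("time_index")["date"])
            )
    return CommunityTimeSeries(
        counts=counts,
        mask=mask,
        species_ids=species,
        time_index=np.arange(t0, t0 + T),
        dates=dates,
    )


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path)
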