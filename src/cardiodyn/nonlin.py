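"""Nonlinear dimensional analysis of motion waveforms.

Two fractal descriptors of a scalar time series are computed:

* **Capacity dimension** from the variogram (variation estimator): the
  variance of increments gamma(tau) scales like tau^P in log-log
  coordinates, and ``D = 2 - P/2``. For fractional Brownian motion with
  Hurst exponent H this recovers the graph dimension ``2 - H``.
* **Correlation dimension** via Takens delay embedding and
  Grassberger-Procaccia pair counting: the correlation integral C_m(r),
  accumulated on 32 bins between the smallest nonzero and largest pairwise
  distance, scales like r^D2 in its scaling region. The plateau of the
  per-embedding-dimension slopes D(m) is the steady correlation dimension.

Supporting machinery: autocorrelation-based delay selection (first lag where
the ACF drops to 1/e of its zero-lag value) and false-nearest-neighbor
selection of the embedding dimension.

Degenerate inputs (constant signals, coincident points) are reported through
flags / sentinel values wherever a batch pipeline needs to keep running;
hard precondition violations raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "VariogramResult",
    "AcfLag",
    "Embedding",
    "FnnResult",
    "CorrelationIntegral",
    "CorrelationResult",
    "variogram",
    "capacity_dimension",
    "acf_lag",
    "fnn_embedding_dim",
    "embed",
    "correlation_integral",
    "correlation_dimension",
    "steady_value",
]


# --------------------------------------------------------------------------
# variogram / capacity dimension
# --------------------------------------------------------------------------


@dataclass
class VariogramResult:
    """Empirical variogram and (once fitted) capacity-dimension estimates.

    ``P`` is the global log-log regression slope over ``fit_range``;
    ``D_capacity_mean = 2 - P/2``. ``D_tau`` is the local-slope curve
    (5-point sliding window on a log-spaced lag subgrid), with
    ``D_tau_mean`` its average over the fitted range.
    """

    tau: np.ndarray
    gamma: np.ndarray
    degenerate: bool = False
    P: float | None = None
    D_capacity_mean: float | None = None
    D_tau: np.ndarray | None = None
    D_tau_lags: np.ndarray | None = None
    D_tau_mean: float | None = None
    fit_range: tuple[int, int] | None = None
    clipped: bool = False

    def to_dict(self) -> dict:
        return {
            "tau_max": int(self.tau[-1]) if self.tau.size else 0,
            "degenerate": self.degenerate,
            "P": self.P,
            "D_capacity_mean": self.D_capacity_mean,
            "D_tau_mean": self.D_tau_mean,
            "fit_range": list(self.fit_range) if self.fit_range else None,
            "clipped": self.clipped,
        }


def variogram(S: Sequence[float], tau_max: int | None = None) -> VariogramResult:
    """Empirical semivariogram gamma(tau) for integer lags 1..tau_max.

    gamma(tau) = sum_i (S_{i+tau} - S_i)^2 / (2 (N - tau)).

    A constant signal gives gamma identically zero and sets the
    ``degenerate`` flag (the log-log slope is then undefined downstream).
    """
    S = np.asarray(S, dtype=float)
    N = S.size
    if N < 8:
        raise InvalidInputError(f"need N >= 8 samples, got {N}")
    if tau_max is None:
        tau_max = N // 4
    tau_max = int(tau_max)
    if not (1 <= tau_max <= N // 2):
        raise InvalidInputError(f"tau_max must be in [1, N/2], got {tau_max}")
    taus = np.arange(1, tau_max + 1)
    gamma = np.array([0.5 * np.mean((S[tt:] - S[:-tt]) ** 2) for tt in taus])
    return VariogramResult(tau=taus, gamma=gamma, degenerate=not np.any(gamma > 0))


def _local_slopes(logx: np.ndarray, logy: np.ndarray, window: int) -> np.ndarray:
    out = np.empty(len(logx) - window + 1)
    for i in range(out.size):
        out[i] = np.polyfit(logx[i : i + window], logy[i : i + window], 1)[0]
    return out


def capacity_dimension(
    v: VariogramResult,
    fit_range: tuple[int, int] | None = None,
    plateau_frac: float = 0.95,
    local_window: int = 5,
    n_curve_lags: int = 48,
) -> VariogramResult:
    """Fit the variogram in log-log coordinates and derive capacity dimension.

    The default fit range runs from lag 1 to the first lag where gamma
    reaches ``plateau_frac`` of its maximum (the variogram levels off once
    the total variability of the signal is reached). The headline value
    ``D_capacity_mean`` comes from the global slope P as ``2 - P/2``; the
    D(tau) curve uses local slopes over ``local_window`` points of a
    log-spaced lag subgrid. Estimates outside [1, 2] are clipped and
    flagged.

    Completes and returns the same :class:`VariogramResult` (degenerate
    variograms get NaN sentinels instead of raising).
    """
    if v.degenerate:
        v.P = float("nan")
        v.D_capacity_mean = float("nan")
        v.D_tau_mean = float("nan")
        return v
    taus, gamma = v.tau, v.gamma
    if fit_range is None:
        cutoff_idx = int(np.argmax(gamma >= plateau_frac * gamma.max()))
        hi = int(taus[cutoff_idx])
        fit_range = (1, max(hi, int(taus[min(local_window, len(taus) - 1)])))
    lo, hi = fit_range
    sel = (taus >= lo) & (taus <= hi) & (gamma > 0)
    if sel.sum() < 2:
        sel = gamma > 0  # fall back to everything usable
        lo, hi = int(taus[sel][0]), int(taus[sel][-1])
    lt, lg = np.log(taus[sel]), np.log(gamma[sel])
    P = float(np.polyfit(lt, lg, 1)[0])
    D = 2.0 - P / 2.0
    clipped = False
    if D < 1.0 or D > 2.0:
        D = float(np.clip(D, 1.0, 2.0))
        clipped = True
    # log-spaced subgrid for the D(tau) curve: equal weight per decade
    sub = np.unique(
        np.round(np.exp(np.linspace(np.log(lo), np.log(max(hi, lo + 1)), n_curve_lags)))
    ).astype(int)
    sub = sub[np.isin(sub, taus[sel])]
    if sub.size >= local_window:
        gsub = gamma[sub - 1]
        slopes = _local_slopes(np.log(sub), np.log(gsub), local_window)
        d_tau = 2.0 - slopes / 2.0
        if np.any(d_tau < 1.0) or np.any(d_tau > 2.0):
            clipped = True
            d_tau = np.clip(d_tau, 1.0, 2.0)
        centers = sub[local_window // 2 : local_window // 2 + d_tau.size]
        v.D_tau = d_tau
        v.D_tau_lags = centers
        v.D_tau_mean = float(np.mean(d_tau))
    else:
        v.D_tau_mean = D
    v.P = P
    v.D_capacity_mean = D
    v.fit_range = (int(lo), int(hi))
    v.clipped = clipped
    return v


# --------------------------------------------------------------------------
# delay selection / embedding
# --------------------------------------------------------------------------


@dataclass
class AcfLag:
    """Autocorrelation-based delay: first lag with C(tau) <= C(0)/e."""

    C: np.ndarray
    C0: float
    k: float
    tau_star: int
    warning: bool = False


def acf_lag(S: Sequence[float], max_lag: int | None = None) -> AcfLag:
    """Select the embedding delay from the autocorrelation function.

    Uses the biased sample autocovariance of the mean-removed signal and
    returns the smallest integer lag where it falls to 1/e of the zero-lag
    value; the fitted decay rate is k = 1/tau_star. If the ACF never
    reaches C(0)/e within N/2 lags, tau_star = N/2 with a warning. A
    constant signal yields a flagged sentinel (tau_star = 1, k = NaN).
    """
    S = np.asarray(S, dtype=float)
    N = S.size
    if N < 16:
        raise InvalidInputError(f"need N >= 16 samples, got {N}")
    x = S - S.mean()
    C0 = float(np.mean(x * x))
    limit = int(max_lag) if max_lag is not None else N // 2
    if C0 == 0.0:
        return AcfLag(np.zeros(limit + 1), 0.0, float("nan"), 1, warning=True)
    nfft = 1 << int(np.ceil(np.log2(2 * N)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: limit + 1] / N  # biased estimator
    target = C0 / np.e
    below = np.nonzero(acov[1:] <= target)[0]
    if below.size == 0:
        return AcfLag(acov, C0, 1.0 / limit, limit, warning=True)
    tau_star = int(below[0]) + 1
    return AcfLag(acov, C0, 1.0 / tau_star, tau_star)


@dataclass
class Embedding:
    """Delay-coordinate trajectory matrix.

    Row j (0-based) is (S_j, S_{j+tau}, ..., S_{j+(m-1)tau}); there are
    exactly N - (m-1) tau rows.
    """

    m: int
    tau: int
    X: np.ndarray


def embed(S: Sequence[float], m: int, tau: int) -> Embedding:
    """Takens delay embedding of a scalar series."""
    S = np.asarray(S, dtype=float)
    if m < 1 or tau < 1:
        raise InvalidInputError("m and tau must be >= 1")
    n_rows = S.size - (m - 1) * tau
    if n_rows < 1:
        raise InvalidInputError(
            f"series too short: embedding with m={m}, tau={tau} needs "
            f"N >= {(m - 1) * tau + 1}, got {S.size}"
        )
    X = np.column_stack([S[i * tau : i * tau + n_rows] for i in range(m)])
    return Embedding(m=m, tau=tau, X=X)


@dataclass
class FnnResult:
    m: int
    fractions: list[float]
    warning: bool = False


def fnn_embedding_dim(
    S: Sequence[float],
    tau: int,
    m_max: int = 12,
    rtol: float = 15.0,
    fnn_frac_threshold: float = 0.01,
    atol: float = 2.0,
) -> FnnResult:
    """False-nearest-neighbor selection of the embedding dimension.

    Kennel-style test: for each m, every point's nearest neighbor in the
    m-dimensional embedding is lifted to dimension m+1; the pair is a false
    neighbor if the extra coordinate inflates their distance by more than
    ``rtol`` relative to the m-dimensional distance, or pushes it beyond
    ``atol`` signal standard deviations. Returns the smallest m whose false
    fraction is below ``fnn_frac_threshold``; if none qualifies (e.g. white
    noise, which has no finite embedding), returns ``m_max`` with
    ``warning=True``.
    """
    S = np.asarray(S, dtype=float)
    if tau < 1:
        raise InvalidInputError("tau must be >= 1")
    if m_max < 2:
        raise InvalidInputError("m_max must be >= 2")
    sigma = float(S.std())
    if sigma == 0.0:
        return FnnResult(m_max, [], warning=True)
    fractions: list[float] = []
    for m in range(1, m_max + 1):
        n = S.size - m * tau  # rows for which the (m+1)-th coordinate exists
        if n < 10:
            break
        X = embed(S, m, tau).X[:n]
        tree = cKDTree(X)
        d, idx = tree.query(X, k=2, workers=-1)
        dm, nn = d[:, 1], idx[:, 1]
        lift = np.abs(S[np.arange(n) + m * tau] - S[nn + m * tau])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dm > 0, lift / np.where(dm > 0, dm, 1.0), np.where(lift > 0, np.inf, 0.0))
        dm1 = np.hypot(dm, lift)
        false = (ratio > rtol) | (dm1 / sigma > atol)
        frac = float(false.mean())
        fractions.append(frac)
        if frac < fnn_frac_threshold:
            return FnnResult(m, fractions)
    return FnnResult(m_max, fractions, warning=True)


# --------------------------------------------------------------------------
# correlation integral / correlation dimension
# --------------------------------------------------------------------------


@dataclass
class CorrelationIntegral:
    """C_m(r) accumulated on ``n_bins`` edges between r_min and r_max.

    ``edges[n]`` is the n-th separation distance r_n (n = 1..n_bins mapped
    to indices 0..n_bins-1, with edges[-1] = r_max); ``C[n]`` is the
    fraction of ordered pairs (i > j) with distance <= r_n, normalized by
    2/(N'(N'-1)); ``counts[n]`` is the incremental pair count deposited in
    bin n.
    """

    edges: np.ndarray
    C: np.ndarray
    counts: np.ndarray
    r_min: float
    r_max: float
    n_points: int
    log_bins: bool = True


def _pair_chunks(X: np.ndarray, theiler: int, chunk: int):
    """Yield flattened pairwise distances for index pairs with j - i > theiler."""
    n = X.shape[0]
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        block = cdist(X[s:e], X[s:])
        rows = np.arange(e - s)[:, None]
        cols = np.arange(n - s)[None, :]
        mask = (cols - rows) > theiler
        yield block[mask]


def correlation_integral(
    X: Embedding | np.ndarray,
    n_bins: int = 32,
    log_bins: bool = True,
    theiler: int = 0,
    chunk: int = 1024,
) -> CorrelationIntegral:
    """Grassberger-Procaccia correlation sum on a fixed bin grid.

    All pairwise Euclidean distances over i > j are computed (optionally
    excluding temporally close pairs via ``theiler``); bin edges are placed
    uniformly between log(r_min) and log(r_max) (or linearly with
    ``log_bins=False``), where r_min is the smallest *nonzero* distance and
    r_max the largest. C at the last edge is exactly 1.

    Raises :class:`DegenerateInputError` when all points coincide.
    Memory stays bounded: distances are produced in row chunks and reduced
    to a histogram, never materialized all at once.
    """
    if isinstance(X, Embedding):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 points")
    theiler = int(theiler)
    # pass 1: distance range
    r_min, r_max = np.inf, 0.0
    n_pairs = 0
    for vals in _pair_chunks(X, theiler, chunk):
        n_pairs += vals.size
        if vals.size == 0:
            continue
        vmax = vals.max()
        if vmax > r_max:
            r_max = float(vmax)
        nz = vals[vals > 0]
        if nz.size:
            vmin = nz.min()
            if vmin < r_min:
                r_min = float(vmin)
    if n_pairs == 0:
        raise InvalidInputError("theiler window excludes all pairs")
    if r_max == 0.0:
        raise DegenerateInputError("all embedded points are identical (r_max = 0)")
    if not np.isfinite(r_min) or r_min == r_max:
        # a single distinct distance: C jumps straight to 1 at every edge
        edges = np.full(n_bins, r_max)
        C = np.ones(n_bins)
        counts = np.zeros(n_bins, dtype=np.int64)
        counts[0] = n_pairs
        return CorrelationIntegral(edges, C, counts, float(r_max), float(r_max), n, log_bins)
    if log_bins:
        edges = np.exp(np.linspace(np.log(r_min), np.log(r_max), n_bins + 1))[1:]
    else:
        edges = r_min + np.arange(1, n_bins + 1) * (r_max - r_min) / n_bins
    edges[-1] = r_max  # guard against round-off
    # pass 2: histogram of pair distances against the edges (d <= r_n)
    counts = np.zeros(n_bins, dtype=np.int64)
    for vals in _pair_chunks(X, theiler, chunk):
        if vals.size == 0:
            continue
        idx = np.searchsorted(edges, vals, side="left")
        np.clip(idx, 0, n_bins - 1, out=idx)
        counts += np.bincount(idx, minlength=n_bins)
    # with a Theiler window the admissible-pair count replaces N(N-1)/2
    norm = 2.0 / (n * (n - 1)) if theiler == 0 else 1.0 / n_pairs
    C = np.cumsum(counts) * norm
    return CorrelationIntegral(edges, C, counts, float(r_min), float(r_max), n, log_bins)


def _fit_window(logr: np.ndarray, logC: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logr, logC, 1)
    pred = slope * logr + intercept
    ss_res = float(np.sum((logC - pred) ** 2))
    ss_tot = float(np.sum((logC - logC.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def select_scaling_region(
    ci: CorrelationIntegral, min_len: int = 8
) -> tuple[tuple[int, int] | None, float, float]:
    """Pick the scaling region of log C(r) vs log r and fit its slope.

    Candidate windows are contiguous runs of bins that actually received
    pairs (nonzero incremental counts) — this trims both the empty small-r
    bins and the saturated large-r plateau — of length >= ``min_len``. The
    window maximizing the R^2 of the linear fit wins; ties go to the longer
    window, then toward smaller r. Returns ((start, stop), slope, r2) with
    stop exclusive, or (None, nan, nan) when no window qualifies, in which
    case callers fall back to all usable bins.
    """
    nz = ci.counts > 0
    logr = np.log(ci.edges)
    with np.errstate(divide="ignore"):
        logC = np.log(ci.C)
    best: tuple[float, int, int] | None = None  # (r2, length, -start)
    best_window = None
    best_slope = float("nan")
    i = 0
    n = len(nz)
    while i < n:
        if not nz[i]:
            i += 1
            continue
        j = i
        while j < n and nz[j]:
            j += 1
        run_len = j - i
        if run_len >= min_len:
            for length in range(min_len, run_len + 1):
                for start in range(i, j - length + 1):
                    sl, r2 = _fit_window(
                        logr[start : start + length], logC[start : start + length]
                    )
                    key = (r2, length, -start)
                    if best is None or key > best:
                        best = key
                        best_window = (start, start + length)
                        best_slope = sl
        i = j
    if best_window is None:
        return None, float("nan"), float("nan")
    return best_window, best_slope, best[0]


@dataclass
class CorrelationResult:
    """Per-m correlation integrals, scaling-region slopes, and plateau value."""

    tau: int
    m_values: list[int]
    integrals: dict[int, CorrelationIntegral] = field(default_factory=dict)
    slopes: dict[int, float] = field(default_factory=dict)
    scaling_regions: dict[int, tuple[int, int]] = field(default_factory=dict)
    r2: dict[int, float] = field(default_factory=dict)
    D_steady: float = float("nan")
    plateau: bool = False
    warnings: list[str] = field(default_factory=list)

    def D_of_m(self) -> np.ndarray:
        return np.array([self.slopes[m] for m in self.m_values if m in self.slopes])

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "m_values": [m for m in self.m_values if m in self.slopes],
            "D_m": {str(m): self.slopes[m] for m in self.m_values if m in self.slopes},
            "r2": {str(m): self.r2[m] for m in self.m_values if m in self.r2},
            "D_steady": self.D_steady,
            "plateau": self.plateau,
            "warnings": list(self.warnings),
        }


def steady_value(D_of_m: Sequence[float], tol: float = 0.1) -> tuple[float, bool]:
    """Plateau of the D(m) curve.

    The steady value is the mean of D(m) over the largest contiguous run of
    m where successive values differ by less than ``tol`` (ties go to the
    run at larger m, where saturation lives). Without any run of >= 2
    values the flag is False and the last D is returned.
    """
    D = np.asarray(D_of_m, dtype=float)
    if D.size == 0:
        return float("nan"), False
    if D.size == 1:
        return float(D[0]), False
    ok = np.abs(np.diff(D)) < tol
    best_len, best_span = 0, None
    i = 0
    while i < ok.size:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < ok.size and ok[j]:
            j += 1
        if j - i >= best_len:  # >= keeps the later (higher-m) run on ties
            best_len, best_span = j - i, (i, j)
        i = j
    if best_span is None:
        return float(D[-1]), False
    a, b = best_span
    return float(np.mean(D[a : b + 2])), True


def correlation_dimension(
    S: Sequence[float],
    tau: int | None = None,
    m_values: Iterable[int] = range(2, 13),
    n_bins: int = 32,
    log_bins: bool = True,
    theiler: int = 0,
    plateau_tol: float = 0.1,
) -> CorrelationResult:
    """Correlation dimension D(m) across embedding dimensions, with plateau.

    For each m the series is delay-embedded, the correlation integral
    accumulated, and the slope of log C_m(r) vs log r fitted over the
    automatically selected scaling region. ``tau=None`` selects the delay
    from the ACF 1/e criterion. Embedding dimensions that leave too few
    points (or degenerate geometry) are omitted with a warning rather than
    failing the whole analysis.
    """
    S = np.asarray(S, dtype=float)
    if tau is None:
        tau = acf_lag(S).tau_star
    tau = int(tau)
    m_list = sorted(set(int(m) for m in m_values))
    res = CorrelationResult(tau=tau, m_values=m_list)
    for m in m_list:
        n_rows = S.size - (m - 1) * tau
        if n_rows < n_bins + 1:
            res.warnings.append(f"m={m}: only {n_rows} embedded points, skipped")
            continue
        try:
            ci = correlation_integral(
                embed(S, m, tau), n_bins=n_bins, log_bins=log_bins, theiler=theiler
            )
        except (DegenerateInputError, InvalidInputError) as exc:
            res.warnings.append(f"m={m}: {exc}")
            continue
        window, slope, r2 = select_scaling_region(ci)
        if window is None:
            usable = ci.C > 0
            if usable.sum() >= 2:
                slope, r2 = _fit_window(
                    np.log(ci.edges[usable]), np.log(ci.C[usable])
                )
                window = (int(np.argmax(usable)), int(len(usable)))
                res.warnings.append(f"m={m}: no >=8-bin scaling window, global fit used")
            else:
                res.warnings.append(f"m={m}: correlation integral unusable, skipped")
                continue
        if slope < 0:
            res.warnings.append(f"m={m}: negative slope clipped to 0")
            slope = 0.0
        res.integrals[m] = ci
        res.slopes[m] = float(slope)
        res.scaling_regions[m] = window
        res.r2[m] = float(r2)
    D = res.D_of_m()
    if D.size:
        res.D_steady, res.plateau = steady_value(D, tol=plateau_tol)
    return res
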