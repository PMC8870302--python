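"""Pairwise Granger causality between EEG channels.

For an ordered channel pair (y -> x) the Granger causality index (GCI) is

    GCI_{y->x} = ln( var(e_hat_1) / var(e_1) )

where ``e_hat_1`` is the residual of the order-p univariate autoregression of
x on its own past, and ``e_1`` the residual of the bivariate regression of x
on the past of both x and y. A positive index means y's past improves the
prediction of x. Sampling noise can make the ratio dip below 1; the index is
clamped at 0 because it quantifies a *reduction* in prediction error.

All fits are ordinary least squares over lags 1..p with no intercept
(band-passed EEG is zero-mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .preprocessing import SegmentSet
from .recording import BandDefinition

__all__ = [
    "ARFit",
    "GCMatrix",
    "fit_ar_univariate",
    "fit_var_bivariate",
    "gci_pair",
    "select_order",
    "gc_matrix",
]

# Narrowband (band-passed) EEG yields legitimately rank-deficient lag designs
# (smallest/largest singular value near machine precision); least squares is
# therefore solved with a pseudo-inverse. Only a channel paired with a
# (scaled) copy of itself is rejected as degenerate, detected directly via
# the correlation of the two series.
_DUPLICATE_TOL = 1e-12


@dataclass(frozen=True)
class ARFit:
    """A least-squares autoregressive fit for one equation."""

    order: int
    coefficients: np.ndarray  # univariate: (p,); bivariate equation: (2p,)
    residual_variance: float  # mean squared residual
    n_used: int


@dataclass
class GCMatrix:
    """N x N matrix of directed GCIs; entry (i, j) is channel i -> channel j.

    The diagonal is fixed at 0. Consumers must read the i->j orientation from
    this type rather than transposing silently.
    """

    values: np.ndarray
    channel_labels: tuple[str, ...]
    order_used: int
    band: BandDefinition | None = None
    n_segments_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.channel_labels):
            raise ValueError("values must be square and match channel_labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GCI values must be finite")
        if np.any(self.values < 0) or np.any(np.diag(self.values) != 0):
            raise ValueError("GCI values must be >= 0 with zero diagonal")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def offdiagonal(self) -> np.ndarray:
        mask = ~np.eye(self.n_channels, dtype=bool)
        return self.values[mask]


def _lagged_design(series: list[np.ndarray], p: int) -> np.ndarray:
    """Design matrix with columns [s1 lag1..lagp, s2 lag1..lagp, ...]."""
    n = series[0].size
    cols = [s[p - l : n - l] for s in series for l in range(1, p + 1)]
    return np.column_stack(cols)


def _check_series(x: np.ndarray, p: int, min_factor: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if p < 1:
        raise ValueError("order p must be >= 1")
    if x.size <= min_factor * p:
        raise ValueError(
            f"series of length {x.size} too short for order {p} "
            f"(need > {min_factor * p} samples)"
        )
    if np.var(x) == 0:
        raise ValueError("series has zero variance (constant input)")
    return x


def fit_ar_univariate(x: np.ndarray, p: int) -> ARFit:
    """OLS fit of x(t) on its own lags 1..p."""
    x = _check_series(x, p, 10)
    X = _lagged_design([x], p)
    y = x[p:]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return ARFit(p, coef, float(np.mean(resid**2)), y.size)


def fit_var_bivariate(x: np.ndarray, y: np.ndarray, p: int) -> tuple[ARFit, ARFit]:
    """Joint OLS fit of the bivariate model; returns (x-equation, y-equation).

    Each equation regresses its target on lags 1..p of both series; the
    coefficient vector is ordered [x-lag coefficients, y-lag coefficients].
    """
    x = _check_series(x, p, 20)
    y = _check_series(y, p, 20)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    r = float(np.corrcoef(x, y)[0, 1])
    if 1.0 - abs(r) < _DUPLICATE_TOL:
        raise ValueError(
            "degenerate design matrix: the two series are (nearly) linearly "
            "dependent"
        )
    X = _lagged_design([x, y], p)
    targets = np.column_stack([x[p:], y[p:]])
    coef, *_ = np.linalg.lstsq(X, targets, rcond=None)
    resid = targets - X @ coef
    n_used = targets.shape[0]
    fit_x = ARFit(p, coef[:, 0], float(np.mean(resid[:, 0] ** 2)), n_used)
    fit_y = ARFit(p, coef[:, 1], float(np.mean(resid[:, 1] ** 2)), n_used)
    return fit_x, fit_y


def gci_pair(x: np.ndarray, y: np.ndarray, p: int) -> tuple[float, float]:
    """Both directed GCIs for a channel pair: (x->y, y->x), clamped at 0."""
    fit_x, fit_y = fit_var_bivariate(x, y, p)
    uni_x = fit_ar_univariate(np.asarray(x, dtype=float).ravel(), p)
    uni_y = fit_ar_univariate(np.asarray(y, dtype=float).ravel(), p)
    gci_y_to_x = max(0.0, float(np.log(uni_x.residual_variance / fit_x.residual_variance)))
    gci_x_to_y = max(0.0, float(np.log(uni_y.residual_variance / fit_y.residual_variance)))
    return gci_x_to_y, gci_y_to_x


def select_order(
    x: np.ndarray,
    y: np.ndarray,
    p_max: int,
    criterion: str = "bic",
) -> int:
    """Model order minimising an information criterion for the bivariate model.

    All candidate orders are scored on the common sample span (rows p_max..n)
    so the criteria are comparable. BIC (default) or AIC.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if criterion not in ("bic", "aic"):
        raise ValueError(f"unknown criterion '{criterion}'")
    x = _check_series(x, p_max, 20)
    y = _check_series(y, p_max, 20)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    X_full = _lagged_design([x, y], p_max)
    targets = np.column_stack([x[p_max:], y[p_max:]])
    rows = targets.shape[0]
    best_p, best_score = 1, np.inf
    for p in range(1, p_max + 1):
        cols = np.r_[0:p, p_max : p_max + p]
        X = X_full[:, cols]
        coef, *_ = np.linalg.lstsq(X, targets, rcond=None)
        resid = targets - X @ coef
        sigma = (resid.T @ resid) / rows
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        k = 4 * p  # 2p coefficients per equation
        penalty = (np.log(rows) if criterion == "bic" else 2.0) * k / rows
        score = logdet + penalty
        if score < best_score:
            best_p, best_score = p, score
    return best_p


def _gc_matrix_one_segment(data: np.ndarray, p: int) -> np.ndarray:
    """All ordered-pair GCIs for one segment.

    The full lagged design over all channels is built once; each fit then
    slices its columns. Univariate residual variances are shared across the
    channel's pairings.
    """
    n_ch, n = data.shape
    series = [data[i] for i in range(n_ch)]
    Z = _lagged_design(series, p)  # rows x (n_ch * p)
    Y = np.ascontiguousarray(data[:, p:].T)  # rows x n_ch

    def _rss(idx: np.ndarray, target: int) -> float:
        y = Y[:, target]
        coef, *_ = sla.lstsq(Z[:, idx], y, lapack_driver="gelsy")
        resid = y - Z[:, idx] @ coef
        return float(resid @ resid)

    lag_cols = [np.arange(i * p, (i + 1) * p) for i in range(n_ch)]
    rss_uni = np.array([_rss(lag_cols[i], i) for i in range(n_ch)])
    if np.any(rss_uni <= 0):
        bad = int(np.argmin(rss_uni))
        raise ValueError(f"channel {bad} has a degenerate autoregressive fit")

    gci = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            idx = np.concatenate([lag_cols[i], lag_cols[j]])
            rss_biv_i = max(_rss(idx, i), np.finfo(float).tiny)
            rss_biv_j = max(_rss(idx, j), np.finfo(float).tiny)
            gci[j, i] = max(0.0, float(np.log(rss_uni[i] / rss_biv_i)))
            gci[i, j] = max(0.0, float(np.log(rss_uni[j] / rss_biv_j)))
    return gci


def gc_matrix(
    segs: SegmentSet,
    p: int | str = "auto",
    p_max: int = 20,
    criterion: str = "bic",
) -> GCMatrix:
    """Averaged GCI matrix over a segment set.

    Per segment, every ordered channel pair's GCI is computed; the matrices
    are then averaged entry-wise (the functional network is built from the
    *average* causality matrix). With ``p="auto"`` a single order is chosen
    by information criterion on the first segment, as the median over up to
    five deterministic channel pairs.
    """
    if segs.n_segments < 1:
        raise ValueError("at least one segment required")
    labels = segs.channel_labels
    n_ch = len(labels)
    if n_ch < 2:
        raise ValueError("need >= 2 channels for pairwise Granger causality")

    if p == "auto":
        first = segs.segments[0].data
        pairs = [(i, (i + 1) % n_ch) for i in range(min(n_ch, 5))]
        orders = [select_order(first[a], first[b], p_max, criterion) for a, b in pairs]
        p_used = int(np.median(orders))
    else:
        p_used = int(p)
        if p_used < 1:
            raise ValueError("order must be >= 1")

    acc = np.zeros((n_ch, n_ch))
    for seg in segs.segments:
        try:
            acc += _gc_matrix_one_segment(seg.data, p_used)
        except ValueError as err:
            raise ValueError(
                f"GC estimation failed in state '{segs.source_state}': {err} "
                f"(labels: {labels})"
            ) from err
    return GCMatrix(
        values=acc / segs.n_segments,
        channel_labels=labels,
        order_used=p_used,
        band=segs.band,
        n_segments_averaged=segs.n_segments,
    )
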