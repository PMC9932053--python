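"""Detrended fluctuation / cross-correlation / partial-correlation numerics.

Conventions
-----------
For data series ``x^j`` (j = 1..m, length N) the *profiles* are the
cumulative sums ``X_i^j = sum_{k<=i} x_k^j``.  At scale ``s`` the
profiles are covered by all N - s overlapping windows of s + 1 points
stepped by one frame; in every window a least-squares polynomial of the
detrending order is subtracted.  Concatenating the residuals of all
windows gives, per series, a residual stream of length (N - s)(s + 1),
and

    F2[j1, j2](s) = sum_l Y_l^j1 Y_l^j2 / ((N - s)(s + 1))

is the detrended covariance matrix.  Its diagonal reproduces squared DFA
fluctuation functions; normalizing by the diagonal yields the DCCA
cross-correlation coefficients R(s), and the negated, rescaled inverse
of R(s) yields the partial (DPCCA) coefficients P(s).

The delayed extension substitutes a relatively shifted copy of one
series into the covariance: for a shift of k frames (|k| <= s/2) the
residual window starting at frame i of one series is paired with the
window starting at frame i + k of the other, and the product sum is
renormalized by the overlap count so values are comparable across
shifts.  The maximizing shift is the coupling delay and the maximum
(after normalization by the zero-shift variances) the coupling strength.
At k = 0 the synchronous detrended covariance is reproduced exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, DegenerateSeriesError, ParameterError

__all__ = [
    "profile",
    "sliding_residuals",
    "fluctuation_matrix",
    "default_scale_grid",
    "compute_fluctuation_matrices",
    "dcca_coefficients",
    "dpcca_coefficients",
    "scale_correlations",
    "delayed_coupling",
    "delay_aligned_matrices",
    "total_squared_displacement",
    "FluctuationMatrix",
    "ScaleCorrelations",
    "DelayedCoupling",
]

#: ridge factor used when R(s) is numerically singular
_RIDGE = 1e-8
_COND_LIMIT = 1e12


# ---------------------------------------------------------------------------
# profiles, residuals, covariance at a single scale

def profile(series) -> np.ndarray:
    """Cumulative-sum profile(s) of one or more data series (last axis)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ParameterError("cannot profile an empty series")
    return np.cumsum(series, axis=-1)


def _poly_projector(s: int, order: int) -> np.ndarray:
    """Orthonormal basis Q (s+1, order+1) of degree-`order` polynomials."""
    t = np.linspace(-1.0, 1.0, s + 1)
    v = t[:, None] ** np.arange(order + 1)
    q, _ = np.linalg.qr(v)
    return q


def _check_scale(s: int, n: int, order: int) -> None:
    if s < order + 1:
        raise ParameterError(
            f"scale s={s} too small for detrending order {order} "
            f"(need s >= order + 1)"
        )
    if s + 1 > n:
        raise ParameterError(f"scale s={s} exceeds series length {n}")


def sliding_residuals(profiles, s: int, order: int = 2) -> np.ndarray:
    """Residuals of polynomial fits in all sliding windows.

    Parameters
    ----------
    profiles : ndarray, shape (m, N) or (N,)
        Profile series (cumulative sums).
    s : int
        Scale; windows contain ``s + 1`` points and start at every frame.
    order : int
        Degree of the detrending polynomial.

    Returns
    -------
    ndarray, shape (m, N - s, s + 1)
        Window-wise residuals; flattening the last two axes gives the
        residual stream of length (N - s)(s + 1).
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    n = profiles.shape[-1]
    _check_scale(s, n, order)
    q = _poly_projector(s, order)
    windows = np.lib.stride_tricks.sliding_window_view(profiles, s + 1, axis=-1)
    coef = windows @ q
    return windows - coef @ q.T


def fluctuation_matrix(residuals: np.ndarray) -> np.ndarray:
    """Detrended covariance matrix F2(s) from aligned residual sets.

    ``residuals`` has shape (m, N - s, s + 1) as produced by
    :func:`sliding_residuals` (all series must share N and s).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 3:
        raise AnalysisError("residuals must have shape (m, n_windows, s + 1)")
    m = residuals.shape[0]
    flat = residuals.reshape(m, -1)
    return (flat @ flat.T) / flat.shape[1]


# ---------------------------------------------------------------------------
# scale grids and the assembled matrices

def default_scale_grid(
    n: int,
    order: int = 2,
    n_scales: int = 20,
    s_min: int | None = None,
    s_max: int | None = None,
) -> np.ndarray:
    """Log-spaced integer scale grid from max(8, order+3) to N // 4."""
    if s_min is None:
        s_min = max(8, order + 3)
    if s_max is None:
        s_max = n // 4
    if s_max < s_min:
        raise ParameterError(
            f"series too short (N={n}) for scale grid [{s_min}, {s_max}]"
        )
    grid = np.unique(
        np.rint(np.geomspace(s_min, s_max, n_scales)).astype(int)
    )
    return grid


@dataclass
class FluctuationMatrix:
    """Scale-indexed m x m detrended covariance matrices.

    ``f2[k]`` is the symmetric matrix F2(s_k); the square root of its
    diagonal gives the DFA fluctuation functions.
    """

    scales: np.ndarray  # (n_scales,) in frames
    f2: np.ndarray  # (n_scales, m, m)
    labels: list[str]
    fps: float = 30.0
    order: int = 2

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.f2 = np.asarray(self.f2, dtype=float)
        if self.f2.shape != (len(self.scales), len(self.labels), len(self.labels)):
            raise AnalysisError("FluctuationMatrix shape mismatch")

    @property
    def seconds(self) -> np.ndarray:
        return self.scales / self.fps

    @property
    def m(self) -> int:
        return len(self.labels)

    def fluctuations(self) -> np.ndarray:
        """F(s) per series: sqrt of the diagonal, shape (n_scales, m)."""
        return np.sqrt(np.diagonal(self.f2, axis1=1, axis2=2))

    def pair(self, label_i: str, label_j: str) -> np.ndarray:
        i, j = self.labels.index(label_i), self.labels.index(label_j)
        return self.f2[:, i, j]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.scales):
            for i, li in enumerate(self.labels):
                for j, lj in enumerate(self.labels[: i + 1]):
                    rows.append((li, lj, int(s), s / self.fps, self.f2[k, i, j]))
        return pd.DataFrame(
            rows,
            columns=["series_i", "series_j", "scale_frames", "scale_seconds", "F2"],
        )


def compute_fluctuation_matrices(
    series,
    scales=None,
    order: int = 2,
    fps: float = 30.0,
    labels: list[str] | None = None,
) -> FluctuationMatrix:
    """Assemble F2(s) over a scale grid for a multivariate data series.

    Series are mean-centred before profiling; for detrending order >= 1
    this leaves F2 unchanged but keeps the window fits well conditioned.

    Instead of materializing the residuals of every sliding window, the
    residual Gram matrix is computed as Gram(windows) minus Gram of the
    projection coefficients onto an orthonormal polynomial basis: the
    first term collapses to a coverage-count-weighted product of the
    profiles, the second to one FFT correlation per series and basis
    function.  Two safeguards keep this numerically equal to the explicit
    residual route (:func:`sliding_residuals` + :func:`fluctuation_matrix`):
    a global degree-``order`` polynomial is removed from every profile
    (invisible to the window fits, but it shrinks the cancelling terms),
    and scales where the Gram difference still cancels catastrophically
    — small scales of strongly persistent series — are recomputed with
    explicit residuals, which is cheap exactly there.
    """
    from scipy.signal import fftconvolve

    series = np.atleast_2d(np.asarray(series, dtype=float))
    m, n = series.shape
    if labels is None:
        labels = [f"s{j}" for j in range(m)]
    if scales is None:
        scales = default_scale_grid(n, order=order)
    scales = np.asarray(scales, dtype=int)
    profs = profile(series - series.mean(axis=1, keepdims=True))
    profs = _remove_global_trend(profs, order)

    t = np.arange(n)
    f2 = np.empty((len(scales), m, m))
    for k, s_ in enumerate(scales):
        s = int(s_)
        _check_scale(s, n, order)
        q = _poly_projector(s, order)
        n_win = n - s
        # how many windows [i, i + s] cover frame t
        cnt = np.minimum(np.minimum(t, n_win - 1), np.minimum(s, n - 1 - t)) + 1
        gram_w = (profs * cnt) @ profs.T
        # projection coefficients of every window onto the basis columns
        coef = np.stack(
            [
                fftconvolve(profs, q[::-1, b][None, :], mode="valid", axes=1)
                for b in range(order + 1)
            ],
            axis=1,
        )  # (m, order + 1, n_win)
        flat = coef.reshape(m, -1)
        gram_c = flat @ flat.T
        gram_r = gram_w - gram_c
        dw, dr = np.diag(gram_w), np.diag(gram_r)
        if np.any(dr <= 0) or np.max(dw / np.maximum(dr, 1e-300)) > 1e6:
            gram_r = _gram_explicit(profs, s, q)
        gram_r = 0.5 * (gram_r + gram_r.T)  # exact symmetry
        f2[k] = gram_r / (n_win * (s + 1))
    return FluctuationMatrix(scales=scales, f2=f2, labels=list(labels), fps=fps, order=order)


def _remove_global_trend(profs: np.ndarray, order: int) -> np.ndarray:
    """Subtract a global degree-``order`` polynomial fit from each profile.

    Window-wise polynomial residuals are exactly invariant under this, so
    F2 is unchanged; the point is purely to reduce float cancellation.
    """
    n = profs.shape[-1]
    t = np.linspace(-1.0, 1.0, n)
    v = t[:, None] ** np.arange(order + 1)
    q, _ = np.linalg.qr(v)
    return profs - (profs @ q) @ q.T


def _gram_explicit(
    profs: np.ndarray, s: int, q: np.ndarray, chunk_elems: int = 2_000_000
) -> np.ndarray:
    """Residual Gram matrix via explicitly materialized window residuals."""
    m, n = profs.shape
    view = np.lib.stride_tricks.sliding_window_view(profs, s + 1, axis=-1)
    n_win = view.shape[1]
    acc = np.zeros((m, m))
    step = max(1, chunk_elems // (s + 1))
    for a in range(0, n_win, step):
        w = np.ascontiguousarray(view[:, a : a + step, :])
        np.subtract(w, (w @ q) @ q.T, out=w)
        flat = w.reshape(m, -1)
        acc += flat @ flat.T
    return acc


# ---------------------------------------------------------------------------
# correlation coefficients

def dcca_coefficients(f2: np.ndarray, labels: list[str] | None = None) -> np.ndarray:
    """DCCA cross-correlation coefficients R(s) from F2(s).

    Accepts a single (m, m) matrix or a (n_scales, m, m) stack.  Raises
    :class:`DegenerateSeriesError` if a diagonal entry is not positive
    (constant input series).
    """
    f2 = np.asarray(f2, dtype=float)
    diag = np.diagonal(f2, axis1=-2, axis2=-1)
    if np.any(diag <= 0):
        bad = np.argwhere(diag <= 0)
        idx = int(bad[0][-1])
        name = labels[idx] if labels else f"series {idx}"
        raise DegenerateSeriesError(
            f"{name} has zero detrended variance; cross-correlation "
            f"coefficients are undefined"
        )
    norm = np.sqrt(diag[..., :, None] * diag[..., None, :])
    return f2 / norm


def dpcca_coefficients(r: np.ndarray) -> np.ndarray:
    """Partial cross-correlation coefficients P(s) from R(s).

    Inverts R (per scale), then P[i, j] = -C[i, j] / sqrt(C[i,i] C[j,j]).
    Numerically singular matrices receive a small ridge
    (lambda = 1e-8 * trace / m); matrices still singular after the ridge
    produce a NaN matrix for that scale with a warning.
    The diagonal is set to 1 by convention.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim == 2:
        return _dpcca_single(r)
    return np.stack([_dpcca_single(rk) for rk in r])


def _dpcca_single(r: np.ndarray) -> np.ndarray:
    m = r.shape[0]
    mat = r
    if np.linalg.cond(mat) > _COND_LIMIT:
        mat = r + np.eye(m) * (_RIDGE * np.trace(r) / m)
    try:
        c = np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        c = None
    if c is None or np.any(np.diag(c) <= 0):
        warnings.warn(
            "cross-correlation matrix singular even after ridge "
            "regularization; scale flagged unusable (NaN)",
            stacklevel=3,
        )
        return np.full_like(r, np.nan)
    d = np.sqrt(np.diag(c))
    p = -c / np.outer(d, d)
    np.fill_diagonal(p, 1.0)
    return p


@dataclass
class ScaleCorrelations:
    """R(s) and P(s) stacks on a common scale grid."""

    scales: np.ndarray
    r: np.ndarray  # (n_scales, m, m)
    p: np.ndarray  # (n_scales, m, m)
    labels: list[str]
    fps: float = 30.0

    @property
    def seconds(self) -> np.ndarray:
        return np.asarray(self.scales) / self.fps

    def pair(self, which: str, label_i: str, label_j: str) -> np.ndarray:
        i, j = self.labels.index(label_i), self.labels.index(label_j)
        mat = self.r if which.upper() == "R" else self.p
        return mat[:, i, j]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(np.asarray(self.scales)):
            for i, li in enumerate(self.labels):
                for j, lj in enumerate(self.labels[:i]):
                    rows.append(
                        (li, lj, int(s), s / self.fps, self.r[k, i, j], self.p[k, i, j])
                    )
        return pd.DataFrame(
            rows,
            columns=["series_i", "series_j", "scale_frames", "scale_seconds", "R", "P"],
        )


def scale_correlations(fm: FluctuationMatrix) -> ScaleCorrelations:
    """Convenience: R(s) and P(s) from an assembled FluctuationMatrix."""
    r = dcca_coefficients(fm.f2, labels=fm.labels)
    p = dpcca_coefficients(r)
    return ScaleCorrelations(
        scales=fm.scales, r=r, p=p, labels=fm.labels, fps=fm.fps
    )


# ---------------------------------------------------------------------------
# delayed coupling

@dataclass
class DelayedCoupling:
    """Shift-maximized coupling between two residual streams at one scale."""

    strength: float
    delay: int  # frames; > 0 means the first series leads
    scale: int
    shifts: np.ndarray = field(repr=False)
    covariances: np.ndarray = field(repr=False)  # normalized, per shift


def _window_cross_covariance(r1, r2, max_shift):
    """Overlap-renormalized delayed cross-covariance of residual windows.

    ``r1``/``r2`` are (n_windows, s + 1) residual arrays.  For a delay of
    k frames the window of the first series starting at frame i is paired
    with the window of the second starting at frame i + k:

        cov(k) = sum_i r1[i] . r2[i + k] / ((n_windows - |k|)(s + 1)),

    which at k = 0 equals the synchronous detrended covariance.  Returns
    ``(shifts, cov)`` for k in [-max_shift, max_shift].
    """
    n_win, w = r1.shape
    if max_shift >= n_win:
        raise ParameterError(
            f"max_shift {max_shift} leaves no window overlap ({n_win} windows)"
        )
    shifts = np.arange(-max_shift, max_shift + 1)
    if (2 * max_shift + 1) * n_win * w <= 2e8:
        cov = np.empty(shifts.shape)
        for i, k in enumerate(shifts):
            if k >= 0:
                cov[i] = np.einsum("ij,ij->", r1[: n_win - k], r2[k:])
            else:
                cov[i] = np.einsum("ij,ij->", r1[-k:], r2[: n_win + k])
    else:
        # FFT path: per-position cross-correlation along the window axis,
        # summed over positions (chunked to bound memory)
        from scipy.fft import irfft, next_fast_len, rfft

        nfft = next_fast_len(2 * n_win - 1)
        spec = None
        chunk = max(1, int(4e6) // nfft)
        for a in range(0, w, chunk):
            f1 = rfft(r1[:, a : a + chunk], n=nfft, axis=0)
            f2 = rfft(r2[:, a : a + chunk], n=nfft, axis=0)
            part = (np.conj(f1) * f2).sum(axis=1)
            spec = part if spec is None else spec + part
        c_full = irfft(spec, n=nfft)
        cov = c_full[shifts % nfft]
    return shifts, cov / ((n_win - np.abs(shifts)) * w)


def _argmax_preferring_small_shift(shifts, values):
    """Index of the maximum; ties go to smallest |k|, then negative k."""
    order = np.lexsort((shifts, np.abs(shifts)))
    best = order[0]
    for idx in order[1:]:
        if values[idx] > values[best]:
            best = idx
    return best


def delayed_coupling(
    resid1: np.ndarray,
    resid2: np.ndarray,
    max_shift: int | None = None,
) -> DelayedCoupling:
    """Shift-maximized normalized cross-covariance of two residual sets.

    ``resid1``/``resid2`` are (N - s, s + 1) residual arrays for the same
    scale s (see :func:`sliding_residuals`).  A shift of k frames pairs
    residual windows starting k frames apart (see
    :func:`_window_cross_covariance`); at k = 0 the synchronous detrended
    covariance is reproduced exactly.  The strength is normalized by the
    zero-shift detrended variances, so identical residual sets give
    strength 1 at delay 0.

    A positive returned delay means the *first* series leads (its
    residuals, shifted forward by the delay, match the second series).
    """
    resid1 = np.asarray(resid1, dtype=float)
    resid2 = np.asarray(resid2, dtype=float)
    if resid1.shape != resid2.shape or resid1.ndim != 2:
        raise AnalysisError("residual sets must share shape (n_windows, s + 1)")
    s = resid1.shape[1] - 1
    if s < 2:
        raise ParameterError(f"scale s={s} too small for delay analysis")
    if max_shift is None:
        max_shift = s // 2
    if max_shift > s // 2:
        raise ParameterError(f"max_shift {max_shift} exceeds s/2 = {s // 2}")
    shifts, cov = _window_cross_covariance(resid1, resid2, max_shift)
    y1 = resid1.ravel()
    y2 = resid2.ravel()
    norm = np.sqrt((y1 @ y1) * (y2 @ y2)) / y1.shape[0]
    if norm == 0:
        raise DegenerateSeriesError("zero detrended variance in delay analysis")
    cov_n = cov / norm
    best = _argmax_preferring_small_shift(shifts, cov_n)
    return DelayedCoupling(
        strength=float(cov_n[best]),
        delay=int(shifts[best]),
        scale=s,
        shifts=shifts,
        covariances=cov_n,
    )


def delay_aligned_matrices(
    series,
    s: int,
    order: int = 2,
    max_shift: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Delay-aligned correlation matrices at a single scale.

    For every pair the cross-covariance is maximized over relative shifts
    |k| <= s/2 *before* normalization, so the aligned matrix R~ feeds the
    partial-correlation step with the dominant coupling of each pair.

    Returns ``(r_aligned, p_aligned, delays)`` where ``delays[i, j] > 0``
    means series i leads series j (antisymmetric).
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    m, _ = series.shape
    profs = profile(series - series.mean(axis=1, keepdims=True))
    resid = sliding_residuals(profs, s, order=order)
    flat = resid.reshape(m, -1)
    var = np.einsum("ij,ij->i", flat, flat) / flat.shape[1]
    if np.any(var <= 0):
        raise DegenerateSeriesError("constant series in delay-aligned analysis")
    if max_shift is None:
        max_shift = s // 2
    r_aligned = np.eye(m)
    delays = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            shifts, cov = _window_cross_covariance(resid[i], resid[j], max_shift)
            cov_n = cov / np.sqrt(var[i] * var[j])
            best = _argmax_preferring_small_shift(shifts, cov_n)
            r_aligned[i, j] = r_aligned[j, i] = cov_n[best]
            delays[i, j] = shifts[best]
            delays[j, i] = -shifts[best]
    p_aligned = dpcca_coefficients(r_aligned)
    return r_aligned, p_aligned, delays


# ---------------------------------------------------------------------------
# axis combination

def total_squared_displacement(
    fm_x: FluctuationMatrix, fm_y: FluctuationMatrix
) -> FluctuationMatrix:
    """Total F2: elementwise sum of the X- and Y-projection matrices."""
    if not np.array_equal(fm_x.scales, fm_y.scales):
        raise AnalysisError("X and Y fluctuation matrices use different scale grids")
    if fm_x.labels != fm_y.labels and len(fm_x.labels) != len(fm_y.labels):
        raise AnalysisError("X and Y fluctuation matrices differ in series count")
    labels = [lb.split(":")[0] for lb in fm_x.labels]
    return FluctuationMatrix(
        scales=fm_x.scales,
        f2=fm_x.f2 + fm_y.f2,
        labels=labels,
        fps=fm_x.fps,
        order=fm_x.order,
    )
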