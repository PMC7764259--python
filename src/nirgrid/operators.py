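"""The seven spectral pre-processing operator families.

Each operator exists in two forms: a plain function on arrays (the ``*_``
functions below, mirroring how a chemometrician would call them on a matrix
of spectra) and a scikit-learn-style transformer class with
``fit``/``transform``/``get_params`` so the operators compose with sklearn
pipelines. The functions are thin wrappers over the same numerics.

Operator summary
----------------
- Savitzky-Golay smoothing (order 2, frame 3 by default; that setting is the
  identity map, since a parabola through three points interpolates them).
- Multiplicative scatter correction (MSC): per-spectrum OLS fit
  ``x ~ a + b * ref`` followed by ``(x - a) / b``; the default reference is
  the column-wise mean spectrum of the block being corrected.
- Detrending: subtraction of a least-squares polynomial (order 2 default) in
  the wavenumber coordinate.
- Gap-segment derivative: finite differences of segment means whose centers
  are ``gap`` points apart, divided by ``gap * step`` (first order) or
  ``(gap * step)**2`` (second order); edge points without a full window are
  dropped and the axis is shortened accordingly.
- Binning: non-overlapping window means; the trailing partial window is
  discarded; the binned axis value is the mean wavenumber of the window.
- Replicate averaging: mean, median, or "median spectrum" (the measured scan
  minimizing the sum of Euclidean distances to the sample's other scans).
- Centering: column-wise mean or median subtraction.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .block import SpectraBlock
from .exceptions import DegenerateFitError, ParameterError

_B_TOL = 1e-12


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing
# ---------------------------------------------------------------------------
def savgol_smooth(y: np.ndarray, order: int = 2, frame: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing along the last axis.

    Edges are handled by evaluating the polynomial fitted to the nearest full
    window (scipy's ``mode="interp"``). With the default (order 2, frame 3)
    the filter is the identity.
    """
    y = np.asarray(y, dtype=float)
    if frame % 2 == 0:
        raise ParameterError("frame size must be odd")
    if frame <= order:
        raise ParameterError("frame size must exceed the polynomial order")
    if y.shape[-1] < frame:
        raise ParameterError("spectrum shorter than the smoothing frame")
    return savgol_filter(y, window_length=frame, polyorder=order, axis=-1, mode="interp")


# ---------------------------------------------------------------------------
# Multiplicative scatter correction
# ---------------------------------------------------------------------------
def msc_correct(
    X: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction of a matrix of spectra.

    Each row ``x`` is regressed onto the reference, ``x ~ a + b * ref``
    (ordinary least squares), and replaced by ``(x - a) / b``. When
    ``reference`` is None the column-wise mean of ``X`` is used, which
    requires at least two rows.

    Returns
    -------
    corrected : ndarray, same shape as X
    reference : ndarray
        The reference actually used (recorded for provenance).

    Raises
    ------
    DegenerateFitError
        If any fitted slope satisfies ``|b| < 1e-12`` (e.g. a scan orthogonal
        to a constant reference), naming the offending row.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise ParameterError("MSC without explicit reference needs >= 2 scans")
        reference = X.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ParameterError("reference length does not match spectrum length")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < _B_TOL:
        raise DegenerateFitError("MSC reference has (near-)zero variance")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) < _B_TOL)
    if bad.size:
        raise DegenerateFitError(f"MSC slope is numerically zero for scan {bad[0]}")
    a = X.mean(axis=1) - b * ref.mean()
    corrected = (X - a[:, None]) / b[:, None]
    return corrected, ref


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------
def detrend(
    y: np.ndarray, axis_values: np.ndarray | None = None, order: int = 2
) -> np.ndarray:
    """Subtract the least-squares polynomial of ``order`` in the wavenumber
    coordinate from each spectrum (rows of ``y``).

    The residual has zero projection onto the polynomial basis up to the
    given order. Wavenumbers are rescaled to [-1, 1] internally for
    conditioning; the fitted subspace is unchanged by that rescaling.
    """
    orig = np.asarray(y, dtype=float)
    y2 = np.atleast_2d(orig)
    n = y2.shape[-1]
    if n <= order:
        raise ParameterError("spectrum length must exceed the polynomial order")
    if axis_values is None:
        axis_values = np.arange(n, dtype=float)
    w = np.asarray(axis_values, dtype=float)
    lo, hi = w.min(), w.max()
    t = (2.0 * w - (hi + lo)) / (hi - lo) if hi > lo else np.zeros_like(w)
    V = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, y2.T, rcond=None)
    out = y2 - (V @ coef).T
    return out if orig.ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# Gap-segment derivative
# ---------------------------------------------------------------------------
def _segment_means(y: np.ndarray, segment: int) -> np.ndarray:
    """Means of all length-``segment`` windows along the last axis."""
    c = np.cumsum(np.concatenate([np.zeros(y.shape[:-1] + (1,)), y], axis=-1), axis=-1)
    return (c[..., segment:] - c[..., :-segment]) / segment


def gap_segment_required_length(deriv_order: str, gap: int, segment: int) -> int:
    """Minimum number of points for one derivative value."""
    span = {"first": gap + segment, "second": 2 * gap + segment}[deriv_order]
    return max(span, gap + 2 * segment)


def gap_segment_derivative(
    y: np.ndarray,
    deriv_order: str,
    gap: int = 11,
    segment: int = 11,
    step: float = 1.0,
) -> np.ndarray:
    """Gap-segment (Norris-style) derivative along the last axis.

    The derivative at an output point is a finite difference of segment
    means; ``gap`` is the center-to-center distance (in points) between
    segments and ``segment`` the number of points averaged per segment.

    first:  ``(right_mean - left_mean) / (gap * step)``
    second: ``(left_mean - 2 * center_mean + right_mean) / (gap * step)**2``

    ``step`` is the signed axis increment per point. Points lacking a full
    window are dropped symmetrically; use :func:`gap_segment_axis` for the
    matching shortened axis.
    """
    y = np.asarray(y, dtype=float)
    if deriv_order not in ("first", "second"):
        raise ParameterError("deriv_order must be 'first' or 'second'")
    if gap < 1 or segment < 1:
        raise ParameterError("gap and segment must be >= 1")
    n = y.shape[-1]
    if n < gap_segment_required_length(deriv_order, gap, segment):
        raise ParameterError(
            f"spectrum of length {n} too short for gap={gap}, segment={segment} "
            f"{deriv_order} derivative"
        )
    means = _segment_means(y, segment)
    if deriv_order == "first":
        out = (means[..., gap:] - means[..., :-gap]) / (gap * step)
    else:
        out = (
            means[..., : -2 * gap]
            - 2.0 * means[..., gap:-gap]
            + means[..., 2 * gap :]
        ) / (gap * step) ** 2
    return out


def gap_segment_axis(
    axis_values: np.ndarray, deriv_order: str, gap: int = 11, segment: int = 11
) -> np.ndarray:
    """Axis positions of the gap-segment derivative outputs.

    First-order outputs sit at the midpoint between the two segment centers
    (a half-step offset when ``gap`` is odd); second-order outputs sit at the
    center-segment center.
    """
    w = np.asarray(axis_values, dtype=float)
    step = w[1] - w[0]
    half_seg = (segment - 1) / 2.0
    if deriv_order == "first":
        offset = half_seg + gap / 2.0
        n_out = w.size - gap - segment + 1
    else:
        offset = half_seg + gap
        n_out = w.size - 2 * gap - segment + 1
    return w[0] + step * (offset + np.arange(n_out))


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------
def bin_spectrum(y: np.ndarray, window: int) -> np.ndarray:
    """Average consecutive non-overlapping windows along the last axis.

    Output length is ``floor(n / window)``; a trailing remainder of fewer
    than ``window`` points is discarded.
    """
    y = np.asarray(y, dtype=float)
    if window < 1:
        raise ParameterError("binning window must be >= 1")
    if window == 1:
        return y.copy()
    n_out = y.shape[-1] // window
    trimmed = y[..., : n_out * window]
    return trimmed.reshape(y.shape[:-1] + (n_out, window)).mean(axis=-1)


def bin_axis(axis_values: np.ndarray, window: int) -> np.ndarray:
    """Binned axis: mean wavenumber of each full window."""
    return bin_spectrum(np.asarray(axis_values, dtype=float), window)


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------
def _median_spectrum_index(scans: np.ndarray) -> int:
    """Index of the scan minimizing the sum of Euclidean distances to the
    sample's other scans (ties -> lowest index)."""
    diffs = scans[:, None, :] - scans[None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=-1))
    return int(np.argmin(dist.sum(axis=1)))


def average_replicates(block: SpectraBlock, method: str = "mean") -> SpectraBlock:
    """Collapse the scans of each sample to a single spectrum.

    ``mean`` and ``median`` are column-wise statistics; ``median_spectrum``
    returns the actually measured scan most central among the sample's scans
    (distance-sum minimizer). Output rows follow the samples' order of first
    appearance; ``replicate_id`` becomes the averaging method name.
    """
    if method not in ("mean", "median", "median_spectrum"):
        raise ParameterError(f"unknown averaging method {method!r}")
    samples = block.unique_samples()
    out = np.empty((samples.size, block.n_wavenumbers))
    classes = np.empty(samples.size, dtype=object)
    for i, sid in enumerate(samples):
        rows = block.scans_of(sid)
        scans = block.intensities[rows]
        if method == "mean":
            out[i] = scans.mean(axis=0)
        elif method == "median":
            out[i] = np.median(scans, axis=0)
        else:
            out[i] = scans[_median_spectrum_index(scans)]
        classes[i] = block.class_label[rows[0]]
    return SpectraBlock(
        axis=block.axis,
        intensities=out,
        sample_id=samples.copy(),
        replicate_id=np.array([method] * samples.size, dtype=object),
        class_label=classes,
        provenance=list(block.provenance) + [f"average:{method}"],
    )


# ---------------------------------------------------------------------------
# Centering
# ---------------------------------------------------------------------------
def center_block(X: np.ndarray, method: str = "mean") -> np.ndarray:
    """Column-wise centering of a matrix of spectra (``none`` is identity)."""
    X = np.asarray(X, dtype=float)
    if method == "none":
        return X.copy()
    if method == "mean":
        return X - X.mean(axis=0)
    if method == "median":
        return X - np.median(X, axis=0)
    raise ParameterError(f"unknown centering method {method!r}")


# ---------------------------------------------------------------------------
# scikit-learn-style transformer classes
# ---------------------------------------------------------------------------
class _ParamsMixin:
    """Minimal get_params/set_params so the operators compose with sklearn."""

    def get_params(self, deep: bool = True):  # noqa: ARG002 - sklearn signature
        import inspect

        names = [
            p
            for p in inspect.signature(type(self).__init__).parameters
            if p != "self"
        ]
        return {n: getattr(self, n) for n in names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ParameterError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def __sklearn_tags__(self):
        from ._sklearn_compat import transformer_tags

        return transformer_tags()

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"


class SavitzkyGolaySmoother(_ParamsMixin):
    """Stateless Savitzky-Golay smoothing transformer."""

    def __init__(self, order: int = 2, frame: int = 3):
        self.order = order
        self.frame = frame

    def fit(self, X, y=None):  # noqa: ARG002
        savgol_smooth(np.atleast_2d(X)[:1], self.order, self.frame)  # validate
        return self

    def transform(self, X):
        return savgol_smooth(X, self.order, self.frame)


class ScatterCorrector(_ParamsMixin):
    """MSC transformer. ``fit`` stores the mean-spectrum reference of the
    training matrix (or a user-supplied reference), so train/test splits can
    be corrected without leakage; ``transform`` applies the per-row affine
    inversion against that stored reference."""

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):  # noqa: ARG002
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.reference is not None:
            self.reference_ = np.asarray(self.reference, dtype=float)
        else:
            if X.shape[0] < 2:
                raise ParameterError("MSC fit needs >= 2 scans")
            self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        corrected, _ = msc_correct(X, self.reference_)
        return corrected


class Detrender(_ParamsMixin):
    """Polynomial detrending transformer (order 2 by default)."""

    def __init__(self, order: int = 2, axis_values: np.ndarray | None = None):
        self.order = order
        self.axis_values = axis_values

    def fit(self, X, y=None):  # noqa: ARG002
        return self

    def transform(self, X):
        return detrend(X, self.axis_values, self.order)


class GapSegmentDerivative(_ParamsMixin):
    """Gap-segment derivative transformer; shortens the feature axis.

    ``axis_out_`` holds the shortened wavenumber axis after ``fit`` when
    ``axis_values`` was provided.
    """

    def __init__(
        self,
        deriv_order: str = "first",
        gap: int = 11,
        segment: int = 11,
        axis_values: np.ndarray | None = None,
    ):
        self.deriv_order = deriv_order
        self.gap = gap
        self.segment = segment
        self.axis_values = axis_values

    def fit(self, X, y=None):  # noqa: ARG002
        if self.axis_values is not None:
            self.axis_out_ = gap_segment_axis(
                self.axis_values, self.deriv_order, self.gap, self.segment
            )
        return self

    def transform(self, X):
        step = 1.0
        if self.axis_values is not None:
            w = np.asarray(self.axis_values, dtype=float)
            step = float(w[1] - w[0])
        return gap_segment_derivative(
            X, self.deriv_order, self.gap, self.segment, step
        )


class Binner(_ParamsMixin):
    """Non-overlapping window-mean binning transformer."""

    def __init__(self, window: int = 1, axis_values: np.ndarray | None = None):
        self.window = window
        self.axis_values = axis_values

    def fit(self, X, y=None):  # noqa: ARG002
        if self.axis_values is not None:
            self.axis_out_ = bin_axis(self.axis_values, self.window)
        return self

    def transform(self, X):
        return bin_spectrum(X, self.window)


class Centerer(_ParamsMixin):
    """Column-statistic centering transformer; the statistic is computed on
    the matrix passed to ``fit`` (training data)."""

    def __init__(self, method: str = "mean"):
        self.method = method

    def fit(self, X, y=None):  # noqa: ARG002
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.method == "mean":
            self.offset_ = X.mean(axis=0)
        elif self.method == "median":
            self.offset_ = np.median(X, axis=0)
        elif self.method == "none":
            self.offset_ = np.zeros(X.shape[1])
        else:
            raise ParameterError(f"unknown centering method {self.method!r}")
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) - self.offset_
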