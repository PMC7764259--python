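"""Pre-processing strategies: ordered combinations of the seven operators.

A :class:`PipelineSpec` names one strategy exactly as a row of the strategy
tables reads: wavenumber range(s), smoothing position, MSC on/off, detrending
on/off, derivative order, binning window, averaging method, centering method.

Application order (the flowchart order):

1. wavenumber reduction into one or more segments
2. smoothing (if at position 2)
3. MSC
4. detrending
5. derivative
6. smoothing (if at position 6)
7. binning

Steps 2-7 run independently per segment; segments are reassembled
(concatenated) only afterwards, then replicate averaging and centering act on
the assembled matrix. A strategy applies smoothing at most once (position 2
xor position 6 xor not at all).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .block import SpectraBlock, WavenumberAxis
from .exceptions import ParameterError, PipelineError, RangeError
from .operators import (
    Centerer,
    average_replicates,
    bin_axis,
    bin_spectrum,
    detrend,
    gap_segment_axis,
    gap_segment_derivative,
    msc_correct,
    savgol_smooth,
)

SMOOTHING_OPTIONS = ("none", "position2", "position6")
DERIVATIVE_OPTIONS = ("none", "first", "second")
AVERAGING_OPTIONS = ("mean", "median", "median_spectrum")
CENTERING_OPTIONS = ("none", "mean", "median")


@dataclass(frozen=True, order=True)
class Segment:
    """Closed wavenumber interval [low, high] in cm^-1, reported (high, low)."""

    high: float
    low: float

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ParameterError(f"segment high ({self.high}) must exceed low ({self.low})")

    def __str__(self) -> str:
        return f"{self.high:g}-{self.low:g}"


@dataclass(frozen=True)
class PipelineSpec:
    """One pre-processing strategy (a single row of a strategy table)."""

    segments: tuple[Segment, ...]
    smoothing: str = "none"
    msc: bool = False
    detrend: bool = False
    derivative: str = "none"
    binning_window: int = 1
    averaging: str = "mean"
    centering: str = "none"
    smoothing_order: int = 2
    smoothing_frame: int = 3
    detrend_order: int = 2
    derivative_gap: int = 11
    derivative_segment: int = 11

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ParameterError("a pipeline needs at least one segment")
        if self.smoothing not in SMOOTHING_OPTIONS:
            raise ParameterError(
                f"smoothing must be one of {SMOOTHING_OPTIONS}, got {self.smoothing!r}"
            )
        if self.derivative not in DERIVATIVE_OPTIONS:
            raise ParameterError(f"unknown derivative {self.derivative!r}")
        if self.averaging not in AVERAGING_OPTIONS:
            raise ParameterError(f"unknown averaging {self.averaging!r}")
        if self.centering not in CENTERING_OPTIONS:
            raise ParameterError(f"unknown centering {self.centering!r}")
        if self.binning_window < 1:
            raise ParameterError("binning window must be >= 1")
        ordered = sorted(self.segments, key=lambda s: -s.high)
        for left, right in zip(ordered, ordered[1:]):
            if right.high >= left.low:
                raise ParameterError(
                    f"segments {left} and {right} overlap"
                )

    # -- table row / serialization ------------------------------------------
    def n_active_steps(self) -> int:
        """Number of optional steps switched on (used for ranking tie-breaks)."""
        return (
            int(self.smoothing != "none")
            + int(self.msc)
            + int(self.detrend)
            + int(self.derivative != "none")
            + int(self.binning_window > 1)
            + int(self.centering != "none")
        )

    def to_record(self) -> dict:
        """Flat record mirroring the strategy-table row layout."""
        return {
            "wavenumber_range": " + ".join(str(s) for s in self.segments),
            "smoothing": {"none": "no", "position2": "position 2", "position6": "position 6"}[
                self.smoothing
            ],
            "msc": "yes" if self.msc else "no",
            "detrending": "yes" if self.detrend else "no",
            "derivative": self.derivative,
            "binning": self.binning_window,
            "averaging": self.averaging.replace("_", " "),
            "centering": self.centering,
        }

    def sort_key(self) -> tuple:
        """Deterministic lexicographic key over the declared field order."""
        return (
            tuple((s.high, s.low) for s in self.segments),
            SMOOTHING_OPTIONS.index(self.smoothing),
            int(self.msc),
            int(self.detrend),
            DERIVATIVE_OPTIONS.index(self.derivative),
            self.binning_window,
            AVERAGING_OPTIONS.index(self.averaging),
            CENTERING_OPTIONS.index(self.centering),
        )

    def replace(self, **changes) -> "PipelineSpec":
        return replace(self, **changes)


def full_range_spec(block: SpectraBlock, **kwargs) -> PipelineSpec:
    """Convenience: spec covering the block's entire axis."""
    w = block.axis.values
    return PipelineSpec(segments=(Segment(high=float(w.max()), low=float(w.min())),), **kwargs)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------
def reduce_wavenumbers(
    block: SpectraBlock, segments: list[Segment] | tuple[Segment, ...]
) -> list[SpectraBlock]:
    """Restrict the block to one or more closed wavenumber intervals.

    Returns one sub-block per segment (columns with low <= w <= high).
    Subsequent operators run per sub-block; reassembly happens at
    classification time.
    """
    w = block.axis.values
    out = []
    for seg in segments:
        mask = (w >= seg.low) & (w <= seg.high)
        if not mask.any():
            raise RangeError(f"segment {seg} does not intersect the axis")
        if seg.low > w.max() or seg.high < w.min():
            raise RangeError(f"segment {seg} outside axis range")
        out.append(block.with_data(w[mask], block.intensities[:, mask], note=f"reduce:{seg}"))
    return out


def _process_segment(
    X: np.ndarray,
    w: np.ndarray,
    spec: PipelineSpec,
    seg: Segment,
    msc_reference: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Steps 2-7 on one segment. Returns (X, axis, msc_reference_used)."""
    ref_used = None
    if spec.smoothing == "position2":
        X = savgol_smooth(X, spec.smoothing_order, spec.smoothing_frame)
    if spec.msc:
        X, ref_used = msc_correct(X, msc_reference)
    if spec.detrend:
        X = detrend(X, w, spec.detrend_order)
    if spec.derivative != "none":
        step = float(w[1] - w[0])
        X = gap_segment_derivative(
            X, spec.derivative, spec.derivative_gap, spec.derivative_segment, step
        )
        w = gap_segment_axis(w, spec.derivative, spec.derivative_gap, spec.derivative_segment)
    if spec.smoothing == "position6":
        X = savgol_smooth(X, spec.smoothing_order, spec.smoothing_frame)
    if spec.binning_window > 1:
        X = bin_spectrum(X, spec.binning_window)
        w = bin_axis(w, spec.binning_window)
    if X.shape[-1] == 0:
        raise PipelineError(f"segment {seg} is empty after binning")
    return X, w, ref_used


def apply_pipeline(
    block: SpectraBlock,
    spec: PipelineSpec,
    msc_references: list[np.ndarray] | None = None,
) -> SpectraBlock:
    """Apply one full pre-processing strategy to a scan-level block.

    Parameters
    ----------
    block : SpectraBlock
        Scan-level spectra.
    spec : PipelineSpec
        The strategy to apply.
    msc_references : list of ndarray, optional
        One reference spectrum per segment (on the reduced, pre-MSC axis).
        Default is the mean spectrum over all scans in each segment, as the
        original workflow prescribes; passing training-fold references here
        is how leakage-free (fold-safe) MSC is achieved.

    Returns
    -------
    SpectraBlock with exactly one row per sample_id; its column count is the
    sum of per-segment post-binning lengths.
    """
    sub_blocks = reduce_wavenumbers(block, spec.segments)
    if msc_references is not None and len(msc_references) != len(sub_blocks):
        raise ParameterError("need one MSC reference per segment")
    parts_X, parts_w = [], []
    prov = list(block.provenance)
    for i, (sub, seg) in enumerate(zip(sub_blocks, spec.segments)):
        ref = None if msc_references is None else msc_references[i]
        X, w, ref_used = _process_segment(sub.intensities, sub.axis.values, spec, seg, ref)
        parts_X.append(X)
        parts_w.append(w)
        steps = [f"reduce:{seg}"]
        if spec.smoothing != "none":
            steps.append(f"savgol@{spec.smoothing}")
        if spec.msc:
            src = "given" if ref is not None else "block-mean"
            steps.append(f"msc:{src}")
        if spec.detrend:
            steps.append(f"detrend:{spec.detrend_order}")
        if spec.derivative != "none":
            steps.append(f"deriv:{spec.derivative}")
        if spec.binning_window > 1:
            steps.append(f"bin:{spec.binning_window}")
        prov.append("segment[" + ", ".join(steps) + "]")
        _ = ref_used
    X = np.concatenate(parts_X, axis=-1)
    w = np.concatenate(parts_w)
    if w.size < 2:
        raise PipelineError("assembled spectrum has fewer than 2 points")
    assembled = SpectraBlock(
        axis=WavenumberAxis(w),
        intensities=X,
        sample_id=block.sample_id.copy(),
        replicate_id=block.replicate_id.copy(),
        class_label=block.class_label.copy(),
        provenance=prov,
    )
    averaged = average_replicates(assembled, spec.averaging)
    centered = Centerer(spec.centering).fit_transform(averaged.intensities)
    return SpectraBlock(
        axis=averaged.axis,
        intensities=centered,
        sample_id=averaged.sample_id,
        replicate_id=averaged.replicate_id,
        class_label=averaged.class_label,
        provenance=averaged.provenance + [f"center:{spec.centering}"],
    )


def msc_references_from_samples(
    block: SpectraBlock, spec: PipelineSpec, sample_ids
) -> list[np.ndarray]:
    """Per-segment MSC references computed from a subset of samples only.

    The reference is the mean spectrum of the chosen samples' scans after
    segment reduction and (if at position 2) smoothing -- i.e. on exactly the
    axis MSC sees inside :func:`apply_pipeline`. Used for fold-safe MSC.
    """
    keep = np.isin(block.sample_id, np.asarray(list(sample_ids), dtype=object))
    if not keep.any():
        raise ParameterError("no scans match the requested sample ids")
    refs = []
    for sub in reduce_wavenumbers(block, spec.segments):
        X = sub.intensities[keep]
        if spec.smoothing == "position2":
            X = savgol_smooth(X, spec.smoothing_order, spec.smoothing_frame)
        refs.append(X.mean(axis=0))
    return refs


class SpectraPreprocessor:
    """Block-to-block transformer wrapping :func:`apply_pipeline`.

    ``fit`` records the per-segment MSC references from the training block
    (when MSC is on), so ``transform`` on held-out data reuses them.
    """

    def __init__(self, spec: PipelineSpec, fold_safe_msc: bool = False):
        self.spec = spec
        self.fold_safe_msc = fold_safe_msc

    def fit(self, block: SpectraBlock, y=None):  # noqa: ARG002
        if self.spec.msc and self.fold_safe_msc:
            self.msc_references_ = msc_references_from_samples(
                block, self.spec, block.unique_samples()
            )
        else:
            self.msc_references_ = None
        return self

    def transform(self, block: SpectraBlock) -> SpectraBlock:
        return apply_pipeline(block, self.spec, self.msc_references_)

    def fit_transform(self, block: SpectraBlock, y=None) -> SpectraBlock:
        return self.fit(block, y).transform(block)
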