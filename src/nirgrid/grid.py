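"""Exhaustive enumeration and ranking of pre-processing strategies.

A :class:`GridConfig` declares the option lists for each pipeline field; the
enumerator forms their Cartesian product (after de-duplication and canonical
sorting of each list), drops any combination violating PipelineSpec
invariants, and returns a deterministic, lexicographically ordered list.

The shipped :func:`default_grid` covers only the wavenumber ranges that are
certain from the published strategy tables; the full range list behind the
published strategy count (50,545) is not recoverable from the text, so the
default grid makes no claim to reproduce that number (it enumerates 11,664).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigError
from .pipeline import (
    AVERAGING_OPTIONS,
    CENTERING_OPTIONS,
    DERIVATIVE_OPTIONS,
    SMOOTHING_OPTIONS,
    PipelineSpec,
    Segment,
)


@dataclass
class GridConfig:
    """Option lists for the strategy grid (every list must be non-empty)."""

    segment_sets: list[tuple[Segment, ...]]
    smoothing_options: list[str] = field(default_factory=lambda: list(SMOOTHING_OPTIONS))
    msc_options: list[bool] = field(default_factory=lambda: [False, True])
    detrend_options: list[bool] = field(default_factory=lambda: [False, True])
    derivative_options: list[str] = field(default_factory=lambda: list(DERIVATIVE_OPTIONS))
    binning_options: list[int] = field(default_factory=lambda: [1, 5, 7, 10, 15, 20])
    averaging_options: list[str] = field(default_factory=lambda: list(AVERAGING_OPTIONS))
    centering_options: list[str] = field(default_factory=lambda: list(CENTERING_OPTIONS))

    def __post_init__(self) -> None:
        for name in (
            "segment_sets",
            "smoothing_options",
            "msc_options",
            "detrend_options",
            "derivative_options",
            "binning_options",
            "averaging_options",
            "centering_options",
        ):
            if not getattr(self, name):
                raise ConfigError(f"{name} must be non-empty")
        if any(b < 1 for b in self.binning_options):
            raise ConfigError("binning windows must be >= 1")
        self.segment_sets = [tuple(s) for s in self.segment_sets]


def _canonical(options, order: tuple | None = None) -> list:
    """De-duplicate, then sort by position in the declared domain order (or
    naturally for numeric / tuple-valued options)."""
    seen = list(dict.fromkeys(options))
    if order is not None:
        return sorted(seen, key=order.index)
    return sorted(seen, key=lambda v: tuple((s.high, s.low) for s in v) if isinstance(v, tuple) else v)


def enumerate_pipelines(config: GridConfig) -> list[PipelineSpec]:
    """All valid PipelineSpecs in the grid, deterministically ordered.

    The order is lexicographic over the fields in their declared order
    (segments, smoothing, msc, detrend, derivative, binning, averaging,
    centering); duplicated options are de-duplicated before the product.
    """
    fields = [
        _canonical(config.segment_sets),
        _canonical(config.smoothing_options, SMOOTHING_OPTIONS),
        _canonical(config.msc_options, (False, True)),
        _canonical(config.detrend_options, (False, True)),
        _canonical(config.derivative_options, DERIVATIVE_OPTIONS),
        _canonical(config.binning_options),
        _canonical(config.averaging_options, AVERAGING_OPTIONS),
        _canonical(config.centering_options, CENTERING_OPTIONS),
    ]
    specs = []
    for segs, smo, msc, det, der, binw, avg, cen in itertools.product(*fields):
        try:
            specs.append(
                PipelineSpec(
                    segments=segs,
                    smoothing=smo,
                    msc=msc,
                    detrend=det,
                    derivative=der,
                    binning_window=binw,
                    averaging=avg,
                    centering=cen,
                )
            )
        except Exception:
            # combinations violating PipelineSpec invariants are dropped
            continue
    return specs


def default_grid() -> GridConfig:
    """The shipped grid: the six wavenumber range choices certain from the
    published tables, crossed with the full option sets."""
    return GridConfig(
        segment_sets=[
            (Segment(11550, 3950),),
            (Segment(11550, 6500),),
            (Segment(11000, 3950),),
            (Segment(9000, 3950),),
            (Segment(8000, 3950),),
            (Segment(11550, 5500), Segment(5000, 3950)),
        ]
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------
class StrategyRanking:
    """Strategies sorted by mean accuracy (descending).

    Ties break toward fewer active pre-processing steps, then by the specs'
    lexicographic order. ``head(k)``/``tail(k)`` give the top/bottom rows in
    the published tables' shape; ``to_frame`` renders the table-row layout
    (wavenumber range, smoothing, MSC, detrending, derivative, binning,
    averaging, centering, accuracy %, std %).
    """

    def __init__(self, rows: list[tuple[PipelineSpec, float, float]]):
        self.rows = sorted(
            rows, key=lambda r: (-r[1], r[0].n_active_steps(), r[0].sort_key())
        )

    def __len__(self) -> int:
        return len(self.rows)

    def head(self, k: int) -> "StrategyRanking":
        out = StrategyRanking([])
        out.rows = self.rows[:k]
        return out

    def tail(self, k: int) -> "StrategyRanking":
        out = StrategyRanking([])
        out.rows = self.rows[-k:]
        return out

    def specs(self) -> list[PipelineSpec]:
        return [r[0] for r in self.rows]

    def position(self, spec: PipelineSpec) -> int:
        """0-based rank of a spec (first matching row)."""
        for i, (s, _, _) in enumerate(self.rows):
            if s == spec:
                return i
        raise KeyError("spec not in ranking")

    def to_frame(self) -> pd.DataFrame:
        records = []
        for spec, acc, std in self.rows:
            rec = spec.to_record()
            rec["accuracy_pct"] = acc
            rec["std_pct"] = std
            records.append(rec)
        return pd.DataFrame(records)

    def to_csv(self, path: str, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=False)


def rank_strategies(results) -> StrategyRanking:
    """Rank (PipelineSpec, ClassificationResult) pairs by mean accuracy.

    Accepts any iterable of ``(spec, result)`` where ``result`` exposes
    ``accuracy_mean`` and ``accuracy_std`` in percent.
    """
    rows = []
    for spec, res in results:
        rows.append((spec, float(res.accuracy_mean), float(res.accuracy_std)))
    if not rows:
        raise ConfigError("rank_strategies needs at least one result")
    return StrategyRanking(rows)
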