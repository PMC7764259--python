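"""Two-stage screening of pre-processing strategies.

Stage 1 evaluates every strategy in the grid with a small number of nested-CV
repetitions (5 in the original protocol); stage 2 re-evaluates the top
``top_k`` strategies (100 in the original protocol) with more repetitions
(20). Per-strategy seeds are derived from (base seed, strategy hash) so
results are independent of evaluation order and a run can resume from a
cache of completed strategies.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import replace

from .block import SpectraBlock
from .classify import ClassificationResult, CVConfig, nested_cv
from .grid import StrategyRanking, rank_strategies
from .pipeline import PipelineSpec, apply_pipeline

logger = logging.getLogger(__name__)


def spec_hash(spec: PipelineSpec) -> str:
    """Stable 12-hex-digit identifier of a strategy."""
    payload = json.dumps(
        {**spec.to_record(), "sort_key": list(map(str, spec.sort_key()))},
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def derive_seed(base_seed: int, spec: PipelineSpec) -> int:
    """Deterministic per-strategy seed below 2**31, independent of order."""
    h = hashlib.sha1(f"{base_seed}:{spec_hash(spec)}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class _Cache:
    """JSON-lines cache of per-strategy accuracies, keyed by (stage, hash)."""

    def __init__(self, path: str | None):
        self.path = path
        self.entries: dict[tuple[str, str], tuple[float, float]] = {}
        if path and os.path.exists(path):
            with open(path) as fh:
                for line in fh:
                    rec = json.loads(line)
                    self.entries[(rec["stage"], rec["hash"])] = (
                        rec["accuracy_mean"],
                        rec["accuracy_std"],
                    )

    def get(self, stage: str, h: str):
        return self.entries.get((stage, h))

    def put(self, stage: str, h: str, acc: float, std: float) -> None:
        self.entries[(stage, h)] = (acc, std)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(
                    json.dumps(
                        {"stage": stage, "hash": h, "accuracy_mean": acc, "accuracy_std": std}
                    )
                    + "\n"
                )


class _CachedResult:
    def __init__(self, acc: float, std: float):
        self.accuracy_mean = acc
        self.accuracy_std = std


def evaluate_strategy(
    block: SpectraBlock, spec: PipelineSpec, cv: CVConfig
) -> ClassificationResult:
    """Preprocess the scan-level block with one strategy and run nested CV."""
    if cv.fold_safe_msc and spec.msc:
        return nested_cv(block, cv, pipeline_spec=spec)
    processed = apply_pipeline(block, spec)
    return nested_cv(processed, cv)


def screen_strategies(
    block: SpectraBlock,
    specs: list[PipelineSpec],
    cv_stage1: CVConfig,
    cv_stage2: CVConfig | None = None,
    top_k: int = 100,
    base_seed: int | None = None,
    cache_path: str | None = None,
    progress: bool = False,
) -> tuple[StrategyRanking, StrategyRanking | None]:
    """Run the two-stage screening protocol over a list of strategies.

    Returns (stage-1 ranking over all specs, stage-2 ranking over the top_k,
    or None if ``cv_stage2`` is None). ``base_seed`` defaults to
    ``cv_stage1.seed``; each strategy runs with a seed derived from it and
    the strategy hash, so partial runs resume identically from the cache.
    """
    if base_seed is None:
        base_seed = cv_stage1.seed
    cache = _Cache(cache_path)

    def run_stage(stage: str, cv: CVConfig, stage_specs: list[PipelineSpec]):
        rows = []
        for i, spec in enumerate(stage_specs):
            h = spec_hash(spec)
            hit = cache.get(stage, h)
            if hit is not None:
                rows.append((spec, _CachedResult(*hit)))
                continue
            cv_spec = replace(cv, seed=derive_seed(base_seed, spec))
            res = evaluate_strategy(block, spec, cv_spec)
            cache.put(stage, h, res.accuracy_mean, res.accuracy_std)
            rows.append((spec, res))
            if progress:
                logger.info(
                    "%s %d/%d %s -> %.2f%%",
                    stage,
                    i + 1,
                    len(stage_specs),
                    h,
                    res.accuracy_mean,
                )
        return rank_strategies(rows)

    ranking1 = run_stage("stage1", cv_stage1, specs)
    if cv_stage2 is None:
        return ranking1, None
    finalists = ranking1.head(min(top_k, len(ranking1))).specs()
    ranking2 = run_stage("stage2", cv_stage2, finalists)
    return ranking1, ranking2
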