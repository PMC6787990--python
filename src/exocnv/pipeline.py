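"""End-to-end pipeline: matrix (or alignments) -> normalization -> calls.

Per-sample discovery work can run on a local process pool; samples are
independent, so concurrent and sequential execution produce the
identical call set — the pool only changes wall-clock time.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from .discovery import CNVCall, discover_sample, write_xcnv
from .hmm import HMMParameters
from .matrix import ReadDepthMatrix
from .normalization import (
    FilterThresholds,
    NormalizationResult,
    RankSelection,
    normalize_matrix,
)

logger = logging.getLogger("exocnv")

__all__ = ["run_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    normalization: NormalizationResult
    calls: list[CNVCall]


def _sample_worker(args) -> list[CNVCall]:
    sample, z_row, orig_row, targets, params = args
    return discover_sample(sample, z_row, orig_row, targets, params)


def run_pipeline(
    matrix: ReadDepthMatrix,
    thresholds: FilterThresholds = FilterThresholds(),
    settings: RankSelection = RankSelection(K=0),
    params: HMMParameters = HMMParameters(),
    workers: int = 1,
    xcnv_path: str | Path | None = None,
) -> PipelineResult:
    """Normalize a raw read-depth matrix and call CNVs in every sample."""
    result = normalize_matrix(matrix, thresholds, settings)
    logger.info(
        "normalization: removed K=%d components (k=%d computed, %d iterations); "
        "excluded %d targets pre, %d samples, %d targets post",
        result.selection.K,
        result.selection.k_used,
        result.selection.iterations,
        len(result.target_report_pre),
        len(result.sample_report),
        len(result.target_report_post),
    )
    jobs = [
        (
            sample,
            result.zscores.depths[i],
            result.original.depths[i],
            result.zscores.targets,
            params,
        )
        for i, sample in enumerate(result.zscores.samples)
    ]
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            per_sample = list(pool.map(_sample_worker, jobs))
    else:
        per_sample = [_sample_worker(job) for job in jobs]
    calls = [c for calls in per_sample for c in calls]
    logger.info("discovery: %d calls at Q_SOME >= %d", len(calls), params.min_some_quality)
    if xcnv_path is not None:
        write_xcnv(calls, xcnv_path)
    return PipelineResult(normalization=result, calls=calls)
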