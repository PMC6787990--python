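"""Per-target mean read depth from coordinate-sorted SAM/BAM alignments.

The counting semantics mirror the GATK DepthOfCoverage invocation of the
XHMM protocol: reads below the mapping-quality floor (default 20),
duplicates, secondary/supplementary records and unmapped reads are
skipped; base qualities are ignored (the protocol sets minBaseQuality 0).
Only reference-consuming aligned bases count toward depth — deletions
within a read (CIGAR D) and clipped or inserted bases do not.

In the default ``fragment`` counting unit, the two mates of a pair
contribute depth 1 to any base both cover (per-base depth is counted at
most once per fragment); in ``read`` mode every passing read contributes
independently.

The per-target value is::

    sum over target bases of per-base depth / target length
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .intervals import TargetInterval, check_sorted
from .matrix import ReadDepthMatrix

__all__ = ["CoverageFilters", "target_coverage", "coverage_matrix"]


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class CoverageFilters:
    """Read-filtering switches for depth counting (protocol defaults)."""

    min_mapping_quality: int = 20
    count_unit: str = "fragment"  # or "read"
    include_duplicates: bool = False
    include_secondary_supplementary: bool = False
    count_deletions: bool = False  # CIGAR D bases toward depth

    def __post_init__(self) -> None:
        if self.min_mapping_quality < 0:
            raise CoverageError("min_mapping_quality must be >= 0")
        if self.count_unit not in ("fragment", "read"):
            raise CoverageError(f"count_unit must be 'fragment' or 'read'")

    def passes(self, read: "pysam.AlignedSegment") -> bool:
        if read.is_unmapped:
            return False
        if read.mapping_quality < self.min_mapping_quality:
            return False
        if not self.include_duplicates and read.is_duplicate:
            return False
        if not self.include_secondary_supplementary and (
            read.is_secondary or read.is_supplementary
        ):
            return False
        return True


def _reference_blocks(
    read: "pysam.AlignedSegment", count_deletions: bool
) -> list[tuple[int, int]]:
    """0-based half-open reference spans consumed by aligned bases."""
    if count_deletions:
        # M/=/X and D all consume reference and count.
        blocks: list[tuple[int, int]] = []
        pos = read.reference_start
        for op, length in read.cigartuples or []:
            if op in (0, 7, 8, 2):  # M, =, X, D
                blocks.append((pos, pos + length))
                pos += length
            elif op == 3:  # N skips reference without depth
                pos += length
        return blocks
    return read.get_blocks()  # M/=/X runs only


class _TargetIndex:
    """Maps reference spans to overlapping targets via binary search."""

    def __init__(self, targets: Sequence[TargetInterval]):
        check_sorted(targets)
        self.targets = list(targets)
        self.by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for idx, t in enumerate(targets):
            self.by_chrom.setdefault(t.chrom, []).append((t.start, t.stop, idx))
        self._starts = {
            chrom: [s for s, _, _ in rows] for chrom, rows in self.by_chrom.items()
        }

    def overlapping(self, chrom: str, begin0: int, end0: int):
        """Yield (index, start0, stop0_excl) for targets hitting [begin0, end0)."""
        rows = self.by_chrom.get(chrom)
        if not rows:
            return
        starts = self._starts[chrom]
        i = bisect_right(starts, end0)  # targets with start (1-based) <= end0
        for start, stop, idx in rows[:i]:
            if stop >= begin0 + 1:
                yield idx, start - 1, stop


def target_coverage(
    alignments: str | Path,
    targets: Sequence[TargetInterval],
    filters: CoverageFilters = CoverageFilters(),
    sample_name: str | None = None,
) -> tuple[str, np.ndarray]:
    """Mean per-base depth over each target for one alignment file.

    Returns ``(sample, values)`` where the sample identity comes from the
    first read group's SM tag, falling back to the file stem.  Input must
    be coordinate-sorted (checked via the @HD SO header when present).
    Targets on chromosomes absent from the alignment header get depth 0.
    """
    path = Path(alignments)
    index = _TargetIndex(targets)
    per_base = [np.zeros(t.length, dtype=np.float64) for t in targets]
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        header = af.header.to_dict()
        so = header.get("HD", {}).get("SO")
        if so is not None and so != "coordinate":
            raise CoverageError(f"{path}: alignments not coordinate-sorted (SO={so})")
        if sample_name is None:
            rgs = header.get("RG", [])
            sample_name = rgs[0].get("SM") if rgs and "SM" in rgs[0] else path.stem
        if filters.count_unit == "fragment":
            fragments: dict[str, list] = {}
            for read in af.fetch(until_eof=True):
                if filters.passes(read):
                    fragments.setdefault(read.query_name, []).append(read)
            for reads in fragments.values():
                covered: set[int] | None = None
                chroms = {r.reference_name for r in reads}
                if len(reads) > 1 and len(chroms) == 1:
                    covered = set()
                    for r in reads:
                        for b0, e0 in _reference_blocks(r, filters.count_deletions):
                            covered.update(range(b0, e0))
                    _add_positions(
                        index, reads[0].reference_name, sorted(covered), per_base
                    )
                else:
                    for r in reads:
                        _add_blocks(
                            index,
                            r.reference_name,
                            _reference_blocks(r, filters.count_deletions),
                            per_base,
                        )
        else:
            for read in af.fetch(until_eof=True):
                if filters.passes(read):
                    _add_blocks(
                        index,
                        read.reference_name,
                        _reference_blocks(read, filters.count_deletions),
                        per_base,
                    )
    values = np.array(
        [arr.sum() / t.length for arr, t in zip(per_base, targets)]
    )
    return sample_name, values


def _add_blocks(index: _TargetIndex, chrom: str, blocks, per_base) -> None:
    for b0, e0 in blocks:
        for idx, t0, t_end in index.overlapping(chrom, b0, e0):
            lo, hi = max(b0, t0), min(e0, t_end)
            if lo < hi:
                per_base[idx][lo - t0 : hi - t0] += 1.0


def _add_positions(index: _TargetIndex, chrom: str, positions, per_base) -> None:
    if not positions:
        return
    # Collapse sorted positions into runs, then reuse the block path.
    blocks = []
    run_start = prev = positions[0]
    for p in positions[1:]:
        if p != prev + 1:
            blocks.append((run_start, prev + 1))
            run_start = p
        prev = p
    blocks.append((run_start, prev + 1))
    _add_blocks(index, chrom, blocks, per_base)


def coverage_matrix(
    alignment_files: Sequence[str | Path],
    targets: Sequence[TargetInterval],
    filters: CoverageFilters = CoverageFilters(),
    sample_names: Sequence[str] | None = None,
) -> ReadDepthMatrix:
    """One matrix row per alignment file, in input order.

    Rows are independent: computing them in any order (or concurrently)
    yields identical results.  Any per-file failure aborts with the file
    named.
    """
    if not alignment_files:
        raise CoverageError("no alignment files supplied")
    samples: list[str] = []
    rows: list[np.ndarray] = []
    for i, path in enumerate(alignment_files):
        name = sample_names[i] if sample_names is not None else None
        try:
            sample, values = target_coverage(path, targets, filters, name)
        except (OSError, ValueError) as exc:
            raise CoverageError(f"coverage failed for {path}: {exc}") from exc
        samples.append(sample)
        rows.append(values)
    return ReadDepthMatrix(samples=samples, targets=list(targets), depths=np.vstack(rows))
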