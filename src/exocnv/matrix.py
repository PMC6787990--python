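"""The XHMM-dialect read-depth matrix: samples x targets mean coverage.

File layout (tab-delimited)::

    Matrix      1:100-199   1:300-399   ...
    SAMPLE_A    31.27       28.94       ...
    SAMPLE_B    30.11       29.53       ...

The first header cell is a free-form corner label; column headers are
``chrom:start-stop`` target strings; the leading column holds sample IDs.
Cells are dense: an unparseable cell is an error, never a NaN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import TargetInterval, check_sorted, parse_target

__all__ = [
    "ReadDepthMatrix",
    "MatrixStage",
    "Stage",
    "read_depth_matrix",
    "write_depth_matrix",
    "merge_gatk_depths",
]


class MatrixFormatError(ValueError):
    """Raised for malformed matrix or coverage-table files."""


@dataclass
class ReadDepthMatrix:
    """``s`` samples x ``t`` targets of mean per-base coverage.

    ``depths`` is a dense float64 array; row ``i`` belongs to
    ``samples[i]``, column ``j`` to ``targets[j]``.  Sample order is
    preserved by every operation in the package — nothing reorders rows
    silently.
    """

    samples: list[str]
    targets: list[TargetInterval]
    depths: np.ndarray
    require_nonnegative: bool = True

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.float64)
        if self.depths.ndim != 2:
            raise MatrixFormatError("depths must be a 2-D array")
        s, t = self.depths.shape
        if s != len(self.samples) or t != len(self.targets):
            raise MatrixFormatError(
                f"matrix is {s}x{t} but labels are "
                f"{len(self.samples)} samples x {len(self.targets)} targets"
            )
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({x for x in self.samples if self.samples.count(x) > 1})
            raise MatrixFormatError(f"duplicate sample IDs: {', '.join(dupes)}")
        check_sorted(self.targets)
        if not np.all(np.isfinite(self.depths)):
            raise MatrixFormatError("matrix contains non-finite values")
        if self.require_nonnegative and np.any(self.depths < 0):
            raise MatrixFormatError("matrix contains negative depths")

    @property
    def n_samples(self) -> int:
        return self.depths.shape[0]

    @property
    def n_targets(self) -> int:
        return self.depths.shape[1]

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        target_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "ReadDepthMatrix":
        """Row/column subset preserving input order of the kept labels."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        ti = np.arange(self.n_targets) if target_idx is None else np.asarray(target_idx)
        return ReadDepthMatrix(
            samples=[self.samples[i] for i in si],
            targets=[self.targets[j] for j in ti],
            depths=self.depths[np.ix_(si, ti)],
            require_nonnegative=self.require_nonnegative,
        )

    def copy_with(self, depths: np.ndarray, require_nonnegative: bool | None = None):
        return ReadDepthMatrix(
            samples=list(self.samples),
            targets=list(self.targets),
            depths=depths,
            require_nonnegative=(
                self.require_nonnegative
                if require_nonnegative is None
                else require_nonnegative
            ),
        )


class Stage(enum.Enum):
    RAW = "raw"
    FILTERED_CENTERED = "filtered_centered"
    PCA_NORMALIZED = "pca_normalized"
    ZSCORED = "zscored"


_STAGE_ORDER = [Stage.RAW, Stage.FILTERED_CENTERED, Stage.PCA_NORMALIZED, Stage.ZSCORED]


@dataclass
class MatrixStage:
    """A matrix tagged with its position in the normalization pipeline."""

    stage: Stage
    matrix: ReadDepthMatrix

    def advance(self, stage: Stage, matrix: ReadDepthMatrix) -> "MatrixStage":
        if _STAGE_ORDER.index(stage) <= _STAGE_ORDER.index(self.stage):
            raise ValueError(
                f"stage transition {self.stage.value} -> {stage.value} is not forward"
            )
        return MatrixStage(stage=stage, matrix=matrix)


def read_depth_matrix(
    path: str | Path, require_nonnegative: bool = True
) -> ReadDepthMatrix:
    """Read an XHMM tab-delimited read-depth matrix.

    Raises :class:`MatrixFormatError` with a line number for ragged rows,
    non-numeric cells or duplicate sample IDs.
    """
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if not header:
            raise MatrixFormatError(f"{path}:1: empty header line")
        target_names = header.split("\t")[1:]
        targets = [parse_target(name) for name in target_names]
        samples: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(targets) + 1:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected {len(targets) + 1} columns, "
                    f"got {len(fields)}"
                )
            samples.append(fields[0])
            try:
                rows.append(np.array([float(x) for x in fields[1:]]))
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: {exc}") from None
        if len(set(samples)) != len(samples):
            raise MatrixFormatError(f"{path}: duplicate sample IDs")
    depths = (
        np.vstack(rows) if rows else np.empty((0, len(targets)), dtype=np.float64)
    )
    return ReadDepthMatrix(
        samples=samples,
        targets=targets,
        depths=depths,
        require_nonnegative=require_nonnegative,
    )


def write_depth_matrix(
    matrix: ReadDepthMatrix,
    path: str | Path,
    precision: int = 2,
    corner_label: str = "Matrix",
) -> None:
    """Write the XHMM-dialect matrix with fixed decimal precision.

    Values are formatted with Python's ``format(x, '.Nf')`` which rounds
    half-even, so 1.005 at precision 2 prints ``1.00`` (the nearest
    representable double of 1.005 is just below it).  The written file
    round-trips through :func:`read_depth_matrix` to within
    ``0.5 * 10**-precision`` per cell.
    """
    path = Path(path)
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as handle:
        handle.write("\t".join([corner_label] + [t.name for t in matrix.targets]))
        handle.write("\n")
        for sample, row in zip(matrix.samples, matrix.depths):
            handle.write(
                "\t".join([sample] + [fmt.format(v) for v in row]) + "\n"
            )


def _split_gatk_line(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.rstrip("\n").split(",")


def merge_gatk_depths(
    paths: Sequence[str | Path],
    sample_names: Sequence[str] | None = None,
    mean_column_suffix: str = "_mean_cvg",
) -> ReadDepthMatrix:
    """Merge per-sample GATK DepthOfCoverage interval summaries into a matrix.

    Each file must carry a ``Target`` column of ``chrom:start-stop`` strings
    and a mean-coverage column whose header ends with *mean_column_suffix*
    (GATK names it ``<sample>_mean_cvg``).  Comma- and tab-separated
    dialects are both accepted.  All files must list identical targets in
    identical order — a permuted target list is an error, never silently
    reordered.
    """
    if not paths:
        raise MatrixFormatError("no coverage files supplied")
    samples: list[str] = []
    rows: list[np.ndarray] = []
    ref_targets: list[TargetInterval] | None = None
    for file_index, path in enumerate(paths):
        path = Path(path)
        with open(path) as handle:
            header = _split_gatk_line(handle.readline())
            try:
                target_col = next(
                    i for i, h in enumerate(header) if h.lower() == "target"
                )
            except StopIteration:
                raise MatrixFormatError(f"{path}: no 'Target' column") from None
            mean_cols = [
                i for i, h in enumerate(header) if h.endswith(mean_column_suffix)
            ]
            if len(mean_cols) != 1:
                raise MatrixFormatError(
                    f"{path}: expected exactly one column ending with "
                    f"{mean_column_suffix!r}, found {len(mean_cols)}"
                )
            mean_col = mean_cols[0]
            sample = header[mean_col][: -len(mean_column_suffix)] or path.stem
            file_targets: list[TargetInterval] = []
            values: list[float] = []
            for lineno, raw in enumerate(handle, start=2):
                if not raw.strip():
                    continue
                fields = _split_gatk_line(raw)
                try:
                    file_targets.append(parse_target(fields[target_col]))
                    values.append(float(fields[mean_col]))
                except (ValueError, IndexError) as exc:
                    raise MatrixFormatError(f"{path}:{lineno}: {exc}") from None
        if ref_targets is None:
            ref_targets = file_targets
        elif [t.name for t in file_targets] != [t.name for t in ref_targets]:
            divergent = next(
                (a.name, b.name)
                for a, b in zip(ref_targets, file_targets)
                if not a.same_span(b)
            ) if len(file_targets) == len(ref_targets) else ("<length>", "<length>")
            raise MatrixFormatError(
                f"{path}: target list differs from {paths[0]}; "
                f"first divergence: {divergent[0]} vs {divergent[1]}"
            )
        if sample_names is not None:
            sample = sample_names[file_index]
        samples.append(sample)
        rows.append(np.array(values))
    assert ref_targets is not None
    return ReadDepthMatrix(samples=samples, targets=ref_targets, depths=np.vstack(rows))
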