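"""Genomic target intervals for exome capture designs.

Targets are stored 1-based inclusive, matching the ``chrom:start-stop``
header dialect of XHMM read-depth matrices.  BED input (0-based,
half-open) is converted at the parsing boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TargetInterval",
    "parse_target",
    "read_targets",
    "inter_target_distances",
]

_TARGET_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<stop>\d+)$")


class TargetFormatError(ValueError):
    """Raised when a target string or target file cannot be parsed."""


@dataclass(frozen=True)
class TargetInterval:
    """One exome capture target with 1-based inclusive coordinates.

    Attributes
    ----------
    chrom : str
        Chromosome / contig name.
    start, stop : int
        1-based inclusive positions; ``stop >= start >= 1``.
    gc_fraction : float or None
        Fraction of G/C reference bases over the span, if annotated.
    complexity_fraction : float or None
        Fraction of masked (low-complexity) reference bases, if annotated.
    """

    chrom: str
    start: int
    stop: int
    gc_fraction: float | None = None
    complexity_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise TargetFormatError(
                f"target {self.chrom}:{self.start}-{self.stop}: start must be >= 1"
            )
        if self.stop < self.start:
            raise TargetFormatError(
                f"target {self.chrom}:{self.start}-{self.stop}: stop < start"
            )
        for name in ("gc_fraction", "complexity_fraction"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise TargetFormatError(
                    f"target {self.chrom}:{self.start}-{self.stop}: "
                    f"{name}={value} outside [0, 1]"
                )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.stop) / 2.0

    @property
    def name(self) -> str:
        """The canonical ``chrom:start-stop`` string form."""
        return f"{self.chrom}:{self.start}-{self.stop}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    def with_annotation(
        self, gc_fraction: float | None, complexity_fraction: float | None
    ) -> "TargetInterval":
        return replace(
            self, gc_fraction=gc_fraction, complexity_fraction=complexity_fraction
        )

    def same_span(self, other: "TargetInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start == other.start
            and self.stop == other.stop
        )


def parse_target(text: str) -> TargetInterval:
    """Parse a ``chrom:start-stop`` string into a :class:`TargetInterval`.

    Coordinates are 1-based inclusive and round-trip exactly through
    :attr:`TargetInterval.name`.
    """
    match = _TARGET_RE.match(text.strip())
    if match is None:
        raise TargetFormatError(
            f"malformed target string {text!r}: expected 'chrom:start-stop'"
        )
    return TargetInterval(
        chrom=match.group("chrom"),
        start=int(match.group("start")),
        stop=int(match.group("stop")),
    )


def _targets_sorted(targets: Sequence[TargetInterval]) -> bool:
    keys = [(t.chrom, t.start, t.stop) for t in targets]
    # Sorted within chromosome runs; chromosomes keep their file order.
    seen: set[str] = set()
    prev_chrom: str | None = None
    prev_key: tuple | None = None
    for key in keys:
        chrom = key[0]
        if chrom != prev_chrom:
            if chrom in seen:
                return False  # chromosome appears in two separate blocks
            seen.add(chrom)
            prev_chrom = chrom
        elif key < prev_key:  # type: ignore[operator]
            return False
        prev_key = key
    return True


def check_sorted(targets: Sequence[TargetInterval]) -> None:
    """Require targets grouped by chromosome and position-sorted within it."""
    if not _targets_sorted(targets):
        raise TargetFormatError(
            "targets are not sorted by position within chromosome blocks"
        )


def read_targets(path: str | Path) -> list[TargetInterval]:
    """Read a target list from BED (3+ columns) or ``chrom:start-stop`` lines.

    BED coordinates (0-based half-open) are converted to the internal
    1-based inclusive convention: ``start_1 = start_0 + 1``, ``stop_1 = end``.
    The dialect is detected per file from the first non-comment line.
    """
    path = Path(path)
    targets: list[TargetInterval] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if len(fields) >= 3 and fields[1].isdigit() and fields[2].isdigit():
                    start0, end = int(fields[1]), int(fields[2])
                    targets.append(
                        TargetInterval(chrom=fields[0], start=start0 + 1, stop=end)
                    )
                elif len(fields) == 1:
                    targets.append(parse_target(fields[0]))
                else:
                    raise TargetFormatError(f"unrecognized target line {line!r}")
            except TargetFormatError as exc:
                raise TargetFormatError(f"{path}:{lineno}: {exc}") from None
    return targets


def inter_target_distances(
    targets: Sequence[TargetInterval], mode: str = "midpoint"
) -> "list[float]":
    """Distances between consecutive targets, used by the HMM transitions.

    Returns ``len(targets) - 1`` values.  ``mode='midpoint'`` measures
    midpoint-to-midpoint; ``mode='gap'`` measures the gap between the end
    of one target and the start of the next.  Both are floored at 0, and a
    chromosome change yields ``inf`` (fully decoupled transition).
    """
    if mode not in ("midpoint", "gap"):
        raise ValueError(f"unknown distance mode {mode!r}")
    out: list[float] = []
    for prev, cur in zip(targets, targets[1:]):
        if prev.chrom != cur.chrom:
            out.append(float("inf"))
        elif mode == "midpoint":
            out.append(max(0.0, cur.midpoint - prev.midpoint))
        else:
            out.append(max(0.0, float(cur.start - prev.stop - 1)))
    return out


def annotate_targets_from_fasta(
    targets: Iterable[TargetInterval], fasta_path: str | Path
) -> list[TargetInterval]:
    """Annotate GC and complexity fractions from a reference FASTA.

    GC fraction counts G/C bases (case-insensitive); complexity fraction is
    the fraction of soft-masked (lowercase) bases over the target span.
    """
    import pysam

    annotated = []
    with pysam.FastaFile(str(fasta_path)) as fasta:
        for t in targets:
            seq = fasta.fetch(t.chrom, t.start - 1, t.stop)
            if len(seq) == 0:
                annotated.append(t)
                continue
            gc = sum(1 for b in seq if b in "gcGC") / len(seq)
            masked = sum(1 for b in seq if b.islower()) / len(seq)
            annotated.append(t.with_annotation(gc, masked))
    return annotated
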