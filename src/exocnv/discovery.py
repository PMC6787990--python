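"""CNV discovery: Viterbi segmentation, phred qualities, .xcnv output.

Each sample is processed independently: the Viterbi path over its
z-scored depths is segmented into maximal DEL/DUP runs, and each run is
scored with five phred-scaled qualities derived from constrained forward
passes divided by the unconstrained likelihood:

* ``Q_SOME``        — some target in the call interval has the called state
  (this is the reporting criterion; default threshold 30).
* ``Q_EXACT``       — every target in the interval has the called state and
  the flanking targets (where they exist) do not.
* ``Q_NON_DIPLOID`` — some target in the interval is not diploid.
* ``Q_START`` / ``Q_STOP`` — the event breakpoints: called state begins
  exactly at the first target / ends exactly at the last.

At the first or last target of a chromosome the nonexistent flanking
constraint is simply dropped (the probability is not conditioned on it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .hmm import (
    DEL,
    DIP,
    DUP,
    STATE_NAMES,
    HMMParameters,
    StatePath,
    constrained_loglikelihood,
    forward_backward_scaled,
    phred,
    viterbi,
)
from .intervals import TargetInterval
from .matrix import ReadDepthMatrix

__all__ = [
    "CNVCall",
    "QualityProbabilities",
    "segment_path",
    "quality_probabilities",
    "quality_scores",
    "discover",
    "discover_sample",
    "write_xcnv",
    "read_xcnv",
    "write_vcf",
    "match_calls",
    "MatchReport",
]

XCNV_COLUMNS = [
    "SAMPLE",
    "CNV",
    "INTERVAL",
    "KB",
    "CHR",
    "MID_BP",
    "TARGETS",
    "NUM_TARG",
    "Q_EXACT",
    "Q_SOME",
    "Q_NON_DIPLOID",
    "Q_START",
    "Q_STOP",
    "MEAN_RD",
    "MEAN_ORIG_RD",
]


@dataclass
class CNVCall:
    """One called deletion or duplication in one sample.

    ``first_target_index``/``last_target_index`` are 0-based inclusive
    indices into the filtered target list (written 1-based in .xcnv).
    """

    sample: str
    type: str  # "DEL" or "DUP"
    interval: TargetInterval
    first_target_index: int
    last_target_index: int
    q_exact: int
    q_some: int
    q_non_diploid: int
    q_start: int
    q_stop: int
    mean_rd: float
    mean_orig_rd: float

    @property
    def num_targets(self) -> int:
        return self.last_target_index - self.first_target_index + 1

    def overlaps(self, other: "CNVCall") -> bool:
        return (
            self.interval.chrom == other.interval.chrom
            and self.interval.start <= other.interval.stop
            and other.interval.start <= self.interval.stop
        )


@dataclass
class QualityProbabilities:
    """The five event probabilities before phred conversion."""

    p_exact: float
    p_some: float
    p_non_diploid: float
    p_start: float
    p_stop: float


def segment_path(
    path: StatePath, targets: Sequence[TargetInterval]
) -> list[tuple[int, int, int]]:
    """Maximal non-diploid runs as ``(state, first, last)`` index triples.

    Runs never span a chromosome boundary: a same-state run crossing a
    chromosome change is split into one run per chromosome.
    """
    states = path.states
    if len(states) != len(targets):
        raise ValueError("state path length does not match target count")
    runs: list[tuple[int, int, int]] = []
    start = None
    for i, s in enumerate(states):
        boundary = i > 0 and targets[i].chrom != targets[i - 1].chrom
        if start is not None and (s != states[start] or boundary):
            if states[start] != DIP:
                runs.append((int(states[start]), start, i - 1))
            start = None
        if start is None:
            start = i
    if start is not None and states[start] != DIP:
        runs.append((int(states[start]), start, len(states) - 1))
    return runs


def _flank_indices(
    first: int, last: int, targets: Sequence[TargetInterval]
) -> tuple[int | None, int | None]:
    """Indices of the flanking targets, or None at a chromosome edge."""
    left = (
        first - 1
        if first > 0 and targets[first - 1].chrom == targets[first].chrom
        else None
    )
    right = (
        last + 1
        if last + 1 < len(targets) and targets[last + 1].chrom == targets[last].chrom
        else None
    )
    return left, right


def quality_probabilities(
    state: int,
    first: int,
    last: int,
    z_row: np.ndarray,
    targets: Sequence[TargetInterval],
    params: HMMParameters,
    log_likelihood: float,
) -> QualityProbabilities:
    """Exact event probabilities for a candidate call via constrained passes."""
    T = len(targets)
    if not (0 <= first <= last < T):
        raise ValueError(f"call interval [{first}, {last}] outside [0, {T - 1}]")
    if state == DIP:
        raise ValueError("diploid runs are not calls")

    def ratio(mask: np.ndarray) -> float:
        log_c = constrained_loglikelihood(z_row, targets, params, mask)
        if log_c == float("-inf"):
            return 0.0
        return min(1.0, float(np.exp(log_c - log_likelihood)))

    def fresh_mask() -> np.ndarray:
        return np.ones((T, 3), dtype=bool)

    left, right = _flank_indices(first, last, targets)

    # P(no target in [a,b] has the called state)
    m = fresh_mask()
    m[first : last + 1, state] = False
    p_some = 1.0 - ratio(m)

    # P(all targets in [a,b] diploid)
    m = fresh_mask()
    m[first : last + 1, :] = False
    m[first : last + 1, DIP] = True
    p_non_diploid = 1.0 - ratio(m)

    # P(all of [a,b] in the called state, flanks not), flanks dropped at edges
    m = fresh_mask()
    m[first : last + 1, :] = False
    m[first : last + 1, state] = True
    if left is not None:
        m[left, state] = False
    if right is not None:
        m[right, state] = False
    p_exact = ratio(m)

    # P(state != c just before a, state = c at a)
    m = fresh_mask()
    m[first, :] = False
    m[first, state] = True
    if left is not None:
        m[left, state] = False
    p_start = ratio(m)

    # P(state = c at b, state != c just after b)
    m = fresh_mask()
    m[last, :] = False
    m[last, state] = True
    if right is not None:
        m[right, state] = False
    p_stop = ratio(m)

    return QualityProbabilities(
        p_exact=p_exact,
        p_some=p_some,
        p_non_diploid=p_non_diploid,
        p_start=p_start,
        p_stop=p_stop,
    )


def quality_scores(probs: QualityProbabilities) -> tuple[int, int, int, int, int]:
    """Phred-convert the five event probabilities (round half up, cap 99)."""
    return (
        phred(probs.p_exact),
        phred(probs.p_some),
        phred(probs.p_non_diploid),
        phred(probs.p_start),
        phred(probs.p_stop),
    )


def discover_sample(
    sample: str,
    z_row: np.ndarray,
    orig_row: np.ndarray,
    targets: Sequence[TargetInterval],
    params: HMMParameters = HMMParameters(),
    apply_threshold: bool = True,
) -> list[CNVCall]:
    """Viterbi -> segment -> score one sample; keep Q_SOME >= threshold."""
    path = viterbi(z_row, targets, params)
    runs = segment_path(path, targets)
    if not runs:
        return []
    fb = forward_backward_scaled(z_row, targets, params)
    calls: list[CNVCall] = []
    for state, first, last in runs:
        probs = quality_probabilities(
            state, first, last, z_row, targets, params, fb.log_likelihood
        )
        q_exact, q_some, q_nd, q_start, q_stop = quality_scores(probs)
        if apply_threshold and q_some < params.min_some_quality:
            continue
        member = slice(first, last + 1)
        calls.append(
            CNVCall(
                sample=sample,
                type=STATE_NAMES[state],
                interval=TargetInterval(
                    chrom=targets[first].chrom,
                    start=targets[first].start,
                    stop=targets[last].stop,
                ),
                first_target_index=first,
                last_target_index=last,
                q_exact=q_exact,
                q_some=q_some,
                q_non_diploid=q_nd,
                q_start=q_start,
                q_stop=q_stop,
                mean_rd=float(np.mean(z_row[member])),
                mean_orig_rd=float(np.mean(orig_row[member])),
            )
        )
    return calls


def discover(
    zscores: ReadDepthMatrix,
    original: ReadDepthMatrix,
    params: HMMParameters = HMMParameters(),
    apply_threshold: bool = True,
) -> list[CNVCall]:
    """Call CNVs in every sample independently.

    The result is a concatenation of per-sample call lists in sample
    order; processing samples in any order (or concurrently) yields the
    identical set.
    """
    if zscores.samples != original.samples or len(zscores.targets) != len(
        original.targets
    ):
        raise ValueError("z-score and original matrices are not aligned")
    calls: list[CNVCall] = []
    for i, sample in enumerate(zscores.samples):
        calls.extend(
            discover_sample(
                sample,
                zscores.depths[i],
                original.depths[i],
                zscores.targets,
                params,
                apply_threshold=apply_threshold,
            )
        )
    return calls


def write_xcnv(calls: Sequence[CNVCall], path: str | Path) -> None:
    """Write calls as an XHMM-style .xcnv table (tab-delimited)."""
    with open(path, "w") as handle:
        handle.write("\t".join(XCNV_COLUMNS) + "\n")
        for c in calls:
            iv = c.interval
            span_kb = (iv.stop - iv.start + 1) / 1000.0
            mid_bp = (iv.start + iv.stop) / 2.0
            handle.write(
                "\t".join(
                    [
                        c.sample,
                        c.type,
                        iv.name,
                        f"{span_kb:.2f}",
                        iv.chrom,
                        f"{mid_bp:.1f}",
                        f"{c.first_target_index + 1}..{c.last_target_index + 1}",
                        str(c.num_targets),
                        str(c.q_exact),
                        str(c.q_some),
                        str(c.q_non_diploid),
                        str(c.q_start),
                        str(c.q_stop),
                        f"{c.mean_rd:.2f}",
                        f"{c.mean_orig_rd:.2f}",
                    ]
                )
                + "\n"
            )


def read_xcnv(path: str | Path) -> list[CNVCall]:
    """Read an .xcnv table written by :func:`write_xcnv`."""
    from .intervals import parse_target

    calls: list[CNVCall] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != XCNV_COLUMNS:
            raise ValueError(f"{path}: unexpected .xcnv header")
        for raw in handle:
            if not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            row = dict(zip(XCNV_COLUMNS, f))
            first, last = row["TARGETS"].split("..")
            calls.append(
                CNVCall(
                    sample=row["SAMPLE"],
                    type=row["CNV"],
                    interval=parse_target(row["INTERVAL"]),
                    first_target_index=int(first) - 1,
                    last_target_index=int(last) - 1,
                    q_exact=int(row["Q_EXACT"]),
                    q_some=int(row["Q_SOME"]),
                    q_non_diploid=int(row["Q_NON_DIPLOID"]),
                    q_start=int(row["Q_START"]),
                    q_stop=int(row["Q_STOP"]),
                    mean_rd=float(row["MEAN_RD"]),
                    mean_orig_rd=float(row["MEAN_ORIG_RD"]),
                )
            )
    return calls


def write_vcf(calls: Sequence[CNVCall], path: str | Path) -> None:
    """Minimal VCF 4.2 export of calls (convenience output).

    One symbolic-allele record per call with SVTYPE/END info and the
    Q_SOME score in the SQ sample field.
    """
    samples = sorted({c.sample for c in calls})
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##ALT=<ID=DEL,Description="Deletion">\n')
        handle.write('##ALT=<ID=DUP,Description="Duplication">\n')
        handle.write(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
        )
        handle.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End">\n')
        handle.write(
            '##FORMAT=<ID=SQ,Number=1,Type=Integer,Description="Some quality">\n'
        )
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for c in sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start)):
            cells = ["."] * len(samples)
            cells[samples.index(c.sample)] = str(c.q_some)
            handle.write(
                "\t".join(
                    [
                        c.interval.chrom,
                        str(c.interval.start),
                        ".",
                        "N",
                        f"<{c.type}>",
                        str(c.q_some),
                        ".",
                        f"SVTYPE={c.type};END={c.interval.stop}",
                        "SQ",
                    ]
                    + cells
                )
                + "\n"
            )


@dataclass
class MatchReport:
    """Concordance of one call set against another.

    ``exact`` — same sample, type and breakpoints; ``overlap`` — same
    sample and type with overlapping intervals but different breakpoints;
    ``unmatched`` — no overlapping same-type call in the other set.
    ``target_differences`` holds |num_targets difference| per overlap pair.
    """

    exact: int
    overlap: int
    unmatched: int
    target_differences: list[int]
    exact_pairs: list[tuple[CNVCall, CNVCall]]
    overlap_pairs: list[tuple[CNVCall, CNVCall]]
    unmatched_calls: list[CNVCall]

    @property
    def total(self) -> int:
        return self.exact + self.overlap + self.unmatched

    @property
    def exact_fraction(self) -> float:
        return self.exact / self.total if self.total else float("nan")


def match_calls(set_a: Sequence[CNVCall], set_b: Sequence[CNVCall]) -> MatchReport:
    """Classify each call in ``set_a`` against ``set_b``."""
    by_sample_type: dict[tuple[str, str], list[CNVCall]] = {}
    for c in set_b:
        by_sample_type.setdefault((c.sample, c.type), []).append(c)
    exact_pairs, overlap_pairs, unmatched = [], [], []
    target_differences: list[int] = []
    for a in set_a:
        candidates = by_sample_type.get((a.sample, a.type), [])
        exact = next(
            (b for b in candidates if a.interval.same_span(b.interval)), None
        )
        if exact is not None:
            exact_pairs.append((a, exact))
            continue
        overlapping = [b for b in candidates if a.overlaps(b)]
        if overlapping:
            best = max(
                overlapping,
                key=lambda b: min(a.interval.stop, b.interval.stop)
                - max(a.interval.start, b.interval.start),
            )
            overlap_pairs.append((a, best))
            target_differences.append(abs(a.num_targets - best.num_targets))
        else:
            unmatched.append(a)
    return MatchReport(
        exact=len(exact_pairs),
        overlap=len(overlap_pairs),
        unmatched=len(unmatched),
        target_differences=target_differences,
        exact_pairs=exact_pairs,
        overlap_pairs=overlap_pairs,
        unmatched_calls=unmatched,
    )
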