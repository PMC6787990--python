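"""Synthetic WES cohorts and SAM fixtures with known ground truth.

The cohort generator emulates the structure the normalization stage is
built to remove: a per-target baseline capture efficiency, a per-sample
sequencing-depth scale, low-rank multiplicative batch effects, counting
noise, and embedded multi-target deletions/duplications at copy-ratio
factors 0.5 (heterozygous loss) and 1.5 (heterozygous gain)::

    depth(s, t) = noise( base_t * scale_s * bias(s, t) * cnv_factor(s, t) )

Batch effects are rank-``r`` outer products with orthonormalized factors,
so the systematic part of the spectrum is designed and the rank-selection
step can be tested against a known ground truth.  Poisson noise on the
per-target base count (mean depth x target length) is the default depth
model; its mean-variance coupling resembles real exome coverage.

Everything is driven by one integer seed through a generator-splitting
scheme (``numpy.random.SeedSequence.spawn``), so identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .discovery import CNVCall, discover, match_calls
from .hmm import HMMParameters
from .intervals import TargetInterval
from .matrix import ReadDepthMatrix
from .normalization import FilterThresholds, RankSelection, normalize_matrix

__all__ = [
    "CNVSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "random_cnv_specs",
    "simulate_sam_fixture",
    "overlapping_mates_fixture",
    "recovery_experiment",
    "RecoveryReport",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CNVSpec:
    """One embedded CNV: which sample, which targets, what copy ratio."""

    sample_index: int
    first_target: int
    num_targets: int
    factor: float  # 0.5 het deletion, 1.5 het duplication

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise SimulationError("CNV factor must be positive")
        if self.num_targets < 1:
            raise SimulationError("CNV must span at least one target")

    @property
    def last_target(self) -> int:
        return self.first_target + self.num_targets - 1

    @property
    def type(self) -> str:
        return "DEL" if self.factor < 1.0 else "DUP"


@dataclass
class SimulationConfig:
    """Cohort generator settings (defaults are the package's study conditions).

    30 samples x 500 targets over two chromosomes, per-target baseline
    depth U(80, 160), per-sample scale U(0.9, 1.1), rank-3 batch effects
    of strength 0.1 (relative), Poisson counting noise.
    """

    n_samples: int = 30
    n_targets: int = 500
    n_chromosomes: int = 2
    target_length_range: tuple[int, int] = (120, 300)
    target_gap_range: tuple[int, int] = (200, 2_000)
    mean_depth_range: tuple[float, float] = (80.0, 160.0)
    sample_scale_range: tuple[float, float] = (0.9, 1.1)
    batch_rank: int = 3
    batch_strength: float = 0.1
    noise_model: str = "poisson"  # poisson | gaussian | none
    gaussian_sd: float = 1.0
    cnv_specs: list[CNVSpec] = field(default_factory=list)
    # planted violations for filter tests
    length_violation_targets: tuple[int, ...] = ()
    gc_violation_targets: tuple[int, ...] = ()
    complexity_violation_targets: tuple[int, ...] = ()
    outlier_samples: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_targets < 1:
            raise SimulationError("sample and target counts must be positive")
        if self.batch_rank < 0 or self.batch_strength < 0:
            raise SimulationError("batch rank/strength must be non-negative")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise SimulationError(f"unknown noise model {self.noise_model!r}")
        for spec in self.cnv_specs:
            if spec.sample_index >= self.n_samples:
                raise SimulationError(f"CNV sample index {spec.sample_index} out of range")
            if spec.last_target >= self.n_targets:
                raise SimulationError(
                    f"CNV targets [{spec.first_target}, {spec.last_target}] "
                    f"outside matrix with {self.n_targets} targets"
                )


@dataclass
class SyntheticTruth:
    """Ground-truth table of embedded CNVs plus the noiseless matrix."""

    specs: list[CNVSpec]
    samples: list[str]
    targets: list[TargetInterval]
    expected_depths: np.ndarray  # noiseless s x t matrix

    def to_calls(self) -> list[CNVCall]:
        """Truth rows as CNVCall records (qualities set to 99)."""
        calls = []
        for spec in self.specs:
            first, last = spec.first_target, spec.last_target
            calls.append(
                CNVCall(
                    sample=self.samples[spec.sample_index],
                    type=spec.type,
                    interval=TargetInterval(
                        chrom=self.targets[first].chrom,
                        start=self.targets[first].start,
                        stop=self.targets[last].stop,
                    ),
                    first_target_index=first,
                    last_target_index=last,
                    q_exact=99,
                    q_some=99,
                    q_non_diploid=99,
                    q_start=99,
                    q_stop=99,
                    mean_rd=float("nan"),
                    mean_orig_rd=float("nan"),
                )
            )
        return calls

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("sample\tinterval\ttype\tfactor\tfirst_target\tlast_target\n")
            for spec, call in zip(self.specs, self.to_calls()):
                handle.write(
                    f"{call.sample}\t{call.interval.name}\t{spec.type}\t"
                    f"{spec.factor}\t{spec.first_target}\t{spec.last_target}\n"
                )


def _make_targets(config: SimulationConfig, rng: np.random.Generator):
    per_chrom = np.array_split(np.arange(config.n_targets), config.n_chromosomes)
    targets: list[TargetInterval] = []
    lo_len, hi_len = config.target_length_range
    lo_gap, hi_gap = config.target_gap_range
    for c, idxs in enumerate(per_chrom, start=1):
        pos = 10_001
        for j in idxs:
            length = int(rng.integers(lo_len, hi_len + 1))
            if j in config.length_violation_targets:
                length = 5  # below the protocol's 10 bp floor
            gc = float(rng.uniform(0.35, 0.65))
            if j in config.gc_violation_targets:
                gc = 0.95
            complexity = float(rng.uniform(0.0, 0.05))
            if j in config.complexity_violation_targets:
                complexity = 0.60
            targets.append(
                TargetInterval(
                    chrom=str(c),
                    start=pos,
                    stop=pos + length - 1,
                    gc_fraction=gc,
                    complexity_fraction=complexity,
                )
            )
            pos += length + int(rng.integers(lo_gap, hi_gap + 1))
    return targets


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ReadDepthMatrix, SyntheticTruth]:
    """Generate a cohort read-depth matrix with known embedded structure."""
    root = np.random.SeedSequence(config.seed)
    rng_targets, rng_base, rng_batch, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    targets = _make_targets(config, rng_targets)
    s, t = config.n_samples, config.n_targets

    base = rng_base.uniform(*config.mean_depth_range, size=t)
    scale = rng_base.uniform(*config.sample_scale_range, size=s)
    for i in config.outlier_samples:
        scale[i] = 0.1  # drives the sample mean far below the filter floor

    bias = np.ones((s, t))
    if config.batch_rank > 0 and config.batch_strength > 0:
        U, _ = np.linalg.qr(rng_batch.standard_normal((s, config.batch_rank)))
        W, _ = np.linalg.qr(rng_batch.standard_normal((t, config.batch_rank)))
        # Rescale orthonormal columns to unit per-entry variance.
        bias = bias + config.batch_strength * (
            (U * np.sqrt(s)) @ (W * np.sqrt(t)).T
        )
        bias = np.clip(bias, 0.05, None)

    cnv_factor = np.ones((s, t))
    for spec in config.cnv_specs:
        cnv_factor[spec.sample_index, spec.first_target : spec.last_target + 1] *= (
            spec.factor
        )

    expected = base[None, :] * scale[:, None] * bias * cnv_factor
    lengths = np.array([tg.length for tg in targets], dtype=np.float64)
    if config.noise_model == "poisson":
        depths = rng_noise.poisson(expected * lengths[None, :]) / lengths[None, :]
    elif config.noise_model == "gaussian":
        depths = np.clip(
            expected + rng_noise.normal(0.0, config.gaussian_sd, size=expected.shape),
            0.0,
            None,
        )
    else:
        depths = expected.copy()

    samples = [f"SYN{i:03d}" for i in range(s)]
    matrix = ReadDepthMatrix(samples=samples, targets=targets, depths=depths)
    truth = SyntheticTruth(
        specs=list(config.cnv_specs),
        samples=samples,
        targets=targets,
        expected_depths=expected,
    )
    return matrix, truth


def random_cnv_specs(
    n_cnvs: int,
    n_samples: int,
    n_targets: int,
    rng: np.random.Generator,
    num_targets_range: tuple[int, int] = (5, 8),
    factors: Sequence[float] = (0.5, 1.5),
    edge_margin: int = 3,
    min_gap: int = 3,
) -> list[CNVSpec]:
    """Draw non-overlapping CNV specs away from the target-list edges."""
    specs: list[CNVSpec] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    attempts = 0
    while len(specs) < n_cnvs:
        attempts += 1
        if attempts > 100 * n_cnvs:
            raise SimulationError("could not place the requested CNVs without overlap")
        sample = int(rng.integers(0, n_samples))
        width = int(rng.integers(num_targets_range[0], num_targets_range[1] + 1))
        first = int(rng.integers(edge_margin, n_targets - width - edge_margin))
        last = first + width - 1
        taken = occupied.setdefault(sample, [])
        if any(first <= b + min_gap and a - min_gap <= last for a, b in taken):
            continue
        taken.append((first, last))
        specs.append(
            CNVSpec(
                sample_index=sample,
                first_target=first,
                num_targets=width,
                factor=float(factors[int(rng.integers(0, len(factors)))]),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# SAM fixtures with analytically known coverage


@dataclass
class SamFixture:
    """SAM text plus the expected per-target mean depth (default filters)."""

    sam_text: str
    sample: str
    expected_fragment: np.ndarray
    expected_read: np.ndarray


def _sam_header(targets: Sequence[TargetInterval], sample: str) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    seen = []
    for t in targets:
        if t.chrom not in seen:
            seen.append(t.chrom)
    max_stop = {c: max(t.stop for t in targets if t.chrom == c) for c in seen}
    for c in seen:
        lines.append(f"@SQ\tSN:{c}\tLN:{max_stop[c] + 10_000}")
    lines.append(f"@RG\tID:rg0\tSM:{sample}")
    return lines


def _read_line(
    name: str,
    chrom: str,
    pos: int,
    cigar: str,
    seq_len: int,
    mapq: int = 60,
    flag: int = 0,
) -> str:
    return "\t".join(
        [
            name,
            str(flag),
            chrom,
            str(pos),
            str(mapq),
            cigar,
            "*",
            "0",
            "0",
            "A" * seq_len,
            "*",
            "RG:Z:rg0",
        ]
    )


def simulate_sam_fixture(
    targets: Sequence[TargetInterval],
    per_target_depths: Sequence[int],
    read_length: int = 100,
    sample: str = "FIX0",
    add_mapq0: bool = False,
    add_duplicates: bool = False,
) -> SamFixture:
    """Build a SAM file whose per-target mean depth is exactly as requested.

    Each depth unit is one tiling layer of reads across the target; the
    final read of a layer is soft-clipped so aligned bases end exactly at
    the target's last base (no bleed into neighbouring targets).  Depths
    must be non-negative integers; anything else is an error.  Optional
    MAPQ-0 and duplicate-flagged reads are added on top — they are
    invisible under the default filters, so the expectation is unchanged.
    """
    if len(per_target_depths) != len(targets):
        raise SimulationError("one integer depth per target is required")
    reads: list[tuple[str, int, str]] = []  # (chrom, pos, line) for sorting
    serial = 0
    for t, depth in zip(targets, per_target_depths):
        if depth != int(depth) or depth < 0:
            raise SimulationError(
                f"depth {depth} on {t.name} is not achievable by read tiling"
            )
        for layer in range(int(depth)):
            pos = t.start
            while pos <= t.stop:
                aligned = min(read_length, t.stop - pos + 1)
                cigar = (
                    f"{read_length}M"
                    if aligned == read_length
                    else f"{aligned}M{read_length - aligned}S"
                )
                reads.append(
                    (
                        t.chrom,
                        pos,
                        _read_line(f"r{serial:05d}", t.chrom, pos, cigar, read_length),
                    )
                )
                serial += 1
                pos += aligned
        if add_mapq0:
            aligned = min(read_length, t.length)
            cigar = (
                f"{read_length}M"
                if aligned == read_length
                else f"{aligned}M{read_length - aligned}S"
            )
            reads.append(
                (
                    t.chrom,
                    t.start,
                    _read_line(
                        f"r{serial:05d}", t.chrom, t.start, cigar, read_length, mapq=0
                    ),
                )
            )
            serial += 1
        if add_duplicates:
            aligned = min(read_length, t.length)
            cigar = (
                f"{read_length}M"
                if aligned == read_length
                else f"{aligned}M{read_length - aligned}S"
            )
            reads.append(
                (
                    t.chrom,
                    t.start,
                    _read_line(
                        f"r{serial:05d}",
                        t.chrom,
                        t.start,
                        cigar,
                        read_length,
                        flag=1024,
                    ),
                )
            )
            serial += 1
    chrom_order = {t.chrom: i for i, t in enumerate(targets)}
    reads.sort(key=lambda r: (chrom_order[r[0]], r[1]))
    lines = _sam_header(targets, sample) + [line for _, _, line in reads]
    expected = np.array([float(d) for d in per_target_depths])
    return SamFixture(
        sam_text="\n".join(lines) + "\n",
        sample=sample,
        expected_fragment=expected,
        expected_read=expected.copy(),
    )


def overlapping_mates_fixture(sample: str = "FIX0") -> tuple[SamFixture, TargetInterval]:
    """A proper pair with mates [1-100] and [51-150] over a 150 bp target.

    Bases 51-100 are covered by both mates: fragment-mode depth counts
    them once (mean 1.0) while read-mode counts twice (mean 200/150).
    """
    target = TargetInterval(chrom="1", start=1, stop=150)
    header = _sam_header([target], sample)
    read1 = "\t".join(
        ["frag0", "99", "1", "1", "60", "100M", "=", "51", "150",
         "A" * 100, "*", "RG:Z:rg0"]
    )
    read2 = "\t".join(
        ["frag0", "147", "1", "51", "60", "100M", "=", "1", "-150",
         "A" * 100, "*", "RG:Z:rg0"]
    )
    fixture = SamFixture(
        sam_text="\n".join(header + [read1, read2]) + "\n",
        sample=sample,
        expected_fragment=np.array([1.0]),
        expected_read=np.array([200.0 / 150.0]),
    )
    return fixture, target


# ---------------------------------------------------------------------------
# End-to-end recovery harness


@dataclass
class RecoveryReport:
    """How well the full pipeline recovers embedded CNVs."""

    n_true: int
    n_detected: int
    detection_rate: float
    breakpoint_errors: list[int]
    false_calls: int
    n_calls: int
    K: int
    n_detected_no_pca: int
    detection_rate_no_pca: float

    @property
    def max_breakpoint_error(self) -> int:
        return max(self.breakpoint_errors) if self.breakpoint_errors else 0


def _detection(
    calls: list[CNVCall], truth: SyntheticTruth
) -> tuple[int, list[int], int]:
    """Overlap-match truth against calls; returns (hits, bp errors, false)."""
    truth_calls = truth.to_calls()
    report = match_calls(truth_calls, calls)
    hits = report.exact + report.overlap
    errors: list[int] = []
    for true_call, found in report.exact_pairs + report.overlap_pairs:
        # Map the found call's span back to original target indices.
        covered = [
            j
            for j, t in enumerate(truth.targets)
            if t.chrom == found.interval.chrom
            and t.start >= found.interval.start
            and t.stop <= found.interval.stop
        ]
        errors.append(
            max(
                abs(covered[0] - true_call.first_target_index),
                abs(covered[-1] - true_call.last_target_index),
            )
        )
    reverse = match_calls(calls, truth_calls)
    return hits, errors, reverse.unmatched


def recovery_experiment(
    config: SimulationConfig,
    params: HMMParameters = HMMParameters(),
    thresholds: FilterThresholds = FilterThresholds(),
    settings: RankSelection = RankSelection(K=0),
) -> RecoveryReport:
    """Simulate, normalize, discover, and score recovery of the truth.

    Runs the pipeline twice — with PCA normalization and with the PCA
    step skipped — to quantify what removing the systematic components
    buys in detection rate.
    """
    if config.n_samples < 2 or not config.cnv_specs:
        raise SimulationError("recovery experiment needs >= 2 samples and CNVs")
    matrix, truth = simulate_cohort(config)

    result = normalize_matrix(matrix, thresholds, settings)
    calls = discover(result.zscores, result.original, params)
    hits, errors, false_calls = _detection(calls, truth)

    result_raw = normalize_matrix(matrix, thresholds, skip_pca=True)
    calls_raw = discover(result_raw.zscores, result_raw.original, params)
    hits_raw, _, _ = _detection(calls_raw, truth)

    n_true = len(truth.specs)
    return RecoveryReport(
        n_true=n_true,
        n_detected=hits,
        detection_rate=hits / n_true,
        breakpoint_errors=errors,
        false_calls=false_calls,
        n_calls=len(calls),
        K=result.selection.K,
        n_detected_no_pca=hits_raw,
        detection_rate_no_pca=hits_raw / n_true,
    )
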