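"""Read-depth normalization: filtering, centering, PCA-denoising, z-scoring.

Systematic biases (capture batch, GC, sequencing depth) dominate the
variance of a WES read-depth matrix and must be removed before a
copy-number signal of ~50% is visible.  Following the XHMM approach, the
matrix is target-centered and the top ``K`` principal components are
subtracted, where ``K`` counts the components whose variance
``v_i = sigma_i^2`` satisfies the relative-variance rule::

    v_i >= c * (sum_j v_j) / n        (c = 0.7 by default)

Computing the full SVD of a large cohort only to pick ``K`` is wasteful:
in practice ``K << n``.  :func:`determine_K` instead runs a truncated SVD
of ``k`` components and brackets the unknown total variance between

* an over-estimate  ``sum_{i<=k} v_i + (n-k-1) * v_k``  (the tail can be
  no larger than ``v_k`` per component, and a centered matrix has at most
  ``n-1`` informative components), and
* an under-estimate ``sum_{i<=k} v_i``                  (tail assumed 0).

``K`` is counted against the cutoff from the over-estimate.  If the first
retained component falls below the cutoff from the under-estimate, no
component beyond ``K`` can pass the true cutoff and the answer is
certified exact; otherwise ``k`` is grown and the SVD recomputed.  The
certified ``K`` always equals the full-spectrum rule's ``K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
import scipy.sparse.linalg

from .matrix import ReadDepthMatrix

__all__ = [
    "FilterThresholds",
    "SVDSpectrum",
    "RankSelection",
    "ExclusionReport",
    "filter_targets_pre",
    "filter_samples",
    "center_targets",
    "truncated_svd",
    "determine_K",
    "pca_normalize",
    "filter_targets_post",
    "zscore_samples",
    "normalize_matrix",
]


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterThresholds:
    """XHMM-protocol filtering thresholds (all user-settable).

    Units: target lengths in bp, depths in mean per-base coverage,
    GC/complexity as fractions, post-normalization SD in the normalized
    matrix's own units.
    """

    min_target_length: float = 10.0
    max_target_length: float = 10_000.0
    min_target_mean_rd: float = 10.0
    max_target_mean_rd: float = 500.0
    min_sample_mean_rd: float = 25.0
    max_sample_mean_rd: float = 200.0
    max_sample_sd_rd: float = 150.0
    min_gc: float = 0.1
    max_gc: float = 0.9
    max_complexity: float = 0.25
    max_target_sd_post: float = 30.0

    def __post_init__(self) -> None:
        pairs = [
            ("min_target_length", "max_target_length"),
            ("min_target_mean_rd", "max_target_mean_rd"),
            ("min_sample_mean_rd", "max_sample_mean_rd"),
            ("min_gc", "max_gc"),
        ]
        for lo, hi in pairs:
            if getattr(self, lo) > getattr(self, hi):
                raise NormalizationError(f"{lo} > {hi}")
        for name in self.__dataclass_fields__:
            if not math.isfinite(getattr(self, name)):
                raise NormalizationError(f"{name} must be finite")


@dataclass
class ExclusionReport:
    """Identifiers removed by a filter, with the rule(s) that fired."""

    kind: str  # "target" or "sample"
    excluded: dict[str, list[str]] = field(default_factory=dict)

    def add(self, identifier: str, reason: str) -> None:
        self.excluded.setdefault(identifier, []).append(reason)

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(f"{self.kind}\treasons\n")
            for identifier, reasons in self.excluded.items():
                handle.write(f"{identifier}\t{','.join(reasons)}\n")

    def __len__(self) -> int:
        return len(self.excluded)


@dataclass
class SVDSpectrum:
    """Top-``k`` singular variances of a centered matrix.

    ``variances[i] = sigma_{i+1}^2``, non-increasing; ``n`` is the number
    of candidate components of the full decomposition.
    """

    variances: np.ndarray
    k: int
    n: int

    def __post_init__(self) -> None:
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if self.k != len(self.variances):
            raise NormalizationError("k must equal len(variances)")
        if self.k > self.n:
            raise NormalizationError("k exceeds candidate component count n")
        if np.any(self.variances < -1e-9):
            raise NormalizationError("negative variance in spectrum")
        if np.any(np.diff(self.variances) > 1e-9 * max(1.0, self.variances[0])):
            raise NormalizationError("variances must be non-increasing")


@dataclass
class RankSelection:
    """Result of the iterative rank-selection procedure.

    ``K`` components will be removed; ``certified`` records that the
    over/under bracket closed (always true on return).  ``k_used`` is the
    number of components actually computed.
    """

    K: int
    variance_coefficient: float = 0.7
    initial_k_fraction: float = 0.1
    over_estimate: float = float("nan")
    under_estimate: float = float("nan")
    certified: bool = False
    k_used: int = 0
    n: int = 0
    iterations: int = 0


@dataclass
class SVDBasis:
    """Left/right singular vectors paired with an :class:`SVDSpectrum`."""

    U: np.ndarray  # s x k
    singular_values: np.ndarray  # k
    Vt: np.ndarray  # k x t


def filter_targets_pre(
    matrix: ReadDepthMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[ReadDepthMatrix, ExclusionReport]:
    """Drop targets with extreme length, mean depth, GC or low complexity.

    GC/complexity rules only fire for targets that carry the annotation.
    """
    report = ExclusionReport(kind="target")
    keep = []
    means = matrix.depths.mean(axis=0) if matrix.n_samples else np.zeros(
        matrix.n_targets
    )
    for j, t in enumerate(matrix.targets):
        reasons = []
        if not (thresholds.min_target_length <= t.length <= thresholds.max_target_length):
            reasons.append("length")
        if matrix.n_samples and not (
            thresholds.min_target_mean_rd <= means[j] <= thresholds.max_target_mean_rd
        ):
            reasons.append("mean_rd")
        if t.gc_fraction is not None and not (
            thresholds.min_gc <= t.gc_fraction <= thresholds.max_gc
        ):
            reasons.append("gc")
        if (
            t.complexity_fraction is not None
            and t.complexity_fraction > thresholds.max_complexity
        ):
            reasons.append("complexity")
        if reasons:
            for r in reasons:
                report.add(t.name, r)
        else:
            keep.append(j)
    if not keep:
        raise NormalizationError("all targets excluded by pre-filters")
    return matrix.subset(target_idx=keep), report


def filter_samples(
    matrix: ReadDepthMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[ReadDepthMatrix, ExclusionReport]:
    """Drop samples whose mean or SD of depth is out of range."""
    report = ExclusionReport(kind="sample")
    keep = []
    means = matrix.depths.mean(axis=1)
    sds = matrix.depths.std(axis=1, ddof=1) if matrix.n_targets > 1 else np.zeros(
        matrix.n_samples
    )
    for i, sample in enumerate(matrix.samples):
        reasons = []
        if not (
            thresholds.min_sample_mean_rd <= means[i] <= thresholds.max_sample_mean_rd
        ):
            reasons.append("mean_rd")
        if sds[i] > thresholds.max_sample_sd_rd:
            reasons.append("sd_rd")
        if reasons:
            for r in reasons:
                report.add(sample, r)
        else:
            keep.append(i)
    if not keep:
        raise NormalizationError("all samples excluded by sample filters")
    return matrix.subset(sample_idx=keep), report


def center_targets(matrix: ReadDepthMatrix) -> ReadDepthMatrix:
    """Subtract each target's cross-sample mean (column centering)."""
    if matrix.n_samples < 2:
        raise NormalizationError("centering requires at least 2 samples")
    centered = matrix.depths - matrix.depths.mean(axis=0, keepdims=True)
    return matrix.copy_with(centered, require_nonnegative=False)


def _deterministic_v0(dim: int) -> np.ndarray:
    # Fixed ARPACK start vector so repeated runs are bit-identical.
    rng = np.random.default_rng(0)
    return rng.standard_normal(dim)


def truncated_svd(
    centered: ReadDepthMatrix | np.ndarray, k: int
) -> tuple[SVDSpectrum, SVDBasis]:
    """Top-``k`` singular triples of the centered matrix.

    Variances are squared singular values in non-increasing order.  Uses
    ARPACK for ``k`` well below ``min(s, t)`` and LAPACK otherwise; both
    paths are deterministic.
    """
    X = centered.depths if isinstance(centered, ReadDepthMatrix) else np.asarray(
        centered, dtype=np.float64
    )
    s, t = X.shape
    rank_bound = min(s, t)
    if not 1 <= k <= rank_bound:
        raise NormalizationError(f"k={k} outside [1, {rank_bound}]")
    use_arpack = k <= rank_bound - 2 and np.any(X != 0)
    if use_arpack:
        try:
            U, sv, Vt = scipy.sparse.linalg.svds(
                X, k=k, v0=_deterministic_v0(min(s, t)), maxiter=10_000
            )
            order = np.argsort(sv)[::-1]
            U, sv, Vt = U[:, order], sv[order], Vt[order, :]
        except scipy.sparse.linalg.ArpackError:
            use_arpack = False  # degenerate spectra: use the dense path
    if not use_arpack:
        U, sv, Vt = np.linalg.svd(X, full_matrices=False)
        U, sv, Vt = U[:, :k], sv[:k], Vt[:k, :]
    spectrum = SVDSpectrum(variances=sv**2, k=k, n=rank_bound)
    return spectrum, SVDBasis(U=U, singular_values=sv, Vt=Vt)


def count_above_cutoff(variances: np.ndarray, cutoff: float) -> int:
    """Number of leading variances ``>= cutoff`` (ties are removed)."""
    return int(np.sum(variances >= cutoff))


def determine_K(
    centered: ReadDepthMatrix | np.ndarray,
    settings: RankSelection = RankSelection(K=0),
    return_basis: bool = False,
) -> RankSelection | tuple[RankSelection, SVDBasis]:
    """Choose ``K`` components to remove via iterative truncated SVD.

    Starting from ``k = ceil(initial_k_fraction * n)`` the truncated
    spectrum brackets the total variance between the over- and
    under-estimates described in the module docstring.  When the bracket
    certifies ``K``, iteration stops; otherwise ``k`` doubles (geometric
    growth bounds the number of SVD recomputations).  At ``k = n - 1`` the
    over-estimate collapses onto the exact total for a centered matrix, so
    termination with a certified — hence exact — ``K`` is guaranteed; as a
    belt-and-braces fallback an uncertified final iteration is resolved
    against the full spectrum directly.
    """
    X = centered.depths if isinstance(centered, ReadDepthMatrix) else np.asarray(
        centered, dtype=np.float64
    )
    s, t = X.shape
    n = min(s, t)
    if n < 2:
        raise NormalizationError("rank selection requires min(s, t) >= 2")
    coeff = settings.variance_coefficient
    k_max = n - 1
    k = max(1, min(k_max, math.ceil(settings.initial_k_fraction * n)))
    iterations = 0
    while True:
        iterations += 1
        spectrum, basis = truncated_svd(X, k)
        v = spectrum.variances
        if not np.all(np.isfinite(v)):
            raise NormalizationError("non-finite variance in SVD spectrum")
        under = float(v.sum())
        over = under + (n - k - 1) * float(v[-1])
        cutoff_over = coeff * over / n
        cutoff_under = coeff * under / n
        K = count_above_cutoff(v, cutoff_over)
        certified = K < k and v[K] < cutoff_under
        if certified or k >= k_max:
            break
        k = min(2 * k, k_max)
    if not certified:
        # Exact full-spectrum resolution (k_max reached without a closed
        # bracket; possible only for pathological near-flat spectra).
        sv = np.linalg.svd(X, compute_uv=False)
        v_full = sv**2
        cutoff = coeff * float(v_full.sum()) / n
        K = count_above_cutoff(v_full, cutoff)
        under = over = float(v_full.sum())
        certified = True
        if K > k:
            spectrum, basis = truncated_svd(X, K)
    selection = replace(
        settings,
        K=K,
        over_estimate=over,
        under_estimate=under,
        certified=certified,
        k_used=spectrum.k,
        n=n,
        iterations=iterations,
    )
    return (selection, basis) if return_basis else selection


def pca_normalize(
    centered: ReadDepthMatrix,
    selection: RankSelection,
    basis: SVDBasis,
) -> ReadDepthMatrix:
    """Subtract the rank-``K`` reconstruction from the centered matrix.

    With SVD ``X = U S V^T``, the output is
    ``X - U[:, :K] diag(S[:K]) V[:K, :]``; its projection onto every
    removed right-singular vector is ~0.
    """
    K = selection.K
    if not selection.certified:
        raise NormalizationError("rank selection is not certified")
    if K > basis.Vt.shape[0]:
        raise NormalizationError(
            f"K={K} exceeds the {basis.Vt.shape[0]} available components"
        )
    if K == 0:
        return centered.copy_with(centered.depths.copy(), require_nonnegative=False)
    low_rank = (basis.U[:, :K] * basis.singular_values[:K]) @ basis.Vt[:K, :]
    return centered.copy_with(centered.depths - low_rank, require_nonnegative=False)


def filter_targets_post(
    matrix: ReadDepthMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[ReadDepthMatrix, ExclusionReport]:
    """Drop targets still hyper-variable after PCA normalization."""
    report = ExclusionReport(kind="target")
    sds = matrix.depths.std(axis=0, ddof=1) if matrix.n_samples > 1 else np.zeros(
        matrix.n_targets
    )
    keep = []
    for j, t in enumerate(matrix.targets):
        if sds[j] > thresholds.max_target_sd_post:
            report.add(t.name, "sd_post")
        else:
            keep.append(j)
    if not keep:
        raise NormalizationError("all targets excluded by post-normalization filter")
    return matrix.subset(target_idx=keep), report


def zscore_samples(matrix: ReadDepthMatrix) -> ReadDepthMatrix:
    """Standardize each sample row: ``(x - row mean) / row SD`` (ddof=1)."""
    if matrix.n_targets < 2:
        raise NormalizationError("z-scoring requires at least 2 targets")
    means = matrix.depths.mean(axis=1, keepdims=True)
    sds = matrix.depths.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sds.ravel() == 0)
    if zero.size:
        raise NormalizationError(
            f"zero depth SD for sample(s): "
            f"{', '.join(matrix.samples[i] for i in zero)}"
        )
    return matrix.copy_with((matrix.depths - means) / sds, require_nonnegative=False)


@dataclass
class NormalizationResult:
    """Everything the discovery stage needs, plus provenance reports."""

    zscores: ReadDepthMatrix
    original: ReadDepthMatrix  # raw depths on the final sample/target set
    selection: RankSelection
    target_report_pre: ExclusionReport
    sample_report: ExclusionReport
    target_report_post: ExclusionReport


def normalize_matrix(
    matrix: ReadDepthMatrix,
    thresholds: FilterThresholds = FilterThresholds(),
    settings: RankSelection = RankSelection(K=0),
    skip_pca: bool = False,
) -> NormalizationResult:
    """The full normalization chain on a raw read-depth matrix.

    filter targets -> filter samples -> center -> rank-select & remove K
    components -> post-filter hyper-variable targets -> z-score rows.
    ``skip_pca=True`` runs the same chain with zero components removed,
    which is useful for quantifying what the PCA step buys.
    """
    filtered, report_pre = filter_targets_pre(matrix, thresholds)
    filtered, report_samples = filter_samples(filtered, thresholds)
    centered = center_targets(filtered)
    if skip_pca:
        selection = RankSelection(
            K=0, certified=True, n=min(centered.n_samples, centered.n_targets)
        )
        normalized = centered
    else:
        selection, basis = determine_K(centered, settings, return_basis=True)
        normalized = pca_normalize(centered, selection, basis)
    normalized, report_post = filter_targets_post(normalized, thresholds)
    zscores = zscore_samples(normalized)
    # Align the raw matrix onto the surviving samples/targets for reporting.
    sample_idx = [matrix.samples.index(s) for s in zscores.samples]
    name_to_col = {t.name: j for j, t in enumerate(matrix.targets)}
    target_idx = [name_to_col[t.name] for t in zscores.targets]
    original = matrix.subset(sample_idx=sample_idx, target_idx=target_idx)
    return NormalizationResult(
        zscores=zscores,
        original=original,
        selection=selection,
        target_report_pre=report_pre,
        sample_report=report_samples,
        target_report_post=report_post,
    )
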