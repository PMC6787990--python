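"""Independent brute-force oracles used across the test suite.

These deliberately share no code with the package implementation: the
rank rule is applied to a full LAPACK spectrum, HMM quantities come from
exhaustive path enumeration, and coverage from a literal per-base tally.
"""

from __future__ import annotations

import itertools

import numpy as np
import pysam
from scipy.special import logsumexp

from exocnv.intervals import TargetInterval


# --- rank selection -------------------------------------------------------


def full_spectrum_K(X: np.ndarray, coefficient: float = 0.7) -> int:
    """Apply the relative-variance rule to the complete singular spectrum."""
    sv = np.linalg.svd(np.asarray(X, dtype=np.float64), compute_uv=False)
    v = sv**2
    n = min(X.shape)
    cutoff = coefficient * v.sum() / n
    return int(np.sum(v >= cutoff))


def matrix_with_spectrum(
    s: int, t: int, singular_values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random-orientation matrix with the given singular values."""
    r = len(singular_values)
    U, _ = np.linalg.qr(rng.standard_normal((s, r)))
    V, _ = np.linalg.qr(rng.standard_normal((t, r)))
    return (U * singular_values) @ V.T


def random_designed_spectrum(
    kind: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Spectra of three shapes: geometric decay, near-flat, mixed."""
    if kind == "steep":
        return 100.0 * (0.6 ** np.arange(n)) * rng.uniform(0.8, 1.2, n)
    if kind == "flat":
        return np.sort(rng.uniform(0.9, 1.1, n))[::-1]
    if kind == "mixed":
        head = 50.0 * (0.5 ** np.arange(max(1, n // 10)))
        tail = rng.uniform(0.5, 1.5, n - len(head))
        return np.sort(np.concatenate([head, tail]))[::-1]
    raise ValueError(kind)


# --- HMM path enumeration -------------------------------------------------


def chain_logscores(z, targets, params) -> tuple[np.ndarray, np.ndarray]:
    """(paths, log joint scores) over all 3^T state paths (vectorized)."""
    from exocnv.hmm import emission_logdensity, transition_matrix
    from exocnv.intervals import inter_target_distances

    T = len(z)
    log_e = np.array(
        [[float(emission_logdensity(zz, s, params)) for s in range(3)] for zz in z]
    )
    log_t = np.array(
        [
            np.log(transition_matrix(d, params))
            for d in inter_target_distances(targets, mode=params.distance_mode)
        ]
    )
    log_pi = np.log(params.initial_distribution)
    paths = np.array(list(itertools.product(range(3), repeat=T)), dtype=np.intp)
    scores = log_pi[paths[:, 0]] + log_e[0, paths[:, 0]]
    for t in range(1, T):
        scores = scores + log_t[t - 1, paths[:, t - 1], paths[:, t]]
        scores = scores + log_e[t, paths[:, t]]
    return paths, scores


def enumerate_viterbi(z, targets, params) -> tuple[np.ndarray, float]:
    paths, scores = chain_logscores(z, targets, params)
    best = int(np.argmax(scores))
    return paths[best], float(scores[best])


def enumerate_loglikelihood(z, targets, params) -> float:
    _, scores = chain_logscores(z, targets, params)
    return float(logsumexp(scores))


def enumerate_call_probabilities(z, targets, params, state, first, last):
    """The five call-quality probabilities by (vectorized) path enumeration."""
    T = len(targets)
    left = first - 1 if first > 0 and targets[first - 1].chrom == targets[first].chrom else None
    right = last + 1 if last + 1 < T and targets[last + 1].chrom == targets[last].chrom else None
    paths, scores = chain_logscores(z, targets, params)
    total = logsumexp(scores)
    seg = paths[:, first : last + 1]
    left_ok = np.ones(len(paths), bool) if left is None else paths[:, left] != state
    right_ok = np.ones(len(paths), bool) if right is None else paths[:, right] != state
    masks = {
        "some": (seg == state).any(axis=1),
        "non_diploid": (seg != 1).any(axis=1),
        "exact": (seg == state).all(axis=1) & left_ok & right_ok,
        "start": (paths[:, first] == state) & left_ok,
        "stop": (paths[:, last] == state) & right_ok,
    }
    return {
        key: (float(np.exp(logsumexp(scores[m]) - total)) if m.any() else 0.0)
        for key, m in masks.items()
    }


def logsumexp_forward(z, targets, params) -> float:
    """Log-space (log-sum-exp) forward recursion, independent of scaling."""
    from exocnv.hmm import emission_logdensity, transition_matrix
    from exocnv.intervals import inter_target_distances

    log_e = np.array(
        [[float(emission_logdensity(zz, s, params)) for s in range(3)] for zz in z]
    )
    a = np.log(params.initial_distribution) + log_e[0]
    for t, d in enumerate(inter_target_distances(targets, mode=params.distance_mode)):
        log_t = np.log(transition_matrix(d, params))
        a = logsumexp(a[:, None] + log_t, axis=0) + log_e[t + 1]
    return float(logsumexp(a))


def make_chain_targets(
    T: int, rng: np.random.Generator, allow_breaks: bool = True
) -> list[TargetInterval]:
    """Random targets with mixed spacings, including abutting and breaks."""
    targets = []
    chrom, pos = 1, 1
    for i in range(T):
        if allow_breaks and i > 0 and rng.random() < 0.15:
            chrom += 1
            pos = 1
        length = int(rng.integers(50, 300))
        targets.append(TargetInterval(str(chrom), pos, pos + length - 1))
        gap_kind = rng.random()
        if gap_kind < 0.3:
            gap = 0  # abutting targets
        elif gap_kind < 0.9:
            gap = int(rng.integers(1, 5_000))
        else:
            gap = int(rng.integers(100_000, 10_000_000))
        pos += length + gap
    return targets


# --- coverage -------------------------------------------------------------


def brute_force_coverage(
    sam_path, targets, min_mapping_quality=20, count_unit="fragment",
    include_duplicates=False,
) -> np.ndarray:
    """Literal per-base, per-fragment depth tally from a SAM file."""
    depth: dict[tuple[str, int], float] = {}
    frag_bases: dict[str, set[tuple[str, int]]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapping_quality:
                continue
            if read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate and not include_duplicates:
                continue
            bases = {
                (read.reference_name, p)
                for p in read.get_reference_positions()
            }
            if count_unit == "fragment":
                frag_bases.setdefault(read.query_name, set()).update(bases)
            else:
                for b in bases:
                    depth[b] = depth.get(b, 0.0) + 1.0
    if count_unit == "fragment":
        for bases in frag_bases.values():
            for b in bases:
                depth[b] = depth.get(b, 0.0) + 1.0
    out = []
    for t in targets:
        total = sum(
            depth.get((t.chrom, p), 0.0) for p in range(t.start - 1, t.stop)
        )
        out.append(total / t.length)
    return np.array(out)
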