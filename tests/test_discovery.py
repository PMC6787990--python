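import numpy as np
import pytest

from exocnv.discovery import (
    CNVCall,
    discover,
    match_calls,
    quality_probabilities,
    read_xcnv,
    segment_path,
    write_vcf,
    write_xcnv,
)
from exocnv.hmm import DEL, DIP, DUP, StatePath, forward_backward_scaled
from exocnv.intervals import TargetInterval, parse_target
from exocnv.matrix import ReadDepthMatrix

from _oracles import enumerate_call_probabilities, make_chain_targets


def _targets(n, chrom="1", offset=0):
    return [
        TargetInterval(chrom, 1 + (i + offset) * 200, 100 + (i + offset) * 200)
        for i in range(n)
    ]


# --- segmentation ---------------------------------------------------------


def test_segment_path_basic_runs():
    targets = _targets(4)
    path = StatePath(np.array([DIP, DEL, DEL, DIP]), 0.0)
    assert segment_path(path, targets) == [(DEL, 1, 2)]
    assert segment_path(StatePath(np.array([DIP] * 4), 0.0), targets) == []
    mixed = StatePath(np.array([DUP, DUP, DEL, DIP]), 0.0)
    assert segment_path(mixed, targets) == [(DUP, 0, 1), (DEL, 2, 2)]


def test_segment_path_splits_at_chromosome_break():
    targets = _targets(2, "1") + _targets(2, "2")
    path = StatePath(np.array([DEL, DEL, DEL, DEL]), 0.0)
    assert segment_path(path, targets) == [(DEL, 0, 1), (DEL, 2, 3)]


# --- quality scores -------------------------------------------------------


def test_single_target_call_some_equals_exact_equals_posterior(params):
    targets = [TargetInterval("1", 1, 100)]
    z = np.array([-3.5])
    fb = forward_backward_scaled(z, targets, params)
    probs = quality_probabilities(DEL, 0, 0, z, targets, params, fb.log_likelihood)
    gamma_del = fb.gamma[0, DEL]
    assert probs.p_some == pytest.approx(gamma_del, abs=1e-12)
    assert probs.p_exact == pytest.approx(gamma_del, abs=1e-12)


def test_quality_probabilities_match_enumeration(params, rng):
    """All five event probabilities equal brute-force path sums."""
    for _ in range(25):
        T = int(rng.integers(2, 7))
        targets = make_chain_targets(T, rng)
        z = rng.uniform(-6, 6, T)
        first = int(rng.integers(0, T))
        last = int(rng.integers(first, T))
        state = DEL if rng.random() < 0.5 else DUP
        fb = forward_backward_scaled(z, targets, params)
        probs = quality_probabilities(
            state, first, last, z, targets, params, fb.log_likelihood
        )
        oracle = enumerate_call_probabilities(z, targets, params, state, first, last)
        assert probs.p_some == pytest.approx(oracle["some"], abs=1e-9)
        assert probs.p_non_diploid == pytest.approx(oracle["non_diploid"], abs=1e-9)
        assert probs.p_exact == pytest.approx(oracle["exact"], abs=1e-9)
        assert probs.p_start == pytest.approx(oracle["start"], abs=1e-9)
        assert probs.p_stop == pytest.approx(oracle["stop"], abs=1e-9)
        # event inclusion: exact implies some implies non-diploid
        assert probs.p_exact <= probs.p_some + 1e-12
        assert probs.p_some <= probs.p_non_diploid + 1e-12


def test_edge_targets_drop_missing_flank_constraint(params, rng):
    """Calls touching the first/last target are pinned against enumeration."""
    T = 5
    targets = make_chain_targets(T, rng, allow_breaks=False)
    z = np.array([-4.0, -4.0, 0.0, 4.0, 4.0])
    fb = forward_backward_scaled(z, targets, params)
    for state, first, last in [(DEL, 0, 1), (DUP, 3, 4)]:
        probs = quality_probabilities(
            state, first, last, z, targets, params, fb.log_likelihood
        )
        oracle = enumerate_call_probabilities(z, targets, params, state, first, last)
        for got, key in [
            (probs.p_exact, "exact"), (probs.p_start, "start"), (probs.p_stop, "stop")
        ]:
            assert got == pytest.approx(oracle[key], abs=1e-9), (state, key)


def test_quality_interval_bounds_checked(params):
    targets = _targets(3)
    z = np.zeros(3)
    with pytest.raises(ValueError):
        quality_probabilities(DEL, 1, 3, z, targets, params, 0.0)


# --- discover -------------------------------------------------------------


def _matrices(z, samples=None):
    z = np.asarray(z, dtype=float)
    targets = _targets(z.shape[1])
    samples = samples or [f"S{i}" for i in range(z.shape[0])]
    zm = ReadDepthMatrix(samples, targets, z, require_nonnegative=False)
    om = ReadDepthMatrix(samples, targets, np.full_like(z, 100.0))
    return zm, om


def test_all_zero_matrix_produces_no_calls(params):
    zm, om = _matrices(np.zeros((3, 8)))
    assert discover(zm, om, params) == []


def test_planted_deletion_is_called_with_high_quality(params):
    z = np.zeros((2, 12))
    z[1, 4:9] = -4.0  # five-target deletion-like stretch in one sample
    zm, om = _matrices(z)
    calls = discover(zm, om, params)
    assert len(calls) == 1
    call = calls[0]
    assert call.sample == "S1" and call.type == "DEL"
    assert (call.first_target_index, call.last_target_index) == (4, 8)
    assert call.q_some >= 30
    assert call.mean_rd == pytest.approx(-4.0)
    assert call.mean_orig_rd == pytest.approx(100.0)
    assert call.interval.start == zm.targets[4].start
    assert call.interval.stop == zm.targets[8].stop


def test_threshold_suppresses_marginal_calls(params):
    """A run whose Q_SOME lands below 30 is segmented but not reported."""
    z = np.zeros((1, 12))
    z[0, 4:9] = -3.0  # decodes as DEL but the posterior evidence is weak
    zm, om = _matrices(z)
    unthresholded = discover(zm, om, params, apply_threshold=False)
    assert len(unthresholded) == 1
    assert unthresholded[0].q_some < 30
    assert discover(zm, om, params) == []


def test_sample_order_independence(params, rng):
    z = rng.uniform(-4, 4, size=(6, 15))
    zm, om = _matrices(z)
    calls = discover(zm, om, params)
    perm = [3, 0, 5, 1, 4, 2]
    zm_p = ReadDepthMatrix(
        [zm.samples[i] for i in perm], zm.targets, z[perm], require_nonnegative=False
    )
    om_p = ReadDepthMatrix(
        [om.samples[i] for i in perm], om.targets, om.depths[perm]
    )
    calls_p = discover(zm_p, om_p, params)
    key = lambda c: (c.sample, c.interval.name, c.type)
    assert sorted(map(key, calls)) == sorted(map(key, calls_p))


# --- xcnv and vcf ---------------------------------------------------------


def _example_call():
    return CNVCall(
        sample="S0", type="DEL", interval=parse_target("1:801-1700"),
        first_target_index=4, last_target_index=8, q_exact=12, q_some=71,
        q_non_diploid=72, q_start=40, q_stop=41, mean_rd=-3.12, mean_orig_rd=87.5,
    )


def test_xcnv_round_trip(tmp_path):
    path = tmp_path / "calls.xcnv"
    call = _example_call()
    write_xcnv([call], path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[:3] == ["SAMPLE", "CNV", "INTERVAL"]
    fields = lines[1].split("\t")
    assert fields[0:3] == ["S0", "DEL", "1:801-1700"]
    assert fields[3] == "0.90"  # KB
    assert fields[6] == "5..9"  # 1-based target span
    back = read_xcnv(path)[0]
    assert back == call


def test_empty_xcnv_is_header_only(tmp_path):
    path = tmp_path / "empty.xcnv"
    write_xcnv([], path)
    assert len(path.read_text().splitlines()) == 1
    assert read_xcnv(path) == []


def test_vcf_export_minimal(tmp_path):
    path = tmp_path / "calls.vcf"
    write_vcf([_example_call()], path)
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(body) == 1
    assert "SVTYPE=DEL" in body[0] and "END=1700" in body[0]


# --- matching -------------------------------------------------------------


def _call(sample, type_, first, last, targets):
    return CNVCall(
        sample=sample, type=type_,
        interval=TargetInterval(
            targets[first].chrom, targets[first].start, targets[last].stop
        ),
        first_target_index=first, last_target_index=last,
        q_exact=50, q_some=99, q_non_diploid=99, q_start=50, q_stop=50,
        mean_rd=0.0, mean_orig_rd=0.0,
    )


def test_identical_sets_match_exactly():
    targets = _targets(20)
    calls = [_call("A", "DEL", 2, 6, targets), _call("B", "DUP", 10, 12, targets)]
    report = match_calls(calls, list(calls))
    assert (report.exact, report.overlap, report.unmatched) == (2, 0, 0)
    assert report.exact_fraction == 1.0


def test_one_target_shift_is_overlap_match_with_difference_one():
    targets = _targets(20)
    a = [_call("A", "DEL", 2, 6, targets)]
    b = [_call("A", "DEL", 2, 7, targets)]
    report = match_calls(a, b)
    assert (report.exact, report.overlap) == (0, 1)
    assert report.target_differences == [1]


def test_type_and_sample_must_agree():
    targets = _targets(20)
    a = [_call("A", "DEL", 2, 6, targets)]
    assert match_calls(a, [_call("A", "DUP", 2, 6, targets)]).unmatched == 1
    assert match_calls(a, [_call("B", "DEL", 2, 6, targets)]).unmatched == 1


def test_jittered_calls_match_brute_force_overlap_check(rng):
    targets = _targets(60)
    set_a, set_b = [], []
    for i in range(15):
        first = int(rng.integers(0, 50))
        last = first + int(rng.integers(0, 6))
        set_a.append(_call(f"S{i % 5}", "DEL" if i % 2 else "DUP", first, last, targets))
        jf = max(0, first + int(rng.integers(-3, 4)))
        jl = max(jf, min(59, last + int(rng.integers(-3, 4))))
        set_b.append(_call(f"S{i % 5}", "DEL" if i % 2 else "DUP", jf, jl, targets))
    report = match_calls(set_a, set_b)
    matched = 0
    for a in set_a:
        hit = any(
            b.sample == a.sample and b.type == a.type
            and not (b.last_target_index < a.first_target_index
                     or b.first_target_index > a.last_target_index)
            for b in set_b
        )
        matched += hit
    assert report.exact + report.overlap == matched
    assert report.total == 15
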