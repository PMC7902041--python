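"""Compliance estimators: segmentation, facility, VF, SR, the phi(P) fit."""

import numpy as np
import pytest

from ocuqtl import perfusion, simkit
from ocuqtl.perfusion import (
    ComplianceFit,
    FacilityEstimate,
    PerfusionTrace,
    SegmentRejected,
    StepComplianceEstimate,
    eq1_compliance,
)


def _levels_trace(levels, q_levels, n_per=40, dt=0.5):
    """Trace with perfectly flat plateaus at given pressure/flow levels."""
    p = np.repeat(levels, n_per).astype(float)
    q = np.repeat(q_levels, n_per).astype(float)
    t = dt * np.arange(p.size)
    return PerfusionTrace(time=t, p_applied=p, p_measured=p, q_in=q, mass=20.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def test_two_ascending_levels_give_two_ascending_segments():
    tr = _levels_trace([8.0, 9.5, 11.0], [0, 0, 0])
    segs = perfusion.segment_steps(tr)
    assert [s.direction for s in segs] == ["ascending", "ascending"]


def test_up_down_protocol_segment_counts():
    levels = list(8.0 + 1.5 * np.arange(9)) + list(20.0 - 1.5 * np.arange(1, 9))
    tr = _levels_trace(levels, np.zeros(len(levels)))
    segs = perfusion.segment_steps(tr)
    assert len(segs) == 16
    assert sum(s.direction == "ascending" for s in segs) == 8
    assert sum(s.direction == "descending" for s in segs) == 8


def test_monotone_ramp_without_plateaus_is_an_error():
    t = np.arange(50.0)
    tr = PerfusionTrace(time=t, p_applied=t, p_measured=t, q_in=np.zeros_like(t))
    with pytest.raises(ValueError, match="no steps"):
        perfusion.segment_steps(tr)


def test_constant_applied_pressure_is_an_error():
    tr = _levels_trace([8.0], [0.0])
    with pytest.raises(ValueError, match="no steps"):
        perfusion.segment_steps(tr)


# ---------------------------------------------------------------------------
# outflow facility
# ---------------------------------------------------------------------------


def test_facility_exact_on_three_point_line():
    tr = _levels_trace([5.0, 10.0, 15.0, 20.0], [1.0, 2.0, 3.0, 4.0])
    segs = perfusion.segment_steps(tr)
    fac = perfusion.estimate_facility(tr, segs)
    assert fac.facility == pytest.approx(0.2, abs=1e-12)
    assert fac.intercept == pytest.approx(0.0, abs=1e-12)
    assert fac.n_plateaus == 3


def test_facility_zero_when_all_flows_zero():
    tr = _levels_trace([10.0, 15.0, 20.0], [0.0, 0.0, 0.0])
    fac = perfusion.estimate_facility(tr, perfusion.segment_steps(tr))
    assert fac.facility == pytest.approx(0.0, abs=1e-12)


def test_facility_recovered_from_simulated_trace(noise_free_trace):
    eye = noise_free_trace.extra["ground_truth"]
    segs = perfusion.segment_steps(noise_free_trace)
    fac = perfusion.estimate_facility(noise_free_trace, segs)
    assert fac.facility == pytest.approx(eye.facility_true, rel=0.01)


def test_negative_facility_flagged_not_dropped():
    tr = _levels_trace([10.0, 15.0, 20.0], [3.0, 2.0, 1.0])
    with pytest.warns(UserWarning, match="negative"):
        fac = perfusion.estimate_facility(tr, perfusion.segment_steps(tr))
    assert fac.facility < 0
    assert "negative_facility" in fac.flags


# ---------------------------------------------------------------------------
# Volume Filling
# ---------------------------------------------------------------------------


def test_vf_rectangle_inflow_toy():
    """10 nl/s into a closed eye for 10 s over a 2 mmHg step: phi = 50."""
    dt = 0.01
    n_pre, n_step = 500, 2000
    t = dt * np.arange(n_pre + n_step)
    pa = np.concatenate([np.full(n_pre, 10.0), np.full(n_step, 12.0)])
    pm = np.concatenate(
        [np.full(n_pre, 10.0), 10.0 + 2.0 * np.minimum(np.arange(n_step) * dt / 10.0, 1.0)]
    )
    q = np.zeros_like(t)
    q[n_pre : n_pre + int(10.0 / dt)] = 10.0
    tr = PerfusionTrace(time=t, p_applied=pa, p_measured=pm, q_in=q)
    seg = perfusion.segment_steps(tr)[0]
    fac = FacilityEstimate(facility=0.0, se=0.0, intercept=0.0, n_plateaus=2)
    est = perfusion.volume_filling_compliance(tr, seg, fac)
    assert est.delta_v == pytest.approx(100.0, rel=1e-3)
    assert est.phi == pytest.approx(50.0, rel=1e-3)
    assert est.p_assign == pytest.approx(11.0, abs=0.01)


def test_vf_matches_closed_form_secant(noise_free_trace):
    eye = noise_free_trace.extra["ground_truth"]
    segs = perfusion.segment_steps(noise_free_trace)
    fac = perfusion.estimate_facility(noise_free_trace, segs)
    for seg in segs:
        est = perfusion.volume_filling_compliance(noise_free_trace, seg, fac)
        secant = (
            eye.phi_r_true * (13.0 + eye.gamma_true)
            * np.log((seg.p_end + eye.gamma_true) / (seg.p_start + eye.gamma_true))
            / (seg.p_end - seg.p_start)
        )
        assert est.phi == pytest.approx(secant, rel=5e-3)


def test_vf_ascending_descending_symmetry(noise_free_trace):
    """The secant integral is direction-symmetric: mirrored steps agree."""
    segs = perfusion.segment_steps(noise_free_trace)
    fac = perfusion.estimate_facility(noise_free_trace, segs)
    by_pair = {}
    for seg in segs:
        est = perfusion.volume_filling_compliance(noise_free_trace, seg, fac)
        key = tuple(sorted([round(seg.p_start, 1), round(seg.p_end, 1)]))
        by_pair.setdefault(key, []).append(est.phi)
    pairs = [v for v in by_pair.values() if len(v) == 2]
    assert pairs, "expected mirrored ascending/descending steps"
    for up, down in pairs:
        assert up == pytest.approx(down, rel=5e-3)


def test_vf_rejects_tiny_pressure_step():
    tr = _levels_trace([10.0, 10.05], [0.0, 0.0])
    seg = perfusion.segment_steps(tr)[0]
    fac = FacilityEstimate(facility=0.0, se=0.0, intercept=0.0, n_plateaus=2)
    with pytest.raises(SegmentRejected, match="floor"):
        perfusion.volume_filling_compliance(tr, seg, fac)


# ---------------------------------------------------------------------------
# Step Response
# ---------------------------------------------------------------------------


def test_sr_round_trip_recovers_local_compliance(noise_free_trace):
    eye = noise_free_trace.extra["ground_truth"]
    segs = perfusion.segment_steps(noise_free_trace)
    fac = perfusion.estimate_facility(noise_free_trace, segs)
    for seg in segs:
        if seg.direction != "ascending":
            continue
        est = perfusion.step_response_compliance(
            noise_free_trace, seg, eye.needle_resistance, fac
        )
        local = eq1_compliance(seg.p_start, eye.phi_r_true, eye.gamma_true)
        assert est.phi == pytest.approx(local, rel=5e-3)


def test_sr_constant_compliance_limit_matches_exponential():
    eye = simkit.GroundTruthEye(
        eye_id="e", strain="s", phi_r_true=50.0, gamma_true=1e7,
        facility_true=0.0, needle_resistance=1.0,
    )
    proto = simkit.Protocol(
        baseline_pressure=8.0, step_size=2.0, n_steps_up=1, n_steps_down=0,
        step_duration=400.0, pressure_noise_sd=0.0, flow_noise_sd=0.0,
    )
    tr = simkit.simulate_perfusion_trace(eye, proto, seed=0)
    segs = perfusion.segment_steps(tr)
    fac = FacilityEstimate(facility=0.0, se=0.0, intercept=0.0, n_plateaus=2)
    est = perfusion.step_response_compliance(tr, segs[0], 1.0, fac)
    assert est.phi == pytest.approx(50.0, rel=5e-3)
    # and the fitted transient reproduces the single-exponential oracle
    sl = slice(segs[0].start, segs[0].end)
    t = tr.time[sl] - tr.time[sl][0]
    oracle = 10.0 - 2.0 * np.exp(-t / (est.phi * 1.0))
    assert np.allclose(tr.p_measured[sl], oracle, atol=2e-3)


def test_sr_rejects_descending_segments(noise_free_trace):
    segs = perfusion.segment_steps(noise_free_trace)
    fac = perfusion.estimate_facility(noise_free_trace, segs)
    descending = next(s for s in segs if s.direction == "descending")
    with pytest.raises(SegmentRejected, match="ascending"):
        perfusion.step_response_compliance(noise_free_trace, descending, 0.5, fac)


# ---------------------------------------------------------------------------
# reference-compliance fit
# ---------------------------------------------------------------------------


def _exact_estimates(phi_r=45.0, gamma=10.0, pressures=None, se=None):
    pressures = np.arange(9.5, 22.0, 1.5) if pressures is None else np.asarray(pressures)
    return [
        StepComplianceEstimate(
            method="VF",
            phi=float(eq1_compliance(p, phi_r, gamma)),
            p_assign=float(p),
            se_phi=float(se) if se is not None else 0.0,
        )
        for p in pressures
    ]


def test_eq1_direct_evaluation():
    assert eq1_compliance(13.0, 45.0, 10.0) == pytest.approx(45.0)
    assert eq1_compliance(33.0, 45.0, 10.0) == pytest.approx(45.0 * 23.0 / 43.0)


def test_exact_points_recovered_to_machine_precision():
    fit = perfusion.fit_reference_compliance(_exact_estimates())
    assert fit.phi_r == pytest.approx(45.0, rel=1e-6)
    assert fit.gamma == pytest.approx(10.0, rel=1e-6)


def test_fit_invariant_to_estimate_order_and_se_rescaling():
    ests = _exact_estimates(se=1.0)
    base = perfusion.fit_reference_compliance(ests)
    reordered = perfusion.fit_reference_compliance(list(reversed(ests)))
    scaled = perfusion.fit_reference_compliance(
        [StepComplianceEstimate(e.method, e.phi, e.p_assign, 7.0 * e.se_phi) for e in ests]
    )
    assert reordered.phi_r == pytest.approx(base.phi_r, rel=1e-9)
    assert scaled.phi_r == pytest.approx(base.phi_r, rel=1e-9)
    assert scaled.gamma == pytest.approx(base.gamma, rel=1e-9)


def test_fit_requires_three_distinct_pressures():
    with pytest.raises(ValueError, match="3"):
        perfusion.fit_reference_compliance(_exact_estimates(pressures=[10.0, 12.0]))
    with pytest.raises(ValueError, match="3"):
        perfusion.fit_reference_compliance(_exact_estimates(pressures=[10.0, 10.0, 10.0]))


def test_fit_rejects_mixed_methods():
    ests = _exact_estimates()
    ests[0].method = "SR"
    with pytest.raises(ValueError, match="mix"):
        perfusion.fit_reference_compliance(ests)


def test_noisy_fit_coverage_of_phi_r():
    """phi_r falls within 3 fitted SEs of truth in ~99.7% of replicates."""
    rng = np.random.default_rng(12345)
    pressures = np.arange(9.5, 22.0, 1.5)
    truth = eq1_compliance(pressures, 45.0, 10.0)
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        noisy = truth * (1.0 + 0.05 * rng.standard_normal(truth.size))
        ests = [
            StepComplianceEstimate("VF", float(v), float(p), float(0.05 * t))
            for v, p, t in zip(noisy, pressures, truth)
        ]
        fit = perfusion.fit_reference_compliance(ests)
        if abs(fit.phi_r - 45.0) <= 3.0 * fit.se_phi_r:
            hits += 1
    assert hits / n_rep >= 0.98


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def test_normalization_arithmetic_and_proportionality():
    fit = ComplianceFit(
        phi_r=46.0, gamma=10.0, p_ref=13.0, se_phi_r=2.0,
        method="VF", residual_rms=0.0, n_steps_used=9,
    )
    phi_norm, se_norm, volume = perfusion.normalize_compliance(fit, mass=22.06)
    assert volume == pytest.approx(20.0, rel=1e-4)
    assert phi_norm == pytest.approx(2.30, rel=1e-3)
    assert se_norm == pytest.approx(2.0 / volume)
    double, _, _ = perfusion.normalize_compliance(fit, mass=44.12)
    assert double == pytest.approx(phi_norm / 2.0)
    with pytest.raises(ValueError):
        perfusion.normalize_compliance(fit, mass=0.0)


def test_analysis_is_deterministic_per_trace(noise_free_trace):
    a = perfusion.analyze_trace(noise_free_trace)
    b = perfusion.analyze_trace(noise_free_trace)
    for m in a:
        assert a[m].phi_r == b[m].phi_r
        assert a[m].gamma == b[m].gamma
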