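"""Per-eye ocular compliance estimation from stepped-pressure perfusion traces.

An enucleated eye is cannulated and perfused while the applied reservoir
pressure is stepped up and down.  Ocular compliance ``phi = dV/dP`` is
estimated for every pressure step by two independent routes:

* **Volume Filling (VF)** — integrate the net inflow (measured inflow minus
  the outflow ``C * P`` draining through the aqueous outflow pathway) over the
  step to obtain the volume change ``dV``, and divide by the plateau pressure
  change ``dP``.  This is a secant estimate, assigned to the step midpoint
  pressure.  Both ascending and descending steps are used.
* **Step Response (SR)** — fit the measured pressure transient after an
  ascending step to the lumped-parameter model of the perfusion circuit
  (needle resistance ``R_n``, outflow facility ``C``, pressure-dependent
  compliance), with the local compliance ``phi`` and a non-linearity term
  ``gamma`` free.  This is a local estimate anchored at the pre-step pressure.

The per-step estimates are then pooled by fitting the empirical pressure
dependence

    phi(P) = phi_r * (P_ref + gamma) / (P + gamma)

which yields the reference compliance ``phi_r`` at ``P_ref`` (13 mmHg, the
normal mouse IOP) with an uncertainty, and finally normalised by ocular
volume derived from eye mass and density (1.103 mg/ul).

Units are fixed throughout: pressure mmHg, flow nl/s, volume nl, time s,
eye volume ul.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "P_REF",
    "EYE_DENSITY",
    "DEFAULT_NEEDLE_RESISTANCE",
    "ConvergenceError",
    "SegmentRejected",
    "PerfusionTrace",
    "StepSegment",
    "StepComplianceEstimate",
    "FacilityEstimate",
    "ComplianceFit",
    "eq1_compliance",
    "segment_steps",
    "estimate_facility",
    "volume_filling_compliance",
    "step_response_compliance",
    "fit_reference_compliance",
    "normalize_compliance",
    "analyze_trace",
]

#: Reference pressure at which compliance is compared across strains [mmHg].
P_REF = 13.0

#: Eye density used to convert eye mass to volume [mg/ul].
EYE_DENSITY = 1.103

#: Default needle + capillary resistance of the perfusion circuit [mmHg*s/nl].
DEFAULT_NEEDLE_RESISTANCE = 0.5

#: Trailing fraction of each step used for steady-state (plateau) statistics.
PLATEAU_FRACTION = 0.25

#: Smallest usable plateau pressure change for a Volume Filling step [mmHg].
DP_FLOOR = 0.2


class ConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge over its multi-start grid."""


class SegmentRejected(ValueError):
    """A pressure step cannot yield a usable compliance estimate."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PerfusionTrace:
    """Sampled pressure/flow record of one perfused eye.

    Attributes
    ----------
    time : array, seconds, strictly increasing
    p_applied : array, mmHg — commanded reservoir pressure (noise free)
    p_measured : array, mmHg — pressure sensor reading
    q_in : array, nl/s — flow sensor reading (into the eye)
    eye_id, strain : identifiers
    mass : eye wet mass, mg
    extra : additional named channels or annotations carried through I/O
    """

    time: np.ndarray
    p_applied: np.ndarray
    p_measured: np.ndarray
    q_in: np.ndarray
    eye_id: str = ""
    strain: str = ""
    mass: float = float("nan")
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.p_applied = np.asarray(self.p_applied, dtype=float)
        self.p_measured = np.asarray(self.p_measured, dtype=float)
        self.q_in = np.asarray(self.q_in, dtype=float)
        n = self.time.size
        for name in ("p_applied", "p_measured", "q_in"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length differs from time")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class StepSegment:
    """One contiguous constant applied-pressure level after the first.

    Sample indices are half-open ``[start, end)``.  ``p_start``/``p_end`` are
    the measured plateau pressures before and at the end of the step;
    ``prev_plateau``/``plateau`` are the index ranges of the trailing windows
    they were computed from.
    """

    direction: str  # "ascending" | "descending"
    start: int
    end: int
    p_applied_level: float
    p_start: float
    p_end: float
    se_p_start: float
    se_p_end: float
    prev_plateau: tuple[int, int]
    plateau: tuple[int, int]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.direction not in ("ascending", "descending"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class StepComplianceEstimate:
    """Compliance of one pressure step by one method."""

    method: str  # "VF" | "SR"
    phi: float  # nl/mmHg
    p_assign: float  # mmHg
    se_phi: float  # nl/mmHg
    delta_v: float = float("nan")  # nl (VF only)
    delta_p: float = float("nan")  # mmHg (VF only)
    gamma_step: float = float("nan")  # mmHg (SR only)
    flags: tuple = ()


@dataclass
class FacilityEstimate:
    """Outflow facility from the plateau flow-vs-pressure regression."""

    facility: float  # nl/s/mmHg
    se: float
    intercept: float  # nl/s, diagnostic
    n_plateaus: int
    flags: tuple = ()


@dataclass
class ComplianceFit:
    """Reference compliance from the pooled per-step estimates."""

    phi_r: float  # nl/mmHg at p_ref
    gamma: float  # mmHg
    p_ref: float
    se_phi_r: float
    method: str
    residual_rms: float  # nl/mmHg
    n_steps_used: int


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def eq1_compliance(p, phi_r, gamma, p_ref=P_REF):
    """Empirical compliance-pressure law phi(P) = phi_r (P_ref+gamma)/(P+gamma)."""
    p = np.asarray(p, dtype=float)
    return phi_r * (p_ref + gamma) / (p + gamma)


# ---------------------------------------------------------------------------
# step segmentation
# ---------------------------------------------------------------------------


def _plateau_window(start: int, end: int) -> tuple[int, int]:
    n = end - start
    lo = end - max(2, int(np.ceil(PLATEAU_FRACTION * n)))
    return (max(start, lo), end)


def _plateau_stats(trace: PerfusionTrace, window: tuple[int, int]) -> tuple[float, float]:
    lo, hi = window
    seg = trace.p_measured[lo:hi]
    mean = float(np.mean(seg))
    se = float(np.std(seg, ddof=1) / np.sqrt(seg.size)) if seg.size > 1 else 0.0
    return mean, se


def segment_steps(trace: PerfusionTrace, protocol_hint=None) -> list[StepSegment]:
    """Split a trace into pressure-step segments at applied-pressure changes.

    One segment is produced per constant applied-pressure level after the
    first; the first level only supplies the pre-step plateau of segment 1.
    ``protocol_hint`` is accepted for interface symmetry but boundaries are
    always taken from the recorded applied-pressure channel.
    """
    pa = trace.p_applied
    if len(trace) < 4:
        raise ValueError("no steps found: trace too short")
    change = np.flatnonzero(np.diff(pa) != 0) + 1
    boundaries = np.concatenate(([0], change, [len(trace)]))
    n_levels = boundaries.size - 1
    if n_levels < 2:
        raise ValueError("no steps found: applied pressure has fewer than 2 levels")
    lengths = np.diff(boundaries)
    if np.all(lengths <= 1):
        raise ValueError("no steps found: applied pressure changes every sample")

    segments: list[StepSegment] = []
    for k in range(1, n_levels):
        start, end = int(boundaries[k]), int(boundaries[k + 1])
        prev_start = int(boundaries[k - 1])
        prev_win = _plateau_window(prev_start, start)
        win = _plateau_window(start, end)
        p_start, se_start = _plateau_stats(trace, prev_win)
        p_end, se_end = _plateau_stats(trace, win)
        level = float(pa[start])
        direction = "ascending" if level > pa[start - 1] else "descending"
        segments.append(
            StepSegment(
                direction=direction,
                start=start,
                end=end,
                p_applied_level=level,
                p_start=p_start,
                p_end=p_end,
                se_p_start=se_start,
                se_p_end=se_end,
                prev_plateau=prev_win,
                plateau=win,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# outflow facility
# ---------------------------------------------------------------------------


def estimate_facility(trace: PerfusionTrace, segments: list[StepSegment]) -> FacilityEstimate:
    """Outflow facility C from OLS of plateau-mean flow on plateau-mean pressure.

    At steady state all inflow drains through the outflow pathway, so plateau
    flow is ``C * P`` (plus any pressure-independent offset, kept as a
    diagnostic intercept).  A negative fitted C is physically impossible but
    is retained with a warning flag.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 plateaus to estimate facility")
    p = np.array([np.mean(trace.p_measured[slice(*s.plateau)]) for s in segments])
    q = np.array([np.mean(trace.q_in[slice(*s.plateau)]) for s in segments])
    if np.ptp(p) == 0:
        raise ValueError("plateau pressures are all identical")
    res = stats.linregress(p, q)
    flags = ()
    if res.slope < 0:
        warnings.warn("negative fitted outflow facility; value retained", stacklevel=2)
        flags = ("negative_facility",)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return FacilityEstimate(
        facility=float(res.slope),
        se=se,
        intercept=float(res.intercept),
        n_plateaus=len(segments),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Volume Filling
# ---------------------------------------------------------------------------


def volume_filling_compliance(
    trace: PerfusionTrace,
    segment: StepSegment,
    facility: FacilityEstimate,
    dp_floor: float = DP_FLOOR,
) -> StepComplianceEstimate:
    """Secant compliance of one step from the integrated net inflow volume.

    ``dV`` is the trapezoidal integral of ``q_in - C * p_measured`` across the
    segment (the integrand vanishes on the bounding plateaus, so the segment
    integral captures the full volume change from pre-step plateau to the end
    of the step's plateau); ``dP`` is the plateau-mean pressure change.  Used
    for ascending and descending steps alike.
    """
    dp = segment.p_end - segment.p_start
    if abs(dp) < dp_floor:
        raise SegmentRejected(
            f"plateau pressure change {dp:.3g} mmHg below floor {dp_floor:g}"
        )
    sl = slice(segment.start, segment.end)
    t = trace.time[sl]
    net = trace.q_in[sl] - facility.facility * trace.p_measured[sl]
    dv = float(np.trapezoid(net, t))
    phi = dv / dp

    # noise propagation: flow-noise SD from detrended plateau residuals,
    # integrated with the trapezoid weights; pressure SE from plateau means
    lo, hi = segment.plateau
    q_plateau = trace.q_in[lo:hi]
    sd_q = float(np.std(q_plateau - np.mean(q_plateau), ddof=1)) if hi - lo > 1 else 0.0
    w = np.zeros_like(t)
    dt = np.diff(t)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0
    se_dv = sd_q * float(np.sqrt(np.sum(w**2)))
    se_dp = float(np.hypot(segment.se_p_start, segment.se_p_end))
    se_phi = abs(phi) * float(np.hypot(se_dv / dv if dv != 0 else 0.0, se_dp / dp))
    return StepComplianceEstimate(
        method="VF",
        phi=phi,
        p_assign=0.5 * (segment.p_start + segment.p_end),
        se_phi=se_phi,
        delta_v=dv,
        delta_p=dp,
    )


# ---------------------------------------------------------------------------
# Step Response
# ---------------------------------------------------------------------------


def _integrate_sr_pressure(t, pa, p0, phi, gamma, c, r_needle, p_anchor):
    """Integrate the step-response pressure ODE on the sample grid (RK4).

    dP/dt = [(pa - P)/R_n - C P] * (P + gamma) / (phi * (p_anchor + gamma))

    ``phi`` is the local compliance at the anchor (pre-step) pressure.  One
    RK4 step per sampling interval is ample: the relaxation time constant is
    tens of seconds against a 0.5 s sampling period.
    """
    denom = phi * (p_anchor + gamma)
    inv_r = 1.0 / r_needle
    out = np.empty(t.size)
    p = float(p0)
    out[0] = p
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        k1 = ((pa - p) * inv_r - c * p) * (p + gamma) / denom
        p2 = p + 0.5 * dt * k1
        k2 = ((pa - p2) * inv_r - c * p2) * (p2 + gamma) / denom
        p3 = p + 0.5 * dt * k2
        k3 = ((pa - p3) * inv_r - c * p3) * (p3 + gamma) / denom
        p4 = p + dt * k3
        k4 = ((pa - p4) * inv_r - c * p4) * (p4 + gamma) / denom
        p += dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i] = p
    return out


_SR_BOUNDS = ([1e-3, 1e-3], [1e5, 1e6])


def step_response_compliance(
    trace: PerfusionTrace,
    segment: StepSegment,
    needle_resistance: float,
    facility: FacilityEstimate,
) -> StepComplianceEstimate:
    """Local compliance from fitting the measured pressure transient.

    Only ascending steps are used (descending steps raise).  The free
    parameters are the local compliance ``phi`` at the pre-step plateau
    pressure and the non-linearity term ``gamma_step``; outflow facility is
    held fixed at the eye-level estimate.
    """
    if segment.direction != "ascending":
        raise SegmentRejected("Step Response analysis uses ascending steps only")
    sl = slice(segment.start, segment.end)
    t = trace.time[sl]
    y = trace.p_measured[sl]
    pa = segment.p_applied_level
    p0 = segment.p_start
    c = facility.facility
    anchor = p0

    # rough phi from the initial pressure slope: dP/dt|0+ ~ (pa - p0)/(R phi)
    n0 = max(3, min(10, t.size // 4))
    slope0 = float(np.polyfit(t[:n0] - t[0], y[:n0], 1)[0])
    if slope0 > 1e-6:
        phi0 = float(np.clip((pa - p0) / (needle_resistance * slope0), 1.0, 1e4))
    else:
        phi0 = 50.0

    def residual(params):
        phi, gamma = params
        return _integrate_sr_pressure(t, pa, p0, phi, gamma, c, needle_resistance, anchor) - y

    best = None
    for gamma0 in (10.0, 3.0, 50.0):
        try:
            res = optimize.least_squares(
                residual,
                x0=[phi0, gamma0],
                bounds=_SR_BOUNDS,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
            at_bound = any(
                np.isclose(v, lo) or np.isclose(v, hi)
                for v, lo, hi in zip(res.x, *_SR_BOUNDS)
            )
            if not at_bound:  # well-interior optimum; further starts unnecessary
                break
    if best is None:
        raise SegmentRejected("step response fit did not converge")

    phi, gamma = best.x
    flags = []
    for val, lo, hi in zip(best.x, *_SR_BOUNDS):
        if np.isclose(val, lo) or np.isclose(val, hi):
            flags.append("gamma_at_bound" if val is best.x[1] else "phi_at_bound")
    # parameter covariance from the Jacobian at the optimum
    m, nparam = best.jac.shape
    dof = max(m - nparam, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_phi = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_phi = float("nan")
    return StepComplianceEstimate(
        method="SR",
        phi=float(phi),
        p_assign=float(p0),
        se_phi=se_phi,
        gamma_step=float(gamma),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# reference-compliance fit and normalisation
# ---------------------------------------------------------------------------


def fit_reference_compliance(
    estimates: list[StepComplianceEstimate],
    p_ref: float = P_REF,
) -> ComplianceFit:
    """Weighted fit of phi(P) = phi_r (p_ref+gamma)/(P+gamma) to step estimates.

    Weights are 1/se^2 when per-step SEs are available (SEs floored at a tiny
    fraction of phi to keep noise-free fits well conditioned); unit weights
    otherwise.  gamma is constrained positive; a small multi-start grid on
    gamma guards against local minima.
    """
    if not estimates:
        raise ValueError("no step estimates supplied")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise ValueError(f"estimates mix methods {sorted(methods)}")
    p = np.array([e.p_assign for e in estimates], dtype=float)
    phi = np.array([e.phi for e in estimates], dtype=float)
    se = np.array([e.se_phi for e in estimates], dtype=float)
    if p.size < 3 or np.unique(p).size < 3:
        raise ValueError("need at least 3 step estimates at 3 distinct pressures")

    if np.all(np.isfinite(se)) and np.all(se >= 0):
        w = 1.0 / np.maximum(se, 1e-6 * np.abs(phi)) ** 2
    else:
        w = np.ones_like(phi)
    sw = np.sqrt(w)

    def residual(params):
        phi_r, gamma = params
        return sw * (eq1_compliance(p, phi_r, gamma, p_ref) - phi)

    phi_r0 = float(np.interp(p_ref, p[np.argsort(p)], phi[np.argsort(p)]))
    best = None
    for gamma0 in (1.0, 3.0, 10.0, 30.0, 100.0):
        try:
            res = optimize.least_squares(
                residual,
                x0=[max(phi_r0, 1e-3), gamma0],
                bounds=([1e-9, 1e-9], [1e9, 1e9]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise ConvergenceError("reference-compliance fit failed over multi-start grid")

    phi_r, gamma = best.x
    m, nparam = best.jac.shape
    dof = max(m - nparam, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_phi_r = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_phi_r = float("nan")
    resid = eq1_compliance(p, phi_r, gamma, p_ref) - phi
    return ComplianceFit(
        phi_r=float(phi_r),
        gamma=float(gamma),
        p_ref=float(p_ref),
        se_phi_r=se_phi_r,
        method=next(iter(methods)),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_steps_used=int(p.size),
    )


def normalize_compliance(
    fit: ComplianceFit, mass: float, density: float = EYE_DENSITY
) -> tuple[float, float, float]:
    """Normalise phi_r by ocular volume derived from eye mass.

    Returns ``(phi_norm, se_phi_norm, volume_ul)`` with
    ``volume = mass / density`` [ul] and ``phi_norm = phi_r / volume``
    [nl/mmHg/ul]; the SE scales by 1/volume.
    """
    if not mass > 0:
        raise ValueError("eye mass must be positive")
    volume = mass / density
    return fit.phi_r / volume, fit.se_phi_r / volume, volume


# ---------------------------------------------------------------------------
# per-trace driver
# ---------------------------------------------------------------------------


def analyze_trace(
    trace: PerfusionTrace,
    needle_resistance: float = DEFAULT_NEEDLE_RESISTANCE,
    methods: tuple[str, ...] = ("VF", "SR"),
    p_ref: float = P_REF,
    dp_floor: float = DP_FLOOR,
) -> dict[str, ComplianceFit]:
    """Run segmentation, facility and per-step estimation, and the phi_r fit.

    Returns one :class:`ComplianceFit` per requested method.  Rejected
    segments are skipped; a method that ends with fewer than three usable
    steps raises :class:`ConvergenceError`.
    """
    segments = segment_steps(trace)
    facility = estimate_facility(trace, segments)
    fits: dict[str, ComplianceFit] = {}
    for method in methods:
        ests: list[StepComplianceEstimate] = []
        for seg in segments:
            try:
                if method == "VF":
                    ests.append(volume_filling_compliance(trace, seg, facility, dp_floor))
                elif method == "SR":
                    if seg.direction != "ascending":
                        continue
                    ests.append(
                        step_response_compliance(trace, seg, needle_resistance, facility)
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
            except SegmentRejected:
                continue
        try:
            fits[method] = fit_reference_compliance(ests, p_ref=p_ref)
        except ValueError as exc:
            raise ConvergenceError(
                f"{method} analysis of {trace.eye_id or 'trace'}: {exc}"
            ) from exc
    return fits
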