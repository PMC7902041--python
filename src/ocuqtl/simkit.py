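"""Synthetic perfusion experiments and recombinant-inbred genetics.

Everything the analysis pipeline consumes can be generated here with known
ground truth: stepped-pressure perfusion traces of eyes obeying the
compliance-pressure law ``phi(P) = phi_r (13+gamma)/(P+gamma)`` with outflow
facility, optional viscoelastic creep and sensor noise; BXD-like recombinant
inbred (RI) genotype panels; and a strain trait architecture with a planted
additive QTL of prescribed effect size.

The forward trace model is the state system

    phi(P) dP/dt = Q_in - C P - dV_creep/dt,     Q_in = (P_a - P)/R_n
    dV_creep/dt  = (c_creep (P - P_base) - V_creep) / tau_creep

integrated per constant applied-pressure level.  RI genotypes are simulated
as two-state Markov mosaics of homozygous B/D blocks: the switching
probability between adjacent markers is the sib-mating RI-expanded
recombination fraction ``R = 4r/(1+6r)`` with ``r`` from the Haldane map
function of the cM gap.

Ground-truth parameters are carried on dedicated objects/columns and are
never written into the estimator-facing trace channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .perfusion import EYE_DENSITY, P_REF, DEFAULT_NEEDLE_RESISTANCE, PerfusionTrace

__all__ = [
    "Protocol",
    "GroundTruthEye",
    "MarkerMap",
    "GenotypeMatrix",
    "TraitArchitecture",
    "haldane_recombination",
    "ri_expansion",
    "flank_dosage",
    "default_marker_map",
    "simulate_ri_genotypes",
    "simulate_trait",
    "simulate_perfusion_trace",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# protocol and eye descriptions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """Stepped-pressure perfusion protocol.

    The applied pressure holds at ``baseline_pressure`` for one
    ``step_duration``, then makes ``n_steps_up`` ascending and
    ``n_steps_down`` descending changes of ``step_size``.  Defaults straddle
    the 13 mmHg reference pressure (8 -> 21.5 -> 9.5 mmHg); sensor noise SDs
    are roughly 5% of the characteristic signal amplitudes.
    """

    baseline_pressure: float = 8.0  # mmHg
    step_size: float = 1.5  # mmHg
    n_steps_up: int = 9
    n_steps_down: int = 8
    step_duration: float = 240.0  # s
    sampling_rate: float = 2.0  # Hz
    pressure_noise_sd: float = 0.05  # mmHg
    flow_noise_sd: float = 0.1  # nl/s

    def __post_init__(self) -> None:
        if self.step_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("step_duration and sampling_rate must be positive")
        if self.n_steps_up < 1 or self.n_steps_down < 0:
            raise ValueError("need n_steps_up >= 1 and n_steps_down >= 0")
        if self.pressure_noise_sd < 0 or self.flow_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def levels(self) -> np.ndarray:
        """Applied-pressure levels in order, baseline first."""
        up = self.baseline_pressure + self.step_size * np.arange(self.n_steps_up + 1)
        down = up[-1] - self.step_size * np.arange(1, self.n_steps_down + 1)
        return np.concatenate([up, down])


@dataclass(frozen=True)
class GroundTruthEye:
    """True biomechanical parameters of one simulated eye."""

    eye_id: str
    strain: str
    mass: float = 21.1  # mg
    phi_r_true: float = 45.0  # nl/mmHg at 13 mmHg
    gamma_true: float = 10.0  # mmHg
    facility_true: float = 0.07  # nl/s/mmHg
    needle_resistance: float = DEFAULT_NEEDLE_RESISTANCE  # mmHg*s/nl
    creep_compliance: float = 0.0  # nl/mmHg; 0 disables creep
    creep_tau: float = 90.0  # s
    animal_id: str = ""
    eye: str = "OD"

    def __post_init__(self) -> None:
        if not (self.mass > 0 and self.phi_r_true > 0 and self.gamma_true > 0):
            raise ValueError("mass, phi_r_true and gamma_true must be positive")
        if self.facility_true < 0 or self.creep_compliance < 0:
            raise ValueError("facility and creep compliance must be non-negative")
        if self.needle_resistance <= 0 or self.creep_tau <= 0:
            raise ValueError("needle_resistance and creep_tau must be positive")

    @property
    def volume_ul(self) -> float:
        return self.mass / EYE_DENSITY

    @property
    def phi_norm_true(self) -> float:
        return self.phi_r_true / self.volume_ul


# ---------------------------------------------------------------------------
# genetic map and genotypes
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered marker scaffold with genetic (cM) and physical (Mb) positions."""

    table: pd.DataFrame  # columns: name, chromosome, cM, Mb

    REQUIRED = ("name", "chromosome", "cM", "Mb")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns {missing}")
        if self.table["name"].duplicated().any():
            dup = self.table.loc[self.table["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate marker name {dup!r}")
        self.table = self.table.reset_index(drop=True)
        for _, grp in self.table.groupby("chromosome", sort=False):
            if not (grp["cM"].is_monotonic_increasing and grp["Mb"].is_monotonic_increasing):
                raise ValueError("marker positions must be non-decreasing within chromosome")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chromosome_slice(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]

    def cm_to_mb(self, chrom, cm: float) -> float:
        """Piecewise-linear cM -> Mb interpolation through the markers."""
        grp = self.chromosome_slice(chrom)
        return float(np.interp(cm, grp["cM"].to_numpy(), grp["Mb"].to_numpy()))


@dataclass
class GenotypeMatrix:
    """Homozygous RI calls, one row per strain, one column per marker.

    ``calls`` holds the D-allele dosage: 0 = B homozygote, 1 = D homozygote,
    -1 = missing (H/U codes in genotype files).
    """

    strains: list
    markers: MarkerMap
    calls: np.ndarray  # int8, shape (n_strains, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.strains), len(self.markers)):
            raise ValueError("calls shape inconsistent with strains x markers")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def to_frame(self) -> pd.DataFrame:
        letters = np.array(["B", "D"])
        data = np.where(self.calls >= 0, letters[np.clip(self.calls, 0, 1)], "U")
        return pd.DataFrame(
            data.T, index=self.markers.table["name"], columns=self.strains
        )


# mouse-like autosome lengths in cM (19 chromosomes, ~1440 cM total)
_CHROM_CM = {
    "1": 98, "2": 103, "3": 82, "4": 89, "5": 92, "6": 79, "7": 89,
    "8": 76, "9": 75, "10": 77, "11": 88, "12": 64, "13": 67, "14": 66,
    "15": 59, "16": 57, "17": 61, "18": 59, "19": 57,
}

#: physical-to-genetic scale of the synthetic map [Mb per cM]
_MB_PER_CM = 2.0


def default_marker_map(spacing_cM: float = 2.0) -> MarkerMap:
    """BXD-like synthetic map: 19 autosomes, markers every ``spacing_cM``."""
    rows = []
    for chrom, length in _CHROM_CM.items():
        positions = np.arange(0.0, length + 1e-9, spacing_cM)
        for i, cm in enumerate(positions):
            rows.append(
                {
                    "name": f"m{chrom}_{i:03d}",
                    "chromosome": chrom,
                    "cM": float(cm),
                    "Mb": float(cm * _MB_PER_CM),
                }
            )
    return MarkerMap(pd.DataFrame(rows))


def haldane_recombination(d_cM) -> np.ndarray:
    """Haldane map function: recombination fraction of a cM gap."""
    d = np.asarray(d_cM, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def ri_expansion(r) -> np.ndarray:
    """Sib-mated RI expansion R = 4r/(1+6r) of a recombination fraction."""
    r = np.asarray(r, dtype=float)
    return 4.0 * r / (1.0 + 6.0 * r)


def flank_dosage(left: int, right: int | None, r_left: float, r_right: float | None) -> float:
    """Expected D dosage at a point conditioned on flanking RI marker calls.

    ``left``/``right`` are D dosages (0/1) of the nearest typed flanking
    markers; ``r_left``/``r_right`` the RI-expanded switching probabilities of
    the two sub-intervals.  With a single flank the conditional reduces to
    switch/no-switch; with two flanks it follows the two-interval two-state
    chain.
    """
    if right is None:
        return left * (1.0 - r_left) + (1 - left) * r_left
    pl_d = (1.0 - r_left) if left == 1 else r_left
    pl_b = 1.0 - pl_d
    pr_given_d = (1.0 - r_right) if right == 1 else r_right
    pr_given_b = r_right if right == 1 else (1.0 - r_right)
    num = pl_d * pr_given_d
    den = num + pl_b * pr_given_b
    return num / den if den > 0 else 0.5


def simulate_ri_genotypes(marker_map: MarkerMap, n_strains: int, seed: int) -> GenotypeMatrix:
    """Simulate a homozygous RI panel as per-chromosome two-state Markov mosaics.

    The first marker of each chromosome is B or D with probability 1/2; each
    subsequent marker switches from its left neighbour with probability
    ``R = 4r/(1+6r)``, ``r`` from the Haldane function of the cM gap.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    rng = np.random.default_rng(seed)
    n_markers = len(marker_map)
    calls = np.empty((n_strains, n_markers), dtype=np.int8)
    col = 0
    for chrom in marker_map.chromosomes:
        grp = marker_map.chromosome_slice(chrom)
        m = len(grp)
        switch_p = ri_expansion(haldane_recombination(np.diff(grp["cM"].to_numpy())))
        block = np.empty((n_strains, m), dtype=np.int8)
        block[:, 0] = rng.random(n_strains) < 0.5
        if m > 1:
            flips = rng.random((n_strains, m - 1)) < switch_p[None, :]
            block[:, 1:] = block[:, [0]] ^ np.cumsum(flips, axis=1, dtype=np.int8) % 2
        calls[:, col : col + m] = block
        col += m
    strains = [f"RIX{i + 1:03d}" for i in range(n_strains)]
    return GenotypeMatrix(strains=strains, markers=marker_map, calls=calls)


# ---------------------------------------------------------------------------
# trait architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitArchitecture:
    """One additive QTL plus strain- and eye-level environmental noise.

    ``variance_explained`` is the fraction of strain-mean trait variance
    contributed by the QTL, relative to QTL + strain-environment variance;
    the additive effect is sized from the theoretical dosage variance 1/4 of
    a balanced RI panel.
    """

    qtl_chromosome: str = "11"
    qtl_position_cM: float = 44.0
    variance_explained: float = 0.37
    strain_env_sd: float = 0.20  # trait units (nl/mmHg/ul)
    eye_env_sd: float = 0.25  # trait units
    increasing_allele: str = "D"

    def __post_init__(self) -> None:
        if not (0.0 <= self.variance_explained < 1.0):
            raise ValueError("variance_explained must lie in [0, 1)")
        if self.strain_env_sd < 0 or self.eye_env_sd < 0:
            raise ValueError("environmental SDs must be non-negative")
        if self.increasing_allele not in ("B", "D"):
            raise ValueError("increasing_allele must be 'B' or 'D'")

    def additive_effect(self) -> float:
        """Allele-substitution effect a with Var_QTL = a^2/4 at dosage var 1/4."""
        ve = self.variance_explained
        if ve == 0.0:
            return 0.0
        if self.strain_env_sd == 0.0:
            raise ValueError(
                "variance_explained in (0,1) requires a positive strain_env_sd"
            )
        a = 2.0 * self.strain_env_sd * np.sqrt(ve / (1.0 - ve))
        return a if self.increasing_allele == "D" else -a


def _qtl_dosage(genotypes: GenotypeMatrix, chrom: str, pos_cM: float) -> np.ndarray:
    """True D dosage of every strain at the QTL position (marker or flanked)."""
    grp = genotypes.markers.chromosome_slice(chrom)
    if len(grp) == 0:
        raise ValueError(f"chromosome {chrom!r} absent from map")
    cms = grp["cM"].to_numpy()
    if not (cms[0] <= pos_cM <= cms[-1]):
        raise ValueError("QTL position outside the map extent")
    cols = grp.index.to_numpy()
    j = int(np.searchsorted(cms, pos_cM))
    if j < len(cms) and np.isclose(cms[j], pos_cM):
        return genotypes.calls[:, cols[j]].astype(float)
    left, right = j - 1, j
    r_l = float(ri_expansion(haldane_recombination(pos_cM - cms[left])))
    r_r = float(ri_expansion(haldane_recombination(cms[right] - pos_cM)))
    out = np.empty(genotypes.n_strains)
    for i in range(genotypes.n_strains):
        out[i] = flank_dosage(
            int(genotypes.calls[i, cols[left]]),
            int(genotypes.calls[i, cols[right]]),
            r_l,
            r_r,
        )
    return out


def simulate_trait(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    arch: TraitArchitecture,
    n_eyes_per_strain: int,
    base_phi_norm: float,
    seed: int,
) -> pd.DataFrame:
    """Per-eye true normalised compliance under the trait architecture.

    Strain genetic value = base + a*(dosage - 0.5) + strain-environment noise;
    each eye adds independent eye-level noise.  Eyes are grouped into animals
    of two (OD/OS), the unit used later for best-eye selection.  The realized
    QTL variance fraction (effect variance over effect + strain-environment
    variance, both sample estimates) is reported in ``DataFrame.attrs``.
    """
    if n_eyes_per_strain < 1:
        raise ValueError("need at least one eye per strain")
    rng = np.random.default_rng(seed)
    a = arch.additive_effect()
    dosage = _qtl_dosage(genotypes, arch.qtl_chromosome, arch.qtl_position_cM)
    strain_env = rng.normal(0.0, arch.strain_env_sd, genotypes.n_strains)
    genetic = a * (dosage - 0.5)
    strain_values = base_phi_norm + genetic + strain_env

    rows = []
    for i, strain in enumerate(genotypes.strains):
        for e in range(n_eyes_per_strain):
            animal = f"{strain}_a{e // 2 + 1}"
            rows.append(
                {
                    "strain": strain,
                    "animal_id": animal,
                    "eye": "OD" if e % 2 == 0 else "OS",
                    "eye_id": f"{animal}_{'OD' if e % 2 == 0 else 'OS'}",
                    "true_phi_norm": strain_values[i]
                    + rng.normal(0.0, arch.eye_env_sd),
                    "qtl_dosage": dosage[i],
                }
            )
    out = pd.DataFrame(rows)
    var_g = float(np.var(genetic, ddof=1)) if genotypes.n_strains > 1 else 0.0
    var_e = float(np.var(strain_env, ddof=1)) if genotypes.n_strains > 1 else 0.0
    out.attrs["additive_effect"] = a
    out.attrs["realized_variance_explained"] = (
        var_g / (var_g + var_e) if (var_g + var_e) > 0 else 0.0
    )
    out.attrs["strain_values"] = dict(zip(genotypes.strains, strain_values))
    return out


# ---------------------------------------------------------------------------
# forward perfusion model
# ---------------------------------------------------------------------------


def simulate_perfusion_trace(
    eye: GroundTruthEye, protocol: Protocol, seed: int
) -> PerfusionTrace:
    """Integrate the forward perfusion model and sample it with sensor noise.

    The state is (P, V_creep); the applied pressure is piecewise constant
    following the protocol.  Recorded pressure and flow carry independent
    Gaussian noise per sample; the true parameters are annotated in
    ``trace.extra['ground_truth']`` for test use only.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / protocol.sampling_rate
    levels = protocol.levels()
    n_per = int(round(protocol.step_duration * protocol.sampling_rate))
    if n_per < 2:
        raise ValueError("step_duration too short for the sampling rate")

    phi_r, gamma = eye.phi_r_true, eye.gamma_true
    c, rn = eye.facility_true, eye.needle_resistance
    cc, tau = eye.creep_compliance, eye.creep_tau
    p_base = protocol.baseline_pressure

    def rhs(t, y, pa):
        p, vc = y
        dvc = (cc * (p - p_base) - vc) / tau
        qin = (pa - p) / rn
        phi = phi_r * (P_REF + gamma) / (p + gamma)
        return ((qin - c * p - dvc) / phi, dvc)

    times, p_true, q_true = [], [], []
    state = (p_base, 0.0)
    t0 = 0.0
    for k, pa in enumerate(levels):
        t_eval = t0 + dt * np.arange(n_per)
        sol = solve_ivp(
            rhs,
            (t_eval[0], t_eval[-1] + dt),
            state,
            t_eval=t_eval,
            args=(pa,),
            method="LSODA",
            rtol=1e-8,
            atol=1e-8,
        )
        if not sol.success:
            raise RuntimeError(
                f"perfusion ODE failed on level {k} (applied {pa:g} mmHg): {sol.message}"
            )
        times.append(sol.t)
        p_true.append(sol.y[0])
        q_true.append((pa - sol.y[0]) / rn)
        # advance the state to the start of the next level
        end = solve_ivp(
            rhs,
            (t_eval[-1], t_eval[-1] + dt),
            (sol.y[0][-1], sol.y[1][-1]),
            args=(pa,),
            method="LSODA",
            rtol=1e-8,
            atol=1e-8,
        )
        state = (end.y[0][-1], end.y[1][-1])
        t0 = t_eval[-1] + dt

    time = np.concatenate(times)
    p = np.concatenate(p_true)
    q = np.concatenate(q_true)
    p_applied = np.repeat(levels, n_per)
    p_meas = p + rng.normal(0.0, protocol.pressure_noise_sd, p.size)
    q_meas = q + rng.normal(0.0, protocol.flow_noise_sd, q.size)
    return PerfusionTrace(
        time=time,
        p_applied=p_applied,
        p_measured=p_meas,
        q_in=q_meas,
        eye_id=eye.eye_id,
        strain=eye.strain,
        mass=eye.mass,
        extra={"ground_truth": eye},
    )


# ---------------------------------------------------------------------------
# whole-study generator
# ---------------------------------------------------------------------------


def simulate_study(
    n_strains: int = 20,
    n_eyes_per_strain: int = 8,
    arch: TraitArchitecture = TraitArchitecture(),
    protocol: Protocol = Protocol(),
    marker_map: MarkerMap | None = None,
    base_phi_norm: float = 2.4,
    mass_mean: float = 21.1,
    mass_strain_sd: float = 1.0,
    mass_eye_sd: float = 0.3,
    gamma_log_sd: float = 0.15,
    facility_mean: float = 0.07,
    facility_sd: float = 0.015,
    creep_compliance: float = 0.0,
    creep_tau: float = 90.0,
    thickness_mean_mm: float = 0.1,
    thickness_sd_mm: float = 0.005,
    seed: int = 0,
) -> dict:
    """Generate a full synthetic study: genotypes, eye truth table, traces.

    Returns a dict with ``genotypes`` (GenotypeMatrix), ``eyes`` (DataFrame of
    GroundTruthEye parameters, one row per eye), ``traces`` (list of
    PerfusionTrace), ``thickness`` (per-strain corneal thickness table, mm)
    and ``arch``.  All randomness flows from ``seed`` via spawned generators.
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_trait, s_body, s_traces, s_cct = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    if marker_map is None:
        marker_map = default_marker_map()
    genotypes = simulate_ri_genotypes(marker_map, n_strains, s_geno)
    trait = simulate_trait(
        genotypes, marker_map, arch, n_eyes_per_strain, base_phi_norm, s_trait
    )

    rng = np.random.default_rng(s_body)
    strain_mass = {
        s: rng.normal(mass_mean, mass_strain_sd) for s in genotypes.strains
    }
    eyes = []
    for _, row in trait.iterrows():
        mass = max(strain_mass[row["strain"]] + rng.normal(0.0, mass_eye_sd), 5.0)
        phi_norm = max(row["true_phi_norm"], 0.2)
        eyes.append(
            GroundTruthEye(
                eye_id=row["eye_id"],
                strain=row["strain"],
                animal_id=row["animal_id"],
                eye=row["eye"],
                mass=mass,
                phi_r_true=phi_norm * (mass / EYE_DENSITY),
                gamma_true=float(np.exp(rng.normal(np.log(10.0), gamma_log_sd))),
                facility_true=float(np.clip(rng.normal(facility_mean, facility_sd), 0.01, None)),
                creep_compliance=creep_compliance,
                creep_tau=creep_tau,
            )
        )

    trace_seeds = np.random.SeedSequence(s_traces).spawn(len(eyes))
    traces = [
        simulate_perfusion_trace(eye, protocol, int(c.generate_state(1)[0] % (2**31)))
        for eye, c in zip(eyes, trace_seeds)
    ]

    rng_cct = np.random.default_rng(s_cct)
    thickness = pd.DataFrame(
        {
            "strain": genotypes.strains,
            "thickness_mm": np.clip(
                rng_cct.normal(thickness_mean_mm, thickness_sd_mm, n_strains),
                0.05,
                None,
            ),
        }
    )

    eye_table = pd.DataFrame(
        {
            "eye_id": [e.eye_id for e in eyes],
            "animal_id": [e.animal_id for e in eyes],
            "strain": [e.strain for e in eyes],
            "eye": [e.eye for e in eyes],
            "mass_mg": [e.mass for e in eyes],
            "phi_r_true": [e.phi_r_true for e in eyes],
            "gamma_true": [e.gamma_true for e in eyes],
            "facility_true": [e.facility_true for e in eyes],
            "phi_norm_true": [e.phi_norm_true for e in eyes],
        }
    )
    eye_table.attrs.update(trait.attrs)
    return {
        "genotypes": genotypes,
        "eyes": eye_table,
        "ground_truth": eyes,
        "traces": traces,
        "thickness": thickness,
        "arch": arch,
    }
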