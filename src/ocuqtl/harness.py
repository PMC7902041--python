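"""File formats, configuration and the end-to-end pipeline.

Formats
-------
* Trace CSV: header ``time_s,p_applied_mmHg,p_measured_mmHg,q_nl_s``; unknown
  columns are preserved round-trip.  A companion metadata CSV carries
  ``eye_id,strain,eye,mass_mg`` (plus optional ``animal_id``).
* Genotypes: GeneNetwork-style tab-delimited text with columns
  ``Chr, Locus, cM, Mb`` followed by one column per strain holding B/D/H/U
  calls (H and U are treated as missing); ``#``/``@`` lines are skipped.
* Config: a YAML file mirroring :class:`RunConfig`.

The pipeline (``run_pipeline``) chains simulation (or file input) ->
per-step compliance estimation -> reference-compliance fit -> volume
normalisation -> QC cascade -> strain aggregation -> heritability -> genome
scan -> permutation thresholds -> peak calling, with optional effective
modulus and VF-vs-SR comparison, all deterministic under the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import linkage, phenotypes, simkit
from .perfusion import (
    DEFAULT_NEEDLE_RESISTANCE,
    EYE_DENSITY,
    P_REF,
    ConvergenceError,
    PerfusionTrace,
    analyze_trace,
    normalize_compliance,
)

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "RunSummary",
    "read_trace",
    "write_trace",
    "read_metadata",
    "write_metadata",
    "read_genotypes",
    "write_genotypes",
    "run_pipeline",
]

log = logging.getLogger("ocuqtl")

TRACE_COLUMNS = ["time_s", "p_applied_mmHg", "p_measured_mmHg", "q_nl_s"]
GENO_FIXED = ["Chr", "Locus", "cM", "Mb"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# trace and metadata I/O
# ---------------------------------------------------------------------------


def write_trace(trace: PerfusionTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "p_applied_mmHg": trace.p_applied,
            "p_measured_mmHg": trace.p_measured,
            "q_nl_s": trace.q_in,
        }
    )
    for name, values in trace.extra.items():
        if isinstance(values, np.ndarray) and values.shape == trace.time.shape:
            df[name] = values
    df.to_csv(path, index=False, float_format="%.10g")


def read_trace(path, eye_id: str = "", strain: str = "", mass: float = float("nan")) -> PerfusionTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trace file {path} missing required column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise DataError(f"trace file {path}: time_s is not strictly increasing")
    extra = {
        c: df[c].to_numpy() for c in df.columns if c not in TRACE_COLUMNS
    }
    return PerfusionTrace(
        time=t,
        p_applied=df["p_applied_mmHg"].to_numpy(dtype=float),
        p_measured=df["p_measured_mmHg"].to_numpy(dtype=float),
        q_in=df["q_nl_s"].to_numpy(dtype=float),
        eye_id=eye_id,
        strain=strain,
        mass=mass,
        extra=extra,
    )


def write_metadata(meta: pd.DataFrame, path) -> None:
    required = ["eye_id", "strain", "eye", "mass_mg"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise DataError(f"metadata missing column(s) {missing}")
    meta.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = ["eye_id", "strain", "eye", "mass_mg"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise DataError(f"metadata file {path} missing column(s) {missing}")
    if "animal_id" not in meta.columns:
        # pair eyes by strain + specimen index when animal ids are absent
        meta = meta.copy()
        idx = meta.groupby("strain").cumcount()
        meta["animal_id"] = meta["strain"] + "_a" + (idx // 2 + 1).astype(str)
    return meta


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def read_genotypes(path) -> simkit.GenotypeMatrix:
    """Parse a GeneNetwork-style genotype file; H/U calls become missing."""
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            rows.append(parts)
    if header is None or header[: len(GENO_FIXED)] != GENO_FIXED:
        raise DataError(
            f"genotype file {path} must start with columns {GENO_FIXED}"
        )
    strains = header[len(GENO_FIXED):]
    if not strains:
        raise DataError(f"genotype file {path} has no strain columns")
    df = pd.DataFrame(rows, columns=header)
    if df["Locus"].duplicated().any():
        dup = df.loc[df["Locus"].duplicated(), "Locus"].iloc[0]
        raise DataError(f"duplicate locus name {dup!r} in {path}")
    try:
        df["cM"] = df["cM"].astype(float)
        df["Mb"] = df["Mb"].astype(float)
    except ValueError as exc:
        raise DataError(f"unsortable positions in {path}: {exc}") from exc
    df = (
        df.sort_values(["Chr", "cM"], kind="stable")
        .reset_index(drop=True)
    )
    mm = simkit.MarkerMap(
        pd.DataFrame(
            {
                "name": df["Locus"],
                "chromosome": df["Chr"],
                "cM": df["cM"],
                "Mb": df["Mb"],
            }
        )
    )
    code = {"B": 0, "D": 1, "H": -1, "U": -1}
    calls = np.empty((len(strains), len(df)), dtype=np.int8)
    n_missing = 0
    for j, s in enumerate(strains):
        col = df[s].str.strip().str.upper().map(code)
        if col.isna().any():
            bad = df[s][col.isna()].iloc[0]
            raise DataError(f"unknown genotype code {bad!r} for strain {s}")
        calls[j] = col.to_numpy(dtype=np.int8)
        n_missing += int((calls[j] < 0).sum())
    gm = simkit.GenotypeMatrix(strains=list(strains), markers=mm, calls=calls)
    if n_missing:
        log.info("genotypes: %d missing (H/U) calls", n_missing)
    return gm


def write_genotypes(genotypes: simkit.GenotypeMatrix, path) -> None:
    mm = genotypes.markers.table
    letters = np.array(["B", "D"])
    with open(path, "w") as fh:
        fh.write("\t".join(GENO_FIXED + list(genotypes.strains)) + "\n")
        for j in range(len(mm)):
            calls = genotypes.calls[:, j]
            codes = [letters[c] if c >= 0 else "U" for c in calls]
            fh.write(
                "\t".join(
                    [
                        str(mm["chromosome"].iloc[j]),
                        str(mm["name"].iloc[j]),
                        f"{mm['cM'].iloc[j]:.6g}",
                        f"{mm['Mb'].iloc[j]:.6g}",
                    ]
                    + codes
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulateBlock:
    """Synthetic-study parameters (used when no input files are given)."""

    n_strains: int = 20
    n_eyes_per_strain: int = 8
    variance_explained: float = 0.37
    qtl_chromosome: str = "11"
    qtl_position_cM: float = 44.0
    strain_env_sd: float = 0.20
    eye_env_sd: float = 0.25
    base_phi_norm: float = 2.4
    creep_compliance: float = 0.0
    creep_tau: float = 90.0
    protocol: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults match the printed constants."""

    methods: tuple[str, ...] = ("VF", "SR")
    p_ref: float = P_REF  # mmHg
    density: float = EYE_DENSITY  # mg/ul
    needle_resistance: float = DEFAULT_NEEDLE_RESISTANCE  # mmHg*s/nl
    qc_percentile: float = 15.0
    iqr_k: float = 1.5
    n_perm: int = 2000
    grid_step_cM: float = 1.0
    seed: int = 0
    outdir: str = "ocuqtl_out"
    simulate: SimulateBlock | None = field(default_factory=SimulateBlock)
    trace_dir: str | None = None
    metadata: str | None = None
    genotypes: str | None = None
    thickness: str | None = None
    run_modulus: bool = True
    run_comparison: bool = True

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        bad = [m for m in self.methods if m not in ("VF", "SR")]
        if bad or not self.methods:
            raise ConfigError(f"methods must be a non-empty subset of VF/SR, got {self.methods}")
        if self.p_ref <= 0 or self.density <= 0 or self.needle_resistance <= 0:
            raise ConfigError("p_ref, density and needle_resistance must be positive")
        if not (0 < self.qc_percentile < 100):
            raise ConfigError("qc_percentile must lie in (0, 100)")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be at least 100")
        if self.simulate is None and (self.trace_dir is None or self.metadata is None):
            raise ConfigError("either a simulate block or trace_dir+metadata is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(SimulateBlock)}
            bad = set(sim) - sim_known
            if bad:
                raise ConfigError(f"unknown simulate keys {sorted(bad)}")
            raw["simulate"] = SimulateBlock(**sim)
        elif "trace_dir" in raw:
            raw["simulate"] = None
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d


@dataclass
class RunSummary:
    seed: int
    config: dict
    counts: dict
    outputs: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "software": "ocuqtl 0.1.0",
                "seed": self.seed,
                "counts": self.counts,
                "outputs": self.outputs,
                "config": self.config,
            },
            indent=2,
            default=str,
        )


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def estimate_eye_table(
    traces: list[PerfusionTrace],
    metadata: pd.DataFrame,
    methods: tuple[str, ...] = ("VF", "SR"),
    needle_resistance: float = DEFAULT_NEEDLE_RESISTANCE,
    p_ref: float = P_REF,
    density: float = EYE_DENSITY,
) -> pd.DataFrame:
    """Per-eye reference compliance for every requested method.

    Eyes whose fit fails are skipped with a log message; the result follows
    the :data:`ocuqtl.phenotypes.EYE_TABLE_COLUMNS` schema.
    """
    meta = metadata.set_index("eye_id")
    rows = []
    failures = 0
    for trace in traces:
        m = meta.loc[trace.eye_id]
        try:
            fits = analyze_trace(
                trace,
                needle_resistance=needle_resistance,
                methods=methods,
                p_ref=p_ref,
            )
        except (ConvergenceError, ValueError) as exc:
            failures += 1
            log.warning("eye %s skipped: %s", trace.eye_id, exc)
            continue
        for method, fit in fits.items():
            phi_norm, se_norm, volume = normalize_compliance(fit, float(m["mass_mg"]), density)
            rows.append(
                {
                    "eye_id": trace.eye_id,
                    "animal_id": m.get("animal_id", trace.eye_id),
                    "strain": m["strain"],
                    "eye": m["eye"],
                    "mass_mg": float(m["mass_mg"]),
                    "volume_ul": volume,
                    "method": method,
                    "phi_r": fit.phi_r,
                    "se_phi_r": fit.se_phi_r,
                    "gamma": fit.gamma,
                    "phi_norm": phi_norm,
                    "n_steps": fit.n_steps_used,
                }
            )
    if failures:
        log.info("estimation: %d eye(s) failed and were skipped", failures)
    return pd.DataFrame(rows, columns=phenotypes.EYE_TABLE_COLUMNS)


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the full analysis and return all stage results.

    Returns a dict with keys ``eye_table`` (QC-annotated records),
    ``qc_report``, ``strain_tables`` (per method), ``heritability``,
    ``scans``, ``thresholds``, ``peaks``, optional ``modulus`` and
    ``bland_altman``, and ``summary`` (:class:`RunSummary`).  With
    ``write=True`` every table is also written under ``config.outdir``.
    """
    ss = np.random.SeedSequence(config.seed)
    seed_sim, seed_perm = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))

    if config.simulate is not None:
        sim = config.simulate
        arch = simkit.TraitArchitecture(
            qtl_chromosome=sim.qtl_chromosome,
            qtl_position_cM=sim.qtl_position_cM,
            variance_explained=sim.variance_explained,
            strain_env_sd=sim.strain_env_sd,
            eye_env_sd=sim.eye_env_sd,
        )
        protocol = simkit.Protocol(**sim.protocol)
        log.info(
            "simulating study: %d strains x %d eyes", sim.n_strains, sim.n_eyes_per_strain
        )
        study = simkit.simulate_study(
            n_strains=sim.n_strains,
            n_eyes_per_strain=sim.n_eyes_per_strain,
            arch=arch,
            protocol=protocol,
            base_phi_norm=sim.base_phi_norm,
            creep_compliance=sim.creep_compliance,
            creep_tau=sim.creep_tau,
            seed=seed_sim,
        )
        traces = study["traces"]
        metadata = study["eyes"][["eye_id", "animal_id", "strain", "eye", "mass_mg"]]
        genotypes = study["genotypes"]
        thickness = study["thickness"]
        truth = study["eyes"]
    else:
        trace_dir = Path(config.trace_dir)
        metadata = read_metadata(config.metadata)
        traces = [
            read_trace(
                trace_dir / f"{row.eye_id}.csv",
                eye_id=row.eye_id,
                strain=row.strain,
                mass=row.mass_mg,
            )
            for row in metadata.itertuples()
        ]
        genotypes = read_genotypes(config.genotypes) if config.genotypes else None
        thickness = (
            pd.read_csv(config.thickness) if config.thickness else None
        )
        truth = None

    log.info("estimating compliance for %d traces (%s)", len(traces), "/".join(config.methods))
    eye_table = estimate_eye_table(
        traces,
        metadata,
        methods=config.methods,
        needle_resistance=config.needle_resistance,
        p_ref=config.p_ref,
        density=config.density,
    )
    if eye_table.empty:
        raise DataError("estimation produced no usable eyes")

    eye_table = phenotypes.apply_qc(eye_table, config.qc_percentile, config.iqr_k)
    report = phenotypes.qc_report(eye_table)
    log.info("QC report:\n%s", report.to_string(index=False))

    strain_tables: dict[str, pd.DataFrame] = {}
    herit: dict[str, phenotypes.HeritabilityResult] = {}
    scans: dict[str, pd.DataFrame] = {}
    thresholds: dict[str, linkage.PermutationThresholds] = {}
    peak_rows = []
    modulus_tables: dict[str, pd.DataFrame] = {}

    grid = dosage = None
    if genotypes is not None:
        grid, dosage = linkage.impute_dosage(genotypes, config.grid_step_cM)

    for method in config.methods:
        sub = eye_table[eye_table["method"] == method]
        table, anova_p = phenotypes.aggregate_strains(sub)
        table.attrs["anova_p"] = anova_p
        strain_tables[method] = table
        log.info("%s: %d strains, ANOVA p=%.3g", method, len(table), anova_p)
        try:
            herit[method] = phenotypes.heritability(table)
        except ValueError as exc:
            log.warning("%s heritability skipped: %s", method, exc)

        if genotypes is not None and len(table) >= 3:
            pheno = table.set_index("strain")["mean_phi_norm"]
            pheno = pheno.reindex(genotypes.strains).dropna()
            keep = [genotypes.strains.index(s) for s in pheno.index]
            scan = linkage.scan_genome(pheno, grid, dosage[keep])
            thr = linkage.permutation_thresholds(
                pheno, grid, dosage[keep], n_perm=config.n_perm, seed=seed_perm
            )
            scans[method] = scan.to_frame()
            thresholds[method] = thr
            for pk in linkage.find_peaks(scan, thr, genotypes.markers):
                peak_rows.append({"method": method, **dataclasses.asdict(pk)})

        if config.run_modulus and thickness is not None:
            merged = sub[sub["kept"]].merge(thickness, on="strain", how="inner")
            dropped = set(sub["strain"]) - set(merged["strain"])
            if dropped:
                log.info(
                    "%s modulus: strains without thickness dropped: %s",
                    method,
                    sorted(dropped),
                )
            if not merged.empty:
                mods = [
                    phenotypes.effective_modulus(
                        phi=row.phi_r,
                        volume=row.volume_ul * 1000.0,
                        thickness=row.thickness_mm,
                        pressure=config.p_ref,
                    ).e_effective_kPa
                    for row in merged.itertuples()
                ]
                merged = merged.assign(e_effective_kPa=mods)
                modulus_tables[method] = merged[
                    ["eye_id", "strain", "method", "thickness_mm", "e_effective_kPa"]
                ]

    bland = None
    if config.run_comparison and {"VF", "SR"} <= set(config.methods):
        kept = eye_table[eye_table["kept"]]
        vf = kept[kept["method"] == "VF"].set_index("eye_id")["phi_norm"]
        sr = kept[kept["method"] == "SR"].set_index("eye_id")["phi_norm"]
        common = vf.index.intersection(sr.index)
        if len(common) >= 2:
            bland = phenotypes.compare_methods(vf.loc[common], sr.loc[common])
            log.info("Bland-Altman VF-SR bias %.4g (n=%d)", bland.bias, bland.n)

    counts = {
        "eyes_in": int(eye_table["eye_id"].nunique()),
        "records_in": len(eye_table),
        "per_method": report.set_index("method").to_dict("index"),
        "strains": {m: len(t) for m, t in strain_tables.items()},
    }
    outputs: dict[str, str] = {}
    summary = RunSummary(
        seed=config.seed, config=config.to_dict(), counts=counts, outputs=outputs
    )
    results = {
        "eye_table": eye_table,
        "qc_report": report,
        "strain_tables": strain_tables,
        "heritability": herit,
        "scans": scans,
        "thresholds": thresholds,
        "peaks": pd.DataFrame(peak_rows),
        "modulus": modulus_tables,
        "bland_altman": bland,
        "truth": truth,
        "genotypes": genotypes,
        "summary": summary,
    }
    if write:
        _write_outputs(config, results)
    return results


def _write_outputs(config: RunConfig, results: dict) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        results["summary"].outputs[name] = str(path)

    save(results["eye_table"], "eye_records.csv")
    save(results["qc_report"], "qc_report.csv")
    for method, table in results["strain_tables"].items():
        save(table, f"strain_phenotypes_{method}.csv")
    if results["heritability"]:
        save(
            pd.DataFrame(
                [
                    {"method": m, "vg": h.vg, "ve": h.ve, "h2": h.h2, "n_strains": h.n_strains}
                    for m, h in results["heritability"].items()
                ]
            ),
            "heritability.csv",
        )
    for method, scan in results["scans"].items():
        save(scan, f"scan_{method}.csv")
    if results["thresholds"]:
        save(
            pd.DataFrame(
                [
                    {
                        "method": m,
                        "n_perm": t.n_perm,
                        "threshold_significant": t.threshold_significant,
                        "threshold_suggestive": t.threshold_suggestive,
                    }
                    for m, t in results["thresholds"].items()
                ]
            ),
            "thresholds.csv",
        )
    if len(results["peaks"]):
        save(results["peaks"], "peaks.csv")
    for method, table in results["modulus"].items():
        save(table, f"modulus_{method}.csv")
    if results["bland_altman"] is not None:
        b = results["bland_altman"]
        save(
            pd.DataFrame(
                [
                    {
                        "bias": b.bias,
                        "sd": b.sd,
                        "loa_low": b.loa_low,
                        "loa_high": b.loa_high,
                        "trend_slope": b.trend_slope,
                        "n": b.n,
                    }
                ]
            ),
            "bland_altman.csv",
        )
    (out / "run_summary.json").write_text(results["summary"].to_json())
    results["summary"].outputs["run_summary.json"] = str(out / "run_summary.json")
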