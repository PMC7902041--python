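"""Quality control, strain aggregation, heritability and derived phenotypes.

Per-eye normalised compliance records pass through a fixed QC cascade:

1. flag eyes in the top 15th percentile of relative uncertainty on phi_r
   (per estimation method, over the whole data set);
2. of each animal's pair of eyes, keep the one with lower uncertainty
   (an uncertainty-flagged eye always loses to an unflagged one);
3. flag within-strain outliers lying more than 1.5 interquartile ranges
   beyond the quartiles.

Surviving eyes are averaged per strain; broad-sense heritability is the
between-strain dispersion over total dispersion, H2 = Vg/(Vg+Ve), computed —
exactly as the source procedure words it — from standard deviations: Vg is
the SD of strain means and Ve the mean within-strain SD.  (A variance-based
variant is available but non-default; the SD form is what the symbols Vg/Ve
are defined to mean here.)

The effective tensile modulus of the corneoscleral shell treats the eye as a
thin-walled incompressible sphere: E = (3R/4t)(V/phi + P), with R from the
sphere volume-radius relation and central corneal thickness standing in for
shell thickness.

Quantile convention throughout: linear interpolation of order statistics
(numpy default).

Eye-record tables are plain DataFrames with the columns listed in
:data:`EYE_TABLE_COLUMNS`; QC adds boolean flag columns and ``kept``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EYE_TABLE_COLUMNS",
    "QC_FLAG_COLUMNS",
    "MMHG_TO_KPA",
    "HeritabilityResult",
    "ModulusResult",
    "BlandAltmanResult",
    "filter_by_uncertainty",
    "select_best_eyes",
    "remove_outliers_iqr",
    "apply_qc",
    "aggregate_strains",
    "heritability",
    "effective_modulus",
    "compare_methods",
    "correlate",
]

#: Schema of a per-eye record table (one row per eye x method).
EYE_TABLE_COLUMNS = [
    "eye_id",
    "animal_id",
    "strain",
    "eye",
    "mass_mg",
    "volume_ul",
    "method",
    "phi_r",
    "se_phi_r",
    "gamma",
    "phi_norm",
    "n_steps",
]

QC_FLAG_COLUMNS = ["flag_high_uncertainty", "flag_not_best_eye", "flag_strain_outlier"]

#: 1 mmHg in kPa.
MMHG_TO_KPA = 0.133322


@dataclass
class HeritabilityResult:
    vg: float  # between-strain dispersion (SD of strain means)
    ve: float  # mean within-strain dispersion
    h2: float  # vg / (vg + ve)
    n_strains: int


@dataclass
class ModulusResult:
    radius_mm: float
    thickness_mm: float
    pressure_mmHg: float
    compliance_nl_mmHg: float
    volume_nl: float
    e_effective_kPa: float


@dataclass
class BlandAltmanResult:
    bias: float  # mean of VF - SR
    sd: float
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    trend_slope: float  # slope of difference on pair mean
    n: int
    differences: np.ndarray
    means: np.ndarray


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------


def filter_by_uncertainty(records: pd.DataFrame, percentile: float = 15.0) -> pd.DataFrame:
    """Flag eyes in the top ``percentile`` of relative phi_r uncertainty.

    The cut is per method: records whose ``se_phi_r / phi_r`` strictly exceed
    the (100 - percentile)th percentile of the whole data set are flagged
    ``flag_high_uncertainty``.  Returns a copy with the flag column set.
    """
    out = records.copy()
    rel = out["se_phi_r"] / out["phi_r"]
    if rel.notna().sum() < 2:
        raise ValueError("need at least 2 records with finite relative SE")
    out["flag_high_uncertainty"] = False
    for _, idx in out.groupby("method").groups.items():
        r = rel.loc[idx]
        finite = r[np.isfinite(r)]
        if len(finite) < 2:
            raise ValueError("need at least 2 records with finite relative SE per method")
        cut = np.quantile(finite, 1.0 - percentile / 100.0)
        out.loc[idx, "flag_high_uncertainty"] = (r > cut).fillna(True)
    return out


def select_best_eyes(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one eye per animal: the unflagged eye with lower uncertainty.

    Within each (method, animal) group, eyes already flagged for high
    uncertainty are out of contention; among the rest, all but the
    lowest-``se_phi_r`` eye are flagged ``flag_not_best_eye``.  Ties break on
    laterality order (OD before OS), which is deterministic.  Singletons are
    kept.
    """
    out = records.copy()
    out["flag_not_best_eye"] = False
    hu = out.get("flag_high_uncertainty", pd.Series(False, index=out.index))
    eye_rank = out["eye"].map({"OD": 0, "OS": 1}).fillna(2)
    for _, idx in out.groupby(["method", "animal_id"]).groups.items():
        idx = pd.Index(idx if isinstance(idx, (list, pd.Index)) else [idx])
        contenders = [i for i in idx if not hu.loc[i]]
        if len(contenders) <= 1:
            continue
        best = min(contenders, key=lambda i: (out.at[i, "se_phi_r"], eye_rank.loc[i]))
        losers = [i for i in contenders if i != best]
        out.loc[losers, "flag_not_best_eye"] = True
    return out


def remove_outliers_iqr(values, k: float = 1.5) -> np.ndarray:
    """Boolean outlier mask by the Tukey fence rule.

    Values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` are flagged; quartiles use
    linear interpolation of order statistics.  With fewer than 4 values no
    removal is attempted (a warning is issued).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        warnings.warn("fewer than 4 values; IQR outlier removal skipped", stacklevel=2)
        return np.zeros(v.size, dtype=bool)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)


def apply_qc(
    records: pd.DataFrame, percentile: float = 15.0, iqr_k: float = 1.5
) -> pd.DataFrame:
    """Run the full QC cascade and annotate (never drop) records.

    Order is fixed: uncertainty filter, best-eye selection, per-strain IQR
    outliers on ``phi_norm`` among the survivors of the first two stages.
    All thresholds are computed on the full input table, so applying
    ``apply_qc`` to its own output reproduces it exactly (idempotence), and
    ``kept + flagged == input`` at every stage.
    """
    base = records.drop(columns=[c for c in QC_FLAG_COLUMNS + ["kept"] if c in records],
                        errors="ignore")
    out = filter_by_uncertainty(base, percentile)
    out = select_best_eyes(out)
    out["flag_strain_outlier"] = False
    survivors = ~(out["flag_high_uncertainty"] | out["flag_not_best_eye"])
    for _, idx in out[survivors].groupby(["method", "strain"]).groups.items():
        idx = pd.Index(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = remove_outliers_iqr(out.loc[idx, "phi_norm"].to_numpy(), iqr_k)
        out.loc[idx[mask], "flag_strain_outlier"] = True
    out["kept"] = ~out[QC_FLAG_COLUMNS].any(axis=1)
    return out


def qc_report(records: pd.DataFrame) -> pd.DataFrame:
    """Per-stage counts, reconciling kept + flagged = input for each method."""
    rows = []
    for method, grp in records.groupby("method"):
        rows.append(
            {
                "method": method,
                "eyes_in": len(grp),
                "flagged_high_uncertainty": int(grp["flag_high_uncertainty"].sum()),
                "flagged_not_best_eye": int(grp["flag_not_best_eye"].sum()),
                "flagged_strain_outlier": int(grp["flag_strain_outlier"].sum()),
                "kept": int(grp["kept"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation and heritability
# ---------------------------------------------------------------------------


def aggregate_strains(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Strain means with SD and t-based 95% CI, plus a one-way ANOVA p-value.

    Operates on QC-kept records of a single method.  Returns
    ``(strain_table, anova_p)``; the ANOVA across strains is a diagnostic and
    is skipped (p = nan, with a warning) when fewer than two strains are
    present.
    """
    if "kept" in records:
        records = records[records["kept"]]
    rows = []
    groups = []
    for strain, grp in records.groupby("strain", sort=True):
        v = grp["phi_norm"].to_numpy(dtype=float)
        if v.size == 0:
            warnings.warn(f"strain {strain} has no kept eyes; omitted", stacklevel=2)
            continue
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        if v.size > 1 and sd > 0:
            half = stats.t.ppf(0.975, v.size - 1) * sd / np.sqrt(v.size)
        else:
            half = 0.0 if v.size > 1 else float("nan")
        rows.append(
            {
                "strain": strain,
                "n_eyes": int(v.size),
                "mean_phi_norm": mean,
                "sd": sd,
                "ci95_low": mean - half,
                "ci95_high": mean + half,
            }
        )
        groups.append(v)
    table = pd.DataFrame(rows)
    usable = [g for g in groups if g.size >= 1]
    if len(usable) >= 2 and sum(g.size for g in usable) > len(usable):
        anova_p = float(stats.f_oneway(*usable).pvalue)
    else:
        warnings.warn("ANOVA skipped: need at least two strains with replicates",
                      stacklevel=2)
        anova_p = float("nan")
    return table, anova_p


def heritability(
    strain_table: pd.DataFrame, use_variances: bool = False
) -> HeritabilityResult:
    """Broad-sense heritability H2 = Vg/(Vg+Ve) across strain summaries.

    Default (literal) form: Vg = SD of strain means, Ve = mean of
    within-strain SDs.  ``use_variances=True`` squares both dispersions
    first.  Strains lacking an SD (single eye) are excluded with a warning.
    """
    t = strain_table
    ok = t["sd"].notna()
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} strain(s) lack an SD and are excluded from H2",
            stacklevel=2,
        )
    t = t[ok]
    if len(t) < 2:
        raise ValueError("need at least 2 strains with SDs for heritability")
    vg = float(np.std(t["mean_phi_norm"].to_numpy(), ddof=1))
    ve = float(np.mean(t["sd"].to_numpy()))
    if use_variances:
        vg, ve = vg**2, ve**2
    h2 = vg / (vg + ve) if (vg + ve) > 0 else 0.0
    return HeritabilityResult(vg=vg, ve=ve, h2=h2, n_strains=len(t))


# ---------------------------------------------------------------------------
# effective modulus
# ---------------------------------------------------------------------------


def effective_modulus(
    phi: float, volume: float, thickness: float, pressure: float = 13.0
) -> ModulusResult:
    """Thin-shell effective tensile modulus E = (3R/4t)(V/phi + P).

    Parameters are ``phi`` [nl/mmHg], ``volume`` [nl], ``thickness`` [mm]
    and ``pressure`` [mmHg].  The radius comes from the sphere relation
    R = (3V/4pi)^(1/3); E is evaluated in mmHg and converted to kPa.
    """
    if not (phi > 0 and volume > 0 and thickness > 0 and pressure > 0):
        raise ValueError("all inputs to effective_modulus must be positive")
    v_mm3 = volume / 1000.0  # 1 ul = 1 mm^3
    radius = (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    e_mmhg = (3.0 * radius / (4.0 * thickness)) * (volume / phi + pressure)
    return ModulusResult(
        radius_mm=radius,
        thickness_mm=thickness,
        pressure_mmHg=pressure,
        compliance_nl_mmHg=phi,
        volume_nl=volume,
        e_effective_kPa=e_mmhg * MMHG_TO_KPA,
    )


# ---------------------------------------------------------------------------
# method comparison and correlations
# ---------------------------------------------------------------------------


def compare_methods(vf: pd.Series, sr: pd.Series) -> BlandAltmanResult:
    """Bland-Altman agreement between paired VF and SR values.

    Inputs are Series indexed by eye (or strain); every index must be present
    in both.  Differences are VF - SR; limits of agreement are
    bias +/- 1.96 SD, and the slope of difference on pair mean is reported as
    a trend diagnostic.
    """
    vf, sr = pd.Series(vf), pd.Series(sr)
    if not vf.index.sort_values().equals(sr.index.sort_values()):
        raise ValueError("VF and SR inputs are not fully paired")
    sr = sr.reindex(vf.index)
    d = (vf - sr).to_numpy(dtype=float)
    m = ((vf + sr) / 2.0).to_numpy(dtype=float)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    slope = float(np.polyfit(m, d, 1)[0]) if np.ptp(m) > 0 and d.size > 2 else 0.0
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        trend_slope=slope,
        n=int(d.size),
        differences=d,
        means=m,
    )


def correlate(x, y) -> tuple[float, float, float]:
    """Pearson correlation with two-sided p-value; returns (r, r2, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlate input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)
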