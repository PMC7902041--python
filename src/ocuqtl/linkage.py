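"""Haley-Knott interval mapping of strain-mean phenotypes on an RI panel.

The strain-mean trait is regressed on the expected D-allele dosage at a grid
of genome positions (1 cM pseudomarker step plus the typed markers).  At each
position the likelihood ratio statistic is

    LRS = n * ln(RSS0 / RSS1),        LOD = LRS / (2 ln 10)

with RSS0 from the mean-only model.  Genome-wide significance is calibrated
empirically: phenotype values are permuted across strains, the genome-wide
maximum LRS recorded per permutation, and the suggestive / significant
thresholds taken as the 37th / 95th percentiles of that sample (genome-wide
p < 0.63 and p < 0.05 respectively).

Dosage expectations between typed markers condition on the nearest typed
flanking calls through the two-interval two-state chain with sib-mated
RI-expanded recombination fractions (Haldane map function); RI panels are
homozygous, so dosages at typed markers are exactly 0 or 1.

Allele coding: dosage is the probability of the D allele, and a positive
additive effect means the D allele increases the trait.  Strain means enter
the regression equally weighted.  Reported per-peak variance explained is
not corrected for the upward bias of RI strain-mean resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simkit import (
    GenotypeMatrix,
    MarkerMap,
    flank_dosage,
    haldane_recombination,
    ri_expansion,
)

__all__ = [
    "LOD_PER_LRS",
    "ScanResult",
    "PermutationThresholds",
    "QtlPeak",
    "impute_dosage",
    "scan_genome",
    "permutation_thresholds",
    "find_peaks",
]

LN10_2 = 2.0 * np.log(10.0)
LOD_PER_LRS = 1.0 / LN10_2

#: LRS drop (1.5 LOD equivalents) bounding a peak's support interval.
PEAK_DROP_LRS = 1.5 * LN10_2


@dataclass
class ScanResult:
    """Per-position linkage profile."""

    grid: pd.DataFrame  # chromosome, cM, Mb, marker
    lrs: np.ndarray
    additive_effect: np.ndarray  # slope: trait change per D-allele substitution
    half_difference: np.ndarray  # half the parental-prediction difference
    variance_explained: np.ndarray
    n_strains: int
    zero_variance: np.ndarray  # positions where dosage had no variance

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.copy()
        out["lrs"] = self.lrs
        out["lod"] = self.lrs * LOD_PER_LRS
        out["additive_effect"] = self.additive_effect
        out["half_difference"] = self.half_difference
        out["variance_explained"] = self.variance_explained
        return out


@dataclass
class PermutationThresholds:
    n_perm: int
    seed: int
    max_lrs_sample: np.ndarray
    threshold_significant: float  # genome-wide p = 0.05
    threshold_suggestive: float  # genome-wide p = 0.63

    def __post_init__(self) -> None:
        if self.threshold_significant < self.threshold_suggestive:
            raise ValueError("significant threshold below suggestive threshold")


@dataclass
class QtlPeak:
    chromosome: str
    peak_cM: float
    peak_Mb: float
    peak_lrs: float
    marker_low: str
    marker_high: str
    bound_low_Mb: float
    bound_high_Mb: float
    window_low_Mb: float  # bounds expanded by 1 Mb
    window_high_Mb: float
    classification: str  # "significant" | "suggestive"
    variance_explained: float
    additive_effect: float


# ---------------------------------------------------------------------------
# dosage imputation
# ---------------------------------------------------------------------------


def impute_dosage(
    genotypes: GenotypeMatrix, step_cM: float = 1.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expected D dosage on a pseudomarker grid for every strain.

    The grid is the union of a regular ``step_cM`` lattice and the typed
    marker positions on each chromosome.  Missing calls defer to the nearest
    typed markers; a strain with no typed marker on a chromosome gets dosage
    0.5 there (with a warning).

    Returns ``(grid, dosage)`` where ``grid`` has columns chromosome, cM, Mb,
    marker (name or "") and ``dosage`` has shape (n_strains, n_positions).
    """
    mm = genotypes.markers
    grids = []
    dosage_blocks = []
    for chrom in mm.chromosomes:
        grp = mm.chromosome_slice(chrom)
        cms = grp["cM"].to_numpy()
        lattice = np.arange(cms[0], cms[-1] + step_cM / 2.0, step_cM)
        pos = np.unique(np.concatenate([lattice, cms]))
        marker_names = pd.Series("", index=range(pos.size))
        match = np.searchsorted(pos, cms)
        marker_names.iloc[match] = grp["name"].to_numpy()
        grids.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "cM": pos,
                    "Mb": np.interp(pos, cms, grp["Mb"].to_numpy()),
                    "marker": marker_names.to_numpy(),
                }
            )
        )
        cols = grp.index.to_numpy()
        block = np.empty((genotypes.n_strains, pos.size))
        for i in range(genotypes.n_strains):
            calls = genotypes.calls[i, cols]
            typed = calls >= 0
            if not typed.any():
                warnings.warn(
                    f"strain {genotypes.strains[i]} untyped on chromosome {chrom}; "
                    "dosage set to 0.5",
                    stacklevel=2,
                )
                block[i] = 0.5
                continue
            t_cms = cms[typed]
            t_calls = calls[typed].astype(int)
            block[i] = _strain_dosage(pos, t_cms, t_calls)
        dosage_blocks.append(block)
    grid = pd.concat(grids, ignore_index=True)
    return grid, np.hstack(dosage_blocks)


def _strain_dosage(pos: np.ndarray, t_cms: np.ndarray, t_calls: np.ndarray) -> np.ndarray:
    """Dosage of one strain along one chromosome given its typed markers."""
    out = np.empty(pos.size)
    j = np.searchsorted(t_cms, pos)
    for k, x in enumerate(pos):
        jr = j[k]
        if jr < t_cms.size and t_cms[jr] == x:
            out[k] = t_calls[jr]
            continue
        jl = jr - 1
        if jl < 0:  # left of the first typed marker: single right flank
            r = float(ri_expansion(haldane_recombination(t_cms[0] - x)))
            out[k] = flank_dosage(int(t_calls[0]), None, r, None)
        elif jr >= t_cms.size:  # right of the last typed marker
            r = float(ri_expansion(haldane_recombination(x - t_cms[-1])))
            out[k] = flank_dosage(int(t_calls[-1]), None, r, None)
        else:
            r_l = float(ri_expansion(haldane_recombination(x - t_cms[jl])))
            r_r = float(ri_expansion(haldane_recombination(t_cms[jr] - x)))
            out[k] = flank_dosage(int(t_calls[jl]), int(t_calls[jr]), r_l, r_r)
    return out


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------


def _align_phenotype(phenotype: pd.Series, strains: list) -> np.ndarray:
    y = pd.Series(phenotype)
    missing = [s for s in strains if s not in y.index]
    if missing:
        raise ValueError(f"phenotype missing strains {missing[:5]}")
    return y.loc[strains].to_numpy(dtype=float)


def scan_genome(
    phenotype: pd.Series,
    grid: pd.DataFrame,
    dosage: np.ndarray,
    strains: list | None = None,
) -> ScanResult:
    """Single-QTL Haley-Knott scan of strain means over the dosage grid.

    ``phenotype`` is a Series indexed by strain.  If ``strains`` is given the
    phenotype is aligned to that order; otherwise the phenotype order must
    already match the dosage rows.
    """
    if strains is not None:
        y = _align_phenotype(phenotype, strains)
    else:
        y = pd.Series(phenotype).to_numpy(dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 strains to scan")
    if dosage.shape[0] != n:
        raise ValueError("dosage rows do not match phenotype length")

    yc = y - y.mean()
    rss0 = float(yc @ yc)
    dc = dosage - dosage.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", dc, dc)
    sxy = yc @ dc
    zero = sxx <= 1e-12 * max(1.0, float(np.max(sxx, initial=0.0)))
    slope = np.zeros(dosage.shape[1])
    np.divide(sxy, sxx, out=slope, where=~zero)
    rss1 = rss0 - slope * sxy
    rss1 = np.clip(rss1, 1e-300, None)
    lrs = np.where(zero, 0.0, n * np.log(rss0 / rss1)) if rss0 > 0 else np.zeros_like(slope)
    ve = np.where(zero, 0.0, 1.0 - rss1 / rss0) if rss0 > 0 else np.zeros_like(slope)
    return ScanResult(
        grid=grid,
        lrs=np.asarray(lrs, dtype=float),
        additive_effect=slope,
        half_difference=slope / 2.0,
        variance_explained=np.clip(ve, 0.0, 1.0),
        n_strains=n,
        zero_variance=zero,
    )


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------


def permutation_thresholds(
    phenotype: pd.Series,
    grid: pd.DataFrame,
    dosage: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    strains: list | None = None,
) -> PermutationThresholds:
    """Empirical genome-wide LRS thresholds from phenotype permutations.

    Each permutation shuffles the phenotype values across strains and records
    the genome-wide maximum LRS; thresholds are the empirical quantiles at
    1 - 0.05 (significant) and 1 - 0.63 (suggestive).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if strains is not None:
        y = _align_phenotype(phenotype, strains)
    else:
        y = pd.Series(phenotype).to_numpy(dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)

    yc = y - y.mean()
    syy = float(yc @ yc)
    dc = dosage - dosage.mean(axis=0, keepdims=True)
    sxx = np.einsum("ij,ij->j", dc, dc)
    usable = sxx > 1e-12 * max(1.0, float(np.max(sxx, initial=0.0)))
    dcu = dc[:, usable]
    norm_x = np.sqrt(sxx[usable])

    perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)  # (n_perm, n)
    cross = dcu.T @ perms.T  # (n_pos, n_perm)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (cross / norm_x[:, None]) ** 2 / syy
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    max_lrs = (-n * np.log1p(-np.max(r2, axis=0))).astype(float)
    sig, sug = np.quantile(max_lrs, [0.95, 1.0 - 0.63])
    return PermutationThresholds(
        n_perm=n_perm,
        seed=seed,
        max_lrs_sample=max_lrs,
        threshold_significant=float(sig),
        threshold_suggestive=float(sug),
    )


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------


def find_peaks(
    scan: ScanResult,
    thresholds: PermutationThresholds,
    marker_map: MarkerMap,
    drop_lrs: float = PEAK_DROP_LRS,
) -> list[QtlPeak]:
    """Local maxima above the suggestive threshold with candidate windows.

    Per chromosome, peaks are taken greedily by descending LRS; each peak's
    support extends until the profile drops ``drop_lrs`` below the peak (or
    the chromosome ends), is snapped outward to the nearest typed markers,
    and the candidate window expands those marker bounds by 1 Mb each side.
    """
    peaks: list[QtlPeak] = []
    df = scan.to_frame()
    for chrom, grp in df.groupby("chromosome", sort=False):
        lrs = grp["lrs"].to_numpy()
        cms = grp["cM"].to_numpy()
        mbs = grp["Mb"].to_numpy()
        markers = marker_map.chromosome_slice(chrom)
        claimed = np.zeros(lrs.size, dtype=bool)
        while True:
            cand = np.where(~claimed & (lrs > thresholds.threshold_suggestive))[0]
            if cand.size == 0:
                break
            top = cand[np.argmax(lrs[cand])]
            lo = top
            while lo > 0 and lrs[lo - 1] > lrs[top] - drop_lrs:
                lo -= 1
            hi = top
            while hi < lrs.size - 1 and lrs[hi + 1] > lrs[top] - drop_lrs:
                hi += 1
            claimed[lo : hi + 1] = True
            m_cms = markers["cM"].to_numpy()
            i_lo = int(np.searchsorted(m_cms, cms[lo], side="right")) - 1
            i_hi = int(np.searchsorted(m_cms, cms[hi], side="left"))
            i_lo = max(i_lo, 0)
            i_hi = min(i_hi, len(markers) - 1)
            b_lo = markers.iloc[i_lo]
            b_hi = markers.iloc[i_hi]
            classification = (
                "significant"
                if lrs[top] > thresholds.threshold_significant
                else "suggestive"
            )
            peaks.append(
                QtlPeak(
                    chromosome=str(chrom),
                    peak_cM=float(cms[top]),
                    peak_Mb=float(mbs[top]),
                    peak_lrs=float(lrs[top]),
                    marker_low=str(b_lo["name"]),
                    marker_high=str(b_hi["name"]),
                    bound_low_Mb=float(b_lo["Mb"]),
                    bound_high_Mb=float(b_hi["Mb"]),
                    window_low_Mb=float(b_lo["Mb"]) - 1.0,
                    window_high_Mb=float(b_hi["Mb"]) + 1.0,
                    classification=classification,
                    variance_explained=float(
                        grp["variance_explained"].to_numpy()[top]
                    ),
                    additive_effect=float(grp["additive_effect"].to_numpy()[top]),
                )
            )
    peaks.sort(key=lambda p: -p.peak_lrs)
    return peaks
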