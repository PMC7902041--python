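"""QC cascade, heritability, effective modulus, method comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocuqtl import phenotypes
from ocuqtl.phenotypes import MMHG_TO_KPA


def _records(se, method="VF", strain=None, phi_norm=None, animal=None, eye=None):
    n = len(se)
    return pd.DataFrame(
        {
            "eye_id": [f"e{i}" for i in range(n)],
            "animal_id": animal if animal is not None else [f"a{i}" for i in range(n)],
            "strain": strain if strain is not None else ["S1"] * n,
            "eye": eye if eye is not None else ["OD"] * n,
            "mass_mg": 21.0,
            "volume_ul": 19.0,
            "method": method,
            "phi_r": 45.0,
            "se_phi_r": se,
            "gamma": 10.0,
            "phi_norm": phi_norm if phi_norm is not None else [2.4] * n,
            "n_steps": 17,
        }
    )


# ---------------------------------------------------------------------------
# uncertainty percentile filter
# ---------------------------------------------------------------------------


def test_fifteen_percent_filter_matches_naive_order_statistics():
    rng = np.random.default_rng(0)
    se = rng.uniform(0.1, 2.0, 20)
    out = phenotypes.filter_by_uncertainty(_records(se))
    # independent naive reimplementation of the type-7 85th percentile
    rel = np.sort(se / 45.0)
    h = 0.85 * (rel.size - 1)
    lo, frac = int(np.floor(h)), 0.85 * (rel.size - 1) % 1
    cut = rel[lo] + frac * (rel[min(lo + 1, rel.size - 1)] - rel[lo])
    expected = (se / 45.0) > cut
    assert expected.sum() == 3
    assert np.array_equal(out["flag_high_uncertainty"].to_numpy(), expected)


def test_equal_uncertainties_flag_nothing():
    out = phenotypes.filter_by_uncertainty(_records([0.5] * 10))
    assert not out["flag_high_uncertainty"].any()


def test_single_record_is_an_error():
    with pytest.raises(ValueError):
        phenotypes.filter_by_uncertainty(_records([0.5]))


# ---------------------------------------------------------------------------
# best-eye selection
# ---------------------------------------------------------------------------


def test_lower_uncertainty_eye_of_pair_kept():
    df = _records([0.5, 0.3], animal=["a1", "a1"], eye=["OD", "OS"])
    df["flag_high_uncertainty"] = False
    out = phenotypes.select_best_eyes(df)
    assert out["flag_not_best_eye"].tolist() == [True, False]


def test_uncertainty_flag_trumps_lower_se():
    df = _records([0.1, 0.9], animal=["a1", "a1"], eye=["OD", "OS"])
    df["flag_high_uncertainty"] = [True, False]
    out = phenotypes.select_best_eyes(df)
    # the flagged eye is out of contention; the other survives regardless of SE
    assert not out["flag_not_best_eye"].any()


def test_singleton_eye_kept():
    df = _records([0.5], animal=["a1"])
    df["flag_high_uncertainty"] = False
    out = phenotypes.select_best_eyes(df)
    assert not out["flag_not_best_eye"].any()


def test_se_tie_breaks_on_laterality():
    df = _records([0.5, 0.5], animal=["a1", "a1"], eye=["OS", "OD"])
    df["flag_high_uncertainty"] = False
    out = phenotypes.select_best_eyes(df)
    assert out.loc[out["eye"] == "OD", "flag_not_best_eye"].tolist() == [False]
    assert out.loc[out["eye"] == "OS", "flag_not_best_eye"].tolist() == [True]


# ---------------------------------------------------------------------------
# IQR outliers
# ---------------------------------------------------------------------------


def test_tukey_fences_hand_computed_example():
    mask = phenotypes.remove_outliers_iqr([1, 2, 3, 4, 5, 100])
    # Q1 = 2.25, Q3 = 4.75, upper fence 8.5 under linear order-statistic quartiles
    assert mask.tolist() == [False, False, False, False, False, True]


def test_equal_values_and_symmetric_sets_have_no_outliers():
    assert not phenotypes.remove_outliers_iqr([3.0] * 6).any()
    assert not phenotypes.remove_outliers_iqr([1, 2, 3, 4, 5, 6]).any()


def test_small_sample_skips_removal_with_warning():
    with pytest.warns(UserWarning, match="fewer than 4"):
        mask = phenotypes.remove_outliers_iqr([1.0, 100.0, 3.0])
    assert not mask.any()


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------


def _cohort(seed=0, n_strains=5, eyes_per_strain=6):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_strains):
        for e in range(eyes_per_strain):
            rows.append(
                {
                    "eye_id": f"s{s}e{e}",
                    "animal_id": f"s{s}a{e // 2}",
                    "strain": f"S{s}",
                    "eye": "OD" if e % 2 == 0 else "OS",
                    "mass_mg": 21.0,
                    "volume_ul": 19.0,
                    "method": "VF",
                    "phi_r": 45.0 * (1 + 0.1 * rng.standard_normal()),
                    "se_phi_r": rng.uniform(0.2, 2.0),
                    "gamma": 10.0,
                    "phi_norm": 2.4 + 0.3 * rng.standard_normal(),
                    "n_steps": 17,
                }
            )
    return pd.DataFrame(rows)


def test_qc_is_idempotent_and_conserves_counts():
    df = _cohort()
    once = phenotypes.apply_qc(df)
    twice = phenotypes.apply_qc(once)
    pd.testing.assert_frame_equal(once, twice)
    report = phenotypes.qc_report(once)
    assert len(once) == len(df)
    assert (once["kept"] | once[phenotypes.QC_FLAG_COLUMNS].any(axis=1)).all()
    assert report["eyes_in"].sum() == len(df)


# ---------------------------------------------------------------------------
# aggregation, ANOVA, heritability
# ---------------------------------------------------------------------------


def test_degenerate_strain_mean_and_ci():
    df = _records([0.1] * 3, phi_norm=[2.0, 2.0, 2.0])
    table, _ = phenotypes.aggregate_strains(df)
    row = table.iloc[0]
    assert row["mean_phi_norm"] == 2.0
    assert row["sd"] == 0.0
    assert row["ci95_low"] == row["ci95_high"] == 2.0


def test_separated_strains_yield_small_anova_p():
    df = _records(
        [0.1] * 6,
        strain=["A"] * 3 + ["B"] * 3,
        phi_norm=[1.0, 1.1, 0.9, 3.0, 3.1, 2.9],
    )
    _, p = phenotypes.aggregate_strains(df)
    assert p < 0.05


def test_single_strain_skips_anova():
    with pytest.warns(UserWarning, match="ANOVA skipped"):
        _, p = phenotypes.aggregate_strains(_records([0.1] * 3))
    assert np.isnan(p)


def test_heritability_symmetric_case_and_zero_case():
    t = pd.DataFrame({"strain": list("abc"), "mean_phi_norm": [2.0, 2.25, 2.5],
                      "sd": [0.25, 0.25, 0.25], "n_eyes": 5})
    h = phenotypes.heritability(t)
    assert h.h2 == pytest.approx(
        np.std([2.0, 2.25, 2.5], ddof=1) / (np.std([2.0, 2.25, 2.5], ddof=1) + 0.25)
    )
    flat = t.assign(mean_phi_norm=2.0)
    assert phenotypes.heritability(flat).h2 == 0.0


def test_heritability_matches_independent_recomputation():
    rng = np.random.default_rng(5)
    means = 2.4 + 0.3 * rng.standard_normal(15)
    sds = rng.uniform(0.1, 0.5, 15)
    t = pd.DataFrame(
        {"strain": [f"S{i}" for i in range(15)], "mean_phi_norm": means, "sd": sds,
         "n_eyes": 8}
    )
    h = phenotypes.heritability(t)
    vg = float(np.std(means, ddof=1))
    ve = float(np.mean(sds))
    assert h.h2 == pytest.approx(vg / (vg + ve), abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(scale=st.floats(0.01, 100.0))
def test_heritability_is_scale_invariant(scale):
    t = pd.DataFrame(
        {"strain": list("abcd"), "mean_phi_norm": [1.0, 2.0, 2.5, 4.0],
         "sd": [0.2, 0.4, 0.3, 0.5], "n_eyes": 6}
    )
    base = phenotypes.heritability(t).h2
    scaled = phenotypes.heritability(
        t.assign(mean_phi_norm=t["mean_phi_norm"] * scale, sd=t["sd"] * scale)
    ).h2
    assert 0.0 <= base <= 1.0
    assert scaled == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# effective modulus
# ---------------------------------------------------------------------------


def _modulus_si(phi_nl_mmhg, volume_nl, thickness_mm, pressure_mmhg):
    """Independent rederivation in SI units (Pa, m, m^3)."""
    mmhg = 133.322  # Pa
    v = volume_nl * 1e-12  # nl -> m^3
    phi = phi_nl_mmhg * 1e-12 / mmhg  # m^3/Pa
    t = thickness_mm * 1e-3
    p = pressure_mmhg * mmhg
    r = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    e_pa = (3.0 * r / (4.0 * t)) * (v / phi + p)
    return e_pa / 1e3  # kPa


def test_modulus_worked_example_against_si_rederivation():
    res = phenotypes.effective_modulus(phi=40.0, volume=20_000.0, thickness=0.1)
    assert res.radius_mm == pytest.approx(1.684, rel=1e-3)
    assert res.e_effective_kPa == pytest.approx(863.7, rel=1e-3)
    assert res.e_effective_kPa == pytest.approx(
        _modulus_si(40.0, 20_000.0, 0.1, 13.0), rel=1e-9
    )


def test_modulus_infinite_compliance_limit():
    res = phenotypes.effective_modulus(phi=1e15, volume=20_000.0, thickness=0.1)
    r = res.radius_mm
    assert res.e_effective_kPa == pytest.approx(
        (3.0 * r / 0.4) * 13.0 * MMHG_TO_KPA, rel=1e-9
    )


def test_modulus_thickness_proportionality_and_validation():
    a = phenotypes.effective_modulus(40.0, 20_000.0, 0.1).e_effective_kPa
    b = phenotypes.effective_modulus(40.0, 20_000.0, 0.2).e_effective_kPa
    assert a == pytest.approx(2.0 * b, rel=1e-12)
    with pytest.raises(ValueError):
        phenotypes.effective_modulus(-1.0, 20_000.0, 0.1)


# ---------------------------------------------------------------------------
# Bland-Altman and correlation
# ---------------------------------------------------------------------------


def test_bland_altman_identical_and_offset_inputs():
    idx = [f"e{i}" for i in range(5)]
    x = pd.Series([2.0, 2.1, 2.2, 2.3, 2.4], index=idx)
    same = phenotypes.compare_methods(x, x)
    assert same.bias == 0.0 and same.loa_low == 0.0 and same.loa_high == 0.0
    off = phenotypes.compare_methods(x + 0.2, x)
    assert off.bias == pytest.approx(0.2)
    assert off.sd == pytest.approx(0.0, abs=1e-12)


def test_bland_altman_requires_paired_input():
    a = pd.Series([1.0, 2.0], index=["e1", "e2"])
    b = pd.Series([1.0, 2.0], index=["e1", "e3"])
    with pytest.raises(ValueError, match="paired"):
        phenotypes.compare_methods(a, b)


def test_correlation_exact_linear_and_null_behaviour():
    x = np.arange(10.0)
    r, r2, p = phenotypes.correlate(x, 2.0 * x)
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    r_null, _, _ = phenotypes.correlate(rng.normal(size=1000), rng.normal(size=1000))
    assert abs(r_null) < 0.1
    with pytest.raises(ValueError, match="variance"):
        phenotypes.correlate(x, np.ones_like(x))
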