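"""Pseudotime ordering, NB-GAM fitting, association tests and pattern
classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibroniche import pseudotime_gam as pg
from fibroniche.synthetic_data import generate_airspace_counts


# ---------------------------------------------------------------------------
# pseudotime ordering
# ---------------------------------------------------------------------------

def test_descending_share_gives_ascending_pseudotime():
    shares = pd.Series({"a1": 0.9, "a2": 0.5, "a3": 0.1})
    out = pg.order_airspaces(shares=shares)
    assert list(out["airspace_id"]) == ["a1", "a2", "a3"]
    np.testing.assert_allclose(out["pseudotime"], [1 / 3, 2 / 3, 1.0])


def test_ties_break_by_airspace_id():
    shares = pd.Series({"b": 0.5, "a": 0.5, "c": 0.5})
    out = pg.order_airspaces(shares=shares)
    assert list(out["airspace_id"]) == ["a", "b", "c"]


def test_ordering_from_labeled_transcripts():
    t = pd.DataFrame({
        "airspace_id": ["a1"] * 10 + ["a2"] * 10,
        "transcript_niche": ["T4"] * 9 + ["T1"] + ["T4"] * 2 + ["T1"] * 8,
    })
    out = pg.order_airspaces(transcript_labels=t, healthy_niche="T4")
    assert list(out["airspace_id"]) == ["a1", "a2"]
    np.testing.assert_allclose(out["healthy_share"], [0.9, 0.2])


def test_pseudotime_invariant_to_relabeling():
    shares = pd.Series({"a1": 0.9, "a2": 0.5, "a3": 0.1})
    out1 = pg.order_airspaces(shares=shares)
    renamed = pd.Series({"x1": 0.9, "x2": 0.5, "x3": 0.1})
    out2 = pg.order_airspaces(shares=renamed)
    np.testing.assert_allclose(out1["pseudotime"], out2["pseudotime"])


def test_recovers_planted_severity_ordering():
    counts, truth = generate_airspace_counts(100, 5, {}, seed=8)
    noisy_share = np.clip(1 - truth.trajectory_truth
                          + np.random.default_rng(0).normal(0, 0.05, 100), 0, 1)
    traj = pg.order_airspaces(shares=pd.Series(noisy_share, index=counts.index))
    t_of = traj.set_index("airspace_id")["pseudotime"]
    rho = stats.spearmanr(t_of[counts.index], truth.trajectory_truth).statistic
    assert rho >= 0.9


# ---------------------------------------------------------------------------
# NB-GAM core
# ---------------------------------------------------------------------------

def _nb_counts(mu, alpha, rng):
    r = 1 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def test_intercept_only_fit_matches_closed_form_glm():
    """With no smooths and Poisson-like data the fit reduces to a GLM whose
    intercept has the closed form log(sum y / sum exp(offset))."""
    rng = np.random.default_rng(0)
    off = rng.normal(3, 0.3, 400)
    y = rng.poisson(np.exp(0.7 + off)).astype(float)
    fit = pg.fit_nb_gam(y, {}, offset=off)
    expect = np.log(y.sum() / np.exp(off).sum())
    assert abs(fit.beta[0] - expect) < 1e-4
    assert fit.alpha < 0.01  # ML dispersion near zero for Poisson data


def test_nb_fit_matches_statsmodels_glm_oracle():
    """At fixed dispersion, the unpenalized intercept-only fit agrees with the
    statsmodels negative-binomial GLM."""
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    off = rng.normal(2, 0.4, 300)
    y = _nb_counts(np.exp(0.5 + off), alpha=0.3, rng=rng)
    fit = pg.fit_nb_gam(y, {}, offset=off)
    glm = sm.GLM(y, np.ones((300, 1)),
                 family=sm.families.NegativeBinomial(alpha=fit.alpha),
                 offset=off).fit()
    assert abs(fit.beta[0] - glm.params[0]) < 1e-5


def test_offset_shift_moves_intercept_only():
    rng = np.random.default_rng(1)
    n = 300
    t = (np.arange(n) + 1) / n
    mu = np.exp(2.0 + np.sin(2 * np.pi * t))
    y = _nb_counts(mu, 0.1, rng)
    f1 = pg.fit_nb_gam(y, {"t": t}, offset=np.zeros(n), lam=1.0)
    f2 = pg.fit_nb_gam(y, {"t": t}, offset=np.full(n, np.log(2.0)), lam=1.0)
    assert abs((f1.beta[0] - f2.beta[0]) - np.log(2.0)) < 1e-6
    sl = f1.smooths["t"].sl
    np.testing.assert_allclose(f1.beta[sl], f2.beta[sl], atol=1e-8)


def test_flat_gene_fits_near_constant_smooth():
    rng = np.random.default_rng(2)
    n = 300
    t = (np.arange(n) + 1) / n
    y = _nb_counts(np.full(n, 50.0), 0.2, rng)
    fit = pg.fit_nb_gam(y, {"t": t})
    grid = np.linspace(0.01, 1, 100)
    s = fit.smooth_values("t", grid)
    assert np.ptp(s) < 0.35


def test_association_null_statistic_zero():
    rng = np.random.default_rng(3)
    n = 200
    t = (np.arange(n) + 1) / n
    y = _nb_counts(np.full(n, 30.0), 0.2, rng)
    fit = pg.fit_nb_gam(y, {"t": t})
    fit.beta[fit.smooths["t"].sl] = 0.0  # zero-coefficient smooth
    res = pg.association_test({"g": fit})
    assert res.iloc[0]["wald"] == 0.0
    assert res.iloc[0]["p_value"] == 1.0


def test_association_statistic_equals_quadratic_form_oracle():
    rng = np.random.default_rng(4)
    n = 250
    t = (np.arange(n) + 1) / n
    y = _nb_counts(np.exp(3 + np.sin(2 * np.pi * t)), 0.15, rng)
    fit = pg.fit_nb_gam(y, {"t": t})
    res = pg.association_test({"g": fit})
    sl = fit.smooths["t"].sl
    b = fit.beta[sl]
    V = fit.cov[sl, sl]
    # independent oracle: explicit eigendecomposition pseudo-inverse
    w, U = np.linalg.eigh(V)
    keep = w > w.max() * 1e-10
    stat = float(((U.T @ b)[keep] ** 2 / w[keep]).sum())
    assert np.isclose(res.iloc[0]["wald"], stat, rtol=1e-8)
    assert res.iloc[0]["df"] == int(keep.sum())


def test_larger_amplitude_gives_smaller_p():
    n = 300
    t = (np.arange(n) + 1) / n
    meds = []
    for amp in [0.0, 0.4, 1.2]:
        ps = []
        for s in range(5):
            rng = np.random.default_rng(10 + s)
            mu = np.exp(3 + amp * np.sin(2 * np.pi * t))
            y = _nb_counts(mu, 0.2, rng)
            fit = pg.fit_nb_gam(y, {"t": t})
            ps.append(pg.association_test({"g": fit}).iloc[0]["p_value"])
        meds.append(np.median(ps))
    assert meds[0] > meds[1] > meds[2]


def test_nonconverged_fits_excluded_from_testing():
    rng = np.random.default_rng(5)
    n = 120
    t = (np.arange(n) + 1) / n
    y = _nb_counts(np.full(n, 20.0), 0.2, rng)
    fit = pg.fit_nb_gam(y, {"t": t})
    fit.converged = False
    res = pg.association_test({"g": fit})
    assert len(res) == 0


def test_eligibility_boundary_cell_type_rule():
    """A feature with enough counts in only 79 airspaces fails the >= 80 rule."""
    n = 200
    X = np.zeros((n, 2), dtype=int)
    X[:79, 0] = 5
    X[:80, 1] = 5
    counts = pd.DataFrame(X, columns=["ct79", "ct80"])
    keep = pg.eligible_features(counts, min_count=3, min_airspaces=80)
    assert list(keep) == ["ct80"]


def test_eligibility_fraction_rule():
    n = 100
    X = np.zeros((n, 2), dtype=int)
    X[:9, 0] = 5
    X[:10, 1] = 5
    counts = pd.DataFrame(X, columns=["n9", "n10"])
    keep = pg.eligible_features(counts, min_count=3, min_airspaces=0.1)
    assert list(keep) == ["n10"]


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def test_rolling_peak_of_triangular_profile():
    prof = np.r_[np.linspace(0, 1, 800), np.linspace(1, 0, 1200)]
    peak = pg.rolling_peak_time(prof, window=100)
    apex = 800 / 1999
    assert abs(peak - apex) <= 50 / 1999  # within half a window


def test_bimodal_rule_on_constructed_profiles():
    grid = np.linspace(0, 1, 2000)
    two_peak = np.exp(-0.5 * ((grid - 0.2) / 0.05) ** 2) + np.exp(-0.5 * ((grid - 0.8) / 0.05) ** 2)
    one_peak = np.exp(-0.5 * ((grid - 0.5) / 0.1) ** 2)

    def z(p):
        return (p - p.mean()) / p.std()

    assert pg._is_bimodal(z(two_peak))
    assert not pg._is_bimodal(z(one_peak))


def test_single_early_peak_labeled_homeostasis():
    grid = np.linspace(1 / 2000, 1, 2000)
    rng = np.random.default_rng(6)
    cols = {}
    truth = {}
    for i, c in enumerate([0.1] * 6 + [0.35] * 6 + [0.6] * 6 + [0.9] * 6):
        prof = np.exp(-0.5 * ((grid - c) / 0.1) ** 2) + rng.normal(0, 0.01, 2000)
        cols[f"g{i}"] = prof
        truth[f"g{i}"] = c
    sm = pd.DataFrame(cols, index=grid)
    out = pg.classify_patterns(sm, seed=0).set_index("gene")
    assert (out.loc[[g for g, c in truth.items() if c == 0.1], "pattern"] == "homeostasis").all()
    assert (out.loc[[g for g, c in truth.items() if c == 0.9], "pattern"] == "late").all()


def test_classification_orders_stages_by_peak_time():
    grid = np.linspace(1 / 2000, 1, 2000)
    rng = np.random.default_rng(7)
    cols = {}
    centers = {"homeostasis": 0.08, "early": 0.35, "intermediate": 0.62, "late": 0.9}
    truth = {}
    i = 0
    for stage, c in centers.items():
        for _ in range(8):
            cols[f"g{i}"] = np.exp(-0.5 * ((grid - c) / 0.09) ** 2) + rng.normal(0, 0.02, 2000)
            truth[f"g{i}"] = stage
            i += 1
    out = pg.classify_patterns(pd.DataFrame(cols, index=grid), seed=0).set_index("gene")
    acc = np.mean([out.loc[g, "pattern"] == s for g, s in truth.items()])
    assert acc >= 0.8
    means = out.groupby("pattern")["peak_time"].mean()
    assert means["homeostasis"] < means["early"] < means["intermediate"] < means["late"]


def test_too_few_unimodal_genes_skips_stage_clustering():
    grid = np.linspace(1 / 2000, 1, 2000)
    cols = {"g0": np.exp(-0.5 * ((grid - 0.2) / 0.08) ** 2),
            "g1": np.exp(-0.5 * ((grid - 0.7) / 0.08) ** 2)}
    out = pg.classify_patterns(pd.DataFrame(cols, index=grid), seed=0)
    assert set(out["pattern"]) <= set(pg.STAGE_LABELS) | {"bimodal"}


# ---------------------------------------------------------------------------
# composition-adjusted GAM
# ---------------------------------------------------------------------------

def _composition_sim(seed, mediated, n=300):
    rng = np.random.default_rng(seed)
    t = (np.arange(n) + 1) / n
    p1 = np.clip(0.1 + 0.5 * t + rng.normal(0, 0.08, n), 0.01, 0.95)
    off = np.log(rng.lognormal(5, 0.3, n))
    if mediated:
        mu = np.exp(1.0 + 2.5 * p1 + off - 5)
    else:
        mu = np.exp(1.0 + 1.2 * np.sin(np.pi * t) + off - 5)
    y = _nb_counts(mu, 0.2, rng)
    traj = pd.DataFrame({"airspace_id": np.arange(n), "pseudotime": t})
    comp = pd.DataFrame({"ct1": p1}, index=np.arange(n))
    return y, traj, comp, off


@pytest.mark.parametrize("mediated,expect_sig", [(True, False), (False, True)])
def test_composition_mediation(mediated, expect_sig):
    y, traj, comp, off = _composition_sim(42, mediated)
    counts = pd.DataFrame({"g": y}, index=np.arange(len(y)))
    fits, res = pg.celltype_level_gam({"A": counts}, traj, comp, offset=off)
    sig = res.iloc[0]["p_value"] < 0.05
    assert sig == expect_sig


def test_celltype_eligibility_rules_applied():
    rng = np.random.default_rng(9)
    n = 200
    t = (np.arange(n) + 1) / n
    traj = pd.DataFrame({"airspace_id": np.arange(n), "pseudotime": t})
    comp = pd.DataFrame({"ct1": np.full(n, 0.5)}, index=np.arange(n))
    cc = pd.DataFrame(
        {"rare": np.r_[np.full(70, 5), np.zeros(130)],
         "common": np.full(n, 5)},
        index=np.arange(n),
    )
    counts = pd.DataFrame({"g": rng.poisson(20, n)}, index=np.arange(n))
    fits, res = pg.celltype_level_gam(
        {"rare": counts, "common": counts}, traj, comp,
        offset=np.zeros(n), celltype_cells=cc, min_celltype_airspaces=80,
        min_composition_airspaces=100,
    )
    assert set(res["cell_type"]) == {"common"}


def test_gene_prevalence_rule():
    rng = np.random.default_rng(10)
    n = 200
    t = (np.arange(n) + 1) / n
    traj = pd.DataFrame({"airspace_id": np.arange(n), "pseudotime": t})
    comp = pd.DataFrame(index=np.arange(n))
    X = pd.DataFrame({
        "rare_gene": np.r_[rng.poisson(10, 80), np.zeros(120, dtype=int)],
        "common_gene": rng.poisson(10, n),
    }, index=np.arange(n))
    fits, res = pg.celltype_level_gam({"A": X}, traj, comp, offset=np.zeros(n))
    assert set(res["gene"]) == {"common_gene"}
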