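"""Odds ratios, logistic and cluster-robust fits, scan, selection, strata."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from concordpgs.association import (
    PerfectSeparationError,
    PhenotypeTable,
    assess_weight_set,
    clustered_fit,
    logistic_fit,
    screening_scan,
    select_best,
    stratified_analysis,
    table_or,
)
from concordpgs.clump import ClumpParams
from concordpgs.scoring import DosageMatrix
from conftest import make_weightset


class TestTableOR:
    def test_symmetric_table(self):
        or_, (lo, hi) = table_or(1, 1, 1, 1)
        assert or_ == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_published_top15_counts(self):
        # four-count row: 1304 / 16106 vs 4356 / 94298
        or_, _ = table_or(1304, 16106, 4356, 94298)
        assert round(or_, 2) == 1.75

    def test_published_bottom40_counts(self):
        or_, _ = table_or(1646, 44780, 4014, 65624)
        assert round(or_, 2) == 0.60

    def test_group_swap_reciprocity(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, 4)
            or1, _ = table_or(a, b, c, d)
            or2, _ = table_or(c, d, a, b)
            assert or1 == pytest.approx(1.0 / or2)

    def test_zero_cell_continuity_correction(self):
        with pytest.warns(UserWarning, match="continuity"):
            or_, (lo, hi) = table_or(0, 10, 10, 10)
        assert 0 < or_ < 1 and 0 < lo < hi < math.inf


def _sim_outcome(rng, n, ind, beta, covar_effect=None, covariates=None):
    eta = -1.0 + beta * ind
    if covar_effect is not None:
        eta = eta + covariates @ covar_effect
    return (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)


class TestLogisticFit:
    def test_no_covariates_matches_table_or(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 400).astype(float)
            ind = rng.integers(0, 2, 400).astype(float)
            counts = (
                int(((y == 1) & (ind == 1)).sum()), int(((y == 0) & (ind == 1)).sum()),
                int(((y == 1) & (ind == 0)).sum()), int(((y == 0) & (ind == 0)).sum()),
            )
            if 0 in counts:
                continue
            fit = logistic_fit(y, ind)
            or_, _ = table_or(*counts)
            assert fit.beta == pytest.approx(math.log(or_), abs=1e-6)

    def test_perfect_separation_raises(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(PerfectSeparationError):
            logistic_fit(y, y.copy())

    def test_null_type_i_error_near_nominal(self, rng):
        rejections = 0
        reps = 300
        for _ in range(reps):
            y = (rng.random(600) < 0.3).astype(float)
            ind = (rng.random(600) < 0.2).astype(float)
            if y.min() == y.max():
                continue
            fit = logistic_fit(y, ind)
            rejections += fit.p < 0.05
        assert 0.02 < rejections / reps < 0.09

    def test_covariate_adjustment_recovers_conditional_beta(self, rng):
        n = 20_000
        ind = (rng.random(n) < 0.3).astype(float)
        x = rng.standard_normal(n) + ind          # confounded covariate
        y = _sim_outcome(rng, n, ind, 0.8, np.array([0.7]), x[:, None])
        cov = pd.DataFrame({"x": x})
        fit = logistic_fit(y, ind, cov)
        assert fit.beta == pytest.approx(0.8, abs=3.5 * fit.se)
        crude = logistic_fit(y, ind)
        assert crude.beta > fit.beta  # confounding inflates the crude estimate


def _sandwich_oracle(y, X, fam):
    """Hand-rolled CR0 cluster sandwich for a logistic MLE."""
    import statsmodels.api as sm

    res = sm.Logit(y, X).fit(disp=0)
    mu = res.predict()
    W = mu * (1 - mu)
    bread = np.linalg.inv(X.T @ (X * W[:, None]))
    scores = X * (y - mu)[:, None]
    meat = np.zeros((X.shape[1], X.shape[1]))
    for f in np.unique(fam):
        s = scores[fam == f].sum(axis=0)
        meat += np.outer(s, s)
    cov = bread @ meat @ bread
    return res.params, np.sqrt(np.diag(cov))


class TestClusteredFit:
    def test_singleton_clusters_equal_plain_fit(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        ind = rng.integers(0, 2, 200).astype(float)
        plain = logistic_fit(y, ind)
        clust = clustered_fit(y, ind, None, np.arange(200))
        assert clust == plain  # exact equality of every field

    def test_duplication_matches_sandwich_oracle(self, rng):
        n = 300
        y = rng.integers(0, 2, n).astype(float)
        ind = rng.integers(0, 2, n).astype(float)
        y2 = np.repeat(y, 2)
        ind2 = np.repeat(ind, 2)
        fam2 = np.repeat(np.arange(n), 2)
        dup = clustered_fit(y2, ind2, None, fam2)
        # duplicating every individual into a 2-member family leaves both the
        # estimate and the cluster sandwich equal to the original-data
        # sandwich, up to the finite-sample factor G/(G-1) x (N-1)/(N-k)
        # applied on the duplicated design (G = n clusters, N = 2n, k = 2)
        X = np.column_stack([np.ones(n), ind])
        params, bse = _sandwich_oracle(y, X, np.arange(n))
        correction = math.sqrt((n / (n - 1)) * ((2 * n - 1) / (2 * n - 2)))
        assert dup.beta == pytest.approx(params[1], abs=1e-8)
        assert dup.se == pytest.approx(bse[1] * correction, rel=1e-6)

    def test_family_random_intercept_coverage(self, rng):
        # Gaussian-copula family correlation keeps the marginal model exact,
        # so the marginal beta is the known truth the CI must cover.
        true_beta = 0.7
        fam_size, n_fam, rho = 4, 150, 0.5
        n = fam_size * n_fam
        fam = np.repeat(np.arange(n_fam), fam_size)
        covered = 0
        reps = 300
        for _ in range(reps):
            ind = (rng.random(n) < 0.4).astype(float)
            p = 1 / (1 + np.exp(-(-0.5 + true_beta * ind)))
            w = math.sqrt(rho) * rng.standard_normal(n_fam)[fam] + math.sqrt(
                1 - rho
            ) * rng.standard_normal(n)
            y = (stats.norm.cdf(w) < p).astype(float)
            try:
                fit = clustered_fit(y, ind, None, fam)
            except (PerfectSeparationError, ValueError):
                continue
            lo, hi = math.log(fit.ci95[0]), math.log(fit.ci95[1])
            covered += lo <= true_beta <= hi
        assert covered / reps >= 0.92  # nominal 95% minus Monte-Carlo slack


def _cohort(rng, n, n_snvs=6, beta=0.0, family=False, carrier=False,
            carrier_weight=0.0):
    snvs = [f"s{j}" for j in range(n_snvs)]
    d = rng.binomial(2, 0.4, (n, n_snvs)).astype(np.float32)
    w = rng.normal(size=n_snvs)
    carrier_flag = np.zeros(n, dtype=bool)
    pgs = d.astype(float) @ w
    eta = -1.2 + beta * (pgs - pgs.mean()) / max(pgs.std(), 1e-9)
    if carrier:
        # the carried allele enters the score with a strongly negative weight
        # AND lowers risk directly, so carriers pool in the bottom PGS tail
        # and drive its protective odds ratio
        cg = rng.binomial(2, 0.08, n).astype(np.float32)
        carrier_flag = cg > 0
        snvs = snvs + ["s_carrier"]
        d = np.column_stack([d, cg])
        w = np.append(w, carrier_weight)
        eta = eta - 2.0 * carrier_flag
    dm = DosageMatrix(
        np.array([f"i{k:05d}" for k in range(n)], dtype=object),
        np.array(snvs, dtype=object),
        np.array(["A"] * len(snvs), dtype=object),
        np.array(["G"] * len(snvs), dtype=object),
        d,
    )
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({
        "individual_id": dm.individual_ids, "case_status": y,
        "sex": rng.integers(0, 2, n),
    })
    for i in range(10):
        df[f"pc{i+1}"] = rng.standard_normal(n)
    df["array"] = np.where(rng.random(n) < 0.5, "A1", "A2")
    if family:
        df["family_id"] = np.repeat(np.arange(-(-n // 3)), 3)[:n]
    df["carrier_flag"] = carrier_flag
    rows = [(snvs[j], "1", 100 * j, "A", "G", w[j], 0.01) for j in range(len(snvs))]
    return make_weightset(rows), dm, PhenotypeTable(df)


class TestScreeningScanAndSelection:
    def test_scan_row_count_is_product(self, rng):
        ws, dm, ph = _cohort(rng, 400, family=True)
        ws2 = make_weightset(
            [(s, c, p, a, o, -wt, pv) for s, c, p, a, o, wt, pv in
             ws.members.itertuples(index=False)],
            ClumpParams(0.5, 0.2, 500),
        )
        scan = screening_scan([ws, ws2], dm, ph,
                              top_fractions=[0.05, 0.10], bottom_fractions=[0.05, 0.10])
        assert len(scan) == 8
        assert set(zip(scan["p_threshold"], scan["r2_threshold"])) == {(1.0, 0.5), (0.5, 0.2)}

    def test_duplicate_member_sets_share_results(self, rng):
        ws, dm, ph = _cohort(rng, 400, family=True)
        twin = make_weightset(
            list(ws.members.itertuples(index=False)), ClumpParams(0.5, 0.1, 500)
        )
        scan = screening_scan([ws, twin], dm, ph,
                              top_fractions=[0.05], bottom_fractions=[0.05])
        a = scan[scan["p_threshold"] == 1.0].drop(columns=["p_threshold", "r2_threshold", "window_kb"])
        b = scan[scan["p_threshold"] == 0.5].drop(columns=["p_threshold", "r2_threshold", "window_kb"])
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_null_scan_maximum_exceeds_single_test(self, rng):
        # stage 2 exists because the screening maximum is selection-biased
        n_sets = 8
        max_abs, single_abs = [], []
        for _ in range(25):
            sets = []
            ws, dm, ph = _cohort(rng, 300, beta=0.0)
            for k in range(n_sets):
                w = rng.normal(size=ws.size)
                sets.append(make_weightset(
                    [(s, c, p, a, o, w[j], pv) for j, (s, c, p, a, o, _, pv)
                     in enumerate(ws.members.itertuples(index=False))],
                    ClumpParams(1.0, 0.1 * (k % 5 + 1) - 0.05, 250),
                ))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scan = screening_scan(sets, dm, ph, top_fractions=[0.2],
                                      bottom_fractions=[])
            betas = scan["beta"].dropna().abs()
            if len(betas):
                max_abs.append(betas.max())
                single_abs.append(betas.iloc[0])
        assert np.mean(max_abs) > np.mean(single_abs)

    def test_select_best_single_set(self, rng):
        ws, dm, ph = _cohort(rng, 500, beta=0.8)
        scan = assess_weight_set(ws, dm, ph, top_fractions=[0.05], bottom_fractions=[])
        assert select_best(scan) == ws.params

    def test_select_best_prefers_clearly_larger_or(self):
        scan = pd.DataFrame({
            "p_threshold": [0.01, 0.5], "r2_threshold": [0.1, 0.2],
            "window_kb": [250, 500], "n_snvs": [9154, 99135],
            "threshold_fraction": [0.05, 0.05], "direction": ["top", "top"],
            "or_adjusted": [2.75, 2.00], "ci_low": [2.05, 1.80], "ci_high": [3.71, 2.04],
        })
        assert select_best(scan) == ClumpParams(0.01, 0.1, 250)

    def test_select_best_prefers_smaller_set_when_comparable(self):
        scan = pd.DataFrame({
            "p_threshold": [0.5, 0.01], "r2_threshold": [0.2, 0.1],
            "window_kb": [500, 250], "n_snvs": [99135, 9154],
            "threshold_fraction": [0.05, 0.05], "direction": ["top", "top"],
            "or_adjusted": [2.80, 2.75], "ci_low": [2.10, 2.05], "ci_high": [3.75, 3.71],
        })
        assert select_best(scan) == ClumpParams(0.01, 0.1, 250)

    def test_recovery_informative_set_beats_noise(self, rng):
        wins = 0
        reps = 10
        for _ in range(reps):
            ws, dm, ph = _cohort(rng, 800, beta=1.0)
            noise = make_weightset(
                [(s, c, p, a, o, rng.normal(), pv) for s, c, p, a, o, _, pv in
                 ws.members.itertuples(index=False)],
                ClumpParams(0.5, 0.2, 500),
            )
            scan = screening_scan([ws, noise], dm, ph,
                                  top_fractions=[0.05], bottom_fractions=[])
            best = select_best(scan)
            wins += best == ws.params
        assert wins >= 7  # far above the 50% chance level


class TestStratified:
    def test_balanced_null_strata_near_one(self, rng):
        ws, dm, ph = _cohort(rng, 3000, beta=0.0)
        res = stratified_analysis(ws, dm, ph, by="sex",
                                  top_fractions=[0.25], bottom_fractions=[])
        ors = res["or_adjusted"].dropna()
        assert len(ors) == 2
        assert np.all((ors > 0.6) & (ors < 1.6))

    def test_excluding_zero_carriers_is_identity(self, rng):
        ws, dm, ph = _cohort(rng, 500, beta=0.5)  # no carriers flagged
        base = assess_weight_set(ws, dm, ph, top_fractions=[0.10], bottom_fractions=[0.10])
        excl = stratified_analysis(ws, dm, ph, exclude_carriers=True,
                                   top_fractions=[0.10], bottom_fractions=[0.10])
        pd.testing.assert_frame_equal(base, excl.drop(columns=["stratum"]))

    def test_excluding_protective_carriers_attenuates_bottom_group(self, rng):
        # carriers hold a strongly protective weight: they pile up in the
        # bottom PGS tail AND have low risk, so removing them moves the
        # bottom-group OR toward 1
        ws, dm, ph = _cohort(rng, 6000, beta=1.0, carrier=True, carrier_weight=-8.0)
        base = assess_weight_set(ws, dm, ph, top_fractions=[], bottom_fractions=[0.10])
        excl = stratified_analysis(ws, dm, ph, exclude_carriers=True,
                                   top_fractions=[], bottom_fractions=[0.10])
        b0 = base.loc[0, "beta"]
        b1 = excl.loc[0, "beta"]
        assert b0 < 0
        assert abs(b1) < abs(b0)

    def test_single_class_stratum_recorded_missing(self, rng):
        ws, dm, ph = _cohort(rng, 200, beta=0.0)
        df = ph.data.copy()
        df.loc[df["sex"] == 1, "case_status"] = 0  # degenerate stratum
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stratified_analysis(ws, dm, PhenotypeTable(df), by="sex",
                                      top_fractions=[0.25], bottom_fractions=[])
        assert res.loc[res["stratum"] == "sex=1", "or_adjusted"].isna().all()
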