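"""Risk-group / outcome association: 2x2 odds ratios, covariate-adjusted
logistic regression, family-cluster-robust fits, the screening-stage scan over
all weight sets and percentile thresholds, best-PGS selection, and
stratified / carrier-exclusion analyses.

Two estimators cover the two cohort designs.  Unrelated cohorts get ordinary
maximum-likelihood logistic regression of case status on the risk-group
indicator plus covariates (sex, 10 ancestry PCs, genotyping-array dummies).
Familial cohorts get the same point estimates with cluster-robust (sandwich)
standard errors by family — the GEE-with-working-independence reading of
family adjustment — which reduces exactly to the plain fit when every family
is a singleton.  All confidence intervals are Wald on the log-odds scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clump import ClumpParams, WeightSet
from .scoring import DosageMatrix, ScoreVector, assign_risk_group, score

__all__ = [
    "PhenotypeTable",
    "FitResult",
    "table_or",
    "logistic_fit",
    "clustered_fit",
    "screening_scan",
    "select_best",
    "stratified_analysis",
    "assess_weight_set",
]

TOP_FRACTIONS = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
BOTTOM_FRACTIONS = tuple(np.round(np.arange(0.05, 0.451, 0.05), 2))

Z95 = stats.norm.ppf(0.975)


@dataclass
class PhenotypeTable:
    """Outcome and covariates for one target cohort.

    Columns: individual_id, case_status (0/1), sex (0/1), pc1..pc10, array
    (categorical label), optional family_id, optional carrier_flag (e.g. the
    large-effect protective rs1229984-analogue T allele).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["individual_id", "case_status", "sex"] + [f"pc{i}" for i in range(1, 11)]
        for c in req:
            if c not in self.data.columns:
                raise ValueError(f"phenotype table lacks column {c!r}")
        if self.data["individual_id"].duplicated().any():
            raise ValueError("duplicate individual_id in phenotype table")
        pcs = self.data[[f"pc{i}" for i in range(1, 11)]].to_numpy(float)
        if not np.all(np.isfinite(pcs)):
            raise ValueError("non-finite principal components")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_families(self) -> bool:
        return "family_id" in self.data.columns and self.data["family_id"].notna().any()

    def aligned_to(self, individual_ids: np.ndarray) -> "PhenotypeTable":
        df = self.data.set_index("individual_id").loc[list(individual_ids)].reset_index()
        return PhenotypeTable(df)


class PerfectSeparationError(RuntimeError):
    """The risk indicator perfectly predicts the outcome; the MLE diverges."""


@dataclass
class FitResult:
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float


def table_or(cases_in: int, controls_in: int, cases_out: int, controls_out: int):
    """Unadjusted odds ratio and Woolf 95% CI from a 2x2 table.

    OR = (cases_in x controls_out) / (controls_in x cases_out); the CI uses the
    log-OR normal approximation with SE = sqrt(sum of reciprocal cell counts).
    Any zero cell triggers the Haldane +0.5 continuity correction on all four
    cells, with a warning.
    """
    cells = np.array([cases_in, controls_in, cases_out, controls_out], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(cells == 0):
        warnings.warn("zero cell: +0.5 continuity correction applied", stacklevel=2)
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - Z95 * se), math.exp(math.log(or_) + Z95 * se)
    return or_, (lo, hi)


def _result_from(beta: float, se: float) -> FitResult:
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    with np.errstate(over="ignore"):  # an enormous SE yields an infinite bound
        ci = (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
    return FitResult(beta=float(beta), se=float(se), or_=math.exp(beta),
                     ci95=ci, p=float(p))


def build_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Covariate design matrix: numeric columns as-is; the ``array`` column as
    dummy indicators with the most frequent array as the reference level."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((n, 0))
    blocks = []
    for col in covariates.columns:
        s = covariates[col]
        if col == "array" or s.dtype == object:
            ref = s.value_counts().idxmax()
            levels = [l for l in sorted(s.unique()) if l != ref]
            for lev in levels:
                blocks.append((s == lev).to_numpy(float))
        else:
            blocks.append(s.to_numpy(float))
    return np.column_stack(blocks) if blocks else np.empty((n, 0))


def _check_separation(res) -> None:
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)) or np.abs(params).max() > 30:
        raise PerfectSeparationError("perfect or quasi-perfect separation detected")


def _fit_mle(y: np.ndarray, X: np.ndarray):
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100)
        except Exception as exc:  # statsmodels raises on hard separation
            raise PerfectSeparationError(str(exc)) from exc
    _check_separation(res)
    return res


def _prepare(outcome, risk_indicator, covariates):
    y = np.asarray(outcome, dtype=float)
    ind = np.asarray(risk_indicator, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    C = build_design(covariates, len(y))
    X = np.column_stack([np.ones(len(y)), ind, C])
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    return y, X


def logistic_fit(outcome, risk_indicator, covariates: pd.DataFrame | None = None) -> FitResult:
    """ML logistic regression of case status on the risk indicator + covariates.

    Returns the indicator's coefficient, its (inverse-Hessian) standard error,
    OR = exp(beta), the Wald 95% CI and two-sided p.  Perfect separation raises
    :class:`PerfectSeparationError`.
    """
    y, X = _prepare(outcome, risk_indicator, covariates)
    res = _fit_mle(y, X)
    return _result_from(res.params[1], res.bse[1])


def clustered_fit(
    outcome, risk_indicator, covariates: pd.DataFrame | None, family_id
) -> FitResult:
    """Logistic point estimates with family-cluster-robust (sandwich) SEs.

    With every family a singleton this is exactly :func:`logistic_fit`; with
    real clusters the point estimates are the same MLE but the covariance is
    the CR0 sandwich grouped by family, acknowledging within-family outcome
    correlation.
    """
    fam = np.asarray(family_id)
    if len(fam) != len(np.asarray(outcome)):
        raise ValueError("family_id length mismatch")
    _, counts = np.unique(fam, return_counts=True)
    if counts.max() == 1:
        return logistic_fit(outcome, risk_indicator, covariates)

    y, X = _prepare(outcome, risk_indicator, covariates)
    codes = pd.factorize(fam)[0]
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": codes})
        except Exception as exc:
            raise PerfectSeparationError(str(exc)) from exc
    _check_separation(res)
    return _result_from(res.params[1], res.bse[1])


def _fit_for(pheno: PhenotypeTable, indicator: np.ndarray, covariate_cols: list[str]) -> FitResult:
    cov = pheno.data[covariate_cols] if covariate_cols else None
    y = pheno.data["case_status"].to_numpy(float)
    if pheno.has_families:
        return clustered_fit(y, indicator, cov, pheno.data["family_id"].to_numpy())
    return logistic_fit(y, indicator, cov)


DEFAULT_COVARIATES = ["sex"] + [f"pc{i}" for i in range(1, 11)] + ["array"]

RESULT_COLUMNS = [
    "p_threshold", "r2_threshold", "window_kb", "n_snvs",
    "threshold_fraction", "direction",
    "cases_in", "controls_in", "cases_out", "controls_out",
    "or_unadjusted", "or_adjusted", "ci_low", "ci_high", "beta", "se", "p",
]


def _risk_group_row(
    params: ClumpParams, n_snvs: int, scores: ScoreVector, pheno: PhenotypeTable,
    fraction: float, direction: str, covariate_cols: list[str],
) -> dict:
    grp = assign_risk_group(scores, fraction, direction)
    y = pheno.data["case_status"].to_numpy(bool)
    ind = grp.indicator
    counts = (
        int((y & ind).sum()), int((~y & ind).sum()),
        int((y & ~ind).sum()), int((~y & ~ind).sum()),
    )
    or_u, _ = table_or(*counts)
    row = {
        "p_threshold": params.p_threshold, "r2_threshold": params.r2_threshold,
        "window_kb": params.window_kb, "n_snvs": n_snvs,
        "threshold_fraction": fraction, "direction": direction,
        "cases_in": counts[0], "controls_in": counts[1],
        "cases_out": counts[2], "controls_out": counts[3],
        "or_unadjusted": or_u,
        "or_adjusted": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        "beta": np.nan, "se": np.nan, "p": np.nan,
    }
    try:
        fit = _fit_for(pheno, ind.astype(float), covariate_cols)
    except (PerfectSeparationError, ValueError) as exc:
        warnings.warn(
            f"fit failed at {params.label()} {direction} {fraction}: {exc}",
            stacklevel=2,
        )
        return row
    row.update(
        or_adjusted=fit.or_, ci_low=fit.ci95[0], ci_high=fit.ci95[1],
        beta=fit.beta, se=fit.se, p=fit.p,
    )
    return row


def assess_weight_set(
    weights: WeightSet,
    dosages: DosageMatrix,
    phenotypes: PhenotypeTable,
    top_fractions=TOP_FRACTIONS,
    bottom_fractions=BOTTOM_FRACTIONS,
    covariate_cols: list[str] | None = None,
    _scores: ScoreVector | None = None,
) -> pd.DataFrame:
    """Evaluate one weight set over all percentile thresholds in one cohort."""
    covariate_cols = _usable_covariates(phenotypes, covariate_cols)
    pheno = phenotypes.aligned_to(dosages.individual_ids)
    scores = _scores if _scores is not None else score(weights, dosages)
    rows = []
    for direction, fractions in (("top", top_fractions), ("bottom", bottom_fractions)):
        for f in fractions:
            rows.append(
                _risk_group_row(weights.params, weights.size, scores, pheno,
                                float(f), direction, covariate_cols)
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _usable_covariates(pheno: PhenotypeTable, covariate_cols) -> list[str]:
    cols = DEFAULT_COVARIATES if covariate_cols is None else covariate_cols
    out = []
    for c in cols:
        if c not in pheno.data.columns:
            continue
        s = pheno.data[c]
        if s.dtype != object and s.nunique() < 2:
            continue  # constant covariate (e.g. single array) carries nothing
        out.append(c)
    return out


def screening_scan(
    weight_sets: list[WeightSet],
    dosages: DosageMatrix,
    phenotypes: PhenotypeTable,
    top_fractions=TOP_FRACTIONS,
    bottom_fractions=BOTTOM_FRACTIONS,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Stage-1 scan: every weight set x threshold x direction in the screening
    cohort, with family-cluster-robust fits.

    Many grid points select the identical SNV set (a loose r² cutoff changes
    nothing for a sparse p-threshold), so results are computed once per unique
    member set and replicated across the grid points that share it.  A failed
    fit is recorded as missing and the scan continues.
    """
    if not weight_sets:
        raise ValueError("no weight sets supplied")
    pheno = phenotypes.aligned_to(dosages.individual_ids)
    cache: dict[tuple, pd.DataFrame] = {}
    frames = []
    for ws in weight_sets:
        key = ws.member_key()
        base = cache.get(key)
        if base is None:
            if ws.size == 0:
                base = pd.DataFrame(columns=RESULT_COLUMNS)
            else:
                base = assess_weight_set(
                    ws, dosages, pheno, top_fractions, bottom_fractions,
                    covariate_cols,
                )
            cache[key] = base
        df = base.copy()
        if len(df):
            df["p_threshold"] = ws.params.p_threshold
            df["r2_threshold"] = ws.params.r2_threshold
            df["window_kb"] = ws.params.window_kb
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def select_best(
    scan: pd.DataFrame,
    weight_sets: list[WeightSet] | None = None,
    *,
    selection_fraction: float = 0.05,
) -> ClumpParams:
    """Pick the stage-2 weight set from the screening scan.

    Primary criterion: largest adjusted OR for the top-``selection_fraction``
    comparison.  Comparability rule: among weight sets whose top-group 95% CI
    overlaps the best one's CI, prefer the smallest SNV count (parsimony), with
    grid order as the final tie-break.
    """
    top = scan[
        (scan["direction"] == "top")
        & (np.isclose(scan["threshold_fraction"], selection_fraction))
        & scan["or_adjusted"].notna()
    ]
    if len(top) == 0:
        raise ValueError("scan contains no usable top-group results")
    best = top.loc[top["or_adjusted"].idxmax()]
    comparable = top[
        (top["ci_low"] <= best["ci_high"]) & (top["ci_high"] >= best["ci_low"])
    ]
    chosen = comparable.sort_values(
        ["n_snvs", "p_threshold", "r2_threshold", "window_kb"], kind="mergesort"
    ).iloc[0]
    return ClumpParams(
        float(chosen["p_threshold"]), float(chosen["r2_threshold"]), int(chosen["window_kb"])
    )


def stratified_analysis(
    weights: WeightSet,
    dosages: DosageMatrix,
    phenotypes: PhenotypeTable,
    *,
    by: str | None = None,
    exclude_carriers: bool = False,
    top_fractions=TOP_FRACTIONS,
    bottom_fractions=BOTTOM_FRACTIONS,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Re-run the assessment within strata (``by``, e.g. "sex") or after
    excluding carriers (``carrier_flag``).  Percentile thresholds are
    re-derived within each analyzed subset.  A stratum with a single outcome
    class yields missing fit columns, not an abort.
    """
    pheno = phenotypes.aligned_to(dosages.individual_ids)
    df = pheno.data
    mask = np.ones(len(df), dtype=bool)
    if exclude_carriers:
        if "carrier_flag" not in df.columns:
            raise ValueError("phenotype table has no carrier_flag column")
        mask &= ~df["carrier_flag"].fillna(False).astype(bool).to_numpy()

    strata: list[tuple[str, np.ndarray]]
    if by is not None:
        if by not in df.columns:
            raise ValueError(f"no stratum column {by!r}")
        strata = [
            (f"{by}={v}", mask & (df[by] == v).to_numpy()) for v in sorted(df[by].unique())
        ]
        cov = [c for c in (covariate_cols or DEFAULT_COVARIATES) if c != by]
    else:
        strata = [("all", mask)]
        cov = covariate_cols

    out = []
    for label, m in strata:
        sub_dos = DosageMatrix(
            dosages.individual_ids[m], dosages.snv_ids, dosages.effect_allele,
            dosages.other_allele, dosages.dosages[m],
        )
        sub_ph = PhenotypeTable(df[m].reset_index(drop=True))
        res = assess_weight_set(
            weights, sub_dos, sub_ph, top_fractions, bottom_fractions, cov
        )
        res.insert(0, "stratum", label)
        out.append(res)
    return pd.concat(out, ignore_index=True)
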