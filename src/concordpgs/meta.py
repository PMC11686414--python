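"""Effective sample sizes, sample-size-weighted z-score meta-analysis, and the
direction-concordance filter.

Case/control GWASs with very unbalanced arms carry less information than their
total N suggests; the effective sample size N_eff = 4/(1/cases + 1/controls)
equalizes them for z-based meta-analysis.  The meta-analytic z for SNV j is the
standard sample-size-weighted scheme

    w_i = sqrt(N_eff,i),    z_meta = sum_i w_i z_i / sqrt(sum_i w_i^2)

and the concordance filter keeps exactly those SNVs whose per-study z-scores
share one strict sign across every discovery study.  Under a complete null with
S independent studies the kept fraction is 2^(1-S) (1/4 for three studies), so
the filter discards most noise SNVs while retaining those with a consistent
true direction.  The meta z doubles as the SNV's weight in the polygenic score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryStatsSet

__all__ = [
    "effective_n",
    "audit_threshold_cases",
    "meta_z",
    "meta_analyze",
    "concordance_filter",
    "write_meta_table",
    "read_meta_table",
]

#: Columns of the meta-analysis table produced by :func:`meta_analyze`.
META_COLUMNS = [
    "snv_id", "chrom", "pos", "effect_allele", "other_allele",
    "directions", "meta_z", "meta_p", "concordant",
]


def effective_n(n_cases, n_controls):
    """Effective sample size 4/(1/n_cases + 1/n_controls).

    Accepts scalars or arrays.  Bounded above by n_cases + n_controls with
    equality iff the arms are balanced.
    """
    n_cases = np.asarray(n_cases, dtype=float)
    n_controls = np.asarray(n_controls, dtype=float)
    if np.any(n_cases < 1) or np.any(n_controls < 1):
        raise ValueError("case and control counts must be >= 1")
    out = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    return float(out) if out.ndim == 0 else out


def audit_threshold_cases(scores, threshold: float = 12.0) -> int:
    """Number of AUDIT scores at or above ``threshold`` (inclusive).

    Supplies the case count of a quantitative AUDIT-style study for the purpose
    of computing its effective sample size.  Scores live on the instrument's
    0-40 scale.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if np.any(scores < 0) or np.any(scores > 40):
        raise ValueError("AUDIT scores must lie in [0, 40]")
    n = int(np.sum(scores >= threshold))
    if n == 0:
        warnings.warn("no scores reach the case threshold", stacklevel=2)
    return n


def meta_z(per_study_z, per_study_neff):
    """Sample-size-weighted meta z and its two-sided normal p.

    ``per_study_z`` and ``per_study_neff`` may be 1-D (one SNV) or 2-D
    (SNVs x studies); returns (meta_z, meta_p) with matching shape.
    """
    z = np.atleast_2d(np.asarray(per_study_z, dtype=float))
    neff = np.atleast_2d(np.asarray(per_study_neff, dtype=float))
    if z.shape != neff.shape:
        raise ValueError("z and N_eff shapes differ")
    if z.shape[1] == 0:
        raise ValueError("need at least one study")
    if np.any(neff <= 0):
        raise ValueError("effective sample sizes must be positive")
    w = np.sqrt(neff)
    mz = (w * z).sum(axis=1) / np.sqrt((w**2).sum(axis=1))
    mp = 2.0 * stats.norm.sf(np.abs(mz))
    # p of exactly 0 is impossible for finite z, but guard the (0,1] contract
    mp = np.clip(mp, np.finfo(float).tiny, 1.0)
    if np.asarray(per_study_z).ndim == 1:
        return float(mz[0]), float(mp[0])
    return mz, mp


def _neff_for_study(study: SummaryStatsSet) -> np.ndarray:
    return effective_n(
        study.records["n_cases"].to_numpy(), study.records["n_controls"].to_numpy()
    )


def meta_analyze(studies: list[SummaryStatsSet]) -> pd.DataFrame:
    """Meta-analyze harmonized studies into one table, one row per shared SNV.

    Requires studies already aligned by :func:`concordpgs.gwas_io.harmonize`
    (identical snv_id order and allele orientation).  The result carries the
    per-study z columns (``z_<label>``), the direction string (one of +/-/0 per
    study), the weighted meta z and p, and the concordance flag.
    """
    if not studies:
        raise ValueError("no studies supplied")
    ids = studies[0].records["snv_id"].to_numpy()
    for s in studies[1:]:
        if len(s.records) != len(ids) or not np.array_equal(
            s.records["snv_id"].to_numpy(), ids
        ):
            raise ValueError("studies are not harmonized (snv_id order differs)")

    z = np.column_stack([s.records["z"].to_numpy() for s in studies])
    neff = np.column_stack([_neff_for_study(s) for s in studies])
    mz, mp = meta_z(z, neff) if z.shape[1] > 1 else (z[:, 0], np.clip(
        2.0 * stats.norm.sf(np.abs(z[:, 0])), np.finfo(float).tiny, 1.0))

    signs = np.sign(z)
    concordant = np.all(signs > 0, axis=1) | np.all(signs < 0, axis=1)
    dir_chars = np.where(signs > 0, "+", np.where(signs < 0, "-", "0"))
    directions = np.array(["".join(row) for row in dir_chars])

    ref = studies[0].records
    out = pd.DataFrame(
        {
            "snv_id": ids,
            "chrom": ref["chrom"].to_numpy(),
            "pos": ref["pos"].to_numpy(),
            "effect_allele": ref["effect_allele"].to_numpy(),
            "other_allele": ref["other_allele"].to_numpy(),
            "directions": directions,
            "meta_z": mz,
            "meta_p": mp,
            "concordant": concordant,
        }
    )
    for s, zcol in zip(studies, z.T):
        out[f"z_{s.study_label}"] = zcol
    return out


def concordance_filter(meta: pd.DataFrame) -> pd.DataFrame:
    """Keep SNVs whose per-study effects all share one strict sign.

    A z of exactly 0 has no direction and fails concordance.
    """
    return meta[meta["concordant"]].reset_index(drop=True)


def write_meta_table(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_meta_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snv_id": str, "chrom": str})
    df["concordant"] = df["concordant"].astype(bool)
    return df
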