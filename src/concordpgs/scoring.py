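"""Per-individual polygenic scores from dosages, and percentile risk groups.

PGS_i = sum_j beta_j * dosage_ij over the SNVs of a weight set, where beta_j is
the meta-analytic z-score and dosage_ij the (possibly imputed) count of the
effect allele in [0, 2].  Scores are used raw: the downstream dichotomization
is rank-based, and ranks are invariant to affine transforms; a standardization
flag exists for reporting only.

Risk groups flag the ceil(fraction x N) individuals with the most extreme
scores in a direction ("top" = highest PGS = high risk), with ties at the cut
broken by ascending individual_id for determinism.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clump import WeightSet

__all__ = ["DosageMatrix", "ScoreVector", "RiskGroupAssignment", "score", "assign_risk_group"]


@dataclass
class DosageMatrix:
    """Target-cohort effect-allele dosages: individuals x SNVs in [0, 2].

    ``dosages`` is float32 with NaN for missing; ``effect_allele[j]`` is the
    allele the j-th column counts.
    """

    individual_ids: np.ndarray
    snv_ids: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snv_ids = np.asarray(self.snv_ids, dtype=object)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.individual_ids), len(self.snv_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        self._index = {s: i for i, s in enumerate(self.snv_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    # ---------------------------------------------------------------- loaders

    @classmethod
    def from_tsv(cls, matrix_path, sites_path) -> "DosageMatrix":
        """Headered dosage matrix TSV (first column individual_id) plus a
        sites TSV with snv_id/effect_allele/other_allele columns."""
        sites = pd.read_csv(sites_path, sep="\t", dtype={"snv_id": str, "chrom": str})
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        mat = mat[list(sites["snv_id"])]
        return cls(
            individual_ids=mat.index.to_numpy(dtype=object),
            snv_ids=sites["snv_id"].to_numpy(),
            effect_allele=sites["effect_allele"].to_numpy(),
            other_allele=sites["other_allele"].to_numpy(),
            dosages=mat.to_numpy(dtype=np.float32),
        )

    @classmethod
    def from_vcf(cls, path) -> "DosageMatrix":
        """Load dosages from a VCF ``DS`` FORMAT field (ALT-allele dosage;
        the effect allele is ALT, the other allele REF)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        individuals = np.array(vcf.samples, dtype=object)
        ids, ea, oa, cols = [], [], [], []
        for var in vcf:
            ds = var.format("DS")
            if ds is None:
                raise ValueError(f"variant {var.ID or var.POS} lacks a DS field")
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            ea.append(var.ALT[0])
            oa.append(var.REF)
            cols.append(np.asarray(ds, dtype=np.float32).ravel())
        vcf.close()
        return cls(individuals, np.array(ids, dtype=object),
                   np.array(ea, dtype=object), np.array(oa, dtype=object),
                   np.column_stack(cols))


@dataclass
class ScoreVector:
    """Per-individual PGS with the count of non-missing SNVs that entered it."""

    individual_ids: np.ndarray
    pgs: np.ndarray
    n_snvs_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual_id": self.individual_ids, "pgs": self.pgs,
             "n_snvs_used": self.n_snvs_used}
        )

    def __len__(self) -> int:
        return len(self.individual_ids)


def score(weights: WeightSet, dosages: DosageMatrix, *, standardize: bool = False) -> ScoreVector:
    """Compute PGS_i = sum_j beta_j x dosage_ij with allele alignment.

    A weight whose effect allele matches the dosage column's *other* allele is
    applied to the flipped dosage 2 - d.  Missing dosages contribute the SNV's
    mean observed dosage (mean imputation); ``n_snvs_used`` counts each
    individual's genuinely observed SNVs.  Weight SNVs absent from the matrix
    (or with an unmatchable allele pair) trigger a warning with the overlap
    fraction; zero overlap is fatal.
    """
    w = weights.members
    if len(w) == 0:
        raise ValueError("empty weight set")
    cols, coefs, flips = [], [], []
    for row in w.itertuples(index=False):
        j = dosages._index.get(row.snv_id)
        if j is None:
            continue
        other = row.other_allele if isinstance(row.other_allele, str) else ""
        if other:  # full pair known: require exact or swapped match
            if row.effect_allele == dosages.effect_allele[j] and other == dosages.other_allele[j]:
                flip = False
            elif row.effect_allele == dosages.other_allele[j] and other == dosages.effect_allele[j]:
                flip = True
            else:
                continue  # allele pair unmatchable even after swap
        else:  # scoring-file input carries the effect allele only
            if row.effect_allele == dosages.effect_allele[j]:
                flip = False
            elif row.effect_allele == dosages.other_allele[j]:
                flip = True
            else:
                continue
        cols.append(j)
        coefs.append(row.weight)
        flips.append(flip)

    if not cols:
        raise ValueError("no weight SNVs found in the dosage matrix")
    overlap = len(cols) / len(w)
    if overlap < 1.0:
        warnings.warn(
            f"only {overlap:.1%} of weight SNVs found in the dosage matrix",
            stacklevel=2,
        )

    d = dosages.dosages[:, cols].astype(np.float64)
    flips = np.asarray(flips)
    d[:, flips] = 2.0 - d[:, flips]
    observed = ~np.isnan(d)
    col_mean = np.nanmean(d, axis=0)
    d = np.where(observed, d, col_mean)

    coefs = np.asarray(coefs, dtype=np.float64)
    pgs = d @ coefs
    if standardize:
        sd = pgs.std()
        if sd > 0:
            pgs = (pgs - pgs.mean()) / sd
    return ScoreVector(dosages.individual_ids, pgs, observed.sum(axis=1))


@dataclass
class RiskGroupAssignment:
    """Indicator for one percentile dichotomization of the PGS distribution."""

    threshold_fraction: float
    direction: str
    indicator: np.ndarray  # bool per individual, aligned with the ScoreVector

    @property
    def n_flagged(self) -> int:
        return int(self.indicator.sum())


def assign_risk_group(scores: ScoreVector, fraction: float, direction: str) -> RiskGroupAssignment:
    """Flag the ceil(fraction x N) most extreme individuals.

    ``direction`` "top" flags the highest-PGS individuals (high risk), "bottom"
    the lowest (low risk).  Quantiles are computed on the full analyzed sample
    (cases + controls combined).  A constant score vector is an error:
    percentile groups are undefined.
    """
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must lie in (0, 0.5]")
    n = len(scores)
    if n < 20:
        raise ValueError("need at least 20 individuals for percentile groups")
    pgs = np.asarray(scores.pgs, dtype=float)
    if np.ptp(pgs) == 0:
        raise ValueError("constant PGS vector: percentile groups undefined")

    k = math.ceil(fraction * n)
    key = -pgs if direction == "top" else pgs
    order = np.lexsort((scores.individual_ids, key))  # ties -> ascending id
    indicator = np.zeros(n, dtype=bool)
    indicator[order[:k]] = True
    return RiskGroupAssignment(fraction, direction, indicator)
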