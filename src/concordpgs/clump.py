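"""P-value thresholding plus greedy LD clumping against a reference panel.

Pruning-and-thresholding selects, for one grid point (p-threshold, r²
threshold, physical window), a set of mutually quasi-independent SNVs: consider
SNVs with p ≤ threshold in ascending-p order and accept each unless it sits
within the window of an already-accepted SNV on the same chromosome with
genotype r² at or above the cutoff.  This is the index-SNV clumping dialect:
deterministic given the documented tie-break (ascending p, then chromosome,
position, snv_id), and directly checkable against a brute-force replay.

The default grid is 17 p-thresholds x 5 r² cutoffs x 2 windows = 170 points;
the loosest p entry (">0.99") is interpreted as 1.0, i.e. no p filtering.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClumpParams",
    "ReferencePanel",
    "WeightSet",
    "DEFAULT_P_THRESHOLDS",
    "DEFAULT_R2_THRESHOLDS",
    "DEFAULT_WINDOWS_KB",
    "parameter_grid",
    "r2",
    "clump",
]

#: 17 p-value thresholds; the ">0.99" grid entry means "keep everything".
DEFAULT_P_THRESHOLDS = (
    1.0, 0.5, 0.2, 0.1, 0.05, 0.01, 5e-3, 1e-3, 5e-4, 1e-4,
    5e-5, 1e-5, 5e-6, 1e-6, 5e-7, 1e-7, 5e-8,
)
DEFAULT_R2_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_WINDOWS_KB = (250, 500)


@dataclass(frozen=True)
class ClumpParams:
    """One pruning-and-thresholding grid point."""

    p_threshold: float
    r2_threshold: float
    window_kb: int

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in (0, 1]")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must lie in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")

    def label(self) -> str:
        return f"p{self.p_threshold:g}_r2{self.r2_threshold:g}_w{self.window_kb}"


def parameter_grid(
    p_list=None, r2_list=None, window_list=None
) -> list[ClumpParams]:
    """Cartesian product of the three grids, p outermost, window innermost."""
    p_list = DEFAULT_P_THRESHOLDS if p_list is None else tuple(p_list)
    r2_list = DEFAULT_R2_THRESHOLDS if r2_list is None else tuple(r2_list)
    window_list = DEFAULT_WINDOWS_KB if window_list is None else tuple(window_list)
    for name, lst in (("p", p_list), ("r2", r2_list), ("window", window_list)):
        if len(lst) == 0:
            raise ValueError(f"empty {name} list")
    return [
        ClumpParams(p, r, w)
        for p, r, w in itertools.product(p_list, r2_list, window_list)
    ]


def r2(g1, g2) -> float:
    """Squared Pearson correlation of two genotype-dosage vectors.

    Missing entries (NaN) are removed pairwise-complete; at least two complete
    pairs and non-zero variance in both vectors are required.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("genotype vectors must be 1-D and of equal length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[ok], g2[ok]
    if g1.size < 2:
        raise ValueError("fewer than 2 pairwise-complete observations")
    v1, v2 = g1.var(), g2.var()
    if v1 == 0 or v2 == 0:
        raise ValueError("monomorphic genotype vector: r2 undefined")
    c = np.corrcoef(g1, g2)[0, 1]
    return float(c * c)


@dataclass
class ReferencePanel:
    """Reference genotypes used only for LD: individuals x SNVs in {0,1,2}.

    ``genotypes`` is float with NaN for missing calls.  ``r2_cached`` memoizes
    pairwise r² values, which repeat heavily across the clumping grid.
    """

    snv_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)
    _r2_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.snv_ids = np.asarray(self.snv_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.float32)
        if self.genotypes.shape[1] != len(self.snv_ids):
            raise ValueError("genotype matrix columns must match snv_ids")
        if len(self.chrom) != len(self.snv_ids) or len(self.pos) != len(self.snv_ids):
            raise ValueError("positions must match snv_ids")
        if np.any(np.all(np.isnan(self.genotypes), axis=0)):
            raise ValueError("a panel SNV has 100% missingness")
        self._index = {s: i for i, s in enumerate(self.snv_ids)}

    def __contains__(self, snv_id) -> bool:
        return snv_id in self._index

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def r2(self, id1: str, id2: str) -> float:
        key = (id1, id2) if id1 <= id2 else (id2, id1)
        val = self._r2_cache.get(key)
        if val is None:
            val = r2(self.genotypes[:, self._index[id1]],
                     self.genotypes[:, self._index[id2]])
            self._r2_cache[key] = val
        return val

    # ---------------------------------------------------------------- loaders

    @classmethod
    def from_tsv(cls, matrix_path, sites_path) -> "ReferencePanel":
        """Load a headered 0/1/2 matrix TSV (rows = individuals, first column
        individual_id) plus a sites TSV (snv_id, chrom, pos, ...)."""
        sites = pd.read_csv(sites_path, sep="\t", dtype={"snv_id": str, "chrom": str})
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        mat = mat[list(sites["snv_id"])]
        return cls(
            snv_ids=sites["snv_id"].to_numpy(),
            chrom=sites["chrom"].to_numpy(),
            pos=sites["pos"].to_numpy(),
            genotypes=mat.to_numpy(dtype=np.float32),
        )

    @classmethod
    def from_vcf(cls, path) -> "ReferencePanel":
        """Load hard genotypes (GT) from a VCF; missing calls become NaN."""
        from cyvcf2 import VCF

        ids, chroms, poss, cols = [], [], [], []
        vcf = VCF(str(path))
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            chroms.append(var.CHROM)
            poss.append(var.POS)
            gt = np.asarray(var.gt_types, dtype=np.float32)  # 0,1,3,2=unknown
            g = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
            cols.append(g)
        vcf.close()
        return cls(
            snv_ids=np.array(ids, dtype=object),
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            genotypes=np.column_stack(cols).astype(np.float32),
        )


@dataclass
class WeightSet:
    """The SNVs selected at one grid point, with their scoring weights.

    ``members`` has columns snv_id, chrom, pos, effect_allele, other_allele,
    weight (the meta z), p; no pair of members on the same chromosome within
    the window has r² at or above the threshold.
    """

    params: ClumpParams
    members: pd.DataFrame

    @property
    def size(self) -> int:
        return len(self.members)

    def member_key(self) -> tuple:
        """Hashable identity of the selected SNVs and weights (for
        de-duplicating identical grid points)."""
        return tuple(zip(self.members["snv_id"], self.members["weight"]))

    def write_scoring_file(self, path) -> None:
        """Scoring-file interchange format: snv_id, effect_allele, weight."""
        self.members[["snv_id", "effect_allele", "weight"]].to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


MEMBER_COLUMNS = ["snv_id", "chrom", "pos", "effect_allele", "other_allele", "weight", "p"]


def clump(meta: pd.DataFrame, panel: ReferencePanel, params: ClumpParams) -> WeightSet:
    """Greedy p-ordered clumping of concordant meta-analyzed SNVs.

    Candidates are the concordant SNVs present in the panel with
    meta_p ≤ p_threshold, visited in ascending (p, chrom, pos, snv_id) order;
    a candidate is accepted iff its r² with every already-accepted SNV on the
    same chromosome within ±window_kb is strictly below r2_threshold.
    """
    cand = meta[meta["concordant"]] if "concordant" in meta.columns else meta
    in_panel = np.fromiter((s in panel for s in cand["snv_id"]), bool, len(cand))
    cand = cand[in_panel]
    cand = cand[cand["meta_p"] <= params.p_threshold]
    cand = cand.sort_values(
        ["meta_p", "chrom", "pos", "snv_id"], kind="mergesort"
    )

    if len(cand) == 0:
        warnings.warn(f"no candidate SNVs at {params.label()}", stacklevel=2)
        return WeightSet(params, pd.DataFrame(columns=MEMBER_COLUMNS))

    window_bp = params.window_kb * 1000
    accepted: dict[str, list[tuple[int, str]]] = {}  # chrom -> [(pos, snv_id)]
    rows = []
    for row in cand.itertuples(index=False):
        ok = True
        for pos_j, id_j in accepted.get(row.chrom, ()):
            if abs(row.pos - pos_j) <= window_bp:
                if panel.r2(row.snv_id, id_j) >= params.r2_threshold:
                    ok = False
                    break
        if ok:
            accepted.setdefault(row.chrom, []).append((row.pos, row.snv_id))
            rows.append(
                (row.snv_id, row.chrom, row.pos, row.effect_allele,
                 row.other_allele, row.meta_z, row.meta_p)
            )
    members = pd.DataFrame(rows, columns=MEMBER_COLUMNS)
    return WeightSet(params, members)
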