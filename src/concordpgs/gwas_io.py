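"""Reading, validation, and cross-study harmonization of GWAS summary statistics.

A discovery study arrives as a headered TSV/CSV of per-SNV associations
(identifier, chromosome, position, effect/other allele, a signed z-score or a
beta/SE pair, a p-value, and case/control counts).  Loading validates every row,
converts beta/SE to z, removes strand-ambiguous (palindromic) SNVs, and keeps a
plain-text report of what was dropped and why.  ``harmonize`` then puts every
study on the first study's allele orientation so that a z-score's sign means the
same thing everywhere — the precondition for any cross-study direction test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "DEFAULT_COLUMNS",
    "LoadReport",
    "SummaryStatsSet",
    "read_sumstats",
    "is_palindromic",
    "harmonize",
    "hwe_exact_test",
]

VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))

#: Default summary-statistics column names.  ``z`` is used when present,
#: otherwise ``beta``/``se`` must both be present and z = beta/se is computed.
DEFAULT_COLUMNS: dict[str, str] = {
    "snv_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "z": "Z",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n_cases": "N_CASES",
    "n_controls": "N_CONTROLS",
}

RECORD_COLUMNS = [
    "snv_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "z",
    "p",
    "n_cases",
    "n_controls",
]


@dataclass
class LoadReport:
    """Counts of rows read, kept, and dropped by reason for one input file."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        if n:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(n)

    def __str__(self) -> str:  # plain-text load report
        lines = [f"rows read: {self.rows_read}", f"rows kept: {self.rows_kept}"]
        for reason, n in sorted(self.dropped.items()):
            lines.append(f"dropped ({reason}): {n}")
        return "\n".join(lines)


@dataclass
class SummaryStatsSet:
    """One study's validated summary statistics.

    ``records`` holds one row per SNV with the columns in :data:`RECORD_COLUMNS`;
    ``snv_id`` is unique within a set.  ``trait_kind`` distinguishes a binary
    case/control GWAS from a quantitative trait scored against a case threshold
    (an AUDIT-style instrument), which matters only for how the effective sample
    size is derived downstream.
    """

    study_label: str
    records: pd.DataFrame
    trait_kind: str = "binary"
    report: LoadReport | None = None

    def __post_init__(self) -> None:
        if self.trait_kind not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_kind: {self.trait_kind!r}")
        if self.records["snv_id"].duplicated().any():
            raise ValueError(f"duplicate snv_id in study {self.study_label!r}")

    @property
    def snv_ids(self) -> pd.Index:
        return pd.Index(self.records["snv_id"])

    def __len__(self) -> int:
        return len(self.records)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    for a in (a1, a2):
        if a not in VALID_ALLELES:
            raise ValueError(f"invalid allele: {a!r}")
    if a1 == a2:
        raise ValueError("alleles must differ")
    return frozenset((a1, a2)) in _PALINDROMIC


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    *,
    study_label: str | None = None,
    trait_kind: str = "binary",
    drop_palindromic: bool = True,
) -> SummaryStatsSet:
    """Load one study's summary statistics from a headered TSV or CSV.

    ``column_map`` overrides entries of :data:`DEFAULT_COLUMNS`.  Rows failing
    validation (non-ACGT or identical alleles, p outside (0, 1], non-finite z,
    missing fields) are dropped and counted in the attached :class:`LoadReport`;
    an absent *required* column is a fatal error naming the column.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"summary statistics file not found: {path}")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    df = pd.read_csv(path, sep=None, engine="python", dtype={cols["snv_id"]: str})
    report = LoadReport(rows_read=len(df))

    required = ["snv_id", "chrom", "pos", "effect_allele", "other_allele", "p",
                "n_cases", "n_controls"]
    for key in required:
        if cols[key] not in df.columns:
            raise ValueError(f"required column {cols[key]!r} ({key}) absent from {path}")

    have_z = cols["z"] in df.columns
    if not have_z:
        for key in ("beta", "se"):
            if cols[key] not in df.columns:
                raise ValueError(
                    f"required column {cols['z']!r} (z) absent and no "
                    f"{cols[key]!r} ({key}) fallback in {path}"
                )

    out = pd.DataFrame(
        {
            "snv_id": df[cols["snv_id"]].astype(str),
            "chrom": df[cols["chrom"]].astype(str),
            "pos": pd.to_numeric(df[cols["pos"]], errors="coerce"),
            "effect_allele": df[cols["effect_allele"]].astype(str).str.upper(),
            "other_allele": df[cols["other_allele"]].astype(str).str.upper(),
            "p": pd.to_numeric(df[cols["p"]], errors="coerce"),
            "n_cases": pd.to_numeric(df[cols["n_cases"]], errors="coerce"),
            "n_controls": pd.to_numeric(df[cols["n_controls"]], errors="coerce"),
        }
    )
    if have_z:
        out["z"] = pd.to_numeric(df[cols["z"]], errors="coerce")
    else:
        beta = pd.to_numeric(df[cols["beta"]], errors="coerce")
        se = pd.to_numeric(df[cols["se"]], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            out["z"] = beta / se

    # row-level validation, each reason counted independently of the others
    missing_allele = df[cols["effect_allele"]].isna() | df[cols["other_allele"]].isna()
    bad_allele = (
        ~out["effect_allele"].isin(list(VALID_ALLELES))
        | ~out["other_allele"].isin(list(VALID_ALLELES))
        | (out["effect_allele"] == out["other_allele"])
    )
    bad_p = ~((out["p"] > 0) & (out["p"] <= 1))
    bad_z = ~np.isfinite(out["z"])
    bad_counts = ~((out["n_cases"] >= 1) & (out["n_controls"] >= 1))
    bad_pos = out["pos"].isna()

    keep = ~(missing_allele | bad_allele | bad_p | bad_z | bad_counts | bad_pos)
    report.add("missing alleles", int(missing_allele.sum()))
    report.add("invalid alleles", int((bad_allele & ~missing_allele).sum()))
    report.add("p outside (0,1]", int(bad_p.sum()))
    report.add("non-finite z", int(bad_z.sum()))
    report.add("invalid counts", int(bad_counts.sum()))
    report.add("missing position", int(bad_pos.sum()))
    out = out[keep]

    dup = out["snv_id"].duplicated(keep="first")
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate snv_id in {path.name}; keeping first occurrence",
            stacklevel=2,
        )
        report.add("duplicate snv_id", int(dup.sum()))
        out = out[~dup]

    if drop_palindromic:
        pal = (
            ((out["effect_allele"] == "A") & (out["other_allele"] == "T"))
            | ((out["effect_allele"] == "T") & (out["other_allele"] == "A"))
            | ((out["effect_allele"] == "C") & (out["other_allele"] == "G"))
            | ((out["effect_allele"] == "G") & (out["other_allele"] == "C"))
        )
        report.add("palindromic", int(pal.sum()))
        out = out[~pal]

    out = out.astype({"pos": np.int64, "n_cases": np.int64, "n_controls": np.int64})
    out = out[RECORD_COLUMNS].reset_index(drop=True)
    report.rows_kept = len(out)
    return SummaryStatsSet(
        study_label=study_label or path.stem,
        records=out,
        trait_kind=trait_kind,
        report=report,
    )


def filter_palindromic(study: SummaryStatsSet) -> tuple[SummaryStatsSet, int]:
    """Remove strand-ambiguous SNVs from an in-memory set; returns the
    filtered set and the number dropped.  (File loads do this already.)"""
    rec = study.records
    pal = np.fromiter(
        (frozenset((a, b)) in _PALINDROMIC
         for a, b in zip(rec["effect_allele"], rec["other_allele"])),
        bool, len(rec),
    )
    out = SummaryStatsSet(
        study.study_label, rec[~pal].reset_index(drop=True),
        study.trait_kind, study.report,
    )
    return out, int(pal.sum())


def harmonize(studies: list[SummaryStatsSet]) -> list[SummaryStatsSet]:
    """Put every study on the first study's effect-allele orientation.

    For each SNV present in *all* studies: if a later study stores the swapped
    allele pair, its z-sign is flipped and the alleles swapped; a pair that does
    not match even after swapping is a cross-study mismatch and the SNV is
    dropped everywhere.  Strand flips are never attempted — palindromic
    exclusion at load time already removed the cases where they would be
    ambiguous, and silent flipping of the rest risks sign errors.  Only SNVs
    surviving in every study are returned, in the first study's row order.
    """
    if len(studies) < 2:
        raise ValueError("harmonize requires at least 2 studies")

    ref = studies[0]
    ref_rec = ref.records.set_index("snv_id")
    shared = ref_rec.index
    for s in studies[1:]:
        shared = shared.intersection(s.records["snv_id"])
    if len(shared) == 0:
        raise ValueError("no SNVs shared by all studies")

    mismatched: set[str] = set()
    flipped_records: list[pd.DataFrame] = []
    for s in studies[1:]:
        rec = s.records.set_index("snv_id").loc[shared].copy()
        ref_sub = ref_rec.loc[shared]
        same = (rec["effect_allele"] == ref_sub["effect_allele"]) & (
            rec["other_allele"] == ref_sub["other_allele"]
        )
        swapped = (rec["effect_allele"] == ref_sub["other_allele"]) & (
            rec["other_allele"] == ref_sub["effect_allele"]
        )
        mismatched.update(shared[~(same | swapped)])
        rec.loc[swapped, "z"] = -rec.loc[swapped, "z"]
        rec.loc[swapped, ["effect_allele", "other_allele"]] = ref_sub.loc[
            swapped, ["effect_allele", "other_allele"]
        ].to_numpy()
        flipped_records.append(rec)

    kept = pd.Index([i for i in shared if i not in mismatched])
    if len(kept) == 0:
        raise ValueError("no SNVs shared by all studies after allele matching")
    if mismatched:
        warnings.warn(
            f"{len(mismatched)} SNVs dropped for cross-study allele mismatch",
            stacklevel=2,
        )

    # preserve the first study's row order
    kept_set = set(kept)
    order = [i for i in ref_rec.index if i in kept_set]
    out = [
        SummaryStatsSet(
            ref.study_label,
            ref_rec.loc[order].reset_index()[RECORD_COLUMNS],
            ref.trait_kind,
            ref.report,
        )
    ]
    for s, rec in zip(studies[1:], flipped_records):
        out.append(
            SummaryStatsSet(
                s.study_label,
                rec.loc[order].reset_index()[RECORD_COLUMNS],
                s.trait_kind,
                s.report,
            )
        )
    return out


def apply_hwe_filter(
    study: SummaryStatsSet,
    genotype_counts: dict[str, tuple[int, int, int]],
    threshold: float = 1e-6,
) -> tuple[SummaryStatsSet, int]:
    """Optional quality filter: drop SNVs whose genotype counts fail the exact
    Hardy-Weinberg test at ``threshold``.  SNVs without supplied counts are
    kept untouched.  Returns the filtered set and the number dropped.
    """
    drop = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # monomorphic sites keep p = 1
        for snv_id, counts in genotype_counts.items():
            if hwe_exact_test(*counts) < threshold:
                drop.add(snv_id)
    rec = study.records
    keep = ~rec["snv_id"].isin(drop)
    out = SummaryStatsSet(
        study.study_label, rec[keep].reset_index(drop=True),
        study.trait_kind, study.report,
    )
    return out, int((~keep).sum())


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts, computes each configuration's probability under HWE conditional on
    the allele counts, and sums the probabilities of configurations no more
    probable than the observed one.  A monomorphic site returns p = 1 by
    convention (with a warning) — there is nothing to test.

    Used by an optional genotyping-quality filter that drops SNVs below a
    configured threshold when genotype counts are available.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = int(n_hom_ref + n_het + n_hom_alt)
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = int(n_het + 2 * n_hom_alt)   # alt allele count
    n_b = 2 * n - n_a                  # ref allele count
    if n_a == 0 or n_b == 0:
        warnings.warn("monomorphic site: HWE p-value set to 1", stacklevel=2)
        return 1.0

    rare = min(n_a, n_b)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # P(het = h | allele counts) ∝ n! / (hr! h! hc!) * 2^h
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs_het = int(n_het)
    obs_prob = prob[np.nonzero(hets == obs_het)[0][0]]
    p = float(prob[prob <= obs_prob * (1 + 1e-12)].sum())
    return min(p, 1.0)
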