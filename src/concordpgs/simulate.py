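"""Synthetic inputs for the two-stage pipeline with known ground truth.

Generates, under one seed: three discovery-GWAS summary-statistics sets with
partially shared true effects (two case/control cohorts and one quantitative
AUDIT-style cohort scored against a case threshold), an LD reference panel,
and screening/testing target cohorts with a binary phenotype from a
liability-threshold model.

Genetics.  Genotypes are block-structured: within a block of consecutive SNVs
a Gaussian copula with equicorrelation ``within_block_r`` is thresholded to
per-haplotype Bernoulli(maf) margins (two independent haplotypes sum to a
Binomial(2, maf) genotype); blocks are independent and placed far enough apart
that no clumping window spans two blocks while every window covers a whole
block.  Liability = standardized-genotype score (variance h2) + optional
family-shared component + optional large-effect protective carrier variant +
Gaussian environment; case iff liability exceeds the threshold implied by the
prevalence.  Screening cohorts are familial and ascertained for cases by
preferentially sampling case-containing families, emulating cohorts recruited
to study the disorder; testing cohorts are population samples.

Discovery summary statistics come in two modes.  ``full`` simulates each
cohort's genotypes and computes per-SNV score-test z-statistics — exact but
only desk-scale.  ``fast`` draws z ~ N(ncp, 1) with the liability-threshold
noncentrality ncp = b_marginal * phi(t) / (K(1-K)) * sqrt(N_eff) / 2, where
b_marginal folds in LD from the reference panel; this makes discovery cohorts
of the real studies' sizes (hundreds of thousands) free to emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .clump import ReferencePanel
from .gwas_io import RECORD_COLUMNS, SummaryStatsSet
from .meta import audit_threshold_cases
from .scoring import DosageMatrix
from .association import PhenotypeTable

__all__ = [
    "DiscoveryCohort",
    "SimConfig",
    "GroundTruth",
    "SimData",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_discovery_gwas",
    "simulate_all",
    "write_run",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

# AUDIT-style score mapping: score = round(clip(AUDIT_A + AUDIT_B * liability)).
# With the 0-40 instrument range and case threshold 12, a standard-normal
# liability puts ~17% of a population sample at or above the threshold.
AUDIT_A, AUDIT_B = 5.0, 6.75


@dataclass(frozen=True)
class DiscoveryCohort:
    """One discovery GWAS: binary (n_cases, n_controls) or quantitative
    (n, audit_threshold).  ``full_n`` caps the sample actually simulated in
    full mode (summary-level sizes are free in fast mode)."""

    label: str
    n_cases: int | None = None
    n_controls: int | None = None
    n: int | None = None
    audit_threshold: float | None = None
    full_n: int | None = None

    @property
    def quantitative(self) -> bool:
        return self.n is not None

    def __post_init__(self) -> None:
        if self.quantitative:
            if self.audit_threshold is None:
                raise ValueError(f"{self.label}: quantitative cohort needs audit_threshold")
        elif self.n_cases is None or self.n_controls is None:
            raise ValueError(f"{self.label}: binary cohort needs n_cases and n_controls")


def default_discovery_cohorts() -> tuple[DiscoveryCohort, ...]:
    """Three discovery cohorts with the real studies' sample sizes: a large
    unbalanced case/control GWAS, a quantitative AUDIT GWAS, and a very
    unbalanced biobank GWAS."""
    return (
        DiscoveryCohort("cohortA", n_cases=34658, n_controls=167346, full_n=4000),
        DiscoveryCohort("cohortB", n=121604, audit_threshold=12.0, full_n=4000),
        DiscoveryCohort("cohortC", n_cases=15715, n_controls=361562, full_n=4000),
    )


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.  Defaults are the conditions
    the pipeline's tests exercise; see docs/methods.md for rationale."""

    seed: int = 0
    # genome
    n_snvs: int = 5000
    n_causal: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    within_block_r: float = 0.5
    block_spacing_bp: int = 2_000_000
    within_block_spacing_bp: int = 1_000
    palindromic_fraction: float = 0.10
    # trait architecture
    h2_liability: float = 0.5
    prevalence: float = 0.05
    effect_jitter_sd: float = 0.10
    # discovery
    discovery_cohorts: tuple[DiscoveryCohort, ...] = field(
        default_factory=default_discovery_cohorts
    )
    gwas_mode: str = "fast"
    study_missing_fraction: float = 0.01
    study_swap_fraction: float = 0.20
    study_mismatch_fraction: float = 0.005
    # cohorts
    n_reference: int = 400
    n_screening: int = 2000
    family_size: int = 4
    family_var: float = 0.2
    screening_case_fraction: float = 0.7
    n_testing: int = 20_000
    # carrier variant (large-effect protective analogue, kept out of the PGS)
    carrier_enabled: bool = True
    carrier_maf: float = 0.03
    carrier_effect_std: float = -0.1
    # target-side data quirks
    dosage_missing_fraction: float = 0.0
    dosage_swap_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.n_causal <= self.n_snvs):
            raise ValueError("n_causal must lie in [1, n_snvs]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        if not (0 <= self.h2_liability < 1):
            raise ValueError("h2_liability must lie in [0, 1)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.gwas_mode not in ("fast", "full"):
            raise ValueError("gwas_mode must be 'fast' or 'full'")
        resid = 1.0 - self.h2_liability - self.family_var - self._carrier_var()
        if resid <= 0:
            raise ValueError("h2 + family_var + carrier variance must be < 1")

    def _carrier_var(self) -> float:
        return self.carrier_effect_std**2 if self.carrier_enabled else 0.0

    @property
    def liability_threshold(self) -> float:
        return float(stats.norm.ppf(1.0 - self.prevalence))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover.

    ``sites`` has one row per SNV: snv_id, chrom, pos, effect_allele,
    other_allele, maf, causal flag, and effect_std — the liability effect per
    standard-deviation of genotype, normalized so that the causal effects sum
    in squares to h2 (sum effect_per_allele^2 x 2 maf (1-maf) = h2, before the
    LD-induced inflation that realized cohorts exhibit).
    """

    sites: pd.DataFrame
    h2_liability: float
    prevalence: float
    carrier_effect_std: float = 0.0
    carrier_maf: float = 0.0

    @property
    def effects_std(self) -> np.ndarray:
        return self.sites["effect_std"].to_numpy()


def make_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    n = config.n_snvs
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, n)
    n_pal = int(round(config.palindromic_fraction * n))
    pal_mask = np.zeros(n, dtype=bool)
    pal_mask[rng.choice(n, n_pal, replace=False)] = True
    pairs = np.empty((n, 2), dtype=object)
    pairs[~pal_mask] = [
        _NONPALINDROMIC_PAIRS[i]
        for i in rng.integers(0, len(_NONPALINDROMIC_PAIRS), int((~pal_mask).sum()))
    ]
    pairs[pal_mask] = [
        _PALINDROMIC_PAIRS[i]
        for i in rng.integers(0, len(_PALINDROMIC_PAIRS), n_pal)
    ]

    block = config.ld_block_size
    block_idx = np.arange(n) // block
    within = np.arange(n) % block
    pos = 1 + block_idx * config.block_spacing_bp + within * config.within_block_spacing_bp

    causal = np.zeros(n, dtype=bool)
    causal[rng.choice(n, config.n_causal, replace=False)] = True
    raw = np.zeros(n)
    raw[causal] = rng.standard_normal(config.n_causal)
    ss = float((raw**2).sum())
    effect_std = raw * np.sqrt(config.h2_liability / ss) if ss > 0 else raw

    width = len(str(n))
    sites = pd.DataFrame(
        {
            "snv_id": [f"snv{i:0{width}d}" for i in range(n)],
            "chrom": "1",
            "pos": pos.astype(np.int64),
            "effect_allele": pairs[:, 0],
            "other_allele": pairs[:, 1],
            "maf": maf,
            "causal": causal,
            "effect_std": effect_std,
        }
    )
    return GroundTruth(
        sites,
        config.h2_liability,
        config.prevalence,
        config.carrier_effect_std if config.carrier_enabled else 0.0,
        config.carrier_maf if config.carrier_enabled else 0.0,
    )


def simulate_genotypes(
    config: SimConfig, truth: GroundTruth, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Block-LD genotypes (int8, individuals x SNVs) via the haplotype copula."""
    n_snvs = len(truth.sites)
    maf = truth.sites["maf"].to_numpy()
    thresh = stats.norm.ppf(maf)  # latent below threshold -> effect allele
    r = config.within_block_r
    G = np.empty((n_individuals, n_snvs), dtype=np.int8)
    block = config.ld_block_size
    for start in range(0, n_snvs, block):
        m = min(block, n_snvs - start)
        g = np.zeros((n_individuals, m), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n_individuals, 1))
            indep = rng.standard_normal((n_individuals, m))
            latent = np.sqrt(r) * shared + np.sqrt(1.0 - r) * indep
            g += latent < thresh[start : start + m]
        G[:, start : start + m] = g
    return G


def _genetic_score(G: np.ndarray, truth: GroundTruth, chunk: int = 512) -> np.ndarray:
    """Standardized-genotype liability score, chunked to keep memory flat."""
    maf = truth.sites["maf"].to_numpy()
    b = truth.effects_std
    mean = 2.0 * maf
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    out = np.zeros(G.shape[0])
    for j0 in range(0, G.shape[1], chunk):
        j1 = min(j0 + chunk, G.shape[1])
        if not np.any(b[j0:j1]):
            continue
        block = (G[:, j0:j1].astype(np.float64) - mean[j0:j1]) / sd[j0:j1]
        out += block @ b[j0:j1]
    return out


@dataclass
class _Cohort:
    genotypes: np.ndarray
    liability: np.ndarray
    case: np.ndarray
    carrier_geno: np.ndarray
    family_id: np.ndarray | None = None


def _simulate_cohort(
    config: SimConfig,
    truth: GroundTruth,
    n: int,
    rng: np.random.Generator,
    *,
    familial: bool = False,
) -> _Cohort:
    G = simulate_genotypes(config, truth, n, rng)
    g = _genetic_score(G, truth)

    carrier_geno = np.zeros(n, dtype=np.int8)
    carrier_term = 0.0
    if config.carrier_enabled:
        carrier_geno = rng.binomial(2, config.carrier_maf, n).astype(np.int8)
        p = config.carrier_maf
        c_std = (carrier_geno - 2 * p) / np.sqrt(2 * p * (1 - p))
        carrier_term = config.carrier_effect_std * c_std

    fam_id = None
    fam_term = 0.0
    if familial and config.family_var > 0:
        fam = config.family_size
        fam_id = np.repeat(np.arange(-(-n // fam)), fam)[:n]
        fam_effect = rng.normal(0.0, np.sqrt(config.family_var), fam_id.max() + 1)
        fam_term = fam_effect[fam_id]

    env_var = 1.0 - config.h2_liability - config._carrier_var() - (
        config.family_var if familial else 0.0
    )
    liab = g + carrier_term + fam_term + rng.normal(0.0, np.sqrt(env_var), n)
    case = liab > config.liability_threshold
    return _Cohort(G, liab, case, carrier_geno, fam_id)


def simulate_phenotypes(
    cohort: _Cohort, config: SimConfig, rng: np.random.Generator, id_prefix: str
) -> PhenotypeTable:
    """Covariate table for one cohort: sex, 10 synthetic ancestry PCs,
    genotyping-array label, family id (familial cohorts), carrier flag."""
    n = len(cohort.case)
    df = pd.DataFrame({"individual_id": [f"{id_prefix}{i:06d}" for i in range(n)]})
    df["case_status"] = cohort.case.astype(int)
    df["sex"] = rng.integers(0, 2, n)
    pcs = rng.standard_normal((n, 10))
    for i in range(10):
        df[f"pc{i+1}"] = pcs[:, i]
    df["array"] = np.where(rng.random(n) < 0.5, "arrayA", "arrayB")
    if cohort.family_id is not None:
        df["family_id"] = [f"fam{f:05d}" for f in cohort.family_id]
    df["carrier_flag"] = cohort.carrier_geno > 0
    return PhenotypeTable(df)


def _ascertained_screening(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> _Cohort:
    """Case-ascertained familial cohort.

    Emulates cohorts recruited to study the disorder: whole families are
    sampled preferentially when they contain cases, and most unaffected
    members are then excluded (the strict-control-definition effect), which
    is what pushes the case fraction far above the population prevalence.
    Family labels survive for the cluster-robust fits; families may lose
    control members but are never split across the kept/dropped boundary
    case-wise.
    """
    fam = config.family_size
    n = config.n_screening
    target_cases = int(round(config.screening_case_fraction * n))
    target_controls = n - target_cases
    pool_n = fam * -(-int(np.ceil(
        1.3 * max(n, target_cases / max(config.prevalence, 1e-3))
    )) // fam)
    pool = _simulate_cohort(config, truth, pool_n, rng, familial=True)

    fam_ids = pool.family_id
    n_fam = fam_ids.max() + 1
    fam_cases = np.bincount(fam_ids, weights=pool.case, minlength=n_fam)
    order = np.lexsort((np.arange(n_fam), -fam_cases))  # case-rich families first
    chosen, cases_so_far = [], 0
    for f in order:
        if cases_so_far >= target_cases:
            break
        if fam_cases[f] == 0:
            break
        chosen.append(f)
        cases_so_far += int(fam_cases[f])
    in_chosen = np.isin(fam_ids, np.array(chosen))

    case_idx = np.flatnonzero(in_chosen & pool.case)
    ctrl_idx = np.flatnonzero(in_chosen & ~pool.case)
    if len(ctrl_idx) < target_controls:  # top up controls from other families
        extra = np.flatnonzero(~in_chosen & ~pool.case)
        ctrl_idx = np.concatenate([ctrl_idx, extra])
    keep_cases = case_idx[: target_cases]
    keep_ctrls = ctrl_idx[np.sort(rng.permutation(len(ctrl_idx))[:target_controls])]
    keep = np.sort(np.concatenate([keep_cases, keep_ctrls]))

    new_ids = pd.factorize(fam_ids[keep])[0]
    return _Cohort(
        pool.genotypes[keep], pool.liability[keep], pool.case[keep],
        pool.carrier_geno[keep], new_ids,
    )


# --------------------------------------------------------------------------
# discovery GWAS
# --------------------------------------------------------------------------

def _panel_marginal_effects(
    truth: GroundTruth, panel_genotypes: np.ndarray, block: int
) -> np.ndarray:
    """Marginal standardized effects b_marg = R @ b within each LD block, with
    R the reference-panel genotype correlation; between blocks R = 0."""
    b = truth.effects_std
    out = np.zeros_like(b)
    for j0 in range(0, len(b), block):
        j1 = min(j0 + block, len(b))
        sub = b[j0:j1]
        if not np.any(sub):
            continue
        g = panel_genotypes[:, j0:j1].astype(np.float64)
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        R = np.corrcoef(g, rowvar=False)
        R = np.atleast_2d(R)
        out[j0:j1] = R @ sub
    return out


def _emit_study(
    config: SimConfig,
    truth: GroundTruth,
    label: str,
    z: np.ndarray,
    n_cases: int,
    n_controls: int,
    trait_kind: str,
    rng: np.random.Generator,
    first_study: bool,
) -> SummaryStatsSet:
    """Package raw z-scores as a study's summary statistics, with realistic
    representation noise: per-study allele-representation swaps (z-sign flips
    with swapped alleles — information-preserving), a few per-study missing
    SNVs, and a few corrupted allele pairs (cross-study mismatches)."""
    sites = truth.sites
    rec = pd.DataFrame(
        {
            "snv_id": sites["snv_id"],
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "effect_allele": sites["effect_allele"].copy(),
            "other_allele": sites["other_allele"].copy(),
            "z": z,
            "p": np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
            "n_cases": int(n_cases),
            "n_controls": int(n_controls),
        }
    )
    n = len(rec)
    if not first_study:
        swap = rng.random(n) < config.study_swap_fraction
        ea = rec.loc[swap, "effect_allele"].to_numpy()
        rec.loc[swap, "effect_allele"] = rec.loc[swap, "other_allele"].to_numpy()
        rec.loc[swap, "other_allele"] = ea
        rec.loc[swap, "z"] = -rec.loc[swap, "z"]
        mism = rng.random(n) < config.study_mismatch_fraction
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}
        bad = rec.loc[mism]
        rec.loc[mism, "other_allele"] = [
            alt[a] if alt[a] != e else "G" if e != "G" else "A"
            for a, e in zip(bad["other_allele"], bad["effect_allele"])
        ]
        drop = rng.random(n) < config.study_missing_fraction
        rec = rec[~drop]
    rec = rec.reset_index(drop=True)[RECORD_COLUMNS]
    return SummaryStatsSet(label, rec, trait_kind)


def simulate_discovery_gwas(
    config: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    *,
    panel_genotypes: np.ndarray | None = None,
    mode: str | None = None,
) -> list[SummaryStatsSet]:
    """Per-cohort summary statistics sharing the true effect directions.

    Cohorts get independent multiplicative effect jitter
    b_cohort = b x (1 + N(0, effect_jitter_sd)), the structure the concordance
    filter exploits: causal SNVs agree in direction across cohorts (up to
    jitter and sampling noise) while null SNVs agree only by chance.
    """
    mode = mode or config.gwas_mode
    K = config.prevalence
    t = config.liability_threshold
    phi_t = stats.norm.pdf(t)

    if mode == "fast":
        if panel_genotypes is None:
            raise ValueError("fast mode needs reference-panel genotypes for LD")
        b_marg = _panel_marginal_effects(truth, panel_genotypes, config.ld_block_size)

    out = []
    for ci, cohort in enumerate(config.discovery_cohorts):
        jitter = 1.0 + rng.normal(0.0, config.effect_jitter_sd, config.n_snvs)
        if mode == "fast":
            b = b_marg * jitter
            if cohort.quantitative:
                n = cohort.n
                ncp = b * np.sqrt(n)
                case_liab = (cohort.audit_threshold - 0.5 - AUDIT_A) / AUDIT_B
                n_cases = int(round(n * stats.norm.sf(case_liab)))
                n_controls = n - n_cases
            else:
                n_cases, n_controls = cohort.n_cases, cohort.n_controls
                neff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
                ncp = b * phi_t / (K * (1.0 - K)) * np.sqrt(neff) / 2.0
            z = ncp + rng.standard_normal(config.n_snvs)
        else:
            n_full = cohort.full_n or (
                cohort.n if cohort.quantitative else cohort.n_cases + cohort.n_controls
            )
            jittered = GroundTruth(
                truth.sites.assign(effect_std=truth.effects_std * jitter),
                truth.h2_liability, truth.prevalence,
                truth.carrier_effect_std, truth.carrier_maf,
            )
            sim = _simulate_cohort(config, jittered, n_full, rng)
            if cohort.quantitative:
                y = np.clip(np.round(AUDIT_A + AUDIT_B * sim.liability), 0, 40)
                n_cases = audit_threshold_cases(y, cohort.audit_threshold)
                n_controls = n_full - n_cases
            else:
                y = sim.case.astype(float)
                n_cases = max(int(sim.case.sum()), 1)
                n_controls = max(n_full - n_cases, 1)
            G = sim.genotypes.astype(np.float64)
            gc = G - G.mean(axis=0)
            yc = y - y.mean()
            denom = np.sqrt((gc**2).sum(axis=0) * (yc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (gc * yc[:, None]).sum(axis=0) / denom
            r = np.nan_to_num(r)
            z = r * np.sqrt(n_full)
        out.append(
            _emit_study(
                config, truth, cohort.label, z, n_cases, n_controls,
                "quantitative" if cohort.quantitative else "binary",
                rng, first_study=(ci == 0),
            )
        )
    return out


# --------------------------------------------------------------------------
# bundles and files
# --------------------------------------------------------------------------

@dataclass
class SimData:
    config: SimConfig
    truth: GroundTruth
    studies: list[SummaryStatsSet]
    panel: ReferencePanel
    screening_dosages: DosageMatrix
    screening_phenotypes: PhenotypeTable
    testing_dosages: DosageMatrix
    testing_phenotypes: PhenotypeTable


def _to_dosage_matrix(
    config: SimConfig, truth: GroundTruth, cohort: _Cohort,
    pheno: PhenotypeTable, rng: np.random.Generator,
) -> DosageMatrix:
    d = cohort.genotypes.astype(np.float32)
    sites = truth.sites
    ea = sites["effect_allele"].to_numpy().copy()
    oa = sites["other_allele"].to_numpy().copy()
    if config.dosage_swap_fraction > 0:
        swap = rng.random(len(sites)) < config.dosage_swap_fraction
        d[:, swap] = 2.0 - d[:, swap]
        ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    if config.dosage_missing_fraction > 0:
        miss = rng.random(d.shape) < config.dosage_missing_fraction
        d[miss] = np.nan
    return DosageMatrix(
        pheno.data["individual_id"].to_numpy(dtype=object),
        sites["snv_id"].to_numpy(), ea, oa, d,
    )


def simulate_all(config: SimConfig) -> SimData:
    """Generate every pipeline input under config.seed, deterministically."""
    rng = np.random.default_rng(config.seed)
    truth = make_truth(config, rng)

    panel_cohort = _simulate_cohort(config, truth, config.n_reference, rng)
    panel = ReferencePanel(
        truth.sites["snv_id"].to_numpy(), truth.sites["chrom"].to_numpy(),
        truth.sites["pos"].to_numpy(), panel_cohort.genotypes.astype(np.float32),
    )

    studies = simulate_discovery_gwas(
        config, truth, rng, panel_genotypes=panel_cohort.genotypes
    )

    screen = _ascertained_screening(config, truth, rng)
    screen_ph = simulate_phenotypes(screen, config, rng, "scr")
    screen_dos = _to_dosage_matrix(config, truth, screen, screen_ph, rng)

    test = _simulate_cohort(config, truth, config.n_testing, rng)
    test_ph = simulate_phenotypes(test, config, rng, "tst")
    test_dos = _to_dosage_matrix(config, truth, test, test_ph, rng)

    return SimData(config, truth, studies, panel,
                   screen_dos, screen_ph, test_dos, test_ph)


def _write_dosage(dos: DosageMatrix, sites: pd.DataFrame, stem: Path) -> None:
    mat = pd.DataFrame(dos.dosages, index=pd.Index(dos.individual_ids, name="individual_id"),
                       columns=dos.snv_ids)
    mat.to_csv(stem.with_suffix(".dosages.tsv"), sep="\t")
    pd.DataFrame(
        {"snv_id": dos.snv_ids, "chrom": sites["chrom"], "pos": sites["pos"],
         "effect_allele": dos.effect_allele, "other_allele": dos.other_allele}
    ).to_csv(stem.with_suffix(".sites.tsv"), sep="\t", index=False)


def write_run(data: SimData, outdir: str | Path) -> Path:
    """Write every generated input under one run directory with a manifest.

    Emits: per-study summary-statistics TSVs (default column names), the
    reference panel (matrix + sites TSV), screening/testing dosage matrices
    with sites and phenotype tables, the ground truth, and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    for s in data.studies:
        f = outdir / f"sumstats_{s.study_label}.tsv"
        out = s.records.rename(
            columns={"snv_id": "SNP", "chrom": "CHR", "pos": "BP",
                     "effect_allele": "A1", "other_allele": "A2", "z": "Z",
                     "p": "P", "n_cases": "N_CASES", "n_controls": "N_CONTROLS"}
        )
        out.to_csv(f, sep="\t", index=False)
        files[f"sumstats_{s.study_label}"] = f.name

    sites = data.truth.sites
    pd.DataFrame(
        data.panel.genotypes,
        index=pd.Index([f"ref{i:05d}" for i in range(data.panel.n_individuals)],
                       name="individual_id"),
        columns=data.panel.snv_ids,
    ).to_csv(outdir / "panel.dosages.tsv", sep="\t")
    sites[["snv_id", "chrom", "pos", "effect_allele", "other_allele"]].to_csv(
        outdir / "panel.sites.tsv", sep="\t", index=False
    )
    files["panel"] = "panel.dosages.tsv"

    for name, dos, ph in (
        ("screening", data.screening_dosages, data.screening_phenotypes),
        ("testing", data.testing_dosages, data.testing_phenotypes),
    ):
        _write_dosage(dos, sites, outdir / name)
        ph.data.to_csv(outdir / f"{name}.phenotypes.tsv", sep="\t", index=False)
        files[name] = f"{name}.dosages.tsv"

    sites.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    files["truth"] = "truth.tsv"

    cfg = asdict(data.config)
    cfg["discovery_cohorts"] = [asdict(c) for c in data.config.discovery_cohorts]
    manifest = {"seed": data.config.seed, "config": cfg, "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
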