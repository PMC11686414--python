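"""End-to-end two-stage orchestration.

Stage 1 (screening): harmonize the discovery studies, meta-analyze, keep
concordant SNVs, clump at every grid point, score the familial screening
cohort with every weight set, and fit every percentile dichotomization with
family-cluster-robust errors.  Exactly one weight set — the one with the best
top-group odds ratio, resolved for parsimony among comparable sets — crosses
to stage 2.  Stage 2 (testing): the selected PGS alone is evaluated in each
independent testing cohort (plus sex-stratified and carrier-exclusion
variants), so the reported testing-stage associations carry no selection bias.

Every run writes its intermediate tables, a plain-text log of per-stage record
counts, and a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gwas_io import SummaryStatsSet, filter_palindromic, harmonize, read_sumstats
from .meta import concordance_filter, meta_analyze, write_meta_table
from .clump import ReferencePanel, WeightSet, clump, parameter_grid
from .scoring import DosageMatrix
from .association import (
    BOTTOM_FRACTIONS,
    TOP_FRACTIONS,
    PhenotypeTable,
    assess_weight_set,
    screening_scan,
    select_best,
    stratified_analysis,
)
from .simulate import SimConfig, DiscoveryCohort, simulate_all

__all__ = ["RunConfig", "StageError", "run_two_stage"]

_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One run's full configuration: either a ``sim`` block (inputs generated
    in memory) or file paths, plus grid and analysis settings."""

    outdir: Path
    seed: int = 0
    sim: SimConfig | None = None
    # file-based inputs (each sumstats entry: path [, label, trait_kind, columns])
    sumstats: list[dict] = field(default_factory=list)
    panel_matrix: str | None = None
    panel_sites: str | None = None
    panel_vcf: str | None = None
    screening_dosages: str | None = None
    screening_sites: str | None = None
    screening_phenotypes: str | None = None
    testing_dosages: str | None = None
    testing_sites: str | None = None
    testing_phenotypes: str | None = None
    # grids and thresholds
    p_thresholds: list[float] | None = None
    r2_thresholds: list[float] | None = None
    windows_kb: list[int] | None = None
    top_fractions: tuple = TOP_FRACTIONS
    bottom_fractions: tuple = BOTTOM_FRACTIONS
    selection_fraction: float = 0.05
    # analysis toggles
    stratified: bool = True
    carrier_exclusion: bool = True
    hwe_threshold: float | None = None  # HWE filter from panel genotype counts

    @classmethod
    def from_dict(cls, raw: dict, **overrides) -> "RunConfig":
        """Rebuild a configuration from a manifest's ``config`` section."""
        raw = dict(raw)
        raw.update(overrides)
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = dict(sim)
            sim["discovery_cohorts"] = tuple(
                DiscoveryCohort(**c) for c in sim.get("discovery_cohorts", ())
            )
            sim["maf_range"] = tuple(sim["maf_range"])
            sim = SimConfig(**sim)
        cfg = cls(sim=sim, **raw)
        cfg.outdir = Path(cfg.outdir)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            cohorts = sim.pop("discovery_cohorts", None)
            if cohorts is not None:
                sim["discovery_cohorts"] = tuple(DiscoveryCohort(**c) for c in cohorts)
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            sim = SimConfig(**sim)
        raw.update(overrides)
        raw.setdefault("outdir", "run")
        cfg = cls(sim=sim, **raw)
        cfg.outdir = Path(cfg.outdir)
        if cfg.sim is not None:
            cfg.sim.seed = cfg.seed
        return cfg


class _Log:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def stage(self, name: str, **counts) -> None:
        kv = " ".join(f"{k}={v}" for k, v in counts.items())
        self.lines.append(f"[{name}] {kv}".rstrip())

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        data = simulate_all(config.sim)
        testing = None
        if config.sim.n_testing > 0:
            testing = (data.testing_dosages, data.testing_phenotypes)
        return (data.studies, data.panel,
                (data.screening_dosages, data.screening_phenotypes), testing)

    studies = []
    for entry in config.sumstats:
        studies.append(
            read_sumstats(
                entry["path"],
                entry.get("columns"),
                study_label=entry.get("label"),
                trait_kind=entry.get("trait_kind", "binary"),
            )
        )
    if config.panel_vcf:
        panel = ReferencePanel.from_vcf(config.panel_vcf)
    elif config.panel_matrix and config.panel_sites:
        panel = ReferencePanel.from_tsv(config.panel_matrix, config.panel_sites)
    else:
        raise StageError("inputs: no reference panel configured")

    def _target(dos, sites, pheno):
        if not dos:
            return None
        if not (sites and pheno):
            raise StageError("inputs: target cohort needs sites and phenotypes")
        dm = (DosageMatrix.from_vcf(dos) if str(dos).endswith(".vcf")
              else DosageMatrix.from_tsv(dos, sites))
        ph = PhenotypeTable(pd.read_csv(pheno, sep="\t", dtype={"individual_id": str}))
        return dm, ph

    screening = _target(config.screening_dosages, config.screening_sites,
                        config.screening_phenotypes)
    if screening is None:
        raise StageError("inputs: no screening cohort configured")
    testing = _target(config.testing_dosages, config.testing_sites,
                      config.testing_phenotypes)
    return studies, panel, screening, testing


def _config_dict(config: RunConfig) -> dict:
    """JSON-serializable image of the run configuration; together with the
    seed it suffices to re-execute the run."""
    from dataclasses import asdict

    d = asdict(config)
    del d["outdir"]  # not part of the run's identity; supplied on replay
    if config.sim is not None:
        d["sim"]["discovery_cohorts"] = [
            asdict(c) for c in config.sim.discovery_cohorts
        ]
    d["top_fractions"] = [float(f) for f in config.top_fractions]
    d["bottom_fractions"] = [float(f) for f in config.bottom_fractions]
    return d


def run_two_stage(config: RunConfig) -> Path:
    """Execute the full two-stage workflow; returns the run directory.

    A stage failure raises :class:`StageError` naming the stage; outputs
    written before the failure are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log()
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "config": _config_dict(config),
    }

    def _run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:
            log.write(out / "run.log")
            raise StageError(f"{stage}: {exc}") from exc

    studies, panel, screening, testing = _run("inputs", _load_inputs, config)
    log.stage("inputs", studies=len(studies),
              snvs_per_study=",".join(str(len(s)) for s in studies),
              panel_snvs=len(panel.snv_ids))

    # palindromic exclusion for in-memory sets (file loads already did it)
    filtered: list[SummaryStatsSet] = []
    n_pal = 0
    for s in studies:
        f, d = filter_palindromic(s)
        filtered.append(f)
        n_pal += d
    log.stage("palindromic_filter", dropped=n_pal)

    if config.hwe_threshold is not None:
        import numpy as _np

        from .gwas_io import apply_hwe_filter

        g = panel.genotypes
        counts = {
            str(sid): (
                int(_np.nansum(g[:, j] == 0)),
                int(_np.nansum(g[:, j] == 1)),
                int(_np.nansum(g[:, j] == 2)),
            )
            for j, sid in enumerate(panel.snv_ids)
        }
        dropped = 0
        filtered2 = []
        for s in filtered:
            f, d = apply_hwe_filter(s, counts, config.hwe_threshold)
            filtered2.append(f)
            dropped += d
        filtered = filtered2
        log.stage("hwe_filter", threshold=config.hwe_threshold, dropped=dropped)

    harmonized = _run("harmonize", harmonize, filtered)
    log.stage("harmonize", shared_snvs=len(harmonized[0]))

    meta = _run("meta_analysis", meta_analyze, harmonized)
    concordant = concordance_filter(meta)
    write_meta_table(meta, out / "meta.tsv")
    log.stage("meta_analysis", snvs=len(meta), concordant=len(concordant))

    grid = parameter_grid(config.p_thresholds, config.r2_thresholds, config.windows_kb)
    weight_sets: list[WeightSet] = []
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        for params in grid:
            weight_sets.append(_run("clump", clump, concordant, panel, params))
    index = pd.DataFrame(
        [
            {"p_threshold": ws.params.p_threshold,
             "r2_threshold": ws.params.r2_threshold,
             "window_kb": ws.params.window_kb, "n_snvs": ws.size}
            for ws in weight_sets
        ]
    )
    index.to_csv(out / "weight_sets.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    manifest["weight_sets"] = index.to_dict("records")
    log.stage("clump", grid_points=len(grid),
              nonempty=int((index["n_snvs"] > 0).sum()))

    scr_dos, scr_ph = screening
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        scan = _run("screening_scan", screening_scan, weight_sets, scr_dos, scr_ph,
                    config.top_fractions, config.bottom_fractions)
    scan.to_csv(out / "screening_scan.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
    log.stage("screening_scan", rows=len(scan))

    best_params = _run("select_best", select_best, scan,
                       selection_fraction=config.selection_fraction)
    best_ws = next(
        ws for ws in weight_sets if ws.params == best_params
    )
    best_ws.write_scoring_file(out / "best_weights.tsv")
    manifest["selected"] = {
        "p_threshold": best_params.p_threshold,
        "r2_threshold": best_params.r2_threshold,
        "window_kb": best_params.window_kb,
        "n_snvs": best_ws.size,
    }
    log.stage("select_best", **manifest["selected"])

    if testing is None:
        log.stage("testing", skipped="no testing cohort configured")
        manifest["testing"] = "skipped"
    else:
        tst_dos, tst_ph = testing
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = _run("testing", assess_weight_set, best_ws, tst_dos, tst_ph,
                       config.top_fractions, config.bottom_fractions)
            res.to_csv(out / "testing_results.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
            log.stage("testing", rows=len(res))
            if config.stratified:
                strat = _run("stratified", stratified_analysis, best_ws, tst_dos,
                             tst_ph, by="sex",
                             top_fractions=config.top_fractions,
                             bottom_fractions=config.bottom_fractions)
                strat.to_csv(out / "testing_by_sex.tsv", sep="\t", index=False,
                             float_format=_FLOAT_FMT)
                log.stage("stratified", rows=len(strat))
            if config.carrier_exclusion and "carrier_flag" in tst_ph.data.columns:
                noc = _run("carrier_exclusion", stratified_analysis, best_ws,
                           tst_dos, tst_ph, exclude_carriers=True,
                           top_fractions=config.top_fractions,
                           bottom_fractions=config.bottom_fractions)
                noc.to_csv(out / "testing_noncarriers.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
                log.stage("carrier_exclusion", rows=len(noc),
                          excluded=int(tst_ph.data["carrier_flag"].sum()))
        manifest["testing"] = "testing_results.tsv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.write(out / "run.log")
    return out
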