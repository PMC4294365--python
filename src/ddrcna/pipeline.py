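"""End-to-end pipeline: simulate -> call -> pga -> cooccur -> survive ->
express -> report.

Each stage reads/writes plain-text files in a run directory, stamps outputs
with a provenance header (tool version, seed, input checksums) and can be
re-run individually: the master seed fans out into fixed per-stage child
seeds.  A stage failure leaves a ``<stage>.failed`` marker and aborts with
the stage named.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .calls import collapse_probes, filter_regions, intersect_genes, gene_frequency_report
from .cooccurrence import results_frame, screen_all_pairs
from .errors import DdrCnaError
from .expression import nanostring_normalize, sf_regression
from .genome import DDR_GENES, default_genome
from .instability import associate_pga, compute_adjusted_pga
from .simulate import (
    CellLinePanelSpec,
    child_rngs,
    generate_expression_panel,
    get_scenario,
    probe_grid,
    simulate_cohort,
)
from . import survival as surv

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "pga", "cooccur", "survive", "express", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: Path
    scenario: str = "igrt_default"
    n_patients: int | None = None
    seed: int = 0
    gene: str = "NBN"
    altered_def: str = "any"
    ties: str = "efron"
    horizon: float = 5.0
    alpha: float = 0.001
    background_mode: str = "mean"
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["outdir"] = Path(raw.get("outdir", "."))
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        # fixed fan-out so stages are individually re-runnable
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)]).generate_state(1)[0]
            % (2**31)
        )

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def _require(cfg: RunConfig, names: list[str], stage: str) -> None:
    missing = [n for n in names if not cfg.path(n).exists()]
    if missing:
        raise DdrCnaError(f"stage {stage!r}: missing input file(s) {missing}")


def _run_stage(cfg: RunConfig, stage: str, fn) -> None:
    marker = cfg.path(f"{stage}.failed")
    t0 = _time.perf_counter()
    try:
        fn(cfg)
    except Exception:
        marker.touch()
        logger.error("stage %s failed", stage)
        raise
    if marker.exists():
        marker.unlink()
    logger.info("stage %s done in %.2fs", stage, _time.perf_counter() - t0)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> None:
    seed = cfg.stage_seed("simulate")
    bundle = simulate_cohort(
        get_scenario(cfg.scenario, **cfg.overrides),
        seed=seed,
        n_patients=cfg.n_patients,
        with_probes=True,
    )
    genome = bundle.genome
    genome.write_genes_bed(cfg.path("genes.bed"))
    genome.write_gaps_bed(cfg.path("gaps.bed"))
    genome.write_chrom_sizes(cfg.path("chrom.sizes"))
    io.write_probes(bundle.probes, cfg.path("probes.seg.tsv"), seed=seed)
    io.write_clinical(bundle.clinical, cfg.path("clinical.csv"), seed=seed)

    rng = child_rngs(seed, 4)[3]
    counts, classes, sf = generate_expression_panel(CellLinePanelSpec(), rng)
    table = counts.copy()
    table.insert(0, "probe_class", classes)
    io.write_table(
        table.rename_axis("probe"),
        cfg.path("expression_counts.tsv"),
        stage="simulate",
        seed=seed,
        index=True,
    )
    io.write_table(
        sf.rename_axis("cell_line").reset_index(),
        cfg.path("sf3gy.tsv"),
        stage="simulate",
        seed=seed,
    )


def stage_call(cfg: RunConfig) -> None:
    _require(cfg, ["probes.seg.tsv", "genes.bed", "gaps.bed", "chrom.sizes"], "call")
    probes = io.read_probes(cfg.path("probes.seg.tsv"))
    genes = io.read_bed(cfg.path("genes.bed"), names=("chrom", "start", "end", "symbol"))
    gaps = io.read_bed(cfg.path("gaps.bed"), names=("chrom", "start", "end", "kind"))
    sizes = io.read_chrom_sizes(cfg.path("chrom.sizes"))
    grid = {
        c: np.unique(probes.loc[probes["chrom"] == c, "pos"].to_numpy())
        for c in sizes
    }
    regions = collapse_probes(probes)
    regions = filter_regions(regions, gaps, grid)
    patients = np.unique(probes["patient_id"])
    matrix, provenance = intersect_genes(regions, genes, patients=patients)
    checks = {"probes_md5": io.file_checksum(cfg.path("probes.seg.tsv"))}
    io.write_table(regions, cfg.path("regions.tsv"), stage="call", **checks)
    io.write_matrix(matrix, cfg.path("gene_calls.tsv"))
    io.write_table(provenance, cfg.path("gene_call_provenance.tsv"), stage="call")


def stage_pga(cfg: RunConfig) -> None:
    _require(cfg, ["regions.tsv", "gene_calls.tsv", "chrom.sizes", "genes.bed",
                   "clinical.csv"], "pga")
    regions = io.read_table(cfg.path("regions.tsv"))
    matrix = io.read_matrix(cfg.path("gene_calls.tsv"))
    sizes = io.read_chrom_sizes(cfg.path("chrom.sizes"))
    genes = io.read_bed(cfg.path("genes.bed"), names=("chrom", "start", "end", "symbol"))
    gene_chroms = dict(zip(genes["symbol"], genes["chrom"]))
    profiles = compute_adjusted_pga(regions, sizes, gene_chroms, matrix.index)
    io.write_table(profiles.rename_axis("patient_id"), cfg.path("pga.tsv"),
                   stage="pga", index=True)

    clinical = io.read_clinical(cfg.path("clinical.csv"))
    rows = []
    for gene in DDR_GENES:
        for method in ("mann_whitney", "t_test"):
            try:
                a = associate_pga(profiles, matrix, gene, method=method,
                                  altered=cfg.altered_def)
            except DdrCnaError as exc:
                logger.warning("pga association skipped for %s: %s", gene, exc)
                continue
            rows.append({"gene": gene, "method": method, "n_altered": a.n_altered,
                         "n_neutral": a.n_neutral, "statistic": a.statistic,
                         "p_value": a.p_value})
    io.write_table(pd.DataFrame(rows), cfg.path("pga_assoc.tsv"), stage="pga")


def stage_cooccur(cfg: RunConfig) -> None:
    _require(cfg, ["gene_calls.tsv"], "cooccur")
    matrix = io.read_matrix(cfg.path("gene_calls.tsv"))
    results = screen_all_pairs(matrix, genes=list(DDR_GENES), alpha=cfg.alpha,
                               altered_def=cfg.altered_def)
    io.write_table(results_frame(results), cfg.path("cooccurrence.tsv"),
                   stage="cooccur")


def stage_survive(cfg: RunConfig) -> None:
    _require(cfg, ["clinical.csv", "gene_calls.tsv"], "survive")
    clinical = io.read_clinical(cfg.path("clinical.csv"))
    matrix = io.read_matrix(cfg.path("gene_calls.tsv"))
    records = surv.censor_at_horizon(clinical, cfg.horizon)
    records = surv.gain_vs_neutral(records, matrix, cfg.gene)
    marker = f"{cfg.gene}_gain"

    curves = surv.km_estimate(records, strata=marker)
    km_frames = [c.to_frame() for c in curves.values()]
    io.write_table(pd.concat(km_frames, ignore_index=True), cfg.path("km.tsv"),
                   stage="survive")
    chi2, logrank_p = surv.logrank_test(records, marker)

    uni = surv.cox_fit(records, [marker], ties=cfg.ties)
    multi = surv.cox_fit(records, [marker] + surv.CLINICAL_COVARIATES,
                         ties=cfg.ties)
    clin_only = surv.cox_fit(records, surv.CLINICAL_COVARIATES, ties=cfg.ties)

    old_risk = clin_only.predicted_risk(records[surv.CLINICAL_COVARIATES],
                                        cfg.horizon)
    new_risk = multi.predicted_risk(
        records[[marker] + surv.CLINICAL_COVARIATES], cfg.horizon
    )
    cstat_old = surv.c_statistic(old_risk, records, cfg.horizon)
    cstat_new = surv.c_statistic(new_risk, records, cfg.horizon)
    added = surv.nri_idi(old_risk, new_risk, records, cfg.horizon)

    cox = {
        "_provenance": {"tool": f"ddrcna v{__version__}", "seed": cfg.seed},
        "gene": cfg.gene,
        "logrank": {"chi2": chi2, "p": logrank_p},
        "five_year_bRFR": {
            label: curve.survival_at(cfg.horizon) for label, curve in curves.items()
        },
        "univariate": uni.summary().to_dict(orient="index"),
        "multivariate": multi.summary().to_dict(orient="index"),
    }
    cfg.path("cox.json").write_text(json.dumps(cox, indent=2, sort_keys=True))
    metrics = {
        "_provenance": {"tool": f"ddrcna v{__version__}", "seed": cfg.seed},
        "c_statistic_clinical": cstat_old.c_statistic,
        "c_statistic_with_marker": cstat_new.c_statistic,
        "nri": added.nri,
        "idi": added.idi,
        "n_events": added.n_events,
        "n_event_free": added.n_event_free,
    }
    cfg.path("metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))


def stage_express(cfg: RunConfig) -> None:
    _require(cfg, ["expression_counts.tsv", "sf3gy.tsv"], "express")
    raw = io.read_table(cfg.path("expression_counts.tsv")).set_index("probe")
    classes = raw.pop("probe_class")
    sf = io.read_table(cfg.path("sf3gy.tsv")).set_index("cell_line")["sf3gy"]
    normalized = nanostring_normalize(raw, classes, background=cfg.background_mode)
    io.write_table(normalized.rename_axis("gene"), cfg.path("normalized.tsv"),
                   stage="express", index=True)
    regressions = {}
    for gene in DDR_GENES:
        if gene not in normalized.index:
            continue
        r = sf_regression(normalized.loc[gene], sf)
        regressions[gene] = vars(r)
    cfg.path("regressions.json").write_text(
        json.dumps(regressions, indent=2, sort_keys=True)
    )


def stage_report(cfg: RunConfig) -> None:
    _require(cfg, ["gene_calls.tsv", "pga_assoc.tsv", "cooccurrence.tsv",
                   "cox.json", "metrics.json", "regressions.json"], "report")
    matrix = io.read_matrix(cfg.path("gene_calls.tsv"))
    freq = gene_frequency_report(matrix, list(DDR_GENES))
    report = {
        "_provenance": {
            "tool": f"ddrcna v{__version__}",
            "seed": cfg.seed,
            "scenario": cfg.scenario,
        },
        "gene_frequencies": freq.to_dict(orient="records"),
        "pga_associations": io.read_table(cfg.path("pga_assoc.tsv")).to_dict(
            orient="records"
        ),
        "cooccurrence": io.read_table(cfg.path("cooccurrence.tsv")).to_dict(
            orient="records"
        ),
        "survival": json.loads(cfg.path("cox.json").read_text()),
        "metrics": json.loads(cfg.path("metrics.json").read_text()),
        "expression": json.loads(cfg.path("regressions.json").read_text()),
    }
    cfg.path("report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    lines = [f"ddrcna v{__version__} — scenario {cfg.scenario}, seed {cfg.seed}", ""]
    lines.append("Gene alteration frequencies (% of patients):")
    for row in report["gene_frequencies"]:
        lines.append(
            f"  {row['symbol']:>7}: gain {row['pct_gain']:.1f}%  "
            f"loss {row['pct_loss']:.1f}%  any {row['pct_any']:.1f}%"
        )
    s = report["survival"]
    lines.append("")
    lines.append(
        f"5-year bRFR by {s['gene']} gain: "
        + ", ".join(f"{k}={v:.3f}" for k, v in s["five_year_bRFR"].items())
        + f"  (log-rank p={s['logrank']['p']:.3g})"
    )
    for label, model in (("univariate", s["univariate"]),
                         ("multivariate", s["multivariate"])):
        for cov, row in model.items():
            lines.append(
                f"  {label} {cov}: HR={row['hr']:.2f} "
                f"({row['hr_lo95']:.2f}-{row['hr_hi95']:.2f}), p={row['wald_p']:.3g}"
            )
    m = report["metrics"]
    lines.append(
        f"  c-statistic {m['c_statistic_clinical']:.3f} -> "
        f"{m['c_statistic_with_marker']:.3f}; NRI={m['nri']:.3f}, IDI={m['idi']:.3f}"
    )
    cfg.path("summary.txt").write_text("\n".join(lines) + "\n")


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "call": stage_call,
    "pga": stage_pga,
    "cooccur": stage_cooccur,
    "survive": stage_survive,
    "express": stage_express,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> Path:
    """Run the requested stages in dependency order; returns report path."""
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        if stage in stages:
            _run_stage(cfg, stage, STAGE_FUNCS[stage])
    return cfg.path("report.json")
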