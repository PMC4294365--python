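"""Synthetic cohort generator.

Produces, from a named scenario and a seed, everything the downstream
analysis consumes: a toy genome, per-patient probe-level copy-number tracks
with planted gene events and background segmental aberration, dichotomized
clinical covariates, proportional-hazards recurrence times with planted
hazard ratios, administrative censoring, and NanoString-style expression
fixtures with control-probe structure.

Model in brief
--------------
* Gene events: per gene, each patient independently draws gain / loss /
  neutral at the configured prevalences.  Probes over the gene body (plus a
  random flanking extension when altered) are set to the planted state, so
  every planted event spans at least two probes and the probe->region->gene
  pipeline reproduces the planted truth exactly.
* Background instability: aberrant segments arrive as a Poisson process
  along each chromosome with exponential lengths; the per-patient rate is
  scaled up for patients carrying any DDR-gene alteration so that their
  expected percent genome aberration rises by ``pga_shift`` points.
* Outcomes: event time ~ Exponential(lambda0 * exp(sum beta x)) with
  independent Bernoulli covariates; censoring is administrative — a uniform
  accrual window against a fixed analysis date, i.e. censor ~ U(lo, hi).
* Expression: endogenous counts are linear in the clonogenic surviving
  fraction SF3Gy on the normalized scale, wrapped in lane scaling,
  additive background and (optionally) negative-binomial noise.

Three named scenarios ship with the package: ``igrt_default`` (radiotherapy
cohort covariate mix), ``km_calibrated`` (group-wise 5-year relapse-free
rates of 77% / 46% for NBN-neutral / NBN-gain), and ``cox_calibrated``
(multivariable log-hazards planted for NBN gain, PSA>=10, T2-T3, GS>=7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genome import DDR_GENES, GenomeSpec, default_genome

# Table-1-style covariate mix of the radiotherapy cohort
IGRT_COVARIATE_PREVALENCE = {
    "psa_ge10": 47 / 139,
    "t2_t3": 89 / 139,
    "gs_ge7": 105 / 139,
}

# per-gene (gain, loss) prevalences for the radiotherapy-style cohort;
# NBN gain 14.4% with total NBN alteration 15.1%
IGRT_GENE_PREVALENCE = {
    "NBN": (0.144, 0.007),
    "ATR": (0.050, 0.036),
    "PRKDC": (0.045, 0.034),
    "ATM": (0.030, 0.028),
    "RAD50": (0.015, 0.015),
    "MRE11A": (0.010, 0.010),
    "MYC": (0.150, 0.010),
    "KPNA2": (0.050, 0.020),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one simulated cohort."""

    name: str = "igrt_default"
    n_patients: int = 139
    probe_spacing: int = 20_000
    gene_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(IGRT_GENE_PREVALENCE)
    )
    #: background aberrant-segment rate per bp per patient
    background_rate: float = 5e-7
    #: mean background segment length (bp, exponential)
    mean_segment_length: float = 100_000.0
    #: additive expected-PGA increase (percentage points) for DDR-altered
    pga_shift: float = 5.0
    #: maximal random flank extension around a planted gene event (bp)
    flank_max: int = 40_000
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(IGRT_COVARIATE_PREVALENCE)
    )
    #: log-hazard per covariate; gene indicators are named "<GENE>_gain"
    log_hazards: dict[str, float] = field(default_factory=dict)
    #: baseline exponential hazard rate per year
    baseline_hazard: float = -math.log(0.85) / 5.0
    #: administrative censoring window (uniform accrual vs analysis date)
    censor_window: tuple[float, float] = (4.0, 10.0)
    follow_up_horizon: float = 5.0

    def __post_init__(self):
        for gene, (pg, pl) in self.gene_prevalence.items():
            if not (0 <= pg <= 1 and 0 <= pl <= 1 and pg + pl <= 1):
                raise ConfigurationError(f"bad prevalences for {gene}: {(pg, pl)}")
        for name, p in self.covariate_prevalence.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"bad prevalence for {name}: {p}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline hazard must be positive")
        if self.background_rate < 0 or self.mean_segment_length <= 0:
            raise ConfigurationError("bad background segment model")


def _km_calibrated() -> ScenarioConfig:
    # group-wise exponential hazards pinned to 5-year relapse-free rates of
    # 77% (NBN neutral) and 46% (NBN gain)
    lam_neutral = -math.log(0.77) / 5.0
    lam_gain = -math.log(0.46) / 5.0
    return ScenarioConfig(
        name="km_calibrated",
        n_patients=20_000,
        baseline_hazard=lam_neutral,
        log_hazards={"NBN_gain": math.log(lam_gain / lam_neutral)},
        covariate_prevalence={},
    )


def _cox_calibrated() -> ScenarioConfig:
    # multivariable log-hazards: NBN gain 3.28, PSA>=10 2.93, T2-T3 0.91,
    # Gleason>=7 0.89
    return ScenarioConfig(
        name="cox_calibrated",
        n_patients=50_000,
        log_hazards={
            "NBN_gain": math.log(3.28),
            "psa_ge10": math.log(2.93),
            "t2_t3": math.log(0.91),
            "gs_ge7": math.log(0.89),
        },
    )


def _cox_univariate() -> ScenarioConfig:
    # NBN gain as the only covariate affecting hazard (univariate HR 3.35)
    return ScenarioConfig(
        name="cox_univariate",
        n_patients=50_000,
        baseline_hazard=-math.log(0.77) / 5.0,
        log_hazards={"NBN_gain": math.log(3.35)},
        covariate_prevalence={},
    )


SCENARIOS = {
    "igrt_default": lambda: ScenarioConfig(
        name="igrt_default",
        log_hazards={
            "NBN_gain": math.log(3.28),
            "psa_ge10": math.log(2.93),
            "t2_t3": math.log(0.91),
            "gs_ge7": math.log(0.89),
        },
    ),
    "km_calibrated": _km_calibrated,
    "cox_calibrated": _cox_calibrated,
    "cox_univariate": _cox_univariate,
}


def get_scenario(name: str, **overrides) -> ScenarioConfig:
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    cfg = SCENARIOS[name]()
    return replace(cfg, **overrides) if overrides else cfg


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a master seed out into independent per-stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------
# gene status and probe tracks
# --------------------------------------------------------------------------

def generate_gene_status(
    cfg: ScenarioConfig, genome: GenomeSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Planted per-patient gene states (int8 in {-1, 0, 1})."""
    patients = pd.RangeIndex(cfg.n_patients, name="patient_id")
    symbols = [s for _, _, _, s in genome.genes]
    status = pd.DataFrame(0, index=patients, columns=symbols, dtype=np.int8)
    for symbol in symbols:
        pg, pl = cfg.gene_prevalence.get(symbol, (0.0, 0.0))
        u = rng.random(cfg.n_patients)
        status[symbol] = np.where(u < pg, 1, np.where(u < pg + pl, -1, 0)).astype(
            np.int8
        )
    return status


def probe_grid(genome: GenomeSpec, spacing: int) -> dict[str, np.ndarray]:
    """Regular probe positions per chromosome (offset half a spacing)."""
    return {
        name: np.arange(spacing // 2, length, spacing, dtype=np.int64)
        for name, length in genome.chromosomes
    }


def generate_probe_tracks(
    genome: GenomeSpec,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    gene_status: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient probe-level states with planted gene events.

    Returns ``(probes, gene_status)`` where ``probes`` is a tidy frame
    (patient_id, chrom, pos, state codes in {-1,0,1}) and ``gene_status``
    the planted truth matrix.

    Background segments are laid first; planted gene states then overwrite
    the probes over each gene body (plus a random flank when altered), so
    gene-level calls derived from the probes equal the planted truth.
    """
    grid = probe_grid(genome, cfg.probe_spacing)
    genes_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, symbol in genome.genes:
        if len(grid[chrom][(grid[chrom] >= start) & (grid[chrom] < end)]) < 2:
            raise ConfigurationError(
                f"probe spacing {cfg.probe_spacing} leaves <2 probes in {symbol}"
            )
        genes_by_chrom.setdefault(chrom, []).append((start, end, symbol))

    if gene_status is None:
        gene_status = generate_gene_status(cfg, genome, rng)
    n = cfg.n_patients
    ddr_altered = (gene_status[list(DDR_GENES)] != 0).any(axis=1).to_numpy()

    # Background rate per patient.  DDR-altered patients get a rate
    # increment calibrated so their expected *realized* PGA (after probe
    # quantization, the single-probe filter and gap/gene masking) rises by
    # pga_shift percentage points.  For exponential segment lengths (mean
    # L) on a probe grid with spacing s, the expected retained span per
    # segment is L*exp(-s/L): E[#probes] = L/s and a K-probe segment keeps
    # (K-1)*s bp, vanishing for K < 2.
    L, s = cfg.mean_segment_length, cfg.probe_spacing
    masked = sum(e - b for _, b, e, _ in genome.gaps) + sum(
        e - b for _, b, e, _ in genome.genes
    )
    calib = math.exp(-s / L) * (1.0 - masked / genome.total_size)
    rate = np.full(n, cfg.background_rate)
    if cfg.pga_shift:
        rate[ddr_altered] += cfg.pga_shift / (100.0 * L * calib)

    frames = []
    for chrom, length in genome.chromosomes:
        pos = grid[chrom]
        states = np.zeros((n, len(pos)), dtype=np.int8)
        # Poisson-count background segments, exponential lengths
        counts = rng.poisson(rate * length)
        for i in np.flatnonzero(counts):
            for _ in range(counts[i]):
                s = rng.uniform(0, length)
                e = s + rng.exponential(cfg.mean_segment_length)
                st = 1 if rng.random() < 0.5 else -1
                j0, j1 = np.searchsorted(pos, [s, e])
                states[i, j0:j1] = st
        # plant gene truth on top
        for gstart, gend, symbol in genes_by_chrom.get(chrom, []):
            planted = gene_status[symbol].to_numpy()
            j0, j1 = np.searchsorted(pos, [gstart, gend])
            states[:, j0:j1] = 0  # gene body reflects planted truth only
            for i in np.flatnonzero(planted):
                f_left = rng.uniform(0, cfg.flank_max)
                f_right = rng.uniform(0, cfg.flank_max)
                k0, k1 = np.searchsorted(pos, [gstart - f_left, gend + f_right])
                states[i, k0:k1] = planted[i]
                states[i, j0:j1] = planted[i]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(
                        np.arange(n, dtype=np.int32), len(pos)
                    ),
                    "chrom": chrom,
                    "pos": np.tile(pos, n),
                    "state": states.reshape(-1),
                }
            )
        )
    probes = pd.concat(frames, ignore_index=True)
    probes["chrom"] = probes["chrom"].astype("category")
    return probes, gene_status


# --------------------------------------------------------------------------
# clinical covariates and outcomes
# --------------------------------------------------------------------------

def generate_clinical_and_outcomes(
    cfg: ScenarioConfig,
    gene_status: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical covariates plus proportional-hazards recurrence outcomes.

    Event time ~ Exponential(lambda0 * exp(sum beta x)); censor time drawn
    uniformly from the administrative window; recorded time is the minimum
    with the event flag set accordingly.
    """
    if cfg.baseline_hazard <= 0:
        raise ConfigurationError("baseline hazard must be positive")
    n = len(gene_status)
    clin = pd.DataFrame({"patient_id": gene_status.index})

    cov = {}
    for name, prev in cfg.covariate_prevalence.items():
        cov[name] = (rng.random(n) < prev).astype(int)
    for name in ("psa_ge10", "t2_t3", "gs_ge7"):
        cov.setdefault(name, np.zeros(n, dtype=int))

    # raw clinical values consistent with the dichotomized indicators
    clin["psa"] = np.where(
        cov["psa_ge10"], rng.uniform(10, 33, n), rng.uniform(1, 9.9, n)
    ).round(1)
    clin["t_category"] = np.where(
        cov["t2_t3"], np.where(rng.random(n) < 0.9, "T2", "T3"), "T1"
    )
    clin["gleason"] = np.where(
        cov["gs_ge7"], np.where(rng.random(n) < 0.93, 7, 8), 6
    )
    for name in ("psa_ge10", "t2_t3", "gs_ge7"):
        clin[name] = cov[name]

    # linear predictor from planted log-hazards
    lp = np.zeros(n)
    for name, beta in cfg.log_hazards.items():
        if name.endswith("_gain"):
            gene = name[: -len("_gain")]
            if gene not in gene_status.columns:
                raise ConfigurationError(f"log-hazard references unknown gene {gene}")
            x = (gene_status[gene].to_numpy() == 1).astype(float)
        elif name.endswith("_loss"):
            gene = name[: -len("_loss")]
            x = (gene_status[gene].to_numpy() == -1).astype(float)
        elif name in clin.columns:
            x = clin[name].to_numpy(float)
        else:
            raise ConfigurationError(f"log-hazard references unknown covariate {name}")
        lp += beta * x

    event_time = rng.exponential(1.0 / (cfg.baseline_hazard * np.exp(lp)))
    lo, hi = cfg.censor_window
    censor_time = rng.uniform(lo, hi, n) if hi > 0 else np.zeros(n)
    clin["time"] = np.minimum(event_time, censor_time)
    clin["event"] = event_time <= censor_time
    if hi == 0:
        clin["event"] = False

    for gene in gene_status.columns:
        clin[f"{gene}_status"] = gene_status[gene].to_numpy()
    return clin


# --------------------------------------------------------------------------
# expression fixtures
# --------------------------------------------------------------------------

#: default prostate cell-line panel with clonogenic surviving fractions at
#: 3 Gy (PrEC carries an SF2Gy surrogate and is excluded from regression
#: fits by default)
DEFAULT_CELL_LINES = (
    ("PrEC", 0.30),
    ("LNCaP", 0.20),
    ("22RV1", 0.40),
    ("PC-3", 0.55),
    ("DU-145", 0.70),
)

POSITIVE_CONTROL_BASE = (12800, 3200, 800, 200, 64, 16)  # 6 probes
N_NEGATIVE_CONTROLS = 8
HOUSEKEEPING_BASE = {"B2M": 8000, "ACTB": 12000, "GAPDH": 20000}  # 3 probes


@dataclass(frozen=True)
class CellLinePanelSpec:
    """NanoString-style cell-line panel layout."""

    lines: tuple[tuple[str, float], ...] = DEFAULT_CELL_LINES
    #: per-gene (intercept, slope) of normalized abundance vs SF3Gy;
    #: integer-valued at the default SF values so the noise-free panel is
    #: exactly linear after rounding
    gene_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "NBN": (200.0, 4000.0),
            "MRE11A": (900.0, 0.0),
            "RAD50": (1100.0, 0.0),
            "ATM": (700.0, 0.0),
            "ATR": (500.0, 0.0),
            "PRKDC": (1300.0, 0.0),
            "KPNA2": (800.0, 0.0),
        }
    )
    dispersion: float = 0.05  # negative-binomial dispersion; 0 = noise-free
    background: float = 30.0  # mean negative-control count

    def __post_init__(self):
        for name, sf in self.lines:
            if not 0 < sf <= 1:
                raise ConfigurationError(f"SF3Gy for {name} outside (0, 1]")


def generate_expression_panel(
    panel: CellLinePanelSpec,
    rng: np.random.Generator,
    lane_factor_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Lane-level count table plus SF3Gy values.

    Returns ``(counts, probe_classes, sf3gy)``: counts indexed by probe with
    one column per lane; ``probe_classes`` maps probe -> class in
    {endogenous, positive, negative, housekeeping}.
    """
    if len(panel.lines) < 3:
        raise ConfigurationError("need at least 3 lanes")
    lanes = [name for name, _ in panel.lines]
    sf = pd.Series({name: v for name, v in panel.lines}, name="sf3gy")

    probes, classes, means = [], [], []
    for g, (a, b) in panel.gene_model.items():
        probes.append(g)
        classes.append("endogenous")
        means.append([a + b * sf[l] for l in lanes])
    for i, base in enumerate(POSITIVE_CONTROL_BASE):
        probes.append(f"POS_{chr(65 + i)}")
        classes.append("positive")
        means.append([float(base)] * len(lanes))
    for i in range(N_NEGATIVE_CONTROLS):
        probes.append(f"NEG_{chr(65 + i)}")
        classes.append("negative")
        means.append([0.0] * len(lanes))
    for hk, base in HOUSEKEEPING_BASE.items():
        probes.append(hk)
        classes.append("housekeeping")
        means.append([float(base)] * len(lanes))

    mu = np.asarray(means)  # probes x lanes, signal scale
    factors = (
        np.exp(rng.normal(0.0, lane_factor_sd, len(lanes)))
        if lane_factor_sd > 0
        else np.ones(len(lanes))
    )
    mu = (mu + panel.background) * factors
    if panel.dispersion > 0:
        r = 1.0 / panel.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = np.rint(mu).astype(np.int64)
    table = pd.DataFrame(counts, index=probes, columns=lanes)
    return table, pd.Series(classes, index=probes, name="probe_class"), sf


def generate_cohort_expression(
    gene_status: pd.DataFrame,
    gene: str,
    shift: float = 1.0,
    noise_sd: float = 1.0,
    baseline: float = 10.0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """CNA-correlated per-patient mRNA abundance (normalized scale).

    Mean abundance is ``baseline + shift * gain - shift * loss`` with
    Gaussian noise — the patient-cohort analogue of a copy-number dosage
    effect on expression.
    """
    rng = np.random.default_rng() if rng is None else rng
    status = gene_status[gene].to_numpy(float)
    values = baseline + shift * status + rng.normal(0, noise_sd, len(status))
    return pd.Series(values, index=gene_status.index, name=f"{gene}_mrna")


# --------------------------------------------------------------------------
# one-call cohort bundle
# --------------------------------------------------------------------------

@dataclass
class CohortBundle:
    config: ScenarioConfig
    genome: GenomeSpec
    gene_status: pd.DataFrame
    clinical: pd.DataFrame
    probes: pd.DataFrame | None = None


def simulate_cohort(
    scenario: str | ScenarioConfig,
    seed: int,
    n_patients: int | None = None,
    with_probes: bool = False,
) -> CohortBundle:
    """Generate a full cohort for a named scenario.

    ``with_probes=False`` skips the probe tracks (outcome-only studies);
    gene status is then drawn directly at the configured prevalences, which
    is the same marginal law.
    """
    cfg = scenario if isinstance(scenario, ScenarioConfig) else get_scenario(scenario)
    if n_patients is not None:
        cfg = replace(cfg, n_patients=n_patients)
    genome = default_genome()
    rng_genes, rng_probes, rng_clin = child_rngs(seed, 3)
    gene_status = generate_gene_status(cfg, genome, rng_genes)
    probes = None
    if with_probes:
        probes, _ = generate_probe_tracks(genome, cfg, rng_probes, gene_status)
    clinical = generate_clinical_and_outcomes(cfg, gene_status, rng_clin)
    return CohortBundle(
        config=cfg,
        genome=genome,
        gene_status=gene_status,
        clinical=clinical,
        probes=probes,
    )
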