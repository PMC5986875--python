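"""End-to-end experiment designs for evaluating proportion estimation.

Three designs are supported, each estimating founder genome proportions
of a simulated admixed cohort against a founder panel and scoring them
against the exact simulation truth:

* **full** — the design matrix carries every founder population (this
  includes over-specification: most admixed genomes contain only a subset
  of them); run in equality and/or inequality mode, with the correlation
  between the two modes' estimation errors reported when both are run.
* **type-1 (under-specified)** — one truly contributing population is
  removed from the design; estimation uses the sum<=1 constraint, that
  population's cells are not scored, and results are broken down by how
  much of the omitted genome each individual carries, including which
  remaining population absorbed it.
* **type-2 (miss-specified)** — the design is reduced to two columns: one
  known focal population plus the mean allele content of genotypes
  sampled from all other founders; only the focal column is scored, over
  individuals that truly carry focal genome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admix_sim, cgr_core, eval_metrics, founder_panel, genotype_io
from .admix_sim import BreedingScheme
from .eval_metrics import CATEGORY_LABELS, MetricsReport
from .founder_panel import FounderPanel
from .genotype_io import GenotypeMatrix, PopulationLabels

logger = logging.getLogger(__name__)


@dataclass
class TrialConfig:
    """Configuration of one trial run (file paths optional for in-memory use)."""

    trial_type: str = "full"  # full | type1 | type2
    constraint: str = "equality"
    excluded_population: str | None = None
    focal_population: str | None = None
    background_size: int = 500
    scheme: BreedingScheme = field(default_factory=BreedingScheme)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.trial_type not in ("full", "type1", "type2"):
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.trial_type == "type1" and not self.excluded_population:
            raise ValueError("type-1 trials require an excluded population")
        if self.trial_type == "type2":
            if not self.focal_population:
                raise ValueError("type-2 trials require a focal population")
            if self.background_size < 1:
                raise ValueError("background size must be >= 1")


@dataclass
class FullTrialResult:
    reports: dict[str, MetricsReport]
    proportions: dict[str, pd.DataFrame]
    error_correlation: float | None


@dataclass
class Type1TrialResult:
    overall: MetricsReport
    by_category: dict[str, MetricsReport]
    absorbed_share: pd.DataFrame  # category x remaining population, mean(b_hat - b_true)
    estimates: pd.DataFrame
    excluded_population: str


@dataclass
class Type2TrialResult:
    report: MetricsReport
    estimates: pd.DataFrame
    focal_population: str
    n_used: int


def run_full_trial(
    panel: FounderPanel,
    admixed: GenotypeMatrix,
    truth: pd.DataFrame,
    modes: tuple[str, ...] = ("equality",),
) -> FullTrialResult:
    """Estimate the whole cohort under each constraint mode and score it."""
    truth = truth.loc[admixed.individual_ids, panel.population_names]
    reports: dict[str, MetricsReport] = {}
    props: dict[str, pd.DataFrame] = {}
    for mode in modes:
        ests = cgr_core.estimate_proportions(admixed, panel, mode=mode)
        df = cgr_core.estimates_to_frame(ests, panel.population_names)
        props[mode] = df
        reports[mode] = eval_metrics.compute_metrics(truth, df)
        logger.info(
            "full trial (%s): L=%d N=%d M=%d R=%.4f MSE=%.5f bias=%.5f",
            mode, len(df), panel.n_populations, panel.n_markers,
            reports[mode].correlation, reports[mode].mse, reports[mode].bias,
        )
    err_corr = None
    if len(modes) == 2:
        err_corr = eval_metrics.error_correlation(props[modes[0]], props[modes[1]], truth)
    return FullTrialResult(reports, props, err_corr)


def run_type1_trial(
    panel: FounderPanel,
    admixed: GenotypeMatrix,
    truth: pd.DataFrame,
    excluded: str,
) -> Type1TrialResult:
    """Estimate with one population removed from the design (sum<=1 constraint)."""
    if excluded not in panel.population_names:
        raise ValueError(f"excluded population {excluded!r} not in panel")
    kept = [p for p in panel.population_names if p != excluded]
    reduced = founder_panel.subset_panel(panel, kept)
    ests = cgr_core.estimate_proportions(admixed, reduced, mode="inequality")
    df = cgr_core.estimates_to_frame(ests, kept)
    truth = truth.loc[admixed.individual_ids, panel.population_names]
    overall = eval_metrics.compute_metrics_subset(truth[kept], df, kept)
    by_cat = eval_metrics.metrics_by_category(
        truth, df.reindex(columns=kept), category_population=excluded, scored_populations=kept
    )
    # where did the omitted genome go: mean estimation excess per remaining pop
    cats = eval_metrics.categorise_by_truth(truth[excluded].to_numpy())
    excess = df[kept].to_numpy() - truth[kept].to_numpy()
    rows = {}
    for label in CATEGORY_LABELS:
        mask = cats == label
        if mask.any():
            rows[label] = excess[mask].mean(axis=0)
    absorbed = pd.DataFrame.from_dict(rows, orient="index", columns=kept)
    logger.info(
        "type-1 trial: excluded=%s MAE=%.5f R=%.4f over %d individuals",
        excluded, overall.mae, overall.correlation, len(df),
    )
    return Type1TrialResult(overall, by_cat, absorbed, df, excluded)


def run_type2_trial(
    panel: FounderPanel,
    founders: GenotypeMatrix,
    labels: PopulationLabels,
    admixed: GenotypeMatrix,
    truth: pd.DataFrame,
    focal: str,
    background_size: int = 500,
    seed: int = 0,
) -> Type2TrialResult:
    """Two-column (focal + sampled background) estimation scored on the focal column."""
    truth = truth.loc[admixed.individual_ids, panel.population_names]
    qualifying = truth.index[truth[focal] > 0.0]
    if len(qualifying) == 0:
        raise ValueError(f"no admixed individuals carry {focal!r} genome")
    pool_ids = [i for i in founders.individual_ids if labels.assignments.get(i) != focal]
    pool = founders.subset_individuals(pool_ids)
    design = founder_panel.build_type2_design(
        panel, focal, pool, n_sample=background_size, rng_seed=seed, labels=labels
    )
    subset = admixed.subset_individuals(list(qualifying))
    ests = cgr_core.estimate_proportions(subset, design, mode="inequality")
    df = cgr_core.estimates_to_frame(ests, design.population_names)
    report = eval_metrics.compute_metrics_subset(
        truth.loc[qualifying, [focal]], df[[focal]], [focal]
    )
    logger.info(
        "type-2 trial: focal=%s n=%d R=%.4f MSE=%.5f MAX=%.4f",
        focal, len(qualifying), report.correlation, report.mse, report.max_abs_error,
    )
    return Type2TrialResult(report, df, focal, len(qualifying))


def panel_correlations(panel: FounderPanel) -> pd.DataFrame:
    """Pearson correlation matrix between the panel's frequency columns.

    A proxy for relatedness between founder populations; constant columns
    yield missing entries (with a warning).
    """
    if panel.n_populations < 2:
        raise ValueError("need at least two populations")
    f = panel.freqs
    centred = f - f.mean(axis=0)
    norms = np.sqrt((centred * centred).sum(axis=0))
    zero = norms == 0
    if zero.any():
        import warnings

        warnings.warn("constant frequency columns: correlations undefined", stacklevel=2)
    norms = np.where(zero, np.nan, norms)
    corr = (centred.T @ centred) / np.outer(norms, norms)
    np.fill_diagonal(corr, np.where(zero, np.nan, 1.0))
    return pd.DataFrame(corr, index=panel.population_names, columns=panel.population_names)


# ---------------------------------------------------------------------------
# config-driven entry point
# ---------------------------------------------------------------------------


def run_trial(
    cfg: TrialConfig,
    founders: GenotypeMatrix,
    labels: PopulationLabels,
) -> FullTrialResult | Type1TrialResult | Type2TrialResult:
    """Simulate a cohort per the config's breeding scheme and run its trial.

    Writes report.json, proportions.tsv, categories.tsv (type-1) and
    run.log when ``cfg.outdir`` is set.
    """
    handler = None
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logging.getLogger("cgreg").addHandler(handler)
        logging.getLogger("cgreg").setLevel(logging.INFO)
    try:
        logger.info("trial config: %s", cfg)
        panel = founder_panel.estimate_frequencies(founders, labels)
        admixed, truths = admix_sim.breed(founders, labels, cfg.scheme)
        truth = admix_sim.truths_to_frame(truths, labels.populations)
        logger.info(
            "simulated %d admixed individuals from %d founders at %d markers",
            admixed.n_individuals, founders.n_individuals, founders.n_markers,
        )
        if cfg.trial_type == "full":
            result = run_full_trial(panel, admixed, truth, modes=(cfg.constraint,))
            report = {cfg.constraint: result.reports[cfg.constraint].to_dict()}
            proportions = result.proportions[cfg.constraint]
        elif cfg.trial_type == "type1":
            result = run_type1_trial(panel, admixed, truth, cfg.excluded_population)
            report = {
                "overall": result.overall.to_dict(),
                "by_category": {k: v.to_dict() for k, v in result.by_category.items()},
            }
            proportions = result.estimates
        else:
            result = run_type2_trial(
                panel, founders, labels, admixed, truth,
                cfg.focal_population, cfg.background_size, seed=cfg.seed,
            )
            report = {"focal": result.report.to_dict(), "n_used": result.n_used}
            proportions = result.estimates
        if cfg.outdir:
            out = Path(cfg.outdir)
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            genotype_io.write_proportions(proportions, out / "proportions.tsv")
            if cfg.trial_type == "type1":
                result.absorbed_share.to_csv(out / "categories.tsv", sep="\t")
        return result
    finally:
        if handler is not None:
            logging.getLogger("cgreg").removeHandler(handler)
            handler.close()


def load_config(path: str | Path) -> TrialConfig:
    """Load a YAML/JSON trial config file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scheme_raw = raw.pop("scheme", {})
    if isinstance(scheme_raw, str):
        factory = {"cattle": admix_sim.cattle_scheme, "human": admix_sim.human_scheme}
        scheme = factory[scheme_raw](seed=raw.get("seed", 0))
    else:
        scheme = BreedingScheme(**scheme_raw)
    return TrialConfig(scheme=scheme, **raw)
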