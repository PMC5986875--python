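"""Founder allele-frequency panels and regression design matrices.

A founder panel holds, for each of N candidate source populations, the
frequency ``p_ik`` of the counted allele at every marker ``i``, estimated
from reference individuals of known origin.  Under Hardy-Weinberg the
expected counted-allele dosage of a pure population-k individual is
``2 p_ik``, so the design matrix ``X`` used for proportion estimation has
column ``k`` equal to twice the population-k frequency vector.

Frequencies are plain sample means of the dosage divided by two — no
pseudo-counts or shrinkage — because the estimation model treats founder
frequencies as known constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationLabels


@dataclass
class FounderPanel:
    """Per-population counted-allele frequencies and the derived design matrix."""

    marker_ids: list[str]
    population_names: list[str]
    freqs: np.ndarray  # (M, N), entries in [0, 1]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.marker_ids), len(self.population_names)):
            raise ValueError("freqs shape does not match marker/population counts")
        if len(self.population_names) < 1:
            raise ValueError("panel needs at least one population")
        if (self.freqs < 0).any() or (self.freqs > 1).any():
            raise ValueError("allele frequencies outside [0, 1]")

    @property
    def design(self) -> np.ndarray:
        """M x N matrix of expected allele contents (2p)."""
        return 2.0 * self.freqs

    @property
    def n_markers(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_populations(self) -> int:
        return self.freqs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=self.marker_ids, columns=self.population_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FounderPanel":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


def estimate_frequencies(
    reference: GenotypeMatrix,
    labels: PopulationLabels,
    maf_min: float | None = None,
    maf_max: float | None = None,
) -> FounderPanel:
    """Estimate per-population counted-allele frequencies from labeled genotypes.

    For population k, ``p_ik`` is the sum of non-missing counts over its
    individuals divided by twice their number.  A (marker, population) cell
    with zero non-missing observations raises, listing offending cells; the
    caller may drop those markers and retry.

    ``maf_min``/``maf_max`` optionally drop markers whose frequency across
    the whole reference sample falls outside the bounds (a preprocessing
    filter; monomorphic markers are otherwise retained).
    """
    labels.validate_against(reference)
    pops = labels.populations
    counts = reference.counts
    freqs = np.empty((reference.n_markers, len(pops)))
    empty_cells: list[tuple[str, str]] = []
    col_of = {ind: j for j, ind in enumerate(reference.individual_ids)}
    for k, pop in enumerate(pops):
        ids = labels.individuals_of(pop)
        if not ids:
            raise ValueError(f"population {pop!r} has no labeled individuals")
        sub = counts[:, [col_of[i] for i in ids]]
        obs = sub != MISSING
        n_obs = obs.sum(axis=1)
        total = np.where(obs, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, k] = total / (2.0 * n_obs)
        for i in np.flatnonzero(n_obs == 0):
            empty_cells.append((reference.marker_ids[i], pop))
    if empty_cells:
        shown = ", ".join(f"({m}, {p})" for m, p in empty_cells[:10])
        raise ValueError(
            f"{len(empty_cells)} (marker, population) cells have no non-missing "
            f"observations: {shown}" + ("..." if len(empty_cells) > 10 else "")
        )
    marker_ids = list(reference.marker_ids)
    if maf_min is not None or maf_max is not None:
        obs = reference.counts != MISSING
        overall = np.where(obs, reference.counts, 0).sum(axis=1) / (2.0 * obs.sum(axis=1))
        keep = np.ones(len(marker_ids), dtype=bool)
        if maf_min is not None:
            keep &= overall >= maf_min
        if maf_max is not None:
            keep &= overall <= maf_max
        freqs = freqs[keep]
        marker_ids = [m for m, k_ in zip(marker_ids, keep) if k_]
    return FounderPanel(marker_ids, list(pops), freqs)


def subset_panel(panel: FounderPanel, keep: list[str]) -> FounderPanel:
    """Restrict (and reorder) panel columns to ``keep``; markers unchanged."""
    if not keep:
        raise ValueError("keep list must be non-empty")
    unknown = [p for p in keep if p not in panel.population_names]
    if unknown:
        raise ValueError(f"unknown populations: {unknown}")
    idx = [panel.population_names.index(p) for p in keep]
    return FounderPanel(list(panel.marker_ids), list(keep), panel.freqs[:, idx])


def mean_allele_content(genotypes: GenotypeMatrix) -> np.ndarray:
    """Mean counted-allele dosage per marker over non-missing calls."""
    obs = genotypes.counts != MISSING
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        bad = [genotypes.marker_ids[i] for i in np.flatnonzero(n_obs == 0)[:10]]
        raise ValueError(f"markers with no non-missing genotypes: {bad}")
    return np.where(obs, genotypes.counts, 0).sum(axis=1) / n_obs


def build_type2_design(
    panel: FounderPanel,
    focal: str,
    pool: GenotypeMatrix,
    n_sample: int = 500,
    rng_seed: int | np.random.Generator = 0,
    labels: PopulationLabels | None = None,
) -> FounderPanel:
    """Two-column panel for miss-specification trials.

    Column one is the focal population's expected allele content; column
    two is the mean allele content of ``n_sample`` genotypes drawn
    uniformly without replacement from ``pool``, which must exclude all
    focal-population individuals (pass the reference matrix minus the
    focal individuals).  The second column stands in for "all other
    populations" when nothing precise is known about them.

    When ``labels`` is given, the pool is checked for focal individuals.
    """
    if focal not in panel.population_names:
        raise ValueError(f"unknown focal population {focal!r}")
    if labels is not None:
        intruders = [
            i for i in pool.individual_ids if labels.assignments.get(i) == focal
        ]
        if intruders:
            raise ValueError(
                f"pool contains {len(intruders)} focal-population individuals "
                f"(first: {intruders[0]})"
            )
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    if n_sample > pool.n_individuals:
        raise ValueError(
            f"n_sample={n_sample} exceeds pool size {pool.n_individuals}"
        )
    if panel.marker_ids != pool.marker_ids:
        raise ValueError("pool markers do not match panel markers")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    chosen = rng.choice(pool.n_individuals, size=n_sample, replace=False)
    sampled = GenotypeMatrix(
        list(pool.marker_ids),
        [pool.individual_ids[j] for j in chosen],
        pool.counts[:, chosen],
        list(pool.allele_labels),
    )
    background_freq = mean_allele_content(sampled) / 2.0
    focal_freq = panel.freqs[:, panel.population_names.index(focal)]
    freqs = np.column_stack([focal_freq, background_freq])
    return FounderPanel(list(panel.marker_ids), [focal, "background"], freqs)
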