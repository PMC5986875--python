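"""Forward-in-time admixture simulation with exact ancestry bookkeeping.

Admixed cohorts are built from reference genotypes of labeled founder
populations: genotypes are randomly phased into haplotypes, gametes are
formed with a fixed number of uniformly placed crossovers on the
concatenated marker sequence, and random-mating rounds (parents sampled
with replacement, one offspring per pair) produce the admixed
individuals.  Every allele carries a founder-population origin label, so
each offspring's true genome proportions are known exactly — they are
rationals with denominator 2M — and serve as ground truth for evaluating
proportion estimators.

:func:`make_synthetic_founders` generates founder genotypes from a
Balding-Nichols allele-frequency model when no real reference panel is
at hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationLabels


@dataclass
class HaplotypePair:
    """Two phased haplotypes plus per-marker founder-origin labels."""

    individual_id: str
    hap1: np.ndarray  # (M,) 0/1
    hap2: np.ndarray
    origin1: np.ndarray  # (M,) founder-population indices
    origin2: np.ndarray


@dataclass
class AncestryTruth:
    """True founder genome proportions of one simulated individual."""

    individual_id: str
    b_true: np.ndarray


@dataclass
class BreedingScheme:
    """Random-mating design: per-round mating pairs, crossovers per gamete.

    Each round draws ``n_pairs`` sires and ``n_pairs`` dams with
    replacement (round 1 from the founders, later rounds from the previous
    round's offspring) and produces one offspring per pair.  All rounds'
    offspring form the admixed cohort.
    """

    n_rounds: int = 5
    n_pairs: int | list[int] = 1000
    n_crossovers: int = 25
    seed: int = 0

    def pairs_per_round(self) -> list[int]:
        if isinstance(self.n_pairs, int):
            counts = [self.n_pairs] * self.n_rounds
        else:
            counts = list(self.n_pairs)
            if len(counts) != self.n_rounds:
                raise ValueError("n_pairs list length must equal n_rounds")
        if self.n_rounds < 1 or any(c < 1 for c in counts) or self.n_crossovers < 0:
            raise ValueError("scheme counts must be >= 1 and n_crossovers >= 0")
        return counts


def cattle_scheme(n_crossovers: int = 25, seed: int = 0, n_pairs: int = 1000) -> BreedingScheme:
    """Five rounds of ``n_pairs`` matings each; cohort = all rounds' offspring."""
    return BreedingScheme(n_rounds=5, n_pairs=n_pairs, n_crossovers=n_crossovers, seed=seed)


def human_scheme(n_crossovers: int = 25, seed: int = 0, n_pairs: int = 200) -> BreedingScheme:
    """Five generations of 200 offspring each (1,000 admixed in total).

    Generation 1 uses 200 sire/dam pairs from the founders (one expected
    progeny per parent); later generations redraw 200 pairs from the
    previous generation's 200 offspring (two expected progeny per parent).
    """
    return BreedingScheme(n_rounds=5, n_pairs=n_pairs, n_crossovers=n_crossovers, seed=seed)


def random_phase(
    genotype: np.ndarray,
    rng: np.random.Generator,
    population_index: int,
    individual_id: str = "",
    population_freq: np.ndarray | None = None,
) -> HaplotypePair:
    """Split a dosage vector into two haplotypes by random phasing.

    Homozygotes split deterministically; at heterozygous markers the
    counted allele lands on haplotype 1 or 2 with probability 1/2,
    independently per marker.  Missing dosages are imputed by a
    Hardy-Weinberg draw from ``population_freq`` (required if any call is
    missing).  Both origin vectors are the individual's own population.
    """
    g = np.asarray(genotype, dtype=np.int16).copy()
    miss = g == MISSING
    if miss.any():
        if population_freq is None:
            raise ValueError("missing genotypes present but no population_freq to impute from")
        g[miss] = rng.binomial(2, population_freq[miss]).astype(np.int16)
    m = g.shape[0]
    hap1 = (g == 2).astype(np.int8)
    hap2 = hap1.copy()
    het = g == 1
    coin = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
    hap1[het] = coin
    hap2[het] = 1 - coin
    origin = np.full(m, population_index, dtype=np.int16)
    return HaplotypePair(individual_id, hap1, hap2, origin, origin.copy())


def make_gamete(
    parent: HaplotypePair, n_crossovers: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Form one gamete with exactly ``n_crossovers`` uniform breakpoints.

    Breakpoints are drawn without replacement from the M-1 inter-marker
    intervals; the starting haplotype is chosen with probability 1/2 and
    the copied source alternates at each breakpoint.  Origin labels travel
    with the alleles.
    """
    m = parent.hap1.shape[0]
    if n_crossovers < 0:
        raise ValueError("n_crossovers must be >= 0")
    if n_crossovers > m - 1:
        raise ValueError(f"n_crossovers={n_crossovers} exceeds {m - 1} intervals")
    source = np.full(m, rng.integers(0, 2), dtype=np.int8)
    if n_crossovers:
        breaks = rng.choice(m - 1, size=n_crossovers, replace=False)
        switch = np.zeros(m, dtype=np.int8)
        switch[breaks + 1] = 1
        source = (source + np.cumsum(switch)) % 2
    hap = np.where(source == 0, parent.hap1, parent.hap2)
    origin = np.where(source == 0, parent.origin1, parent.origin2)
    return hap.astype(np.int8), origin.astype(np.int16)


def true_proportions(
    origin1: np.ndarray, origin2: np.ndarray, n_populations: int, individual_id: str = ""
) -> AncestryTruth:
    """Fraction of the 2M allele-origin labels attributable to each population."""
    m = origin1.shape[0]
    counts = np.bincount(origin1, minlength=n_populations) + np.bincount(
        origin2, minlength=n_populations
    )
    return AncestryTruth(individual_id, counts / (2.0 * m))


def breed(
    founders: GenotypeMatrix,
    labels: PopulationLabels,
    scheme: BreedingScheme,
    founder_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, list[AncestryTruth]]:
    """Simulate the multi-round random-mating cohort.

    Returns the admixed genotypes (all rounds' offspring) and their exact
    ancestry truths.  ``founder_freqs`` (markers x populations) is only
    needed to impute missing founder genotypes before phasing.

    Reproducible: the scheme's seed fixes sexes, parent draws, phasing and
    crossovers.
    """
    labels.validate_against(founders)
    rng = np.random.default_rng(scheme.seed)
    pairs = scheme.pairs_per_round()
    pop_index = {p: k for k, p in enumerate(labels.populations)}
    n_pops = len(labels.populations)

    phased: list[HaplotypePair] = []
    for j, ind in enumerate(founders.individual_ids):
        pop = labels.assignments.get(ind)
        if pop is None:
            raise ValueError(f"founder {ind} has no population label")
        k = pop_index[pop]
        freq = founder_freqs[:, k] if founder_freqs is not None else None
        phased.append(
            random_phase(founders.counts[:, j], rng, k, individual_id=ind, population_freq=freq)
        )

    all_offspring: list[HaplotypePair] = []
    truths: list[AncestryTruth] = []
    pool = phased
    for r, n_pairs in enumerate(pairs, start=1):
        sex = rng.integers(0, 2, size=len(pool))
        males = [h for h, s in zip(pool, sex) if s == 0]
        females = [h for h, s in zip(pool, sex) if s == 1]
        if not males or not females:
            raise ValueError(
                f"round {r}: parent pool of {len(pool)} has no "
                f"{'males' if not males else 'females'}"
            )
        sires = rng.integers(0, len(males), size=n_pairs)
        dams = rng.integers(0, len(females), size=n_pairs)
        offspring = []
        for i in range(n_pairs):
            hap_s, ori_s = make_gamete(males[sires[i]], scheme.n_crossovers, rng)
            hap_d, ori_d = make_gamete(females[dams[i]], scheme.n_crossovers, rng)
            child_id = f"adm_r{r}_{i}"
            offspring.append(HaplotypePair(child_id, hap_s, hap_d, ori_s, ori_d))
            truths.append(true_proportions(ori_s, ori_d, n_pops, individual_id=child_id))
        all_offspring.extend(offspring)
        pool = offspring

    counts = np.empty((founders.n_markers, len(all_offspring)), dtype=np.int16)
    for j, child in enumerate(all_offspring):
        counts[:, j] = child.hap1 + child.hap2
    admixed = GenotypeMatrix(
        list(founders.marker_ids),
        [c.individual_id for c in all_offspring],
        counts,
        list(founders.allele_labels),
    )
    return admixed, truths


def truths_to_frame(truths: list[AncestryTruth], populations: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        np.vstack([t.b_true for t in truths]),
        index=[t.individual_id for t in truths],
        columns=populations,
    )


def make_synthetic_founders(
    n_pops: int,
    n_markers: int,
    n_per_pop: int,
    fst: float,
    rng: int | np.random.Generator = 0,
    relative_of: int | None = None,
    relative_fst: float | None = None,
) -> tuple[GenotypeMatrix, PopulationLabels, pd.DataFrame]:
    """Simulate differentiated founder populations and their genotypes.

    Ancestral frequencies are uniform on [0.05, 0.95]; population
    frequencies follow a Balding-Nichols (beta) distribution with
    differentiation ``fst`` around the ancestral value, and genotypes are
    binomial(2, p) per individual and marker (Hardy-Weinberg).

    ``relative_of``/``relative_fst`` optionally make the *last* population
    a close relative of population index ``relative_of``, drawn
    Balding-Nichols around that population's realised frequencies at the
    (small) divergence ``relative_fst`` — useful for studying estimation
    when near-duplicate founder populations are present.

    Returns genotypes, labels and the true markers-by-populations
    frequency table.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    if n_pops < 1 or n_markers < 1 or n_per_pop < 1:
        raise ValueError("n_pops, n_markers and n_per_pop must be >= 1")
    if (relative_of is None) != (relative_fst is None):
        raise ValueError("relative_of and relative_fst must be given together")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def bn_draw(center: np.ndarray, f: float) -> np.ndarray:
        a = center * (1.0 - f) / f
        b = (1.0 - center) * (1.0 - f) / f
        return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)

    p_anc = rng.uniform(0.05, 0.95, size=n_markers)
    freqs = np.column_stack([bn_draw(p_anc, fst) for _ in range(n_pops)])
    if relative_of is not None:
        if not 0 <= relative_of < n_pops - 1:
            raise ValueError("relative_of must index a population other than the last")
        if not 0.0 < relative_fst < 1.0:
            raise ValueError("relative_fst must be in (0, 1)")
        freqs[:, -1] = bn_draw(freqs[:, relative_of], relative_fst)

    pop_names = [f"pop{k + 1}" for k in range(n_pops)]
    counts = np.empty((n_markers, n_pops * n_per_pop), dtype=np.int16)
    ids, pairs = [], []
    for k, pop in enumerate(pop_names):
        block = rng.binomial(2, freqs[:, k][:, None], size=(n_markers, n_per_pop))
        counts[:, k * n_per_pop : (k + 1) * n_per_pop] = block
        for j in range(n_per_pop):
            ind = f"{pop}_ind{j}"
            ids.append(ind)
            pairs.append((ind, pop))
    allele_labels = [("A", "B")] * n_markers
    genotypes = GenotypeMatrix(
        [f"snp{i + 1}" for i in range(n_markers)], ids, counts, allele_labels
    )
    labels = PopulationLabels.from_pairs(pairs)
    freq_table = pd.DataFrame(freqs, index=genotypes.marker_ids, columns=pop_names)
    return genotypes, labels, freq_table
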