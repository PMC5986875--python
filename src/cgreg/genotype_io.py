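"""Genotype, label, frequency and proportion table I/O.

Genotypes are stored as counts of a designated ("counted") allele per
bi-allelic marker: 0, 1 or 2 copies, with missing calls kept as missing.
The counted allele is recorded per marker so that target and reference
matrices genotyped on different strands/panels can be reconciled
(:func:`align_markers`) before any frequency arithmetic happens.

Supported formats
-----------------
* VCF (v4.x, GT field) via cyvcf2; the ALT allele is counted.
* PLINK text ``.ped``/``.map`` pairs; the alphabetically first observed
  allele at each marker is counted (deterministic, not frequency based).
* Plain TSV dialects (tab separated, ``#`` comments allowed):

  - genotype matrix: header ``marker_id [allele_a allele_b] ind1 ind2 ...``,
    one row per marker, entries 0/1/2 or ``NA``/``.`` for missing;
  - labels: two columns ``individual_id  population``;
  - frequency table: ``marker_id pop1 pop2 ...`` with values in [0, 1];
  - proportions: ``individual_id pop1 pop2 ...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call in integer count matrices
MISSING = -1

_RESERVED_COLS = ("marker_id", "allele_a", "allele_b")


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed or fails validation."""


@dataclass
class GenotypeMatrix:
    """Marker-by-individual matrix of counted-allele dosages.

    ``counts`` has shape (M, L) with entries in {0, 1, 2} or :data:`MISSING`.
    ``allele_labels[i]`` is the pair ``(other_allele, counted_allele)`` for
    marker ``i``; it may be ``None`` when the source format carries no
    allele identities (plain TSV without allele columns).
    """

    marker_ids: list[str]
    individual_ids: list[str]
    counts: np.ndarray
    allele_labels: list[tuple[str, str] | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int16)
        m, n = self.counts.shape
        if len(self.marker_ids) != m or len(self.individual_ids) != n:
            raise GenotypeParseError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.individual_ids)} individuals"
            )
        if len(set(self.marker_ids)) != m:
            raise GenotypeParseError("duplicate marker ids")
        if len(set(self.individual_ids)) != n:
            raise GenotypeParseError("duplicate individual ids")
        bad = ~np.isin(self.counts, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"genotype count out of range at marker {self.marker_ids[i]}, "
                f"individual {self.individual_ids[j]}: {self.counts[i, j]}"
            )
        if self.allele_labels is None:
            self.allele_labels = [None] * m
        elif len(self.allele_labels) != m:
            raise GenotypeParseError("allele_labels length does not match marker count")

    @property
    def n_markers(self) -> int:
        return self.counts.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[1]

    def subset_individuals(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.individual_ids.index(i) for i in ids]
        return GenotypeMatrix(
            list(self.marker_ids), list(ids), self.counts[:, idx], list(self.allele_labels)
        )

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        pos = {m: i for i, m in enumerate(self.marker_ids)}
        idx = [pos[m] for m in marker_ids]
        return GenotypeMatrix(
            list(marker_ids),
            list(self.individual_ids),
            self.counts[idx, :],
            [self.allele_labels[i] for i in idx],
        )


@dataclass
class PopulationLabels:
    """Mapping individual id -> population name, with a fixed population order."""

    assignments: dict[str, str]
    populations: list[str]

    def __post_init__(self) -> None:
        if len(self.populations) < 1:
            raise ValueError("at least one population required")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population names")
        unknown = set(self.assignments.values()) - set(self.populations)
        if unknown:
            raise ValueError(f"labels reference unknown populations: {sorted(unknown)}")

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "PopulationLabels":
        order: list[str] = []
        for _, pop in pairs:
            if pop not in order:
                order.append(pop)
        return cls(dict(pairs), order)

    def individuals_of(self, population: str) -> list[str]:
        return [i for i, p in self.assignments.items() if p == population]

    def validate_against(self, genotypes: GenotypeMatrix) -> None:
        present = set(genotypes.individual_ids)
        missing = [i for i in self.assignments if i not in present]
        if missing:
            raise ValueError(
                f"{len(missing)} labeled individuals absent from genotype matrix "
                f"(first: {missing[0]})"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix; ``format`` is one of ``vcf``, ``plink_text``, ``tsv``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"vcf": _read_vcf, "plink_text": _read_plink_text, "tsv": _read_tsv_genotypes}
    try:
        reader = readers[format]
    except KeyError:
        raise ValueError(f"unknown genotype format {format!r}") from None
    return reader(path)


def _read_tsv_genotypes(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "marker_id":
        raise GenotypeParseError(f"{path}: first column must be 'marker_id', got {df.columns[0]!r}")
    has_alleles = list(df.columns[1:3]) == ["allele_a", "allele_b"]
    ind_cols = list(df.columns[(3 if has_alleles else 1):])
    if not ind_cols:
        raise GenotypeParseError(f"{path}: no individual columns")
    raw = df[ind_cols].to_numpy()
    counts = np.full(raw.shape, MISSING, dtype=np.int16)
    for token, value in (("0", 0), ("1", 1), ("2", 2)):
        counts[raw == token] = value
    unknown = ~np.isin(raw, ("0", "1", "2", "NA", ".", "nan")) & ~pd.isna(raw).astype(bool)
    if unknown.any():
        i, j = np.argwhere(unknown)[0]
        raise GenotypeParseError(
            f"{path}: invalid genotype entry {raw[i, j]!r} at line {i + 2}, "
            f"column {ind_cols[j]}"
        )
    labels = None
    if has_alleles:
        labels = list(zip(df["allele_a"].astype(str), df["allele_b"].astype(str)))
    return GenotypeMatrix(df["marker_id"].astype(str).tolist(), ind_cols, counts, labels)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individual_ids = list(vcf.samples)
    marker_ids, labels, rows = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeParseError(
                f"multi-allelic marker {rec.ID or f'{rec.CHROM}:{rec.POS}'} not supported"
            )
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        labels.append((rec.REF, rec.ALT[0]))
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        gt = np.asarray(rec.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING
        rows.append(gt)
    if not rows:
        raise GenotypeParseError(f"{path}: no variant records")
    return GenotypeMatrix(marker_ids, individual_ids, np.vstack(rows), labels)


def _read_plink_text(path: Path) -> GenotypeMatrix:
    """Read a PLINK text fileset; ``path`` may be the .ped file or the prefix."""
    ped = path if path.suffix == ".ped" else path.with_suffix(".ped")
    map_ = ped.with_suffix(".map")
    if not ped.exists() or not map_.exists():
        raise FileNotFoundError(f"need both {ped} and {map_}")
    marker_ids = []
    with open(map_) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise GenotypeParseError(f"{map_}: line {lineno}: expected >=2 fields")
            marker_ids.append(parts[1])
    m = len(marker_ids)
    individual_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped}: line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            individual_ids.append(parts[1])
            allele_rows.append(list(zip(parts[6::2], parts[7::2])))
    # fix the counted allele per marker: alphabetically first observed allele
    counts = np.full((m, len(individual_ids)), MISSING, dtype=np.int16)
    labels: list[tuple[str, str] | None] = []
    for i in range(m):
        observed = sorted(
            {a for row in allele_rows for a in row[i] if a != "0"}
        )
        if len(observed) > 2:
            raise GenotypeParseError(f"multi-allelic marker {marker_ids[i]}: alleles {observed}")
        if not observed:
            labels.append(None)
            continue
        counted = observed[0]
        other = observed[1] if len(observed) == 2 else "0"
        labels.append((other, counted))
        for j, row in enumerate(allele_rows):
            a, b = row[i]
            if a == "0" or b == "0":
                continue
            counts[i, j] = (a == counted) + (b == counted)
    return GenotypeMatrix(marker_ids, individual_ids, counts, labels)


def read_labels(path: str | Path) -> PopulationLabels:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["individual_id", "population"]:
        raise GenotypeParseError(
            f"{path}: expected columns individual_id, population; got {list(df.columns)}"
        )
    return PopulationLabels.from_pairs(list(zip(df["individual_id"], df["population"])))


def write_labels(labels: PopulationLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tpopulation\n")
        for ind, pop in labels.assignments.items():
            fh.write(f"{ind}\t{pop}\n")


# ---------------------------------------------------------------------------
# tabular writers / readers for proportions and frequencies
# ---------------------------------------------------------------------------


def write_proportions(estimates: pd.DataFrame, path: str | Path) -> None:
    """Write an individuals-by-populations proportion table as TSV.

    ``estimates`` must be a DataFrame indexed by individual id with one
    column per population (a shared population order); values are written
    with six decimal places.
    """
    if estimates.columns.duplicated().any():
        raise ValueError("inconsistent population order: duplicate population columns")
    df = estimates.copy()
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_proportions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="individual_id")
    return df.astype(float)


def write_frequency_table(freqs: pd.DataFrame, path: str | Path) -> None:
    """Write a markers-by-populations allele-frequency table as TSV."""
    df = freqs.copy()
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="marker_id")
    return df.astype(float)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix in the TSV dialect read by :func:`read_genotypes`."""
    has_alleles = all(lab is not None for lab in genotypes.allele_labels)
    with open(path, "w") as fh:
        cols = ["marker_id"]
        if has_alleles:
            cols += ["allele_a", "allele_b"]
        cols += genotypes.individual_ids
        fh.write("\t".join(cols) + "\n")
        for i, mid in enumerate(genotypes.marker_ids):
            row = [mid]
            if has_alleles:
                row += list(genotypes.allele_labels[i])
            row += ["NA" if c == MISSING else str(c) for c in genotypes.counts[i]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# marker reconciliation
# ---------------------------------------------------------------------------


def align_markers(
    target: GenotypeMatrix, reference: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both matrices to shared markers and harmonise counted alleles.

    The reference matrix defines the counted allele.  Where the target
    counted the opposite allele its counts are flipped (``2 - count``,
    missing preserved); markers whose allele pairs cannot be reconciled
    are dropped (a tally is logged).  Raises if no shared markers survive.
    """
    for g, name in ((target, "target"), (reference, "reference")):
        if any(lab is None for lab in g.allele_labels):
            raise ValueError(f"{name} matrix lacks allele labels; cannot harmonise")
    ref_pos = {m: i for i, m in enumerate(reference.marker_ids)}
    shared = [m for m in target.marker_ids if m in ref_pos]
    if not shared:
        raise ValueError("no markers shared between target and reference")
    keep_t, keep_r, flip, dropped = [], [], [], 0
    tgt_pos = {m: i for i, m in enumerate(target.marker_ids)}
    for m in shared:
        ti, ri = tgt_pos[m], ref_pos[m]
        t_other, t_counted = target.allele_labels[ti]
        r_other, r_counted = reference.allele_labels[ri]
        if (t_counted, t_other) == (r_counted, r_other):
            keep_t.append(ti), keep_r.append(ri), flip.append(False)
        elif (t_counted, t_other) == (r_other, r_counted):
            keep_t.append(ti), keep_r.append(ri), flip.append(True)
        else:
            dropped += 1
    if dropped:
        logger.info("align_markers: dropped %d markers with irreconcilable alleles", dropped)
    if not keep_t:
        raise ValueError("no markers shared after allele reconciliation")
    t_counts = target.counts[keep_t, :].copy()
    flip = np.asarray(flip)
    if flip.any():
        rows = t_counts[flip, :]
        nonmissing = rows != MISSING
        rows[nonmissing] = 2 - rows[nonmissing]
        t_counts[flip, :] = rows
    kept_ids = [target.marker_ids[i] for i in keep_t]
    aligned_target = GenotypeMatrix(
        kept_ids,
        list(target.individual_ids),
        t_counts,
        [reference.allele_labels[i] for i in keep_r],
    )
    aligned_reference = GenotypeMatrix(
        kept_ids,
        list(reference.individual_ids),
        reference.counts[keep_r, :],
        [reference.allele_labels[i] for i in keep_r],
    )
    return aligned_target, aligned_reference
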