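"""EIGENSTRAT genotype I/O and pseudo-haploid genotype handling.

Genotype triplets (``.geno``/``.snp``/``.ind``) are the lingua franca of
human ancient-DNA work.  This module reads and writes the plain-text
(one character per call per line) dialect, computes per-individual
coverage, and implements the two standard cohort-level transforms:
random-allele pseudo-haploidization and coverage-based filtering.

Conventions
-----------
* ``.geno`` stores one row per SNP, one character per individual:
  ``0``/``1``/``2`` = alternate-allele dosage, ``9`` = missing.
  Internally missing is coded ``-1`` in an ``int8`` matrix.
* Pseudo-haploid individuals carry only ``{0, 2, missing}``: a single
  sampled allele represented as a homozygous diploid call.
* Genetic positions are Morgans internally (as in ``.snp`` files);
  user-facing interfaces elsewhere in the package use centimorgans.
* Chromosomes 1-22 are autosomes; higher codes (X=23, Y=24, ...) are
  parsed and carried along but excluded from autosomal statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
AUTOSOMES = range(1, 23)

SNP_COLUMNS = ["snp_id", "chromosome", "genetic_pos", "physical_pos", "ref_allele", "alt_allele"]
IND_COLUMNS = ["individual_id", "sex", "group_label"]

_SEX_CODES = {"M": "male", "F": "female", "U": "unknown"}
_SEX_CHARS = {v: k for k, v in _SEX_CODES.items()}


class EigenstratFormatError(ValueError):
    """Raised when the .geno/.snp/.ind triplet is malformed or inconsistent."""


@dataclass
class GenotypeTable:
    """Pseudo-haploid (or diploid) calls over SNPs x individuals.

    Attributes
    ----------
    snps : pandas.DataFrame
        Columns ``snp_id, chromosome, genetic_pos, physical_pos,
        ref_allele, alt_allele``; ``genetic_pos`` in Morgans.
    individuals : pandas.DataFrame
        Columns ``individual_id, sex, group_label`` plus optional
        metadata (``site``, ``region``, ``date_class``) and the derived
        ``n_snps_covered``.
    calls : numpy.ndarray
        ``int8`` matrix of shape (n_snps, n_individuals); alternate
        allele dosage 0/1/2, ``-1`` for missing.
    pseudo_haploid : bool
        True when calls are single sampled alleles stored as 0/2.
    """

    snps: pd.DataFrame
    individuals: pd.DataFrame
    calls: np.ndarray
    pseudo_haploid: bool = False

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.snps), len(self.individuals)):
            raise EigenstratFormatError(
                f"calls matrix {self.calls.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.individuals)} individuals"
            )
        if self.pseudo_haploid and (self.calls == 1).any():
            raise EigenstratFormatError("pseudo-haploid table contains heterozygous calls")
        if "n_snps_covered" not in self.individuals.columns:
            self.individuals = self.individuals.copy()
            self.individuals["n_snps_covered"] = self.n_snps_covered()

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def autosomal_mask(self) -> np.ndarray:
        chrom = self.snps["chromosome"].to_numpy()
        return (chrom >= 1) & (chrom <= 22)

    def n_snps_covered(self) -> np.ndarray:
        """Count of non-missing autosomal calls per individual."""
        auto = self.autosomal_mask()
        return (self.calls[auto] != MISSING).sum(axis=0).astype(int)

    def individual_index(self, individual_id: str) -> int:
        ids = self.individuals["individual_id"]
        hits = np.flatnonzero(ids.to_numpy() == individual_id)
        if len(hits) == 0:
            raise KeyError(f"individual {individual_id!r} not in table")
        return int(hits[0])

    def members_of(self, label: str) -> np.ndarray:
        """Column indices of a population label, falling back to a single
        individual id (per-individual targets are legal populations)."""
        groups = self.individuals["group_label"].to_numpy()
        cols = np.flatnonzero(groups == label)
        if len(cols) == 0:
            ids = self.individuals["individual_id"].to_numpy()
            cols = np.flatnonzero(ids == label)
        if len(cols) == 0:
            raise KeyError(f"population or individual {label!r} not in table")
        return cols

    def allele_frequencies(self, label: str) -> np.ndarray:
        """Per-SNP alternate-allele frequency among covered members; NaN
        where no member has data."""
        cols = self.members_of(label)
        sub = self.calls[:, cols].astype(float)
        sub[sub == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(sub, axis=1) / 2.0


def read_eigenstrat(prefix: str | Path, metadata: str | Path | None = None) -> GenotypeTable:
    """Read a ``.geno``/``.snp``/``.ind`` triplet.

    Parameters
    ----------
    prefix
        Path prefix; ``<prefix>.geno`` etc. must exist.
    metadata
        Optional sidecar TSV with columns ``individual_id, site, region,
        date_class`` merged onto the individual table.
    """
    prefix = Path(prefix)
    snp_path, ind_path, geno_path = (prefix.with_suffix(s) for s in (".snp", ".ind", ".geno"))
    for p in (snp_path, ind_path, geno_path):
        if not p.exists():
            raise EigenstratFormatError(f"missing file: {p}")

    snps = _read_snp(snp_path)
    individuals = _read_ind(ind_path)

    n_ind = len(individuals)
    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_ind:
                raise EigenstratFormatError(
                    f"{geno_path}:{lineno}: expected {n_ind} genotype characters, got {len(line)}"
                )
            try:
                row = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            except UnicodeEncodeError as exc:
                raise EigenstratFormatError(f"{geno_path}:{lineno}: non-ASCII genotype line") from exc
            if not np.isin(row, (0, 1, 2, 9)).all():
                raise EigenstratFormatError(f"{geno_path}:{lineno}: genotype characters must be 0/1/2/9")
            rows.append(row)
    calls = np.array(rows, dtype=np.int8)
    if len(calls) != len(snps):
        raise EigenstratFormatError(
            f"{geno_path}: {len(calls)} genotype rows but {snp_path} lists {len(snps)} SNPs"
        )
    calls[calls == 9] = MISSING

    if metadata is not None:
        meta = pd.read_csv(metadata, sep="\t", dtype=str)
        individuals = individuals.merge(meta, on="individual_id", how="left")

    pseudo = not (calls == 1).any()
    return GenotypeTable(snps=snps, individuals=individuals, calls=calls, pseudo_haploid=pseudo)


def write_eigenstrat(table: GenotypeTable, prefix: str | Path) -> None:
    """Write the table back out as a ``.geno``/``.snp``/``.ind`` triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(prefix.with_suffix(".snp"), "w") as fh:
        for rec in table.snps.itertuples(index=False):
            fh.write(
                f"{rec.snp_id:>20} {rec.chromosome:>2} {rec.genetic_pos:>12.6f} "
                f"{rec.physical_pos:>12d} {rec.ref_allele} {rec.alt_allele}\n"
            )
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for rec in table.individuals.itertuples(index=False):
            fh.write(f"{rec.individual_id:>20} {_SEX_CHARS.get(rec.sex, 'U')} {rec.group_label}\n")
    geno = table.calls.copy()
    geno[geno == MISSING] = 9
    chars = geno + ord("0")
    with open(prefix.with_suffix(".geno"), "wb") as fh:
        for row in chars.astype(np.uint8):
            fh.write(row.tobytes() + b"\n")


def _read_snp(path: Path) -> pd.DataFrame:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise EigenstratFormatError(f"{path}:{lineno}: expected >=4 fields, got {len(parts)}")
            ref, alt = (parts[4], parts[5]) if len(parts) >= 6 else ("A", "C")
            try:
                recs.append(
                    (parts[0], int(parts[1]), float(parts[2]), int(parts[3]), ref, alt)
                )
            except ValueError as exc:
                raise EigenstratFormatError(f"{path}:{lineno}: unparseable record: {line!r}") from exc
    return pd.DataFrame(recs, columns=SNP_COLUMNS)


def _read_ind(path: Path) -> pd.DataFrame:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise EigenstratFormatError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            recs.append((parts[0], _SEX_CODES.get(parts[1].upper(), "unknown"), parts[2]))
    return pd.DataFrame(recs, columns=IND_COLUMNS)


def pseudo_haploidize(table: GenotypeTable, seed: int) -> GenotypeTable:
    """Collapse diploid calls to a single randomly sampled allele.

    Heterozygotes become 0 or 2 with equal probability; homozygotes are
    unchanged.  Deterministic given ``seed``; idempotent on its own
    output (no hets remain).
    """
    rng = np.random.default_rng(seed)
    calls = table.calls.copy()
    hets = calls == 1
    calls[hets] = rng.integers(0, 2, size=int(hets.sum()), dtype=np.int8) * 2
    return GenotypeTable(
        snps=table.snps,
        individuals=table.individuals.drop(columns=["n_snps_covered"], errors="ignore"),
        calls=calls,
        pseudo_haploid=True,
    )


def filter_individuals(table: GenotypeTable, min_snps: int) -> GenotypeTable:
    """Keep individuals with strictly more than ``min_snps`` covered
    autosomal SNPs (the conventional ">20,000 SNPs" quality gate).

    Set ``min_snps`` one lower to emulate an at-least threshold.
    """
    if min_snps < 0:
        raise ValueError("min_snps must be >= 0")
    covered = table.n_snps_covered()
    keep = covered > min_snps
    if not keep.any():
        warnings.warn(f"no individuals exceed {min_snps} covered SNPs; returning empty table")
    individuals = (
        table.individuals.loc[keep]
        .drop(columns=["n_snps_covered"], errors="ignore")
        .reset_index(drop=True)
    )
    return GenotypeTable(
        snps=table.snps,
        individuals=individuals,
        calls=table.calls[:, keep],
        pseudo_haploid=table.pseudo_haploid,
    )


def concat_individuals(tables: list[GenotypeTable]) -> GenotypeTable:
    """Column-concatenate tables sharing an identical SNP list."""
    first = tables[0]
    for t in tables[1:]:
        if not first.snps["snp_id"].equals(t.snps["snp_id"]):
            raise EigenstratFormatError("cannot concatenate tables with differing SNP lists")
    individuals = pd.concat(
        [t.individuals.drop(columns=["n_snps_covered"], errors="ignore") for t in tables],
        ignore_index=True,
    )
    calls = np.hstack([t.calls for t in tables])
    return GenotypeTable(
        snps=first.snps,
        individuals=individuals,
        calls=calls,
        pseudo_haploid=all(t.pseudo_haploid for t in tables),
    )
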