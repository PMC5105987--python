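"""Case-control genotype data: container, PLINK text/binary I/O, and filters.

The central object is :class:`GwasDataset`, holding biallelic genotypes for
``|C|`` loci over ``|S|`` samples together with a dichotomous phenotype
(case=1, control=0). Genotypes are stored as the number of copies of the
locus's second allele (0, 1, 2; -1 for missing), which is the natural
encoding of the PLINK binary format. The minor allele is derived per dataset
from the loaded samples; ties at frequency 0.5 are broken toward the
lexicographically smaller allele symbol so that subsetting is deterministic.

Missing genotypes are excluded from allele frequencies and association
tables (the denominator shrinks); this is an explicit convention of the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConsistencyError,
    ParseError,
    UndefinedTestError,
    ValidationError,
)

MISSING = -1
_PHENO_MAP = {"1": 0, "2": 1}  # PLINK coding: 1=control, 2=case
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major .bed


@dataclass(frozen=True)
class Locus:
    """One genotyped biallelic locus (1-based, inclusive coordinates)."""

    id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str


@dataclass
class GwasDataset:
    """A GWA dataset: loci, samples, genotype matrix and phenotype.

    ``genotypes[i, j]`` is the number of copies of ``loci[i].allele2``
    carried by ``samples[j]`` (-1 if missing). ``phenotype[j]`` is 1 for
    cases and 0 for controls.
    """

    loci: list[Locus]
    samples: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.validate()

    # -- bookkeeping ------------------------------------------------------

    def validate(self) -> None:
        if self.genotypes.shape != (len(self.loci), len(self.samples)):
            raise ConsistencyError(
                f"genotype matrix is {self.genotypes.shape}, expected "
                f"({len(self.loci)}, {len(self.samples)})"
            )
        if self.phenotype.shape != (len(self.samples),):
            raise ConsistencyError(
                f"phenotype vector has length {self.phenotype.shape}, "
                f"expected {len(self.samples)}"
            )
        bad = ~np.isin(self.phenotype, (0, 1))
        if bad.any():
            raise ValidationError(
                f"phenotype must be 0 (control) or 1 (case); "
                f"offending samples: {[self.samples[i] for i in np.flatnonzero(bad)[:5]]}"
            )
        bad_g = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad_g.any():
            raise ValidationError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @cached_property
    def locus_ids(self) -> list[str]:
        return [c.id for c in self.loci]

    @cached_property
    def locus_index(self) -> dict[str, int]:
        return {c.id: i for i, c in enumerate(self.loci)}

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotype == 0

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_mask.sum())

    # -- derived allele quantities ---------------------------------------

    @cached_property
    def allele2_frequency(self) -> np.ndarray:
        """Frequency of allele2 per locus over non-missing genotypes (nan if all missing)."""
        g = self.genotypes
        obs = g != MISSING
        n_obs = obs.sum(axis=1)
        counts = np.where(obs, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)

    @cached_property
    def minor_is_allele2(self) -> np.ndarray:
        """Whether allele2 is the minor allele; 0.5 ties go to the smaller symbol."""
        f2 = self.allele2_frequency
        out = np.empty(self.n_loci, dtype=bool)
        for i, locus in enumerate(self.loci):
            if np.isnan(f2[i]) or f2[i] < 0.5:
                out[i] = True
            elif f2[i] > 0.5:
                out[i] = False
            else:
                out[i] = locus.allele2 < locus.allele1
        return out

    @cached_property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per locus, in [0, 0.5] (nan if all missing)."""
        f2 = self.allele2_frequency
        return np.where(self.minor_is_allele2, f2, 1.0 - f2)

    def minor_allele(self, locus_id: str) -> str:
        i = self._idx(locus_id)
        c = self.loci[i]
        return c.allele2 if self.minor_is_allele2[i] else c.allele1

    @cached_property
    def minor_counts(self) -> np.ndarray:
        """Genotypes recoded as minor-allele copy counts (-1 preserved)."""
        g = self.genotypes
        flipped = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
        return np.where(self.minor_is_allele2[:, None], g, flipped)

    # -- subsetting -------------------------------------------------------

    def subset_loci(self, keep: Sequence[int] | np.ndarray) -> "GwasDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GwasDataset(
            loci=[self.loci[i] for i in keep],
            samples=list(self.samples),
            genotypes=self.genotypes[keep],
            phenotype=self.phenotype.copy(),
        )

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "GwasDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GwasDataset(
            loci=list(self.loci),
            samples=[self.samples[i] for i in keep],
            genotypes=self.genotypes[:, keep],
            phenotype=self.phenotype[keep],
        )

    def _idx(self, locus_id: str) -> int:
        try:
            return self.locus_index[locus_id]
        except KeyError:
            raise KeyError(f"unknown locus id: {locus_id!r}") from None

    # -- semantic equality ------------------------------------------------

    def equals(self, other: "GwasDataset") -> bool:
        """Field-by-field equality up to allele1/allele2 orientation.

        The text dialect infers allele order from observed symbols, so two
        loads of the same cohort may disagree on which symbol is allele1;
        genotypes are compared as unordered allele pairs.
        """
        if self.samples != other.samples:
            return False
        if len(self.loci) != len(other.loci):
            return False
        if not np.array_equal(self.phenotype, other.phenotype):
            return False
        for i, (a, b) in enumerate(zip(self.loci, other.loci)):
            if (a.id, a.chrom, a.pos) != (b.id, b.chrom, b.pos):
                return False
            ga, gb = self.genotypes[i], other.genotypes[i]
            if (a.allele1, a.allele2) == (b.allele1, b.allele2):
                same = np.array_equal(ga, gb)
            elif (a.allele1, a.allele2) == (b.allele2, b.allele1):
                same = np.array_equal(ga, np.where(gb == MISSING, MISSING, 2 - gb))
            else:
                # monomorphic loci may carry a '0' placeholder for the unseen allele
                obs_a = {a.allele1, a.allele2} - {"0"}
                obs_b = {b.allele1, b.allele2} - {"0"}
                if obs_a != obs_b:
                    return False
                same = np.array_equal(ga != MISSING, gb != MISSING)
            if not same:
                return False
        return True


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def load_gwas(prefix: str | Path, format: str = "ped") -> GwasDataset:
    """Load a cohort from PLINK files sharing ``prefix``.

    ``format`` is ``"ped"`` (``.ped``/``.map`` text dialect) or ``"bed"``
    (``.bed``/``.bim``/``.fam`` binary dialect). The on-disk phenotype coding
    (1=control, 2=case) is mapped to 0/1.
    """
    prefix = Path(prefix)
    if format in ("ped", "ped_map"):
        return _load_ped_map(prefix)
    if format in ("bed", "bed_bim_fam"):
        return _load_bed_bim_fam(prefix)
    raise ValueError(f"unknown format {format!r}; expected 'ped' or 'bed'")


def write_gwas(dataset: GwasDataset, prefix: str | Path, format: str = "ped") -> None:
    """Write a cohort to PLINK files sharing ``prefix`` (dialects as in load_gwas)."""
    prefix = Path(prefix)
    if format in ("ped", "ped_map"):
        _write_ped_map(dataset, prefix)
    elif format in ("bed", "bed_bim_fam"):
        _write_bed_bim_fam(dataset, prefix)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'ped' or 'bed'")


def _parse_pheno(token: str, path, line_no: int) -> int:
    try:
        return _PHENO_MAP[token]
    except KeyError:
        raise ValidationError(
            f"phenotype must be 1 (control) or 2 (case), got {token!r} "
            f"[{path}:{line_no}]"
        ) from None


def _read_map(path: Path) -> list[tuple[str, str, int]]:
    records = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) not in (3, 4):
                raise ParseError("malformed .map line", path, ln)
            chrom, lid = parts[0], parts[1]
            try:
                pos = int(parts[-1])
            except ValueError:
                raise ParseError("non-integer base-pair position", path, ln)
            records.append((chrom, lid, pos))
    return records


def _load_ped_map(prefix: Path) -> GwasDataset:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    map_records = _read_map(map_path)
    n_loci = len(map_records)

    samples: list[str] = []
    phenos: list[int] = []
    rows: list[np.ndarray] = []  # per-sample allele pairs, shape (n_loci, 2), dtype object
    with open(ped_path) as fh:
        for ln, raw in enumerate(fh, 1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6 + 2 * n_loci:
                raise ParseError(
                    f"expected {6 + 2 * n_loci} fields, got {len(parts)}",
                    ped_path,
                    ln,
                )
            samples.append(parts[1])
            phenos.append(_parse_pheno(parts[5], ped_path, ln))
            rows.append(np.array(parts[6:], dtype=object).reshape(n_loci, 2))
    if not samples:
        raise ParseError("no sample records", ped_path, 1)

    alleles_by_sample = np.stack(rows)  # (n_samples, n_loci, 2)
    loci: list[Locus] = []
    genotypes = np.empty((n_loci, len(samples)), dtype=np.int8)
    for i, (chrom, lid, pos) in enumerate(map_records):
        pair = alleles_by_sample[:, i, :]
        observed = sorted(set(pair.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValidationError(
                f"locus {lid}: more than two allele symbols {observed}"
            )
        a1 = observed[0] if observed else "0"
        a2 = observed[1] if len(observed) == 2 else "0"
        missing = (pair == "0").any(axis=1)
        count2 = (pair == a2).sum(axis=1) if a2 != "0" else np.zeros(len(samples), int)
        genotypes[i] = np.where(missing, MISSING, count2)
        loci.append(Locus(lid, chrom, pos, a1, a2))

    return GwasDataset(loci, samples, genotypes, np.array(phenos))


def _write_ped_map(dataset: GwasDataset, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for c in dataset.loci:
            fh.write(f"{c.chrom}\t{c.id}\t0\t{c.pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for j, sample in enumerate(dataset.samples):
            fields = [sample, sample, "0", "0", "0", str(dataset.phenotype[j] + 1)]
            col = dataset.genotypes[:, j]
            for i, c in enumerate(dataset.loci):
                g = col[i]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [c.allele1, c.allele1]
                elif g == 1:
                    fields += [c.allele1, c.allele2]
                else:
                    fields += [c.allele2, c.allele2]
            fh.write(" ".join(fields) + "\n")


def _load_bed_bim_fam(prefix: Path) -> GwasDataset:
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    bed_path = prefix.with_suffix(".bed")

    loci: list[Locus] = []
    with open(bim_path) as fh:
        for ln, raw in enumerate(fh, 1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6:
                raise ParseError("malformed .bim line", bim_path, ln)
            chrom, lid, _cm, pos, a1, a2 = parts
            try:
                pos = int(pos)
            except ValueError:
                raise ParseError("non-integer base-pair position", bim_path, ln)
            loci.append(Locus(lid, chrom, pos, a1, a2))

    samples: list[str] = []
    phenos: list[int] = []
    with open(fam_path) as fh:
        for ln, raw in enumerate(fh, 1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 6:
                raise ParseError("malformed .fam line", fam_path, ln)
            samples.append(parts[1])
            phenos.append(_parse_pheno(parts[5], fam_path, ln))

    data = np.fromfile(bed_path, dtype=np.uint8)
    if data[:3].tobytes() != _BED_MAGIC:
        raise ParseError("bad .bed magic bytes (expected SNP-major v1)", bed_path, 1)
    n_loci, n_samples = len(loci), len(samples)
    bytes_per_locus = (n_samples + 3) // 4
    expected = 3 + n_loci * bytes_per_locus
    if data.size != expected:
        raise ConsistencyError(
            f"{bed_path}: {data.size} bytes on disk, expected {expected} for "
            f"{n_loci} loci x {n_samples} samples"
        )
    body = data[3:].reshape(n_loci, bytes_per_locus)
    # 2-bit codes, little-endian within each byte: 00=hom a1, 01=missing,
    # 10=het, 11=hom a2
    codes = np.empty((n_loci, bytes_per_locus * 4), dtype=np.int8)
    lut = np.array([0, MISSING, 1, 2], dtype=np.int8)
    for shift in range(4):
        codes[:, shift::4] = lut[(body >> (2 * shift)) & 0b11]
    genotypes = codes[:, :n_samples]
    return GwasDataset(loci, samples, genotypes, np.array(phenos))


def _write_bed_bim_fam(dataset: GwasDataset, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for c in dataset.loci:
            fh.write(f"{c.chrom}\t{c.id}\t0\t{c.pos}\t{c.allele1}\t{c.allele2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for j, sample in enumerate(dataset.samples):
            fh.write(f"{sample} {sample} 0 0 0 {dataset.phenotype[j] + 1}\n")

    n_loci, n_samples = dataset.n_loci, dataset.n_samples
    bytes_per_locus = (n_samples + 3) // 4
    inverse = np.array([0b00, 0b10, 0b11], dtype=np.uint8)
    g = dataset.genotypes
    two_bit = np.where(g == MISSING, 0b01, inverse[np.clip(g, 0, 2)]).astype(np.uint8)
    padded = np.zeros((n_loci, bytes_per_locus * 4), dtype=np.uint8)
    padded[:, :n_samples] = two_bit
    body = np.zeros((n_loci, bytes_per_locus), dtype=np.uint8)
    for shift in range(4):
        body |= padded[:, shift::4] << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(body.tobytes())


# ---------------------------------------------------------------------------
# Filters and single-locus association
# ---------------------------------------------------------------------------


def filter_by_maf(dataset: GwasDataset, threshold: float = 0.05) -> GwasDataset:
    """Remove loci with minor allele frequency <= ``threshold``.

    The boundary is inclusive on the removal side (a locus at exactly the
    threshold is removed). An empty result is allowed; downstream operations
    must tolerate zero loci.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    maf = dataset.maf
    keep = maf > threshold  # nan compares False -> all-missing loci removed
    return dataset.subset_loci(keep)


def _allele_table(minor_counts_row: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """2x2 allele-count table [[minor, major] x [case, control]].

    Each non-missing individual contributes two alleles.
    """
    obs = minor_counts_row != MISSING
    table = np.zeros((2, 2), dtype=np.int64)
    for row, mask in enumerate((case_mask, ~case_mask)):
        m = obs & mask
        n = int(m.sum())
        minor = int(minor_counts_row[m].sum())
        table[row] = (minor, 2 * n - minor)
    return table  # rows: case, control; cols: minor, major


def _chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """1-df Pearson chi-square without continuity correction; zero-margin -> p=1."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    if n == 0 or (r == 0).any() or (c == 0).any():
        return 0.0, 1.0
    det = table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]
    chi2 = n * det * det / (r[0] * r[1] * c[0] * c[1])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def allelic_association_pvalue(dataset: GwasDataset, locus_id: str) -> float:
    """Basic allelic-test p-value for one locus.

    1-df chi-square on the 2x2 minor/major x case/control allele-count
    table, each individual contributing two alleles (PLINK ``--assoc``
    semantics, no continuity correction). A table with a zero margin yields
    p=1 by convention.
    """
    i = dataset._idx(locus_id)
    row = dataset.minor_counts[i]
    obs = row != MISSING
    if not (obs & dataset.case_mask).any() or not (obs & dataset.control_mask).any():
        raise UndefinedTestError(
            f"locus {locus_id}: no non-missing genotypes in one phenotype class"
        )
    _, p = _chi2_2x2(_allele_table(row, dataset.case_mask))
    return p


def allelic_association_pvalues(dataset: GwasDataset) -> np.ndarray:
    """Vectorized allelic-test p-values for all loci.

    Loci with zero non-missing genotypes in a phenotype class get nan;
    zero-margin tables get p=1.
    """
    mc = dataset.minor_counts
    obs = mc != MISSING
    case = dataset.case_mask
    out = np.ones(dataset.n_loci)

    n_case = (obs & case).sum(axis=1)
    n_ctrl = (obs & ~case).sum(axis=1)
    minor_case = np.where(obs & case, mc, 0).sum(axis=1).astype(float)
    minor_ctrl = np.where(obs & ~case, mc, 0).sum(axis=1).astype(float)

    a, b = minor_case, 2 * n_case - minor_case
    c, d = minor_ctrl, 2 * n_ctrl - minor_ctrl
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    valid = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    det = a * d - b * c
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(valid, n * det * det / (r1 * r2 * c1 * c2), 0.0)
    out = np.where(valid, stats.chi2.sf(chi2, df=1), 1.0)
    out[(n_case == 0) | (n_ctrl == 0)] = np.nan
    return out


def exclude_strong_marginals(dataset: GwasDataset, alpha: float = 1e-7) -> GwasDataset:
    """Remove loci whose single-locus association p-value is below ``alpha``.

    Applied before locus-set discovery so that discovered sets reflect joint
    rather than single-locus effects. Loci whose test is undefined (a fully
    missing phenotype class) are retained.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    p = allelic_association_pvalues(dataset)
    keep = ~(p < alpha)  # nan -> keep
    return dataset.subset_loci(keep)
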