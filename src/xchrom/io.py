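"""Readers and writers for the genotype file formats the pipeline touches.

Supports the PLINK 1 binary fileset (``.bed``/``.bim``/``.fam``,
SNP-major), the PLINK text fileset (``.ped``/``.map``), the long-format
genotype-call export produced by array-genotyping cloud software
(three columns: SNP reference, sample id, genotype call), and numeric
dosage export under an X-inactivation model.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    FEMALE,
    MALE,
    MISSING,
    PHENO_MISSING,
    X_CODE,
    Cohort,
    SampleRecord,
    SnpRecord,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit PLINK codes (LSB-first within a byte):
# 00 = hom A1 -> 2 copies of A1, 01 = missing, 10 = het, 11 = hom A2
_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

#: genotype-call tokens treated as no-calls in long-format exports
UNDETERMINED_TOKENS = frozenset(
    {"", "-", "--", "NA", "N/A", "UND", "UNDETERMINED", "NOAMP", "./.", "-/-"}
)

VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """A genotype file violates its format contract."""


def _with_ext(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


def _chrom_code(token: str) -> int:
    if token.upper() == "X":
        return X_CODE
    return int(token)


# ---------------------------------------------------------------------------
# PLINK binary fileset
# ---------------------------------------------------------------------------


def read_bed(path_prefix: str | Path) -> Cohort:
    """Read a PLINK binary fileset ``prefix.{bed,bim,fam}`` into a Cohort.

    The ``.bed`` must be SNP-major (third header byte 0x01); each SNP
    occupies ``ceil(n_samples / 4)`` bytes of 2-bit genotype codes.
    """
    prefix = Path(path_prefix)
    bed, bim, fam = (_with_ext(prefix, s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(f"missing companion file: {p}")

    samples = _read_fam(fam)
    snps = _read_bim(bim)

    raw = bed.read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes {raw[:2]!r}")
    if len(raw) < 3 or raw[2] != _BED_SNP_MAJOR:
        raise FormatError(f"{bed}: mode byte must be 0x01 (SNP-major)")

    n, m = len(samples), len(snps)
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * m:
        raise FormatError(
            f"{bed}: expected {bytes_per_snp * m} payload bytes for "
            f"{n} samples x {m} SNPs, found {payload.size}"
        )

    if m == 0 or n == 0:
        genotypes = np.empty((n, m), dtype=np.int8)
    else:
        blocks = payload.reshape(m, bytes_per_snp)
        shifts = np.arange(4, dtype=np.uint8) * 2
        two_bit = (blocks[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
        codes = _DECODE[two_bit.reshape(m, -1)[:, :n]]
        genotypes = np.ascontiguousarray(codes.T)

    return Cohort(samples=samples, snps=snps, genotypes=genotypes)


def write_bed(cohort: Cohort, path_prefix: str | Path) -> None:
    """Write ``prefix.{bed,bim,fam}``; ``read_bed`` round-trips bit-exactly.

    A male heterozygote call is written as-is but logged: hemizygous males
    cannot be heterozygous, so such calls indicate an upstream calling
    error that QC (not I/O) is responsible for removing.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    male_hets = (cohort.genotypes[cohort.is_male, :] == 1).sum()
    if male_hets:
        logger.warning(
            "writing %d male heterozygote call(s); run QC male-het sanitation",
            male_hets,
        )

    _write_fam(cohort.samples, _with_ext(prefix, ".fam"))
    _write_bim(cohort.snps, _with_ext(prefix, ".bim"))

    n, m = cohort.n_samples, cohort.n_snps
    bytes_per_snp = (n + 3) // 4
    out = bytearray(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
    if n and m:
        enc = np.zeros(cohort.genotypes.shape, dtype=np.uint8)
        for code, bits in _ENCODE.items():
            enc[cohort.genotypes == code] = bits
        padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)  # zero-bit padding
        padded[:, :n] = enc.T
        quads = padded.reshape(m, bytes_per_snp, 4)
        shifts = np.arange(4, dtype=np.uint8) * 2
        packed = (quads << shifts).sum(axis=2, dtype=np.uint16).astype(np.uint8)
        out += packed.tobytes()
    elif m:
        out += bytes(bytes_per_snp * m)
    _with_ext(prefix, ".bed").write_bytes(bytes(out))


def _read_fam(path: Path) -> list[SampleRecord]:
    samples = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        fid, iid, pat, mat, sex, pheno = line.split()[:6]
        samples.append(
            SampleRecord(
                family_id=fid,
                sample_id=iid,
                paternal_id=pat,
                maternal_id=mat,
                sex=int(sex),
                phenotype=int(pheno),
            )
        )
    return samples


def _write_fam(samples: Sequence[SampleRecord], path: Path) -> None:
    with path.open("w") as fh:
        for s in samples:
            fh.write(
                f"{s.family_id}\t{s.sample_id}\t{s.paternal_id}\t{s.maternal_id}"
                f"\t{s.sex}\t{s.phenotype}\n"
            )


def _read_bim(path: Path) -> list[SnpRecord]:
    snps = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        chrom, snp_id, dist, bp, a1, a2 = line.split()[:6]
        snps.append(
            SnpRecord(
                chromosome=_chrom_code(chrom),
                snp_id=snp_id,
                genetic_distance=float(dist),
                bp_position=int(bp),
                allele1=a1,
                allele2=a2,
            )
        )
    return snps


def _write_bim(snps: Sequence[SnpRecord], path: Path) -> None:
    with path.open("w") as fh:
        for s in snps:
            dist = int(s.genetic_distance) if s.genetic_distance == 0 else s.genetic_distance
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t{dist}\t{s.bp_position}"
                f"\t{s.allele1}\t{s.allele2}\n"
            )


# ---------------------------------------------------------------------------
# PLINK text fileset
# ---------------------------------------------------------------------------


def write_pedmap(cohort: Cohort, path_prefix: str | Path) -> None:
    """Write the whitespace-delimited ``.ped``/``.map`` text fileset.

    Each genotype becomes two allele characters ("0 0" for missing);
    males are written with their hemizygous allele doubled, the PLINK
    text convention for X markers.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with _with_ext(prefix, ".map").open("w") as fh:
        for s in cohort.snps:
            dist = int(s.genetic_distance) if s.genetic_distance == 0 else s.genetic_distance
            fh.write(f"{s.chromosome}\t{s.snp_id}\t{dist}\t{s.bp_position}\n")
    with _with_ext(prefix, ".ped").open("w") as fh:
        for i, s in enumerate(cohort.samples):
            fields = [
                s.family_id,
                s.sample_id,
                s.paternal_id,
                s.maternal_id,
                str(s.sex),
                str(s.phenotype),
            ]
            for j, snp in enumerate(cohort.snps):
                g = cohort.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [snp.allele1, snp.allele1]
                elif g == 1:
                    fields += [snp.allele1, snp.allele2]
                else:
                    fields += [snp.allele2, snp.allele2]
            fh.write("\t".join(fields) + "\n")


def read_pedmap(path_prefix: str | Path) -> Cohort:
    """Read a ``.ped``/``.map`` text fileset.

    The text dialect does not record which allele is counted, so A1 is
    re-derived as the minor allele over all genotyped samples (females
    contributing two alleles, males one; frequency ties broken
    alphabetically).  Round trips through the binary representation are
    lossless up to this per-SNP allele orientation.
    """
    prefix = Path(path_prefix)
    map_path, ped_path = _with_ext(prefix, ".map"), _with_ext(prefix, ".ped")
    for p in (map_path, ped_path):
        if not p.exists():
            raise FileNotFoundError(f"missing companion file: {p}")

    map_rows = []
    for line in map_path.read_text().splitlines():
        if not line.strip():
            continue
        chrom, snp_id, dist, bp = line.split()[:4]
        map_rows.append((_chrom_code(chrom), snp_id, float(dist), int(bp)))
    m = len(map_rows)

    samples: list[SampleRecord] = []
    allele_rows: list[list[str]] = []
    for line in ped_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f"{ped_path}: expected {6 + 2 * m} columns, found {len(parts)}"
            )
        fid, iid, pat, mat, sex, pheno = parts[:6]
        samples.append(
            SampleRecord(fid, iid, pat, mat, sex=int(sex), phenotype=int(pheno))
        )
        alleles = parts[6:]
        bad = set(alleles) - VALID_ALLELES - {"0"}
        if bad:
            raise FormatError(f"{ped_path}: invalid allele characters {sorted(bad)}")
        allele_rows.append(alleles)

    n = len(samples)
    genotypes = np.full((n, m), MISSING, dtype=np.int8)
    snps: list[SnpRecord] = []
    for j, (chrom, snp_id, dist, bp) in enumerate(map_rows):
        counts: Counter[str] = Counter()
        for i, row in enumerate(allele_rows):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            if samples[i].sex == MALE:
                counts[a] += 1  # hemizygous: one allele copy
            else:
                counts[a] += 1
                counts[b] += 1
        a1, a2 = _orient_alleles(counts)
        snps.append(
            SnpRecord(
                chromosome=chrom,
                snp_id=snp_id,
                genetic_distance=dist,
                bp_position=bp,
                allele1=a1,
                allele2=a2,
            )
        )
        for i, row in enumerate(allele_rows):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            genotypes[i, j] = (a == a1) + (b == a1)

    return Cohort(samples=samples, snps=snps, genotypes=genotypes)


def _orient_alleles(counts: Counter[str]) -> tuple[str, str]:
    """(A1, A2) = (minor, major); frequency ties broken alphabetically.

    A SNP with fewer than two observed alleles gets the placeholder "0"
    for the unobserved minor allele (the PLINK convention); a column with
    no calls at all gets ("0", "N") so the record stays well-formed.
    """
    observed = sorted(counts)
    if not observed:
        return "0", "N"
    if len(observed) == 1:
        return "0", observed[0]
    if len(observed) > 2:
        raise FormatError(f"more than two alleles observed: {observed}")
    a, b = observed  # alphabetical
    if counts[a] == counts[b]:
        return a, b
    return (a, b) if counts[a] < counts[b] else (b, a)


# ---------------------------------------------------------------------------
# Long-format array-genotyping export
# ---------------------------------------------------------------------------


def _parse_call(call: str) -> tuple[str, ...] | None:
    """Split a genotype-call token into allele characters; None = no call."""
    token = call.strip().upper()
    if token in UNDETERMINED_TOKENS:
        return None
    alleles = tuple(token.split("/")) if "/" in token else tuple(token)
    if not all(a in VALID_ALLELES for a in alleles) or len(alleles) not in (1, 2):
        raise FormatError(f"unparseable genotype call: {call!r}")
    return alleles


def long_to_wide(
    records: Iterable[tuple[str, str, str]],
    sexes: Mapping[str, int] | None = None,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> Cohort:
    """Pivot a long-format call export into a sample-by-SNP Cohort.

    ``records`` holds (snp_reference, sample_id, genotype_call) rows in
    any order; duplicates with identical calls are tolerated, conflicting
    duplicates are an error.  Calls are two-allele ("A/G"), single-allele
    hemizygous ("A"), or an undetermined token (-> missing).  Sample and
    SNP order in the result is sorted for input-order invariance.

    ``sexes`` maps sample id to 1/2; samples absent from the map (or when
    no map is given) are inferred male if any of their calls is
    single-allele, female otherwise.  ``alleles`` optionally fixes
    (A1, A2) per SNP; otherwise A1 is the minor allele by weighted count
    (ties alphabetical).
    """
    calls: dict[tuple[str, str], tuple[str, ...] | None] = {}
    for snp_ref, sample_id, call in records:
        parsed = _parse_call(call)
        key = (sample_id, snp_ref)
        if key in calls and calls[key] != parsed:
            raise FormatError(
                f"conflicting duplicate records for sample {sample_id!r} "
                f"at {snp_ref!r}"
            )
        calls[key] = parsed

    sample_ids = sorted({k[0] for k in calls})
    snp_ids = sorted({k[1] for k in calls})

    sex_of: dict[str, int] = {}
    for sid in sample_ids:
        if sexes is not None and sid in sexes:
            sex_of[sid] = sexes[sid]
        else:
            hemi = any(
                calls.get((sid, snp)) is not None
                and len(calls[(sid, snp)]) == 1  # type: ignore[arg-type]
                for snp in snp_ids
            )
            sex_of[sid] = MALE if hemi else FEMALE

    snps: list[SnpRecord] = []
    n, m = len(sample_ids), len(snp_ids)
    genotypes = np.full((n, m), MISSING, dtype=np.int8)
    for j, snp in enumerate(snp_ids):
        if alleles is not None and snp in alleles:
            a1, a2 = alleles[snp]
        else:
            counts: Counter[str] = Counter()
            for sid in sample_ids:
                parsed = calls.get((sid, snp))
                if parsed is None:
                    continue
                if sex_of[sid] == MALE:
                    counts[parsed[0]] += 1
                else:
                    pair = parsed if len(parsed) == 2 else parsed * 2
                    counts[pair[0]] += 1
                    counts[pair[1]] += 1
            a1, a2 = _orient_alleles(counts)
        snps.append(
            SnpRecord(
                chromosome=X_CODE,
                snp_id=snp,
                bp_position=j + 1,
                allele1=a1,
                allele2=a2,
            )
        )
        for i, sid in enumerate(sample_ids):
            parsed = calls.get((sid, snp))
            if parsed is None:
                continue
            pair = parsed if len(parsed) == 2 else parsed * 2
            genotypes[i, j] = sum(a == a1 for a in pair)

    samples = [
        SampleRecord(family_id=sid, sample_id=sid, sex=sex_of[sid])
        for sid in sample_ids
    ]
    return Cohort(samples=samples, snps=snps, genotypes=genotypes)


def read_long_export(path: str | Path) -> Cohort:
    """Read a 3-column long-format export file (delimiter auto-detected)."""
    path = Path(path)
    text = path.read_text()
    dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t")
    rows = list(csv.reader(text.splitlines(), dialect))
    header = [h.strip().lower() for h in rows[0]]
    if "genotype_call" in header or "sample_id" in header:
        rows = rows[1:]
    return long_to_wide([(r[0], r[1], r[2]) for r in rows if r])


# ---------------------------------------------------------------------------
# Dosage export
# ---------------------------------------------------------------------------


def export_dosage(cohort: Cohort, xci_model: str = "inactivation") -> pd.DataFrame:
    """Numeric A1 dosages per sample and SNP under an XCI model.

    Females are always 0/1/2.  Hemizygous males carry 0 or 1 allele copy:
    under ``"escape"`` (both female X copies expressed) they are coded
    0/1; under ``"inactivation"`` (one female copy silenced, so a male
    allele is dose-equivalent to a female homozygote) they are coded 0/2.
    Missing genotypes propagate as NaN.
    """
    if xci_model not in ("inactivation", "escape"):
        raise ValueError(f"unknown xci_model: {xci_model!r}")
    male_hets = (cohort.genotypes[cohort.is_male, :] == 1).sum()
    if male_hets:
        raise ValueError(
            f"{male_hets} male heterozygote call(s) present; sanitize with "
            "qc.male_het_scan before exporting dosages"
        )
    dosage = cohort.genotypes.astype(float)
    dosage[cohort.genotypes == MISSING] = np.nan
    if xci_model == "escape":
        male = cohort.is_male[:, None] & (cohort.genotypes == 2)
        dosage[male] = 1.0
    return pd.DataFrame(dosage, index=cohort.sample_ids, columns=cohort.snp_ids)
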