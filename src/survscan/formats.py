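"""Readers for Oxford GEN genotype files, VCF, and Oxford-style sample files.

GEN dialect: whitespace-delimited lines with five leading metadata columns
(snp_id, rs_id, position, allele_a, allele_b) followed by one probability
triple (P(0 copies), P(1 copy), P(2 copies) of allele_b) per subject.  The
chromosome is not a file column; it is supplied by the caller (the ``-chr``
flag) and attached to every record.

Sample dialect: whitespace-delimited header naming each column, an optional
SNPTEST-style type-code row (all tokens in {0, D, C, B, P}) which is detected
and skipped, then one row per subject.  The literal token ``NA`` marks a
missing value.

Compressed inputs (.gz, .zip) are decompressed transparently; detection is by
magic bytes first, file extension second.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import zipfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

# Probability-triple cleanup thresholds: triples whose sum falls below
# RENORM_MIN indicate an imputation shortfall too large to rescale, so the
# subject is treated as missing at that SNP; anything else with a positive
# sum is renormalised to sum to one.
RENORM_MIN = 0.9

#: tokens of an Oxford sample-file type-code row
_TYPE_CODES = {"0", "D", "C", "B", "P"}


@dataclass
class GenotypeRecord:
    """One biallelic variant with per-subject genotype evidence.

    ``probs`` is an (n_subjects, 3) array of probabilities of carrying
    0/1/2 copies of ``allele_b``; for ``source_kind == "dosages"`` it is
    absent and ``dosages`` holds the expected allele-b count directly.
    ``subject_missing`` flags subjects with no usable genotype at this site.
    """

    snp_id: str
    rs_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str
    source_kind: str = "probabilities"  # probabilities | dosages | hard_calls
    probs: np.ndarray | None = None
    dosages: np.ndarray | None = None
    subject_missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_subjects
        if self.subject_missing is None:
            self.subject_missing = np.zeros(n, dtype=bool)

    @property
    def n_subjects(self) -> int:
        if self.probs is not None:
            return self.probs.shape[0]
        return len(self.dosages)

    def subset(self, index: np.ndarray) -> "GenotypeRecord":
        """Restrict the record to the given subject indices (order kept)."""
        return GenotypeRecord(
            snp_id=self.snp_id,
            rs_id=self.rs_id,
            chromosome=self.chromosome,
            position_bp=self.position_bp,
            allele_a=self.allele_a,
            allele_b=self.allele_b,
            source_kind=self.source_kind,
            probs=None if self.probs is None else self.probs[index],
            dosages=None if self.dosages is None else self.dosages[index],
            subject_missing=self.subject_missing[index],
        )


@dataclass
class PhenotypeTable:
    """Per-subject survival time, event indicator and covariates.

    ``time`` and ``event`` use NaN for missing; covariate columns likewise.
    Subjects stay in file order throughout.
    """

    subject_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def missing_mask(self, used_covariates: Sequence[str]) -> np.ndarray:
        """True where time, event or any *used* covariate is missing."""
        mask = np.isnan(self.time) | np.isnan(self.event)
        for name in used_covariates:
            mask |= np.isnan(self.covariates[name].to_numpy())
        return mask


# ---------------------------------------------------------------------------
# genotype line streams


def open_genotype_stream(path: str | os.PathLike, compression: str = "auto") -> Iterator[str]:
    """Yield decoded text lines from a plain, gzip or zip genotype file.

    ``compression`` is one of ``auto``/``none``/``gzip``/``zip``; ``auto``
    sniffs magic bytes and falls back to the file extension.  Lines are
    yielded lazily so arbitrarily large files stream in constant memory.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"genotype file not found: {path}")
    if compression == "auto":
        compression = _sniff_compression(path)
    try:
        if compression == "gzip":
            fh: io.TextIOBase = gzip.open(path, "rt")
        elif compression == "zip":
            zf = zipfile.ZipFile(path)
            names = zf.namelist()
            if not names:
                raise DataError(f"zip archive is empty: {path}")
            fh = io.TextIOWrapper(zf.open(names[0]))
        else:
            fh = open(path, "rt")
        with fh:
            for line in fh:
                yield line.rstrip("\n")
    except (OSError, zipfile.BadZipFile, gzip.BadGzipFile, EOFError) as exc:
        raise DataError(f"cannot read genotype file {path}: {exc}") from exc


def _sniff_compression(path: str) -> str:
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] == b"\x1f\x8b":
        return "gzip"
    if magic == b"PK\x03\x04":
        return "zip"
    if path.endswith(".gz"):
        return "gzip"
    if path.endswith(".zip"):
        return "zip"
    return "none"


def clean_prob_triples(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Validate and renormalise an (n, 3) probability array.

    Returns the cleaned array and a per-subject missing flag.  A subject is
    missing when the triple contains NaN or a negative entry, or when the sum
    falls below ``RENORM_MIN`` (IMPUTE emits a shortfall for uncertain
    imputation).  All other triples are rescaled to sum to exactly one.
    """
    probs = np.asarray(probs, dtype=float)
    sums = probs.sum(axis=1)
    missing = ~np.isfinite(sums) | (probs < 0).any(axis=1) | (sums < RENORM_MIN)
    ok = ~missing
    cleaned = probs.copy()
    cleaned[ok] /= sums[ok, None]
    cleaned[missing] = np.nan
    return cleaned, missing


def read_gen_records(
    stream: Iterable[str],
    n_subjects: int,
    line_start: int = 0,
    line_stop: int | None = None,
    bp_start: int | None = None,
    bp_stop: int | None = None,
    chromosome_label: str = "NA",
) -> Iterator[GenotypeRecord]:
    """Parse GEN lines within a 0-based inclusive line range into records.

    ``line_start``/``line_stop`` select lines [line_start, line_stop] of the
    file (both inclusive); the optional base-pair window [bp_start, bp_stop]
    (1-based, inclusive) is applied on top of the line range.
    """
    expected = 5 + 3 * n_subjects
    for lineno, line in enumerate(stream):
        if lineno < line_start:
            continue
        if line_stop is not None and lineno > line_stop:
            break
        fields = line.split()
        if not fields:
            continue
        if len(fields) != expected:
            raise DataError(
                f"genotype line {lineno}: expected {expected} fields "
                f"(5 + 3x{n_subjects} subjects), found {len(fields)}"
            )
        snp_id, rs_id, pos_s, allele_a, allele_b = fields[:5]
        try:
            position = int(pos_s)
        except ValueError as exc:
            raise DataError(f"genotype line {lineno}: bad position {pos_s!r}") from exc
        if bp_start is not None and position < bp_start:
            continue
        if bp_stop is not None and position > bp_stop:
            continue
        try:
            raw = np.array(fields[5:], dtype=float).reshape(n_subjects, 3)
        except ValueError as exc:
            raise DataError(
                f"genotype line {lineno} ({snp_id}): non-numeric probability"
            ) from exc
        probs, missing = clean_prob_triples(raw)
        yield GenotypeRecord(
            snp_id=snp_id,
            rs_id=rs_id,
            chromosome=chromosome_label,
            position_bp=position,
            allele_a=allele_a,
            allele_b=allele_b,
            source_kind="probabilities",
            probs=probs,
            subject_missing=missing,
        )


def write_gen(records: Iterable[GenotypeRecord], path: str | os.PathLike) -> None:
    """Write probability records in the GEN dialect (6-decimal probabilities)."""
    with open(path, "wt") as fh:
        for rec in records:
            if rec.probs is None:
                raise DataError(f"{rec.snp_id}: only probability records can be written as GEN")
            probs = np.nan_to_num(rec.probs, nan=0.0)
            body = " ".join(f"{p:.6f}" for p in probs.ravel())
            fh.write(
                f"{rec.snp_id} {rec.rs_id} {rec.position_bp} "
                f"{rec.allele_a} {rec.allele_b} {body}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def read_vcf_records(
    path: str | os.PathLike,
    line_start: int = 0,
    line_stop: int | None = None,
    bp_start: int | None = None,
    bp_stop: int | None = None,
) -> Iterator[GenotypeRecord]:
    """Yield records from a VCF, extracting genotype evidence as GP > DS > GT.

    GP triples become probability records with allele_b = ALT; DS becomes a
    dosage record; GT hard calls become degenerate 0/1 triples.  Multiallelic
    sites and sites with no usable genotype field are skipped with a warning.
    The line range indexes variant sites (0-based, inclusive), mirroring the
    GEN reader.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"VCF file not found: {path}")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise DataError(f"cannot read VCF {path}: {exc}") from exc
    for siteno, var in enumerate(vcf):
        if siteno < line_start:
            continue
        if line_stop is not None and siteno > line_stop:
            break
        if bp_start is not None and var.POS < bp_start:
            continue
        if bp_stop is not None and var.POS > bp_stop:
            continue
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s at %s:%d", var.ID, var.CHROM, var.POS)
            continue
        rec = _vcf_site_to_record(var)
        if rec is None:
            logger.warning(
                "skipping site %s at %s:%d: no GP, DS or GT genotype field",
                var.ID, var.CHROM, var.POS,
            )
            continue
        yield rec


def _vcf_site_to_record(var) -> GenotypeRecord | None:
    ident = var.ID or f"{var.CHROM}:{var.POS}"
    meta = dict(
        snp_id=ident,
        rs_id=ident,
        chromosome=str(var.CHROM),
        position_bp=int(var.POS),
        allele_a=var.REF,
        allele_b=var.ALT[0],
    )
    gp = _format_field(var, "GP")
    if gp is not None and gp.shape[1] >= 3:
        probs, missing = clean_prob_triples(gp[:, :3])
        return GenotypeRecord(source_kind="probabilities", probs=probs,
                              subject_missing=missing, **meta)
    ds = _format_field(var, "DS")
    if ds is not None:
        values = ds[:, 0].astype(float)
        missing = ~np.isfinite(values)
        return GenotypeRecord(source_kind="dosages", dosages=values,
                              subject_missing=missing, **meta)
    gts = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
    if gts is not None and len(gts):
        gts = np.asarray(gts)
        n = len(gts)
        probs = np.zeros((n, 3))
        probs[gts == 0, 0] = 1.0
        probs[gts == 1, 1] = 1.0
        probs[gts == 3, 2] = 1.0
        missing = gts == 2
        probs[missing] = np.nan
        return GenotypeRecord(source_kind="hard_calls", probs=probs,
                              subject_missing=missing, **meta)
    return None


def _format_field(var, key: str) -> np.ndarray | None:
    try:
        arr = var.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    # cyvcf2 encodes per-sample missing values as large negatives or NaN
    arr[arr < -1e6] = np.nan
    return arr


# ---------------------------------------------------------------------------
# sample file


def read_sample_file(
    path: str | os.PathLike,
    time_name: str,
    censor_name: str,
    covariate_names: Sequence[str] = (),
) -> PhenotypeTable:
    """Read an Oxford-style sample file into a :class:`PhenotypeTable`.

    The header row must contain ``time_name``, ``censor_name`` and every
    requested covariate; a missing name is fatal and the error lists the
    headers that are available.  An optional type-code second row is
    auto-detected and skipped.  ``NA`` tokens become missing values.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"sample file not found: {path}")
    with open(path) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows:
        raise DataError(f"sample file is empty: {path}")
    header = rows[0]
    if len(set(header)) != len(header):
        raise DataError(f"sample file {path}: duplicate column names in header")
    body = rows[1:]
    if body and all(tok.upper() in _TYPE_CODES for tok in body[0]):
        body = body[1:]  # SNPTEST type-code row
    for row_i, row in enumerate(body):
        if len(row) != len(header):
            raise DataError(
                f"sample file {path}: row {row_i + 1} has {len(row)} fields, "
                f"header has {len(header)}"
            )
    frame = pd.DataFrame(body, columns=header, dtype=str)

    requested = [time_name, censor_name, *covariate_names]
    missing_cols = [name for name in requested if name not in header]
    if missing_cols:
        raise DataError(
            f"column(s) {missing_cols} not found in sample file header; "
            f"available columns: {header}"
        )

    time = _numeric_column(frame, time_name, path)
    event = _numeric_column(frame, censor_name, path)
    bad_time = time[np.isfinite(time)] < 0
    if bad_time.any():
        raise DataError(f"sample file {path}: negative survival time in '{time_name}'")
    finite_ev = event[np.isfinite(event)]
    if not np.isin(finite_ev, (0.0, 1.0)).all():
        raise DataError(
            f"sample file {path}: censoring indicator '{censor_name}' must be 0/1 or NA"
        )
    covs = pd.DataFrame(
        {name: _numeric_column(frame, name, path) for name in covariate_names}
    )
    return PhenotypeTable(
        subject_ids=frame.iloc[:, 0].tolist(),
        time=time,
        event=event,
        covariates=covs,
    )


def _numeric_column(frame: pd.DataFrame, name: str, path: str) -> np.ndarray:
    col = frame[name].replace("NA", np.nan)
    try:
        return col.astype(float).to_numpy()
    except ValueError as exc:
        raise DataError(
            f"sample file {path}: column '{name}' contains non-numeric values; "
            "categorical factors must be recoded as binary (0/1) columns"
        ) from exc
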