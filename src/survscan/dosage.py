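"""Dosage conversion, allele-frequency / imputation-quality QC, case alignment.

The additive dosage for subject i is S_i = p_i1 + 2*p_i2, the expected count
of the effect allele.  The effect allele is oriented to the empirical minor
allele: when the mean dosage over non-missing subjects exceeds 1 (allele
frequency > 0.5) the vector is flipped (S' = 2 - S) and the allele labels
swapped.  Imputation quality is summarised by the IMPUTE info measure,

    info = 1 - sum(f_i - e_i^2) / (2N * theta * (1 - theta)),

with e_i = p_i1 + 2 p_i2, f_i = p_i1 + 4 p_i2 and theta = sum(e_i) / 2N; it
equals 1 for fully certain genotypes and is not clamped below (a negative
value is a diagnostic, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, FitError
from .formats import GenotypeRecord, PhenotypeTable


@dataclass
class DosageVector:
    """Per-subject expected effect-allele count in [0, 2]."""

    values: np.ndarray
    effect_allele: str
    noneffect_allele: str
    subject_missing: np.ndarray
    flipped: bool = False

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def flip(self) -> "DosageVector":
        """Swap effect/non-effect alleles; S' = 2 - S. An involution."""
        values = self.values.copy()
        ok = ~self.subject_missing
        values[ok] = 2.0 - values[ok]
        return DosageVector(
            values=values,
            effect_allele=self.noneffect_allele,
            noneffect_allele=self.effect_allele,
            subject_missing=self.subject_missing,
            flipped=not self.flipped,
        )


@dataclass
class SnpQc:
    """Allele frequencies and imputation quality for one variant.

    ``eaf`` is the frequency of the most common allele, ``maf = 1 - eaf``;
    ``info`` is NaN for dosage-only input (the triple-based formula does not
    apply).
    """

    eaf: float
    maf: float
    info: float
    n_used: int


@dataclass
class AnalysisDataset:
    """Complete-case design inputs for one SNP."""

    dosage: np.ndarray
    covariate_matrix: np.ndarray
    covariate_names: list[str]
    time: np.ndarray
    event: np.ndarray
    dropped_subjects: list[str] = field(default_factory=list)

    @property
    def n_used(self) -> int:
        return len(self.time)


def compute_dosage(record: GenotypeRecord) -> DosageVector:
    """Convert a genotype record to an additive dosage for the minor allele.

    Probability triples give S_i = p_i1 + 2 p_i2 against allele_b; dosage
    records pass through.  If the allele-b frequency among non-missing
    subjects exceeds 0.5 the vector is flipped so the effect allele is the
    empirical minor allele (ties at exactly 0.5 are not flipped).
    """
    if record.source_kind == "dosages":
        values = record.dosages.astype(float).copy()
    else:
        p = record.probs
        values = p[:, 1] + 2.0 * p[:, 2]
    missing = record.subject_missing.copy()
    values[missing] = np.nan
    dv = DosageVector(
        values=values,
        effect_allele=record.allele_b,
        noneffect_allele=record.allele_a,
        subject_missing=missing,
    )
    ok = ~missing
    if ok.any() and values[ok].mean() / 2.0 > 0.5:
        dv = dv.flip()
    return dv


def compute_qc(dosage: DosageVector, record: GenotypeRecord) -> SnpQc:
    """Allele frequencies and IMPUTE info for the subjects in ``dosage``.

    Frequencies always refer to the record's allele_b axis via theta =
    mean(e)/2; maf = min(theta, 1-theta) and eaf = 1 - maf.  info is
    computed from the probability triples (flip-invariant) and reported as
    NaN for dosage-only records; monomorphic sites get info = 1.
    """
    ok = ~dosage.subject_missing
    n = int(ok.sum())
    if n == 0:
        raise FitError("no usable subjects for QC")
    if record.source_kind == "dosages":
        theta = float(record.dosages[ok].mean()) / 2.0
        info = np.nan
    else:
        p = record.probs[ok]
        e = p[:, 1] + 2.0 * p[:, 2]
        f = p[:, 1] + 4.0 * p[:, 2]
        theta = float(e.sum()) / (2.0 * n)
        if theta <= 0.0 or theta >= 1.0:
            info = 1.0
        else:
            info = 1.0 - float((f - e**2).sum()) / (2.0 * n * theta * (1.0 - theta))
    maf = min(theta, 1.0 - theta)
    return SnpQc(eaf=1.0 - maf, maf=maf, info=info, n_used=n)


def align_complete_cases(
    dosage: DosageVector,
    phen: PhenotypeTable,
    used_covariates: Sequence[str] = (),
) -> AnalysisDataset:
    """Listwise-delete subjects missing time, event, a used covariate or genotype.

    Survivor order is preserved; removed subjects are named in
    ``dropped_subjects``.  Zero remaining rows raises :class:`FitError`
    (handled per SNP by the scan, never fatal).
    """
    if dosage.n_subjects != phen.n_subjects:
        raise DataError(
            f"genotype file has {dosage.n_subjects} subjects but sample file "
            f"has {phen.n_subjects}"
        )
    drop = phen.missing_mask(used_covariates) | dosage.subject_missing
    keep = ~drop
    if not keep.any():
        raise FitError("no complete cases remain after removing missing values")
    cov = phen.covariates[list(used_covariates)].to_numpy(dtype=float)
    return AnalysisDataset(
        dosage=dosage.values[keep],
        covariate_matrix=cov[keep] if len(used_covariates) else np.empty((int(keep.sum()), 0)),
        covariate_names=list(used_covariates),
        time=phen.time[keep],
        event=phen.event[keep],
        dropped_subjects=[sid for sid, d in zip(phen.subject_ids, drop) if d],
    )
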