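"""Per-SNP scan orchestration: design building, model dispatch, output table.

For each variant the pipeline is

    compute_dosage -> align_complete_cases -> compute_qc -> build_design
    -> fit (Cox or Weibull) -> per-coefficient tests -> overall LRT

and one output row is written per fitted coefficient (plus intercept and
shape rows for the Weibull model).  Any per-SNP failure — no events after
alignment, a monomorphic dosage, non-convergence, singular information —
produces a single NA row carrying a reason code in the ``note`` column; the
scan itself never aborts on a per-SNP failure.

Output is a tab-delimited text table with a fixed header.  Estimates carry
6 significant digits, p-values are printed in scientific notation and
missing entries render as ``NA``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import numpy as np

from . import models
from .dosage import AnalysisDataset, align_complete_cases, compute_dosage, compute_qc
from .errors import FitError, UsageError
from .formats import GenotypeRecord, PhenotypeTable

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = [
    "variable", "rs_id", "chr", "pos", "effect_allele", "noneffect_allele",
    "coef", "HR", "SE", "ci_low", "ci_high", "p", "lrt_stat", "lrt_p",
    "EAF", "MAF", "info", "n", "note",
]


@dataclass
class ModelSpec:
    """What to fit at every SNP and which rows to print."""

    method: str  # "cox" | "weibull"
    covariate_names: list[str] = field(default_factory=list)
    interaction_names: list[str] = field(default_factory=list)
    print_mode: str = "all"  # all | onlysnp | onlyint

    def __post_init__(self) -> None:
        if self.method not in ("cox", "weibull"):
            raise UsageError(f"unknown method {self.method!r}; choose 'cox' or 'weibull'")
        if self.print_mode not in ("all", "onlysnp", "onlyint"):
            raise UsageError(
                f"unknown print mode {self.print_mode!r}; choose 'all', 'onlysnp' or 'onlyint'"
            )
        extra = [n for n in self.interaction_names if n not in self.covariate_names]
        if extra:
            raise UsageError(
                f"interaction covariate(s) {extra} are not in the covariate list"
            )


@dataclass
class AssociationRow:
    """One output line: a coefficient (or failure placeholder) at one SNP."""

    variable: str
    rs_id: str
    chromosome: str
    position_bp: int
    effect_allele: str
    noneffect_allele: str
    coefficient: float = np.nan
    hazard_ratio: float = np.nan
    standard_error: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    lrt_statistic: float = np.nan
    lrt_p: float = np.nan
    eaf: float = np.nan
    maf: float = np.nan
    info: float = np.nan
    n_used: int = 0
    note: str = ""
    role: str = "other"  # snp | covariate | interaction | intercept | shape | other


@dataclass
class ScanSummary:
    n_analysed: int = 0
    n_failed: int = 0


def build_design(dosage: np.ndarray, covariates: np.ndarray,
                 covariate_names: list[str],
                 spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix [SNP dosage | covariates | SNP x covariate interactions].

    Interaction column j is the elementwise product of the dosage with the
    j-th requested interaction covariate; names are "SNP", the covariate
    names, then "SNPx<name>".
    """
    cols = [np.asarray(dosage, float)]
    names = ["SNP"]
    for j, name in enumerate(covariate_names):
        cols.append(covariates[:, j])
        names.append(name)
    for name in spec.interaction_names:
        j = covariate_names.index(name)
        cols.append(cols[0] * covariates[:, j])
        names.append(f"SNPx{name}")
    return np.column_stack(cols), names


def analyse_snp(record: GenotypeRecord, phen: PhenotypeTable,
                spec: ModelSpec) -> list[AssociationRow]:
    """Run the full per-SNP pipeline and return its output rows."""
    base = dict(
        rs_id=record.rs_id,
        chromosome=record.chromosome,
        position_bp=record.position_bp,
        effect_allele=record.allele_b,
        noneffect_allele=record.allele_a,
    )

    # complete cases first so allele orientation and frequencies refer to
    # the analysed subjects
    raw = compute_dosage(record)
    try:
        aligned = align_complete_cases(raw, phen, spec.covariate_names)
    except FitError as exc:
        return [_failure_row(record, base, str(exc))]
    keep = ~(phen.missing_mask(spec.covariate_names) | record.subject_missing)
    sub_record = record.subset(np.flatnonzero(keep))
    dosage = compute_dosage(sub_record)
    qc = compute_qc(dosage, sub_record)
    base.update(
        effect_allele=dosage.effect_allele,
        noneffect_allele=dosage.noneffect_allele,
        eaf=qc.eaf, maf=qc.maf, info=qc.info, n_used=aligned.n_used,
    )
    data = AnalysisDataset(
        dosage=dosage.values,
        covariate_matrix=aligned.covariate_matrix,
        covariate_names=aligned.covariate_names,
        time=aligned.time,
        event=aligned.event,
        dropped_subjects=aligned.dropped_subjects,
    )
    if np.ptp(data.dosage) == 0:
        return [_failure_row(record, base, "monomorphic in analysed subjects")]

    X, names = build_design(data.dosage, data.covariate_matrix,
                            data.covariate_names, spec)
    try:
        if spec.method == "cox":
            rows = _cox_rows(data, X, names, record, base)
        else:
            rows = _weibull_rows(data, X, names, record, base)
    except FitError as exc:
        return [_failure_row(record, base, str(exc))]
    return _filter_rows(rows, spec.print_mode)


def _failure_row(record: GenotypeRecord, base: dict, reason: str) -> AssociationRow:
    return AssociationRow(variable=record.snp_id, note=reason, role="snp", **base)


def _role(name: str) -> str:
    if name == "SNP":
        return "snp"
    if name.startswith("SNPx"):
        return "interaction"
    return "covariate"


def _cox_rows(data: AnalysisDataset, X, names, record, base) -> list[AssociationRow]:
    fit = models.fit_cox(data.time, data.event, X, names)
    lrt = models.likelihood_ratio_test(fit)
    rows = []
    for j, name in enumerate(names):
        wald = models.wald_test(fit.estimates[j], fit.standard_errors[j],
                                hazard_ratio_ci=True)
        rows.append(AssociationRow(
            variable=record.snp_id if name == "SNP" else name,
            coefficient=float(fit.estimates[j]),
            hazard_ratio=float(np.exp(fit.estimates[j])),
            standard_error=float(fit.standard_errors[j]),
            ci_low=wald.ci_low, ci_high=wald.ci_high,
            p_value=wald.p_value,
            lrt_statistic=lrt.statistic, lrt_p=lrt.p_value,
            role=_role(name),
            **base,
        ))
    return rows


def _weibull_rows(data: AnalysisDataset, X, names, record, base) -> list[AssociationRow]:
    fit = models.fit_weibull(data.time, data.event, X, names)
    lrt = models.likelihood_ratio_test(fit)
    rows = []
    for j, name in enumerate(names):
        score = models.score_test(data.time, data.event, X, [j], names)
        rows.append(AssociationRow(
            variable=record.snp_id if name == "SNP" else name,
            coefficient=float(fit.estimates[j]),
            hazard_ratio=float(np.exp(fit.estimates[j])),
            standard_error=float(fit.standard_errors[j]),
            p_value=score.p_value,
            lrt_statistic=lrt.statistic, lrt_p=lrt.p_value,
            role=_role(name),
            **base,
        ))
    # intercept and shape rows: Wald p-values (alpha = 0; log shape = 0,
    # i.e. shape test against the exponential sub-model); no hazard ratio
    intercept_wald = models.wald_test(fit.intercept, fit.intercept_se)
    rows.append(AssociationRow(
        variable="intercept",
        coefficient=fit.intercept,
        standard_error=fit.intercept_se,
        p_value=intercept_wald.p_value,
        lrt_statistic=lrt.statistic, lrt_p=lrt.p_value,
        role="intercept",
        **base,
    ))
    shape_wald = models.wald_test(fit.log_shape, fit.log_shape_se)
    rows.append(AssociationRow(
        variable="shape",
        coefficient=fit.shape,
        standard_error=fit.shape * fit.log_shape_se,  # delta method
        p_value=shape_wald.p_value,
        lrt_statistic=lrt.statistic, lrt_p=lrt.p_value,
        role="shape",
        **base,
    ))
    return rows


def _filter_rows(rows: list[AssociationRow], print_mode: str) -> list[AssociationRow]:
    if print_mode == "onlysnp":
        return [r for r in rows if r.role == "snp"]
    if print_mode == "onlyint":
        return [r for r in rows if r.role == "interaction"]
    return rows


# ---------------------------------------------------------------------------
# output writing


def _fmt(value, scientific: bool = False) -> str:
    if value is None:
        return "NA"
    if isinstance(value, str):
        return value if value else "NA"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, float) and (math.isnan(value) or math.isinf(value)):
        return "NA"
    return f"{value:.6e}" if scientific else f"{value:.6g}"


def format_row(row: AssociationRow) -> str:
    fields = [
        row.variable, row.rs_id, row.chromosome, str(row.position_bp),
        row.effect_allele, row.noneffect_allele,
        _fmt(row.coefficient), _fmt(row.hazard_ratio), _fmt(row.standard_error),
        _fmt(row.ci_low), _fmt(row.ci_high), _fmt(row.p_value, scientific=True),
        _fmt(row.lrt_statistic), _fmt(row.lrt_p, scientific=True),
        _fmt(row.eaf), _fmt(row.maf), _fmt(row.info), str(row.n_used),
        row.note if row.note else "NA",
    ]
    return "\t".join(fields)


def write_output(rows: Iterable[AssociationRow], path: str) -> None:
    """Write a complete output table (header + rows) to ``path``."""
    with open(path, "wt") as fh:
        fh.write("\t".join(OUTPUT_COLUMNS) + "\n")
        for row in rows:
            fh.write(format_row(row) + "\n")


def run_scan(records: Iterator[GenotypeRecord], phen: PhenotypeTable,
             spec: ModelSpec, output_path: str) -> ScanSummary:
    """Stream records through :func:`analyse_snp`, writing rows as they come.

    Memory use is constant in the number of SNPs.  Returns counts of SNPs
    analysed and of SNPs that produced a failure row.
    """
    summary = ScanSummary()
    try:
        fh: TextIO = open(output_path, "wt")
    except OSError as exc:
        raise FitError(f"cannot write output file {output_path}: {exc}") from exc
    with fh:
        fh.write("\t".join(OUTPUT_COLUMNS) + "\n")
        for record in records:
            rows = analyse_snp(record, phen, spec)
            failed = any(r.note for r in rows)
            if failed:
                summary.n_failed += 1
                logger.warning("SNP %s: %s", record.snp_id,
                               next(r.note for r in rows if r.note))
            summary.n_analysed += 1
            for row in rows:
                fh.write(format_row(row) + "\n")
    return summary
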