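"""Synthetic genotype and time-to-event data for testing the scan end to end.

The generator emulates a pharmacogenetic GWAS simulation design: biallelic
SNPs with independent genotypes drawn at per-SNP allele frequencies, an
exactly balanced 1:1 binary treatment assignment, and survival times from a
Weibull baseline under either a proportional-hazards (ph) or an accelerated
failure-time (aft) generative model with SNP, treatment and SNP x treatment
interaction effects.  Censoring is uniform "administrative" censoring whose
upper bound is calibrated numerically so that the expected censored fraction
matches the requested target (roughly 20% by default).

Under the PH model the linear predictor eta = b_snp*S + b_trt*Z + b_int*S*Z
multiplies the baseline hazard h0(t) = (shape/scale) * (t/scale)^(shape-1),
so event times arise by inverse-transform sampling,

    T = scale * (-log U / exp(eta))^(1/shape).

Under the AFT model log T = log(scale) - eta + (1/shape) * G with G a
standard minimum Gumbel variate; for the Weibull family the two forms
coincide when beta_aft = beta_ph / shape.

Optional imputation noise mixes each subject's one-hot genotype triple with
a random triple, mimicking the genotype uncertainty of imputed data.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import optimize

from .formats import GenotypeRecord, write_gen


@dataclass
class SimScenario:
    """Generative parameters for one synthetic dataset.

    Defaults describe the reference study conditions: 1000 patients, a
    causal SNP at minor allele frequency 0.3 with hazard ratio 2 per allele
    (log-hazard 0.693), a balanced binary treatment with no effect, a unit
    exponential baseline (shape = scale = 1) and ~20% random censoring.
    """

    n_subjects: int = 1000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_index: int = 0
    causal_maf: float = 0.3
    generative_model: str = "ph"  # ph | aft
    beta_snp: float = math.log(2.0)
    beta_treatment: float = 0.0
    beta_interaction: float = 0.0
    baseline_shape: float = 1.0
    baseline_scale: float = 1.0
    censor_fraction: float = 0.2
    imputation_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.causal_index < self.n_snps:
            raise ValueError("causal_index must lie in [0, n_snps)")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must lie in [0, 1)")
        if self.generative_model not in ("ph", "aft"):
            raise ValueError("generative_model must be 'ph' or 'aft'")


@dataclass
class SimOutput:
    gen_path: str
    sample_path: str
    truth_path: str
    truth: dict


def simulate_genotypes(scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """(n_snps, n_subjects, 3) probability triples, hard calls plus noise.

    Per SNP an allele frequency is drawn uniformly from ``maf_range`` (the
    causal SNP uses ``causal_maf``), hard genotypes are Binomial(2, freq)
    per subject, and when ``imputation_noise`` > 0 each one-hot triple is
    mixed with a random Dirichlet-like triple at that weight and
    renormalised.
    """
    n, m = scenario.n_subjects, scenario.n_snps
    freqs = rng.uniform(*scenario.maf_range, size=m)
    freqs[scenario.causal_index] = scenario.causal_maf
    counts = rng.binomial(2, freqs[:, None], size=(m, n))
    probs = np.zeros((m, n, 3))
    snp_idx = np.arange(m)[:, None]
    subj_idx = np.arange(n)[None, :]
    probs[snp_idx, subj_idx, counts] = 1.0
    w = scenario.imputation_noise
    if w > 0:
        noise = rng.random(size=(m, n, 3))
        noise /= noise.sum(axis=2, keepdims=True)
        probs = (1.0 - w) * probs + w * noise
        probs /= probs.sum(axis=2, keepdims=True)
    return probs


def simulate_treatment(n_subjects: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly balanced 1:1 binary assignment by random permutation."""
    z = np.zeros(n_subjects, dtype=int)
    z[: n_subjects // 2 + n_subjects % 2] = 1
    return rng.permutation(z)


def _linear_predictor(dosage, treatment, scenario: SimScenario) -> np.ndarray:
    return (scenario.beta_snp * dosage
            + scenario.beta_treatment * treatment
            + scenario.beta_interaction * dosage * treatment)


def simulate_survival(dosage: np.ndarray, treatment: np.ndarray,
                      scenario: SimScenario,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Event/censoring times per subject: returns (time, event).

    Event times come from the Weibull baseline under the scenario's
    generative model; censoring times are Uniform(0, c_max) with c_max
    solved so the expected censored fraction equals ``censor_fraction``.
    """
    n = len(dosage)
    eta = _linear_predictor(dosage, treatment, scenario)
    u = rng.random(n)
    shape, scale = scenario.baseline_shape, scenario.baseline_scale
    if scenario.generative_model == "ph":
        t = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)
    else:
        gumbel_min = np.log(-np.log(u))
        t = np.exp(np.log(scale) - eta + gumbel_min / shape)

    if scenario.censor_fraction == 0.0:
        return t, np.ones(n)
    c_max = _calibrate_censoring(t, scenario.censor_fraction)
    c = rng.random(n) * c_max
    event = (t <= c).astype(float)
    time = np.minimum(t, c)
    return time, event


def _calibrate_censoring(event_times: np.ndarray, target: float) -> float:
    """Upper bound of Uniform(0, c_max) censoring with expected censored
    fraction ``target`` on the realised event-time sample.

    With C ~ U(0, c_max), P(censored | T=t) = min(t / c_max, 1); the mean of
    that over the sample is monotone decreasing in c_max, so the root is
    bracketed and solved by Brent's method.
    """
    def realised(c_max: float) -> float:
        return float(np.minimum(event_times / c_max, 1.0).mean()) - target

    lo = float(event_times.min()) * 1e-6 + 1e-12
    hi = float(event_times.max()) / max(target, 1e-9) * 10.0
    if realised(hi) > 0:  # even huge bounds censor too much (should not happen)
        return hi
    return float(optimize.brentq(realised, lo, hi, xtol=1e-10, rtol=1e-12))


def simulate_dataset(scenario: SimScenario):
    """In-memory dataset: (records, treatment, time, event, truth dict)."""
    rng = np.random.default_rng(scenario.seed)
    probs = simulate_genotypes(scenario, rng)
    treatment = simulate_treatment(scenario.n_subjects, rng)
    causal = probs[scenario.causal_index]
    dosage = causal[:, 1] + 2.0 * causal[:, 2]
    time, event = simulate_survival(dosage, treatment, scenario, rng)

    records = [
        GenotypeRecord(
            snp_id=f"snp{j + 1:06d}",
            rs_id=f"rs{j + 1:06d}",
            chromosome="1",
            position_bp=(j + 1) * 1000,
            allele_a="A",
            allele_b="G",
            source_kind="probabilities",
            probs=probs[j],
        )
        for j in range(scenario.n_snps)
    ]
    truth = asdict(scenario)
    truth["causal_snp_id"] = records[scenario.causal_index].snp_id
    truth["realised_censored_fraction"] = float(1.0 - event.mean())
    return records, treatment, time, event, truth


def write_fixture(scenario: SimScenario, out_dir: str | os.PathLike) -> SimOutput:
    """Write a GEN file, a sample file and a truth sidecar to ``out_dir``.

    The sample file has columns ID, event_times, censoring, treatment —
    directly consumable by the command-line scan.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    records, treatment, time, event, truth = simulate_dataset(scenario)

    gen_path = os.path.join(out_dir, "data.gen")
    write_gen(records, gen_path)

    sample_path = os.path.join(out_dir, "data.sample")
    with open(sample_path, "wt") as fh:
        fh.write("ID event_times censoring treatment\n")
        for i in range(scenario.n_subjects):
            fh.write(f"id{i + 1:05d} {time[i]:.8g} {int(event[i])} {treatment[i]}\n")

    truth_path = os.path.join(out_dir, "truth.json")
    with open(truth_path, "wt") as fh:
        json.dump(truth, fh, indent=1)
    return SimOutput(gen_path=gen_path, sample_path=sample_path,
                     truth_path=truth_path, truth=truth)
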