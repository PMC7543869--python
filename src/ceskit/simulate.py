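"""Monte-Carlo comparison of the three survey designs on a fixed frame.

Each design is run for R independent replicates against the same
synthetic district; treatment truth stays fixed while presence and proxy
availability are re-randomized per replicate, so the summaries isolate
design (sampling) variance from population variance.  Replicate seeds are
derived from a master seed via ``numpy.random.SeedSequence`` spawned per
(design, replicate), so designs share the frame without stream collision.

Summaries report mean estimate, bias against census truth, the Monte-
Carlo SE of that bias, the empirical SD of estimates versus the mean
design-based SE, CI coverage of the truth, mean design effect and — for
the stratified LQAS design — supervisory-area misclassification rates.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import sampling_fraction
from .estimation import CoverageSurvey, UndefinedEstimateError
from .frame import SamplingFrame, true_coverage
from .lqas import LQASRule, classify_strata
from .samplers import epi_survey, pss_survey, slqas_survey

__all__ = ["SimulationSummary", "run_design", "run_comparison", "report",
           "read_report", "report_text"]

logger = logging.getLogger(__name__)

_SUMMARY_COLUMNS = [
    "design", "drug", "R", "n_failures", "true_coverage", "mean_estimate",
    "bias", "mc_se_of_mean", "empirical_sd", "mean_estimated_se",
    "ci_coverage_rate", "mean_deff", "mean_n", "classification_error_rate",
    "seed",
]


@dataclass
class SimulationSummary:
    design: str
    drug: str
    R: int
    n_failures: int
    true_coverage: float
    mean_estimate: float
    bias: float
    mc_se_of_mean: float
    empirical_sd: float
    mean_estimated_se: float
    ci_coverage_rate: float
    mean_deff: float
    mean_n: float
    classification_error_rate: float  # NaN unless slqas with a rule
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _design_seeds(master_seed: int, design_index: int, R: int) -> list[int]:
    """Deterministic per-replicate seeds: one spawned stream per design."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(design_index,))
    children = ss.spawn(R)
    return [int(c.generate_state(1, dtype=np.uint32)[0]) for c in children]


def _run_sampler(design, frame, seed, present, proxy, *, epi_quota,
                 pss_f, slqas_per_stratum):
    if design == "epi":
        return epi_survey(frame, cluster_quota=epi_quota, seed=seed,
                          present=present, proxy_available=proxy)
    if design == "slqas":
        return slqas_survey(frame, villages_per_stratum=slqas_per_stratum,
                            seed=seed, present=present, proxy_available=proxy)
    if design == "pss":
        return pss_survey(frame, f=pss_f, seed=seed, present=present,
                          proxy_available=proxy)
    raise ValueError(f"unknown design {design!r}")


def run_design(
    frame: SamplingFrame,
    design: str,
    R: int,
    seed: int,
    drug: str | None = None,
    design_index: int = 0,
    epi_quota: int = 61,
    pss_f: float | None = None,
    target_n: int = 1537,
    slqas_per_stratum: int = 19,
    lqas_rule: LQASRule | None = None,
    level: float = 0.95,
    progress_every: int = 100,
) -> SimulationSummary:
    """R replicate surveys of one design on one frame, summarized."""
    if drug is None:
        drug = frame.drugs[0]
    if pss_f is None:
        avg_hh = float(frame.hh_size.mean())
        pss_f = sampling_fraction(target_n, 30, avg_hh, 50, r=0.0)
    truth = true_coverage(frame, drug)
    sa_pops = frame.sa_populations()

    seeds = _design_seeds(seed, design_index, R)
    estimates, ses, deffs, ns, covered = [], [], [], [], []
    misclass = []
    n_failures = 0
    if lqas_rule is not None:
        ind_sa = frame.sa_id[frame.ind_psu]
        sa_truth = {
            int(sa): float(frame.treated[drug][ind_sa == sa].mean())
            for sa in np.unique(frame.sa_id)
        }
    for i, rep_seed in enumerate(seeds):
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("%s replicate %d/%d", design, i + 1, R)
        rng = np.random.default_rng(rep_seed)
        present, proxy = frame.redraw_presence(rng)
        sampler_seed = rep_seed ^ 0x5AFE
        try:
            sample = _run_sampler(design, frame, sampler_seed, present, proxy,
                                  epi_quota=epi_quota, pss_f=pss_f,
                                  slqas_per_stratum=slqas_per_stratum)
            model = CoverageSurvey(
                sample,
                stratum_weights=sa_pops if design == "slqas" else None,
            )
            est = model.fit(drugs=drug, level=level)[drug]
        except (UndefinedEstimateError, ValueError) as exc:
            n_failures += 1
            logger.warning("%s replicate %d failed: %s", design, i, exc)
            continue
        estimates.append(est.p_hat)
        ses.append(est.se)
        deffs.append(est.deff)
        ns.append(est.n_valid)
        covered.append(est.ci2[0] <= truth <= est.ci2[1])
        if lqas_rule is not None and design == "slqas":
            cls = classify_strata(sample, lqas_rule, drug)
            wrong = 0
            for _, row in cls.iterrows():
                truly_at_or_above = sa_truth[row["sa_id"]] >= lqas_rule.p_upper
                wrong += (row["classification"] == "at_or_above") != truly_at_or_above
            misclass.append(wrong / len(cls))

    est_arr = np.array(estimates)
    R_ok = len(est_arr)
    mean_est = float(est_arr.mean()) if R_ok else float("nan")
    emp_sd = float(est_arr.std(ddof=1)) if R_ok > 1 else float("nan")
    return SimulationSummary(
        design=design,
        drug=drug,
        R=R,
        n_failures=n_failures,
        true_coverage=truth,
        mean_estimate=mean_est,
        bias=mean_est - truth if R_ok else float("nan"),
        mc_se_of_mean=emp_sd / np.sqrt(R_ok) if R_ok > 1 else float("nan"),
        empirical_sd=emp_sd,
        mean_estimated_se=float(np.mean(ses)) if R_ok else float("nan"),
        ci_coverage_rate=float(np.mean(covered)) if R_ok else float("nan"),
        mean_deff=float(np.nanmean(deffs)) if R_ok else float("nan"),
        mean_n=float(np.mean(ns)) if R_ok else float("nan"),
        classification_error_rate=float(np.mean(misclass)) if misclass else float("nan"),
        seed=seed,
    )


def run_comparison(
    frame: SamplingFrame,
    designs: list[str],
    R: int,
    seed: int,
    **kwargs,
) -> list[SimulationSummary]:
    """Run the listed designs on one frame with independent replicate
    streams derived from a single master seed."""
    if R < 1:
        raise ValueError("R must be >= 1")
    return [
        run_design(frame, design, R, seed, design_index=i, **kwargs)
        for i, design in enumerate(designs)
    ]


def report(summaries: list[SimulationSummary]) -> pd.DataFrame:
    """Comparison table, one row per design summary, fixed column order.
    Round-trips exactly through CSV."""
    if not summaries:
        raise ValueError("need at least one summary")
    return pd.DataFrame([s.to_dict() for s in summaries], columns=_SUMMARY_COLUMNS)


def read_report(path) -> pd.DataFrame:
    """Re-parse a report CSV with correctly rounded float parsing so the
    round trip reproduces the summaries bit-for-bit."""
    return pd.read_csv(path, float_precision="round_trip")


def report_text(df: pd.DataFrame) -> str:
    with pd.option_context("display.width", 140, "display.max_columns", None):
        return df.to_string(index=False, float_format=lambda v: f"{v:.5f}")
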