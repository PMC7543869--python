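"""Design-based estimation of MDA coverage from survey records.

The modelling surface follows the Model/Results convention: build a
:class:`CoverageSurvey` from a realized sample (or a records DataFrame),
call :meth:`~CoverageSurvey.fit`, and read estimates, standard errors,
design effects, confidence limits and threshold decisions off the
returned :class:`CoverageResults`.

Variance estimation depends on the design:

* EPI and PSS cluster surveys use the paired-selection (collapsed
  stratum) model: selection events, taken in the geographic order of the
  systematic PPES pass, are paired consecutively, and the variance of the
  ratio estimate r = Σy/Σx is built from within-pair contrasts of
  z_i = y_i − r·x_i.  This captures both the implicit stratification of
  the ordered frame and intra-cluster correlation.  An odd number of
  clusters collapses the final three into a triple with the standard 3/2
  adjustment.
* Stratified LQAS uses exact stratified-proportion theory with supervisory
  areas as strata, weighted by projected SA population.

"Not sure" responses are excluded from numerator and denominator alike
before any estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import _round_half_away
from .samplers import RESPONSE_NOT_SURE, RESPONSE_YES, SurveySample

__all__ = [
    "UndefinedEstimateError",
    "EstimateResult",
    "CoverageSurvey",
    "CoverageResults",
    "point_estimate",
    "kish_paired_variance",
    "stratified_estimate",
    "confidence_limits",
]


class UndefinedEstimateError(ValueError):
    """Raised when every response for a drug is 'not sure' (empty
    denominator after exclusion)."""


@dataclass
class EstimateResult:
    """Coverage estimate for one drug with design-based uncertainty."""

    drug: str
    n_valid: int
    n_treated: int
    p_hat: float
    se: float
    ci2: tuple[float, float]
    lower_cl1: float
    deff: float
    level: float = 0.95
    threshold: float | None = None
    reported: float | None = None
    threshold_met: bool | None = None
    lower_cl_meets_threshold: bool | None = None
    reported_validated: bool | None = None

    @property
    def percent(self) -> int:
        """Point estimate rounded to the nearest whole percent
        (half away from zero), as conventionally reported."""
        return _round_half_away(100.0 * self.p_hat)


def point_estimate(responses: np.ndarray) -> tuple[int, int, float]:
    """(n_valid, n_treated, p_hat) after excluding 'not sure' responses
    from both numerator and denominator."""
    responses = np.asarray(responses)
    valid = responses != RESPONSE_NOT_SURE
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise UndefinedEstimateError(
            "all responses are 'not sure': coverage estimate undefined"
        )
    n_treated = int((responses[valid] == RESPONSE_YES).sum())
    return n_valid, n_treated, n_treated / n_valid


def kish_paired_variance(
    y: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Paired-selection variance of the ratio estimate r = Σy/Σx.

    ``y`` and ``x`` are per-cluster treated and valid counts, in the
    geographic order the clusters were selected.  Returns (se, deff, v)
    where v is the estimated variance of r and deff compares v with the
    binomial variance p(1−p)/n of a simple random sample of the same
    size.  deff is NaN when p ∈ {0, 1}.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("paired variance needs at least 2 clusters")
    total_x = x.sum()
    if total_x <= 0:
        raise UndefinedEstimateError("no valid responses in any cluster")
    r = y.sum() / total_x
    z = y - r * x
    if k % 2 == 0:
        ss = float(((z[0::2] - z[1::2]) ** 2).sum())
    else:
        head = z[: k - 3]
        ss = float(((head[0::2] - head[1::2]) ** 2).sum())
        triple = z[k - 3:]
        ss += 1.5 * float(((triple - triple.mean()) ** 2).sum())
    v = ss / total_x**2
    se = float(np.sqrt(v))
    denom = r * (1.0 - r) / total_x
    deff = float(v / denom) if denom > 0 else float("nan")
    return se, deff, v


def stratified_estimate(
    p_h: np.ndarray, n_h: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Population-weighted stratified proportion and its standard error,

        p̂ = Σ W_h p̂_h,   v = Σ W_h² p̂_h(1−p̂_h)/(n_h − 1).
    """
    p_h = np.asarray(p_h, dtype=float)
    n_h = np.asarray(n_h, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(n_h <= 1):
        raise ValueError("every stratum needs n_h > 1 for a variance estimate")
    if not np.isclose(weights.sum(), 1.0):
        weights = weights / weights.sum()
    p_hat = float((weights * p_h).sum())
    v = float((weights**2 * p_h * (1.0 - p_h) / (n_h - 1.0)).sum())
    return p_hat, float(np.sqrt(v))


def confidence_limits(
    p_hat: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Wald two-sided limits and the one-sided lower limit, truncated to
    [0, 1]: (low, high, lower_one_sided)."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    z2 = norm.ppf(0.5 + level / 2.0)
    z1 = norm.ppf(level)
    lo = max(0.0, p_hat - z2 * se)
    hi = min(1.0, p_hat + z2 * se)
    lower1 = max(0.0, p_hat - z1 * se)
    return lo, hi, lower1


def _apply_decisions(est: EstimateResult, threshold: float | None,
                     reported: float | None) -> EstimateResult:
    if threshold is not None:
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        est.threshold = threshold
        # decided on the whole-percent point estimate, as reported
        est.threshold_met = bool(est.percent >= threshold * 100.0 - 1e-9)
        est.lower_cl_meets_threshold = bool(est.lower_cl1 >= threshold - 1e-12)
    if reported is not None:
        est.reported = reported
        lo, hi = est.ci2
        est.reported_validated = bool(lo <= reported <= hi)  # closed interval
    return est


class CoverageSurvey:
    """Design-based coverage model for one realized survey.

    Parameters
    ----------
    sample : SurveySample or pandas.DataFrame
        A sampler output, or a records table with columns ``stratum_id``,
        ``cluster_index`` and one ``response_<drug>`` column per drug
        (values yes/no/not_sure).
    design : str, optional
        Required for DataFrame input: one of ``epi``, ``slqas``, ``pss``.
    stratum_weights : mapping or pandas.Series, optional
        Projected population per SA; required for the stratified LQAS
        design and ignored otherwise.
    """

    def __init__(self, sample, design=None, stratum_weights=None):
        if isinstance(sample, SurveySample):
            self.design = sample.design
            self.drugs = sample.drugs
            self._stratum = sample.stratum
            self._cluster = sample.cluster
            self._n_events = sample.n_events
            self._responses = sample.responses
        else:
            records = sample
            if design is None:
                if "design" in records.columns and len(records):
                    design = str(records["design"].iloc[0])
                else:
                    raise ValueError("design must be given for DataFrame input")
            self.design = design
            resp_cols = [c for c in records.columns if c.startswith("response_")]
            self.drugs = tuple(c[len("response_"):] for c in resp_cols)
            code = {"no": 0, "yes": 1, "not_sure": 2}
            self._responses = {
                d: records[f"response_{d}"].astype(str).map(code).to_numpy(dtype=np.int8)
                for d in self.drugs
            }
            self._stratum = records["stratum_id"].to_numpy()
            self._cluster = records["cluster_index"].to_numpy()
            self._n_events = int(self._cluster.max()) + 1 if len(records) else 0
        if self.design not in ("epi", "slqas", "pss"):
            raise ValueError(f"unknown design {self.design!r}")
        if stratum_weights is not None:
            stratum_weights = pd.Series(dict(stratum_weights))
        self.stratum_weights = stratum_weights
        if self.design == "slqas" and stratum_weights is None:
            raise ValueError("stratified LQAS estimation needs stratum_weights "
                             "(projected population per SA)")

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, design: str,
                       stratum_weights=None) -> "CoverageSurvey":
        return cls(records, design=design, stratum_weights=stratum_weights)

    # -- fitting -----------------------------------------------------------

    def _fit_drug(self, drug: str, level: float) -> EstimateResult:
        resp = self._responses[drug]
        n_valid, n_treated, p_hat = point_estimate(resp)
        valid = resp != RESPONSE_NOT_SURE
        treated = (resp == RESPONSE_YES) & valid

        if self.design in ("epi", "pss"):
            x = np.bincount(self._cluster[valid], minlength=self._n_events).astype(float)
            y = np.bincount(self._cluster[treated], minlength=self._n_events).astype(float)
            se, deff, _ = kish_paired_variance(y, x)
        else:
            sas = self.stratum_weights.index.to_numpy()
            p_h, n_h = [], []
            for sa in sas:
                m = (self._stratum == sa) & valid
                n_sa = int(m.sum())
                if n_sa == 0:
                    raise UndefinedEstimateError(f"SA {sa} has no valid responses")
                p_h.append((resp[m] == RESPONSE_YES).sum() / n_sa)
                n_h.append(n_sa)
            w = self.stratum_weights.to_numpy(dtype=float)
            w = w / w.sum()
            p_hat, se = stratified_estimate(np.array(p_h), np.array(n_h), w)
            srs = p_hat * (1.0 - p_hat) / n_valid
            deff = float(se**2 / srs) if srs > 0 else float("nan")

        lo, hi, lower1 = confidence_limits(p_hat, se, level)
        return EstimateResult(
            drug=drug, n_valid=n_valid, n_treated=n_treated, p_hat=p_hat,
            se=se, ci2=(lo, hi), lower_cl1=lower1, deff=deff, level=level,
        )

    def fit(self, drugs=None, level: float = 0.95,
            threshold: float | None = None,
            reported: float | dict | None = None) -> "CoverageResults":
        """Fit the design-based estimator.

        ``threshold`` is the programme target coverage (fraction) used for
        the met/not-met decisions; ``reported`` is the administratively
        reported coverage (fraction, or a per-drug dict) to validate
        against the two-sided CI.
        """
        if drugs is None:
            drugs = self.drugs
        elif isinstance(drugs, str):
            drugs = (drugs,)
        estimates = {}
        for d in drugs:
            if d not in self._responses:
                raise KeyError(f"drug {d!r} not in survey; have {self.drugs}")
            est = self._fit_drug(d, level)
            rep = reported.get(d) if isinstance(reported, dict) else reported
            estimates[d] = _apply_decisions(est, threshold, rep)
        return CoverageResults(self, estimates, level)


class CoverageResults:
    """Container for fitted coverage estimates, one per drug."""

    def __init__(self, model: CoverageSurvey, estimates: dict[str, EstimateResult],
                 level: float):
        self.model = model
        self.estimates = estimates
        self.level = level

    def __getitem__(self, drug: str) -> EstimateResult:
        return self.estimates[drug]

    def __iter__(self):
        return iter(self.estimates.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self:
            rows.append(
                {
                    "drug": e.drug,
                    "design": self.model.design,
                    "n_valid": e.n_valid,
                    "n_treated": e.n_treated,
                    "coverage_pct": e.percent,
                    "p_hat": e.p_hat,
                    "se": e.se,
                    "ci2_low": e.ci2[0],
                    "ci2_high": e.ci2[1],
                    "lower_cl1": e.lower_cl1,
                    "deff": e.deff,
                    "threshold_met": e.threshold_met,
                    "lower_cl_meets_threshold": e.lower_cl_meets_threshold,
                    "reported_validated": e.reported_validated,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        pct = int(round(self.level * 100))
        lines = [
            f"Coverage survey estimates ({self.model.design} design, "
            f"{pct}% confidence)",
            "-" * 78,
            f"{'drug':<10}{'n':>7}{'treated':>9}{'cov%':>6}"
            f"{'2-sided CI':>16}{'lower 1-sided':>15}{'DEFF':>8}",
        ]
        for e in self:
            ci = f"({100*e.ci2[0]:.0f}, {100*e.ci2[1]:.0f})"
            lines.append(
                f"{e.drug:<10}{e.n_valid:>7}{e.n_treated:>9}{e.percent:>6}"
                f"{ci:>16}{100*e.lower_cl1:>14.0f} {e.deff:>7.2f}"
            )
            extra = []
            if e.threshold_met is not None:
                extra.append(f"target {100*e.threshold:.0f}%: "
                             f"{'met' if e.threshold_met else 'not met'}")
            if e.reported_validated is not None:
                extra.append(f"reported {100*e.reported:.0f}%: "
                             f"{'validated' if e.reported_validated else 'not validated'}")
            if extra:
                lines.append(" " * 10 + "; ".join(extra))
        return "\n".join(lines)
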