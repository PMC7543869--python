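"""Closed-form survey design computations.

Sample size for a coverage proportion under a cluster design, segment
counts for probability sampling with segmentation (PSS), the fixed
within-segment household sampling fraction, the resulting per-individual
inclusion probability, and systematic probability-proportional-to-
estimated-size (PPES) selection over a geographically ordered frame.

The sample-size formula is the standard one for estimating a proportion
P to precision ±delta at confidence z, inflated by the anticipated design
effect and by 1/(1-r) for nonresponse:

    n = DEFF * z^2 * P(1-P) / delta^2,   n_inflated = n / (1 - r)

Rounding is half-away-from-zero to the nearest integer, the convention
consistent with the canonical printed values (e.g. 1536.64 -> 1537).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SampleSizeSpec",
    "PssDesignSpec",
    "sample_size",
    "segment_count",
    "sampling_fraction",
    "pss_inclusion_probability",
    "ppes_systematic",
]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the coverage-survey sample-size formula.

    p: expected coverage (0.5 is the conservative choice);
    delta: desired half-width of the two-sided CI;
    z: normal critical value (1.96 for 95% two-sided);
    deff: anticipated design effect; r: anticipated nonresponse rate.
    """

    p: float
    delta: float
    z: float = 1.96
    deff: float = 1.0
    r: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("expected coverage p must lie in (0, 1)")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("precision delta must lie in (0, 1)")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.deff <= 0:
            raise ValueError("deff must be positive")
        if not 0.0 <= self.r < 1.0:
            raise ValueError("nonresponse rate r must lie in [0, 1)")


@dataclass(frozen=True)
class PssDesignSpec:
    """PSS design parameters and the derived household sampling fraction."""

    target_n: int
    avg_household_size: float
    n_clusters: int = 30
    segment_size_households: int = 50
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("paired variance estimation needs >= 2 clusters")
        f = self.f
        if not 0.0 < f <= 1.0:
            raise ValueError(f"sampling fraction f={f:.4g} outside (0, 1]")

    @property
    def f(self) -> float:
        return sampling_fraction(
            self.target_n,
            self.n_clusters,
            self.avg_household_size,
            self.segment_size_households,
            self.r,
        )


def sample_size(spec: SampleSizeSpec) -> tuple[int, int]:
    """Base and nonresponse-inflated sample sizes.

    >>> sample_size(SampleSizeSpec(p=0.5, delta=0.05, z=1.96, deff=4, r=0.15))
    (1537, 1808)
    """
    spec.validate()
    base = spec.deff * spec.z**2 * spec.p * (1.0 - spec.p) / spec.delta**2
    base_n = _round_half_away(base)
    inflated_n = _round_half_away(base_n / (1.0 - spec.r))
    return base_n, inflated_n


def segment_count(n_households: int, segment_size: int = 50) -> int:
    """Number of segments to assign to a PSU: household count divided by
    the segment size, rounded to the nearest integer, with a floor of one
    so small PSUs keep a nonzero measure of size."""
    if n_households < 1:
        raise ValueError("n_households must be >= 1")
    if segment_size < 1:
        raise ValueError("segment_size must be >= 1")
    return max(1, _round_half_away(n_households / segment_size))


def sampling_fraction(
    target_n: int,
    n_clusters: int = 30,
    avg_hh_size: float = 5.0,
    segment_size: int = 50,
    r: float = 0.0,
) -> float:
    """Fixed within-segment household sampling fraction

        f = target_n / (n_clusters * avg_hh_size * segment_size * (1 - r))

    shared by all selected segments.  f > 1 means the design cannot reach
    the target with these parameters and raises."""
    if min(target_n, n_clusters, avg_hh_size, segment_size) <= 0:
        raise ValueError("all design parameters must be positive")
    if not 0.0 <= r < 1.0:
        raise ValueError("r must lie in [0, 1)")
    f = target_n / (n_clusters * avg_hh_size * segment_size * (1.0 - r))
    if f > 1.0:
        raise ValueError(
            f"required sampling fraction {f:.4g} exceeds 1: "
            "target sample size unreachable with these parameters"
        )
    return f


def pss_inclusion_probability(
    segments_in_psu: int,
    total_segments: int,
    f: float,
    n_clusters: int = 30,
) -> float:
    """Per-individual inclusion probability under PSS.

    The PSU term (segments_in_psu / total) and the segment term
    (1 / segments_in_psu) cancel, so the probability

        n_clusters * f / total_segments

    is identical for every individual in the frame — the equal-probability
    property that makes the PSS point estimate directly interpretable.
    """
    if not 1 <= segments_in_psu <= total_segments:
        raise ValueError("need total_segments >= segments_in_psu >= 1")
    pi = n_clusters * f / total_segments
    if pi > 1.0:
        raise ValueError(f"inclusion probability {pi:.4g} exceeds 1: infeasible design")
    return pi


def ppes_systematic(
    units: Sequence[tuple[object, float]],
    k: int,
    rng: np.random.Generator,
) -> list[tuple[object, int]]:
    """Systematic PPS selection of ``k`` draws over an ordered frame.

    ``units`` is the geographically ordered list of (id, size measure).
    A single random start u ~ U(0, I) with interval I = total/k defines
    selection points u, u+I, ..., u+(k-1)I on the cumulated size scale;
    large units can be hit more than once.  Returns the selected units in
    frame order with their hit counts; total hits always equal k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = [u[0] for u in units]
    sizes = np.asarray([u[1] for u in units], dtype=float)
    if len(sizes) == 0:
        raise ValueError("empty frame")
    if np.any(sizes <= 0):
        raise ValueError("all size measures must be positive")
    total = sizes.sum()
    interval = total / k
    start = rng.uniform(0.0, interval)
    points = start + interval * np.arange(k)
    cum = np.cumsum(sizes)
    idx = np.searchsorted(cum, points, side="right")
    counts = np.bincount(idx, minlength=len(sizes))
    return [(ids[i], int(counts[i])) for i in np.nonzero(counts)[0]]
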