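"""The three field-selection protocols, as seeded stochastic procedures.

Each sampler walks a :class:`~ceskit.frame.SamplingFrame` exactly the way
a field team would walk a district, and returns a :class:`SurveySample`
of interviewed individuals:

* ``epi_survey`` — the classic EPI cluster survey: 30 PSUs drawn by
  systematic PPES on population, a random direction from the PSU centre
  to pick a start household, then a nearest-neighbour walk enrolling whole
  households until the cluster quota is met.  Not a probability sample —
  household inclusion probabilities are unknowable — which is precisely
  what the simulation harness demonstrates.
* ``slqas_survey`` — stratified LQAS: 19 villages per supervisory area by
  systematic PPES on households, one household per selection event, one
  randomly drawn individual per household (proxy if absent, else move to
  the nearest neighbour and redraw).
* ``pss_survey`` — probability sampling with segmentation: PSUs drawn by
  PPES on their 50-household segment count, one segment chosen at random,
  a fixed fraction f of its households taken systematically, every member
  enrolled; absentees without a proxy are dropped with no make-up
  selection.  An equal-probability design.

Responses are coded per drug as 1 (swallowed), 0 (did not), 2 (not sure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ppes_systematic, segment_count
from .frame import SamplingFrame

__all__ = ["SurveySample", "epi_survey", "slqas_survey", "pss_survey",
           "RESPONSE_YES", "RESPONSE_NO", "RESPONSE_NOT_SURE"]

RESPONSE_NO = 0
RESPONSE_YES = 1
RESPONSE_NOT_SURE = 2
_RESPONSE_LABELS = {RESPONSE_NO: "no", RESPONSE_YES: "yes", RESPONSE_NOT_SURE: "not_sure"}


@dataclass
class SurveySample:
    """One realized survey: flat record arrays plus design metadata."""

    design: str
    seed: int | None
    drugs: tuple[str, ...]
    individual: np.ndarray        # frame individual indices
    household: np.ndarray
    psu: np.ndarray
    stratum: np.ndarray           # SA id (slqas) or 0
    cluster: np.ndarray           # selection-event index, frame order
    segment: np.ndarray           # segment index within PSU, -1 if n/a
    proxy: np.ndarray
    hh_size: np.ndarray           # selection metadata (weighting for slqas)
    responses: dict[str, np.ndarray]
    n_events: int
    params: dict = field(default_factory=dict)
    shortfalls: list = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.individual)

    @cached_property
    def records(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "design": self.design,
                "stratum_id": self.stratum,
                "psu_id": self.psu,
                "cluster_index": self.cluster,
                "segment_id": self.segment,
                "household_id": self.household,
                "individual_id": self.individual,
                "hh_size": self.hh_size,
                "proxy": self.proxy.astype(int),
            }
        )
        for d in self.drugs:
            df[f"response_{d}"] = pd.Categorical(
                [_RESPONSE_LABELS[v] for v in self.responses[d]],
                categories=list(_RESPONSE_LABELS.values()),
            )
        return df

    def cluster_tallies(self) -> np.ndarray:
        """Interviewed individuals per selection event."""
        return np.bincount(self.cluster, minlength=self.n_events)

    def export_csv(self, path) -> None:
        self.records.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# shared helpers

def _members_of(frame: SamplingFrame, hh_indices: np.ndarray) -> np.ndarray:
    """Concatenated member indices of several households (frame order)."""
    starts = frame.hh_ind_start[hh_indices]
    counts = frame.hh_ind_start[hh_indices + 1] - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    offs = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return np.repeat(starts, counts) + (np.arange(total) - np.repeat(offs, counts))


def _expand_events(selections: list[tuple[int, int]]) -> list[int]:
    """PPES hit counts -> flat event list preserving frame order."""
    events: list[int] = []
    for psu, times in selections:
        events.extend([psu] * times)
    return events


def _frame_flags(frame, present, proxy_available):
    if present is None:
        present = frame.present
    if proxy_available is None:
        proxy_available = frame.proxy_available
    return present, proxy_available


def _response_arrays(frame: SamplingFrame, idx: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for d in frame.drugs:
        resp = frame.treated[d][idx].astype(np.int8)
        resp[frame.not_sure[d][idx]] = RESPONSE_NOT_SURE
        out[d] = resp
    return out


def _assemble(design, seed, frame, rows, n_events, params, shortfalls=None):
    """rows: list of (ind_idx_array, psu, stratum, cluster, segment, proxy_array)."""
    if rows:
        ind = np.concatenate([r[0] for r in rows])
        psu = np.concatenate([np.full(len(r[0]), r[1], dtype=np.int64) for r in rows])
        stratum = np.concatenate([np.full(len(r[0]), r[2], dtype=np.int64) for r in rows])
        cluster = np.concatenate([np.full(len(r[0]), r[3], dtype=np.int64) for r in rows])
        segment = np.concatenate([np.full(len(r[0]), r[4], dtype=np.int64) for r in rows])
        proxy = np.concatenate([r[5] for r in rows])
    else:
        ind = psu = stratum = cluster = segment = np.empty(0, dtype=np.int64)
        proxy = np.empty(0, dtype=bool)
    return SurveySample(
        design=design,
        seed=seed,
        drugs=frame.drugs,
        individual=ind,
        household=frame.ind_household[ind],
        psu=psu,
        stratum=stratum,
        cluster=cluster,
        segment=segment,
        proxy=proxy,
        hh_size=frame.hh_size[frame.ind_household[ind]],
        responses=_response_arrays(frame, ind),
        n_events=n_events,
        params=params,
        shortfalls=shortfalls or [],
    )


# ---------------------------------------------------------------------------
# EPI cluster survey

def epi_survey(
    frame: SamplingFrame,
    cluster_quota: int,
    n_clusters: int = 30,
    seed: int | None = None,
    present: np.ndarray | None = None,
    proxy_available: np.ndarray | None = None,
) -> SurveySample:
    """EPI 30-cluster survey with random-direction start and
    nearest-neighbour household walk.

    The "spin a pen at the village centre" step is modelled as a random
    bearing with a sector of initial half-width 15 degrees, doubled until
    it contains at least one household; the start household is uniform
    within the sector.  The walk then repeatedly visits the unvisited
    household nearest (Euclidean) to the current one, enrolling every
    member, until the cluster tally reaches the quota — always finishing
    the household it is in.  A PSU exhausted before quota is recorded as a
    shortfall, not an error.
    """
    if cluster_quota < 1:
        raise ValueError("cluster_quota must be >= 1")
    present, proxy_available = _frame_flags(frame, present, proxy_available)
    rng = np.random.default_rng(seed)
    units = list(zip(frame.psu_id, frame.psu_n_population))
    events = _expand_events(ppes_systematic(units, n_clusters, rng))

    rows = []
    shortfalls = []
    for event_idx, psu in enumerate(events):
        hh = frame.psu_households(psu)
        if len(hh) == 0:
            raise ValueError(f"PSU {psu} has no households: malformed frame")
        x = frame.hh_x[hh]
        y = frame.hh_y[hh]
        angles = np.arctan2(y, x)

        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        half_width = np.pi / 12.0  # 15 degrees
        diff = np.abs(np.mod(angles - theta0 + np.pi, 2.0 * np.pi) - np.pi)
        in_sector = diff <= half_width
        while not in_sector.any():
            half_width *= 2.0
            in_sector = diff <= half_width
        current = int(rng.choice(np.nonzero(in_sector)[0]))

        visited = np.zeros(len(hh), dtype=bool)
        tally = 0
        while True:
            visited[current] = True
            members = frame.household_members(hh[current])
            keep = present[members] | proxy_available[members]
            kept = members[keep]
            rows.append(
                (kept, psu, 0, event_idx, -1,
                 (~present[members] & proxy_available[members])[keep])
            )
            tally += len(kept)
            if tally >= cluster_quota:
                break
            if visited.all():
                shortfalls.append({"cluster": event_idx, "psu": int(psu),
                                   "achieved": tally, "quota": cluster_quota})
                break
            d2 = (x - x[current]) ** 2 + (y - y[current]) ** 2
            d2[visited] = np.inf
            current = int(np.argmin(d2))  # ties -> lowest household id

    return _assemble(
        "epi", seed, frame, rows, len(events),
        {"cluster_quota": cluster_quota, "n_clusters": n_clusters},
        shortfalls,
    )


# ---------------------------------------------------------------------------
# Stratified LQAS survey

def slqas_survey(
    frame: SamplingFrame,
    villages_per_stratum: int = 19,
    seed: int | None = None,
    enumerable_threshold: int = 150,
    present: np.ndarray | None = None,
    proxy_available: np.ndarray | None = None,
) -> SurveySample:
    """Stratified LQAS: per supervisory area, ``villages_per_stratum``
    systematic PPES draws on household counts; one household and one
    randomly drawn member per draw.

    Household selection uses the village register when one exists, a
    leader's enumeration for villages of at most ``enumerable_threshold``
    households, and otherwise segment-then-enumerate (one equal-size
    segment picked at random, then a uniform household within it).  An
    absent selectee answers by proxy when possible; with no proxy the team
    moves to the nearest-neighbour household and redraws.
    """
    present, proxy_available = _frame_flags(frame, present, proxy_available)
    rng = np.random.default_rng(seed)
    sas = np.unique(frame.sa_id)
    rows = []
    event_idx = 0
    for sa in sas:
        psus = frame.psu_id[frame.sa_id == sa]
        if frame.psu_n_households[psus].sum() == 0:
            raise ValueError(f"SA {sa} has no households")
        units = [(p, frame.psu_n_households[p]) for p in psus]
        events = _expand_events(ppes_systematic(units, villages_per_stratum, rng))
        for psu in events:
            hh = frame.psu_households(psu)
            n_hh = len(hh)
            if frame.register_listed[psu] or n_hh <= enumerable_threshold:
                local = int(rng.integers(n_hh))
            else:
                # too big to enumerate: equal segments, pick one, enumerate it
                n_seg = int(np.ceil(n_hh / enumerable_threshold))
                bounds = np.linspace(0, n_hh, n_seg + 1).astype(int)
                j = int(rng.integers(n_seg))
                local = int(rng.integers(bounds[j], bounds[j + 1]))

            visited = np.zeros(n_hh, dtype=bool)
            x = frame.hh_x[hh]
            y = frame.hh_y[hh]
            chosen = None
            while True:
                visited[local] = True
                members = frame.household_members(hh[local])
                pick = int(rng.choice(members))
                if present[pick]:
                    chosen, is_proxy = pick, False
                    break
                if proxy_available[pick]:
                    chosen, is_proxy = pick, True
                    break
                if visited.all():
                    break  # stratum shortfall: no reachable respondent
                d2 = (x - x[local]) ** 2 + (y - y[local]) ** 2
                d2[visited] = np.inf
                local = int(np.argmin(d2))
            if chosen is not None:
                rows.append(
                    (np.array([chosen]), psu, int(sa), event_idx, -1,
                     np.array([is_proxy]))
                )
            event_idx += 1

    return _assemble(
        "slqas", seed, frame, rows, event_idx,
        {"villages_per_stratum": villages_per_stratum,
         "enumerable_threshold": enumerable_threshold},
    )


# ---------------------------------------------------------------------------
# Probability sampling with segmentation

def pss_survey(
    frame: SamplingFrame,
    f: float,
    n_clusters: int = 30,
    segment_size: int = 50,
    seed: int | None = None,
    present: np.ndarray | None = None,
    proxy_available: np.ndarray | None = None,
) -> SurveySample:
    """PSS: PPES on segment counts, one random segment per hit, fixed
    systematic household fraction ``f`` within the segment, all members
    enrolled; absentees without a proxy are simply lost (the sample size
    already carries nonresponse inflation).

    Households are put in polar-angle order around the PSU centre before
    being split into the PSU's predetermined number of contiguous
    segments of near-equal size (remainder spread one per segment).  A PSU
    hit more than once contributes one independent segment draw per hit.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("sampling fraction f must lie in (0, 1]")
    present, proxy_available = _frame_flags(frame, present, proxy_available)
    rng = np.random.default_rng(seed)
    n_segments = np.array(
        [segment_count(int(nh), segment_size) for nh in frame.psu_n_households]
    )
    units = list(zip(frame.psu_id, n_segments))
    events = _expand_events(ppes_systematic(units, n_clusters, rng))

    interval = 1.0 / f
    rows = []
    warnings = []
    for event_idx, psu in enumerate(events):
        hh_ang = frame.psu_households_by_angle(psu)
        m = len(hh_ang)
        n_seg = int(n_segments[psu])
        base, rem = divmod(m, n_seg)
        sizes = np.full(n_seg, base)
        sizes[:rem] += 1
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        j = int(rng.integers(n_seg))
        seg_hh = hh_ang[bounds[j]:bounds[j + 1]]
        m_seg = len(seg_hh)
        if m_seg * f < 1.0:
            warnings.append({"cluster": event_idx, "psu": int(psu),
                             "note": "expected households below 1 in segment"})
        u = rng.uniform(0.0, interval)
        if u >= m_seg:
            continue  # segment contributes no household this draw
        n_take = int(np.ceil((m_seg - u) / interval))
        take = np.minimum(np.floor(u + interval * np.arange(n_take)).astype(int), m_seg - 1)
        sel_hh = seg_hh[np.unique(take)]
        members = _members_of(frame, sel_hh)
        keep = present[members] | proxy_available[members]
        kept = members[keep]
        rows.append(
            (kept, psu, 0, event_idx, j,
             (~present[members] & proxy_available[members])[keep])
        )

    return _assemble(
        "pss", seed, frame, rows, len(events),
        {"f": f, "n_clusters": n_clusters, "segment_size": segment_size},
        warnings,
    )
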