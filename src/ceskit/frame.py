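"""Synthetic district sampling frames.

A coverage evaluation survey operates on a sampling frame of primary
sampling units (PSUs — villages or census enumeration areas), grouped
into supervisory areas (SAs) and listed in geographic order.  This module
generates complete synthetic districts down to the individual level —
PSUs → households → people, with planar household coordinates inside each
PSU — together with per-drug treatment truth, so every sampling design and
estimator in the package can be exercised and validated without any
external data.

Treatment truth follows a beta-binomial construction: each PSU draws a
coverage level from a Beta distribution whose mean is ``mean_coverage``
and whose overdispersion yields an intra-cluster correlation (ICC) of
``coverage_icc`` (``1/(1+a+b) = ICC``); individuals are then Bernoulli
with log-odds optionally shifted by distance from the PSU centre
(``spatial_effect``) and by household size (``hh_size_effect``).  These
two effects are the levers that make the EPI random walk and the
one-person-per-household LQAS selection demonstrably biased while leaving
equal-probability designs unbiased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = ["FrameConfig", "SamplingFrame", "generate_frame", "true_coverage"]


@dataclass(frozen=True)
class FrameConfig:
    """Parameters of a synthetic district.

    ``psu_household_count_distribution`` is (mean, sigma-of-log) for a
    lognormal draw rounded to an integer with a floor of 5 households, so
    frames always contain both small PSUs (single segment, leader
    enumeration) and large ones (segmentation, multiple selection hits).
    ``household_size_distribution`` is (mean, dispersion) for a shifted
    negative binomial truncated at 1 person.
    """

    n_sas: int = 5
    n_psus: int = 100
    psu_household_count_distribution: tuple[float, float] = (80.0, 0.6)
    household_size_distribution: tuple[float, float] = (5.0, 4.0)
    coverage_icc: float = 0.05
    mean_coverage: float = 0.8
    spatial_effect: float = 0.0
    hh_size_effect: float = 0.0
    not_sure_prob: float = 0.03
    absence_prob: float = 0.10
    proxy_available_prob: float = 0.80
    register_listed_prob: float = 0.5
    drugs: tuple[str, ...] = ("alb",)
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "coverage_icc": self.coverage_icc,
            "not_sure_prob": self.not_sure_prob,
            "absence_prob": self.absence_prob,
            "proxy_available_prob": self.proxy_available_prob,
            "register_listed_prob": self.register_listed_prob,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.coverage_icc >= 1.0:
            raise ValueError("coverage_icc must be < 1")
        if not 0.0 < self.mean_coverage < 1.0:
            raise ValueError("mean_coverage must lie in (0, 1)")
        if self.household_size_distribution[0] < 1.0:
            raise ValueError("mean household size must be >= 1")
        if self.n_psus < self.n_sas:
            raise ValueError("need at least one PSU per SA")
        if self.n_sas < 1 or self.n_psus < 1:
            raise ValueError("n_sas and n_psus must be positive")
        if not self.drugs:
            raise ValueError("at least one drug id required")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["psu_household_count_distribution"] = list(d["psu_household_count_distribution"])
        d["household_size_distribution"] = list(d["household_size_distribution"])
        d["drugs"] = list(d["drugs"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FrameConfig":
        d = json.loads(Path(path).read_text())
        d["psu_household_count_distribution"] = tuple(d["psu_household_count_distribution"])
        d["household_size_distribution"] = tuple(d["household_size_distribution"])
        d["drugs"] = tuple(d["drugs"])
        return cls(**d)


@dataclass
class SamplingFrame:
    """A fully enumerated synthetic district.

    PSU-level arrays are indexed 0..n_psus-1 in geographic order (the
    order index is the identity permutation of the storage order, and SAs
    are contiguous blocks of it, mimicking a census frame sorted by
    locality).  Households are stored contiguously per PSU and individuals
    contiguously per household, so PSU/household membership is resolved by
    slicing precomputed start offsets instead of joins.
    """

    config: FrameConfig | None
    # PSU level
    psu_id: np.ndarray
    sa_id: np.ndarray
    order_index: np.ndarray
    psu_n_households: np.ndarray
    psu_n_population: np.ndarray
    register_listed: np.ndarray
    psu_hh_start: np.ndarray          # len n_psus+1, household slice bounds
    # household level
    hh_psu: np.ndarray
    hh_size: np.ndarray
    hh_x: np.ndarray
    hh_y: np.ndarray
    hh_ind_start: np.ndarray          # len n_hh+1, individual slice bounds
    # individual level
    ind_household: np.ndarray
    ind_psu: np.ndarray
    present: np.ndarray
    proxy_available: np.ndarray
    treated: dict[str, np.ndarray]
    not_sure: dict[str, np.ndarray]
    _angle_order: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    # ---- basic accessors -------------------------------------------------

    @property
    def n_psus(self) -> int:
        return len(self.psu_id)

    @property
    def n_households(self) -> int:
        return len(self.hh_size)

    @property
    def n_individuals(self) -> int:
        return len(self.ind_household)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.treated.keys())

    def psu_households(self, psu: int) -> np.ndarray:
        """Household indices of one PSU, in storage (id) order."""
        return np.arange(self.psu_hh_start[psu], self.psu_hh_start[psu + 1])

    def household_members(self, hh: int) -> np.ndarray:
        return np.arange(self.hh_ind_start[hh], self.hh_ind_start[hh + 1])

    def psu_households_by_angle(self, psu: int) -> np.ndarray:
        """Household indices of one PSU ordered by polar angle about the
        PSU centre — the contiguity proxy used when segmenting."""
        cached = self._angle_order.get(psu)
        if cached is None:
            hh = self.psu_households(psu)
            ang = np.arctan2(self.hh_y[hh], self.hh_x[hh])
            cached = hh[np.argsort(ang, kind="stable")]
            self._angle_order[psu] = cached
        return cached

    def sa_populations(self) -> pd.Series:
        """Projected population per SA (stratum weights for S-LQAS)."""
        return pd.Series(self.psu_n_population).groupby(pd.Series(self.sa_id)).sum()

    # ---- export / import -------------------------------------------------

    def psus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "psu_id": self.psu_id,
                "sa_id": self.sa_id,
                "order_index": self.order_index,
                "n_households": self.psu_n_households,
                "n_population": self.psu_n_population,
                "register_listed": self.register_listed.astype(int),
            }
        )

    def individuals_frame(self) -> pd.DataFrame:
        hh = self.ind_household
        df = pd.DataFrame(
            {
                "psu_id": self.ind_psu,
                "household_id": hh,
                "individual_id": np.arange(self.n_individuals),
                "hh_size": self.hh_size[hh],
                "x": self.hh_x[hh],
                "y": self.hh_y[hh],
                "present": self.present.astype(int),
                "proxy_available": self.proxy_available.astype(int),
            }
        )
        for d in self.drugs:
            df[f"treated_{d}"] = self.treated[d].astype(int)
            df[f"notsure_{d}"] = self.not_sure[d].astype(int)
        return df

    def export_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.psus_frame().to_csv(directory / "psus.csv", index=False, lineterminator="\n")
        self.individuals_frame().to_csv(
            directory / "individuals.csv", index=False, float_format="%.10f", lineterminator="\n"
        )
        if self.config is not None:
            self.config.to_json(directory / "config.json")

    @classmethod
    def import_csv(cls, directory: str | Path) -> "SamplingFrame":
        directory = Path(directory)
        psus = pd.read_csv(directory / "psus.csv")
        ind = pd.read_csv(directory / "individuals.csv")
        config = None
        cfg_path = directory / "config.json"
        if cfg_path.exists():
            config = FrameConfig.from_json(cfg_path)
        drugs = tuple(c[len("treated_"):] for c in ind.columns if c.startswith("treated_"))

        ind = ind.sort_values(["household_id", "individual_id"], kind="stable")
        hh_first = ind.drop_duplicates("household_id").sort_values("household_id")
        hh_psu = hh_first["psu_id"].to_numpy()
        hh_size = hh_first["hh_size"].to_numpy(dtype=np.int64)
        hh_x = hh_first["x"].to_numpy()
        hh_y = hh_first["y"].to_numpy()
        hh_counts = ind.groupby("household_id").size().sort_index().to_numpy()
        hh_ind_start = np.concatenate([[0], np.cumsum(hh_counts)])
        psus = psus.sort_values("psu_id")
        hh_per_psu = pd.Series(hh_psu).value_counts().reindex(psus["psu_id"], fill_value=0).to_numpy()
        psu_hh_start = np.concatenate([[0], np.cumsum(hh_per_psu)])
        return cls(
            config=config,
            psu_id=psus["psu_id"].to_numpy(),
            sa_id=psus["sa_id"].to_numpy(),
            order_index=psus["order_index"].to_numpy(),
            psu_n_households=psus["n_households"].to_numpy(),
            psu_n_population=psus["n_population"].to_numpy(),
            register_listed=psus["register_listed"].to_numpy(dtype=bool),
            psu_hh_start=psu_hh_start,
            hh_psu=hh_psu,
            hh_size=hh_size,
            hh_x=hh_x,
            hh_y=hh_y,
            hh_ind_start=hh_ind_start,
            ind_household=ind["household_id"].to_numpy(),
            ind_psu=ind["psu_id"].to_numpy(),
            present=ind["present"].to_numpy(dtype=bool),
            proxy_available=ind["proxy_available"].to_numpy(dtype=bool),
            treated={d: ind[f"treated_{d}"].to_numpy(dtype=bool) for d in drugs},
            not_sure={d: ind[f"notsure_{d}"].to_numpy(dtype=bool) for d in drugs},
        )

    # ---- derived randomness (used by the simulation harness) -------------

    def redraw_presence(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Fresh presence / proxy-availability flags from the config's
        rates, leaving treatment truth untouched.  Falls back to the stored
        flags when the frame was imported without a config."""
        if self.config is None:
            return self.present, self.proxy_available
        n = self.n_individuals
        present = rng.random(n) >= self.config.absence_prob
        proxy = rng.random(n) < self.config.proxy_available_prob
        return present, proxy


def generate_frame(config: FrameConfig) -> SamplingFrame:
    """Draw a complete synthetic district. Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_psus = config.n_psus
    # contiguous SA blocks over the geographically ordered PSU list
    sa_id = (np.arange(n_psus) * config.n_sas) // n_psus
    order_index = np.arange(n_psus)

    mean_hh, sigma = config.psu_household_count_distribution
    mu = np.log(mean_hh) - sigma**2 / 2.0
    psu_n_households = np.maximum(
        5, np.rint(rng.lognormal(mu, sigma, size=n_psus)).astype(np.int64)
    )
    psu_hh_start = np.concatenate([[0], np.cumsum(psu_n_households)])
    n_hh = int(psu_hh_start[-1])
    hh_psu = np.repeat(np.arange(n_psus), psu_n_households)

    size_mean, size_disp = config.household_size_distribution
    extra_mean = size_mean - 1.0
    if extra_mean <= 0:
        hh_size = np.ones(n_hh, dtype=np.int64)
    else:
        p_nb = size_disp / (size_disp + extra_mean)
        hh_size = 1 + rng.negative_binomial(size_disp, p_nb, size=n_hh)

    # uniform positions in the unit disc, PSU centre at the origin
    radius = np.sqrt(rng.random(n_hh))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_hh)
    hh_x = radius * np.cos(theta)
    hh_y = radius * np.sin(theta)

    hh_ind_start = np.concatenate([[0], np.cumsum(hh_size)])
    n_ind = int(hh_ind_start[-1])
    ind_household = np.repeat(np.arange(n_hh), hh_size)
    ind_psu = hh_psu[ind_household]
    psu_n_population = np.bincount(hh_psu, weights=hh_size, minlength=n_psus).astype(np.int64)

    # PSU-level coverage with the requested intra-cluster correlation
    if config.coverage_icc > 0:
        ab = (1.0 - config.coverage_icc) / config.coverage_icc
        a = config.mean_coverage * ab
        b = ab - a
        psu_p = rng.beta(a, b, size=n_psus)
        psu_p = np.clip(psu_p, 1e-9, 1.0 - 1e-9)
    else:
        psu_p = np.full(n_psus, config.mean_coverage)

    base_logodds = logit(psu_p)[ind_psu]
    if config.spatial_effect != 0.0:
        base_logodds = base_logodds + config.spatial_effect * radius[ind_household]
    if config.hh_size_effect != 0.0:
        centered = hh_size - hh_size.mean()
        base_logodds = base_logodds + config.hh_size_effect * centered[ind_household]
    p_ind = expit(base_logodds)

    treated = {d: rng.random(n_ind) < p_ind for d in config.drugs}
    not_sure = {d: rng.random(n_ind) < config.not_sure_prob for d in config.drugs}
    present = rng.random(n_ind) >= config.absence_prob
    proxy_available = rng.random(n_ind) < config.proxy_available_prob
    register_listed = rng.random(n_psus) < config.register_listed_prob

    return SamplingFrame(
        config=config,
        psu_id=np.arange(n_psus),
        sa_id=sa_id,
        order_index=order_index,
        psu_n_households=psu_n_households,
        psu_n_population=psu_n_population,
        register_listed=register_listed,
        psu_hh_start=psu_hh_start,
        hh_psu=hh_psu,
        hh_size=hh_size,
        hh_x=hh_x,
        hh_y=hh_y,
        hh_ind_start=hh_ind_start,
        ind_household=ind_household,
        ind_psu=ind_psu,
        present=present,
        proxy_available=proxy_available,
        treated=treated,
        not_sure=not_sure,
    )


def true_coverage(frame: SamplingFrame, drug: str) -> float:
    """Census truth: treated individuals over all individuals."""
    if drug not in frame.treated:
        raise KeyError(f"unknown drug id {drug!r}; frame has {frame.drugs}")
    return float(frame.treated[drug].mean())
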