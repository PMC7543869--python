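"""Shared fixtures: generated frames and hand-built regular frames."""

from __future__ import annotations

import numpy as np
import pytest

from ceskit.frame import FrameConfig, SamplingFrame, generate_frame


@pytest.fixture(scope="session")
def default_frame() -> SamplingFrame:
    """A mid-sized district with the package's default structure."""
    return generate_frame(FrameConfig(seed=42))


@pytest.fixture(scope="session")
def flat_frame() -> SamplingFrame:
    """No clustering, no covariate effects: iid Bernoulli(0.8) truth."""
    return generate_frame(
        FrameConfig(
            n_psus=60,
            coverage_icc=0.0,
            mean_coverage=0.8,
            spatial_effect=0.0,
            hh_size_effect=0.0,
            not_sure_prob=0.0,
            absence_prob=0.0,
            seed=7,
        )
    )


def make_grid_frame(
    n_psus: int = 30,
    hh_per_psu: int = 20,
    hh_size: int = 3,
    n_sas: int = 5,
    coverage_icc: float = 0.0,
    mean_coverage: float = 0.7,
    seed: int = 0,
) -> SamplingFrame:
    """Hand-built perfectly regular frame: every PSU has exactly
    ``hh_per_psu`` households of exactly ``hh_size`` members, everyone
    present, no proxies needed, no 'not sure' answers.  Treatment truth is
    beta-binomial at the requested ICC.  Used wherever a test needs exact
    counts rather than realistic heterogeneity."""
    rng = np.random.default_rng(seed)
    n_hh = n_psus * hh_per_psu
    n_ind = n_hh * hh_size
    hh_psu = np.repeat(np.arange(n_psus), hh_per_psu)
    sizes = np.full(n_hh, hh_size, dtype=np.int64)
    radius = np.sqrt(rng.random(n_hh))
    theta = rng.uniform(0, 2 * np.pi, n_hh)
    ind_household = np.repeat(np.arange(n_hh), sizes)
    if coverage_icc > 0:
        ab = (1 - coverage_icc) / coverage_icc
        a = mean_coverage * ab
        psu_p = rng.beta(a, ab - a, size=n_psus)
    else:
        psu_p = np.full(n_psus, mean_coverage)
    treated = rng.random(n_ind) < psu_p[hh_psu[ind_household]]
    return SamplingFrame(
        config=None,
        psu_id=np.arange(n_psus),
        sa_id=(np.arange(n_psus) * n_sas) // n_psus,
        order_index=np.arange(n_psus),
        psu_n_households=np.full(n_psus, hh_per_psu, dtype=np.int64),
        psu_n_population=np.full(n_psus, hh_per_psu * hh_size, dtype=np.int64),
        register_listed=np.ones(n_psus, dtype=bool),
        psu_hh_start=np.arange(n_psus + 1) * hh_per_psu,
        hh_psu=hh_psu,
        hh_size=sizes,
        hh_x=radius * np.cos(theta),
        hh_y=radius * np.sin(theta),
        hh_ind_start=np.arange(n_hh + 1) * hh_size,
        ind_household=ind_household,
        ind_psu=hh_psu[ind_household],
        present=np.ones(n_ind, dtype=bool),
        proxy_available=np.ones(n_ind, dtype=bool),
        treated={"alb": treated},
        not_sure={"alb": np.zeros(n_ind, dtype=bool)},
    )


@pytest.fixture(scope="session")
def grid_frame() -> SamplingFrame:
    return make_grid_frame(seed=3)
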