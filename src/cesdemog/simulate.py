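"""Generator of CES-like ringing datasets with known variance structure.

Demographic rates live on the logit scale as an additive decomposition

    logit(rate[k, t]) = mu + eps[t] + eta_site[k] + eta_int[k, t]

with eps ~ N(0, T2) (year effects), eta_site ~ N(0, K2) (site effects) and
eta_int ~ N(0, P2) (site-by-year interaction), independently per species and
per rate.  The implied population-level targets are STS = K2/(T2+K2) and
ICC = T2/(T2+P2); a dataset simulated from a config therefore has a known
truth for every downstream statistic.

Individuals are adults in an open population: Poisson recruitment each year,
Bernoulli survival between years, Bernoulli detection within years.  Juvenile
captures are attached per site-year so that the proportion of juveniles among
captures follows the productivity rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ces_io import ADULT, JUVENILE, RECORD_FIELDS, RecordSet

#: default variance regime emulating productivity as reported for European
#: passerines: mostly spatial (high STS) and asynchronous (low ICC).
PRODUCTIVITY_REGIME = {"site_var": 0.30, "year_var": 0.10, "interaction_var": 0.40}

#: variance regime emulating adult apparent survival: more annual variation
#: and moderate synchrony.
SURVIVAL_REGIME = {"site_var": 0.12, "year_var": 0.18, "interaction_var": 0.36}


@dataclass
class SimulationConfig:
    """Conditions of a synthetic constant-effort ringing study.

    Variances are on the logit scale and apply to both demographic rates
    (survival and productivity draw independent effects from the same
    variances).  ``adults_per_site_year`` is the expected number of newly
    recruited adults per site per year; ``recapture_prob`` is the per-year
    detection probability of an alive adult.
    """

    n_species: int = 8
    n_sites: int = 40
    year_range: tuple[int, int] = (2004, 2014)
    mean_survival_logit: float = 0.0          # logit(0.5): typical adult apparent survival
    mean_prod_logit: float = 0.2              # logit(0.55): slight juvenile excess in catches
    site_var: float = PRODUCTIVITY_REGIME["site_var"]
    year_var: float = PRODUCTIVITY_REGIME["year_var"]
    interaction_var: float = PRODUCTIVITY_REGIME["interaction_var"]
    recapture_prob: float = 0.5
    adults_per_site_year: float = 25.0
    visits_per_year: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.site_var, self.year_var, self.interaction_var) < 0:
            raise ValueError("variances must be >= 0")
        if not (0 < self.recapture_prob < 1):
            raise ValueError("recapture_prob must be in (0, 1)")
        lo, hi = self.year_range
        if hi - lo + 1 < 2:
            raise ValueError("year_range must span at least 2 years")
        if self.n_species < 1 or self.n_sites < 1:
            raise ValueError("need at least one species and one site")
        if self.visits_per_year < 1:
            raise ValueError("visits_per_year must be positive")
        if self.adults_per_site_year <= 0:
            raise ValueError("adults_per_site_year must be positive")

    @property
    def years(self) -> np.ndarray:
        lo, hi = self.year_range
        return np.arange(lo, hi + 1)

    @property
    def n_years(self) -> int:
        return self.years.size

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "year_range" in data:
            data["year_range"] = tuple(data["year_range"])
        return cls(**data)


@dataclass
class RateField:
    """Realized effects and rate matrix (sites x years) for one species-rate."""

    mu: float
    eps: np.ndarray        # (T,) year effects
    eta_site: np.ndarray   # (K,) site effects
    eta_int: np.ndarray    # (K, T) site-by-year effects
    matrix: np.ndarray     # (K, T) rates on the probability scale

    @property
    def logit_matrix(self) -> np.ndarray:
        return self.mu + self.eps[None, :] + self.eta_site[:, None] + self.eta_int


@dataclass
class TrueRates:
    """Ground truth of a simulated dataset, for recovery checks.

    ``survival[s]`` / ``productivity[s]`` hold the realized effect draws and
    the rate matrices per species; the bookkeeping arrays record the latent
    alive process and the realized captures per species, site and year.
    """

    species_codes: list[str]
    site_ids: list[str]
    years: np.ndarray
    survival: list[RateField]
    productivity: list[RateField]
    n_alive: np.ndarray             # (S, K, T) adults alive
    n_captured_adults: np.ndarray   # (S, K, T)
    n_captured_juveniles: np.ndarray  # (S, K, T)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def draw_effects(
    rng: np.random.Generator,
    n_sites: int,
    n_years: int,
    mu: float,
    site_var: float,
    year_var: float,
    interaction_var: float,
) -> RateField:
    """Draw one species' effect vectors and rate matrix from the model."""
    eps = rng.normal(0.0, np.sqrt(year_var), size=n_years)
    eta_site = rng.normal(0.0, np.sqrt(site_var), size=n_sites)
    eta_int = rng.normal(0.0, np.sqrt(interaction_var), size=(n_sites, n_years))
    logit = mu + eps[None, :] + eta_site[:, None] + eta_int
    return RateField(mu=mu, eps=eps, eta_site=eta_site, eta_int=eta_int, matrix=_expit(logit))


def true_sts(cfg: SimulationConfig) -> float | None:
    """Population-level STS implied by the config, or None when 0/0."""
    denom = cfg.year_var + cfg.site_var
    if denom == 0:
        return None
    return cfg.site_var / denom


def true_icc(cfg: SimulationConfig) -> float | None:
    """Population-level ICC implied by the config, or None when 0/0."""
    denom = cfg.year_var + cfg.interaction_var
    if denom == 0:
        return None
    return cfg.year_var / denom


def simulate_dataset(cfg: SimulationConfig) -> tuple[RecordSet, pd.DataFrame, TrueRates]:
    """Simulate records, visit effort and ground truth from a config.

    Fully reproducible from ``cfg.rng_seed``; three independent substreams
    (effects, demography, detection) keep the latent rates invariant to
    changes in detection noise.

    Per species and site: new adults recruit each year (Poisson), existing
    adults survive each between-year interval (Bernoulli with the survival
    rate of the interval's starting year), and every alive adult is captured
    with probability ``recapture_prob``.  Given A captured adults, the number
    of juvenile captures is drawn negative-binomially so that each capture
    event is independently a juvenile with the productivity-rate probability,
    making the downstream binomial proportion-juvenile likelihood exact.
    Captures are assigned uniformly to visits.
    """
    ss = np.random.SeedSequence(cfg.rng_seed)
    eff_rng, demo_rng, det_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    years = cfg.years
    K, T, S = cfg.n_sites, cfg.n_years, cfg.n_species
    species_codes = [f"SP{i + 1:02d}" for i in range(S)]
    site_ids = [f"ST{i + 1:03d}" for i in range(K)]

    surv_fields, prod_fields = [], []
    for _ in range(S):
        surv_fields.append(
            draw_effects(eff_rng, K, T, cfg.mean_survival_logit,
                         cfg.site_var, cfg.year_var, cfg.interaction_var)
        )
        prod_fields.append(
            draw_effects(eff_rng, K, T, cfg.mean_prod_logit,
                         cfg.site_var, cfg.year_var, cfg.interaction_var)
        )

    n_alive = np.zeros((S, K, T), dtype=np.int64)
    n_cap_ad = np.zeros((S, K, T), dtype=np.int64)
    n_cap_juv = np.zeros((S, K, T), dtype=np.int64)

    rows: list[tuple] = []
    for s, sp in enumerate(species_codes):
        phi = surv_fields[s].matrix
        rho = prod_fields[s].matrix
        for k, site in enumerate(site_ids):
            alive: np.ndarray = np.empty(0, dtype=np.int64)  # individual ids
            next_id = 0
            for t, year in enumerate(years):
                if t > 0:
                    survived = demo_rng.random(alive.size) < phi[k, t - 1]
                    alive = alive[survived]
                n_new = demo_rng.poisson(cfg.adults_per_site_year)
                recruits = np.arange(next_id, next_id + n_new, dtype=np.int64)
                next_id += n_new
                alive = np.concatenate([alive, recruits])
                n_alive[s, k, t] = alive.size

                captured = alive[det_rng.random(alive.size) < cfg.recapture_prob]
                n_cap_ad[s, k, t] = captured.size
                visits_ad = det_rng.integers(1, cfg.visits_per_year + 1, size=captured.size)
                for ind, v in zip(captured, visits_ad):
                    rows.append((f"{sp}-{site}-A{ind:06d}", sp, site, int(year), int(v), ADULT))

                n_ad = captured.size
                n_juv = int(det_rng.negative_binomial(n_ad, 1.0 - rho[k, t])) if n_ad > 0 else 0
                n_cap_juv[s, k, t] = n_juv
                visits_juv = det_rng.integers(1, cfg.visits_per_year + 1, size=n_juv)
                for j, v in enumerate(visits_juv):
                    rows.append(
                        (f"{sp}-{site}-J{int(year)}-{j:05d}", sp, site, int(year), int(v), JUVENILE)
                    )

    records = pd.DataFrame(rows, columns=list(RECORD_FIELDS))
    rs = RecordSet(records, provenance=f"simulated(seed={cfg.rng_seed})")

    effort = pd.DataFrame(
        [(site, int(year), cfg.visits_per_year) for site in site_ids for year in years],
        columns=["site_id", "year", "n_visits"],
    )
    truth = TrueRates(
        species_codes=species_codes,
        site_ids=site_ids,
        years=years,
        survival=surv_fields,
        productivity=prod_fields,
        n_alive=n_alive,
        n_captured_adults=n_cap_ad,
        n_captured_juveniles=n_cap_juv,
    )
    return rs, effort, truth
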