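"""Hierarchical Bayesian models of productivity and apparent survival.

Both demographic rates are modelled per site-year on the logit scale under one
of two random-effect structures:

* ``STS``:  logit(rate[k, t]) = mu + eps[t] + eta[k],  eps ~ N(0, T2),
  eta ~ N(0, K2) — a global mean with additive year and site effects, whose
  variance components feed the spatio-temporal structure statistic
  STS = K2/(T2+K2).
* ``ICC``:  logit(rate[k, t]) = mu_k + eps[t] + eta[k, t],  eps ~ N(0, T2),
  eta ~ N(0, P2) — per-site means with a globally shared year effect and a
  site-specific residual year effect, whose components feed the synchrony
  statistic ICC = T2/(T2+P2).

Productivity uses a binomial likelihood on the number of juveniles among all
captured individuals; apparent survival uses the Cormack-Jolly-Seber m-array
likelihood with one recapture probability per site.  Posteriors are sampled
with an adaptive Metropolis-within-Gibbs scheme (vectorized over conditionally
independent blocks) plus slice updates and a centred/non-centred interweaving
move for the variance scales, which avoids the usual funnel pathology when a
variance component is small.

Priors (overridable via :class:`Priors`): half-Normal(0, 1.5) on the standard
deviations sqrt(T2), sqrt(K2), sqrt(P2); Normal(0, 1.5^2) on mu and mu_k;
Uniform(0, 1) on p.  These are weakly informative on the logit scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._sampler import AdaptiveScale, metropolis_accept, slice_sample
from .ces_io import CaptureHistoryMatrix
from .cjs import build_m_array, marray_loglik

STS = "STS"
ICC = "ICC"
STRUCTURES = (STS, ICC)
RATES = ("survival", "productivity")

#: registry of random-effect structures; a third model variant can be added by
#: registering its name here together with fitter support.
STRUCTURE_REGISTRY: dict[str, str] = {
    STS: "mu + eps_t + eta_k (global mean, additive year and site effects)",
    ICC: "mu_k + eps_t + eta_kt (site means, shared + site-specific year effects)",
}


class ConvergenceError(RuntimeError):
    """Raised when unconverged draws are used without being forced."""


@dataclass(frozen=True)
class ModelStructure:
    """Which rate is modelled and under which random-effect structure."""

    rate: Literal["survival", "productivity"]
    structure: Literal["STS", "ICC"]
    link: str = "logit"

    def __post_init__(self):
        if self.rate not in RATES:
            raise ValueError(f"rate must be one of {RATES}")
        if self.structure not in STRUCTURE_REGISTRY:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.link != "logit":
            raise ValueError("only the logit link is supported")


@dataclass
class Priors:
    """Weakly-informative defaults on the logit scale."""

    sd_scale: float = 1.5      # half-Normal scale for sqrt(T2), sqrt(K2), sqrt(P2)
    mu_sd: float = 1.5         # Normal sd for mu and mu_k
    # p keeps a Uniform(0,1) prior


@dataclass
class MCMCConfig:
    chains: int = 3
    warmup: int = 1000
    draws: int = 1000
    rng_seed: int = 0
    rhat_threshold: float = 1.1
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ValueError("chains, warmup and draws must be positive")


@dataclass
class VarianceDraws:
    """Posterior draws of one fitted model's variance components.

    ``posterior`` maps parameter names to arrays of shape (chains, draws) or
    (chains, draws, dim): always ``T2`` plus ``K2`` (STS) or ``P2`` (ICC),
    with ``mu`` (STS) or ``mu_k`` (ICC), and ``p`` for survival fits.
    ``diagnostics`` holds split-chain rhat per monitored parameter and the
    overall ``converged`` flag (all rhat <= threshold).
    """

    species_code: str
    rate: str
    structure: str
    posterior: dict[str, np.ndarray]
    diagnostics: dict

    def __post_init__(self):
        for key in ("T2", self.second_variance_name):
            if key not in self.posterior:
                raise ValueError(f"posterior missing {key!r}")
            if np.any(self.posterior[key] < 0):
                raise ValueError(f"{key} draws must be >= 0")

    @property
    def second_variance_name(self) -> str:
        return "K2" if self.structure == STS else "P2"

    @property
    def n_draws(self) -> int:
        arr = self.posterior["T2"]
        return int(arr.shape[0] * arr.shape[1])

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    @property
    def meets_minimum_draws(self) -> bool:
        """At least 700 retained draws, the comparison-stage subsample size."""
        return self.n_draws >= 700

    def variance_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened paired draws: (T2, K2) for STS or (T2, P2) for ICC."""
        return (
            self.posterior["T2"].reshape(-1),
            self.posterior[self.second_variance_name].reshape(-1),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: one row per draw per scalar parameter."""
        rows = []
        for name, arr in self.posterior.items():
            C, D = arr.shape[:2]
            if arr.ndim == 2:
                cols = {name: arr}
            else:
                cols = {f"{name}[{i}]": arr[:, :, i] for i in range(arr.shape[2])}
            for pname, values in cols.items():
                chain = np.repeat(np.arange(C), D)
                it = np.tile(np.arange(D), C)
                rows.append(
                    pd.DataFrame(
                        {
                            "species_code": self.species_code,
                            "rate": self.rate,
                            "structure": self.structure,
                            "chain": chain,
                            "iteration": it,
                            "parameter": pname,
                            "value": values.reshape(-1),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, diagnostics: dict | None = None) -> "VarianceDraws":
        species = df["species_code"].iloc[0]
        rate = df["rate"].iloc[0]
        structure = df["structure"].iloc[0]
        posterior: dict[str, np.ndarray] = {}
        vector_parts: dict[str, dict[int, np.ndarray]] = {}
        C = int(df["chain"].max()) + 1
        D = int(df["iteration"].max()) + 1
        for pname, grp in df.groupby("parameter"):
            grp = grp.sort_values(["chain", "iteration"])
            arr = grp["value"].to_numpy().reshape(C, D)
            if "[" in pname:
                base, idx = pname[:-1].split("[")
                vector_parts.setdefault(base, {})[int(idx)] = arr
            else:
                posterior[pname] = arr
        for base, parts in vector_parts.items():
            posterior[base] = np.stack([parts[i] for i in sorted(parts)], axis=2)
        return cls(
            species_code=str(species),
            rate=str(rate),
            structure=str(structure),
            posterior=posterior,
            diagnostics=diagnostics or {"converged": True, "rhat": {}, "restored": True},
        )


# ---------------------------------------------------------------------------
# shared numerics


def _expit(x):
    from scipy.special import expit

    return np.clip(expit(np.asarray(x, dtype=float)), 1e-12, 1.0 - 1e-12)


def _binom_ll_cells(j: np.ndarray, n: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood per cell on the logit scale (constants dropped)."""
    return j * x - n * np.logaddexp(0.0, x)


def _half_normal_lp(s: float, scale: float) -> float:
    return -0.5 * (s / scale) ** 2


def _normal_lp(x, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * (x / sd) ** 2 - np.log(sd)


def _update_sd(sd, effects, prior_scale, rng):
    """Slice-update a variance scale given its effects (centred step)."""
    x = np.asarray(effects, dtype=float).reshape(-1)
    n, ssq = x.size, float(np.sum(np.asarray(effects) ** 2))

    def logf(z):
        s = np.exp(z)
        return -n * z - ssq / (2.0 * s * s) + _half_normal_lp(s, prior_scale) + z

    return float(np.exp(slice_sample(logf, np.log(sd), rng, w=0.8)))


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    import arviz as az

    C, D = x.shape
    if D < 4:
        return float("nan")
    return float(az.rhat(x.astype(float)))


# ---------------------------------------------------------------------------
# productivity (binomial GLMM)


def _prepare_counts(counts: pd.DataFrame):
    needed = {"species_code", "site_id", "year", "n_adult", "n_juvenile"}
    missing = needed - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    species = counts["species_code"].unique()
    if len(species) != 1:
        raise ValueError(f"counts must cover exactly one species, got {sorted(species)}")
    sites = sorted(counts["site_id"].astype(str).unique())
    years = sorted(int(y) for y in counts["year"].unique())
    K, T = len(sites), len(years)
    j = np.zeros((K, T))
    n = np.zeros((K, T))
    site_pos = {s: i for i, s in enumerate(sites)}
    year_pos = {y: i for i, y in enumerate(years)}
    for _, row in counts.iterrows():
        a, b = site_pos[str(row["site_id"])], year_pos[int(row["year"])]
        j[a, b] = row["n_juvenile"]
        n[a, b] = row["n_adult"] + row["n_juvenile"]
    return str(species[0]), sites, years, j, n


def _binomial_chain(j, n, structure, warmup, draws, priors, rng):
    K, T = j.shape
    ps, ms = priors.sd_scale, priors.mu_sd
    sd_t, sd_2 = 0.3, 0.3  # sd_2 is sqrt(K2) for STS, sqrt(P2) for ICC
    eps = 0.01 * rng.standard_normal(T)
    p_hat = (j.sum() + 0.5) / (n.sum() + 1.0)
    mu0 = float(np.log(p_hat / (1 - p_hat)))

    if structure == STS:
        mu = mu0
        eta = 0.01 * rng.standard_normal(K)

        def lin():
            return mu + eps[None, :] + eta[:, None]
    else:
        with np.errstate(divide="ignore"):
            row_rate = (j.sum(axis=1) + 0.5) / (n.sum(axis=1) + 1.0)
        mu_k = np.log(row_rate / (1 - row_rate))
        eta = 0.01 * rng.standard_normal((K, T))

        def lin():
            return mu_k[:, None] + eps[None, :] + eta

    ll = _binom_ll_cells(j, n, lin())

    sc_mu = AdaptiveScale(() if structure == STS else (K,))
    sc_eps = AdaptiveScale((T,))
    sc_eta = AdaptiveScale((K,) if structure == STS else (K, T))
    sc_shift = AdaptiveScale((), init=-1.5)
    sc_shift2 = AdaptiveScale((K,) if structure == ICC else (), init=-1.5)
    sc_shift3 = AdaptiveScale((T,), init=-1.5) if structure == ICC else None
    sc_iw_t = AdaptiveScale((), init=-1.5)
    sc_iw_2 = AdaptiveScale((), init=-1.5)

    n_iter = warmup + draws
    out = {
        "T2": np.empty(draws),
        ("K2" if structure == STS else "P2"): np.empty(draws),
        "rate_mean": np.empty(draws),
    }
    if structure == STS:
        out["mu"] = np.empty(draws)
    else:
        out["mu_k"] = np.empty((draws, K))

    for it in range(n_iter):
        adapting = it < warmup

        # --- mean level
        if structure == STS:
            prop = mu + sc_mu.scale * rng.standard_normal()
            x_new = prop + eps[None, :] + eta[:, None]
            ll_new = _binom_ll_cells(j, n, x_new)
            dl = ll_new.sum() - ll.sum() + _normal_lp(prop, ms) - _normal_lp(mu, ms)
            if metropolis_accept(rng, dl):
                mu, ll = prop, ll_new
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                sc_mu.update(acc, it)
        else:
            prop = mu_k + sc_mu.scale * rng.standard_normal(K)
            x_new = prop[:, None] + eps[None, :] + eta
            ll_new = _binom_ll_cells(j, n, x_new)
            dl = (ll_new - ll).sum(axis=1) + _normal_lp(prop, ms) - _normal_lp(mu_k, ms)
            acc = metropolis_accept(rng, dl)
            mu_k = np.where(acc, prop, mu_k)
            ll = np.where(acc[:, None], ll_new, ll)
            if adapting:
                sc_mu.update(acc, it)

        # --- year effects (columns are conditionally independent)
        prop = eps + sc_eps.scale * rng.standard_normal(T)
        x_new = lin() + (prop - eps)[None, :]
        ll_new = _binom_ll_cells(j, n, x_new)
        dl = (ll_new - ll).sum(axis=0) + _normal_lp(prop, sd_t) - _normal_lp(eps, sd_t)
        acc = metropolis_accept(rng, dl)
        eps = np.where(acc, prop, eps)
        ll = np.where(acc[None, :], ll_new, ll)
        if adapting:
            sc_eps.update(acc, it)

        # --- site / interaction effects
        prop = eta + sc_eta.scale * rng.standard_normal(eta.shape)
        if structure == STS:
            x_new = lin() + (prop - eta)[:, None]
            ll_new = _binom_ll_cells(j, n, x_new)
            dl = (ll_new - ll).sum(axis=1) + _normal_lp(prop, sd_2) - _normal_lp(eta, sd_2)
            acc = metropolis_accept(rng, dl)
            eta = np.where(acc, prop, eta)
            ll = np.where(acc[:, None], ll_new, ll)
        else:
            x_new = lin() + (prop - eta)
            ll_new = _binom_ll_cells(j, n, x_new)
            dl = (ll_new - ll) + _normal_lp(prop, sd_2) - _normal_lp(eta, sd_2)
            acc = metropolis_accept(rng, dl)
            eta = np.where(acc, prop, eta)
            ll = np.where(acc, ll_new, ll)
        if adapting:
            sc_eta.update(acc, it)

        # --- likelihood-invariant translation moves (identifiability mixing)
        if structure == STS:
            d = sc_shift.scale * rng.standard_normal()
            dl = (
                _normal_lp(mu + d, ms) - _normal_lp(mu, ms)
                + (_normal_lp(eps - d, sd_t) - _normal_lp(eps, sd_t)).sum()
            )
            if metropolis_accept(rng, dl):
                mu, eps = mu + d, eps - d
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                sc_shift.update(acc, it)
            d = sc_shift2.scale * rng.standard_normal()
            dl = (
                _normal_lp(mu + d, ms) - _normal_lp(mu, ms)
                + (_normal_lp(eta - d, sd_2) - _normal_lp(eta, sd_2)).sum()
            )
            if metropolis_accept(rng, dl):
                mu, eta = mu + d, eta - d
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                sc_shift2.update(acc, it)
        else:
            # global shift mu_k <-> eps
            d = sc_shift.scale * rng.standard_normal()
            dl = (
                (_normal_lp(mu_k + d, ms) - _normal_lp(mu_k, ms)).sum()
                + (_normal_lp(eps - d, sd_t) - _normal_lp(eps, sd_t)).sum()
            )
            if metropolis_accept(rng, dl):
                mu_k, eps = mu_k + d, eps - d
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                sc_shift.update(acc, it)
            # per-site shift mu_k[k] <-> eta[k, :]
            d = sc_shift2.scale * rng.standard_normal(K)
            dl = (
                _normal_lp(mu_k + d, ms) - _normal_lp(mu_k, ms)
                + (_normal_lp(eta - d[:, None], sd_2) - _normal_lp(eta, sd_2)).sum(axis=1)
            )
            acc = metropolis_accept(rng, dl)
            mu_k = np.where(acc, mu_k + d, mu_k)
            eta = np.where(acc[:, None], eta - d[:, None], eta)
            if adapting:
                sc_shift2.update(acc, it)
            # per-year shift eps[t] <-> eta[:, t]
            d = sc_shift3.scale * rng.standard_normal(T)
            dl = (
                _normal_lp(eps + d, sd_t) - _normal_lp(eps, sd_t)
                + (_normal_lp(eta - d[None, :], sd_2) - _normal_lp(eta, sd_2)).sum(axis=0)
            )
            acc = metropolis_accept(rng, dl)
            eps = np.where(acc, eps + d, eps)
            eta = np.where(acc[None, :], eta - d[None, :], eta)
            if adapting:
                sc_shift3.update(acc, it)

        # --- variance scales: centred slice update ...
        sd_t = _update_sd(sd_t, eps, ps, rng)
        sd_2 = _update_sd(sd_2, eta, ps, rng)

        # ... interleaved with a non-centred rescaling move
        z = sc_iw_t.scale * rng.standard_normal()
        s_new = sd_t * np.exp(z)
        eps_new = eps * (s_new / sd_t)
        ll_new = _binom_ll_cells(j, n, lin() + (eps_new - eps)[None, :])
        dl = (
            ll_new.sum() - ll.sum()
            + _half_normal_lp(s_new, ps) - _half_normal_lp(sd_t, ps)
            + z  # Jacobian of the log-scale random walk on sigma
        )
        if metropolis_accept(rng, dl):
            sd_t, eps, ll = s_new, eps_new, ll_new
            acc = 1.0
        else:
            acc = 0.0
        if adapting:
            sc_iw_t.update(acc, it)

        z = sc_iw_2.scale * rng.standard_normal()
        s_new = sd_2 * np.exp(z)
        eta_new = eta * (s_new / sd_2)
        delta = (eta_new - eta)[:, None] if structure == STS else (eta_new - eta)
        ll_new = _binom_ll_cells(j, n, lin() + delta)
        dl = (
            ll_new.sum() - ll.sum()
            + _half_normal_lp(s_new, ps) - _half_normal_lp(sd_2, ps)
            + z
        )
        if metropolis_accept(rng, dl):
            sd_2, eta, ll = s_new, eta_new, ll_new
            acc = 1.0
        else:
            acc = 0.0
        if adapting:
            sc_iw_2.update(acc, it)

        if it >= warmup:
            d = it - warmup
            out["T2"][d] = sd_t**2
            out["K2" if structure == STS else "P2"][d] = sd_2**2
            out["rate_mean"][d] = _expit(lin()).mean()
            if structure == STS:
                out["mu"][d] = mu
            else:
                out["mu_k"][d] = mu_k
    return out


def fit_productivity(
    counts: pd.DataFrame,
    structure: ModelStructure | str,
    mcmc: MCMCConfig | None = None,
) -> VarianceDraws:
    """Fit the binomial proportion-juvenile model for one species.

    ``counts`` is a site-year count table (one species); the likelihood is
    n_juvenile ~ Binomial(n_adult + n_juvenile, rate[k, t]) with logit(rate)
    given by the requested structure.  Requires at least two distinct years
    (and, for the ICC structure, at least two sites).
    """
    struct = structure.structure if isinstance(structure, ModelStructure) else str(structure)
    if isinstance(structure, ModelStructure) and structure.rate != "productivity":
        raise ValueError("structure.rate must be 'productivity'")
    if struct not in STRUCTURE_REGISTRY:
        raise ValueError(f"unknown structure {struct!r}")
    mcmc = mcmc or MCMCConfig()
    species, sites, years, j, n = _prepare_counts(counts)
    if len(years) < 2:
        raise ValueError("at least 2 years are required; the structure is unidentifiable with one")
    if struct == ICC and len(sites) < 2:
        raise ValueError("the ICC structure requires at least 2 sites")

    ss = np.random.SeedSequence(mcmc.rng_seed)
    chains = []
    for child in ss.spawn(mcmc.chains):
        rng = np.random.default_rng(child)
        chains.append(_binomial_chain(j, n, struct, mcmc.warmup, mcmc.draws, mcmc.priors, rng))
    posterior = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    return _finalize_draws(species, "productivity", struct, posterior, mcmc)


# ---------------------------------------------------------------------------
# apparent survival (CJS)


def _prepare_histories(histories: list[CaptureHistoryMatrix]):
    if not histories:
        raise ValueError("no capture histories supplied")
    species = {c.species_code for c in histories}
    if len(species) != 1:
        raise ValueError(f"histories must cover exactly one species, got {sorted(species)}")
    years0 = histories[0].years
    for chm in histories[1:]:
        if not np.array_equal(chm.years, years0):
            raise ValueError(
                "all sites must share one retained year vector for the survival model; "
                f"site {chm.site_id} differs from site {histories[0].site_id}"
            )
    histories = sorted(histories, key=lambda c: c.site_id)
    T = years0.size
    K = len(histories)
    m = np.zeros((K, T - 1, T), dtype=np.int64)
    never = np.zeros((K, T - 1), dtype=np.int64)
    for k, chm in enumerate(histories):
        m[k], never[k] = build_m_array(chm)
    return species.pop(), [c.site_id for c in histories], years0, m, never


def _cjs_chain(m, never, structure, warmup, draws, priors, rng, fix_p):
    K, Tm1, _ = m.shape
    ps, ms = priors.sd_scale, priors.mu_sd
    sd_t, sd_2 = 0.3, 0.3
    eps = 0.01 * rng.standard_normal(Tm1)
    # crude initial recapture rate: immediate recaptures / releases
    rel = m.sum(axis=(1, 2)) + never.sum(axis=1)
    imm = np.array([np.trace(m[k], offset=1) for k in range(K)])
    p0 = np.clip((imm.sum() + 1.0) / (rel.sum() + 2.0) * 2.0, 0.05, 0.9)
    logit_p = np.full(K, np.log(p0 / (1 - p0)))
    if fix_p is not None:
        if not (0 < fix_p <= 1):
            raise ValueError("fix_p must be in (0, 1]")
        p_fixed = np.full(K, float(fix_p))

    if structure == STS:
        mu = 0.0
        eta = 0.01 * rng.standard_normal(K)

        def lin():
            return mu + eps[None, :] + eta[:, None]
    else:
        mu_k = 0.01 * rng.standard_normal(K)
        eta = 0.01 * rng.standard_normal((K, Tm1))

        def lin():
            return mu_k[:, None] + eps[None, :] + eta

    def p_vec():
        return p_fixed if fix_p is not None else _expit(logit_p)

    def ll_sites(phi=None, p=None):
        return marray_loglik(m, never, phi if phi is not None else _expit(lin()),
                             p if p is not None else p_vec())

    ll = ll_sites()  # per-site vector

    sc_mu = AdaptiveScale(() if structure == STS else (K,))
    sc_eps = AdaptiveScale((Tm1,))
    sc_eta = AdaptiveScale((K,) if structure == STS else (K, Tm1))
    sc_p = AdaptiveScale((K,))
    sc_shift = AdaptiveScale((), init=-1.5)
    sc_shift2 = AdaptiveScale((K,) if structure == ICC else (), init=-1.5)
    sc_shift3 = AdaptiveScale((Tm1,), init=-1.5) if structure == ICC else None
    sc_iw_t = AdaptiveScale((), init=-1.5)
    sc_iw_2 = AdaptiveScale((), init=-1.5)

    out = {
        "T2": np.empty(draws),
        ("K2" if structure == STS else "P2"): np.empty(draws),
        "rate_mean": np.empty(draws),
        "p": np.empty((draws, K)),
    }
    if structure == STS:
        out["mu"] = np.empty(draws)
    else:
        out["mu_k"] = np.empty((draws, K))

    for it in range(warmup + draws):
        adapting = it < warmup

        # --- mean level
        if structure == STS:
            prop = mu + sc_mu.scale * rng.standard_normal()
            ll_new = ll_sites(phi=_expit(prop + eps[None, :] + eta[:, None]))
            dl = ll_new.sum() - ll.sum() + _normal_lp(prop, ms) - _normal_lp(mu, ms)
            if metropolis_accept(rng, dl):
                mu, ll = prop, ll_new
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                sc_mu.update(acc, it)
        else:
            prop = mu_k + sc_mu.scale * rng.standard_normal(K)
            ll_new = ll_sites(phi=_expit(prop[:, None] + eps[None, :] + eta))
            dl = ll_new - ll + _normal_lp(prop, ms) - _normal_lp(mu_k, ms)
            acc = metropolis_accept(rng, dl)
            mu_k = np.where(acc, prop, mu_k)
            ll = np.where(acc, ll_new, ll)
            if adapting:
                sc_mu.update(acc, it)

        # --- year effects: sequential scalars (each touches all sites)
        accs = np.zeros(Tm1)
        for t in range(Tm1):
            prop_t = eps[t] + sc_eps.scale[t] * rng.standard_normal()
            eps_new = eps.copy()
            eps_new[t] = prop_t
            x = lin() + (eps_new - eps)[None, :]
            ll_new = ll_sites(phi=_expit(x))
            dl = ll_new.sum() - ll.sum() + _normal_lp(prop_t, sd_t) - _normal_lp(eps[t], sd_t)
            if metropolis_accept(rng, dl):
                eps, ll = eps_new, ll_new
                accs[t] = 1.0
        if adapting:
            sc_eps.update(accs, it)

        # --- site / interaction effects (sites are independent)
        if structure == STS:
            prop = eta + sc_eta.scale * rng.standard_normal(K)
            ll_new = ll_sites(phi=_expit(lin() + (prop - eta)[:, None]))
            dl = ll_new - ll + _normal_lp(prop, sd_2) - _normal_lp(eta, sd_2)
            acc = metropolis_accept(rng, dl)
            eta = np.where(acc, prop, eta)
            ll = np.where(acc, ll_new, ll)
            if adapting:
                sc_eta.update(acc, it)
        else:
            acc_mat = np.zeros((K, Tm1))
            for t in range(Tm1):
                prop_col = eta[:, t] + sc_eta.scale[:, t] * rng.standard_normal(K)
                eta_new = eta.copy()
                eta_new[:, t] = prop_col
                ll_new = ll_sites(phi=_expit(lin() + (eta_new - eta)))
                dl = ll_new - ll + _normal_lp(prop_col, sd_2) - _normal_lp(eta[:, t], sd_2)
                acc = metropolis_accept(rng, dl)
                eta[:, t] = np.where(acc, prop_col, eta[:, t])
                ll = np.where(acc, ll_new, ll)
                acc_mat[:, t] = acc
            if adapting:
                sc_eta.update(acc_mat, it)

        # --- recapture probabilities
        if fix_p is None:
            prop = logit_p + sc_p.scale * rng.standard_normal(K)
            ll_new = ll_sites(p=_expit(prop))
            # Uniform(0,1) prior on p => logistic density on logit_p
            lp_new = prop - 2.0 * np.logaddexp(0.0, prop)
            lp_old = logit_p - 2.0 * np.logaddexp(0.0, logit_p)
            dl = ll_new - ll + lp_new - lp_old
            acc = metropolis_accept(rng, dl)
            logit_p = np.where(acc, prop, logit_p)
            ll = np.where(acc, ll_new, ll)
            if adapting:
                sc_p.update(acc, it)

        # --- likelihood-invariant translation moves
        if structure == STS:
            d = sc_shift.scale * rng.standard_normal()
            dl = (
                _normal_lp(mu + d, ms) - _normal_lp(mu, ms)
                + (_normal_lp(eps - d, sd_t) - _normal_lp(eps, sd_t)).sum()
            )
            if metropolis_accept(rng, dl):
                mu, eps = mu + d, eps - d
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                sc_shift.update(acc, it)
            d = sc_shift2.scale * rng.standard_normal()
            dl = (
                _normal_lp(mu + d, ms) - _normal_lp(mu, ms)
                + (_normal_lp(eta - d, sd_2) - _normal_lp(eta, sd_2)).sum()
            )
            if metropolis_accept(rng, dl):
                mu, eta = mu + d, eta - d
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                sc_shift2.update(acc, it)
        else:
            d = sc_shift.scale * rng.standard_normal()
            dl = (
                (_normal_lp(mu_k + d, ms) - _normal_lp(mu_k, ms)).sum()
                + (_normal_lp(eps - d, sd_t) - _normal_lp(eps, sd_t)).sum()
            )
            if metropolis_accept(rng, dl):
                mu_k, eps = mu_k + d, eps - d
                acc = 1.0
            else:
                acc = 0.0
            if adapting:
                sc_shift.update(acc, it)
            d = sc_shift2.scale * rng.standard_normal(K)
            dl = (
                _normal_lp(mu_k + d, ms) - _normal_lp(mu_k, ms)
                + (_normal_lp(eta - d[:, None], sd_2) - _normal_lp(eta, sd_2)).sum(axis=1)
            )
            acc = metropolis_accept(rng, dl)
            mu_k = np.where(acc, mu_k + d, mu_k)
            eta = np.where(acc[:, None], eta - d[:, None], eta)
            if adapting:
                sc_shift2.update(acc, it)
            d = sc_shift3.scale * rng.standard_normal(Tm1)
            dl = (
                _normal_lp(eps + d, sd_t) - _normal_lp(eps, sd_t)
                + (_normal_lp(eta - d[None, :], sd_2) - _normal_lp(eta, sd_2)).sum(axis=0)
            )
            acc = metropolis_accept(rng, dl)
            eps = np.where(acc, eps + d, eps)
            eta = np.where(acc[None, :], eta - d[None, :], eta)
            if adapting:
                sc_shift3.update(acc, it)

        # --- variance scales: centred slice + non-centred rescale
        sd_t = _update_sd(sd_t, eps, ps, rng)
        sd_2 = _update_sd(sd_2, eta, ps, rng)

        z = sc_iw_t.scale * rng.standard_normal()
        s_new = sd_t * np.exp(z)
        eps_new = eps * (s_new / sd_t)
        ll_new = ll_sites(phi=_expit(lin() + (eps_new - eps)[None, :]))
        dl = (
            ll_new.sum() - ll.sum()
            + _half_normal_lp(s_new, ps) - _half_normal_lp(sd_t, ps) + z
        )
        if metropolis_accept(rng, dl):
            sd_t, eps, ll = s_new, eps_new, ll_new
            acc = 1.0
        else:
            acc = 0.0
        if adapting:
            sc_iw_t.update(acc, it)

        z = sc_iw_2.scale * rng.standard_normal()
        s_new = sd_2 * np.exp(z)
        eta_new = eta * (s_new / sd_2)
        delta = (eta_new - eta)[:, None] if structure == STS else (eta_new - eta)
        ll_new = ll_sites(phi=_expit(lin() + delta))
        dl = (
            ll_new.sum() - ll.sum()
            + _half_normal_lp(s_new, ps) - _half_normal_lp(sd_2, ps) + z
        )
        if metropolis_accept(rng, dl):
            sd_2, eta, ll = s_new, eta_new, ll_new
            acc = 1.0
        else:
            acc = 0.0
        if adapting:
            sc_iw_2.update(acc, it)

        if it >= warmup:
            d = it - warmup
            out["T2"][d] = sd_t**2
            out["K2" if structure == STS else "P2"][d] = sd_2**2
            out["rate_mean"][d] = _expit(lin()).mean()
            out["p"][d] = p_vec()
            if structure == STS:
                out["mu"][d] = mu
            else:
                out["mu_k"][d] = mu_k
    return out


def fit_survival(
    histories: list[CaptureHistoryMatrix],
    structure: ModelStructure | str,
    mcmc: MCMCConfig | None = None,
    fix_p: float | None = None,
) -> VarianceDraws:
    """Fit the CJS apparent-survival model for one species across its sites.

    The likelihood conditions on first capture (m-array form); survival per
    site-interval follows the requested logit-scale structure; recapture
    probability is one Uniform(0,1) parameter per site (or fixed via
    ``fix_p``).  Requires >= 2 sites, >= 3 years, and at least one recapture.
    """
    struct = structure.structure if isinstance(structure, ModelStructure) else str(structure)
    if isinstance(structure, ModelStructure) and structure.rate != "survival":
        raise ValueError("structure.rate must be 'survival'")
    if struct not in STRUCTURE_REGISTRY:
        raise ValueError(f"unknown structure {struct!r}")
    mcmc = mcmc or MCMCConfig()
    species, sites, years, m, never = _prepare_histories(histories)
    if years.size < 3:
        raise ValueError("the CJS model needs >= 3 years (two intervals) to separate phi from p")
    if len(sites) < 2:
        raise ValueError("at least 2 sites are required")
    if m.sum() == 0 and fix_p is None:
        raise ValueError("no recaptures anywhere: phi and p are jointly unidentifiable")

    ss = np.random.SeedSequence(mcmc.rng_seed)
    chains = []
    for child in ss.spawn(mcmc.chains):
        rng = np.random.default_rng(child)
        chains.append(
            _cjs_chain(m, never, struct, mcmc.warmup, mcmc.draws, mcmc.priors, rng, fix_p)
        )
    posterior = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    return _finalize_draws(species, "survival", struct, posterior, mcmc)


# ---------------------------------------------------------------------------


def _finalize_draws(species, rate, struct, posterior, mcmc: MCMCConfig) -> VarianceDraws:
    monitored = {"T2": posterior["T2"], ("K2" if struct == STS else "P2"): posterior[
        "K2" if struct == STS else "P2"
    ]}
    if "mu" in posterior:
        monitored["mu"] = posterior["mu"]
    if "mu_k" in posterior:
        monitored["mu_k_mean"] = posterior["mu_k"].mean(axis=2)
    if "p" in posterior:
        monitored["p_mean"] = posterior["p"].mean(axis=2)
    rhat = {k: _split_rhat(v) for k, v in monitored.items()}
    finite = [v for v in rhat.values() if np.isfinite(v)]
    converged = bool(finite) and all(v <= mcmc.rhat_threshold for v in finite)
    diagnostics = {
        "rhat": rhat,
        "converged": converged,
        "rhat_threshold": mcmc.rhat_threshold,
        "chains": mcmc.chains,
        "warmup": mcmc.warmup,
        "draws_per_chain": mcmc.draws,
        "priors": dataclasses.asdict(mcmc.priors),
    }
    return VarianceDraws(
        species_code=species,
        rate=rate,
        structure=struct,
        posterior=posterior,
        diagnostics=diagnostics,
    )
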