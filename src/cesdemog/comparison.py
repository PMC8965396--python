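"""Cross-species comparison of the two demographic rates, and the quadrant map.

For each species, ``n_sub`` posterior draws of a statistic (STS or ICC) are
subsampled without replacement from the productivity fit and, independently,
from the survival fit; the two subsamples are paired by position and
differenced (productivity minus survival).  Averaging the differences across
species per position yields a distribution of across-species mean differences,
summarized by its mean and 2.5/97.5% quantiles; the difference is significant
when that interval excludes zero.

The quadrant framework crosses spatial-vs-annual dominance (STS above/below
0.5) with synchrony (ICC above/below 0.5):

    i   STS > 0.5, ICC < 0.5   spatial, asynchronous  -> local action at poor sites
    ii  STS > 0.5, ICC >= 0.5  spatial, synchronous   -> local action in poor years
    iii STS <= 0.5, ICC < 0.5  annual, asynchronous   -> local action at poor sites-years
    iv  STS <= 0.5, ICC >= 0.5 annual, synchronous    -> widespread action in poor years

Exact 0.5 ties (never observed in practice) go to the annual side for STS and
the synchronous side for ICC, per the table above.
"""

from __future__ import annotations

import zlib
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import SpeciesDecomposition

QUADRANTS = ("i", "ii", "iii", "iv")

#: default subsample size: the smallest per-species posterior sample the
#: cross-species comparison was designed around
DEFAULT_N_SUB = 700


@dataclass
class ComparisonResult:
    """Across-species mean differences (productivity - survival) of a statistic."""

    statistic: str
    n_sub: int
    diffs: np.ndarray          # (n_sub,) across-species mean differences
    mean: float
    q_low: float
    q_high: float
    significant: bool
    n_species: int
    rng_seed: int | None

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "n_sub": self.n_sub,
            "n_species": self.n_species,
            "mean_difference": self.mean,
            "q2.5": self.q_low,
            "q97.5": self.q_high,
            "significant": self.significant,
        }


def _subsample_indices(
    n_total: int, n_sub: int, species: str, rate: str, rng_seed: int | None
) -> np.ndarray:
    """Deterministic without-replacement indices, keyed by (species, rate).

    Keying the stream by the rate label (not the argument position) makes the
    comparison exactly antisymmetric under swapping the two rates.  With
    ``n_sub == n_total`` the identity order is used, so the full-draw statistic
    is reproduced with no seed dependence.
    """
    if n_sub == n_total:
        return np.arange(n_total)
    key = zlib.crc32(f"{species}:{rate}".encode())
    rng = np.random.default_rng(np.random.SeedSequence([0 if rng_seed is None else rng_seed, key]))
    return rng.choice(n_total, size=n_sub, replace=False)


def compare_rates(
    prod: Mapping[str, SpeciesDecomposition],
    surv: Mapping[str, SpeciesDecomposition],
    statistic: str | None = None,
    n_sub: int = DEFAULT_N_SUB,
    rng_seed: int | None = 0,
    auto_reduce: bool = False,
) -> ComparisonResult:
    """Subsample, difference and average a statistic across species.

    ``prod`` and ``surv`` map species codes to decompositions of the same
    statistic for the productivity and survival rate respectively; both must
    cover the same species.  With ``auto_reduce`` the subsample size drops to
    the smallest per-species draw count (the minimum-iterations rule);
    otherwise a species with fewer than ``n_sub`` draws is an error.
    """
    if set(prod) != set(surv):
        raise ValueError(
            f"species mismatch: {sorted(set(prod) ^ set(surv))} present for only one rate"
        )
    if not prod:
        raise ValueError("no species to compare")
    species = sorted(prod)
    stats = {d.statistic for d in prod.values()} | {d.statistic for d in surv.values()}
    if len(stats) != 1:
        raise ValueError(f"mixed statistics {sorted(stats)} in one comparison")
    stat = stats.pop()
    if statistic is not None and statistic != stat:
        raise ValueError(f"requested {statistic} but decompositions hold {stat}")

    if auto_reduce:
        n_sub = min(n_sub, *(d.n_draws for m in (prod, surv) for d in m.values()))
    short = [
        sp
        for sp in species
        if prod[sp].n_draws < n_sub or surv[sp].n_draws < n_sub
    ]
    if short:
        raise ValueError(
            f"species {short} have fewer than n_sub={n_sub} draws "
            "(use auto_reduce=True to apply the minimum-iterations rule)"
        )

    per_species = np.empty((len(species), n_sub))
    for i, sp in enumerate(species):
        ip = _subsample_indices(prod[sp].n_draws, n_sub, sp, prod[sp].rate, rng_seed)
        iv = _subsample_indices(surv[sp].n_draws, n_sub, sp, surv[sp].rate, rng_seed)
        per_species[i] = prod[sp].values[ip] - surv[sp].values[iv]
    diffs = per_species.mean(axis=0)
    q_low, q_high = np.quantile(diffs, [0.025, 0.975])
    return ComparisonResult(
        statistic=stat,
        n_sub=int(n_sub),
        diffs=diffs,
        mean=float(diffs.mean()),
        q_low=float(q_low),
        q_high=float(q_high),
        significant=bool(q_low > 0 or q_high < 0),
        n_species=len(species),
        rng_seed=rng_seed,
    )


@dataclass
class QuadrantAssignment:
    """A species-rate point in the STS x ICC plane and its quadrant."""

    species_code: str
    rate: str
    sts_mean: float
    icc_mean: float
    quadrant: str

    def __post_init__(self):
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"quadrant must be one of {QUADRANTS}")


def classify_quadrant(
    sts: SpeciesDecomposition, icc: SpeciesDecomposition
) -> QuadrantAssignment:
    """Place one species-rate in the quadrant framework from posterior means."""
    if sts.statistic != "STS" or icc.statistic != "ICC":
        raise TypeError("arguments must be an STS and an ICC decomposition, in that order")
    if sts.species_code != icc.species_code or sts.rate != icc.rate:
        raise ValueError(
            f"decompositions disagree: {sts.species_code}/{sts.rate} vs "
            f"{icc.species_code}/{icc.rate}"
        )
    s, c = sts.mean, icc.mean
    if s > 0.5:
        quadrant = "i" if c < 0.5 else "ii"
    else:
        quadrant = "iii" if c < 0.5 else "iv"
    return QuadrantAssignment(
        species_code=sts.species_code,
        rate=sts.rate,
        sts_mean=s,
        icc_mean=c,
        quadrant=quadrant,
    )


def quadrant_table(assignments: list[QuadrantAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_code": a.species_code,
                "rate": a.rate,
                "sts_mean": a.sts_mean,
                "icc_mean": a.icc_mean,
                "quadrant": a.quadrant,
            }
            for a in assignments
        ]
    )


def quadrant_counts(assignments: list[QuadrantAssignment]) -> dict[str, int]:
    counts = {q: 0 for q in QUADRANTS}
    for a in assignments:
        counts[a.quadrant] += 1
    return counts
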