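"""Per-draw variance-decomposition statistics.

* ``STS = K2 / (T2 + K2)`` — the fraction of combined site-plus-year variance
  that is spatial; values above 0.5 mean a rate differs more between sites
  than between years.
* ``ICC = T2 / (T2 + P2)`` — the fraction of temporal variance shared across
  all sites; values near 1 mean good and bad years coincide across sites
  (spatial synchrony).

Both are computed draw by draw from the posterior of the matching model
structure and then summarized — never as a ratio of posterior-mean variances.
Draws with a zero denominator carry no information about a ratio and are
dropped (and counted) rather than mapped to an arbitrary value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ICC, STS, ConvergenceError, VarianceDraws


@dataclass
class SpeciesDecomposition:
    """Posterior draws of one statistic (STS or ICC) for one species-rate."""

    species_code: str
    rate: str
    statistic: str
    values: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.size and (np.any(self.values < 0) or np.any(self.values > 1)):
            raise ValueError("per-draw values must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))

    @property
    def n_draws(self) -> int:
        return self.values.size

    def summary(self) -> dict:
        lo, hi = np.quantile(self.values, [0.025, 0.975])
        return {
            "species_code": self.species_code,
            "rate": self.rate,
            "statistic": self.statistic,
            "mean": self.mean,
            "sd": self.sd,
            "q2.5": float(lo),
            "q97.5": float(hi),
            "n_draws": self.n_draws,
            "n_dropped": self.n_dropped,
        }


def _ratio_decomposition(
    draws: VarianceDraws, statistic: str, expected_structure: str, force: bool
) -> SpeciesDecomposition:
    if draws.structure != expected_structure:
        raise TypeError(
            f"{statistic} requires draws from the {expected_structure} structure, "
            f"got {draws.structure}"
        )
    if not draws.converged and not force:
        raise ConvergenceError(
            f"{draws.species_code}/{draws.rate}/{draws.structure}: sampler did not converge "
            f"(rhat {draws.diagnostics.get('rhat')}); pass force=True to use anyway"
        )
    t2, other = draws.variance_pairs()
    if statistic == "STS":
        num, denom = other, t2 + other      # K2 / (T2 + K2)
    else:
        num, denom = t2, t2 + other         # T2 / (T2 + P2)
    keep = denom > 0
    values = num[keep] / denom[keep]
    return SpeciesDecomposition(
        species_code=draws.species_code,
        rate=draws.rate,
        statistic=statistic,
        values=values,
        n_dropped=int((~keep).sum()),
    )


def compute_sts(draws: VarianceDraws, force: bool = False) -> SpeciesDecomposition:
    """Per-draw STS = K2/(T2+K2) from an STS-structure fit."""
    return _ratio_decomposition(draws, "STS", STS, force)


def compute_icc(draws: VarianceDraws, force: bool = False) -> SpeciesDecomposition:
    """Per-draw ICC = T2/(T2+P2) from an ICC-structure fit."""
    return _ratio_decomposition(draws, "ICC", ICC, force)


def decomposition_table(decs: list[SpeciesDecomposition]) -> pd.DataFrame:
    """Tidy per-draw table: species, rate, statistic, draw index, value."""
    frames = [
        pd.DataFrame(
            {
                "species_code": d.species_code,
                "rate": d.rate,
                "statistic": d.statistic,
                "draw": np.arange(d.n_draws),
                "value": d.values,
            }
        )
        for d in decs
    ]
    return pd.concat(frames, ignore_index=True)


def summary_table(decs: list[SpeciesDecomposition]) -> pd.DataFrame:
    return pd.DataFrame([d.summary() for d in decs])
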