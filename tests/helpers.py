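"""Independent brute-force oracles used by the test suite.

Everything here deliberately re-derives results by exhaustive counting or
enumeration, without touching the package's own implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def brute_force_filter(
    records: pd.DataFrame,
    effort: pd.DataFrame,
    min_years: int,
    min_visits: int,
    min_adults: int,
    min_juveniles: int,
) -> pd.DataFrame:
    """Re-apply the three CES rules by exhaustive counting over plain rows."""
    visits = {
        (str(r.site_id), int(r.year)): int(r.n_visits) for r in effort.itertuples()
    }
    qual: dict[str, set[int]] = {}
    for (site, year), n in visits.items():
        if n >= min_visits:
            qual.setdefault(site, set()).add(year)
    good_sites = {s for s, ys in qual.items() if len(ys) >= min_years}

    kept = []
    for row in records.itertuples():
        site, year = str(row.site_id), int(row.year)
        if site in good_sites and year in qual[site]:
            kept.append(row.Index)
    step_b = records.loc[kept]

    pair_ok = set()
    for (sp, site), grp in step_b.groupby(["species_code", "site_id"]):
        adults = set(grp[grp.age_class == "adult"].ring_id)
        juvs = set(grp[grp.age_class == "juvenile"].ring_id)
        if len(adults) >= min_adults and len(juvs) >= min_juveniles:
            pair_ok.add((sp, site))
    kept = [
        i
        for i, row in zip(step_b.index, step_b.itertuples())
        if (row.species_code, row.site_id) in pair_ok
    ]
    return step_b.loc[kept]


def brute_force_counts(records: pd.DataFrame) -> dict[tuple, tuple[int, int]]:
    """Distinct adult/juvenile individuals per (species, site, year) via sets."""
    out: dict[tuple, tuple[set, set]] = {}
    seen: dict[tuple, str] = {}
    for row in records.itertuples():
        key = (row.species_code, row.site_id, int(row.year))
        ind = (key, row.ring_id)
        if ind in seen:
            continue
        seen[ind] = row.age_class
        a, j = out.setdefault(key, (set(), set()))
        (a if row.age_class == "adult" else j).add(row.ring_id)
    return {k: (len(a), len(j)) for k, (a, j) in out.items()}


def cjs_prob_by_death_time(history, first_idx: int, phi, p: float) -> float:
    """Exact CJS history probability by summing over the death interval."""
    h = list(history)
    T = len(h)
    phi = list(np.broadcast_to(phi, (T - 1,)))
    last = max(i for i, v in enumerate(h) if v)
    total = 0.0
    for alive_until in range(last, T):  # last occasion the bird is alive for
        pr = 1.0
        for t in range(first_idx, alive_until):
            pr *= phi[t]
        if alive_until < T - 1:
            pr *= 1.0 - phi[alive_until]
        for t in range(first_idx + 1, alive_until + 1):
            pr *= p if h[t] else (1.0 - p)
        total += pr
    return total


def all_continuations(T: int, first_idx: int):
    """Every possible post-first-capture history of length T."""
    tail = T - first_idx - 1
    for bits in itertools.product([0, 1], repeat=tail):
        h = [0] * T
        h[first_idx] = 1
        h[first_idx + 1 :] = bits
        yield h


def subsample_mean_diffs(prod_values, surv_values, index_pairs) -> np.ndarray:
    """Independent oracle for the subsample-and-average comparison.

    ``index_pairs`` maps species -> (prod_indices, surv_indices); returns the
    per-position across-species mean differences.
    """
    per = []
    for sp, (ip, iv) in index_pairs.items():
        per.append(np.asarray(prod_values[sp])[ip] - np.asarray(surv_values[sp])[iv])
    return np.mean(per, axis=0)
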