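"""Reading, validation, filtering and reshaping of constant-effort ringing records.

The raw currency is one row per capture event: an individually ringed bird of a
given species and age class (adult or juvenile) caught at a site on a numbered
within-season visit in a calendar year.  This module turns such tables into the
two model-ready structures used downstream:

* site-year counts of distinct adult and juvenile individuals (productivity), and
* per-individual binary capture histories over a site's year vector (survival).

Filtering follows the constant-effort-site (CES) protocol: only site-years with
sufficient visit effort, sites operating enough qualifying years, and
species-site pairs with enough captured individuals are retained.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ADULT = "adult"
JUVENILE = "juvenile"
AGE_CLASSES = (ADULT, JUVENILE)

#: canonical record fields, in canonical column order
RECORD_FIELDS = ("ring_id", "species_code", "site_id", "year", "visit", "age_class")

#: default study window (closed interval of calendar years)
DEFAULT_STUDY_WINDOW = (2004, 2014)

#: default CES inclusion thresholds
DEFAULT_MIN_YEARS = 5
DEFAULT_MIN_VISITS = 8
DEFAULT_MIN_ADULTS = 25
DEFAULT_MIN_JUVENILES = 25


class FormatError(ValueError):
    """The input table does not have the expected columns/shape."""


class RecordValidationError(ValueError):
    """One or more rows violate record invariants.

    Parameters
    ----------
    message : str
    lines : list of (line_number, description)
        1-based physical line numbers in the source file (header is line 1).
    """

    def __init__(self, message: str, lines: list[tuple[int, str]] | None = None):
        self.lines = lines or []
        if self.lines:
            detail = "; ".join(f"line {n}: {why}" for n, why in self.lines[:20])
            if len(self.lines) > 20:
                detail += f"; ... ({len(self.lines) - 20} more)"
            message = f"{message} [{detail}]"
        super().__init__(message)


class MissingEffortError(KeyError):
    """A (site, year) present in the records has no row in the visit-effort table."""


@dataclass
class RecordSet:
    """An ordered, validated collection of ringing records.

    ``records`` is a DataFrame with the canonical columns of
    :data:`RECORD_FIELDS`.  Duplicate ``(ring_id, site_id, year, visit)`` rows
    are collapsed to the first occurrence; row order is otherwise preserved.
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in RECORD_FIELDS if c not in df.columns]
        if missing:
            raise FormatError(f"records missing mandatory columns: {missing}")
        df = df.loc[:, list(RECORD_FIELDS)].copy()
        df["year"] = df["year"].astype(np.int64)
        df["visit"] = df["visit"].astype(np.int64)
        for col in ("ring_id", "species_code", "site_id", "age_class"):
            df[col] = df[col].astype(str)
        bad_age = ~df["age_class"].isin(AGE_CLASSES)
        if bad_age.any():
            raise RecordValidationError(
                "age_class must be 'adult' or 'juvenile'",
                [(int(i) + 2, f"age_class={df['age_class'].iloc[i]!r}")
                 for i in np.flatnonzero(bad_age.to_numpy())],
            )
        if (df["visit"] < 1).any():
            raise RecordValidationError("visit indices are 1-based positive integers")
        df = df.drop_duplicates(subset=["ring_id", "site_id", "year", "visit"], keep="first")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def species(self) -> list[str]:
        return sorted(self.records["species_code"].unique())

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _load_format_config(format_config) -> dict[str, str]:
    """Resolve a column-mapping config (dict, YAML/JSON path, or None)."""
    if format_config is None:
        return {f: f for f in RECORD_FIELDS}
    if isinstance(format_config, Mapping):
        mapping = dict(format_config)
    else:
        text = Path(format_config).read_text()
        mapping = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(mapping, Mapping):
            raise FormatError(f"format config {format_config!r} is not a key-value mapping")
    out = {f: f for f in RECORD_FIELDS}
    for key, col in mapping.items():
        if key not in RECORD_FIELDS:
            raise FormatError(f"unknown record field {key!r} in format config")
        out[key] = str(col)
    return out


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_records(
    path: str | Path,
    format_config=None,
    study_window: tuple[int, int] | None = DEFAULT_STUDY_WINDOW,
) -> RecordSet:
    """Read a delimited capture table into a validated :class:`RecordSet`.

    CSV/TSV is auto-detected from the file extension; the header must name the
    six record fields, optionally via ``format_config`` (a mapping from
    canonical field name to the column name used in the file, or a path to a
    YAML/JSON file holding such a mapping).  Years outside ``study_window``
    (closed interval; ``None`` disables the check) and unknown age classes are
    rejected with their 1-based line numbers.
    """
    raw = _read_delimited(path)
    mapping = _load_format_config(format_config)
    missing = [col for col in mapping.values() if col not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}; found {list(raw.columns)}")
    df = pd.DataFrame({f: raw[mapping[f]] for f in RECORD_FIELDS})

    problems: list[tuple[int, str]] = []

    def _to_int(col: str) -> pd.Series:
        out = pd.to_numeric(df[col], errors="coerce")
        for i in np.flatnonzero(out.isna().to_numpy()):
            problems.append((int(i) + 2, f"unparseable {col} {df[col].iloc[i]!r}"))
        return out

    year = _to_int("year")
    visit = _to_int("visit")
    age = df["age_class"].str.strip().str.lower()
    for i in np.flatnonzero(~age.isin(AGE_CLASSES).to_numpy()):
        problems.append((int(i) + 2, f"unknown age_class {df['age_class'].iloc[i]!r}"))
    if study_window is not None:
        lo, hi = study_window
        bad = year.notna() & ((year < lo) | (year > hi))
        for i in np.flatnonzero(bad.to_numpy()):
            problems.append((int(i) + 2, f"year {int(year.iloc[i])} outside study window [{lo}, {hi}]"))
    if visit.notna().any() and (visit.dropna() < 1).any():
        for i in np.flatnonzero((visit < 1).to_numpy()):
            problems.append((int(i) + 2, f"visit {df['visit'].iloc[i]!r} is not a positive integer"))
    if problems:
        problems.sort()
        raise RecordValidationError(f"{path}: invalid rows", problems)

    df["year"] = year.astype(np.int64)
    df["visit"] = visit.astype(np.int64)
    df["age_class"] = age
    return RecordSet(df, provenance=str(path))


def read_effort(path: str | Path) -> pd.DataFrame:
    """Read a visit-effort table with columns site_id, year, n_visits."""
    raw = _read_delimited(path)
    needed = ["site_id", "year", "n_visits"]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: effort table missing column(s) {missing}")
    df = raw[needed].copy()
    df["site_id"] = df["site_id"].astype(str)
    df["year"] = pd.to_numeric(df["year"]).astype(np.int64)
    df["n_visits"] = pd.to_numeric(df["n_visits"]).astype(np.int64)
    return df


def qualifying_site_years(
    effort: pd.DataFrame,
    min_visits: int = DEFAULT_MIN_VISITS,
    min_years: int = DEFAULT_MIN_YEARS,
) -> dict[str, list[int]]:
    """Site-years passing the effort rules, keyed by site.

    A year qualifies when the site logged at least ``min_visits`` visits; a
    site is retained when it has at least ``min_years`` qualifying years.
    Determined purely from the effort table: a visited year with no captures
    still counts as effort.
    """
    ok = effort[effort["n_visits"] >= min_visits]
    out: dict[str, list[int]] = {}
    for site, grp in ok.groupby("site_id"):
        years = sorted(grp["year"].unique())
        if len(years) >= min_years:
            out[str(site)] = [int(y) for y in years]
    return out


def apply_ces_filters(
    rs: RecordSet,
    visits_per_site_year: pd.DataFrame,
    min_years: int = DEFAULT_MIN_YEARS,
    min_visits: int = DEFAULT_MIN_VISITS,
    min_adults: int = DEFAULT_MIN_ADULTS,
    min_juveniles: int = DEFAULT_MIN_JUVENILES,
) -> RecordSet:
    """Apply the CES protocol filters, in their fixed order.

    (a) drop site-years with fewer than ``min_visits`` visits, then
    (b) drop sites with fewer than ``min_years`` qualifying years, then
    (c) drop species-site pairs with fewer than ``min_adults`` distinct adult
        or ``min_juveniles`` distinct juvenile individuals over the retained
        years (an individual recaptured in several years counts once).

    ``visits_per_site_year`` must cover every (site, year) present in the
    records; effort cannot be inferred from captures because a visit with no
    captures leaves no record.
    """
    df = rs.records
    effort = visits_per_site_year
    eff_keys = set(zip(effort["site_id"].astype(str), effort["year"].astype(int)))
    rec_keys = set(zip(df["site_id"], df["year"].astype(int)))
    unknown = sorted(rec_keys - eff_keys)
    if unknown:
        raise MissingEffortError(
            f"no visit-effort entry for {len(unknown)} site-year(s), e.g. {unknown[:5]}"
        )

    qual = qualifying_site_years(effort, min_visits=min_visits, min_years=min_years)
    keep_sy = {(s, y) for s, ys in qual.items() for y in ys}
    mask = [
        (s, y) in keep_sy
        for s, y in zip(df["site_id"], df["year"].astype(int))
    ]
    df = df[np.asarray(mask, dtype=bool)]

    # (c): distinct individuals per species-site per age class over retained years
    dedup = df.drop_duplicates(subset=["species_code", "site_id", "age_class", "ring_id"])
    counts = (
        dedup.groupby(["species_code", "site_id", "age_class"])["ring_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    for col in AGE_CLASSES:
        if col not in counts.columns:
            counts[col] = 0
    ok_pairs = set(
        counts[(counts[ADULT] >= min_adults) & (counts[JUVENILE] >= min_juveniles)].index
    )
    mask = [
        (sp, si) in ok_pairs
        for sp, si in zip(df["species_code"], df["site_id"])
    ]
    df = df[np.asarray(mask, dtype=bool)].reset_index(drop=True)
    return RecordSet(df, provenance=rs.provenance)


def build_site_year_counts(rs: RecordSet) -> pd.DataFrame:
    """Count distinct adult and juvenile individuals per (species, site, year).

    Individuals are deduplicated by ring within each site-year (repeat captures
    within a season count once; the first record decides the age class).
    Returns a DataFrame with columns species_code, site_id, year, n_adult,
    n_juvenile, one row per site-year with at least one capture.
    """
    df = rs.records.drop_duplicates(subset=["species_code", "site_id", "year", "ring_id"], keep="first")
    tab = (
        df.groupby(["species_code", "site_id", "year", "age_class"])["ring_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    for col in AGE_CLASSES:
        if col not in tab.columns:
            tab[col] = 0
    out = tab.reset_index().rename(columns={ADULT: "n_adult", JUVENILE: "n_juvenile"})
    out = out[["species_code", "site_id", "year", "n_adult", "n_juvenile"]]
    out.columns.name = None
    return out.sort_values(["species_code", "site_id", "year"]).reset_index(drop=True)


@dataclass
class CaptureHistoryMatrix:
    """Binary adult encounter histories for one species at one site.

    Rows are individuals first captured as adults; columns are the site's
    retained years in order.  ``first_idx[i]`` is the column of row *i*'s first
    capture.  Within-season recaptures collapse to a single 1.
    """

    species_code: str
    site_id: str
    years: np.ndarray
    histories: np.ndarray
    first_idx: np.ndarray
    ring_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.histories = np.asarray(self.histories, dtype=np.int8)
        self.first_idx = np.asarray(self.first_idx, dtype=np.int64)
        if self.histories.ndim != 2 or self.histories.shape[1] != self.years.size:
            raise ValueError("histories must be (n_individuals, n_years)")
        if self.histories.size:
            if not (self.histories.sum(axis=1) >= 1).all():
                raise ValueError("every history row needs at least one capture")
            first = self.histories.argmax(axis=1)
            if not np.array_equal(first, self.first_idx):
                raise ValueError("first_idx does not match the first 1 of each row")

    @property
    def n_individuals(self) -> int:
        return self.histories.shape[0]

    @property
    def n_years(self) -> int:
        return self.years.size


def build_capture_histories(
    rs: RecordSet,
    site_years: Mapping[str, Sequence[int]] | None = None,
) -> list[CaptureHistoryMatrix]:
    """Build adult capture histories per (species, site).

    Only individuals whose first capture at the site was as an adult contribute
    rows; a bird ringed as a juvenile and recaptured later as an adult is
    excluded (its history would not start at an adult release).  The year
    vector per site is taken from ``site_years`` (e.g. the qualifying years
    from the effort table) or, failing that, from the years with any capture
    at that site.  Individuals seen at two sites get independent histories at
    each (no cross-site linking).
    """
    df = rs.records
    out: list[CaptureHistoryMatrix] = []
    inferred = {
        str(site): sorted(int(y) for y in grp["year"].unique())
        for site, grp in df.groupby("site_id")
    }
    for (species, site), grp in df.groupby(["species_code", "site_id"], sort=True):
        years = [int(y) for y in (site_years or inferred)[str(site)]]
        year_pos = {y: i for i, y in enumerate(years)}
        rows, firsts, rings = [], [], []
        order = grp.sort_values(["year", "visit"], kind="stable")
        for ring, g in order.groupby("ring_id", sort=True):
            if g["age_class"].iloc[0] != ADULT:
                continue
            hist = np.zeros(len(years), dtype=np.int8)
            for y in g["year"].unique():
                pos = year_pos.get(int(y))
                if pos is not None:
                    hist[pos] = 1
            if not hist.any():
                continue
            rows.append(hist)
            firsts.append(int(hist.argmax()))
            rings.append(str(ring))
        if rows:
            out.append(
                CaptureHistoryMatrix(
                    species_code=str(species),
                    site_id=str(site),
                    years=np.array(years),
                    histories=np.array(rows),
                    first_idx=np.array(firsts),
                    ring_ids=rings,
                )
            )
    return out


# ---------------------------------------------------------------------------
# plain-text persistence for inspection and pipeline resume


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"species_code": str, "site_id": str})
    df["year"] = df["year"].astype(np.int64)
    return df


def write_histories(chms: Iterable[CaptureHistoryMatrix], path: str | Path) -> None:
    rows = []
    for chm in chms:
        years = ";".join(str(y) for y in chm.years)
        for i in range(chm.n_individuals):
            rows.append(
                {
                    "species_code": chm.species_code,
                    "site_id": chm.site_id,
                    "ring_id": chm.ring_ids[i] if chm.ring_ids else str(i),
                    "years": years,
                    "history": "".join(str(int(v)) for v in chm.histories[i]),
                }
            )
    pd.DataFrame(rows, columns=["species_code", "site_id", "ring_id", "years", "history"]).to_csv(
        path, index=False
    )


def read_histories(path: str | Path) -> list[CaptureHistoryMatrix]:
    df = pd.read_csv(path, dtype=str)
    out = []
    for (species, site), grp in df.groupby(["species_code", "site_id"], sort=True):
        years = np.array([int(y) for y in grp["years"].iloc[0].split(";")])
        hist = np.array([[int(c) for c in h] for h in grp["history"]], dtype=np.int8)
        out.append(
            CaptureHistoryMatrix(
                species_code=str(species),
                site_id=str(site),
                years=years,
                histories=hist,
                first_idx=hist.argmax(axis=1),
                ring_ids=list(grp["ring_id"]),
            )
        )
    return out
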