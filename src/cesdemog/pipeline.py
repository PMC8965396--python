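"""Orchestration: simulate/ingest -> filter -> fit -> decompose -> compare.

Each stage writes delimited outputs under its own subdirectory of the run's
output directory, and a JSON manifest records the configuration hash, seeds,
per-stage input hashes, timings and convergence flags.  A stage whose inputs
and configuration are unchanged since the previous run is skipped and its
outputs reused, so long runs are resumable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ces_io
from .ces_io import RecordSet
from .comparison import compare_rates, classify_quadrant, quadrant_table
from .decomposition import (
    SpeciesDecomposition,
    compute_icc,
    compute_sts,
    decomposition_table,
    summary_table,
)
from .models import ICC, STS, MCMCConfig, VarianceDraws, fit_productivity, fit_survival
from .simulate import SimulationConfig, simulate_dataset, true_icc, true_sts

log = logging.getLogger("cesdemog")

STAGES = ("simulate", "filter", "fit", "decompose", "compare")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending unit."""


@dataclass
class PipelineConfig:
    """Everything needed for a full run; YAML-serializable."""

    mode: str = "simulate"                 # "simulate" | "files"
    records_path: str | None = None        # files mode
    effort_path: str | None = None
    format_config: dict | None = None
    study_window: tuple[int, int] | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_years: int = ces_io.DEFAULT_MIN_YEARS
    min_visits: int = ces_io.DEFAULT_MIN_VISITS
    min_adults: int = ces_io.DEFAULT_MIN_ADULTS
    min_juveniles: int = ces_io.DEFAULT_MIN_JUVENILES
    rates: tuple[str, ...] = ("productivity", "survival")
    structures: tuple[str, ...] = (STS, ICC)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    n_sub: int = 700
    auto_reduce: bool = True
    comparison_seed: int = 0
    allow_unconverged: bool = True         # proceed past rhat failures, flagging them
    make_figures: bool = False
    outdir: str = "cesdemog_run"

    def __post_init__(self):
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files":
            for name in ("records_path", "effort_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"files mode requires {name}")
                if not Path(p).exists():
                    raise ValueError(f"{name} {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "simulation" in data and isinstance(data["simulation"], dict):
            sim = dict(data["simulation"])
            if "year_range" in sim:
                sim["year_range"] = tuple(sim["year_range"])
            data["simulation"] = SimulationConfig(**sim)
        if "mcmc" in data and isinstance(data["mcmc"], dict):
            data["mcmc"] = MCMCConfig(**data["mcmc"])
        for key in ("rates", "structures"):
            if key in data:
                data[key] = tuple(data[key])
        if data.get("study_window"):
            data["study_window"] = tuple(data["study_window"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _canonical_hash(obj) -> str:
    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o))

    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=default).encode()
    ).hexdigest()[:16]


def _stage_config(cfg: PipelineConfig, stage: str) -> dict:
    d = cfg.to_dict()
    keys = {
        "simulate": ["mode", "records_path", "effort_path", "format_config",
                     "study_window", "simulation"],
        "filter": ["min_years", "min_visits", "min_adults", "min_juveniles"],
        "fit": ["rates", "structures", "mcmc"],
        "decompose": ["allow_unconverged"],
        "compare": ["n_sub", "auto_reduce", "comparison_seed", "make_figures"],
    }[stage]
    return {k: d[k] for k in keys}


def _derived_seed(base: int, *labels: str) -> int:
    import zlib

    key = zlib.crc32(":".join(labels).encode())
    return int(np.random.SeedSequence([int(base), key]).generate_state(1)[0] % (2**31))


def run(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text()).get("stages", {})
        except json.JSONDecodeError:
            previous = {}

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _canonical_hash(config.to_dict()),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }

    upstream_hash = ""
    state: dict = {}
    for stage in STAGES:
        stage_hash = _canonical_hash({"cfg": _stage_config(config, stage), "up": upstream_hash})
        stage_dir = outdir / stage
        prev = previous.get(stage, {})
        runner = _STAGE_RUNNERS[stage]
        entry = {"hash": stage_hash, "outputs": []}
        t0 = time.time()
        can_skip = (
            prev.get("hash") == stage_hash
            and prev.get("status") in ("computed", "skipped")
            and all((outdir / p).exists() for p in prev.get("outputs", []))
            and prev.get("outputs")
        )
        try:
            if can_skip:
                log.info("stage %s: inputs unchanged, reusing outputs", stage)
                runner(config, stage_dir, state, load_only=True)
                entry["status"] = "skipped"
                entry["outputs"] = prev["outputs"]
            else:
                stage_dir.mkdir(parents=True, exist_ok=True)
                outputs = runner(config, stage_dir, state, load_only=False)
                entry["status"] = "computed"
                entry["outputs"] = [str(Path(stage) / o) for o in outputs]
        except PipelineError:
            raise
        except Exception as e:  # halt with the stage name attached
            raise PipelineError(f"stage {stage}: {e}") from e
        entry["seconds"] = round(time.time() - t0, 3)
        log.info("stage %s: %s in %.2fs", stage, entry["status"], entry["seconds"])
        manifest["stages"][stage] = entry
        upstream_hash = stage_hash

    manifest["convergence"] = state.get("convergence", {})
    manifest["seeds"] = {
        "simulation": config.simulation.rng_seed if config.mode == "simulate" else None,
        "mcmc_base": config.mcmc.rng_seed,
        "comparison": config.comparison_seed,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# stage runners: populate `state`, return output file names (relative to stage dir)


def _stage_simulate(cfg: PipelineConfig, d: Path, state: dict, load_only: bool):
    if load_only:
        df = pd.read_csv(d / "records.csv", dtype=str)
        df["year"] = df["year"].astype(np.int64)
        df["visit"] = df["visit"].astype(np.int64)
        state["records"] = RecordSet(df, provenance=str(d / "records.csv"))
        state["effort"] = ces_io.read_effort(d / "effort.csv")
        return
    if cfg.mode == "simulate":
        rs, effort, truth = simulate_dataset(cfg.simulation)
        rows = []
        for rate, fields in (("survival", truth.survival), ("productivity", truth.productivity)):
            for s, f in enumerate(fields):
                for k, site in enumerate(truth.site_ids):
                    for t, year in enumerate(truth.years):
                        rows.append(
                            (rate, truth.species_codes[s], site, int(year), f.matrix[k, t])
                        )
        pd.DataFrame(
            rows, columns=["rate", "species_code", "site_id", "year", "true_value"]
        ).to_csv(d / "true_rates.csv", index=False)
        (d / "truth.json").write_text(
            json.dumps(
                {
                    "true_sts": true_sts(cfg.simulation),
                    "true_icc": true_icc(cfg.simulation),
                    "config": dataclasses.asdict(cfg.simulation),
                },
                indent=2,
                default=str,
            )
        )
        outputs = ["records.csv", "effort.csv", "true_rates.csv", "truth.json"]
    else:
        rs = ces_io.read_records(
            cfg.records_path, cfg.format_config,
            study_window=cfg.study_window or ces_io.DEFAULT_STUDY_WINDOW,
        )
        effort = ces_io.read_effort(cfg.effort_path)
        outputs = ["records.csv", "effort.csv"]
    rs.to_csv(d / "records.csv")
    effort.to_csv(d / "effort.csv", index=False)
    state["records"] = rs
    state["effort"] = effort
    return outputs


def _stage_filter(cfg: PipelineConfig, d: Path, state: dict, load_only: bool):
    if load_only:
        df = pd.read_csv(d / "filtered_records.csv", dtype=str)
        df["year"] = df["year"].astype(np.int64)
        df["visit"] = df["visit"].astype(np.int64)
        state["filtered"] = RecordSet(df)
        state["counts"] = ces_io.read_counts(d / "counts.csv")
        state["histories"] = ces_io.read_histories(d / "histories.csv")
        return
    rs = ces_io.apply_ces_filters(
        state["records"], state["effort"],
        min_years=cfg.min_years, min_visits=cfg.min_visits,
        min_adults=cfg.min_adults, min_juveniles=cfg.min_juveniles,
    )
    if len(rs) == 0:
        raise PipelineError("stage filter: no data after filtering")
    site_years = ces_io.qualifying_site_years(
        state["effort"], min_visits=cfg.min_visits, min_years=cfg.min_years
    )
    counts = ces_io.build_site_year_counts(rs)
    histories = ces_io.build_capture_histories(rs, site_years=site_years)
    rs.to_csv(d / "filtered_records.csv")
    ces_io.write_counts(counts, d / "counts.csv")
    ces_io.write_histories(histories, d / "histories.csv")
    state["filtered"] = rs
    state["counts"] = counts
    state["histories"] = histories
    return ["filtered_records.csv", "counts.csv", "histories.csv"]


def _stage_fit(cfg: PipelineConfig, d: Path, state: dict, load_only: bool):
    if load_only:
        df = pd.read_csv(d / "draws.csv")
        conv = json.loads((d / "convergence.json").read_text())
        fits = {}
        for (sp, rate, struct), grp in df.groupby(["species_code", "rate", "structure"]):
            diag = conv.get(f"{sp}/{rate}/{struct}", {})
            fits[(sp, rate, struct)] = VarianceDraws.from_dataframe(grp, diagnostics=diag)
        state["fits"] = fits
        state["convergence"] = {k: v.get("converged") for k, v in conv.items()}
        return
    counts = state["counts"]
    histories = state["histories"]
    fits: dict[tuple, VarianceDraws] = {}
    convergence: dict[str, dict] = {}
    species = sorted(counts["species_code"].unique())
    for sp in species:
        for rate in cfg.rates:
            for struct in cfg.structures:
                seed = _derived_seed(cfg.mcmc.rng_seed, sp, rate, struct)
                mc = dataclasses.replace(cfg.mcmc, rng_seed=seed)
                t0 = time.time()
                try:
                    if rate == "productivity":
                        vd = fit_productivity(
                            counts[counts["species_code"] == sp], struct, mc
                        )
                    else:
                        chms = [c for c in histories if c.species_code == sp]
                        vd = fit_survival(chms, struct, mc)
                except Exception as e:
                    raise PipelineError(f"stage fit: species {sp} {rate}/{struct}: {e}") from e
                log.info(
                    "fit %s %s/%s in %.1fs (converged=%s)",
                    sp, rate, struct, time.time() - t0, vd.converged,
                )
                fits[(sp, rate, struct)] = vd
                convergence[f"{sp}/{rate}/{struct}"] = {
                    "converged": vd.converged,
                    "rhat": vd.diagnostics["rhat"],
                    "seed": seed,
                }
    pd.concat([vd.to_dataframe() for vd in fits.values()], ignore_index=True).to_csv(
        d / "draws.csv", index=False
    )
    (d / "convergence.json").write_text(json.dumps(convergence, indent=2, default=str))
    state["fits"] = fits
    state["convergence"] = {k: v["converged"] for k, v in convergence.items()}
    return ["draws.csv", "convergence.json"]


def _stage_decompose(cfg: PipelineConfig, d: Path, state: dict, load_only: bool):
    if load_only:
        df = pd.read_csv(d / "decomposition_draws.csv")
        decs = {}
        for (sp, rate, stat), grp in df.groupby(["species_code", "rate", "statistic"]):
            decs[(sp, rate, stat)] = SpeciesDecomposition(
                species_code=sp, rate=rate, statistic=stat,
                values=grp.sort_values("draw")["value"].to_numpy(),
            )
        state["decompositions"] = decs
        return
    decs: dict[tuple, SpeciesDecomposition] = {}
    for (sp, rate, struct), vd in state["fits"].items():
        fn = compute_sts if struct == STS else compute_icc
        try:
            dec = fn(vd, force=cfg.allow_unconverged)
        except Exception as e:
            raise PipelineError(f"stage decompose: species {sp} {rate}/{struct}: {e}") from e
        decs[(sp, rate, dec.statistic)] = dec
    table = decomposition_table(list(decs.values()))
    table.to_csv(d / "decomposition_draws.csv", index=False)
    summary_table(list(decs.values())).to_csv(d / "decomposition_summary.csv", index=False)
    state["decompositions"] = decs
    return ["decomposition_draws.csv", "decomposition_summary.csv"]


def _stage_compare(cfg: PipelineConfig, d: Path, state: dict, load_only: bool):
    if load_only:
        state["comparisons"] = json.loads((d / "comparison.json").read_text())
        return
    decs = state["decompositions"]
    outputs = []
    results = {}
    if set(cfg.rates) >= {"productivity", "survival"}:
        for stat in ("STS", "ICC"):
            if stat not in [s for (_, _, s) in decs]:
                continue
            prod = {sp: v for (sp, r, s), v in decs.items() if r == "productivity" and s == stat}
            surv = {sp: v for (sp, r, s), v in decs.items() if r == "survival" and s == stat}
            res = compare_rates(
                prod, surv, statistic=stat, n_sub=cfg.n_sub,
                rng_seed=cfg.comparison_seed, auto_reduce=cfg.auto_reduce,
            )
            results[stat] = res.summary()
    (d / "comparison.json").write_text(json.dumps(results, indent=2))
    outputs.append("comparison.json")

    assignments = []
    species_rates = sorted({(sp, r) for (sp, r, _) in decs})
    for sp, rate in species_rates:
        sts = decs.get((sp, rate, "STS"))
        icc = decs.get((sp, rate, "ICC"))
        if sts is not None and icc is not None:
            assignments.append(classify_quadrant(sts, icc))
    if assignments:
        qt = quadrant_table(assignments)
        qt.to_csv(d / "quadrants.csv", index=False)
        outputs.append("quadrants.csv")
        state["quadrants"] = qt
    if cfg.make_figures:
        from .plotting import plot_quadrants, plot_rate_comparison

        summaries = summary_table(list(decs.values()))
        plot_rate_comparison(summaries).savefig(d / "rate_comparison.png", dpi=150)
        outputs.append("rate_comparison.png")
        if assignments:
            plot_quadrants(qt).savefig(d / "quadrants.png", dpi=150)
            outputs.append("quadrants.png")
    state["comparisons"] = results
    return outputs


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "fit": _stage_fit,
    "decompose": _stage_decompose,
    "compare": _stage_compare,
}
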