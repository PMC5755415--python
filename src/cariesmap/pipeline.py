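"""End-to-end two-year comparison workflow.

Stages: (optionally) simulate a region and its yearly cohorts; filter each
year's cohort and build parish counts; fit the BYM mapping model; classify
certainty and export the map; compute the polarization index with its
outlier sensitivity; optionally score parishes and allocate the capitation
budget; and write a one-page text report comparing the years.

Each stage reads its inputs from, and writes its outputs to, the run's
output directory, so the CLI subcommands (simulate / map / polarize /
allocate) compose to exactly what :func:`run_pipeline` produces.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as co
from . import geojson_io as gio
from . import mapping as mp
from . import polarization as pol
from .capitation import CapitationAllocator
from .simulate import PROFILE_2010, PROFILE_2016, SimConfig, YearProfile, simulate_cohort, simulate_region

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    seed: int = 0
    output_dir: str = "cariesmap_out"
    years: list = field(default_factory=lambda: [2010, 2016])
    age_min: int = 3
    age_max: int = 6
    birth_class: str = "domestic"
    children_path: str | None = None     # None -> simulate
    edges_path: str | None = None
    geometry_path: str | None = None
    ses_path: str | None = None
    mcmc: dict = field(default_factory=dict)         # MCMCConfig overrides
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    capitation: dict = field(default_factory=lambda: {"total_budget": None, "unit": 1.0})
    quartile_method: str = "linear"

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("years must be non-empty")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config_yaml() -> str:
    """The full default configuration, as self-documenting YAML."""
    return yaml.safe_dump(RunConfig().to_dict(), sort_keys=False)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _mcmc_seed(config: RunConfig, year: int) -> int:
    return int(np.random.SeedSequence([config.seed, 977, year]).generate_state(1)[0] % 2**31)


def _sim_config(config: RunConfig) -> SimConfig:
    overrides = dict(config.sim)
    overrides.pop("seed", None)  # the run seed governs everything
    profiles = {}
    for y in config.years:
        base = {2010: PROFILE_2010, 2016: PROFILE_2016}.get(y, YearProfile(exam_year=y))
        profiles[y] = dataclasses.replace(base, exam_year=y)
    for y, spec in (overrides.pop("year_profiles", None) or {}).items():
        y = int(y)
        base = profiles.get(y, YearProfile(exam_year=y))
        profiles[y] = dataclasses.replace(base, **spec)
    rr_range = overrides.pop("rr_range", None)
    if rr_range is not None:
        rr_range = tuple(rr_range)
    return SimConfig(seed=config.seed, rr_range=rr_range, year_profiles=profiles, **overrides)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> dict:
    """Generate the synthetic region and cohorts; write every input file
    the later stages consume, plus the ground-truth table."""
    out = _outdir(config)
    truth = simulate_region(_sim_config(config))
    frames = [simulate_cohort(truth, y) for y in config.years]
    children = pd.concat(frames, ignore_index=True)
    co.write_children(children, out / "children.csv")
    mp.write_edge_list(truth.graph, out / "edges.csv")
    truth.ses.assign(n_children=truth.n_children).to_csv(
        out / "ses.csv", index=False, float_format=_FLOAT_FMT
    )
    truth.truth_table().to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FMT)
    geoms = gio.square_geometries(truth.coords)
    with open(out / "geometry.geojson", "w") as fh:
        json.dump(
            {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "geometry": gio.mapping(geoms[p]),
                        "properties": {"parish_id": p},
                    }
                    for p in truth.parish_ids
                ],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return {"truth": truth, "children": children}


def _load_children(config: RunConfig) -> pd.DataFrame:
    path = config.children_path or Path(config.output_dir) / "children.csv"
    return co.read_children(path)


def _load_graph(config: RunConfig):
    if config.edges_path:
        return mp.load_edge_list(config.edges_path)
    if config.geometry_path:
        return gio.queen_contiguity(gio.read_geojson_features(config.geometry_path))
    out = Path(config.output_dir)
    if (out / "edges.csv").exists():
        return mp.load_edge_list(out / "edges.csv")
    return gio.queen_contiguity(gio.read_geojson_features(out / "geometry.geojson"))


def _load_geometries(config: RunConfig):
    path = config.geometry_path or Path(config.output_dir) / "geometry.geojson"
    if Path(path).exists():
        return gio.read_geojson_features(path)
    return None


def stage_map(config: RunConfig) -> dict:
    """Per year: filter the cohort, build parish counts, fit the BYM model,
    write the posterior table and (when geometry exists) the certainty map."""
    out = _outdir(config)
    children = _load_children(config)
    graph = _load_graph(config)
    geometries = _load_geometries(config)
    results = {}
    for year in config.years:
        sub = co.filter_cohort(
            children,
            year=year,
            age_min=config.age_min,
            age_max=config.age_max,
            birth_class=config.birth_class,
        )
        if len(sub) == 0:
            raise ValueError(f"no records for year {year} after filtering")
        counts = co.expected_counts(sub)
        co.write_parish_table(counts, out / f"counts_{year}.csv")
        mcmc = dict(config.mcmc)
        mcmc.setdefault("seed", _mcmc_seed(config, year))
        mapper = mp.BYMMapper(**mcmc)
        mapper.fit(counts, graph)
        table = mapper.summary_
        co.write_parish_table(table, out / f"posterior_{year}.csv")
        meta = {
            "year": year,
            "alpha": mapper.alpha_,
            "sigma_u": mapper.sigma_u_,
            "sigma_v": mapper.sigma_v_,
            "max_rhat": max(mapper.rhat_.values()),
            "rhat_warning": bool(mapper.rhat_warning_),
            "n_children": int(sub.shape[0]),
            "prevalence_percent": co.prevalence(sub).percent,
        }
        with open(out / f"fit_{year}.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
        if geometries is not None:
            gio.export_geojson(geometries, table, out / f"map_{year}.geojson")
        results[year] = {"counts": counts, "summary": table, "meta": meta}
    return results


def stage_polarize(config: RunConfig) -> pd.DataFrame:
    """Polarization index + box-plot sensitivity for each mapped year."""
    out = _outdir(config)
    rows = []
    for year in config.years:
        table = pd.read_csv(out / f"posterior_{year}.csv")
        res = pol.analyze_polarization(
            table["smrr"].to_numpy(),
            ids=table["parish_id"].astype(str).to_numpy(),
            quartile_method=config.quartile_method,
        )
        rows.append(
            {
                "year": year,
                "index": res.index,
                "sensitivity_index": res.sensitivity_index,
                "n_outliers": len(res.outliers.outlier_ids),
                "excluded_parishes": ";".join(map(str, res.outliers.outlier_ids)),
                "smrr_min": table["smrr"].min(),
                "smrr_max": table["smrr"].max(),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "polarization.csv", index=False, float_format=_FLOAT_FMT)
    return df


def stage_allocate(config: RunConfig) -> dict:
    """Score parishes (Table-style algorithm) and split the budget."""
    out = _outdir(config)
    ses_path = config.ses_path or out / "ses.csv"
    if not Path(ses_path).exists():
        raise ValueError("no parish SES table available for capitation")
    ses = pd.read_csv(ses_path, dtype={"parish_id": str})
    # the per-year child count comes from that year's count table
    ses = ses.drop(columns=["n_children"], errors="ignore")
    cap = config.capitation or {}
    results = {}
    for year in config.years:
        post = pd.read_csv(out / f"posterior_{year}.csv", dtype={"parish_id": str})
        counts = pd.read_csv(out / f"counts_{year}.csv", dtype={"parish_id": str})
        X = (
            ses.merge(post[["parish_id", "smrr"]], on="parish_id")
            .merge(counts[["parish_id", "n_children"]], on="parish_id")
            .rename(columns={"smrr": "caries_risk"})
        )
        allocator = CapitationAllocator(
            total_budget=cap.get("total_budget"),
            unit=cap.get("unit", 1.0),
            tertile_indicators=cap.get("tertile_indicators", False),
        )
        allocator.fit(X)
        scores = allocator.scores_
        if cap.get("total_budget") is not None:
            alloc = allocator.allocation_.drop(columns=["total_score", "n_children"])
            scores = scores.merge(alloc, on="parish_id")
        scores.to_csv(out / f"allocation_{year}.csv", index=False, float_format=_FLOAT_FMT)
        results[year] = scores
    return results


def stage_report(config: RunConfig) -> str:
    """One-page text comparison of the analyzed years."""
    out = _outdir(config)
    polar = pd.read_csv(out / "polarization.csv")
    lines = ["Parish-level caries risk: multi-year comparison", "=" * 48, ""]
    for year in config.years:
        with open(out / f"fit_{year}.json") as fh:
            meta = json.load(fh)
        post = pd.read_csv(out / f"posterior_{year}.csv")
        prow = polar.loc[polar["year"] == year].iloc[0]
        n_cat = post["category"].value_counts()
        lines += [
            f"Year {year}:",
            f"  children analyzed: {meta['n_children']}"
            f"  (caries prevalence {meta['prevalence_percent']}%)",
            f"  SmRR range: {prow['smrr_min']:.2f}-{prow['smrr_max']:.2f}",
            f"  polarization index: {prow['index']:.1f}"
            f"  (outlier-excluded: {prow['sensitivity_index']:.1f},"
            f" {int(prow['n_outliers'])} outlying parish(es))",
            f"  certainty map: {int(n_cat.get('elevated', 0))} elevated (red),"
            f" {int(n_cat.get('lowered', 0))} lowered (green),"
            f" {int(n_cat.get('uncertain', 0))} uncertain (yellow)",
        ]
        if meta["rhat_warning"]:
            lines.append(
                f"  WARNING: MCMC convergence suspect (max R-hat {meta['max_rhat']:.3f})"
            )
        lines.append("")
    if len(config.years) >= 2:
        first, last = config.years[0], config.years[-1]
        i0 = float(polar.loc[polar["year"] == first, "index"].iloc[0])
        i1 = float(polar.loc[polar["year"] == last, "index"].iloc[0])
        direction = "decreased" if i1 < i0 else ("increased" if i1 > i0 else "unchanged")
        lines += [
            f"Polarization index {direction} from {i0:.1f} ({first}) to {i1:.1f} ({last})"
            f" (difference {i1 - i0:+.1f}).",
            "",
        ]
    text = "\n".join(lines)
    with open(out / "report.txt", "w") as fh:
        fh.write(text)
    return text


_STAGES = (
    ("simulate", stage_simulate),
    ("map", stage_map),
    ("polarize", stage_polarize),
    ("allocate", stage_allocate),
    ("report", stage_report),
)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; any stage failure raises PipelineError naming it."""
    results: dict = {}
    for name, fn in _STAGES:
        if name == "simulate" and config.children_path is not None:
            continue
        if name == "allocate":
            ses_available = config.ses_path or (Path(config.output_dir) / "ses.csv").exists()
            if not ses_available or (config.capitation or {}).get("skip"):
                continue
        logger.info("pipeline stage: %s", name)
        try:
            results[name] = fn(config)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return results
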