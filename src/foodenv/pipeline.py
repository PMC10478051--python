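"""End-to-end orchestration: simulate -> classify -> indices -> hotspots -> regress.

Each stage reads and writes plain-text artefacts (CSV / GeoJSON) so any
stage can be re-run from its on-disk inputs; a JSON manifest records file
hashes and row counts for byte-level reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import indices as indices_mod
from . import ppml, spatial, synth, taxonomy
from .geo import read_geojson, write_geojson

logger = logging.getLogger("foodenv")

__all__ = ["RunConfig", "run_all", "make_fixtures"]


@dataclasses.dataclass
class RunConfig:
    outdir: str = "foodenv_run"
    seed: int = 0
    synth: dict[str, Any] | None = None  # SynthConfig kwargs; None = user data
    establishments: str | None = None  # used when synth is None
    attributes: str | None = None
    geoms: str | None = None
    dollar_tier: str = "UNHEALTHY"
    weights_scheme: str = "queen"
    hotspot_value: str = "mrfei"
    hotspot_years: list[int] | None = None  # default: first, middle, last
    include_svi: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True), encoding="utf-8"
        )

    def synth_config(self) -> synth.SynthConfig:
        kwargs = dict(self.synth or {})
        if "cluster_spec" in kwargs and isinstance(kwargs["cluster_spec"], dict):
            kwargs["cluster_spec"] = synth.ClusterSpec(**kwargs["cluster_spec"])
        if "years" in kwargs:
            kwargs["years"] = tuple(kwargs["years"])
        kwargs.setdefault("seed", self.seed)
        return synth.SynthConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_entry(stage: str, started: float, outputs: dict[str, Path], **extra) -> dict:
    entry = {
        "stage": stage,
        "wall_time_s": round(time.perf_counter() - started, 4),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    entry.update(extra)
    return entry


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    # stage 1: simulate (or locate user-supplied inputs)
    t0 = time.perf_counter()
    if config.synth is not None:
        paths = synth.write_bundle(config.synth_config(), outdir)
        est_path, attr_path, geo_path = (
            paths["establishments"],
            paths["tract_attributes"],
            paths["tracts"],
        )
        n_est = sum(1 for _ in open(est_path)) - 1
        manifest["stages"].append(
            _stage_entry(
                "simulate",
                t0,
                {"establishments": est_path, "attributes": attr_path, "geoms": geo_path},
                n_establishment_rows=n_est,
            )
        )
        logger.info("simulate: %d establishment rows", n_est)
    else:
        est_path = Path(config.establishments or "")
        attr_path = Path(config.attributes or "")
        geo_path = Path(config.geoms or "")
        for p, stage in ((est_path, "classify"), (attr_path, "regress"), (geo_path, "hotspots")):
            if not p.is_file():
                raise FileNotFoundError(f"stage '{stage}': required input {p} not found")

    # stage 2: classify
    t0 = time.perf_counter()
    est = pd.read_csv(est_path, dtype={"naics": str, "tract_id": str})
    classified = taxonomy.classify_frame(est, taxonomy.HealthTier(config.dollar_tier))
    classified_path = outdir / "establishments_classified.csv"
    classified.to_csv(classified_path, index=False)
    manifest["stages"].append(
        _stage_entry("classify", t0, {"classified": classified_path}, n_rows=len(classified))
    )
    logger.info("classify: %d rows", len(classified))

    # stage 3: indices
    t0 = time.perf_counter()
    geoms = read_geojson(geo_path)
    years = sorted(classified["year"].unique())
    panel = indices_mod.build_panel(classified, years, tract_ids=[g.tract_id for g in geoms])
    panel_path = outdir / "indices_panel.csv"
    panel.to_csv(panel_path, index=False)
    manifest["stages"].append(
        _stage_entry("indices", t0, {"panel": panel_path}, n_rows=len(panel))
    )
    logger.info("indices: %d tract-year rows", len(panel))

    # stage 4: hotspots
    t0 = time.perf_counter()
    weights = spatial.build_weights(geoms, scheme=config.weights_scheme)
    hotspot_years = config.hotspot_years or sorted({years[0], years[len(years) // 2], years[-1]})
    results_by_year: dict[int, pd.DataFrame] = {}
    hotspot_outputs: dict[str, Path] = {}
    for year in hotspot_years:
        values = panel[panel["year"] == year].set_index("tract_id")[config.hotspot_value]
        table = spatial.hotspot_table(values, weights, year=year)
        results_by_year[year] = table
        csv_path = outdir / f"hotspots_{config.hotspot_value}_{year}.csv"
        table.to_csv(csv_path, index=False)
        hotspot_outputs[f"csv_{year}"] = csv_path
        props = {
            r.tract_id: {"gi_z": r.gi_z, "p_value": r.p_value, "bin": int(r.bin)}
            for r in table.itertuples()
        }
        gj_path = outdir / f"hotspots_{config.hotspot_value}_{year}.geojson"
        write_geojson(geoms, gj_path, extra_properties=props)
        hotspot_outputs[f"geojson_{year}"] = gj_path
    if len(results_by_year) >= 2:
        transitions, yearly = spatial.compare_years(results_by_year)
        tr_path = outdir / "hotspot_transitions.csv"
        transitions.to_csv(tr_path, index=False)
        hotspot_outputs["transitions"] = tr_path
        yc_path = outdir / "hotspot_yearly_counts.csv"
        yearly.to_csv(yc_path, index=False)
        hotspot_outputs["yearly_counts"] = yc_path
    manifest["stages"].append(
        _stage_entry("hotspots", t0, hotspot_outputs, years=list(map(int, hotspot_years)))
    )
    logger.info("hotspots: years %s", hotspot_years)

    # stage 5: regress
    t0 = time.perf_counter()
    attrs = pd.read_csv(attr_path, dtype={"tract_id": str})
    coef = ppml.run_model_suite(panel, attrs, include_svi=config.include_svi)
    coef_path = outdir / "coefficients.csv"
    coef.to_csv(coef_path, index=False)
    n_models = int(coef["model_id"].nunique()) if len(coef) else 0
    manifest["stages"].append(
        _stage_entry("regress", t0, {"coefficients": coef_path}, n_models=n_models)
    )
    logger.info("regress: %d models", n_models)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a 5x5-lattice, 3-year mini bundle for unit tests.

    Two hand-written records are appended so the reclassification rules are
    always exercised: a grocery-coded store with fewer than five employees
    and a 452319 record without "dollar" in its name.
    """
    config = synth.SynthConfig(n_rows=5, n_cols=5, years=(2000, 2002), seed=seed)
    outdir = Path(outdir)
    paths = synth.write_bundle(config, outdir)
    est = pd.read_csv(paths["establishments"], dtype={"naics": str, "tract_id": str})
    extra = pd.DataFrame(
        [
            {
                "establishment_id": "FIX0000001",
                "tract_id": "000000",
                "year": 2000,
                "naics": "445110",
                "name": "Tiny Corner Grocery",
                "employees": 2,
                "sales": 150000.0,
            },
            {
                "establishment_id": "FIX0000002",
                "tract_id": "000000",
                "year": 2000,
                "naics": "452319",
                "name": "Big Bargain Mart",
                "employees": 8,
                "sales": 900000.0,
            },
        ]
    )
    pd.concat([est, extra], ignore_index=True).to_csv(paths["establishments"], index=False)
    return paths
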