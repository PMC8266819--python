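"""End-to-end orchestration: chronology -> source aggregation -> polygon
screening -> per-season SIMM fits over the covariate structures -> LOO model
selection -> report bundle.

Every run writes its artefacts (categories.csv, chronology.csv,
polygon_report.csv, model_comparison.csv, posterior_summaries.csv,
per_bear_summaries.csv, convergence.csv, run_summary.json, run.log) into one
output directory stamped with the config hash and master seed, so two runs
with identical configs are identical.
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

from . import chronology as chron
from .mixing import DEFAULT_TEFS, TrophicEnrichment, build_mixing_space, simulate_mixing_polygons
from .selection import compare_models, psis_loo
from .simm import (
    MCMCSettings,
    MODEL_STRUCTURES,
    ModelSpec,
    fit_mcmc,
    prior_from_edec,
    summarize_posterior,
)
from .sources import aggregate_all, read_sources, write_categories

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("hairsimm")


class ConfigError(ValueError):
    """Raised with the full list of config violations."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid run config:\n" + "\n".join(f"- {e}" for e in self.errors))


@dataclass
class RunConfig:
    sources_csv: str
    bears_csv: str
    hairs_csv: str
    sections_csv: str
    outdir: str
    seed: int = 0
    seasons: tuple[str, ...] = tuple(chron.SEASONS)
    models: tuple[str, ...] = tuple(MODEL_STRUCTURES)
    #: EDEC% prior vector per season over the alphabetical source order.
    #: Placeholder default: uniform (reduces to the flat Dirichlet(1) prior).
    edec: dict = field(default_factory=dict)
    tefs: dict = field(default_factory=lambda: dict(DEFAULT_TEFS))
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    polygon_n_iter: int = 1500
    polygon_threshold: float = 0.05
    digestibility: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["tefs"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
                     for k, v in self.tefs.items()}
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a YAML/JSON path or a dict, reporting every
    violated constraint at once."""
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
    else:
        raw = dict(source)
    errors = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    for key in ("sources_csv", "bears_csv", "hairs_csv", "sections_csv", "outdir"):
        if key not in raw:
            errors.append(f"{key}: missing required path")
        elif key != "outdir" and not Path(raw[key]).exists():
            errors.append(f"{key}: file does not exist: {raw[key]}")
    if "tef" in raw or "tefs" in raw:
        tef_raw = raw.pop("tefs", raw.pop("tef", None))
        tefs = {}
        for cls in ("vegetable", "animal"):
            if cls not in tef_raw:
                errors.append(f"tef: missing trophic class {cls!r}")
                continue
            try:
                tefs[cls] = TrophicEnrichment(trophic_class=cls, **tef_raw[cls])
            except (TypeError, ValueError) as e:
                errors.append(f"tef.{cls}: {e}")
        raw["tefs"] = tefs or dict(DEFAULT_TEFS)
    if "mcmc" in raw:
        try:
            raw["mcmc"] = MCMCSettings(**raw["mcmc"])
        except (TypeError, ValueError) as e:
            errors.append(f"mcmc: {e}")
            del raw["mcmc"]
    for key in ("seasons", "models"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "models" in raw:
        bad = set(raw["models"]) - set(MODEL_STRUCTURES)
        if bad:
            errors.append(f"models: unknown structure(s) {sorted(bad)}")
    if "seasons" in raw:
        bad = set(raw["seasons"]) - set(chron.SEASONS)
        if bad:
            errors.append(f"seasons: unknown season(s) {sorted(bad)}")
    if "edec" in raw:
        for season, vec in raw["edec"].items():
            if np.any(np.asarray(vec, dtype=float) < 0):
                errors.append(f"edec.{season}: negative entries")
    if raw.get("polygon_threshold") is not None and not (
        0 <= float(raw.get("polygon_threshold", 0.05)) < 1
    ):
        errors.append("polygon_threshold: must be in [0, 1)")
    if errors:
        raise ConfigError(errors)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError([f"unknown config key(s): {sorted(unknown)}"])
    try:
        return RunConfig(**raw)
    except (TypeError, ValueError) as e:
        raise ConfigError([str(e)]) from None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _derived_seed(master: int, *idx: int) -> int:
    return int(np.random.SeedSequence([master, *idx]).generate_state(1)[0] % (2**31))


def run_pipeline(config) -> dict:
    """Run the full analysis; returns a results bundle (also written to disk).

    The bundle maps season -> {"comparison": DataFrame, "polygon": DataFrame,
    "fits": {label: PosteriorResult}, "selected": [labels]} plus "categories".
    """
    config = validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    timings = {}
    bundle: dict = {}
    try:
        # --- sources
        t = time.time()
        samples = read_sources(config.sources_csv)
        categories = aggregate_all(samples, digestibility=config.digestibility)
        write_categories(categories, outdir / "categories.csv")
        bundle["categories"] = categories
        timings["sources"] = time.time() - t
        logger.info("aggregated %d samples into %d categories", len(samples), len(categories))

        # --- chronology
        t = time.time()
        bears = pd.read_csv(config.bears_csv, dtype=str)
        hairs = pd.read_csv(config.hairs_csv)
        sections = pd.read_csv(config.sections_csv)
        chrono = chron.build_chronology(hairs, sections)
        chrono.to_csv(outdir / "chronology.csv", index=False)
        usable = chrono[(chrono["exclusion_reason"] == "") & chrono["season"].notna()]
        usable = usable.merge(bears, on="bear_id", how="left", validate="m:1")
        if usable[["sex", "status"]].isna().any().any():
            raise PipelineError("chronology", "bears.csv is missing some bear_ids")
        timings["chronology"] = time.time() - t
        logger.info("chronology: %d sections, %d usable", len(chrono), len(usable))
        if usable.empty:
            raise PipelineError("chronology", "no usable sections")

        space = build_mixing_space(categories, config.tefs)
        k = space.n_sources

        # --- per-season screening, fits, selection
        poly_reports, comparison_rows, conv_rows = [], [], []
        post_rows, bear_rows = [], []
        for s_idx, season in enumerate(config.seasons):
            sdat = usable[usable["season"] == season].copy()
            if sdat.empty:
                logger.warning("season %s: no sections, skipped", season)
                continue
            sspace = dataclasses.replace(space, season=season)
            t = time.time()
            sdat["consumer_id"] = (
                sdat["sample_id"].astype(str) + ":" + sdat["section_index"].astype(str)
            )
            poly = simulate_mixing_polygons(
                sspace,
                sdat,
                n_iter=config.polygon_n_iter,
                threshold=config.polygon_threshold,
                seed=_derived_seed(config.seed, s_idx, 999),
            )
            poly_reports.append(poly)
            keep_ids = set(poly.loc[~poly["excluded"], "consumer_id"])
            n_excl = len(sdat) - len(keep_ids)
            logger.info("season %s: polygon excluded %d of %d sections",
                        season, n_excl, len(sdat))
            sdat = sdat[sdat["consumer_id"].isin(keep_ids)]
            timings[f"polygon:{season}"] = time.time() - t
            if sdat.empty:
                raise PipelineError(
                    "polygon",
                    f"season {season}: every consumer fell outside the simulated "
                    "mixing region; check sources, TEFs and consumer data",
                )

            edec = config.edec.get(season, [1.0] * k)
            prior = prior_from_edec(edec)
            fits = {}
            loos = []
            for m_idx, label in enumerate(config.models):
                t = time.time()
                spec = ModelSpec.from_label(label, season=season)
                result = fit_mcmc(
                    sdat, sspace, spec, prior,
                    settings=config.mcmc,
                    seed=_derived_seed(config.seed, s_idx, m_idx),
                )
                fits[label] = result
                loos.append((label, psis_loo(result.pointwise_loglik)))
                cf = result.convergence.to_frame()
                cf.insert(0, "season", season)
                cf.insert(1, "model", label)
                conv_rows.append(cf)
                timings[f"fit:{season}:{label}"] = time.time() - t
                logger.info(
                    "season %s model %s: fitted (convergence %s)",
                    season, label, "ok" if result.convergence.passed else "FAILED",
                )
            comparison = compare_models(loos)
            comparison.insert(0, "season", season)
            comparison_rows.append(comparison)
            selected = list(comparison.loc[comparison["selected"], "model"])
            bundle[season] = {
                "polygon": poly,
                "fits": fits,
                "comparison": comparison,
                "selected": selected,
            }
            # posterior tables for the selected model(s)
            for label in selected or [comparison.iloc[0]["model"]]:
                result = fits[label]
                for level in _summary_levels(result):
                    tab = summarize_posterior(result, level=level, min_draws=1)
                    tab.insert(0, "season", season)
                    tab.insert(1, "model", label)
                    post_rows.append(tab)
                per_bear = summarize_posterior(result, level="bears", min_draws=1)
                per_bear.insert(0, "season", season)
                per_bear.insert(1, "model", label)
                bear_rows.append(per_bear)

        # --- reports
        pd.concat(poly_reports, ignore_index=True).to_csv(
            outdir / "polygon_report.csv", index=False
        )
        comparison_all = pd.concat(comparison_rows, ignore_index=True)
        comparison_all.to_csv(outdir / "model_comparison.csv", index=False)
        pd.concat(conv_rows, ignore_index=True).to_csv(
            outdir / "convergence.csv", index=False
        )
        post_all = pd.concat(post_rows, ignore_index=True)
        post_all.to_csv(outdir / "posterior_summaries.csv", index=False)
        pd.concat(bear_rows, ignore_index=True).to_csv(
            outdir / "per_bear_summaries.csv", index=False
        )
        bundle["comparison"] = comparison_all
        bundle["posterior_summaries"] = post_all

        all_converged = all(
            r.convergence.passed
            for season in config.seasons
            if season in bundle
            for r in bundle[season]["fits"].values()
        )
        summary = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "seasons": list(config.seasons),
            "models": list(config.models),
            "all_converged": bool(all_converged),
            "timings_s": {k_: round(v, 3) for k_, v in timings.items()},
            "selected": {
                season: bundle[season]["selected"]
                for season in config.seasons if season in bundle
            },
        }
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        (outdir / "config.json").write_text(
            json.dumps(config.to_jsonable(), indent=1, sort_keys=True, default=str)
        )
        bundle["summary"] = summary
        logger.info("pipeline finished in %.1fs", time.time() - t0)
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()


def _summary_levels(result) -> list[str]:
    levels = ["population"]
    for factor, level in result.coef_labels:
        levels.append(f"{factor}:{level}")
    return levels
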