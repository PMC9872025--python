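"""End-to-end orchestration with reproducible configuration and logging.

``run_pipeline`` executes load/simulate -> classify (maturity,
specialization) -> score -> fit (season and growth models per outcome) ->
predictions / contrasts / diagnostics, writing every stage's output before
the next begins plus a manifest with the effective config and seed.  One
seed governs the run; per-stage seeds are derived from it deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import maturation, specialization
from .core_data import ObservationTable, load_observations, validate_table
from .fitness_scoring import ScalingRecord, pooled_zscores
from .hierarchical_models import (
    SamplerSettings,
    build_growth_model,
    build_season_model,
    fit,
)
from .posterior_analysis import (
    build_prediction_grid,
    contrast_specialization,
    diagnostics,
    predict_expected,
)
from .synthetic_cohort import SimulationConfig, default_config, simulate_cohort

logger = logging.getLogger("hoopgrowth")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2**31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def build_analysis_frame(
    table: ObservationTable,
    coeffs: maturation.OffsetCoefficients | None = None,
    refs: maturation.ReferenceMilestones | None = None,
    scalings: dict[str, ScalingRecord] | None = None,
) -> tuple[pd.DataFrame, dict[str, ScalingRecord]]:
    """Classified and scored model-ready frame: one row per observation with
    ``maturity_status`` and ``specialization`` merged in as player constants."""
    scored = pooled_zscores(table, scalings=scalings)
    mat = maturation.assess_players(table, coeffs=coeffs, refs=refs)
    spc = specialization.assess_players(table, refs=refs)
    df = scored.df.merge(
        mat[["player_id", "maturity_status"]], on="player_id", how="left"
    ).merge(
        spc[["player_id", "specialization"]], on="player_id", how="left"
    )
    return df, scored.scalings


@dataclasses.dataclass
class RunConfig:
    output_dir: str = "results/run"
    seed: int = 1
    input_path: str | None = None          # None -> simulate
    column_map: dict | None = None
    simulation: SimulationConfig | None = None
    outcomes: tuple[str, ...] = ("fitness_score",)
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    fit_growth: bool = True
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run every stage; returns a map of artifact names to file paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.time()

    def log(msg: str) -> None:
        if config.verbosity:
            logger.info("[%7.1fs] %s", time.time() - t0, msg)

    def save(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    # --- load or simulate -------------------------------------------------
    try:
        if config.input_path is not None:
            table = load_observations(config.input_path, column_map=config.column_map)
        else:
            sim = config.simulation or default_config()
            sim = SimulationConfig.from_dict({**sim.to_dict(),
                                              "seed": stage_seed(config.seed, "simulate")})
            table, truth = simulate_cohort(sim)
            p = out / "truth.json"
            p.write_text(truth.to_json())
            save("truth", p)
    except FileNotFoundError as e:
        raise RuntimeError(f"stage 'load': input file not found: {e}") from e
    p = out / "observations.csv"
    table.write_csv(p)
    save("observations", p)
    report = validate_table(table)
    p = out / "validation.csv"
    report.summary().to_csv(p, index=False)
    save("validation", p)
    log(f"loaded {len(table)} observations from {table.provenance}")

    # --- classification ---------------------------------------------------
    mat = maturation.assess_players(table)
    p = out / "maturity.csv"
    mat.to_csv(p, index=False)
    save("maturity", p)
    spc = specialization.assess_players(table)
    p = out / "specialization.csv"
    spc.to_csv(p, index=False)
    save("specialization", p)
    log("classified maturity and specialization")

    # --- scoring ----------------------------------------------------------
    frame, scalings = build_analysis_frame(table)
    p = out / "scored.csv"
    frame.to_csv(p, index=False)
    save("scored", p)
    p = out / "scalings.json"
    p.write_text(json.dumps({k: v.to_dict() for k, v in scalings.items()}, indent=2))
    save("scalings", p)
    log("computed pooled z-scores and composite")

    # --- model fits -------------------------------------------------------
    diag_frames = []
    for outcome in config.outcomes:
        for kind, builder in (("season", build_season_model),
                              ("growth", build_growth_model)):
            if kind == "growth" and not config.fit_growth:
                continue
            spec = builder(outcome)
            settings = SamplerSettings(
                chains=config.chains, iterations=config.iterations,
                warmup=config.warmup,
                seed=stage_seed(config.seed, f"fit-{kind}-{outcome}"),
            )
            try:
                draws = fit(spec, frame, settings)
            except ValueError as e:
                raise RuntimeError(f"stage 'fit-{kind}' ({outcome}): {e}") from e
            log(f"fitted {kind} model for {outcome} "
                f"({settings.chains}x{settings.iterations} iterations)")

            p = out / f"draws_{kind}_{outcome}.csv"
            keep = [n for n in draws.parameters
                    if not n.startswith("r_player[")]  # player effects omitted from export
            tidy = draws.to_frame()
            tidy[tidy["parameter"].isin(keep)].to_csv(p, index=False)
            save(f"draws_{kind}_{outcome}", p)
            p = out / f"fitlog_{kind}_{outcome}.json"
            p.write_text(json.dumps(draws.fit_log(), indent=2))
            save(f"fitlog_{kind}_{outcome}", p)

            grid = build_prediction_grid(draws)
            pred = predict_expected(draws, grid)
            p = out / f"predictions_{kind}_{outcome}.csv"
            pred.to_csv(p, index=False)
            save(f"predictions_{kind}_{outcome}", p)

            spec_block = "spec_sex" if kind == "season" else "spec_onset"
            cats = set()
            for lv in draws.group_levels[spec_block]:
                cats.add(lv.split(":")[0])
            contrast_rows = []
            for sex in ("female", "male"):
                for a in sorted(cats):
                    for b in sorted(cats):
                        if a >= b:
                            continue
                        try:
                            c = contrast_specialization(draws, sex, a, b)
                        except ValueError:
                            continue  # level absent within this sex
                        contrast_rows.append(c.summary())
            if contrast_rows:
                p = out / f"contrasts_{kind}_{outcome}.csv"
                pd.concat(contrast_rows, ignore_index=True).to_csv(p, index=False)
                save(f"contrasts_{kind}_{outcome}", p)

            d = diagnostics(draws)
            dt = d.table.copy()
            dt.insert(0, "model", f"{kind}_{outcome}")
            diag_frames.append(dt)

    if diag_frames:
        p = out / "diagnostics.csv"
        pd.concat(diag_frames, ignore_index=True).to_csv(p, index=False)
        save("diagnostics", p)

    # --- manifest ---------------------------------------------------------
    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": config.seed,
        "artifacts": artifacts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest"] = str(p)
    log("wrote manifest")
    return artifacts
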