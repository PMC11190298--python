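"""Pipeline orchestration: simulate -> MAIC -> Markov/CUA -> DSA/PSA -> BIA.

Every stage writes delimited-text or JSON outputs into the run directory and
is recorded in a manifest (configuration hash, seed, package versions,
per-stage status), so a run is reproducible from its manifest.  A stage
failure halts the pipeline with the stage named; outputs of completed stages
are preserved.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import __version__
from .budget import BIAInputs, run_bia
from .config import RunConfig, config_hash, default_config
from .economics import decide, run_base_case
from .maic import (
    AggregateBaseline,
    aggregate_or,
    balance_table,
    bucher_combine,
    estimate_weights,
    weighted_outcome_or,
)
from .synthetic import (
    ANAPRAZOLE_PROFILE,
    ILAPRAZOLE_PROFILE,
    generate_ipd,
    write_ipd,
)
from .uncertainty import ceac, run_dsa, run_psa

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage_simulate(cfg: RunConfig, outdir: Path, seed: int) -> dict[str, Any]:
    ipd = generate_ipd(ANAPRAZOLE_PROFILE, seed=seed)
    write_ipd(ipd, outdir / "ipd_anaprazole.csv")
    return {"ipd": ipd, "n": len(ipd)}

def _stage_maic(cfg: RunConfig, outdir: Path, state: dict) -> dict[str, Any]:
    ipd = state["ipd"]
    target = AggregateBaseline.from_profile(ILAPRAZOLE_PROFILE)
    weights = estimate_weights(ipd, target)
    bal = balance_table(ipd, weights, target)
    bal.to_csv(outdir / "balance_table.csv", index=False)
    comp = cfg.comparison
    results = {}
    for outcome, col, comparator_rate in (
        ("healing", "healed", comp.comparator_healing_rate),
        ("adr", "adr", comp.comparator_adr_rate),
    ):
        anchor1 = (comp.anchor1_healing_rate if outcome == "healing"
                   else comp.anchor1_adr_rate)
        anchor2 = (comp.anchor2_healing_rate if outcome == "healing"
                   else comp.anchor2_adr_rate)
        ac = weighted_outcome_or(ipd[col].to_numpy(), weights,
                                 anchor1, comp.anchor1_n)
        bc = aggregate_or(comparator_rate, comp.comparator_n,
                          anchor2, comp.anchor2_n)
        results[outcome] = {
            "ac": ac.as_dict(), "bc": bc.as_dict(),
            "ab": bucher_combine(ac, bc).as_dict(),
        }
    doc = {"ess": weights.ess, "comparisons": results}
    (outdir / "maic_results.json").write_text(json.dumps(doc, indent=2))
    return {"weights": weights, "maic": doc}

def _stage_cua(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    res = run_base_case(cfg)
    table = pd.DataFrame(
        {
            "group": ["anaprazole", "ilaprazole"],
            "cost": [res.cost1, res.cost2],
            "qalys": [res.qalys1, res.qalys2],
            "cost_per_qaly": [res.cost_utility_ratio_1,
                              res.cost_utility_ratio_2],
            "icur": [res.icur, np.nan],
        }
    )
    table.to_csv(outdir / "cua_table.csv", index=False)
    return {"cua": res, "cost_effective": decide(res, cfg.wtp)}

def _stage_dsa(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    tornado = run_dsa(cfg)
    tornado.to_csv(outdir / "tornado.csv", index=False)
    return {"tornado": tornado}

def _stage_psa(cfg: RunConfig, outdir: Path, seed: int) -> dict[str, Any]:
    samples = run_psa(cfg, seed=seed)
    samples.to_csv(outdir / "psa_samples.csv", index=False)
    grid = np.linspace(0.0, 3.0 * cfg.gdp_per_capita,
                       cfg.uncertainty.ceac_grid_points)
    curve = ceac(samples, grid)
    curve.to_csv(outdir / "ceac.csv", index=False)
    return {"psa": samples, "ceac": curve}

def _stage_bia(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    if cfg.bia is None:
        return {"bia": None}
    table = run_bia(BIAInputs.from_dict(cfg.bia))
    table.to_csv(outdir / "bia.csv", index=False)
    return {"bia": table}


def run_pipeline(
    cfg: RunConfig | None = None,
    outdir: str | Path = "ducem_run",
    seed: int | None = None,
) -> dict[str, Any]:
    """Execute the full analysis; returns the in-memory stage results.

    ``seed`` overrides the configured seed for the stochastic stages
    (IPD simulation and PSA).  Identical configuration and seed produce
    byte-identical outputs.
    """
    if cfg is None:
        cfg = default_config()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_sha256": config_hash(cfg),
        "seed": seed,
        "stages": {},
    }
    state: dict[str, Any] = {}
    stages: list[tuple[str, Callable[[], dict[str, Any]]]] = [
        ("simulate", lambda: _stage_simulate(cfg, outdir, seed)),
        ("maic", lambda: _stage_maic(cfg, outdir, state)),
        ("cua", lambda: _stage_cua(cfg, outdir)),
        ("dsa", lambda: _stage_dsa(cfg, outdir)),
        ("psa", lambda: _stage_psa(cfg, outdir, seed)),
        ("bia", lambda: _stage_bia(cfg, outdir)),
    ]
    try:
        for name, fn in stages:
            try:
                state.update(fn())
                manifest["stages"][name] = "ok"
            except Exception as exc:
                manifest["stages"][name] = f"failed: {exc}"
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return state
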