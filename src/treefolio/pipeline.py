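"""End-to-end orchestration: generate -> value -> optimize -> sweep -> evaluate.

``run_pipeline`` executes the whole seeded analysis from a ``RunConfig``,
writes every intermediate artifact as delimited text under an output
directory, and emits a plain-text JSON manifest (file hashes, seeds, solver
statuses, versions).  Outputs carry no timestamps, so identical configs and
seeds produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings

import numpy as np
import pandas as pd

from . import __version__
from .config import OptimizationSpec, RunConfig, run_config_to_yaml
from .evaluate import (
    cross_evaluation_matrix,
    empirical_cvar,
    evaluate_strategy,
    loss_probability,
    regret_table,
    species_group_covariance,
)
from .optimize import (
    cvar_optimal,
    expected_value_optimal,
    mixed_technology_sweep,
    scenario_optimal,
    write_strategy,
)
from .synthetic import generate_ensemble, generate_grid, write_ensemble, write_grid
from .valuation import assemble_valuation

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"
FOCUS_PATHWAYS = ("rcp26", "rcp45", "rcp85")


class PipelineError(RuntimeError):
    """A stage failed; the stage name is part of the message."""


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return _Ctx()


def build_valuation(config: RunConfig):
    """Regenerate the seeded inputs of a run: grid, ensemble and valuation.

    Returns ``(grid, cers, growths, probs, valuation)``; every quantity is a
    deterministic function of the config and its master seed.
    """
    config.validate()
    grid = generate_grid(config.grid.n_cells, config.seed, config.grid)
    cers, growths, probs = generate_ensemble(
        grid, config.n_cer, config.seed, config.cer, config.species,
        config.valuation.horizon,
    )
    valuation = assemble_valuation(
        growths, cers, grid,
        rho=config.valuation.rho, horizon=config.valuation.horizon, probs=probs,
    )
    return grid, cers, growths, probs, valuation


def base_spec(config: RunConfig) -> OptimizationSpec:
    return OptimizationSpec(
        target_q=config.target_q,
        beta=config.beta,
        gamma=None,
        value_form=config.headline_value_form,
    )


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    files: dict[str, str] = {}
    statuses: dict[str, str] = {}
    notes: list[str] = []

    def _write(name, writer):
        path = os.path.join(outdir, name)
        writer(path)
        files[name] = path
        return path

    with _stage("config"):
        _write("config.yaml", lambda p: run_config_to_yaml(config, p))

    with _stage("grid"):
        grid = generate_grid(config.grid.n_cells, config.seed, config.grid)
        _write("grid.csv", lambda p: write_grid(grid, p))

    with _stage("ensemble"):
        cers, growths, probs = generate_ensemble(
            grid, config.n_cer, config.seed, config.cer, config.species,
            config.valuation.horizon,
        )
        written = write_ensemble(cers, outdir)
        for key, path in written.items():
            files[os.path.basename(path)] = path

    with _stage("valuation"):
        valuation = assemble_valuation(
            growths, cers, grid,
            rho=config.valuation.rho, horizon=config.valuation.horizon, probs=probs,
        )
        _write("valuation.csv", valuation.write)
        n_excluded = int((~valuation.retained).sum())
        notes.append(f"excluded net-emitting cell-species pairs: {n_excluded}")

    if config.write_growth_tables:
        with _stage("growth_tables"):
            from .synthetic import growth_table

            frames = [
                growth_table(g, grid, valuation.rotation[:, :, s].astype(int),
                             config.valuation.horizon)
                for s, g in enumerate(growths)
            ]
            _write(
                "growth.csv",
                lambda p: pd.concat(frames, ignore_index=True).to_csv(
                    p, index=False, float_format=_FLOAT_FMT
                ),
            )

    spec = base_spec(config)
    solutions = {}
    with _stage("optimize"):
        focus = []
        for pathway in FOCUS_PATHWAYS:
            idx = next(
                (s for s, c in enumerate(cers) if c.pathway == pathway), None
            )
            if idx is None:
                notes.append(f"no CER drawn for pathway {pathway}; focus strategy skipped")
            else:
                focus.append((f"P-{pathway}", idx))
        if not focus:  # tiny ensembles may miss every focus pathway
            focus = [(f"P-{cers[0].pathway}", 0)]
        for label, idx in focus:
            solutions[label] = scenario_optimal(valuation, idx, spec, label=label)
        solutions["P-EV"] = expected_value_optimal(valuation, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-integer (1-beta)S noted below
            solutions["P-RA"] = cvar_optimal(valuation, spec)
        tail = (1.0 - config.beta) * config.n_cer
        if abs(tail - round(tail)) > 1e-9:
            notes.append(f"(1-beta)*S = {tail:.6g} non-integer; CVaR interpolates")
        for label, sol in solutions.items():
            statuses[label] = f"{sol.solver_status} (gap={sol.mip_gap:.3g})"
            fname = f"strategy_{label}.csv"
            _write(fname, lambda p, s=sol: write_strategy(s.strategy, p, spec))

    with _stage("sweep"):
        sweep_spec = dataclasses.replace(spec, value_form=config.sweep_value_form)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sweep = mixed_technology_sweep(valuation, sweep_spec, config.gamma_grid)
        _write("sweep.csv", lambda p: sweep.to_csv(p, index=False, float_format=_FLOAT_FMT))

    with _stage("evaluate"):
        strategies = {label: sol.strategy for label, sol in solutions.items()}
        matrix = cross_evaluation_matrix(strategies, valuation, spec)
        _write("cross_values.csv", lambda p: matrix.to_csv(p, float_format=_FLOAT_FMT))
        _write("regret.csv", lambda p: regret_table(matrix).to_csv(p, float_format=_FLOAT_FMT))

        rows = []
        cov_rows = []
        for label, sol in solutions.items():
            dist = evaluate_strategy(sol.strategy, valuation, spec, label=label)
            row = dist.summary_row()
            row["loss_prob"] = loss_probability(
                dist.per_cer_value, valuation.probs, config.loss_threshold
            )
            row["z"] = sol.strategy.z
            for sp, ha in sol.hectares.items():
                row[f"hectares_{sp}"] = ha
            rows.append(row)
            if sol.strategy.assignment and valuation.n_cer >= 2:
                cov = species_group_covariance(sol.strategy, valuation, units=1e9)
                names = list(cov.index)
                cov_rows.append(
                    {
                        "label": label,
                        "var_" + names[0]: cov.iloc[0, 0],
                        "var_" + names[1]: cov.iloc[1, 1],
                        "cov": cov.iloc[0, 1],
                    }
                )
        summary = pd.DataFrame(rows)
        _write("summary.csv", lambda p: summary.to_csv(p, index=False, float_format=_FLOAT_FMT))
        covariance = pd.DataFrame(cov_rows)
        _write("covariance.csv",
               lambda p: covariance.to_csv(p, index=False, float_format=_FLOAT_FMT))

        comparison = compare_strategies(
            {label: sol.per_cer_value for label, sol in solutions.items()},
            valuation.probs,
            config.beta,
        )
        _write("comparison.csv",
               lambda p: comparison.to_csv(p, index=False, float_format=_FLOAT_FMT))

    with _stage("manifest"):
        manifest = {
            "package": "treefolio",
            "version": __version__,
            "seed": config.seed,
            "n_cells": config.grid.n_cells,
            "n_cer": config.n_cer,
            "target_q_MtCO2e": config.target_q,
            "beta": config.beta,
            "solver_statuses": statuses,
            "notes": notes,
            "files": {name: _sha256(path) for name, path in sorted(files.items())},
        }
        path = os.path.join(outdir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["manifest_path"] = path

    return manifest


def compare_strategies(per_cer_values: dict, probs, beta: float) -> pd.DataFrame:
    """EV / CVaR ordering table for >= 2 stored strategies.

    ``per_cer_values`` maps label -> (S,) value vector.  Regret is measured
    per CER against the best stored strategy and summarized by its maximum.
    """
    if len(per_cer_values) < 2:
        raise ValueError("need at least two strategies to compare")
    probs = np.asarray(probs, dtype=float)
    matrix = pd.DataFrame(per_cer_values).T  # labels x CERs
    best = matrix.max(axis=0)
    rows = []
    for label in matrix.index:
        values = matrix.loc[label].to_numpy()
        regret = best.to_numpy() - values
        rows.append(
            {
                "label": label,
                "expected_value": float(probs @ values),
                "cvar_beta": empirical_cvar(values, probs, beta),
                "min": float(values.min()),
                "max": float(values.max()),
                "max_regret": float(regret.max()),
                "mean_regret": float(probs @ regret),
            }
        )
    return pd.DataFrame(rows)


def load_manifest(outdir: str) -> dict:
    with open(os.path.join(outdir, "manifest.json")) as fh:
        return json.load(fh)


def verify_manifest(outdir: str) -> bool:
    """Re-hash every referenced file; True iff all exist and match."""
    manifest = load_manifest(outdir)
    for name, digest in manifest["files"].items():
        path = os.path.join(outdir, name)
        if not os.path.exists(path) or _sha256(path) != digest:
            return False
    return True
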