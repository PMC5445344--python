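"""Config-driven orchestration of the analysis stages: tree preparation,
regime-model ranking by marginal likelihood, SSE scans/MCMC, and ΔAIC nulls.

A run is described by a YAML document (see :class:`RunConfig`); each stage
writes TSV/JSON artifacts plus a log line with its derived seed, and the
result bundle keeps every stage's in-memory result addressable by name.
Stage seeds are derived deterministically from the master seed via
``numpy.random.SeedSequence(master).spawn``, so a rerun with the same config
reproduces deterministic stages bit-identically.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .birthdeath import Regime, RegimeModel, fit_regime_ml
from .nulls import delta_aic_null, summarize_null
from .sse import ConstraintSpec, TipStates, aic_table, enumerate_geosse_models, fit_ml, mcmc_sse
from .ti import PowerLadder, compare_models, ti_logml, treeset_logml
from .treeio import CladeDefinition, branching_times, read_newick, read_newick_list

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "report", "load_config"]

log = logging.getLogger("saxdiv")


class PipelineError(RuntimeError):
    """A stage failed; partial results are preserved on the exception."""

    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    tree_text: str | None = None
    trees_text: str | None = None
    clades: dict[str, list[str]] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_dict(cls, doc: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path.cwd()

        def read_maybe(key):
            if key in doc:
                return doc[key]
            if f"{key}_file" in doc:
                return (base / doc[f"{key}_file"]).read_text()
            return None

        clades = {}
        for name, spec in (doc.get("clades") or {}).items():
            if isinstance(spec, str):
                spec = (base / spec).read_text().split()
            clades[name] = list(spec)
        stages = doc.get("stages") or []
        for st in stages:
            if "kind" not in st:
                raise ValueError("every stage needs a 'kind'")
        return cls(
            tree_text=read_maybe("tree"),
            trees_text=read_maybe("trees"),
            clades=clades,
            stages=stages,
            seed=int(doc.get("seed", 0)),
            outdir=doc.get("outdir"),
        )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    return RunConfig.from_dict(yaml.safe_load(path.read_text()), base=path.parent)


def _clade(config: RunConfig, name: str) -> CladeDefinition:
    if name not in config.clades:
        raise ValueError(f"unknown clade {name!r}")
    return CladeDefinition(name, frozenset(config.clades[name]))


def _regime_model(config: RunConfig, spec: dict) -> RegimeModel:
    regimes = []
    for item in spec["regimes"]:
        clade = _clade(config, item["clade"]) if item.get("clade") else None
        regimes.append(
            Regime(
                clade,
                item.get("process", "BD"),
                item.get("link"),
                float(item.get("rho", 1.0)),
            )
        )
    return RegimeModel(regimes, name=spec.get("name", "model"))


def _tips_from_stage(stage: dict, n_states_hint: int | None = None) -> TipStates:
    rho = stage.get("rho", 1.0)
    if isinstance(rho, dict):
        rho = [rho[k] for k in sorted(rho)]
    states = stage["states"]
    if isinstance(states, str):
        return TipStates.from_csv(states, rho=rho)
    if all(isinstance(v, str) for v in states.values()):
        return TipStates.geographic(states, rho)
    k = n_states_hint or (max(states.values()) + 1)
    return TipStates(dict(states), k, np.atleast_1d(rho))


def _constraints(spec) -> ConstraintSpec:
    if spec in (None, "full"):
        return ConstraintSpec()
    return ConstraintSpec(
        tuple(tuple(p) for p in spec.get("equalities", ())),
        tuple(spec.get("zeros", ())),
        spec.get("name", ""),
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order; returns the result bundle.

    Each stage's tabular output is written to ``<outdir>/<stage>.tsv`` (plus a
    JSON sidecar with scalars) when an output directory is configured.
    """
    t_start = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    log.info("saxdiv %s pipeline start, master seed %d", __version__, config.seed)

    tree = read_newick(config.tree_text) if config.tree_text else None
    trees = read_newick_list(config.trees_text) if config.trees_text else None
    if tree is None and trees is not None:
        tree = trees[0]

    bundle: dict[str, Any] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(max(len(config.stages), 1))
    for i, stage in enumerate(config.stages):
        kind = stage["kind"]
        name = stage.get("name", f"{i:02d}_{kind}")
        seed = int(seeds[i].generate_state(1)[0] % (2**31))
        log.info("stage %s (%s) seed=%d", name, kind, seed)
        t0 = time.time()
        try:
            result = _run_stage(kind, stage, config, tree, trees, seed)
        except Exception as exc:
            if outdir:
                (outdir / f"{name}.error.json").write_text(
                    json.dumps({"stage": name, "kind": kind, "error": str(exc)})
                )
            raise PipelineError(name, exc, bundle) from exc
        bundle[name] = result
        log.info("stage %s done in %.2fs", name, time.time() - t0)
        if outdir:
            _write_stage(outdir, name, result, seed)
    log.info("pipeline done in %.2fs", time.time() - t_start)
    return bundle


def _run_stage(kind, stage, config, tree, trees, seed):
    if kind == "tree_stats":
        if tree is None:
            raise ValueError("tree_stats needs a tree")
        bt = branching_times(tree)
        return {
            "scalars": {
                "n_tips": tree.n_tips,
                "crown_age": tree.crown_age,
                "total_branch_length": tree.total_branch_length(),
            },
            "table": pd.DataFrame({"branching_time": bt}),
        }

    if kind == "regime_comparison":
        models = [_regime_model(config, m) for m in stage["models"]]
        ladder = PowerLadder.friel_pettitt(int(stage.get("ladder", 11)))
        iters = int(stage.get("iterations", 20_000))
        engine = stage.get("engine", "ti")
        rows, logmls = [], {}
        mseeds = np.random.SeedSequence(seed).spawn(len(models))
        for model, ms in zip(models, mseeds):
            ms = int(ms.generate_state(1)[0] % (2**31))
            if engine == "ml":
                params, ll, aic = fit_regime_ml(tree, model)
                rows.append({"model": model.name, "loglik": ll, "aic": aic,
                             "k": model.n_free_params})
                logmls[model.name] = -0.5 * aic  # rank by AIC when ML engine
            elif trees is not None and stage.get("treeset", False):
                res = treeset_logml(trees, model, ladder, iters, ms)
                logmls[model.name] = res.logml
            else:
                lml, _ = ti_logml(tree, model, ladder, iters, ms)
                logmls[model.name] = lml
        comp = compare_models(logmls)
        table = comp.table.reset_index(names="model")
        if rows:
            table = table.merge(pd.DataFrame(rows), on="model", how="left")
        return {"scalars": {"best": comp.best}, "table": table}

    if kind == "sse_scan":
        family = stage["family"]
        tips = _tips_from_stage(stage)
        if stage.get("models") == "geosse_enumeration":
            specs = enumerate_geosse_models()
        else:
            specs = [_constraints(m) for m in stage.get("models", [None])]
        fits = [
            fit_ml(tree, tips, family, c, starts=int(stage.get("starts", 3)),
                   seed=seed + j)
            for j, c in enumerate(specs)
        ]
        table = aic_table(fits)
        return {"scalars": {"best": table["model"].iloc[0]}, "table": table,
                "fits": fits}

    if kind == "sse_mcmc":
        family = stage["family"]
        tips = _tips_from_stage(stage)
        trace, summary = mcmc_sse(
            tree, tips, family, _constraints(stage.get("constraints")),
            iterations=int(stage.get("iterations", 50_000)),
            burn_in=int(stage.get("burn_in", 500)),
            seed=seed,
        )
        return {"scalars": {"accept_rate": trace.accept_rate},
                "table": summary, "trace": trace}

    if kind == "null":
        family = stage["family"]
        tips = _tips_from_stage(stage)
        res = delta_aic_null(
            tree, tips, family, stage["rates"],
            _constraints(stage.get("unconstrained")),
            _constraints(stage["constrained"]),
            nsim=int(stage.get("nsim", 100)),
            seed=seed,
            starts=int(stage.get("starts", 2)),
        )
        return {"scalars": {"p": res.p,
                            "empirical_delta_aic": res.empirical_delta_aic},
                "table": summarize_null(res), "null": res}

    raise ValueError(f"unknown stage kind {kind!r}")


def _write_stage(outdir: Path, name: str, result: dict, seed: int) -> None:
    table = result.get("table")
    if isinstance(table, pd.DataFrame):
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    scalars = dict(result.get("scalars", {}))
    scalars["seed"] = seed
    scalars["saxdiv_version"] = __version__
    (outdir / f"{name}.json").write_text(json.dumps(scalars, default=str, indent=1))


def report(bundle: dict[str, Any]) -> str:
    """Human-readable summary of a result bundle (empty bundle -> empty report)."""
    lines = []
    for name, result in bundle.items():
        lines.append(f"== {name} ==")
        for k, v in result.get("scalars", {}).items():
            lines.append(f"  {k}: {v}")
        table = result.get("table")
        if isinstance(table, pd.DataFrame) and not table.empty:
            lines.append(table.to_string(index=False, float_format="%.4f"))
        lines.append("")
    return "\n".join(lines)
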