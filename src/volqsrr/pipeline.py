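"""End-to-end orchestration of the QSRR and chemotype workflows.

``run_qsrr`` drives descriptor computation -> collinearity pre-filter ->
genetic-algorithm subset selection -> boosted-trees grid search ->
goodness-of-fit reporting, per year, writing every artifact plus a
reproducibility manifest under a run directory named by the configuration
hash.  ``run_chemotypes`` drives composition clustering and rule-based
chemotype calls.  Both are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import descriptors as desc
from .boosting import BRTConfig, grid_search, predictor_importance
from .chemotypes import (
    assign_chemotype,
    complete_linkage,
    euclidean_distances,
    load_rules,
    to_newick,
    validate_composition,
)
from .selection import GAConfig, correlation_prefilter, ga_select
from .validation import FitMetrics, goodness_of_fit, metrics_frame
from .volatiles import VolatilesTable, load_table

__all__ = ["PipelineConfig", "run_qsrr", "run_chemotypes", "default_grid"]

logger = logging.getLogger(__name__)


def default_grid(seed: int = 0) -> list[BRTConfig]:
    """Small tuning grid inside the allowed hyperparameter ranges."""
    grid = []
    for lr in (0.05, 0.1):
        for sub in (0.5, 0.8):
            grid.append(BRTConfig(n_trees=500, learning_rate=lr,
                                  test_proportion=0.2, subsample=sub,
                                  seed=seed))
    return grid


@dataclass
class PipelineConfig:
    """Configuration of one QSRR run.

    ``descriptor_set`` chooses the feature space: ``"mandatory"`` restricts
    to the seven descriptors of the retention-index models (GA skipped),
    ``"catalogue"`` computes the full registered catalogue and runs the
    collinearity pre-filter plus GA selection.
    """

    fixture: str | None = None
    years: tuple[int, ...] = (2019, 2020)
    descriptor_set: str = "mandatory"
    prefilter_threshold: float = 0.95
    ga: GAConfig | None = None
    grid: list[BRTConfig] | None = None
    seed: int = 0
    outdir: str = "runs"

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _as_jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_qsrr(cfg: PipelineConfig) -> dict:
    """Execute the retention-index modeling pipeline; returns the report.

    Artifacts (descriptor table, selected subset, model JSON, predictions,
    fit metrics, manifest) are written under ``outdir/run-<confighash>``.
    Reruns with the same configuration are bit-identical.
    """
    rundir = Path(cfg.outdir) / f"run-{cfg.config_hash()}"
    rundir.mkdir(parents=True, exist_ok=True)
    t0 = _stage("load")
    try:
        table = load_table(cfg.fixture)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    _stage("descriptors")
    names = (desc.MANDATORY_DESCRIPTORS if cfg.descriptor_set == "mandatory"
             else desc.catalogue())
    try:
        feats = desc.descriptor_table(table, names=names)
    except Exception as exc:
        raise RuntimeError(f"stage 'descriptors' failed: {exc}") from exc
    feats.to_csv(rundir / "descriptors.csv")

    report: dict = {"n_compounds": len(table), "years": {},
                    "rundir": str(rundir)}
    metrics_all: dict[str, FitMetrics] = {}
    for year in cfg.years:
        yr = str(year)
        rows = [r.row_index for r in table.modeled(year)]
        X = feats.loc[[i for i in rows if i in feats.index]]
        y = pd.Series({i: table[i].ri(year) for i in X.index}, name="ri")

        if cfg.descriptor_set == "catalogue":
            _stage(f"prefilter {yr}")
            try:
                Xf = correlation_prefilter(X, cfg.prefilter_threshold)
            except Exception as exc:
                raise RuntimeError(f"stage 'prefilter' failed: {exc}") from exc
            _stage(f"ga {yr}")
            ga_cfg = cfg.ga or GAConfig(seed=cfg.seed)
            try:
                subset, trace = ga_select(Xf, y.to_numpy(), ga_cfg)
            except Exception as exc:
                raise RuntimeError(f"stage 'ga' failed: {exc}") from exc
        else:
            subset, trace = list(X.columns), []
        Xsel = X[subset]

        _stage(f"gridsearch {yr}")
        grid = cfg.grid if cfg.grid is not None else default_grid(cfg.seed)
        try:
            model, results = grid_search(Xsel, y.to_numpy(), grid, seed=cfg.seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'gridsearch' failed: {exc}") from exc
        results.to_csv(rundir / f"gridsearch_{yr}.csv", index=False)
        (rundir / f"model_{yr}.json").write_text(
            json.dumps(model.to_dict()) + "\n")

        _stage(f"validate {yr}")
        pred = model.predict(Xsel)
        preds = pd.DataFrame({"row_index": Xsel.index, "ri_obs": y.to_numpy(),
                              "ri_pred": pred}).set_index("row_index")
        preds.to_csv(rundir / f"predictions_{yr}.csv")
        n_params = len(subset)
        overall = goodness_of_fit(y.to_numpy(), pred, n_params=n_params)
        tr, te = model.train_indices_, model.test_indices_
        part = {}
        for part_name, idx in (("train", tr), ("test", te)):
            if idx.size > n_params + 1:
                part[part_name] = goodness_of_fit(
                    y.to_numpy()[idx], pred[idx], n_params=n_params)
        metrics_all[yr] = overall
        report["years"][yr] = {
            "n_modeled": int(len(y)),
            "subset": list(subset),
            "fitness_trace": trace,
            "best_config": {k: _as_jsonable(v) for k, v in results
                            .sort_values(["test_lse", "n_trees", "learning_rate"])
                            .iloc[0].to_dict().items()},
            "metrics_overall": dataclasses.asdict(overall),
            "metrics_partitions": {k: dataclasses.asdict(v)
                                   for k, v in part.items()},
            "importance": {str(k): float(v) for k, v in
                           predictor_importance(model).items()},
        }

    metrics_frame(metrics_all).to_csv(rundir / "metrics.csv")
    manifest = {
        "config": _as_jsonable(asdict(cfg)),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_compounds": len(table),
    }
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    (rundir / "report.json").write_text(
        json.dumps(_as_jsonable(report), indent=2, sort_keys=True) + "\n")
    report["manifest"] = manifest
    logger.info("run complete in %.1fs", time.perf_counter() - t0)
    return report


def run_chemotypes(
    composition: pd.DataFrame | str | Path,
    outdir: str | Path | None = None,
    rules_path: str | Path | None = None,
    strip_stereo: bool = False,
) -> tuple[str, pd.DataFrame]:
    """Cluster a composition matrix and call chemotypes per sample.

    Returns (newick, calls) and, when ``outdir`` is given, writes
    ``tree.nwk`` and ``chemotype_calls.csv``.
    """
    if not isinstance(composition, pd.DataFrame):
        composition = pd.read_csv(composition, index_col=0)
    m = validate_composition(composition)
    if len(m) < 2:
        raise ValueError("need at least 2 samples for chemotype clustering")
    rules = load_rules(rules_path)
    dist = euclidean_distances(m)
    tree = complete_linkage(dist)
    newick = to_newick(tree)
    calls = pd.DataFrame({
        "chemotype": [assign_chemotype(m.loc[s], rules,
                                       strip_stereo=strip_stereo)
                      for s in m.index]
    }, index=m.index)
    calls.index.name = "sample"
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(newick + "\n")
        calls.to_csv(outdir / "chemotype_calls.csv")
    return newick, calls
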