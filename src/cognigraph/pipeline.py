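"""One-command end-to-end run.

Stage order mirrors the analysis protocol: generate (or load) the cohort,
standardize/encode features, build the similarity graph, split with
class-and-sex awareness, grid-search-train each requested model, evaluate on
the test partition, and write every artifact (cohort CSV, feature CSV +
manifest, edge TSV, graph summary JSON, per-model histories and reports, a
comparison table).

A single master seed fans out to per-stage seeds by fixed offsets, so any
stage can be re-run in isolation and the whole bundle is a pure function of
(config, seed).  If the requested output directory already holds files, a
versioned sibling (``<dir>-001``, ...) is used instead of overwriting.
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

from . import cohort as cohort_mod
from . import graph as graph_mod
from . import preprocessing as prep
from .cohort import CohortTable, default_config, generate_cohort, read_cohort_csv
from .models import ModelSpec, save_params
from .train import DEFAULT_GRID, evaluate, grid_search

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config",
           "LABEL_TO_INT"]

log = logging.getLogger("cognigraph")

LABEL_TO_INT = {"Control": 0, "MCI": 1, "AD": 2}

# Fixed per-stage seed offsets from the master seed.
SEED_OFFSETS = {"cohort": 0, "split": 1, "MLP": 2, "GCN": 3, "GAT": 4}


@dataclass
class PipelineConfig:
    cohort_csv: str | None = None          # load instead of generating
    seed: int = 0
    percentile: float = 80.0
    bandwidth: float | str = "median"
    fractions: tuple[float, float, float] = prep.DEFAULT_FRACTIONS
    models: tuple[str, ...] = ("MLP", "GCN", "GAT")
    epochs: int = 100
    grid: dict = field(default_factory=lambda: {
        "learning_rate": list(DEFAULT_GRID["learning_rate"]),
        "weight_decay": list(DEFAULT_GRID["weight_decay"]),
    })
    cohort_config: dict | None = None      # overrides for the synthetic cohort
    out_dir: str = "cognigraph_out"
    plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fractions"] = list(self.fractions)
        d["models"] = list(self.models)
        return d


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "fractions" in raw:
        raw["fractions"] = tuple(raw["fractions"])
    if "models" in raw:
        raw["models"] = tuple(raw["models"])
    return PipelineConfig(**raw)


def _resolve_out_dir(base: Path) -> Path:
    if not base.exists() or not any(base.iterdir()):
        base.mkdir(parents=True, exist_ok=True)
        return base
    for k in range(1, 1000):
        candidate = base.parent / f"{base.name}-{k:03d}"
        if not candidate.exists():
            candidate.mkdir(parents=True)
            log.warning("output directory %s not empty; writing to %s",
                        base, candidate)
            return candidate
    raise RuntimeError("could not allocate a versioned output directory")


def _cohort_from_config(config: PipelineConfig) -> CohortTable:
    if config.cohort_csv:
        log.info("loading cohort from %s", config.cohort_csv)
        return read_cohort_csv(config.cohort_csv)
    base = default_config(seed=config.seed + SEED_OFFSETS["cohort"])
    if config.cohort_config:
        groups = []
        overrides = {g["label"]: g for g in config.cohort_config.get("groups", [])}
        for spec in base.groups:
            if spec.label in overrides:
                fields = {**dataclasses.asdict(spec), **overrides[spec.label]}
                for key in ("mmse_range", "moca_range"):
                    fields[key] = tuple(fields[key])
                spec = cohort_mod.GroupSpec(**fields)
            groups.append(spec)
        base = cohort_mod.CohortConfig(groups=tuple(groups), seed=base.seed)
    log.info("generating synthetic cohort (seed %d)", base.seed)
    return generate_cohort(base)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a summary dict (also written to disk)."""
    out = _resolve_out_dir(Path(config.out_dir))
    _json_dump(config.to_dict(), out / "pipeline_config.json")

    table = _cohort_from_config(config)
    cohort_mod.write_cohort_csv(table, out / "cohort.csv")

    features = prep.build_feature_matrix(table)
    features.to_frame().to_csv(out / "features.csv", index=False)
    _json_dump(features.encoding_manifest, out / "feature_manifest.json")
    _json_dump(features.scaler.to_dict(), out / "scaler.json")

    g = graph_mod.build_graph(features.values, percentile=config.percentile,
                              bandwidth=config.bandwidth)
    summary = graph_mod.graph_summary(g)
    log.info("graph: %d nodes, %d directed edge entries, avg degree %.1f, "
             "%d isolated (bandwidth %.4f, threshold %.4f)",
             summary.n_nodes, summary.n_edge_entries, summary.avg_degree,
             summary.n_isolated, g.bandwidth, g.threshold)
    edges = pd.DataFrame({
        "source": [features.row_ids[i] for i in g.edge_index[:, 0]],
        "target": [features.row_ids[j] for j in g.edge_index[:, 1]],
    })
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    _json_dump({**summary.to_dict(), "bandwidth": g.bandwidth,
                "threshold": g.threshold, "percentile": g.percentile},
               out / "graph_summary.json")

    split = prep.stratified_split(table, fractions=config.fractions,
                                  seed=config.seed + SEED_OFFSETS["split"])
    split.to_frame().to_csv(out / "split.csv", index=False)
    sizes = {p: int((split.partition == p).sum()) for p in prep.PARTITIONS}
    log.info("split sizes: %s", sizes)

    labels = table.records["diagnosis"].map(LABEL_TO_INT).to_numpy()
    masks = {p: split.mask(features.row_ids, p) for p in prep.PARTITIONS}

    comparison = []
    for kind in config.models:
        spec = ModelSpec.for_kind(kind)
        model_seed = config.seed + SEED_OFFSETS[kind]
        edge_index = None if kind == "MLP" else g.edge_index
        log.info("grid search for %s (seed %d, %d epochs, %dx%d grid)",
                 kind, model_seed, config.epochs,
                 len(config.grid["learning_rate"]),
                 len(config.grid["weight_decay"]))
        best_config, best_params, histories = grid_search(
            spec, features.values, edge_index, labels,
            masks["train"], masks["val"],
            grid={k: tuple(v) for k, v in config.grid.items()},
            epochs=config.epochs, seed=model_seed)
        log.info("%s winner: lr=%g wd=%g", kind,
                 best_config.learning_rate, best_config.weight_decay)
        report = evaluate(best_params, spec, features.values, edge_index,
                          labels, masks["test"])
        win_hist = histories[(best_config.learning_rate,
                              best_config.weight_decay)]
        win_hist.to_frame().to_csv(out / f"history_{kind}.csv", index=False)
        _json_dump(report.to_dict(), out / f"eval_{kind}.json")
        pd.DataFrame(report.confusion,
                     index=list(LABEL_TO_INT), columns=list(LABEL_TO_INT)
                     ).to_csv(out / f"confusion_{kind}.csv")
        _json_dump({"learning_rate": best_config.learning_rate,
                    "weight_decay": best_config.weight_decay,
                    "epochs": best_config.epochs, "seed": best_config.seed},
                   out / f"best_config_{kind}.json")
        save_params(best_params, out / f"params_{kind}.json")
        if config.plots:
            _plot_confusion(report.confusion, kind,
                            out / f"confusion_{kind}.png")
        comparison.append({
            "model": kind,
            "accuracy": report.accuracy,
            "weighted_ppv": report.weighted_ppv,
            "weighted_recall": report.weighted_recall,
            "learning_rate": best_config.learning_rate,
            "weight_decay": best_config.weight_decay,
        })

    comparison_df = pd.DataFrame(comparison)
    comparison_df.to_csv(out / "comparison.csv", index=False)
    result = {
        "out_dir": str(out),
        "graph": summary.to_dict(),
        "split_sizes": sizes,
        "comparison": comparison,
    }
    _json_dump(result, out / "summary.json")
    return result


def _plot_confusion(cm: np.ndarray, kind: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(cm, cmap="Blues")
    names = list(LABEL_TO_INT)
    ax.set_xticks(range(len(names)), names)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    ax.set_title(kind)
    for r in range(cm.shape[0]):
        for c in range(cm.shape[1]):
            ax.text(c, r, str(int(cm[r, c])), ha="center", va="center",
                    color="black" if cm[r, c] < cm.max() / 2 else "white")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
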