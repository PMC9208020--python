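"""TSV/JSON readers and writers, run configuration, and the pipeline driver.

All artifacts are plain text: labeled TSV matrices with an optional JSON
sidecar for metadata (subject, state, run, seed, generative parameters).
Every pipeline output directory carries a manifest with the package
version, seed, and a hash of the configuration, so identical inputs and
seed reproduce identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actflow import actflow_predict, compare_prediction_models, evaluate_predictions
from .fc import FCMatrix, FCStack, devectorize, edge_index_pairs, n_edges
from .latent import estimate_latent_fc, average_fc, summarize_loadings
from .simulate import simulate_actflow_activations, simulate_behavior, simulate_fc_stack
from .stats import compare_similarity, fc_similarity
from .behavior import cross_sample_ridge_predict, evaluate_behavior_prediction

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_stack",
    "write_stack",
    "RunConfig",
    "run_pipeline",
]


def write_matrix(matrix, path, row_labels=None, col_labels=None, sidecar: dict | None = None) -> None:
    """Write a labeled numeric matrix as TSV (values at full precision)."""
    path = Path(path)
    m = np.asarray(matrix, dtype=float)
    df = pd.DataFrame(m, index=row_labels, columns=col_labels)
    df.to_csv(path, sep="\t", float_format="%.17g")
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path) -> pd.DataFrame:
    """Read a labeled TSV matrix, validating shape and labels."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    seen = set()
    for c in cols:
        if c in seen:
            raise ValueError(f"duplicate column label {c!r} in {path}")
        seen.add(c)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row label {dup!r} in {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for i, row in enumerate(values):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
                    ) from None
    if not np.all(np.isfinite(values.astype(float))):
        raise ValueError(f"non-finite values in {path}")
    return df


def read_fc_matrix(path, state_label: str = "rest", subject_id: str = "sub-0") -> FCMatrix:
    df = read_matrix(path)
    return FCMatrix(values=df.to_numpy(), state_label=state_label, subject_id=subject_id)


def write_stack(stack: FCStack, path) -> None:
    """Write an FC stack as a long-format TSV (subject, state, edge, value)."""
    path = Path(path)
    n, s, e = stack.values.shape
    sub = np.repeat(stack.subject_ids, s * e)
    st = np.tile(np.repeat(stack.state_labels, e), n)
    edge = np.tile(np.arange(e), n * s)
    pd.DataFrame(
        {"subject": sub, "state": st, "edge": edge, "value": stack.values.ravel()}
    ).to_csv(path, sep="\t", index=False)
    sidecar = {
        "n_subjects": n,
        "n_states": s,
        "n_edges": e,
        "state_labels": stack.state_labels,
        "subject_ids": stack.subject_ids,
        "edge_index": [list(p) for p in stack.edge_index],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_stack(path) -> FCStack:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n, s, e = meta["n_subjects"], meta["n_states"], meta["n_edges"]
    values = df["value"].to_numpy().reshape(n, s, e)
    return FCStack(
        values=values,
        edge_index=[tuple(p) for p in meta["edge_index"]],
        state_labels=meta["state_labels"],
        subject_ids=meta["subject_ids"],
    )


@dataclasses.dataclass
class RunConfig:
    """Configuration for a full synthetic-study pipeline run."""

    out_dir: str
    seed: int = 0
    n_subjects: int = 40
    n_regions: int = 20
    n_states: int = 9
    loading: float = 0.7
    n_conditions: int = 6
    n_measures: int = 11
    factor_method: str = "minres"
    exclude_state: str | None = None
    alpha: float = 0.05
    tails: str = "two"
    stack_path: str | None = None  # fit an existing stack instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.stack_path is not None and not Path(cfg.stack_path).exists():
            raise ValueError(f"stack_path {cfg.stack_path!r} does not exist")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Simulate (or load), fit latent FC with LOSO, and run every analysis.

    Stages: fc stack -> latent / average FC -> held-out-state similarity
    -> activity-flow prediction -> g prediction.  Any stage failure
    aborts with the stage name; completed outputs are listed in the
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": [],
    }
    stage = "simulate"
    try:
        if config.stack_path:
            stack = read_stack(config.stack_path)
            truth = None
        else:
            stack, truth = simulate_fc_stack(
                config.n_subjects,
                config.n_regions,
                config.n_states,
                loading_spec=config.loading,
                seed=config.seed,
            )
        write_stack(stack, out / "stack.tsv")
        manifest["stages"].append(stage)

        stage = "latent"
        latent = estimate_latent_fc(stack, exclude_state=config.exclude_state, method=config.factor_method)
        write_matrix(
            latent.scores,
            out / "latent_scores.tsv",
            row_labels=latent.subject_ids,
            col_labels=[f"e{i}" for i in range(latent.n_edges)],
            sidecar={"seed": config.seed, "method": config.factor_method,
                     "excluded_state": config.exclude_state,
                     "n_fallback_edges": int(latent.fallback_mask.sum())},
        )
        write_matrix(latent.group_matrix, out / "latent_group_matrix.tsv")
        summarize_loadings(latent).to_csv(out / "loading_summary.tsv", sep="\t")
        avg = average_fc(stack)
        write_matrix(avg, out / "average_fc.tsv")
        manifest["stages"].append(stage)

        stage = "similarity"
        rest_label = stack.state_labels[0]
        task_labels = stack.state_labels[1:]
        rest_edges = stack.state_slice(rest_label)
        sim_latent, sim_rest = [], []
        for held_out in task_labels:
            loso = estimate_latent_fc(stack, exclude_state=held_out, method=config.factor_method)
            held = stack.state_slice(held_out)
            sim_latent.append(
                [fc_similarity(loso.scores[i], held[i]) for i in range(stack.n_subjects)]
            )
            sim_rest.append(
                [fc_similarity(rest_edges[i], held[i]) for i in range(stack.n_subjects)]
            )
        sim_table = compare_similarity(
            np.array(sim_latent).T,
            np.array(sim_rest).T,
            alpha=config.alpha,
            comparison_labels=list(task_labels),
            tails=config.tails,
        )
        sim_table.to_csv(out / "similarity_comparison.tsv", sep="\t")
        manifest["stages"].append(stage)

        stage = "actflow"
        # activations generated over each subject's cross-state average
        # connectivity; latent-FC and rest-FC models compete to predict them
        preds_latent, preds_rest, actuals = [], [], []
        latent_full = estimate_latent_fc(stack, method=config.factor_method)
        for i in range(stack.n_subjects):
            gen_fc = devectorize(avg[i], stack.n_regions, diagonal=0.0)
            act, _ = simulate_actflow_activations(
                gen_fc, config.n_conditions, seed=(config.seed * 1009 + i) % (2**31)
            )
            subj_latent = devectorize(latent_full.scores[i], stack.n_regions, diagonal=0.0)
            subj_rest = devectorize(rest_edges[i], stack.n_regions, diagonal=0.0)
            preds_latent.append(actflow_predict(act, subj_latent))
            preds_rest.append(actflow_predict(act, subj_rest))
            actuals.append(act.values)
        ev_latent = evaluate_predictions(preds_latent, actuals, axis="region")
        ev_rest = evaluate_predictions(preds_rest, actuals, axis="region")
        compare_prediction_models(ev_latent, ev_rest, alpha=config.alpha, tails=config.tails).to_csv(
            out / "actflow_region_comparison.tsv", sep="\t"
        )
        manifest["stages"].append(stage)

        stage = "predict-g"
        if truth is not None and stack.n_subjects >= 40:
            behavior = simulate_behavior(truth, n_measures=config.n_measures, seed=config.seed)
            half = stack.n_subjects // 2
            splits = np.array(["exploratory"] * half + ["validation"] * (stack.n_subjects - half))
            pred_latent, actual = cross_sample_ridge_predict(latent_full.scores, behavior, splits)
            pred_rest, _ = cross_sample_ridge_predict(rest_edges, behavior, splits)
            result = evaluate_behavior_prediction(pred_latent, actual, splits, predicted_b=pred_rest)
            meta = result.pop("meta", None)
            if meta is not None:
                result["meta"] = {"pooled_delta_z": meta.pooled_z, "chi_square": meta.chi_square, "p": meta.p}
            (out / "g_prediction.json").write_text(json.dumps(result, indent=2, default=float))
            manifest["stages"].append(stage)
        else:
            logger.info("skipping g prediction (no ground truth or too few subjects)")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
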