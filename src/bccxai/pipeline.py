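"""End-to-end orchestration: simulate -> consensus -> train -> evaluate -> xai.

Runs the whole desk-scale workflow on synthetic data and leaves a
reproducibility manifest (seeds, config snapshot, artifact paths, step
timings) next to the artifacts.  Each step consumes the previous step's
serialized outputs; a step whose outputs already exist under a matching
config hash is skipped on rerun.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import cohort_agreement_report
from .consensus import DawidSkeneConsensus
from .metrics import _confusion_rates
from .nn.gradcam import gradcam
from .nn.model import MultiTaskPatternCNN
from .patterns import PATTERN_NAMES, encode_diagnoses
from .synthetic import (
    RaterSpec,
    generate_lesion_dataset,
    load_annotations,
    load_dataset,
    save_dataset,
    simulate_raters,
)
from .training import StageConfig, TrainConfig, evaluate_model, stratified_kfold_split

DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_images": 300,
        "image_size": 64,
        "prevalence": [0.35, 0.30, 0.25, 0.15, 0.15, 0.12, 0.30],
        "n_raters": 4,
        "rater_sensitivity": 0.85,
        "rater_specificity": 0.90,
    },
    "consensus": {"tol": 1e-6, "max_iter": 500, "init": "majority"},
    "train": {"test_fold": 0, "k_folds": 5},
    "xai": {"alpha": 0.05, "n_bins": 50, "alternative": "two_sided",
            "head": "binary"},
}


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _merge(v, override.get(k, {}))
        else:
            out[k] = override.get(k, v)
    return out


def _config_hash(config: dict, seed: int) -> str:
    blob = json.dumps({"config": config, "seed": seed}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(path: Path, step: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"step '{step}' needs missing artifact {path}; "
            f"rerun step '{produced_by}' first"
        )
    return path


def run_pipeline(out_dir, seed: int = 0, config: dict | None = None,
                 train_config: TrainConfig | None = None) -> dict:
    """Run all five steps; returns the manifest (also written to disk).

    ``config`` overrides :data:`DEFAULT_CONFIG` entries; ``train_config``
    overrides the stage schedule (its seed is forced to the pipeline seed).
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg, seed)
    manifest_path = out / "manifest.json"
    manifest = {
        "tool": "bccxai",
        "version": __version__,
        "seed": int(seed),
        "config": cfg,
        "config_hash": chash,
        "steps": {},
        "paths": {},
    }
    prior = {}
    if manifest_path.exists():
        try:
            with open(manifest_path) as fh:
                prior = json.load(fh)
        except json.JSONDecodeError:
            raise RuntimeError(
                f"corrupt manifest {manifest_path}; delete it or the "
                "output directory and rerun"
            )
    resume = prior.get("config_hash") == chash

    def _step(name, outputs, fn):
        paths = [out / p for p in outputs]
        if resume and all(p.exists() for p in paths) and name in prior.get(
            "steps", {}
        ):
            manifest["steps"][name] = {**prior["steps"][name], "resumed": True}
        else:
            t0 = time.perf_counter()
            fn()
            manifest["steps"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "resumed": False,
            }
        manifest["paths"][name] = [str(p) for p in paths]
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)

    # ---------------------------------------------------------------- 1 simulate
    sim = cfg["simulate"]
    data_dir = out / "data"

    def do_simulate():
        ds = generate_lesion_dataset(
            n_images=sim["n_images"], prevalence=sim["prevalence"],
            image_size=sim["image_size"], seed=seed,
        )
        specs = [
            RaterSpec(sim["rater_sensitivity"], sim["rater_specificity"])
            for _ in range(sim["n_raters"])
        ]
        votes = simulate_raters(ds.true_labels, specs, seed=seed)
        save_dataset(ds, data_dir, votes=votes)

    _step("simulate", ["data/labels.csv", "data/annotations.csv",
                       "data/params.json"], do_simulate)

    # ---------------------------------------------------------------- 2 consensus
    def do_consensus():
        votes, image_ids, rater_ids = load_annotations(
            _require(data_dir / "annotations.csv", "consensus", "simulate")
        )
        est = DawidSkeneConsensus(**cfg["consensus"]).fit(votes)
        sr = pd.DataFrame(est.labels_, columns=list(PATTERN_NAMES))
        sr.insert(0, "image_id", image_ids)
        sr.to_csv(out / "sr.csv", index=False)
        profiles = []
        for r, rid in enumerate(rater_ids):
            for j, name in enumerate(PATTERN_NAMES):
                profiles.append({
                    "rater_id": rid, "pattern": name,
                    "sensitivity": est.sensitivity_[r, j],
                    "specificity": est.specificity_[r, j],
                })
        pd.DataFrame(profiles).to_csv(out / "rater_profiles.csv", index=False)
        with open(out / "consensus_fit.json", "w") as fh:
            json.dump({
                "converged": est.converged_.tolist(),
                "n_iter": est.n_iter_.tolist(),
                "estimable": est.estimable_.tolist(),
                "prevalence": est.prevalence_.tolist(),
                "loglik_traces": [t.tolist() for t in est.loglik_traces_],
            }, fh, indent=2)

    _step("consensus", ["sr.csv", "rater_profiles.csv", "consensus_fit.json"],
          do_consensus)

    # ---------------------------------------------------------------- 3 train
    tcfg = train_config if train_config is not None else TrainConfig()
    tcfg.seed = int(seed)
    tcfg.k_folds = cfg["train"]["k_folds"]

    def _load_sr():
        sr = pd.read_csv(_require(out / "sr.csv", "train", "consensus"))
        return sr[list(PATTERN_NAMES)].to_numpy().astype(int)

    def _splits(sr_labels):
        strat = np.column_stack([sr_labels, encode_diagnoses(sr_labels)])
        folds = stratified_kfold_split(strat, k=tcfg.k_folds, seed=seed)
        test_idx = folds[cfg["train"]["test_fold"]]
        train_idx = np.setdiff1d(np.arange(sr_labels.shape[0]), test_idx)
        return train_idx, test_idx

    def do_train():
        ds = load_dataset(data_dir)
        sr_labels = _load_sr()
        train_idx, _ = _splits(sr_labels)
        X = np.stack(ds.images)
        model = MultiTaskPatternCNN(random_state=seed, config=tcfg)
        model.fit(X[train_idx], sr_labels[train_idx])
        model.save_weights(out / "model.npz")
        with open(out / "history.json", "w") as fh:
            json.dump(model.history_, fh, indent=2)

    _step("train", ["model.npz", "history.json"], do_train)

    # ---------------------------------------------------------------- 4 evaluate
    def do_evaluate():
        ds = load_dataset(data_dir)
        sr_labels = _load_sr()
        _, test_idx = _splits(sr_labels)
        X = np.stack(ds.images)
        model = MultiTaskPatternCNN(random_state=seed).load_weights(
            _require(out / "model.npz", "evaluate", "train")
        )
        model.history_ = {}
        report = evaluate_model(model, X[test_idx], sr_labels[test_idx])
        report["test_fold"] = cfg["train"]["test_fold"]
        report["n_train"] = int(X.shape[0] - test_idx.size)
        with open(out / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)

    _step("evaluate", ["metrics.json"], do_evaluate)

    # ---------------------------------------------------------------- 5 xai
    def do_xai():
        ds = load_dataset(data_dir)
        sr_labels = _load_sr()
        _, test_idx = _splits(sr_labels)
        X = np.stack(ds.images)
        model = MultiTaskPatternCNN(random_state=seed).load_weights(
            _require(out / "model.npz", "xai", "train")
        )
        xcfg = cfg["xai"]
        maps, masks, ids, correct = [], [], [], []
        diag_head = model.predict(X[test_idx])
        diag_ref = encode_diagnoses(sr_labels[test_idx])
        for pos, i in enumerate(test_idx):
            union = ds.union_mask(i)
            if not union.any():
                continue    # pattern-free image: no foreground to validate
            maps.append(gradcam(model, ds.images[i], head=xcfg["head"]))
            masks.append(union)
            ids.append(ds.image_ids[i])
            correct.append(bool(diag_head[pos] == diag_ref[pos]))
        report = cohort_agreement_report(
            maps, masks, image_ids=ids, correctness_flags=correct,
            alpha=xcfg["alpha"], n_bins=xcfg["n_bins"],
            alternative=xcfg["alternative"],
        )
        pd.DataFrame([asdict(r) for r in report.images]).to_csv(
            out / "agreement_per_image.csv", index=False
        )
        with open(out / "agreement.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)

    _step("xai", ["agreement.json", "agreement_per_image.csv"], do_xai)

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
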