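"""End-to-end pipeline over a JSON config: simulate -> featurize -> train ->
predict -> explain -> evaluate, with a run manifest for reproducibility."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io
from .evaluation import evaluate
from .model import (CNNConfig, CNNModel, GCNConfig, GCNModel, TrainConfig,
                    predict_matrix, prepare_cnn_inputs, prepare_gcn_inputs,
                    train_model)
from .saliency import evaluate_saliency_suite
from .synthetic import MotifSpec, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"seed", "simulate", "model", "train", "evaluate", "explain",
               "language_model", "test_fraction"}


def _child_seed(root: int, stage: str) -> int:
    # per-stage seeds derived from one root seed, kept below 2^31
    # (zlib.crc32 is stable across processes, unlike hash())
    import zlib

    return int(np.random.SeedSequence([root, zlib.crc32(stage.encode())])
               .generate_state(1)[0] % (2**31))


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the requested stages in dependency order; writes all artifacts
    plus a RunManifest JSON into ``outdir`` and returns a result summary."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = int(config.get("seed", 0))
    timings: dict[str, float] = {}
    manifest = {"config": config, "seed": root_seed, "stages": [],
                "timings": timings}

    # ---- simulate
    t0 = time.time()
    sim_cfg = dict(config.get("simulate", {}))
    motif_lib = [MotifSpec(**m) for m in sim_cfg.pop("motif_library", [])]
    syn_cfg = SyntheticConfig(seed=_child_seed(root_seed, "simulate"),
                              motif_library=motif_lib, **sim_cfg)
    records, space = generate_dataset(syn_cfg)
    io.write_dataset(records, space, syn_cfg, outdir / "dataset")
    test_fraction = float(config.get("test_fraction", 0.2))
    n_test = max(1, int(round(test_fraction * len(records))))
    test, train = records[:n_test], records[n_test:]
    timings["simulate"] = time.time() - t0
    manifest["stages"].append("simulate")

    # ---- language model (optional)
    lm_state = None
    if config.get("language_model", {}).get("enabled", False):
        from .features import LMConfig, train_language_model

        t0 = time.time()
        lm_keys = {k: v for k, v in config["language_model"].items()
                   if k != "enabled"}
        lm_cfg = LMConfig(seed=_child_seed(root_seed, "lm"), **lm_keys)
        lm_state = train_language_model([r.sequence for r in train], lm_cfg)
        timings["language_model"] = time.time() - t0
        manifest["stages"].append("language_model")

    # ---- train
    t0 = time.time()
    model_cfg = dict(config.get("model", {}))
    kind = model_cfg.pop("type", "gcn")
    seed = _child_seed(root_seed, "train")
    if kind == "gcn":
        gcfg = GCNConfig(**{k: tuple(v) if k == "channels" else v
                            for k, v in model_cfg.items()})
        model = GCNModel(len(space), gcfg, seed=seed,
                         lm_dim=None if lm_state is None
                         else lm_state.config.hidden)
        train_inputs = prepare_gcn_inputs(train, lm_state)
        test_inputs = prepare_gcn_inputs(test, lm_state)
    elif kind == "cnn":
        ccfg = CNNConfig(**{k: tuple(v) if k == "filter_widths" else v
                            for k, v in model_cfg.items()})
        model = CNNModel(len(space), ccfg, seed=seed)
        train_inputs = prepare_cnn_inputs(train)
        test_inputs = prepare_cnn_inputs(test)
    else:
        raise ValueError(f"unknown model type {kind!r}")
    labels_train = np.stack([r.labels for r in train])
    tcfg = TrainConfig(seed=seed, **config.get("train", {}))
    state = train_model(model, train_inputs, labels_train,
                        space.weight_vector, tcfg)
    io.save_checkpoint(model, outdir / "model", terms=space.terms)
    timings["train"] = time.time() - t0
    manifest["stages"].append("train")

    # ---- predict
    t0 = time.time()
    scores = predict_matrix(model, test_inputs)
    io.write_predictions_tsv(scores, [r.id for r in test], space,
                             outdir / "predictions.tsv")
    timings["predict"] = time.time() - t0
    manifest["stages"].append("predict")

    # ---- evaluate
    t0 = time.time()
    labels_test = np.stack([r.labels for r in test])
    n_boot = int(config.get("evaluate", {}).get("n_boot", 0))
    result = evaluate(scores, labels_test, n_boot=n_boot,
                      seed=_child_seed(root_seed, "evaluate"))
    result.pr_curve.to_csv(outdir / "pr_curve.tsv", sep="\t", index=False)
    report = {"fmax": result.fmax, "fmax_threshold": result.fmax_threshold,
              "macro_aupr": result.macro_aupr,
              "aupr_per_term": {space.terms[j]: v
                                for j, v in result.aupr_per_term.items()},
              "bootstrap": result.bootstrap}
    timings["evaluate"] = time.time() - t0
    manifest["stages"].append("evaluate")

    # ---- explain (grad-CAM against planted motifs; GCN only)
    if kind == "gcn" and config.get("explain", {}).get("enabled", True):
        t0 = time.time()
        suite = evaluate_saliency_suite(model, test, test_inputs, space)
        if suite["n_pairs"]:
            suite["table"].to_csv(outdir / "saliency_auroc.tsv", sep="\t",
                                  index=False)
            report["saliency"] = {k: v for k, v in suite.items()
                                  if k not in ("table",)}
        timings["explain"] = time.time() - t0
        manifest["stages"].append("explain")

    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
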