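"""One-command orchestration of the full analysis.

Stages run in the order of the study: SSI computation, per-character
correlation tests (Kruskal-Wallis, Blomberg's K, OLS/PGLS), the
classifier battery, then skull-shape PCA and the C1 convergence test on
the suction-labeled taxa. Each stage writes a JSON report into the run
directory; a failure halts the run with a stage-tagged error, preserving
the reports already written. All randomness flows from the single config
seed. Configs are flat TOML files (stdlib ``tomllib``); explicit keyword
arguments override config values.
"""

from __future__ import annotations

import hashlib
import logging
import time
import tomllib
from pathlib import Path

import numpy as np

from . import classify, comparative, data_io, morphospace, ssi, synthetic
from .data_io import AnalysisConfig, write_report
from .phylo import Phylogeny

log = logging.getLogger("suctionmorph")

_CONFIG_KEYS = {
    "seed": int, "test_fraction": float, "n_permutations": int,
    "n_bm_simulations": int, "suction_matrix": str, "skull_matrix": str,
    "labels": str, "tree": str, "simulate": bool, "n_taxa": int,
    "delta": float, "n_specialist_clades": int, "require_phylo": bool,
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg: dict = {}
    if path is not None:
        cfg.update(tomllib.loads(Path(path).read_text(encoding="utf-8")))
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(cfg) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "run",
    **overrides,
) -> dict:
    """Execute the full analysis; returns the in-memory stage outputs.

    With ``simulate=True`` (or no input paths) a synthetic dataset is
    generated from the seed and analysed in place of user data.
    """
    cfg = (config if isinstance(config, dict)
           else load_config(config, **overrides))
    cfg = {**cfg, **{k: v for k, v in overrides.items() if v is not None}}
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acfg = AnalysisConfig(
        seed=seed,
        test_fraction=float(cfg.get("test_fraction", 0.25)),
        n_permutations=int(cfg.get("n_permutations", 1000)),
        n_bm_simulations=int(cfg.get("n_bm_simulations", 1000)),
    )
    provenance: dict = {"seed": seed, "inputs": {}}
    run: dict = {"config": dict(cfg), "provenance": provenance}

    t0 = time.time()
    if cfg.get("simulate") or "suction_matrix" not in cfg:
        scfg = synthetic.SynthConfig(
            n_taxa=int(cfg.get("n_taxa", 68)),
            delta=float(cfg.get("delta", 5.0)),
            n_specialist_clades=int(cfg.get("n_specialist_clades", 5)),
            seed=seed,
        )
        ds = synthetic.generate_dataset(scfg, out / "inputs")
        matrix, labels, skull, tree = (ds.suction_matrix, ds.labels,
                                       ds.skull_matrix, ds.tree)
        provenance["inputs"]["simulated"] = True
        run["truth"] = ds.truth
    else:
        matrix = data_io.read_suction_matrix(cfg["suction_matrix"])
        labels = data_io.read_label_table(cfg["labels"])
        skull = (data_io.read_character_matrix(cfg["skull_matrix"])
                 if "skull_matrix" in cfg else None)
        tree = (Phylogeny.from_file(cfg["tree"]) if "tree" in cfg else None)
        for key in ("suction_matrix", "labels", "skull_matrix", "tree"):
            if key in cfg:
                provenance["inputs"][key] = _hash_file(Path(cfg[key]))
    if tree is None and cfg.get("require_phylo"):
        raise StageError(
            "correlate: a tree is required (require_phylo) but none was given")
    log.info("inputs ready (%.1fs)", time.time() - t0)

    def stage(name, fn):
        t = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise StageError(f"{name}: {exc}") from exc
        log.info("stage %s done (%.1fs)", name, time.time() - t)
        return result

    ssi_table = stage("ssi", lambda: ssi.compute_ssi(
        matrix, specialization_threshold=1.0))
    write_report(ssi_table, out / "ssi.json", "ssi", acfg)
    run["ssi"] = ssi_table

    corr = stage("correlate", lambda: comparative.correlate_characters(
        matrix, labels, tree, ssi_table, acfg.n_permutations, seed))
    write_report(corr, out / "correlation.json", "correlate", acfg)
    run["correlation"] = corr

    battery = stage("classify", lambda: classify.run_predictor_battery(
        matrix, labels, ssi_table, acfg))
    write_report(battery, out / "battery.json", "classify", acfg)
    run["battery"] = battery

    if skull is not None:
        pca = stage("morphospace", lambda: morphospace.standardized_pca(skull))
        focal = [t for t, v in labels.items() if v == data_io.SUCTION_LABEL]
        run["morphospace"] = pca
        conv = None
        if tree is not None:
            pruned, _ = tree.prune_to(pca.taxa)
            scores = {t: pca.scores[i] for i, t in enumerate(pca.taxa)}
            focal = [t for t in focal
                     if data_io.normalize_name(t) in pruned._tip_index]
            conv = stage("converge", lambda: morphospace.c1_group_test(
                pruned, scores, focal, acfg.n_bm_simulations, seed))
            run["convergence"] = conv
        write_report({"pca_variance_fraction": pca.variance_fraction,
                      "convergence": conv},
                     out / "morphospace.json", "morphospace", acfg)
    else:
        run["morphospace"] = None
        log.info("stage morphospace skipped: no skull matrix supplied")

    write_report(run["config"], out / "run_config.json", "config", acfg)
    return run
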