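"""End-to-end orchestration: score -> bootstrap -> network -> coexpression.

``run_all`` drives the whole analysis from a single config mapping (or
YAML file), writes every stage's output under a run directory and emits
a machine-readable manifest tying each headline statistic to the stage
file it came from.  Stage outputs are pure functions of (inputs, config,
seed), so re-running with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap_significance import BootstrapConfig, significance_table
from .coexpression import compare_sets, noninteracting_pairs
from .confidence_scoring import (ScoringConfig, replicate_agreement, score_all)
from .io_formats import (CONTROL_ID, PulldownMatrix, read_expression,
                         read_hits, read_pulldown_table, read_roles,
                         write_network, write_pulldown_table, write_roles,
                         write_expression)
from .network_metrics import (build_network, degree_summary,
                              functional_agreement, permutation_test,
                              profile_correlations, reciprocal_rate)
from .ortholog_overlap import interaction_coverage, reciprocal_best_hits
from .synthetic_data import SimConfig, generate, study_design, evaluate_recovery

logger = logging.getLogger("apmsnet")

STAGES = ("score", "bootstrap", "network", "coexpr", "orthology")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def merge_control(matrix: PulldownMatrix, control: PulldownMatrix) -> PulldownMatrix:
    """Fold a separately-read control table under the reserved bait id."""
    entries = dict(matrix.entries)
    for (protein, _bait, rep, frac), value in control.entries.items():
        entries[(protein, CONTROL_ID, rep, frac)] = value
    return PulldownMatrix(entries)


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def run_all(config: Mapping[str, Any], out_dir: str | Path,
            seed: int | None = None) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    ``config`` keys: ``simulate`` (SimConfig overrides or
    ``study_scale: true``) or ``inputs`` (file paths: pulldowns, control,
    roles, expression, hits_ab, hits_ba, reference_edges); per-stage
    sections ``scoring``, ``bootstrap``, ``network``, ``coexpression``,
    ``orthology``; ``skip``: list of stage names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    skip = set(config.get("skip", ()))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "config": json.loads(json.dumps(config, default=str, sort_keys=True)),
        "stages": {},
        "inputs": {},
    }

    truth = None
    roles = None
    expression = None
    if "simulate" in config:
        sim_section = dict(config.get("simulate") or {})
        study_scale = sim_section.pop("study_scale", True)
        sim = study_design() if study_scale else SimConfig()
        for key, value in sim_section.items():
            if not hasattr(sim, key):
                raise StageError("simulate", f"unknown SimConfig field {key!r}")
            setattr(sim, key, value)
        sim.rng_seed = seed
        dataset = generate(sim, np.random.default_rng(seed))
        matrix, truth = dataset.matrix, dataset.truth
        roles, expression = dataset.roles, dataset.expression
        write_pulldown_table(matrix, str(out / "pulldowns.tsv"))
        write_roles(roles, str(out / "roles.tsv"))
        write_expression(expression, str(out / "expression.tsv"))
        manifest["stages"]["simulate"] = {
            "n_proteins": len(matrix.proteins()),
            "n_baits": len(matrix.baits()),
            "n_truth_edges": len(truth.edges),
        }
    else:
        inputs = config.get("inputs") or {}
        if "pulldowns" not in inputs:
            raise StageError("inputs", "config needs either 'simulate' or inputs.pulldowns")
        for name, path in inputs.items():
            if path:
                manifest["inputs"][name] = _digest_file(Path(path))
        matrix = read_pulldown_table(inputs["pulldowns"])
        if inputs.get("control"):
            matrix = merge_control(matrix, read_pulldown_table(inputs["control"]))
        if inputs.get("roles"):
            roles = read_roles(inputs["roles"])
        if inputs.get("expression"):
            expression = read_expression(inputs["expression"])

    # ---- score ----------------------------------------------------------
    t0 = time.perf_counter()
    scoring_cfg = ScoringConfig(**(config.get("scoring") or {}))
    try:
        mm_tables, baseline, conf = score_all(matrix, scoring_cfg)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage coordinates
        raise StageError("score", str(exc)) from exc
    conf.to_csv(out / "scores.tsv", sep="\t", index=False)
    agreement = replicate_agreement(matrix, scoring_cfg)
    hc = conf[conf["high_confidence"]]
    manifest["stages"]["score"] = {
        "file": "scores.tsv",
        "n_control_proteins": len(baseline),
        "n_scored_pairs": int(len(conf)),
        "n_high_confidence": int(len(hc)),
        "replicate_agreement_raw_mean": float(np.nanmean(list(agreement["raw"].values()))),
    }
    logger.info("score: %.2fs", time.perf_counter() - t0)

    # ---- bootstrap ------------------------------------------------------
    pvals = None
    if "bootstrap" not in skip:
        t0 = time.perf_counter()
        boot_cfg = BootstrapConfig(**(config.get("bootstrap") or {}), rng_seed=seed) \
            if "rng_seed" not in (config.get("bootstrap") or {}) \
            else BootstrapConfig(**(config.get("bootstrap") or {}))
        try:
            result = significance_table(matrix, boot_cfg)
        except Exception as exc:  # noqa: BLE001
            raise StageError("bootstrap", str(exc)) from exc
        pvals = result.table
        pvals.to_csv(out / "pvals.tsv", sep="\t", index=False)
        sig = pvals[pvals["p_value"] < 0.001]
        manifest["stages"]["bootstrap"] = {
            "file": "pvals.tsv",
            "n_boot": boot_cfg.n_boot,
            "n_pairs": int(len(pvals)),
            "n_significant_interactions": int(
                (sig["bait"] != sig["prey"]).sum()),
            "n_significant_baits": int((sig["bait"] == sig["prey"]).sum()),
        }
        logger.info("bootstrap: %.2fs", time.perf_counter() - t0)
    else:
        manifest["stages"]["bootstrap"] = {"skipped": True}

    # ---- network --------------------------------------------------------
    if "network" not in skip:
        t0 = time.perf_counter()
        net_cfg = dict(config.get("network") or {})
        network = build_network(conf, roles, pvals)
        for fmt, suffix in [("pajek_net", "net"), ("sif", "sif"),
                            ("graphml", "graphml"), ("edge_tsv", "edges.tsv")]:
            write_network(network, str(out / f"network.{suffix}"), fmt)
        obs, poss, rate = reciprocal_rate(network)
        stage: dict[str, Any] = {
            "files": ["network.net", "network.sif", "network.graphml", "network.edges.tsv"],
            **degree_summary(network),
            "reciprocal_observed": obs,
            "reciprocal_possible": poss,
            "reciprocal_rate": rate,
        }
        if roles is not None and network.n_edges() > 0:
            n_perm = int(net_cfg.get("n_perm", 100_000))
            drop = bool(net_cfg.get("drop_unannotated", False))
            agreement_result = permutation_test(
                network, roles, n_perm, np.random.default_rng(seed), drop)
            stage.update({
                "functional_agreement": agreement_result.observed_agreement,
                "permuted_mean_agreement": agreement_result.permuted_mean,
                "agreement_p_value": agreement_result.p_value,
                "n_perm": n_perm,
            })
        # bait/control pull-down profile correlations
        profiles: dict[str, dict[str, float]] = {}
        for bait in matrix.baits():
            profiles[bait] = {
                r.prey: float(r.score)
                for r in conf[conf["bait"] == bait].itertuples()
            }
        if matrix.has_control():
            profiles["control"] = dict(baseline)
        if len(profiles) >= 2:
            corr = profile_correlations(profiles)
            corr.to_csv(out / "profile_correlations.tsv", sep="\t")
            stage["max_bait_bait_correlation"] = float(
                np.nanmax(np.where(np.eye(len(corr), dtype=bool), np.nan, corr.values)))
        if truth is not None:
            precision, recall, f1, contamination = evaluate_recovery(network, truth)
            stage.update({"precision": precision, "recall": recall,
                          "f1": f1, "sticky_contamination": contamination})
        logger.info("network: %.2fs", time.perf_counter() - t0)
        manifest["stages"]["network"] = stage
        manifest["stages"]["network"]["n_edges"] = network.n_edges()
    else:
        manifest["stages"]["network"] = {"skipped": True}
        network = None

    # ---- coexpression ---------------------------------------------------
    if "coexpr" not in skip and expression is not None and network is not None \
            and network.n_edges() > 0:
        t0 = time.perf_counter()
        coexpr_cfg = dict(config.get("coexpression") or {})
        interacting = sorted(network.graph.edges)
        nonint = noninteracting_pairs(conf)
        if len(interacting) < 2 or len(nonint) < 2:
            manifest["stages"]["coexpr"] = {
                "skipped": True,
                "reason": "fewer than two pairs in a comparison set",
            }
            report = None
        else:
            try:
                report = compare_sets(interacting, nonint, expression,
                                      n_bins=int(coexpr_cfg.get("n_bins", 20)))
            except Exception as exc:  # noqa: BLE001
                raise StageError("coexpr", str(exc)) from exc
        if report is not None:
            summary = report.summary()
            logger.info("coexpr: %.2fs", time.perf_counter() - t0)
            with open(out / "coexpr.json", "w", encoding="utf-8") as fh:
                json.dump({**summary,
                           "polygon": report.polygon.to_dict(orient="list")},
                          fh, indent=2, sort_keys=True)
            manifest["stages"]["coexpr"] = {"file": "coexpr.json", **summary}
    else:
        manifest["stages"]["coexpr"] = {"skipped": True}

    # ---- orthology ------------------------------------------------------
    inputs = config.get("inputs") or {}
    if "orthology" not in skip and inputs.get("hits_ab") and inputs.get("hits_ba") \
            and inputs.get("reference_edges") and network is not None:
        ortho_cfg = dict(config.get("orthology") or {})
        omap = reciprocal_best_hits(
            read_hits(inputs["hits_ab"]), read_hits(inputs["hits_ba"]),
            float(ortho_cfg.get("evalue_cutoff", 1e-4)))
        ref = pd.read_csv(inputs["reference_edges"], sep="\t")
        ref_pairs = list(zip(ref.iloc[:, 0].astype(str), ref.iloc[:, 1].astype(str)))
        shared, expected, fraction = interaction_coverage(network, ref_pairs, omap)
        manifest["stages"]["orthology"] = {
            "n_orthologs": len(omap), "shared": shared,
            "expected": expected, "coverage": fraction,
        }
    else:
        manifest["stages"]["orthology"] = {"skipped": True}

    manifest_text = json.dumps(manifest, indent=2, sort_keys=True, default=float)
    (out / "manifest.json").write_text(manifest_text, encoding="utf-8")
    return manifest
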