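"""End-to-end orchestration: profiles -> networks -> instances -> model.

``run_pipeline`` executes the whole workflow from a declarative run
configuration and writes a self-describing run directory: seasonal
networks (GraphML + edge lists), instance and feature tables, the trained
model's evaluation report, predictions for candidate pathways, and a
manifest recording versions, seeds, and input digests.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .catalog import FeatureCatalog, default_catalog, read_catalog, write_catalog
from .graphfeat import FeatureVector, NetworkFeatureCache, featurize
from .mlcore import (ForestConfig, assemble_training_set, evaluate, info_gain_rank,
                     predict, save_feature_table, sensitivity_analysis,
                     subset_vector, top_features, train_forest, training_set_from_vectors)
from .netbuild import (CorrelationNetwork, common_metabolites, network_from_profile,
                       read_profiles, write_edgelist, write_graphml)
from .pathmap import (map_pathway, read_pathways, read_synonyms, write_instances)
from .synthfix import SimulationConfig, simulate_panel


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    profiles: list[str] = field(default_factory=list)   # one table per season
    pathways: str | None = None
    synonyms: str | None = None
    catalog: str | None = None
    out_dir: str = "run"
    r_threshold: float = 0.3
    p_threshold: float = 0.01
    prediction_threshold: float = 0.5
    n_trees: int = 100
    m_try: int | None = None
    cv_scheme: str = "kfold"
    cv_folds: int = 10
    top_k_features: int = 20
    sensitivity_iterations: int = 100
    sensitivity_fraction: float = 0.8
    seed: int = 0
    simulate: bool = False  # generate a synthetic panel instead of reading profiles

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**payload)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pathcna_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
    }

    # ---- stage: profiles -> networks
    try:
        if config.simulate:
            profiles, truth = simulate_panel(SimulationConfig(seed=config.seed))
        else:
            if not config.profiles:
                raise FileNotFoundError("no profile tables configured")
            truth = None
            profiles = []
            for p in config.profiles:
                path = Path(p)
                if not path.exists():
                    raise FileNotFoundError(f"profile table not found: {path}")
                manifest["inputs"][str(path)] = _digest(path)
                profiles.append(read_profiles(path))
        networks = [network_from_profile(p, config.r_threshold, config.p_threshold)
                    for p in profiles]
        for net in networks:
            write_graphml(net, out / f"network_{net.season_label}.graphml")
            write_edgelist(net, out / f"network_{net.season_label}.tsv")
        common = common_metabolites(networks)
        manifest["stages"]["build-net"] = {
            "seasons": [{"label": n.season_label, "nodes": n.n_nodes, "edges": n.n_edges}
                        for n in networks],
            "common_metabolites": len(common),
        }
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("build-net", str(exc)) from exc

    # ---- stage: map pathways
    try:
        if config.pathways:
            path = Path(config.pathways)
            if not path.exists():
                raise FileNotFoundError(f"pathway file not found: {path}")
            manifest["inputs"][str(path)] = _digest(path)
            pathways = read_pathways(path)
        elif truth is not None:
            pathways = truth.positive_pathways + truth.negative_pathways
        else:
            raise FileNotFoundError("no pathway definitions configured")
        synonyms = read_synonyms(config.synonyms) if config.synonyms else None
        instances = [map_pathway(pw, networks, common, synonyms) for pw in pathways]
        eligible = [i for i in instances if i.eligible]
        write_instances(instances, out / "instances.tsv")
        manifest["stages"]["map"] = {
            "mapped": len(instances), "eligible": len(eligible),
            "ineligible": len(instances) - len(eligible),
        }
        if not eligible:
            raise ValueError("no eligible pathway instances after mapping")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("map", str(exc)) from exc

    # ---- stage: featurize
    try:
        catalog = read_catalog(config.catalog) if config.catalog else default_catalog()
        write_catalog(catalog, out / "catalog.tsv")
        caches = {n.season_label: NetworkFeatureCache(n, seed=config.seed) for n in networks}
        vectors = {i.instance_id: featurize(i, networks, catalog, caches) for i in eligible}
        save_feature_table(list(vectors.values()), out / "features.tsv")
        manifest["stages"]["featurize"] = {
            "instances": len(vectors),
            "vector_length": catalog.per_network_count * len(networks),
        }
    except Exception as exc:
        raise StageError("featurize", str(exc)) from exc

    # ---- stage: train / evaluate
    try:
        labels = {}
        for inst in eligible:
            src = inst.pathway.source
            labels[inst.instance_id] = (1 if src == "positive_collection"
                                        else 0 if src in ("negative_collection", "random")
                                        else None)
        positives = [vectors[i] for i, l in labels.items() if l == 1]
        negatives = [vectors[i] for i, l in labels.items() if l == 0]
        candidates = [vectors[i] for i, l in labels.items() if l is None]
        if len(positives) < 2 or len(negatives) < 2:
            raise ValueError("need >= 2 positive and >= 2 labeled negative instances")
        training = training_set_from_vectors(positives, negatives)
        forest_config = ForestConfig(n_trees=config.n_trees, m_try=config.m_try,
                                     seed=config.seed)
        report = evaluate(training, forest_config, scheme=config.cv_scheme,
                          k=min(config.cv_folds, len(training.y)),
                          threshold=config.prediction_threshold)
        ranked = info_gain_rank(training)
        selected = top_features(ranked, config.top_k_features)
        reduced = training.subset_features(selected)
        model, oob_error = train_forest(reduced, forest_config,
                                        manifest_hash=catalog.manifest_hash())
        (out / "ranked_features.tsv").write_text(
            "feature\tinformation_gain\n"
            + "".join(f"{n}\t{g!r}\n" for n, g in ranked))
        metrics = {
            "cv": {"scheme": config.cv_scheme, "auc": report.auc,
                   "accuracy": report.accuracy, "counts": report.counts,
                   "per_class": report.per_class, "weighted": report.weighted,
                   "roc_points": report.roc_points},
            "oob_error_top%d" % config.top_k_features: oob_error,
            "top_features": selected,
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
        manifest["stages"]["train"] = {"n_training": len(training.y),
                                       "cv_auc": report.auc,
                                       "oob_error": oob_error}
    except StageError:
        raise
    except Exception as exc:
        raise StageError("train", str(exc)) from exc

    # ---- stage: predict candidates (+ sensitivity)
    try:
        if candidates:
            reduced_candidates = [subset_vector(v, selected) for v in candidates]
            records = sensitivity_analysis(
                reduced, reduced_candidates, forest_config,
                iterations=config.sensitivity_iterations,
                fraction=config.sensitivity_fraction, seed=config.seed,
                threshold=config.prediction_threshold)
            with open(out / "predictions.tsv", "w") as fh:
                fh.write("pathway_id\tprediction_value\tclass\t"
                         "sensitivity_mean\tsensitivity_variance\tconform\n")
                for rec in records:
                    fh.write("%s\t%r\t%d\t%r\t%r\t%s\n" % (
                        rec.pathway_id, rec.prediction_value, rec.predicted_class,
                        rec.sensitivity_mean, rec.sensitivity_variance, rec.conform))
            manifest["stages"]["predict"] = {
                "candidates": len(records),
                "predicted_positive": sum(r.predicted_class == 1 for r in records),
            }
    except Exception as exc:
        raise StageError("predict", str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
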