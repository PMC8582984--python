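"""End-to-end orchestration: responses -> scores -> components -> network
-> layout -> clusters -> profiles, with a manifest for reproducibility.

One global seed fans out deterministically to every stochastic stage
(fixed offsets), so a pipeline run is a pure function of its configuration.
Constant dummy columns (categories nobody or everybody chose) carry no
information and are dropped with a note before the optimal-scaling PCA,
which rejects constant variables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codebook import load_codebook
from .catpca import ScalingSpec, fit_princals, select_components
from .clustering import DbscanParams, dbscan, heterogeneity_summary, \
    profile_clusters, suggest_eps
from .encoding import encode_risk_matrix
from .layout import LayoutParams, run_layout
from .network import build_graph, export_graph
from .responses import load_responses
from .scoring import assign_quartiles, contingency_table, detect_bimodality, \
    frequency_profile, risk_histogram, risk_score
from .synthetic import GeneratorConfig, generate, recovery_report

log = logging.getLogger("perceptrisk")

# deterministic per-stage seed offsets from the global seed
_SEED_OFFSETS = {"simulate": 0, "catpca": 1, "layout": 2, "bimodality": 3}

STAGES = ("encode", "score", "reduce", "network", "layout", "cluster", "profile")


@dataclass
class PipelineConfig:
    """Everything a run needs; see docs/methods.md for parameter rationale."""

    responses_path: str | None = None
    codebook_path: str | None = None
    simulate: GeneratorConfig | None = None

    scaling: str = "ordinal"
    ndim: int = 150
    catpca_tol: float = 1e-6
    catpca_max_iter: int = 150
    variance_threshold: float = 0.8

    similarity_cutoff: float = 0.5
    block_size: int = 1024

    layout: LayoutParams = field(default_factory=lambda: LayoutParams(iterations=500))

    eps: float | None = None          # None = choose via the k-distance elbow
    min_pts: int = 10
    top_k: int = 13
    bin_width: int = 2

    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "simulate" in doc and doc["simulate"] is not None:
            doc["simulate"] = GeneratorConfig(**doc["simulate"])
        if "layout" in doc and doc["layout"] is not None:
            doc["layout"] = LayoutParams(**doc["layout"])
        return cls(**doc)


def paper_like_config(n: int = 2000, seed: int = 0, outdir=None) -> PipelineConfig:
    """The package's reference study conditions at desk scale."""
    sim = GeneratorConfig(n=n, seed=seed + _SEED_OFFSETS["simulate"])
    return PipelineConfig(simulate=sim, seed=seed, outdir=outdir)


@dataclass
class PipelineResult:
    responses: object
    codebook: object
    risk_matrix: object
    scores: np.ndarray
    quartiles: np.ndarray
    bimodality: object
    model: object
    reduced: np.ndarray
    graph: object
    layout: object
    assignment: np.ndarray
    profiles: object
    heterogeneity: pd.DataFrame
    recovery: dict | None
    manifest: dict


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; optionally write artifacts + manifest to outdir."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {}}
    stage = "input"

    try:
        # ---- input -------------------------------------------------
        truth = None
        if config.simulate is not None:
            survey = generate(config.simulate)
            responses, codebook, truth = survey.responses, survey.codebook, survey.truth
            manifest["input"] = {"simulated": True,
                                 "generator_seed": config.simulate.seed,
                                 "n": len(responses)}
            if outdir:
                survey.write(outdir)
        else:
            if not (config.responses_path and config.codebook_path):
                raise ValueError("provide responses_path + codebook_path, or simulate")
            codebook = load_codebook(config.codebook_path)
            responses = load_responses(config.responses_path, codebook)
            manifest["input"] = {"simulated": False, "n": len(responses),
                                 "responses_path": str(config.responses_path)}

        # ---- encode ------------------------------------------------
        stage = "encode"
        matrix = encode_risk_matrix(responses, codebook)
        manifest["stages"][stage] = {"n": matrix.n, "m": matrix.m}

        # ---- score / quartiles / describe --------------------------
        stage = "score"
        scores = risk_score(matrix)
        quartiles = assign_quartiles(scores)
        bimod = detect_bimodality(
            scores, random_state=config.seed + _SEED_OFFSETS["bimodality"])
        hist = risk_histogram(scores, config.bin_width)
        gender_table = contingency_table(responses.data["gender"], quartiles,
                                         "gender", "quartile")
        age_table = contingency_table(responses.age_bands, quartiles,
                                      "age_band", "quartile")
        emotions = frequency_profile(
            pd.DataFrame({"quartile": quartiles, "gender": responses.data["gender"]}),
            responses.flags("emotion"))
        media = frequency_profile(
            pd.DataFrame({"quartile": quartiles, "gender": responses.data["gender"]}),
            responses.flags("media"))
        manifest["stages"][stage] = {
            "score_min": int(scores.min()), "score_max": int(scores.max()),
            "quartile_sizes": np.bincount(quartiles, minlength=5)[1:].tolist(),
            "is_bimodal": bool(bimod.is_bimodal),
        }
        if outdir:
            hist.to_csv(outdir / "risk_histogram.csv", index=False)
            gender_table.with_margins.to_csv(outdir / "gender_by_quartile.csv")
            age_table.with_margins.to_csv(outdir / "age_by_quartile.csv")
            emotions.to_csv(outdir / "emotion_profile.csv", index=False)
            media.to_csv(outdir / "media_profile.csv", index=False)
            pd.DataFrame({"respondent_id": responses.respondent_ids,
                          "score": scores, "quartile": quartiles}
                         ).to_csv(outdir / "scores.csv", index=False)

        # ---- reduce (CAT-PCA) --------------------------------------
        stage = "reduce"
        dummies = matrix.to_dataframe()
        keep = [c for c in dummies.columns if dummies[c].nunique() > 1]
        dropped = dummies.shape[1] - len(keep)
        if dropped:
            log.info("dropping %d constant dummy column(s) before CAT-PCA", dropped)
        dummies = dummies[keep]
        dummies.columns = [f"{it}:{cat}" for it, cat in keep]
        spec = ScalingSpec(scaling=config.scaling,
                           ndim=min(config.ndim, dummies.shape[1], matrix.n - 1),
                           tol=config.catpca_tol,
                           max_iter=config.catpca_max_iter,
                           seed=config.seed + _SEED_OFFSETS["catpca"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-convergence is recorded instead
            model = fit_princals(dummies, spec)
        reduced = select_components(model, config.variance_threshold)
        manifest["stages"][stage] = {
            "m_variables": dummies.shape[1], "dropped_constant": dropped,
            "ndim_fitted": model.ndim, "n_components_selected": reduced.shape[1],
            "converged": model.converged, "n_iter": model.n_iter,
            "cumulative_vaf": float(np.cumsum(model.vaf)[reduced.shape[1] - 1]),
        }
        if outdir:
            model.vaf_table().to_csv(outdir / "vaf.csv", index=False)
            pd.DataFrame(reduced, index=responses.respondent_ids).to_csv(
                outdir / "component_scores.csv")

        # ---- network -----------------------------------------------
        stage = "network"
        attrs = pd.DataFrame({
            "quartile": quartiles,
            "gender": responses.data["gender"].to_numpy(),
            "age_band": responses.age_bands.to_numpy(),
        })
        graph = build_graph(reduced, cutoff=config.similarity_cutoff,
                            node_ids=list(responses.respondent_ids),
                            node_attrs=attrs, block_size=config.block_size)
        manifest["stages"][stage] = {
            "nodes": graph.number_of_nodes(), "edges": graph.number_of_edges(),
            "cutoff": config.similarity_cutoff,
        }
        if outdir:
            export_graph(graph, outdir / "network.gexf")
            export_graph(graph, outdir / "edges.csv")

        # ---- layout ------------------------------------------------
        stage = "layout"
        lp = config.layout
        lp.seed = config.seed + _SEED_OFFSETS["layout"]
        layout = run_layout(graph, lp)
        manifest["stages"][stage] = {
            "iterations": lp.iterations, "kr": lp.kr, "gravity": lp.gravity,
            "final_swinging": float(layout.swinging[-1]),
        }
        if outdir:
            layout.to_dataframe().to_csv(outdir / "layout.csv", index=False)

        # ---- cluster -----------------------------------------------
        stage = "cluster"
        eps = config.eps
        if eps is None:
            eps, curve = suggest_eps(layout.positions, k=config.min_pts)
            if outdir:
                pd.DataFrame({"k_distance": curve}).to_csv(
                    outdir / "k_distance_curve.csv", index=False)
        assignment = dbscan(layout.positions, DbscanParams(eps=eps,
                                                           min_pts=config.min_pts))
        log.info("dbscan: eps=%.4g min_pts=%d -> %d clusters",
                 eps, config.min_pts, assignment.max())
        manifest["stages"][stage] = {
            "eps": float(eps), "min_pts": config.min_pts,
            "n_clusters": int(assignment.max()),
            "noise": int((assignment == 0).sum()),
        }

        # ---- profile -----------------------------------------------
        stage = "profile"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # fewer clusters than top_k is fine
            profiles = profile_clusters(assignment, responses, quartiles,
                                        top_k=config.top_k)
        het = heterogeneity_summary(assignment, quartiles)
        manifest["stages"][stage] = {
            "coverage": profiles.coverage,
            "cluster_sizes": profiles.cluster_sizes.tolist(),
        }
        recovery = None
        if truth is not None:
            recovery = recovery_report(truth, scores, quartiles, assignment)
            manifest["recovery"] = recovery
        if outdir:
            profiles.table.to_csv(outdir / "cluster_profiles.csv", index=False)
            het.to_csv(outdir / "heterogeneity.csv", index=False)
            pd.DataFrame({"respondent_id": responses.respondent_ids,
                          "cluster": assignment}
                         ).to_csv(outdir / "clusters.csv", index=False)

    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if outdir:
        manifest["artifacts"] = {
            p.name: _checksum(p) for p in sorted(outdir.glob("*.csv"))
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(_to_jsonable(manifest), fh, indent=2)

    return PipelineResult(
        responses=responses, codebook=codebook, risk_matrix=matrix,
        scores=scores, quartiles=quartiles, bimodality=bimod, model=model,
        reduced=reduced, graph=graph, layout=layout, assignment=assignment,
        profiles=profiles, heterogeneity=het, recovery=recovery,
        manifest=manifest,
    )


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
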