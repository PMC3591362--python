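"""End-to-end pipeline: simulate/load -> filter -> differential -> multivariate
-> classifier -> enrichment, with a manifest enabling exact re-runs.

A single global seed deterministically derives per-stage substream seeds
(via ``numpy.random.SeedSequence.spawn``), so adding a stage never perturbs
earlier stages' randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, classifier, differential, enrichment, io, multivariate, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_STAGES = (
    "input",
    "filter",
    "diffexp",
    "ca",
    "hcluster",
    "classify",
    "kmedians",
    "enrich",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameters for a full pipeline run."""

    out_dir: str = "specdiff_out"
    seed: int = 0
    # inputs: either simulate, or provide counts+design paths
    simulate: bool = True
    counts_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    sim: dict[str, Any] = field(default_factory=dict)  # SyntheticConfig overrides
    # differential
    n_perm: int = 10_000
    confidence: float = 0.95
    mode: str = "global"
    # multivariate
    n_axes: int = 3
    k: int = 2
    n_restarts: int = 50
    # classifier
    signature_size: int = 3
    cv_scheme: str = "loo"
    positive_label: str | None = None
    # enrichment
    enrich_n_perm: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if self.n_perm < 1 or self.enrich_n_perm < 1:
            raise ValueError("permutation counts must be >= 1")
        if self.mode not in ("global", "per_protein"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not self.simulate and (self.counts_path is None or self.design_path is None):
            raise ValueError("counts_path and design_path required when simulate=false")
        simulate_fields = {f.name for f in dataclasses.fields(simulate_config_cls())}
        unknown = set(self.sim) - simulate_fields
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(payload)


def simulate_config_cls():
    return simulate.SyntheticConfig


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0])
        for name, child in zip(_STAGES, children)
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage, writing outputs and a reproducibility manifest.

    Returns the manifest.  On stage failure a ``<stage>.partial`` marker is
    left in the output directory and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "stages": {},
    }

    state: dict[str, Any] = {}

    def record(stage: str, outputs: dict[str, str], **summary: Any) -> None:
        manifest["stages"][stage] = {"outputs": outputs, "summary": summary}

    def run_stage(stage: str, fn) -> None:
        marker = out / f"{stage}.partial"
        marker.touch()
        try:
            fn()
        except Exception as exc:  # marker left behind for post-mortem
            logger.error("stage %r failed: %s", stage, exc)
            raise PipelineError(stage, exc) from exc
        marker.unlink(missing_ok=True)

    def stage_input() -> None:
        if config.simulate:
            sim_cfg = simulate.SyntheticConfig(**{"seed": seeds["input"], **config.sim})
            matrix, design, truth = simulate.generate_counts(sim_cfg)
            io.write_count_matrix(matrix, out / "counts.tsv")
            io.write_design(design, out / "design.tsv")
            truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
            outputs = {
                "counts": str(out / "counts.tsv"),
                "design": str(out / "design.tsv"),
                "truth": str(out / "truth.tsv"),
            }
        else:
            matrix = io.read_count_matrix(config.counts_path)
            design = io.read_design(config.design_path)
            outputs = {"counts": str(config.counts_path), "design": str(config.design_path)}
        state["matrix"], state["design"] = matrix, design
        record("input", outputs, n_proteins=matrix.shape[0], n_samples=matrix.shape[1])

    def stage_filter() -> None:
        filtered = differential.apply_presence_filter(state["matrix"], state["design"])
        io.write_count_matrix(filtered, out / "filtered_counts.tsv")
        state["filtered"] = filtered
        record(
            "filter",
            {"filtered_counts": str(out / "filtered_counts.tsv")},
            n_before=state["matrix"].shape[0],
            n_after=filtered.shape[0],
        )

    def stage_diffexp() -> None:
        result = differential.call_differential(
            state["filtered"],
            state["design"],
            n_perm=config.n_perm,
            confidence=config.confidence,
            mode=config.mode,  # type: ignore[arg-type]
            seed=seeds["diffexp"],
        )
        io.write_differential_table(result, out / "differential.tsv")
        state["differential"] = result
        record(
            "diffexp",
            {"differential": str(out / "differential.tsv")},
            n_significant=result.n_significant,
            null_band=list(result.null_band),
            **result.direction_counts(),
        )

    def stage_ca() -> None:
        emb = multivariate.correspondence_analysis(state["filtered"], n_axes=config.n_axes)
        axes = [f"axis{i + 1}" for i in range(emb.sample_coordinates.shape[1])]
        pd.DataFrame(
            emb.sample_coordinates, index=list(emb.sample_ids), columns=axes
        ).to_csv(out / "ca_samples.tsv", sep="\t", index_label="sample")
        pd.DataFrame(
            emb.protein_coordinates, index=list(emb.protein_ids), columns=axes
        ).to_csv(out / "ca_proteins.tsv", sep="\t", index_label="protein")
        record(
            "ca",
            {"samples": str(out / "ca_samples.tsv"), "proteins": str(out / "ca_proteins.tsv")},
            axis_inertias=emb.axis_inertias.tolist(),
            total_inertia=emb.total_inertia,
        )

    def stage_hcluster() -> None:
        sig_proteins = state["differential"].significant_proteins()
        summary: dict[str, Any] = {"n_differential": len(sig_proteins)}
        outputs: dict[str, str] = {}
        if len(sig_proteins) >= 2:
            sub = state["filtered"].subset_proteins(list(sig_proteins))
            transformed = multivariate.log_zscore(sub.counts)
            rows = multivariate.hierarchical_cluster(transformed, labels=sub.protein_ids)
            cols = multivariate.hierarchical_cluster(
                transformed.T, labels=sub.sample_ids
            )
            payload = {
                "proteins": _dendrogram_dict(rows),
                "samples": _dendrogram_dict(cols),
            }
            path = out / "dendrograms.json"
            path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
            outputs["dendrograms"] = str(path)
        else:
            logger.warning("fewer than 2 differential proteins; skipping clustering")
        record("hcluster", outputs, **summary)

    def stage_classify() -> None:
        filtered = state["filtered"]
        features = np.log2(filtered.counts.astype(float) + 1.0)
        delta, cv_table = classifier.cross_validate_delta(
            features,
            state["design"],
            scheme=config.cv_scheme,
            feature_ids=filtered.protein_ids,
        )
        model = classifier.fit_nsc(
            features, state["design"], delta=delta, feature_ids=filtered.protein_ids
        )
        io.save_model(model, out / "model.json")
        cv_table.to_csv(out / "cv_table.tsv", sep="\t", index=False)
        signature = classifier.select_signature(
            model,
            state["differential"],
            size=config.signature_size,
            positive_label=config.positive_label,
        )
        io.write_signature(signature, out / "signature.json")
        scores = classifier.combined_score(filtered, signature)
        scores.to_frame().to_csv(out / "combined_scores.tsv", sep="\t", index_label="sample")
        roc = classifier.roc_curve(scores, state["design"], signature.positive_label)
        pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        ).to_csv(out / "roc.tsv", sep="\t", index=False)
        state["signature"], state["scores"] = signature, scores
        record(
            "classify",
            {
                "model": str(out / "model.json"),
                "cv_table": str(out / "cv_table.tsv"),
                "signature": str(out / "signature.json"),
                "scores": str(out / "combined_scores.tsv"),
                "roc": str(out / "roc.tsv"),
            },
            delta=delta,
            signature=list(state["signature"].proteins),
            auc=roc.auc,
            youden=list(roc.youden_point),
        )

    def stage_kmedians() -> None:
        signature = state["signature"]
        outputs: dict[str, str] = {}
        summary: dict[str, Any] = {}
        if len(signature) >= 1:
            sub = state["filtered"].subset_proteins(list(signature.proteins))
            profile = multivariate.log_zscore(sub.counts).T  # samples x proteins
            part = multivariate.kmedians(
                profile,
                k=config.k,
                n_restarts=config.n_restarts,
                seed=seeds["kmedians"],
                point_ids=sub.sample_ids,
            )
            pd.DataFrame(
                {"sample": list(sub.sample_ids), "cluster": part.assignments}
            ).to_csv(out / "kmedians.tsv", sep="\t", index=False)
            outputs["assignments"] = str(out / "kmedians.tsv")
            summary["objective"] = part.objective
            if config.k == 2:
                accuracy, mapping = multivariate.match_partition_to_labels(
                    part, state["design"]
                )
                summary["accuracy"] = accuracy
                summary["mapping"] = {str(k): v for k, v in mapping.items()}
        else:
            logger.warning("empty signature; skipping k-medians")
        record("kmedians", outputs, **summary)

    def stage_enrich() -> None:
        outputs: dict[str, str] = {}
        summary: dict[str, Any] = {}
        if config.gmt_path is not None:
            annotations = io.read_gmt(config.gmt_path)
            background = set(state["filtered"].protein_ids)
            hits = set(state["differential"].significant_proteins())
            records = enrichment.test_enrichment(
                hits,
                background,
                annotations,
                n_perm=config.enrich_n_perm,
                seed=seeds["enrich"],
            )
            io.write_enrichment_table(records, out / "enrichment.tsv")
            outputs["enrichment"] = str(out / "enrichment.tsv")
            summary["n_significant"] = sum(r.significant for r in records)
        record("enrich", outputs, **summary)

    run_stage("input", stage_input)
    run_stage("filter", stage_filter)
    run_stage("diffexp", stage_diffexp)
    run_stage("ca", stage_ca)
    run_stage("hcluster", stage_hcluster)
    run_stage("classify", stage_classify)
    run_stage("kmedians", stage_kmedians)
    run_stage("enrich", stage_enrich)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
    )
    return manifest


def _dendrogram_dict(d: multivariate.Dendrogram) -> dict[str, Any]:
    return {
        "merges": [list(m) for m in d.merges],
        "leaf_order": list(d.leaf_order),
        "leaf_labels": list(d.leaf_labels),
        "linkage": d.linkage_name,
        "distance": d.distance_name,
    }
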