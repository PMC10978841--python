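"""End-to-end orchestration with a structured config and provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError, ProxiprofError
from .io import read_annotations, read_protein_groups, write_table
from .orphans import OrphanDetector
from .qc import basic_filter, merge_replicates
from .ratiometric import RatioCutoffSelector, ratio_distribution

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    ``threshold`` and ``target_specificity`` are mutually exclusive cutoff
    modes.  All referenced input paths must exist at validation time.
    """

    protein_group_tables: list[str]
    annotations: str
    output_dir: str
    dialect: str = "generic"
    min_detections: int = 2
    min_unique_peptides: int = 2
    threshold: float | None = None
    target_specificity: float | None = None
    n_bins: int = 30
    orphans: bool = False
    orphan_k: int = 10
    orphan_min_fraction: float = 0.8
    orphan_perplexity: float = 20.0
    orphan_embedding: str = "tsne"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        try:
            config = cls(**data)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from None
        return config

    def validate(self) -> None:
        if self.threshold is not None and self.target_specificity is not None:
            raise ConfigurationError(
                "threshold and target_specificity are mutually exclusive"
            )
        if not self.protein_group_tables:
            raise ConfigurationError("no protein-group tables configured")
        for path in [*self.protein_group_tables, self.annotations]:
            if not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute QC -> replicate merge -> ratiometric cutoff (-> orphans).

    Writes the retained proteome, removal reports, histogram and metrics
    under ``config.output_dir`` and returns the manifest (also written as
    ``manifest.json``) listing every output with a content hash.  A stage
    failure is re-raised naming the stage, after a manifest with a FAILED
    marker is written for the partial outputs.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {
        "tool": {"name": "proxiprof", "version": __version__},
        "seed": config.seed,
        "parameters": {
            k: v for k, v in vars(config).items() if k != "output_dir"
        },
        "inputs": [str(p) for p in config.protein_group_tables]
        + [str(config.annotations)],
        "stages": {},
    }
    stage = "read"
    try:
        replicates = [
            read_protein_groups(p, dialect=config.dialect)
            for p in config.protein_group_tables
        ]
        ann = read_annotations(config.annotations)

        stage = "basic_filter"
        filtered, reports = [], []
        for i, frame in enumerate(replicates, start=1):
            kept, report = basic_filter(
                frame, min_unique_peptides=config.min_unique_peptides
            )
            report = report.assign(replicate=i)
            filtered.append(kept)
            reports.append(report)
            counts = report["reason"].value_counts().to_dict()
            logger.info("replicate %d removals: %s", i, counts)
        import pandas as pd

        removal_report = pd.concat(reports, ignore_index=True)
        outputs["removal_report"] = out_dir / "removal_report.tsv"
        write_table(removal_report, outputs["removal_report"])
        manifest["stages"]["basic_filter"] = {
            "removed": int(len(removal_report)),
            "per_reason": removal_report["reason"]
            .value_counts()
            .to_dict(),
        }

        stage = "merge_replicates"
        profiles, merge_report = merge_replicates(
            filtered, min_detections=config.min_detections
        )
        outputs["merge_report"] = out_dir / "merge_report.tsv"
        write_table(merge_report, outputs["merge_report"])
        manifest["stages"]["merge_replicates"] = {
            "profiles": int(len(profiles)),
            "removed": int(len(merge_report)),
        }

        stage = "cutoff"
        selector = RatioCutoffSelector(
            threshold=config.threshold,
            target_specificity=config.target_specificity,
        ).fit(profiles, ann)
        result = selector.result_
        logger.info(
            "cutoff %.4g retains %d proteins at %.1f%% specificity",
            selector.threshold_,
            len(result.retained),
            100 * result.specificity,
        )
        outputs["retained_proteome"] = out_dir / "retained_proteome.tsv"
        write_table(result.retained, outputs["retained_proteome"])
        hist = ratio_distribution(profiles, ann, n_bins=config.n_bins)
        outputs["histogram"] = out_dir / "ratio_histogram.tsv"
        hist.to_frame().to_csv(outputs["histogram"], sep="\t", index=False)
        metrics = result.metrics() | {"auc": selector.auc_}
        outputs["metrics"] = out_dir / "metrics.json"
        outputs["metrics"].write_text(
            json.dumps(metrics, indent=2, sort_keys=True) + "\n"
        )
        manifest["stages"]["cutoff"] = metrics

        if config.orphans:
            stage = "orphans"
            detector = OrphanDetector(
                k=config.orphan_k,
                min_fraction=config.orphan_min_fraction,
                perplexity=config.orphan_perplexity,
                seed=config.seed,
                method=config.orphan_embedding,
            ).fit([profiles], ann)
            coords = detector.embedding_.coords.reset_index(names="protein")
            outputs["embedding"] = out_dir / "embedding.tsv"
            write_table(coords, outputs["embedding"])
            outputs["orphan_candidates"] = out_dir / "orphan_candidates.tsv"
            write_table(detector.candidates_, outputs["orphan_candidates"])
            manifest["stages"]["orphans"] = {
                "candidates": int(detector.candidates_["passes"].sum()),
                "seed": config.seed,
                "embedding": config.orphan_embedding,
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["outputs"] = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in outputs.items()
            if p.exists()
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
        )
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise ProxiprofError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["outputs"] = {
        name: {"path": str(p), "sha256": _sha256(p)}
        for name, p in outputs.items()
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest
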