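"""End-to-end orchestration: cluster -> compile -> augment -> train -> evaluate -> scan.

A single :class:`RunConfig` carries every tunable with defaults equal to
the published operating point (identity cutoff 50%, inflation 1.4, contact
cutoff 4.5 A, K_D cutoff 100 uM, SSL window [0.5, 0.8], negative:positive
ratio 5, 5 CV folds, disorder cutoff 0.4) plus explicit seeds and input
paths. ``run_all`` executes the stages into an artifacts directory, writing
a manifest with the config and its hash; stages whose outputs already exist
are skipped, so a run is resumable from intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as pio
from .align import pairwise_identity_matrix, write_identity_matrix
from .cluster import (
    assign_families,
    build_identity_graph,
    mcl,
    write_abc_graph,
    write_family_table,
)
from .models import (
    SMALL_GRID,
    FamilyEncoder,
    TrainedFamilyModel,
    cross_validate,
    eligible_for_cv,
    eligible_for_modeling,
    grid_search,
    train_family_model,
)
from .negatives import extract_cterm_peptides, random_negatives, self_train_negatives
from .records import InteractionRecord
from .scan import ProteomeEntry, hits_to_frame, scan_proteome

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline tunables; defaults are the published operating point."""

    domains_fasta: Optional[str] = None
    interactions_tsv: Optional[str] = None
    proteome_fasta: Optional[str] = None
    disorder_tsv: Optional[str] = None
    go_tsv: Optional[str] = None

    identity_cutoff: float = 50.0
    inflation: float = 1.4
    contact_cutoff: float = 4.5
    kd_cutoff_um: float = 100.0
    ssl_window_low: float = 0.5
    ssl_window_high: float = 0.8
    negative_ratio: int = 5
    cv_folds: int = 5
    disorder_cutoff: float = 0.4
    scan_top_k: int = 50
    seed: int = 0
    #: hyperparameter grid as [[C, gamma], ...]; the compact default keeps
    #: pipeline runs fast, the full grid lives in models.DEFAULT_GRID
    grid: list = field(default_factory=lambda: [list(p) for p in SMALL_GRID])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _outputs_exist(paths: Sequence[Path]) -> bool:
    return all(p.exists() for p in paths)


def run_all(config: RunConfig, outdir) -> Path:
    """Run every applicable stage into ``outdir`` and return it.

    Requires at least ``domains_fasta``; later stages run only when their
    inputs are configured (interactions for compile/augment/train/evaluate,
    proteome + disorder + GO for scan). Any stage failure aborts with a
    :class:`StageError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    stages_run: list[str] = []

    # --- cluster ---------------------------------------------------------
    identity_path = outdir / "identity.tsv"
    graph_path = outdir / "graph.abc"
    families_path = outdir / "families.tsv"
    try:
        if config.domains_fasta is None:
            raise ValueError("domains_fasta is required")
        domains = pio.read_domain_fasta(config.domains_fasta)
        if _outputs_exist([identity_path, graph_path, families_path]):
            logger.info("cluster: outputs exist, skipping")
            family_table = pd.read_csv(families_path, sep="\t")
        else:
            identity = pairwise_identity_matrix(domains)
            write_identity_matrix(identity, identity_path)
            graph = build_identity_graph(identity, cutoff=config.identity_cutoff)
            write_abc_graph(graph, graph_path)
            result = mcl(graph, inflation=config.inflation)
            family_table = assign_families(result)
            write_family_table(family_table, families_path)
            stages_run.append("cluster")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("cluster", exc) from exc

    member_to_family: dict[str, str] = {}
    for row in family_table.itertuples(index=False):
        if row.family_id == "unclassified":
            continue
        for member in str(row.members).split(","):
            member_to_family[member] = row.family_id

    if config.interactions_tsv is None:
        _write_manifest(manifest_path, config, stages_run)
        return outdir

    # --- compile ---------------------------------------------------------
    compiled_path = outdir / "family_interactions.tsv"
    try:
        records = pio.read_interaction_table(config.interactions_tsv)
        by_family: dict[str, list[InteractionRecord]] = {}
        for r in records:
            fam = member_to_family.get(r.domain_id)
            if fam is None:
                continue  # unclassified domains are not modelled
            by_family.setdefault(fam, []).append(r)
        if not compiled_path.exists():
            rows = [
                {
                    "family_id": fam,
                    "domain_id": r.domain_id,
                    "peptide": str(r.peptide),
                    "label": r.label,
                    "provenance": r.provenance,
                }
                for fam in sorted(by_family)
                for r in by_family[fam]
            ]
            pd.DataFrame(
                rows,
                columns=["family_id", "domain_id", "peptide", "label", "provenance"],
            ).to_csv(compiled_path, sep="\t", index=False)
            stages_run.append("compile")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("compile", exc) from exc

    # --- augment ---------------------------------------------------------
    augmented_path = outdir / "augmented_interactions.tsv"
    pool = None
    try:
        if config.proteome_fasta is not None:
            proteome = pio.read_proteome_fasta(config.proteome_fasta)
            pool = extract_cterm_peptides(proteome)
        augmented: dict[str, list[InteractionRecord]] = {}
        for fam in sorted(by_family):
            recs = by_family[fam]
            if not eligible_for_modeling(recs):
                continue
            if pool is None:
                augmented[fam] = list(recs)
                continue
            n_neg = sum(1 for r in recs if r.label == -1)
            if n_neg > 0:
                ssl = self_train_negatives(
                    recs,
                    pool,
                    window=(config.ssl_window_low, config.ssl_window_high),
                    ratio=config.negative_ratio,
                    seed=config.seed,
                )
                augmented[fam] = ssl.records
            else:
                positives = [r for r in recs if r.label == 1]
                augmented[fam] = list(recs) + random_negatives(
                    positives, pool, ratio=config.negative_ratio, seed=config.seed
                )
        if augmented and not augmented_path.exists():
            all_records = [r for fam in sorted(augmented) for r in augmented[fam]]
            pio.write_interaction_table(all_records, augmented_path)
            stages_run.append("augment")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("augment", exc) from exc

    # --- train -----------------------------------------------------------
    models_dir = outdir / "models"
    grid = tuple((float(c), float(g)) for c, g in config.grid)
    models: dict[str, TrainedFamilyModel] = {}
    ran_train = False
    try:
        for fam in sorted(augmented):
            fam_dir = models_dir / fam
            if (fam_dir / "model.joblib").exists():
                models[fam] = TrainedFamilyModel.load(fam_dir)
                continue
            recs = augmented[fam]
            if len({r.label for r in recs}) < 2:
                logger.warning("train: family %s has a single class, skipped", fam)
                continue
            hyper = grid_search(recs, grid=grid, k=config.cv_folds, seed=config.seed)
            model = train_family_model(fam, recs, hyper, seed=config.seed)
            model.save(fam_dir)
            models[fam] = model
            ran_train = True
        if ran_train:
            stages_run.append("train")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("train", exc) from exc

    # --- evaluate --------------------------------------------------------
    report_path = outdir / "report.tsv"
    try:
        if ran_train or not report_path.exists():
            rows = []
            for fam in sorted(by_family):
                recs = by_family[fam]
                if not eligible_for_cv(recs):
                    continue
                report = cross_validate(
                    fam,
                    recs,
                    k=config.cv_folds,
                    seed=config.seed,
                    grid=grid,
                    pool=pool,
                    ratio=config.negative_ratio,
                    window=(config.ssl_window_low, config.ssl_window_high),
                )
                row = {"family_id": fam, **report.summary()}
                rows.append(row)
            pd.DataFrame(rows).to_csv(report_path, sep="\t", index=False)
            stages_run.append("evaluate")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", exc) from exc

    # --- scan (optional) -------------------------------------------------
    hits_path = outdir / "hits.tsv"
    summary_path = outdir / "scan_summary.json"
    scan_ready = (
        config.proteome_fasta is not None
        and config.disorder_tsv is not None
        and config.go_tsv is not None
        and models
    )
    if scan_ready:
        try:
            if not _outputs_exist([hits_path, summary_path]) or ran_train:
                proteome = pio.read_proteome_fasta(config.proteome_fasta)
                disorder = pio.read_disorder_tsv(config.disorder_tsv)
                go = pio.read_go_annotations(config.go_tsv)
                entries = [
                    ProteomeEntry(
                        protein_id=pid,
                        sequence=seq,
                        disorder=disorder.get(pid),
                        go_terms=go.get(pid),
                    )
                    for pid, seq in proteome.items()
                ]
                # one representative model per member domain of each family
                domain_models = {}
                domain_go = {}
                for fam, model in models.items():
                    for row in family_table.itertuples(index=False):
                        if row.family_id != fam:
                            continue
                        for member in str(row.members).split(","):
                            if member in go:
                                domain_models[member] = model
                                domain_go[member] = go[member]
                if domain_models:
                    hits, summary = scan_proteome(
                        domain_models,
                        entries,
                        domain_go,
                        disorder_cutoff=config.disorder_cutoff,
                        top_k=config.scan_top_k,
                    )
                    hits_to_frame(hits).to_csv(hits_path, sep="\t", index=False)
                    summary_path.write_text(json.dumps(summary.to_dict(), indent=2))
                    stages_run.append("scan")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("scan", exc) from exc

    _write_manifest(manifest_path, config, stages_run)
    return outdir


def _write_manifest(path: Path, config: RunConfig, stages_run: list[str]) -> None:
    path.write_text(
        json.dumps(
            {
                "config": config.to_dict(),
                "config_hash": config.config_hash(),
                "stages_run": stages_run,
            },
            indent=2,
        )
    )
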