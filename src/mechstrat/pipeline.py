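"""End-to-end orchestration: discovery clustering and validation transfer.

`run_discovery` chains burden encoding → consensus sNMF over a k grid →
permutation-null calibration → k selection → top mechanisms, writing every
artifact (TSV/JSON) plus a manifest with the seed and SHA-256 hashes so
downstream stages can detect tampering and reruns can be checked for
bit-identity. `run_validation` runs both validation arms: an independent
re-clustering of the validation cohort (does it re-suggest the same k?) and
classifier-based transfer with IGP coherence testing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import BurdenEncoder, EncoderSpec, apply_encoders, compute_burden_scores
from .catalog import MechanismCatalog, default_catalog, group_snps_by_mechanism
from .consensus import consensus_cluster, permutation_null, select_k, top_mechanisms
from .io import GenotypeMatrix, write_genotypes_tsv
from .simulate import SyntheticConfig, generate_cohort, generate_validation_cohort
from .transfer import (
    TransferClassifier,
    assign_clusters,
    cross_validate,
    igp,
    igp_permutation_test,
)

logger = logging.getLogger("mechstrat")

__all__ = ["PipelineConfig", "run_discovery", "run_validation"]


@dataclass
class PipelineConfig:
    """Stage parameters and artifact layout for a pipeline run."""

    out_dir: Path
    seed: int = 0
    k_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    n_runs: int = 50
    n_perm: int = 20
    sparsity: float = 0.01
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    cv_repeats: int = 10
    cv_folds: int = 10
    igp_n_perm: int = 1000
    feature_space: str = "burden"  # or "snp"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.k_grid = tuple(int(k) for k in self.k_grid)
        if self.feature_space not in ("burden", "snp"):
            raise ValueError("feature_space must be 'burden' or 'snp'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load stage parameters from a YAML or JSON mapping; overrides win.

        Encoder settings live under an ``encoder:`` sub-mapping.
        """
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: config must be a mapping")
        enc = payload.pop("encoder", {})
        payload.update(overrides)
        if enc and "encoder" not in payload:
            payload["encoder"] = EncoderSpec(**enc)
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, seed: int, files: list[Path], extra: dict) -> None:
    manifest = {
        "package": "mechstrat",
        "version": __version__,
        "seed": seed,
        "files": {f.name: _sha256(f) for f in sorted(files)},
        **extra,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def run_discovery(
    genotypes: GenotypeMatrix,
    config: PipelineConfig,
    catalog: MechanismCatalog | None = None,
) -> dict:
    """Discovery stage: burden profile, consensus clustering, k selection.

    Returns a dict with the burden profile, per-k consensus results, the
    permutation nulls, the selected k, final labels and top mechanisms; all
    artifacts are also written under ``config.out_dir``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    catalog = catalog or default_catalog()
    logger.info("grouping %d SNPs by mechanism", genotypes.n_snps)
    grouping = group_snps_by_mechanism(catalog, genotypes.snp_ids)
    spec = config.encoder
    spec.seed = config.seed
    logger.info("training %d mechanism encoders", len(grouping))
    profile = compute_burden_scores(genotypes, grouping, spec)
    X = profile.values()

    results, consensus = {}, {}
    for k in config.k_grid:
        res = consensus_cluster(
            X, k, n_runs=config.n_runs, seed=config.seed, sparsity=config.sparsity
        )
        consensus[k] = res
        results[k] = res.metrics
        logger.info("k=%d pac=%.3f sil=%.3f coph=%.3f", k, *[res.metrics[m] for m in ("pac", "silhouette", "cophenetic")])
    nulls = permutation_null(
        X, config.k_grid, n_perm=config.n_perm, n_runs=config.n_runs,
        seed=config.seed, sparsity=config.sparsity,
    )
    k_sel = select_k(results, nulls)
    logger.info("selected k = %s", k_sel)
    artifacts: list[Path] = []

    profile.scores.to_csv(out / "burden.tsv", sep="\t")
    artifacts.append(out / "burden.tsv")
    profile.encoder.save(out / "encoders.json")
    artifacts.append(out / "encoders.json")
    metrics_payload = {
        "per_k": {str(k): results[k] for k in config.k_grid},
        "null": {str(k): nulls[k] for k in config.k_grid},
        "selected_k": k_sel,
    }
    (out / "metrics.json").write_text(json.dumps(metrics_payload, indent=1))
    artifacts.append(out / "metrics.json")

    labels = tops = None
    if k_sel is not None:
        final = consensus[k_sel]
        labels = pd.Series(final.labels, index=profile.scores.index, name="cluster")
        labels.to_csv(out / "labels.tsv", sep="\t")
        artifacts.append(out / "labels.tsv")
        pd.DataFrame(final.C, index=profile.scores.index, columns=profile.scores.index).to_csv(
            out / "consensus.tsv", sep="\t"
        )
        artifacts.append(out / "consensus.tsv")
        pd.DataFrame(
            final.best_run.S, columns=profile.mechanism_names
        ).to_csv(out / "loadings.tsv", sep="\t")
        artifacts.append(out / "loadings.tsv")
        tops = top_mechanisms(final.best_run.S, mechanism_names=profile.mechanism_names)
        (out / "top_mechanisms.json").write_text(json.dumps(tops, indent=1))
        artifacts.append(out / "top_mechanisms.json")
    _write_manifest(out, config.seed, artifacts, {"stage": "discovery", "selected_k": k_sel})
    return {
        "profile": profile,
        "grouping": grouping,
        "consensus": consensus,
        "nulls": nulls,
        "selected_k": k_sel,
        "labels": labels,
        "top_mechanisms": tops,
    }


def run_validation(
    validation_genotypes: GenotypeMatrix,
    discovery: dict,
    discovery_genotypes: GenotypeMatrix,
    config: PipelineConfig,
) -> dict:
    """Validation stage: independent re-clustering plus transfer + IGP.

    Arm 1 re-runs the full model-selection procedure on the validation
    cohort's burden scores (computed with the discovery-trained encoders).
    Arm 2 fits the LASSO transfer classifier on discovery features, reports
    its repeated-CV Hand–Till AUC, assigns validation patients, and tests
    IGP coherence by permutation.
    """
    if discovery.get("selected_k") is None or discovery.get("labels") is None:
        raise ValueError("discovery stage selected no clustering; cannot validate")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    encoder: BurdenEncoder = discovery["profile"].encoder
    val_profile = apply_encoders(encoder, validation_genotypes)
    Xv = val_profile.values()

    # arm 1: independent re-clustering of the validation cohort
    results = {}
    for k in config.k_grid:
        res = consensus_cluster(
            Xv, k, n_runs=config.n_runs, seed=config.seed + 1, sparsity=config.sparsity
        )
        results[k] = res.metrics
    nulls = permutation_null(
        Xv, config.k_grid, n_perm=config.n_perm, n_runs=config.n_runs,
        seed=config.seed + 1, sparsity=config.sparsity,
    )
    k_reselect = select_k(results, nulls)
    logger.info("validation re-clustering selects k = %s", k_reselect)

    # arm 2: classifier transfer + IGP
    disc_labels = discovery["labels"].to_numpy()
    if config.feature_space == "burden":
        Xd = discovery["profile"].values()
        Xv_feat = Xv
        genotype_frame = discovery_genotypes.dosages
        grouping = discovery["grouping"]
    else:
        Xd = discovery_genotypes.values()
        Xv_feat = validation_genotypes.values()
        genotype_frame = None
        grouping = None
    auc = cross_validate(
        Xd, disc_labels, repeats=config.cv_repeats, folds=config.cv_folds,
        seed=config.seed, genotypes=genotype_frame, grouping=grouping,
        encoder_spec=config.encoder,
    )
    clf = TransferClassifier(random_state=config.seed).fit(Xd, disc_labels)
    pred, proba = assign_clusters(clf, Xv_feat)
    igp_res = igp(Xv_feat, pred, Xd, disc_labels)
    igp_res = igp_permutation_test(igp_res, n_perm=config.igp_n_perm, seed=config.seed)

    artifacts = []
    pred_tab = pd.DataFrame(
        proba, index=validation_genotypes.patient_ids,
        columns=[f"p_cluster_{c}" for c in clf.classes_],
    )
    pred_tab.insert(0, "predicted_cluster", pred)
    pred_tab.to_csv(out / "validation_predictions.tsv", sep="\t")
    artifacts.append(out / "validation_predictions.tsv")
    payload = {
        "cv_auc": auc,
        "selected_k_validation": k_reselect,
        "validation_metrics_per_k": {str(k): results[k] for k in config.k_grid},
        "igp_overall": igp_res.overall,
        "igp_per_cluster": {str(k): v for k, v in igp_res.per_cluster.items()},
        "igp_p_overall": igp_res.p_overall,
        "igp_p_per_cluster": {str(k): v for k, v in igp_res.p_per_cluster.items()},
        "n_perm": igp_res.n_perm,
        "lambda": clf.lambda_,
    }
    (out / "validation.json").write_text(json.dumps(payload, indent=1))
    artifacts.append(out / "validation.json")
    _write_manifest(out, config.seed, artifacts, {"stage": "validation"})
    return {
        "reselected_k": k_reselect,
        "validation_metrics": results,
        "cv_auc": auc,
        "classifier": clf,
        "predicted_labels": pred,
        "igp": igp_res,
    }


def simulate_to_dir(config: SyntheticConfig, out_dir: Path) -> None:
    """Write a synthetic discovery + validation cohort as TSV artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    disc = generate_cohort(config)
    val = generate_validation_cohort(config)
    cfg_payload = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in vars(config).items()
        if k != "outcomes"
    }
    (out_dir / "config.json").write_text(json.dumps(cfg_payload, indent=1, default=str))
    write_genotypes_tsv(disc.genotypes, out_dir / "discovery_genotypes.tsv")
    write_genotypes_tsv(val.genotypes, out_dir / "validation_genotypes.tsv")
    disc.covariates.to_csv(out_dir / "discovery_covariates.tsv", sep="\t")
    disc.outcomes.to_csv(out_dir / "discovery_outcomes.tsv", sep="\t")
    disc.true_labels.to_csv(out_dir / "discovery_true_labels.tsv", sep="\t")
    val.true_labels.to_csv(out_dir / "validation_true_labels.tsv", sep="\t")
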