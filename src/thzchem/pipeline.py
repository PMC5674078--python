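"""End-to-end pipeline: simulate -> preprocess -> maps -> cluster -> link -> predict.

Every stage writes its artifact to the run directory and records a SHA-256
checksum in ``summary.json``; rerunning with the same configuration
reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clustering, maps, pls
from .errors import InvalidArgumentError
from .pca import biplot_vectors, pca_fit
from .preprocessing import SpectraMatrix, crop_matrix, normalize_matrix
from .synthetic import SimConfig, simulate_dataset, write_dataset

log = logging.getLogger("thzchem")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run (YAML-serializable)."""

    n_samples: int = 27
    seed: int = 1
    band: tuple[float, float] = (20.0, 80.0)
    normalization: str = "snv"
    descriptor_pca_scale: bool = False
    cut_height: float | None = None          # default: height of the 3-cluster cut
    knn_k: int = 3
    n_groups: int = 8
    permutations: int = 2000
    pls_k: int = 4
    pls_iterations: int = 500
    train_mre_target: float = 10.0
    max_components: int = 10
    mp_link_strength: float = 0.9
    n_averages: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["band"] = list(self.band)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages on a synthetic dataset and write artifacts.

    Returns the machine-readable summary (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo, hi = cfg.band
    if not lo < hi:
        raise InvalidArgumentError("band lower bound must be < upper bound")

    summary: dict[str, Any] = {"config": cfg.to_dict(), "stages": {}}

    # -- simulate ---------------------------------------------------------
    log.info("stage simulate: n=%d seed=%d", cfg.n_samples, cfg.seed)
    sim_cfg = SimConfig(
        n_samples=cfg.n_samples,
        seed=cfg.seed,
        mp_link_strength=cfg.mp_link_strength,
        n_averages=cfg.n_averages,
    )
    ds = simulate_dataset(sim_cfg)
    paths = write_dataset(ds, out)
    summary["stages"]["simulate"] = {
        "seed": cfg.seed,
        "files": {k: _sha256(p) for k, p in paths.items()},
    }

    # -- preprocess -------------------------------------------------------
    log.info("stage preprocess: band %s-%s cm^-1, %s", lo, hi, cfg.normalization)
    matrix = crop_matrix(ds.spectra_matrix(), lo, hi)
    normalized = normalize_matrix(matrix, cfg.normalization)  # type: ignore[arg-type]
    norm_path = out / f"spectra_{cfg.normalization}.csv"
    normalized.to_csv(norm_path)
    summary["stages"]["preprocess"] = {"files": {"normalized": _sha256(norm_path)}}

    # -- maps (a priori descriptors / a posteriori spectra) ---------------
    log.info("stage pca: descriptor and spectral maps")
    desc_map = maps.build_map(ds.descriptors, scale=cfg.descriptor_pca_scale)
    spec_map = maps.build_map(normalized, normalize="none")
    desc_model = pca_fit(
        ds.descriptors.to_numpy(float),
        n_components=2,
        scale=cfg.descriptor_pca_scale,
    )
    bi = biplot_vectors(desc_model, feature_names=list(ds.descriptors.columns))
    pd.DataFrame(
        {"sample_id": desc_map.sample_ids, "PC1": desc_map.coords[:, 0], "PC2": desc_map.coords[:, 1]}
    ).to_csv(out / "descriptor_scores.csv", index=False)
    pd.DataFrame(
        {"sample_id": spec_map.sample_ids, "PC1": spec_map.coords[:, 0], "PC2": spec_map.coords[:, 1]}
    ).to_csv(out / "spectral_scores.csv", index=False)
    pd.DataFrame(bi.arrows, index=bi.feature_names, columns=["PC1", "PC2"]).to_csv(
        out / "biplot.csv"
    )
    summary["stages"]["pca"] = {
        "descriptor_map_variance": list(desc_map.explained_variance_pair),
        "spectral_map_variance": list(spec_map.explained_variance_pair),
        "files": {
            name: _sha256(out / name)
            for name in ("descriptor_scores.csv", "spectral_scores.csv", "biplot.csv")
        },
    }

    # -- cluster ----------------------------------------------------------
    log.info("stage cluster: UPGMA on spectral distances")
    dm = clustering.distance_matrix(normalized)
    tree = clustering.upgma(dm)
    if cfg.cut_height is not None:
        labels = clustering.cut_tree(tree, cfg.cut_height)
        cut_height = cfg.cut_height
    else:
        labels = clustering.cut_tree_k(tree, min(3, len(tree.sample_ids)))
        cut_height = None
    (out / "tree.nwk").write_text(clustering.to_newick(tree) + "\n")
    pd.DataFrame(
        [(a, b, h, s) for a, b, h, s in tree.merges],
        columns=["cluster_a", "cluster_b", "height", "new_size"],
    ).to_csv(out / "linkage.csv", index=False)
    pd.Series(labels, name="cluster").rename_axis("sample_id").to_csv(out / "clusters.csv")
    clustering.ordered_matrix(normalized, tree).to_csv(out / "ordered_spectra.csv")
    summary["stages"]["cluster"] = {
        "cut_height": cut_height,
        "n_clusters": int(len(set(labels.values()))),
        "files": {
            name: _sha256(out / name)
            for name in ("tree.nwk", "linkage.csv", "clusters.csv", "ordered_spectra.csv")
        },
    }

    # -- link -------------------------------------------------------------
    log.info("stage link: map concordance (k=%d, %d permutations)", cfg.knn_k, cfg.permutations)
    conc = maps.knn_concordance(
        desc_map, spec_map, k=cfg.knn_k, permutations=cfg.permutations, seed=cfg.seed
    )
    grp = maps.group_concordance(desc_map, spec_map, n_groups=cfg.n_groups)
    link_report = {
        "knn_k": conc.knn_k,
        "mean_overlap": conc.mean_overlap,
        "null_mean": conc.null_mean,
        "null_q95": conc.null_q95,
        "p_value": conc.p_value,
        "n_groups": grp.n_groups,
        "pair_agreement": grp.pair_agreement,
        "majority_mapping_fraction": grp.majority_mapping_fraction,
    }
    with open(out / "concordance.json", "w") as fh:
        json.dump(link_report, fh, indent=1)
    for descriptor in ("MP", "Mr"):
        table, corr = maps.descriptor_overlay(spec_map, ds.descriptors, descriptor)
        table.to_csv(out / f"overlay_{descriptor}.csv", index=False)
    summary["stages"]["link"] = {
        "seed": cfg.seed,
        "report": link_report,
        "files": {"concordance.json": _sha256(out / "concordance.json")},
    }

    # -- predict ----------------------------------------------------------
    log.info("stage predict: leave-%d-out, %d iterations", cfg.pls_k, cfg.pls_iterations)
    y = ds.descriptors["MP"].to_numpy(float)
    report = pls.leave_k_out(
        normalized.values,
        y,
        k=cfg.pls_k,
        iterations=cfg.pls_iterations,
        seed=cfg.seed,
        selection="auto",
        max_components=cfg.max_components,
        target_train_mre=cfg.train_mre_target,
        sample_ids=normalized.sample_ids,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    summary["stages"]["predict"] = {
        "seed": cfg.seed,
        "mean_relative_error_pct": report.mean_relative_error,
        "files": {"report.json": _sha256(out / "report.json")},
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
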