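"""Pipeline orchestration: annotate → quantify → indices → multivariate → concordance.

A :class:`PipelineConfig` (YAML/JSON-friendly, unknown keys rejected)
drives the stages; every stochastic stage carries an explicit seed.  Each
run writes a manifest recording input checksums, the config snapshot and
package version, so deterministic stages reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .annotation import AnnotationConfig, annotate_run
from .concordance import concordance_report
from .io import read_ms2, read_peaklists, write_ms2, write_peaklists
from .library import default_library, load_library
from .multivariate import OPLSDA, PCAModel, ParetoScaler, PLSDA, select_markers
from .quant import FeatureTable, QuantConfig, class_index_report, relative_areas
from .synthetic import SyntheticDesign, gen_feature_table, gen_spectra, gen_alignment, write_fasta

log = logging.getLogger("dinolipid")

__all__ = ["PipelineConfig", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Strict):
    annotate: bool = True
    quantify: bool = True
    indices: bool = True
    multivar: bool = True
    concord: bool = False


class PipelineConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    stages: StageToggles = Field(default_factory=StageToggles)
    # inputs
    peaklist_file: Optional[str] = None
    ms2_file: Optional[str] = None
    feature_table_file: Optional[str] = None
    alignment_file: Optional[str] = None
    library_file: Optional[str] = None
    out_dir: str = "results"
    # parameters
    tolerance: float = 0.3
    F: float = 1.0
    cv_folds: int = 7
    n_permutations: int = 200
    p_corr_threshold: float = 0.75
    alpha: float = 0.05
    mantel_permutations: int = 999
    bootstrap_B: int = 1000
    concord_mode: str = "%area"
    groups: Optional[dict[str, str]] = None  # sample -> label; PCA-derived if absent
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def pca_groups(table: FeatureTable) -> pd.Series:
    """Derive two-group labels from the sign of PCA component 1.

    The first group (lexicographically) is put on the negative side of
    axis 1 — a cosmetic sign convention only.
    """
    X, _ = _preprocessed(table)
    scores = PCAModel(n_components=min(2, len(table.samples) - 1)).fit(X).scores_
    side = scores[:, 0] >= 0
    labels = np.where(side, "group2", "group1")
    if (labels == "group1").sum() == 0 or (labels == "group2").sum() == 0:
        raise ValueError("PCA axis 1 does not split the samples into two groups")
    # sign convention: group1 loads negative on axis 1
    if scores[labels == "group1", 0].mean() > scores[labels == "group2", 0].mean():
        labels = np.where(side, "group1", "group2")
    return pd.Series(labels, index=table.samples, name="group")


def _preprocessed(table: FeatureTable):
    scaler = ParetoScaler().fit(table.data)
    return scaler.transform(table.data), scaler


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the in-memory report bundle.

    Stage outputs land in ``config.out_dir`` along with ``manifest.json``.
    A missing input for an enabled stage raises a named error before any
    later stage runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "inputs": {},
        "outputs": [],
    }
    for key in ("peaklist_file", "ms2_file", "feature_table_file", "alignment_file",
                "library_file"):
        val = getattr(config, key)
        if val and Path(val).exists():
            manifest["inputs"][key] = _sha256(Path(val))

    library = (
        load_library(config.library_file) if config.library_file else default_library()
    )
    table: Optional[FeatureTable] = None
    raw_areas: Optional[pd.DataFrame] = None

    if config.stages.annotate:
        if not config.peaklist_file:
            raise FileNotFoundError("annotate stage enabled but no peaklist_file given")
        log.info("annotating %s", config.peaklist_file)
        peaklists = read_peaklists(config.peaklist_file)
        ms2 = read_ms2(config.ms2_file) if config.ms2_file else []
        annotated = annotate_run(
            peaklists, ms2, library, AnnotationConfig(tolerance=config.tolerance)
        )
        annotated.to_csv(out / "annotations.tsv", sep="\t", index=False)
        manifest["outputs"].append("annotations.tsv")
        bundle["annotations"] = annotated

    if config.stages.quantify:
        if "annotations" in bundle:
            quant = bundle["annotations"].query("quantified")
            raw_areas = quant.pivot_table(
                index="sample", columns="species", values="area", fill_value=0.0
            )
            raw_areas.columns.name = None
        elif config.feature_table_file:
            table = FeatureTable.from_csv(config.feature_table_file)
        else:
            raise FileNotFoundError(
                "quantify stage needs annotations or a feature_table_file"
            )
        if raw_areas is not None:
            table = relative_areas(raw_areas)
        table.to_csv(out / "feature_table.tsv")
        manifest["outputs"].append("feature_table.tsv")
        bundle["feature_table"] = table

    if config.stages.indices:
        if table is None:
            raise FileNotFoundError("indices stage needs the quantify stage or a table")
        report = class_index_report(table, raw_areas, QuantConfig(F=config.F))
        report.to_csv(out / "class_indices.tsv", sep="\t")
        manifest["outputs"].append("class_indices.tsv")
        bundle["class_indices"] = report

    if config.stages.multivar:
        if table is None:
            raise FileNotFoundError("multivar stage needs a feature table")
        X, scaler = _preprocessed(table)
        kept = list(scaler.kept_feature_names())
        pca = PCAModel(n_components=min(2, len(table.samples) - 1)).fit(X)
        groups = (
            pd.Series(config.groups).reindex(table.samples)
            if config.groups
            else pca_groups(table)
        )
        plsda = PLSDA(
            cv_folds=config.cv_folds,
            n_permutations=config.n_permutations,
            random_state=config.seed,
        ).fit(X, groups.to_numpy())
        oplsda = OPLSDA(random_state=config.seed).fit(X, groups.to_numpy())
        percent = table.data[kept] * 100.0
        markers = select_markers(
            oplsda, percent, groups.to_numpy(),
            p_corr_threshold=config.p_corr_threshold, alpha=config.alpha,
        )
        markers.to_csv(out / "markers.tsv", sep="\t")
        summary = pd.DataFrame(
            {
                "statistic": ["pca_r2x_1", "pca_r2x_2", "plsda_q2", "plsda_permutation_p"],
                "value": [
                    float(pca.r2x_[0]),
                    float(pca.r2x_[1]) if len(pca.r2x_) > 1 else np.nan,
                    plsda.q2_,
                    plsda.permutation_p_,
                ],
            }
        )
        summary.to_csv(out / "multivariate_summary.tsv", sep="\t", index=False)
        pd.DataFrame(
            pca.scores_, index=table.samples,
            columns=[f"PC{i+1}" for i in range(pca.scores_.shape[1])],
        ).to_csv(out / "pca_scores.tsv", sep="\t")
        manifest["outputs"] += ["markers.tsv", "multivariate_summary.tsv", "pca_scores.tsv"]
        bundle.update(
            {"pca": pca, "plsda": plsda, "oplsda": oplsda,
             "markers": markers, "groups": groups}
        )

    if config.stages.concord:
        if table is None:
            raise FileNotFoundError("concord stage needs a feature table")
        if not config.alignment_file:
            raise FileNotFoundError("concord stage enabled but no alignment_file given")
        report = concordance_report(
            table,
            config.alignment_file,
            mode=config.concord_mode,
            n_perm=config.mantel_permutations,
            B=config.bootstrap_B,
            seed=config.seed,
        )
        rows = [
            {"class": cls, "mantel_r": e["mantel_r"], "mantel_p": e["mantel_p"],
             "nmds_stress": e["nmds"].stress}
            for cls, e in report.items()
        ]
        pd.DataFrame(rows).to_csv(out / "concordance.tsv", sep="\t", index=False)
        manifest["outputs"].append("concordance.tsv")
        for cls, e in report.items():
            if e.get("tree") is not None:
                (out / f"tree_{cls}.nwk").write_text(e["tree"].to_newick() + "\n")
                manifest["outputs"].append(f"tree_{cls}.nwk")
        bundle["concordance"] = report

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle


def simulate_to_dir(design: SyntheticDesign, out_dir: str | Path) -> dict[str, Path]:
    """Write a full synthetic dataset in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaklists, ms2, truth = gen_spectra(design)
    paths = {
        "peaklists": out / "peaklists.tsv",
        "ms2": out / "ms2.tsv",
        "feature_table": out / "true_feature_table.tsv",
        "alignment": out / "alignment.fasta",
        "groups": out / "groups.tsv",
    }
    write_peaklists(peaklists, paths["peaklists"])
    write_ms2(ms2, paths["ms2"])
    truth["table"].to_csv(paths["feature_table"])
    records, _ = gen_alignment(design)
    write_fasta(records, paths["alignment"])
    truth["groups"].to_frame().to_csv(paths["groups"], sep="\t")
    return paths
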