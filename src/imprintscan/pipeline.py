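"""End-to-end orchestration: preprocess -> profiles -> permutation screen ->
consistency filter -> DMR aggregation -> tissue/gestation classification,
with a JSON manifest recording the probe counts at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError
from .io import (
    BetaMatrix,
    read_annotation,
    read_bed,
    read_beta_table,
    read_sample_sheet,
    write_dml_table,
    write_dmr_bed,
)
from .preprocess import filter_by_detection
from .profiles import cluster_samples, correlation_distance_matrix, group_mean_frame
from .sam import SamConfig, sam_two_class
from .screen import (
    aggregate_dml_to_dmrs,
    annotate_cnv_overlap,
    apply_consistency_filter,
    call_candidate_dml,
)
from .tissue import (
    TISSUE_PANEL,
    classification_table,
    classify_dmrs,
    gestation_change_probes,
    placenta_specific_probes,
    tissue_differential_probes,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    beta_path: str
    annotation_path: str
    sample_sheet_path: str
    output_dir: str
    detection_path: str | None = None
    cnv_bed_path: str | None = None
    known_imprinted_genes: list[str] = field(default_factory=list)
    detection_alpha: float = 0.05
    fdr_target: float = 0.001
    delta_threshold: float = 0.15
    placenta_margin: float = 0.15
    monoallelic_threshold: float = 0.3
    sam: SamConfig = field(default_factory=SamConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sam_kwargs = raw.pop("sam", {})
        cfg = cls(**raw)
        cfg.sam = SamConfig(**sam_kwargs)
        cfg.sam.seed = cfg.seed
        cfg.sam.fdr_target = cfg.fdr_target
        return cfg


def run_all(
    cfg: RunConfig,
    bm: BetaMatrix | None = None,
    ann: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
) -> dict:
    """Execute the full screen; returns the manifest dict (also written as
    manifest.json).  In-memory inputs may be passed directly for testing;
    otherwise files referenced by the config are read."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": f"imprintscan {__version__}",
        "seed": cfg.seed,
        "thresholds": {
            "detection_alpha": cfg.detection_alpha,
            "fdr_target": cfg.fdr_target,
            "delta_threshold": cfg.delta_threshold,
            "placenta_margin": cfg.placenta_margin,
        },
        "stages": [],
        "outputs": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        if bm is None:
            bm = read_beta_table(cfg.beta_path, cfg.detection_path)
        if ann is None:
            ann = read_annotation(cfg.annotation_path)
        if sheet is None:
            sheet = read_sample_sheet(cfg.sample_sheet_path)
        manifest["n_probes_input"] = int(bm.shape[0])
        manifest["n_samples"] = int(bm.shape[1])

        stage("detection_filter")
        bm, removed = filter_by_detection(bm, cfg.detection_alpha, allow_missing=True)
        manifest["n_probes_removed_detection"] = len(removed)
        manifest["n_probes_after_detection"] = int(bm.shape[0])

        stage("profiles")
        profiles = group_mean_frame(bm, sheet)
        if bm.shape[1] >= 3:
            dend = cluster_samples(bm)
            (outdir / "cluster.newick").write_text(dend.to_newick() + "\n")
            correlation_distance_matrix(bm).to_csv(outdir / "distances.tsv", sep="\t")
            manifest["outputs"]["cluster"] = "cluster.newick"

        stage("sam_two_class")
        sam_cfg = cfg.sam
        sam_cfg.seed = cfg.seed
        result = sam_two_class(bm, sheet, "diandric", "digynic", sam_cfg)
        result.delta_table.to_csv(outdir / "delta_table.tsv", sep="\t", index=False)

        stage("screen")
        candidates = call_candidate_dml(
            result, profiles, cfg.fdr_target, cfg.delta_threshold
        )
        retained, eliminated = apply_consistency_filter(candidates)
        if cfg.cnv_bed_path:
            intervals = read_bed(cfg.cnv_bed_path)
            retained = annotate_cnv_overlap(retained, intervals, ann)
            eliminated = annotate_cnv_overlap(eliminated, intervals, ann)
        write_dml_table(retained + eliminated, outdir / "dml_table.tsv")
        write_dml_table(eliminated, outdir / "eliminated.tsv")
        dmrs = aggregate_dml_to_dmrs(retained, ann)
        write_dmr_bed(dmrs, outdir / "dmrs.bed")
        manifest["outputs"].update(
            {"dml": "dml_table.tsv", "eliminated": "eliminated.tsv", "dmrs": "dmrs.bed"}
        )
        manifest["n_candidates"] = len(candidates)
        manifest["n_eliminated"] = len(eliminated)
        manifest["n_final_dml"] = len(retained)
        manifest["n_dmrs"] = len(dmrs)
        manifest["n_genes"] = len({d.gene_symbol for d in dmrs})
        manifest["n_maternal"] = sum(1 for d in dmrs if d.origin == "maternal")
        manifest["n_paternal"] = sum(1 for d in dmrs if d.origin == "paternal")
        manifest["n_cnv_overlap"] = (
            sum(1 for c in retained if c.cnv_overlap) if cfg.cnv_bed_path else None
        )

        stage("classify")
        present = set(sheet.loc[[s for s in bm.samples if s in sheet.index], "group"])
        can_classify = (
            all(t in present for t in TISSUE_PANEL)
            and "placenta_term" in present
            and dmrs
        )
        if can_classify:
            dml_probes = sorted({p for d in dmrs for p in d.probe_ids})
            sub = bm.select_probes(dml_probes)
            tissue_called = tissue_differential_probes(sub, sheet, sam_cfg)
            placenta_flags = placenta_specific_probes(sub, sheet, cfg.placenta_margin)
            gestation_called = gestation_change_probes(sub, sheet, sam_cfg)
            classifications = classify_dmrs(
                dmrs,
                tissue_called,
                placenta_flags,
                gestation_called,
                set(cfg.known_imprinted_genes),
                set(sub.probes),
            )
            classification_table(classifications).to_csv(
                outdir / "classification.tsv", sep="\t", index=False
            )
            manifest["outputs"]["classification"] = "classification.tsv"
            manifest["n_tissue_differential"] = sum(
                1 for c in classifications if c.tissue_differential
            )
            manifest["n_placenta_specific"] = sum(
                1 for c in classifications if c.placenta_specific
            )
            manifest["n_gestation_change"] = sum(
                1 for c in classifications if c.gestation_change
            )
            manifest["n_stable"] = sum(1 for c in classifications if c.stable)
        else:
            manifest["n_stable"] = None
            log.info("classification skipped: tissue panel incomplete")

        manifest["complete"] = True
    except Exception as exc:
        manifest["complete"] = False
        manifest["error"] = f"{manifest['stages'][-1] if manifest['stages'] else '?'}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
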