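"""End-to-end orchestration: karyotypes → groups → classification → screen."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import cerna, foldchange, io
from .cohort import Target, assign_groups, groups_table
from .genome import call_karyotypes

logger = logging.getLogger(__name__)


def run_pipeline(config: io.RunConfig) -> dict:
    """Run every stage for every target region and write the report bundle.

    Outputs per run: arm_calls.tsv, karyotypes.tsv; per target:
    groups.<target>.tsv, classification.<target>.tsv and, when a pairs
    file is configured, correlations.<target>.tsv.  A JSON summary with
    per-class counts and every threshold and group size used is written
    to summary.json and returned.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = io.read_expression(config.expression)
    segments = io.read_segments(config.segments)
    sheet = io.read_sample_sheet(config.samples)
    arms = io.read_cytobands(config.cytobands)
    annotation = io.read_annotation(config.annotation) if config.annotation else None
    pairs = io.read_pairs(config.pairs) if config.pairs else None

    missing = sorted(set(sheet["sample_id"]) - set(matrix.columns))
    if missing:
        raise ValueError(f"sample sheet samples absent from matrix: {missing}")

    tissue = dict(zip(sheet["sample_id"], sheet["tissue"]))
    tumor_ids = sorted(s for s, t in tissue.items() if t == "tumor")
    logger.info("calling karyotypes for %d samples", len(tumor_ids))
    calls, karyotypes = call_karyotypes(
        segments, arms, config.broad_threshold, sample_ids=tumor_ids
    )
    io.write_arm_calls(calls, outdir / "arm_calls.tsv")
    io.write_karyotypes(karyotypes, outdir / "karyotypes.tsv")

    summary: dict = {
        "broad_threshold": config.broad_threshold,
        "thresholds": {
            "upt_fc3": config.thresholds.upt_fc3,
            "upt_fc4": config.thresholds.upt_fc4,
            "over_fc2": config.thresholds.over_fc2,
            "over_fc3": config.thresholds.over_fc3,
            "fdr_alpha": config.thresholds.fdr_alpha,
            "require_upt": config.thresholds.require_upt,
        },
        "n_samples": len(tissue),
        "n_transcripts": len(matrix),
        "targets": {},
    }

    for target_text in config.targets:
        target = Target.parse(target_text)
        design = assign_groups(karyotypes, tissue, target)
        logger.info(
            "target %s: %d Selected, %d Control, %d excluded",
            target.label,
            len(design.selected_ids),
            len(design.control_ids),
            len(design.excluded_ids),
        )
        safe = target.label.replace(":", "_").replace(",", "")
        pd.DataFrame(
            groups_table(design), columns=["sample_id", "group"]
        ).to_csv(outdir / f"groups.{safe}.tsv", sep="\t", index=False)

        result = foldchange.classify_matrix(
            matrix,
            design,
            config.thresholds,
            annotation=annotation,
            biotype_allowlist=config.biotype_allowlist,
            fdr_filter=config.fdr_filter,
        )
        if annotation is not None and {"chrom", "start"} <= set(result.columns):
            result = result.sort_values(["chrom", "start"], kind="stable")
        result.to_csv(outdir / f"classification.{safe}.tsv", sep="\t")

        target_summary = {
            "groups": {
                "normal": len(design.normal_ids),
                "all_crc": len(design.all_crc_ids),
                "selected": len(design.selected_ids),
                "control": len(design.control_ids),
                "excluded": len(design.excluded_ids),
            },
            "flagged": design.flagged,
            "class_counts": result["class_label"].value_counts().to_dict(),
        }

        if pairs is not None:
            corr_ids = (
                sorted(tissue) if config.include_normals_in_correlation else tumor_ids
            )
            results = cerna.sponge_screen(matrix, pairs, corr_ids, config.alpha)
            cerna.correlation_table(results).to_csv(
                outdir / f"correlations.{safe}.tsv", sep="\t", index=False
            )
            target_summary["consistency_counts"] = (
                cerna.correlation_table(results)["consistency"].value_counts().to_dict()
            )
        summary["targets"][target.label] = target_summary

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
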