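"""End-to-end orchestration: simulate -> filter -> cnv -> de -> enrich.

``run_pipeline`` executes the stages in order on a set of input files,
logging per-stage record counts, and emits eight artifacts into the
output directory:

    filtered.vcf        variants surviving the somatic approximation filter
    decisions.tsv       per-variant decision provenance
    gene_frequency.tsv  per-gene mutated-line counts and fractions
    cnv_calls.tsv       per gene x line log2 ratios and categories
    de_nb.tsv           NB exact-test table with BH q and direction
    de_summary.json     (total, up, down) gene counts per stage
    enrichment.tsv      combined-score enrichment of the up and down lists
    oncoprint.tsv       gene x line mutation/CNV/expression summary

A stage failure aborts with the stage name and the offending record;
artifacts already written by earlier stages remain on disk.  All outputs
carry the tool version and a config hash in a header comment and are
byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cnv import CNVThresholds, cnv_pipeline
from .enrichment import enrich
from .expression import (
    DEMode,
    DEThresholds,
    call_de,
    cpm,
    moderated_t_table,
    nb_de_table,
)
from .panel_io import (
    read_count_matrix,
    read_depth_matrix,
    read_gene_sets,
    read_hotspot_catalog,
    read_multisample_vcf,
    read_population_db,
    write_filtered_vcf,
    write_table,
)
from .somatic_filter import (
    FilterConfig,
    FilterStatus,
    HotspotCatalog,
    PanelRecord,
    PanelVariantTable,
    apply_filter,
    gene_mutation_frequency,
    rejection_counts,
)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "make_oncoprint_table", "ARTIFACTS"]

ARTIFACTS = (
    "filtered.vcf",
    "decisions.tsv",
    "gene_frequency.tsv",
    "cnv_calls.tsv",
    "de_nb.tsv",
    "de_summary.json",
    "enrichment.tsv",
    "oncoprint.tsv",
)

logger = logging.getLogger("oncopanel")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    vcf: Path
    popdb: Path
    hotspots: Path
    depths: Path
    counts: Path
    groups: Path
    gmt: Path
    out_dir: Path
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    cnv_thresholds: CNVThresholds = field(default_factory=CNVThresholds)
    de_thresholds: DEThresholds = field(default_factory=DEThresholds)
    group_order: tuple[str, str] = ("normal", "cancer")
    panel_members: Optional[Sequence[str]] = None
    permutations: int = 1000
    top_n_genes: int = 30
    expression_tier_breakpoint: float = 1.0

    def __post_init__(self) -> None:
        for name in ("vcf", "popdb", "hotspots", "depths", "counts", "groups", "gmt", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "cnv_thresholds" in raw:
            raw["cnv_thresholds"] = CNVThresholds(**raw["cnv_thresholds"])
        if "de_thresholds" in raw:
            raw["de_thresholds"] = DEThresholds(**raw["de_thresholds"])
        if "group_order" in raw:
            raw["group_order"] = tuple(raw["group_order"])
        return cls(**raw)

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: str(v) if isinstance(v, Path) else v for k, v in out.items()}


def _select_lines(table: PanelVariantTable, members: Sequence[str]) -> PanelVariantTable:
    missing = [m for m in members if m not in table.lines]
    if missing:
        raise ValueError(f"panel members absent from the VCF: {missing}")
    idx = [table.lines.index(m) for m in members]
    records = []
    for rec in table.records:
        presence = tuple(rec.presence[i] for i in idx)
        if any(presence):
            records.append(PanelRecord(rec.key, presence, rec.annotation))
    return PanelVariantTable(tuple(members), records)


def make_oncoprint_table(
    filtered: PanelVariantTable,
    catalog: HotspotCatalog,
    cnv_calls: pd.DataFrame,
    expr_log2_vs_median: pd.DataFrame,
    genes: Sequence[str],
    tier_breakpoint: float = 1.0,
) -> pd.DataFrame:
    """Gene x line summary of mutation, copy number and expression.

    Mutation cells distinguish catalogued hotspots from novel variants;
    expression tiers bucket log2(sample / panel median) at the +/-
    breakpoint, so a line sitting exactly at the panel median is tier 0.
    """
    lines = list(filtered.lines)
    missing = [l for l in lines if l not in set(cnv_calls["line"])]
    if missing:
        raise ValueError(f"lines absent from CNV calls: {missing}")

    mutation: dict[tuple[str, str], str] = {}
    for rec in filtered.records:
        gene = rec.annotation.gene_symbol
        is_hotspot = catalog.contains(rec.key, rec.annotation)
        for line, present in zip(lines, rec.presence):
            if not present:
                continue
            prev = mutation.get((gene, line))
            if is_hotspot or prev is None:
                mutation[(gene, line)] = "hotspot" if is_hotspot else "novel"

    cnv_map = {
        (g, l): cat
        for g, l, cat in zip(cnv_calls["gene"], cnv_calls["line"], cnv_calls["category"])
    }
    rows = []
    for gene in genes:
        for line in lines:
            v = np.nan
            tier = pd.NA
            if gene in expr_log2_vs_median.index and line in expr_log2_vs_median.columns:
                v = float(expr_log2_vs_median.loc[gene, line])
                tier = 0
                if v >= tier_breakpoint:
                    tier = 1
                elif v <= -tier_breakpoint:
                    tier = -1
            rows.append(
                {
                    "gene": gene,
                    "line": line,
                    "mutation": mutation.get((gene, line), "none"),
                    "cnv_category": cnv_map.get((gene, line), "na"),
                    "expression_log2_vs_median": v,
                    "expression_tier": tier,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all stages; returns the artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.as_dict()
    meta.pop("out_dir")  # provenance hashes parameters, not output location
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # -- stage: filter ------------------------------------------------------
    try:
        table = read_multisample_vcf(config.vcf)
        db = read_population_db(config.popdb)
        catalog = read_hotspot_catalog(config.hotspots)
        if config.panel_members is not None:
            table = _select_lines(table, config.panel_members)
        filtered, decisions = apply_filter(table, db, catalog, config.filter)
        counts_by_reason = rejection_counts(decisions)
        log(f"filter: {len(table)} variants in, {len(filtered)} kept ({counts_by_reason})")
        write_filtered_vcf(filtered, out / "filtered.vcf", meta)
        dec_df = pd.DataFrame(
            {
                "variant": [str(d.key) for d in decisions],
                "presence_count": [d.presence_count for d in decisions],
                "status": [d.status.value for d in decisions],
                "reason": [d.reason.value for d in decisions],
                "rescued": [d.rescued for d in decisions],
            }
        ).sort_values("variant", kind="stable")
        write_table(dec_df, out / "decisions.tsv", meta, index=False)
        freq = gene_mutation_frequency(filtered)
        freq_df = pd.DataFrame(freq, columns=["gene", "n_lines_mutated", "fraction"])
        write_table(freq_df, out / "gene_frequency.tsv", meta, index=False)
    except Exception as exc:
        raise PipelineStageError("filter", str(exc)) from exc

    # -- stage: cnv ---------------------------------------------------------
    try:
        depth_matrix = read_depth_matrix(config.depths)
        cnv_calls = cnv_pipeline(depth_matrix, config.cnv_thresholds)
        n_aberrant = int((cnv_calls["category"] != "neutral").sum())
        log(f"cnv: {len(cnv_calls)} gene x line calls, {n_aberrant} non-neutral")
        write_table(cnv_calls, out / "cnv_calls.tsv", meta, index=False)
    except Exception as exc:
        raise PipelineStageError("cnv", str(exc)) from exc

    # -- stage: de ----------------------------------------------------------
    try:
        count_matrix = read_count_matrix(config.counts, config.groups)
        nb = nb_de_table(count_matrix, config.group_order)
        up, down, nb_counts = call_de(nb, config.de_thresholds, DEMode.NB_FDR)
        log(f"de (NB exact): {nb_counts}")
        summary = {"nb_fdr": nb_counts, "phi": nb.attrs["phi"], "contrast": nb.attrs["contrast"]}
        g1, g2 = config.group_order
        sizes = count_matrix.groups.value_counts()
        if sizes.get(g1, 0) >= 2 and sizes.get(g2, 0) >= 2:
            modt = moderated_t_table(count_matrix, config.group_order)
            _, _, modt_counts = call_de(modt, config.de_thresholds, DEMode.MODT_P)
            write_table(modt, out / "de_modt.tsv", meta)
            summary["modt_p"] = modt_counts
            log(f"de (moderated t): {modt_counts}")
        write_table(nb, out / "de_nb.tsv", meta)
        (out / "de_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    except Exception as exc:
        raise PipelineStageError("de", str(exc)) from exc

    # -- stage: enrich ------------------------------------------------------
    try:
        library = read_gene_sets(config.gmt, universe=list(count_matrix.counts.index))
        frames = []
        for direction, genes in (("up", up), ("down", down)):
            if genes:
                frames.append(
                    enrich(genes, direction, library, B=config.permutations, seed=config.seed)
                )
        enrichment = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["term", "combined_score", "direction"])
        )
        log(f"enrich: {len(enrichment)} term scores from {len(up)} up / {len(down)} down genes")
        write_table(enrichment, out / "enrichment.tsv", meta, index=False)
    except Exception as exc:
        raise PipelineStageError("enrich", str(exc)) from exc

    # -- stage: oncoprint ---------------------------------------------------
    try:
        freq_order = [g for g, _n, _f in freq]
        top_genes = freq_order[: config.top_n_genes]
        panel_cols = [c for c in count_matrix.counts.columns if c in set(filtered.lines)]
        cpm_mat = cpm(count_matrix.counts)
        expr = pd.DataFrame(index=count_matrix.counts.index)
        if panel_cols:
            panel_cpm = cpm_mat[panel_cols] + 0.5
            expr = np.log2(panel_cpm.div(panel_cpm.median(axis=1), axis=0))
        oncoprint = make_oncoprint_table(
            filtered,
            catalog,
            cnv_calls,
            expr,
            top_genes,
            config.expression_tier_breakpoint,
        )
        log(f"oncoprint: {len(top_genes)} genes x {filtered.n_lines} lines")
        write_table(oncoprint, out / "oncoprint.tsv", meta, index=False)
    except Exception as exc:
        raise PipelineStageError("oncoprint", str(exc)) from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {name: out / name for name in ARTIFACTS}
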