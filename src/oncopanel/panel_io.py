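"""Readers and writers for the panel pipeline's external formats.

VCF v4.2 (multi-sample panel calls, via pysam), TSV (population allele
frequencies, hotspot catalog, depth and count matrices, result tables)
and GMT gene-set libraries.  Readers return the pipeline's domain types;
writers emit TSV with a stable column order and a header comment carrying
the tool version and a config hash, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .somatic_filter import (
    Annotation,
    EffectClass,
    HotspotCatalog,
    PanelRecord,
    PanelVariantTable,
    PopulationDB,
    VariantKey,
    normalize_variant,
)

__all__ = [
    "FormatError",
    "ParseReport",
    "read_multisample_vcf",
    "write_filtered_vcf",
    "read_population_db",
    "read_hotspot_catalog",
    "CountMatrix",
    "DepthMatrix",
    "GeneSetLibrary",
    "read_count_matrix",
    "read_depth_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "write_table",
    "config_hash",
]

#: default INFO keys carrying the annotation (Number=A, one value per alt)
DEFAULT_ANNOTATION_FIELDS = {
    "gene_symbol": "GENE",
    "effect_class": "EFFECT",
    "protein_change": "PCHANGE",
    "deleteriousness_score": "DSCORE",
}

_MISSING = "."


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ParseReport:
    """Record-level warnings accumulated while reading a file."""

    unparseable_genotypes: int = 0
    messages: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.messages.append(message)


def config_hash(config: Mapping | None) -> str:
    """Short stable hash of a configuration mapping, for output headers."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_comment(config: Mapping | None = None) -> str:
    return f"# oncopanel {__version__} config={config_hash(config)}"


# ---------------------------------------------------------------------------
# VCF


def _annotation_from_info(info, fields: Mapping[str, str], alt_index: int) -> Annotation:
    def pick(key: str):
        if key not in fields:
            return None
        value = info.get(fields[key])
        if value is None:
            return None
        if isinstance(value, tuple):
            value = value[alt_index] if alt_index < len(value) else None
        return value

    gene = pick("gene_symbol") or "NA"
    effect = pick("effect_class") or EffectClass.OTHER.value
    pchange = pick("protein_change")
    if pchange in (None, _MISSING, ""):
        pchange = None
    score = pick("deleteriousness_score")
    if score is not None:
        score = float(score)
    return Annotation(str(gene), EffectClass(str(effect)), pchange, score)


def read_multisample_vcf(
    path: str | os.PathLike,
    annotation_fields: Mapping[str, str] | None = None,
    report: ParseReport | None = None,
) -> PanelVariantTable:
    """Read a multi-sample VCF into a :class:`PanelVariantTable`.

    Multi-allelic sites are split into one record per (site, alt allele);
    a sample is flagged present iff its genotype contains at least one
    copy of that alt allele.  Unparseable genotypes are counted in the
    parse report and treated as absent.  Records whose keys coincide
    after normalization are merged (presence flags OR-ed, first
    annotation retained).
    """
    fields = dict(annotation_fields or DEFAULT_ANNOTATION_FIELDS)
    report = report if report is not None else ParseReport()
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = tuple(vcf.header.samples)
        if not samples:
            raise FormatError(f"{path}: VCF has no sample columns")
        merged: dict[VariantKey, tuple[list[bool], Annotation]] = {}
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                if alt is None or set(alt) - set("ACGT"):
                    report.warn(f"{rec.chrom}:{rec.pos} skipping symbolic alt {alt!r}")
                    continue
                key = normalize_variant(VariantKey(rec.chrom, rec.pos, rec.ref, alt))
                presence = []
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or all(g is None for g in gt):
                        report.unparseable_genotypes += 1
                        presence.append(False)
                    else:
                        presence.append((ai + 1) in gt)
                annotation = _annotation_from_info(rec.info, fields, ai)
                if key in merged:
                    old_presence, old_ann = merged[key]
                    merged[key] = (
                        [a or b for a, b in zip(old_presence, presence)],
                        old_ann,
                    )
                else:
                    merged[key] = (presence, annotation)
    records = [
        PanelRecord(key, tuple(presence), ann) for key, (presence, ann) in merged.items()
    ]
    return PanelVariantTable(samples, records)


def write_filtered_vcf(
    table: PanelVariantTable,
    path: str | os.PathLike,
    config: Mapping | None = None,
) -> None:
    """Write a panel table as an uncompressed single-alt-per-record VCF."""
    header = pysam.VariantHeader()
    header.add_line(f"##oncopanel={__version__},config={config_hash(config)}")
    for chrom in sorted({r.key.chrom for r in table.records}):
        header.contigs.add(chrom, length=300_000_000)
    header.info.add("GENE", "A", "String", "Gene symbol")
    header.info.add("EFFECT", "A", "String", "Effect class")
    header.info.add("PCHANGE", "A", "String", "Protein change")
    header.info.add("DSCORE", "A", "Float", "Deleteriousness score (more negative = worse)")
    header.formats.add("GT", "1", "String", "Genotype")
    for line in table.lines:
        header.add_sample(line)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for rec in sorted(table.records, key=lambda r: (r.key.chrom, r.key.pos, r.key.ref, r.key.alt)):
            v = out.new_record(
                contig=rec.key.chrom,
                start=rec.key.pos - 1,
                alleles=(rec.key.ref, rec.key.alt),
            )
            ann = rec.annotation
            v.info["GENE"] = (ann.gene_symbol,)
            v.info["EFFECT"] = (ann.effect_class.value,)
            if ann.protein_change is not None:
                v.info["PCHANGE"] = (ann.protein_change,)
            if ann.deleteriousness_score is not None:
                v.info["DSCORE"] = (ann.deleteriousness_score,)
            for line, present in zip(table.lines, rec.presence):
                v.samples[line]["GT"] = (0, 1) if present else (0, 0)
            out.write(v)


# ---------------------------------------------------------------------------
# TSV lookup tables


def read_population_db(path: str | os.PathLike) -> PopulationDB:
    """Read a chrom/pos/ref/alt/allele_frequency TSV into a PopulationDB."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "allele_frequency"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    db = PopulationDB()
    for row in df.itertuples(index=False):
        freq = float(row.allele_frequency)
        if not 0.0 <= freq <= 1.0:
            raise FormatError(
                f"{path}: allele frequency {freq} outside [0, 1] at "
                f"{row.chrom}:{row.pos} {row.ref}>{row.alt}"
            )
        db.add(VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt), freq)
    return db


def read_hotspot_catalog(path: str | os.PathLike) -> HotspotCatalog:
    """Read a hotspot TSV; rows may carry a genomic key, a
    (gene, protein_change) pair, or both."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    catalog = HotspotCatalog()
    for i, row in enumerate(df.itertuples(index=False)):
        has_key = all(
            getattr(row, c, None) not in (None, "") and pd.notna(getattr(row, c, None))
            for c in ("chrom", "pos", "ref", "alt")
        )
        gene = getattr(row, "gene", None)
        pchange = getattr(row, "protein_change", None)
        has_protein = (
            gene is not None and pd.notna(gene) and pchange is not None and pd.notna(pchange)
        )
        if not has_key and not has_protein:
            raise FormatError(
                f"{path}: row {i} has neither a genomic key nor (gene, protein_change)"
            )
        if has_key:
            catalog.add_key(VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt))
        if has_protein:
            catalog.add_protein(str(gene), str(pchange))
    return catalog


# ---------------------------------------------------------------------------
# matrices

@dataclass
class CountMatrix:
    """genes × samples nonnegative integer read counts with group labels."""

    counts: pd.DataFrame
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)) or np.isnan(values).any():
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise FormatError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise FormatError(f"samples missing from group labels: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.counts.columns)]
        if self.groups.nunique() < 1 or self.groups.value_counts().min() < 1:
            raise FormatError("every group needs at least one sample")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())


@dataclass
class DepthMatrix:
    """genes × lines mean capture depth (reads, >= 0)."""

    depths: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.depths.to_numpy() < 0).any():
            raise FormatError("depths must be nonnegative")
        if self.depths.index.duplicated().any() or self.depths.columns.duplicated().any():
            raise FormatError("gene and line identifiers must be unique")

    @property
    def genes(self) -> list[str]:
        return list(self.depths.index)

    @property
    def lines(self) -> list[str]:
        return list(self.depths.columns)


@dataclass
class GeneSetLibrary:
    """term -> gene set, plus the background universe."""

    terms: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise FormatError(f"term {term!r} is empty")
            if not genes <= self.universe:
                raise FormatError(f"term {term!r} has genes outside the universe")

    @property
    def term_names(self) -> list[str]:
        return sorted(self.terms)


def read_count_matrix(path: str | os.PathLike, groups_path: str | os.PathLike) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", comment="#", dtype=str)
    if not {"sample", "group"} <= set(groups_df.columns):
        raise FormatError(f"{groups_path}: needs columns sample, group")
    groups = groups_df.set_index("sample")["group"]
    return CountMatrix(counts, groups)


def read_depth_matrix(path: str | os.PathLike) -> DepthMatrix:
    return DepthMatrix(pd.read_csv(path, sep="\t", comment="#", index_col=0))


def read_gene_sets(
    path: str | os.PathLike, universe: Optional[Sequence[str]] = None
) -> GeneSetLibrary:
    """Read a GMT file (term<TAB>description<TAB>gene...).

    When no explicit universe is given, the union of all term genes is
    used as the background.
    """
    terms: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs term, description, genes")
            term, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no genes")
            terms[term] = frozenset(genes)
    if universe is None:
        uni = frozenset().union(*terms.values()) if terms else frozenset()
    else:
        uni = frozenset(universe)
    return GeneSetLibrary(terms, uni)


def write_gene_sets(terms: Mapping[str, Sequence[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for term in terms:
            genes = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    config: Mapping | None = None,
    index: bool = True,
) -> None:
    """Write a result table as TSV with the provenance header comment."""
    buf = io.StringIO()
    buf.write(_header_comment(config) + "\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())
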