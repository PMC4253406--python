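"""Synthetic inputs with known ground truth for the panel pipeline.

Every file the pipeline consumes can be generated here, emulating the
statistical structure of a 22-line tumor-only cell-line panel study:

* a multi-sample VCF mixing germline variants (present in the population
  database at Beta-distributed allele frequencies, shared across lines
  under Hardy-Weinberg carrier probabilities), recurrent artifacts
  (absent from the database but planted in more lines than the
  recurrence cutoff tolerates), private somatic variants (one line each)
  and hotspot somatics (listed in the catalog, planted in an arbitrary
  number of lines);
* a per-gene depth matrix with planted copy-number states and per-line
  library-size multipliers;
* a negative-binomial count matrix with planted fold changes between two
  labeled groups;
* a GMT library with terms planted to overlap the true up/down lists.

All generators are pure functions of (config, seed); one seeded stream
per artifact keeps each artifact independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel_io import (
    CountMatrix,
    DepthMatrix,
    GeneSetLibrary,
    write_filtered_vcf,
    write_gene_sets,
)
from .somatic_filter import (
    Annotation,
    EffectClass,
    PanelRecord,
    PanelVariantTable,
    VariantKey,
)

__all__ = [
    "GermlineSim",
    "ArtifactSim",
    "PrivateSomaticSim",
    "HotspotSim",
    "CnvSim",
    "DeSim",
    "EnrichmentSim",
    "SimConfig",
    "simulate_panel",
    "random_filter_inputs",
    "simulate_depths",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_all",
]

_CHROMS = [f"chr{i}" for i in range(1, 23)]
_EFFECTS = [
    (EffectClass.SYNONYMOUS, 0.30),
    (EffectClass.MISSENSE, 0.50),
    (EffectClass.NONSENSE, 0.05),
    (EffectClass.FRAMESHIFT, 0.05),
    (EffectClass.SPLICE, 0.05),
    (EffectClass.OTHER, 0.05),
]


@dataclass(frozen=True)
class GermlineSim:
    """Population variants: allele frequency ~ Beta(a, b) truncated away
    from 0; per-line carrier probability 1 - (1 - f)^2 (diploid HWE)."""

    count: int = 120
    beta_a: float = 0.5
    beta_b: float = 8.0


@dataclass(frozen=True)
class ArtifactSim:
    """Recurrent artifacts: absent from the population database but shared
    by more lines than the recurrence rule tolerates (for 22 lines the
    cutoff is 4, so artifacts occupy at least 5)."""

    count: int = 15
    min_lines: int = 5
    max_lines: int = 9


@dataclass(frozen=True)
class PrivateSomaticSim:
    per_line: int = 3


@dataclass(frozen=True)
class HotspotSim:
    """Catalogued somatic hotspots; a fraction of catalog rows carry only
    (gene, protein_change), exercising the secondary index."""

    count: int = 8
    min_lines: int = 1
    max_lines: int = 12
    protein_only_fraction: float = 0.25


@dataclass(frozen=True)
class CnvSim:
    """Per-gene copy-number truth: each gene draws a state from
    ``state_weights``; aberrant genes carry the state in 1..max_aberrant_lines
    random lines (copy 2 elsewhere).  Aberrations are kept to a couple of
    lines per gene so that the self-inclusion of the queried line in the
    pseudonormal attenuates ratios by no more than ~1/11 on the linear
    scale.  Copy-0 cells emit residual background depth.  Per-line depth
    multipliers exercise library-size scaling."""

    n_genes: int = 2000
    base_depth: float = 100.0
    noise_cv: float = 0.08
    state_weights: tuple[tuple[int, float], ...] = (
        (0, 0.02),
        (1, 0.06),
        (2, 0.80),
        (3, 0.07),
        (5, 0.05),
    )
    max_aberrant_lines: int = 2
    multiplier_low: float = 0.5
    multiplier_high: float = 2.0
    background_fraction: float = 0.02


@dataclass(frozen=True)
class DeSim:
    """NB counts: baseline mean ~ lognormal, planted |log2FC| in a fixed
    number of up/down genes, common dispersion phi.  ``n_group2=None``
    uses one sample per panel line (the pipeline's layout)."""

    n_genes: int = 2000
    n_group1: int = 4
    n_group2: int | None = None
    group1: str = "normal"
    group2: str = "cancer"
    logmean_mean: float = float(np.log(150.0))
    logmean_sd: float = 0.7
    phi: float = 0.1
    n_up: int = 30
    n_down: int = 50
    log2fc: float = 2.0
    depth_factor_low: float = 0.7
    depth_factor_high: float = 1.3


@dataclass(frozen=True)
class EnrichmentSim:
    n_terms: int = 50
    term_size: int = 50
    planted_overlap: float = 0.8


@dataclass(frozen=True)
class SimConfig:
    seed: int  # mandatory
    n_lines: int = 22
    germline: GermlineSim = field(default_factory=GermlineSim)
    artifact: ArtifactSim = field(default_factory=ArtifactSim)
    somatic_private: PrivateSomaticSim = field(default_factory=PrivateSomaticSim)
    somatic_hotspot: HotspotSim = field(default_factory=HotspotSim)
    cnv: CnvSim = field(default_factory=CnvSim)
    de: DeSim = field(default_factory=DeSim)
    enrichment: EnrichmentSim = field(default_factory=EnrichmentSim)

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.artifact.min_lines <= int(np.ceil(0.15 * self.n_lines)):
            raise ValueError(
                "artifact.min_lines must exceed ceil(0.15 * n_lines) so artifacts "
                "trip the recurrence rule"
            )

    @property
    def line_names(self) -> list[str]:
        return [f"LINE_{i + 1:02d}" for i in range(self.n_lines)]

    def gene_names(self, n: int) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(n)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# variant panel


def _draw_effect(rng: np.random.Generator) -> EffectClass:
    classes, weights = zip(*_EFFECTS)
    return classes[rng.choice(len(classes), p=np.array(weights))]


def _protein_change(rng: np.random.Generator, effect: EffectClass) -> str | None:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    pos = int(rng.integers(1, 800))
    if effect in (EffectClass.MISSENSE,):
        a, b = rng.choice(list(aa), size=2, replace=False)
        return f"{a}{pos}{b}"
    if effect is EffectClass.NONSENSE:
        return f"{rng.choice(list(aa))}{pos}*"
    if effect is EffectClass.FRAMESHIFT:
        return f"{rng.choice(list(aa))}{pos}fs"
    return None


def _presence_with_min_one(
    rng: np.random.Generator, n_lines: int, prob: float
) -> np.ndarray:
    for _ in range(200):
        flags = rng.random(n_lines) < prob
        if flags.any():
            return flags
    flags = np.zeros(n_lines, dtype=bool)
    flags[int(rng.integers(n_lines))] = True
    return flags


def simulate_panel(
    config: SimConfig,
) -> tuple[PanelVariantTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Variant panel with truth.

    Returns (table, popdb_df, hotspots_df, truth_df): the multi-sample
    panel table, the population-database and hotspot-catalog tables in
    their on-disk TSV layouts, and the per-variant truth classes.
    """
    rng = _rng(config, 1)
    n = config.n_lines
    gene_pool = config.gene_names(500)
    bases = np.array(list("ACGT"))

    used_pos: set[tuple[str, int]] = set()

    def new_site() -> tuple[str, int, str, str]:
        while True:
            chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
            pos = int(rng.integers(1_000, 50_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                ref, alt = rng.choice(bases, size=2, replace=False)
                return chrom, pos, str(ref), str(alt)

    records: list[PanelRecord] = []
    truth_rows: list[dict] = []
    popdb_rows: list[dict] = []
    hotspot_rows: list[dict] = []

    def add_record(key, presence, ann, klass):
        records.append(PanelRecord(key, tuple(bool(x) for x in presence), ann))
        truth_rows.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "gene": ann.gene_symbol,
                "class": klass,
                "n_lines": int(sum(presence)),
            }
        )

    # germline: nonzero population frequency, HWE carrier probability
    for _ in range(config.germline.count):
        chrom, pos, ref, alt = new_site()
        freq = float(
            np.clip(rng.beta(config.germline.beta_a, config.germline.beta_b), 1e-4, 0.99)
        )
        carrier = 1.0 - (1.0 - freq) ** 2
        presence = _presence_with_min_one(rng, n, carrier)
        effect = _draw_effect(rng)
        ann = Annotation(
            gene_pool[int(rng.integers(len(gene_pool)))], effect, _protein_change(rng, effect)
        )
        key = VariantKey(chrom, pos, ref, alt)
        add_record(key, presence, ann, "germline")
        popdb_rows.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "allele_frequency": freq}
        )

    # recurrent artifacts: DB frequency 0, forced above the recurrence cutoff
    for _ in range(config.artifact.count):
        chrom, pos, ref, alt = new_site()
        k = int(rng.integers(config.artifact.min_lines, config.artifact.max_lines + 1))
        presence = np.zeros(n, dtype=bool)
        presence[rng.choice(n, size=k, replace=False)] = True
        effect = _draw_effect(rng)
        ann = Annotation(
            gene_pool[int(rng.integers(len(gene_pool)))], effect, _protein_change(rng, effect)
        )
        add_record(VariantKey(chrom, pos, ref, alt), presence, ann, "artifact")

    # private somatics: exactly one line each
    for line_idx in range(n):
        for _ in range(config.somatic_private.per_line):
            chrom, pos, ref, alt = new_site()
            presence = np.zeros(n, dtype=bool)
            presence[line_idx] = True
            effect = _draw_effect(rng)
            ann = Annotation(
                gene_pool[int(rng.integers(len(gene_pool)))],
                effect,
                _protein_change(rng, effect),
                float(rng.normal(-2.0, 2.0)),
            )
            add_record(VariantKey(chrom, pos, ref, alt), presence, ann, "somatic_private")

    # hotspot somatics: catalogued, planted in an arbitrary number of lines
    for h in range(config.somatic_hotspot.count):
        chrom, pos, ref, alt = new_site()
        k = int(
            rng.integers(config.somatic_hotspot.min_lines, config.somatic_hotspot.max_lines + 1)
        )
        presence = np.zeros(n, dtype=bool)
        presence[rng.choice(n, size=k, replace=False)] = True
        gene = gene_pool[int(rng.integers(len(gene_pool)))]
        pchange = _protein_change(rng, EffectClass.MISSENSE)
        ann = Annotation(gene, EffectClass.MISSENSE, pchange, float(rng.normal(-4.0, 1.0)))
        add_record(VariantKey(chrom, pos, ref, alt), presence, ann, "somatic_hotspot")
        protein_only = rng.random() < config.somatic_hotspot.protein_only_fraction
        if protein_only:
            hotspot_rows.append(
                {"chrom": "", "pos": "", "ref": "", "alt": "", "gene": gene,
                 "protein_change": pchange}
            )
        else:
            hotspot_rows.append(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
                 "protein_change": pchange}
            )

    # decoy database rows at sites absent from the panel
    for _ in range(10):
        chrom, pos, ref, alt = new_site()
        popdb_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "allele_frequency": float(np.clip(rng.beta(0.5, 8.0), 1e-4, 0.99)),
            }
        )

    table = PanelVariantTable(tuple(config.line_names), records)
    popdb = pd.DataFrame(popdb_rows)
    hotspots = pd.DataFrame(hotspot_rows)
    truth = pd.DataFrame(truth_rows)
    return table, popdb, hotspots, truth


def random_filter_inputs(
    seed: int, n_variants: int = 200, n_lines: int = 22
) -> tuple[PanelVariantTable, "PopulationDB", "HotspotCatalog"]:
    """Adversarial random panel for filter stress tests.

    Population-database membership (including frequency-zero rows, which
    must not reject), catalog membership (genomic key or protein index)
    and presence patterns are all drawn independently, so every corner of
    the kept-set algebra V \\ ((P u R) \\ C) is exercised.
    """
    from .somatic_filter import HotspotCatalog, PopulationDB

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    lines = tuple(f"L{i + 1:02d}" for i in range(n_lines))
    db = PopulationDB()
    catalog = HotspotCatalog()
    records = []
    for i in range(n_variants):
        chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
        ref, alt = rng.choice(bases, size=2, replace=False)
        key = VariantKey(chrom, 1_000 + i * 10, str(ref), str(alt))
        prob = rng.beta(0.5, 3.0)
        presence = tuple(bool(b) for b in rng.random(n_lines) < prob)
        effect = _draw_effect(rng)
        ann = Annotation(f"G{i % 40:03d}", effect, _protein_change(rng, effect))
        records.append(PanelRecord(key, presence, ann))
        u = rng.random()
        if u < 0.35:
            db.add(key, float(rng.uniform(0.0005, 0.2)))
        elif u < 0.45:
            db.add(key, 0.0)  # present in the DB at frequency zero
        v = rng.random()
        if v < 0.15:
            catalog.add_key(key)
        elif v < 0.25 and ann.protein_change is not None:
            catalog.add_protein(ann.gene_symbol, ann.protein_change)
    return PanelVariantTable(lines, records), db, catalog


# ---------------------------------------------------------------------------
# depths


def simulate_depths(config: SimConfig) -> tuple[DepthMatrix, pd.DataFrame]:
    """Depth matrix with planted per-gene copy-number states.

    Truth is long-form (gene, line, copy_number) covering every cell.
    """
    rng = _rng(config, 2)
    c = config.cnv
    genes = config.gene_names(c.n_genes)
    lines = config.line_names
    n_genes, n_lines = len(genes), len(lines)

    states, weights = zip(*c.state_weights)
    gene_state = np.array(states)[rng.choice(len(states), size=n_genes, p=np.array(weights))]

    copy = np.full((n_genes, n_lines), 2, dtype=np.int64)
    for gi in range(n_genes):
        if gene_state[gi] == 2:
            continue
        k = int(rng.integers(1, c.max_aberrant_lines + 1))
        cols = rng.choice(n_lines, size=k, replace=False)
        copy[gi, cols] = gene_state[gi]

    noise = _lognormal_noise(rng, c.noise_cv, (n_genes, n_lines))
    multipliers = rng.uniform(c.multiplier_low, c.multiplier_high, size=n_lines)
    depth = c.base_depth * (copy / 2.0)
    depth[copy == 0] = c.base_depth * c.background_fraction
    depth = depth * noise * multipliers[None, :]

    matrix = DepthMatrix(pd.DataFrame(depth, index=genes, columns=lines))
    truth = (
        pd.DataFrame(copy, index=pd.Index(genes, name="gene"), columns=lines)
        .stack()
        .rename("copy_number")
        .rename_axis(["gene", "line"])
        .reset_index()
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# counts


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix with planted differential expression.

    Truth is per-gene (status in {up, down, ns}, true log2 fold change of
    group2 over group1).
    """
    rng = _rng(config, 3)
    d = config.de
    genes = config.gene_names(d.n_genes)
    if d.n_up + d.n_down > d.n_genes:
        raise ValueError("planted up + down genes exceed n_genes")

    n2 = d.n_group2 if d.n_group2 is not None else config.n_lines
    samples1 = [f"NOK_{i + 1}" for i in range(d.n_group1)]
    samples2 = (
        config.line_names if d.n_group2 is None else [f"TUM_{i + 1}" for i in range(n2)]
    )
    samples = samples1 + samples2
    groups = pd.Series(
        [d.group1] * len(samples1) + [d.group2] * len(samples2), index=samples, name="group"
    )

    baseline = rng.lognormal(d.logmean_mean, d.logmean_sd, size=d.n_genes)
    status = np.array(["ns"] * d.n_genes, dtype=object)
    planted = rng.choice(d.n_genes, size=d.n_up + d.n_down, replace=False)
    status[planted[: d.n_up]] = "up"
    status[planted[d.n_up:]] = "down"
    log2fc = np.zeros(d.n_genes)
    log2fc[status == "up"] = d.log2fc
    log2fc[status == "down"] = -d.log2fc

    depth_factor = rng.uniform(d.depth_factor_low, d.depth_factor_high, size=len(samples))
    mu = np.empty((d.n_genes, len(samples)))
    mu[:, : len(samples1)] = baseline[:, None]
    mu[:, len(samples1):] = (baseline * 2.0 ** log2fc)[:, None]
    mu *= depth_factor[None, :]

    if d.phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / d.phi
        counts = rng.negative_binomial(r, r / (r + mu))

    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), groups)
    truth = pd.DataFrame(
        {"gene": genes, "status": status, "true_log2_fold_change": log2fc}
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# gene sets


def simulate_gene_sets(
    config: SimConfig, de_truth: pd.DataFrame
) -> tuple[GeneSetLibrary, pd.DataFrame]:
    """GMT library over the count-matrix gene universe.

    ``PLANTED_UP`` / ``PLANTED_DOWN`` terms draw ``planted_overlap`` of
    the true up/down lists; the remaining terms are uniform draws.
    """
    rng = _rng(config, 4)
    e = config.enrichment
    universe = list(de_truth["gene"])
    terms: dict[str, frozenset] = {}
    truth_rows = []

    for name, direction in (("PLANTED_UP", "up"), ("PLANTED_DOWN", "down")):
        source = list(de_truth.loc[de_truth["status"] == direction, "gene"])
        n_overlap = int(round(e.planted_overlap * len(source)))
        chosen = list(rng.choice(source, size=n_overlap, replace=False))
        others = [g for g in universe if g not in set(source)]
        n_fill = max(e.term_size - n_overlap, 0)
        fill = list(rng.choice(others, size=n_fill, replace=False))
        terms[name] = frozenset(chosen + fill)
        truth_rows.append(
            {"term": name, "planted": True, "direction": direction, "overlap": n_overlap}
        )

    for t in range(e.n_terms):
        name = f"T{t + 1:03d}"
        terms[name] = frozenset(rng.choice(universe, size=e.term_size, replace=False))
        truth_rows.append({"term": name, "planted": False, "direction": "", "overlap": 0})

    library = GeneSetLibrary(terms, frozenset(universe))
    return library, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bundle


def simulate_all(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the full input bundle plus truth tables; returns file paths."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)

    table, popdb, hotspots, variant_truth = simulate_panel(config)
    depths, cnv_truth = simulate_depths(config)
    counts, de_truth = simulate_counts(config)
    library, set_truth = simulate_gene_sets(config, de_truth)

    paths = {
        "vcf": out / "panel.vcf",
        "popdb": out / "popdb.tsv",
        "hotspots": out / "hotspots.tsv",
        "depths": out / "depths.tsv",
        "counts": out / "counts.tsv",
        "groups": out / "groups.tsv",
        "gmt": out / "sets.gmt",
        "truth_variants": out / "truth" / "variants.tsv",
        "truth_cnv": out / "truth" / "cnv.tsv",
        "truth_de": out / "truth" / "de.tsv",
        "truth_sets": out / "truth" / "sets.tsv",
    }
    write_filtered_vcf(table, paths["vcf"])
    popdb.to_csv(paths["popdb"], sep="\t", index=False)
    hotspots.to_csv(paths["hotspots"], sep="\t", index=False)
    depths.depths.to_csv(paths["depths"], sep="\t")
    counts.counts.to_csv(paths["counts"], sep="\t")
    counts.groups.rename_axis("sample").reset_index().to_csv(
        paths["groups"], sep="\t", index=False
    )
    write_gene_sets({t: sorted(g) for t, g in sorted(library.terms.items())}, paths["gmt"])
    variant_truth.to_csv(paths["truth_variants"], sep="\t", index=False)
    cnv_truth.to_csv(paths["truth_cnv"], sep="\t", index=False)
    de_truth.to_csv(paths["truth_de"], sep="\t", index=False)
    set_truth.to_csv(paths["truth_sets"], sep="\t", index=False)
    return paths
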