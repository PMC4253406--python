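"""Tumor-only somatic-mutation approximation for cell-line panels.

Established cancer cell lines have no matched normal DNA, so germline
variants cannot be subtracted directly.  This module approximates somatic
calls with two rejection rules, each overridden by a hotspot rescue:

1. population-database rejection — any variant with nonzero allele
   frequency in a population database (ESP6500-like) is treated as
   germline and rejected;
2. panel-recurrence rejection — any variant present in more than a fixed
   fraction of the panel's lines (default 15%; for a 22-line panel this
   means >3 lines, i.e. rejection from 4 lines up) is treated as an
   uncatalogued SNP or pipeline artifact and rejected;

unless the allele is present in a somatic hotspot catalog (COSMIC-like),
in which case it is rescued and kept regardless of either rule.

It also summarizes per-gene mutation frequencies (fraction of lines
carrying at least one protein-altering variant in the gene).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "VariantKey",
    "EffectClass",
    "Annotation",
    "PanelVariantTable",
    "PanelRecord",
    "PopulationDB",
    "HotspotCatalog",
    "FilterConfig",
    "FilterDecision",
    "FilterStatus",
    "RejectReason",
    "InvalidVariantError",
    "normalize_variant",
    "classify_variant",
    "apply_filter",
    "gene_mutation_frequency",
    "PROTEIN_ALTERING",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_PCHANGE_RE = re.compile(r"[A-Z*]\d+[A-Za-z*]+|.+fs")


class InvalidVariantError(ValueError):
    """Raised for malformed variant representations."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic identity of a (site, alt allele) pair.

    Coordinates are 1-based inclusive as in VCF; alleles are uppercase
    A/C/G/T strings in minimal (flank-trimmed) representation.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> None:
        if self.pos < 1:
            raise InvalidVariantError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not _ALLELE_RE.match(allele):
                raise InvalidVariantError(f"allele {allele!r} is not a nonempty ACGT string")
        if self.ref == self.alt:
            raise InvalidVariantError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # used in reports and error messages
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class EffectClass(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    OTHER = "other"


#: effect classes counted as protein-altering in gene frequencies
PROTEIN_ALTERING = frozenset(
    {
        EffectClass.MISSENSE,
        EffectClass.NONSENSE,
        EffectClass.FRAMESHIFT,
        EffectClass.SPLICE,
        EffectClass.OTHER,
    }
)


@dataclass(frozen=True)
class Annotation:
    """Functional annotation attached to a variant (consumed, not computed).

    ``deleteriousness_score`` is a PROVEAN-like score: more negative means
    more deleterious.
    """

    gene_symbol: str
    effect_class: EffectClass
    protein_change: Optional[str] = None
    deleteriousness_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.effect_class, EffectClass):
            object.__setattr__(self, "effect_class", EffectClass(self.effect_class))
        if self.protein_change is not None and not _PCHANGE_RE.match(self.protein_change):
            raise ValueError(f"malformed protein change {self.protein_change!r}")


@dataclass(frozen=True)
class PanelRecord:
    key: VariantKey
    presence: tuple[bool, ...]
    annotation: Annotation

    @property
    def presence_count(self) -> int:
        return sum(self.presence)


@dataclass
class PanelVariantTable:
    """Normalized variant identities with per-line presence flags."""

    lines: tuple[str, ...]
    records: list[PanelRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lines = tuple(self.lines)
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("line identifiers must be unique")
        seen: set[VariantKey] = set()
        for rec in self.records:
            if len(rec.presence) != len(self.lines):
                raise ValueError(
                    f"presence vector of {rec.key} has length {len(rec.presence)}, "
                    f"expected {len(self.lines)}"
                )
            if rec.key in seen:
                raise ValueError(f"duplicate variant {rec.key}")
            seen.add(rec.key)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, keys: Iterable[VariantKey]) -> "PanelVariantTable":
        wanted = set(keys)
        return PanelVariantTable(
            self.lines, [r for r in self.records if r.key in wanted]
        )


class PopulationDB:
    """Population allele frequencies keyed by normalized variant identity.

    Lookup of an absent key returns 0; duplicate keys collapse to the
    maximum frequency seen.
    """

    def __init__(self, frequencies: Mapping[VariantKey, float] | None = None):
        self._freq: dict[VariantKey, float] = {}
        if frequencies:
            for key, f in frequencies.items():
                self.add(key, f)

    def add(self, key: VariantKey, frequency: float) -> None:
        if not 0.0 <= frequency <= 1.0:
            raise ValueError(f"allele frequency {frequency} for {key} outside [0, 1]")
        norm = normalize_variant(key)
        self._freq[norm] = max(self._freq.get(norm, 0.0), frequency)

    def frequency(self, key: VariantKey) -> float:
        return self._freq.get(normalize_variant(key), 0.0)

    def __len__(self) -> int:
        return len(self._freq)

    def __contains__(self, key: VariantKey) -> bool:
        return self.frequency(key) > 0.0


class HotspotCatalog:
    """Somatic hotspot membership, by genomic key with an optional
    (gene, protein_change) secondary index."""

    def __init__(
        self,
        keys: Iterable[VariantKey] = (),
        protein_index: Iterable[tuple[str, str]] = (),
    ):
        self._keys = {normalize_variant(k) for k in keys}
        self._protein = {(g, p) for g, p in protein_index}

    def add_key(self, key: VariantKey) -> None:
        self._keys.add(normalize_variant(key))

    def add_protein(self, gene: str, protein_change: str) -> None:
        self._protein.add((gene, protein_change))

    def contains(self, key: VariantKey, annotation: Annotation | None = None) -> bool:
        """Genomic-key match first, then (gene, protein_change) fallback."""
        if normalize_variant(key) in self._keys:
            return True
        if annotation is not None and annotation.protein_change is not None:
            return (annotation.gene_symbol, annotation.protein_change) in self._protein
        return False

    def __len__(self) -> int:
        return len(self._keys) + len(self._protein)


@dataclass(frozen=True)
class FilterConfig:
    """Knobs of the somatic approximation filter.

    ``recurrence_fraction`` is the panel fraction above which a variant is
    rejected as recurrent; the default 0.15 reproduces the ">3 cell lines"
    rule on a 22-line panel (0.15 * 22 = 3.3, so rejection fires at 4).
    """

    recurrence_fraction: float = 0.15
    rescue_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.recurrence_fraction < 1.0:
            raise ValueError(
                f"recurrence_fraction must lie in (0, 1), got {self.recurrence_fraction}"
            )


class FilterStatus(str, enum.Enum):
    KEPT = "kept"
    REJECTED = "rejected"


class RejectReason(str, enum.Enum):
    NONE = "none"
    POPULATION_DB = "population_db"
    RECURRENT_PANEL = "recurrent_panel"


@dataclass(frozen=True)
class FilterDecision:
    key: VariantKey
    status: FilterStatus
    reason: RejectReason
    rescued: bool
    presence_count: int

    def __post_init__(self) -> None:
        if self.status is FilterStatus.REJECTED and self.reason is RejectReason.NONE:
            raise ValueError("rejected decision must carry a reason")
        if self.rescued and self.status is not FilterStatus.KEPT:
            raise ValueError("a rescued variant is kept by definition")


# ---------------------------------------------------------------------------
# variant normalization


def normalize_variant(key: VariantKey) -> VariantKey:
    """Trim shared flanking bases to the minimal left-aligned representation.

    The shared suffix is trimmed first, then the shared prefix (each
    keeping at least one base); the position advances by the number of
    prefix bases removed.  Idempotent.  No reference sequence is
    consulted, so repeat-mediated left shifts are out of scope.
    """
    key.validate()
    ref, alt, pos = key.ref, key.alt, key.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise InvalidVariantError(f"{key} trims to ref == alt")
    if ref == key.ref and alt == key.alt:
        return key
    return VariantKey(key.chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# the filter itself


def classify_variant(
    key: VariantKey,
    annotation: Annotation,
    presence_count: int,
    n_lines: int,
    db: PopulationDB,
    catalog: HotspotCatalog,
    config: FilterConfig = FilterConfig(),
) -> FilterDecision:
    """Apply both rejection rules and the hotspot rescue to one variant.

    A variant is rejected if its population allele frequency is nonzero,
    or if it is present in strictly more than ``recurrence_fraction`` of
    the panel's lines.  Either rejection is overridden when the catalog
    contains the variant.  When both rules fire the recorded reason is
    ``population_db`` (the rules apply in that order).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not 0 <= presence_count <= n_lines:
        raise ValueError(
            f"presence_count {presence_count} outside [0, {n_lines}] for {key}"
        )
    in_db = db.frequency(key) != 0.0
    recurrent = presence_count / n_lines > config.recurrence_fraction
    if not (in_db or recurrent):
        return FilterDecision(key, FilterStatus.KEPT, RejectReason.NONE, False, presence_count)
    if config.rescue_enabled and catalog.contains(key, annotation):
        return FilterDecision(key, FilterStatus.KEPT, RejectReason.NONE, True, presence_count)
    reason = RejectReason.POPULATION_DB if in_db else RejectReason.RECURRENT_PANEL
    return FilterDecision(key, FilterStatus.REJECTED, reason, False, presence_count)


def apply_filter(
    table: PanelVariantTable,
    db: PopulationDB,
    catalog: HotspotCatalog,
    config: FilterConfig = FilterConfig(),
) -> tuple[PanelVariantTable, list[FilterDecision]]:
    """Classify every record; return the kept table and the decision list.

    The kept set equals V \\ ((P ∪ R) \\ C) where P are population-DB
    hits, R recurrent hits and C catalog hits; the result is independent
    of record order.
    """
    decisions: list[FilterDecision] = []
    kept: list[PanelRecord] = []
    for rec in table.records:
        try:
            dec = classify_variant(
                rec.key,
                rec.annotation,
                rec.presence_count,
                table.n_lines,
                db,
                catalog,
                config,
            )
        except ValueError as exc:
            raise ValueError(f"while classifying {rec.key}: {exc}") from exc
        decisions.append(dec)
        if dec.status is FilterStatus.KEPT:
            kept.append(rec)
    return PanelVariantTable(table.lines, kept), decisions


def rejection_counts(decisions: Sequence[FilterDecision]) -> dict[str, int]:
    """Summary counts by outcome, for reports."""
    out = {
        "kept": 0,
        "rescued": 0,
        RejectReason.POPULATION_DB.value: 0,
        RejectReason.RECURRENT_PANEL.value: 0,
    }
    for dec in decisions:
        if dec.status is FilterStatus.KEPT:
            out["kept"] += 1
            if dec.rescued:
                out["rescued"] += 1
        else:
            out[dec.reason.value] += 1
    return out


def gene_mutation_frequency(
    filtered: PanelVariantTable,
    effect_filter: frozenset[EffectClass] | set[EffectClass] = PROTEIN_ALTERING,
) -> list[tuple[str, int, float]]:
    """Per-gene (n_lines_mutated, fraction of panel) on a filtered table.

    A line counts once per gene no matter how many qualifying variants it
    carries.  Ordered by descending fraction, then gene symbol.
    """
    for eff in effect_filter:
        if not isinstance(eff, EffectClass):
            raise ValueError(f"unknown effect class {eff!r}")
    lines_by_gene: dict[str, set[int]] = {}
    for rec in filtered.records:
        if rec.annotation.effect_class not in effect_filter:
            continue
        carriers = lines_by_gene.setdefault(rec.annotation.gene_symbol, set())
        carriers.update(i for i, flag in enumerate(rec.presence) if flag)
    n = filtered.n_lines
    rows = [(gene, len(ls), len(ls) / n) for gene, ls in lines_by_gene.items()]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return rows
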