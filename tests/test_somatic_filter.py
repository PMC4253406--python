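"""The somatic approximation filter: normalization, the two rejection
rules, hotspot rescue, set-algebra equivalence and gene frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncopanel.simulate import random_filter_inputs
from oncopanel.somatic_filter import (
    Annotation,
    EffectClass,
    FilterConfig,
    FilterStatus,
    HotspotCatalog,
    InvalidVariantError,
    PanelRecord,
    PanelVariantTable,
    PopulationDB,
    RejectReason,
    VariantKey,
    apply_filter,
    classify_variant,
    gene_mutation_frequency,
    normalize_variant,
)

ANN = Annotation("GENE1", EffectClass.MISSENSE, "A100T")
EMPTY_DB = PopulationDB()
EMPTY_CATALOG = HotspotCatalog()


def brute_force_minimal(key: VariantKey) -> VariantKey:
    """Enumerate every flank trim keeping >= 1 base; minimal total allele
    length wins, ties broken by the left-most (smallest) position."""
    candidates = []
    ref, alt = key.ref, key.alt
    max_trim = min(len(ref), len(alt)) - 1
    for i in range(max_trim + 1):  # prefix
        if ref[:i] != alt[:i]:
            continue
        for j in range(max_trim - i + 1):  # suffix
            r = ref[i:len(ref) - j] if j else ref[i:]
            a = alt[i:len(alt) - j] if j else alt[i:]
            if j and (key.ref[len(ref) - j:] != key.alt[len(alt) - j:]):
                continue
            if r and a and r != a:
                candidates.append(VariantKey(key.chrom, key.pos + i, r, a))
    return min(candidates, key=lambda c: (len(c.ref) + len(c.alt), c.pos))


class TestNormalize:
    def test_shared_prefix_trimming(self):
        key = normalize_variant(VariantKey("chr1", 1000, "AT", "AC"))
        assert key == VariantKey("chr1", 1001, "T", "C")

    def test_snv_identity(self):
        key = VariantKey("chr2", 5, "G", "A")
        assert normalize_variant(key) is key

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(InvalidVariantError):
            normalize_variant(VariantKey("chr1", 1, "A", "A"))

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=4),
        st.text(alphabet="ACGT", min_size=1, max_size=4),
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_bruteforce_minimal_search_and_idempotent(self, ref, alt):
        if ref == alt:
            return
        key = VariantKey("chr1", 500, ref, alt)
        normalized = normalize_variant(key)
        assert normalized == brute_force_minimal(key)
        assert normalize_variant(normalized) == normalized


class TestClassify:
    def test_population_db_rejection(self):
        db = PopulationDB({VariantKey("chr1", 10, "A", "T"): 0.004})
        dec = classify_variant(
            VariantKey("chr1", 10, "A", "T"), ANN, 1, 22, db, EMPTY_CATALOG
        )
        assert dec.status is FilterStatus.REJECTED
        assert dec.reason is RejectReason.POPULATION_DB

    def test_recurrent_panel_rejection(self):
        dec = classify_variant(
            VariantKey("chr1", 10, "A", "T"), ANN, 4, 22, EMPTY_DB, EMPTY_CATALOG
        )
        assert dec.status is FilterStatus.REJECTED
        assert dec.reason is RejectReason.RECURRENT_PANEL

    def test_catalog_rescue_overrides_population_db(self):
        key = VariantKey("chr1", 10, "A", "T")
        db = PopulationDB({key: 0.02})
        catalog = HotspotCatalog(keys=[key])
        dec = classify_variant(key, ANN, 1, 22, db, catalog)
        assert dec.status is FilterStatus.KEPT
        assert dec.rescued

    def test_rescue_disabled_by_config(self):
        key = VariantKey("chr1", 10, "A", "T")
        db = PopulationDB({key: 0.02})
        catalog = HotspotCatalog(keys=[key])
        dec = classify_variant(key, ANN, 1, 22, db, catalog, FilterConfig(rescue_enabled=False))
        assert dec.status is FilterStatus.REJECTED

    def test_three_line_boundary_keeps(self):
        dec = classify_variant(
            VariantKey("chr1", 10, "A", "T"), ANN, 3, 22, EMPTY_DB, EMPTY_CATALOG
        )
        assert dec.status is FilterStatus.KEPT
        assert dec.reason is RejectReason.NONE and not dec.rescued

    def test_both_rules_record_population_db_first(self):
        key = VariantKey("chr1", 10, "A", "T")
        db = PopulationDB({key: 0.3})
        dec = classify_variant(key, ANN, 10, 22, db, EMPTY_CATALOG)
        assert dec.reason is RejectReason.POPULATION_DB

    def test_zero_db_frequency_does_not_reject(self):
        key = VariantKey("chr1", 10, "A", "T")
        db = PopulationDB({key: 0.0})
        dec = classify_variant(key, ANN, 1, 22, db, EMPTY_CATALOG)
        assert dec.status is FilterStatus.KEPT

    def test_invalid_presence_count(self):
        with pytest.raises(ValueError):
            classify_variant(
                VariantKey("chr1", 10, "A", "T"), ANN, 23, 22, EMPTY_DB, EMPTY_CATALOG
            )


def brute_force_kept(table, db, catalog, fraction):
    """Direct evaluation of V \\ ((P u R) \\ C)."""
    V = {r.key for r in table.records}
    P = {r.key for r in table.records if db.frequency(r.key) != 0}
    R = {r.key for r in table.records if r.presence_count / table.n_lines > fraction}
    C = {r.key for r in table.records if catalog.contains(r.key, r.annotation)}
    return V - ((P | R) - C)


class TestApplyFilter:
    def test_empty_table(self):
        table = PanelVariantTable(("L1", "L2"), [])
        filtered, decisions = apply_filter(table, EMPTY_DB, EMPTY_CATALOG)
        assert len(filtered) == 0 and decisions == []

    def test_rescue_dominates_when_everything_catalogued(self):
        table, db, _ = random_filter_inputs(seed=3, n_variants=40)
        catalog = HotspotCatalog(keys=[r.key for r in table.records])
        filtered, _ = apply_filter(table, db, catalog)
        assert len(filtered) == len(table)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kept_set_equals_bruteforce_set_expression(self, seed):
        table, db, catalog = random_filter_inputs(seed, n_variants=50)
        config = FilterConfig()
        filtered, decisions = apply_filter(table, db, catalog, config)
        assert {r.key for r in filtered.records} == brute_force_kept(
            table, db, catalog, config.recurrence_fraction
        )
        assert len(decisions) == len(table)

    def test_order_invariance(self):
        table, db, catalog = random_filter_inputs(seed=9, n_variants=60)
        reversed_table = PanelVariantTable(table.lines, list(reversed(table.records)))
        kept1, _ = apply_filter(table, db, catalog)
        kept2, _ = apply_filter(reversed_table, db, catalog)
        assert {r.key for r in kept1.records} == {r.key for r in kept2.records}

    def test_catalog_monotonicity_never_shrinks_kept(self):
        table, db, catalog = random_filter_inputs(seed=5, n_variants=80)
        kept_small, _ = apply_filter(table, db, catalog)
        bigger = HotspotCatalog(keys=[r.key for r in table.records[:40]])
        for rec in table.records:
            if catalog.contains(rec.key, rec.annotation):
                bigger.add_key(rec.key)
        kept_big, _ = apply_filter(table, db, bigger)
        assert {r.key for r in kept_small.records} <= {r.key for r in kept_big.records}

    def test_db_monotonicity_never_grows_kept(self):
        table, db, catalog = random_filter_inputs(seed=6, n_variants=80)
        kept_before, _ = apply_filter(table, db, catalog)
        bigger_db = PopulationDB({r.key: db.frequency(r.key) for r in table.records})
        for rec in table.records[:40]:
            bigger_db.add(rec.key, 0.01)
        kept_after, _ = apply_filter(table, bigger_db, catalog)
        assert {r.key for r in kept_after.records} <= {r.key for r in kept_before.records}


def _table(lines, rows):
    """rows: (gene, effect, presence tuple)"""
    records = [
        PanelRecord(
            VariantKey("chr1", 100 + i, "A", "T"),
            presence,
            Annotation(gene, effect),
        )
        for i, (gene, effect, presence) in enumerate(rows)
    ]
    return PanelVariantTable(lines, records)


class TestGeneFrequency:
    def test_line_counts_once_per_gene(self):
        lines = tuple(f"L{i}" for i in range(4))
        table = _table(
            lines,
            [
                ("G1", EffectClass.MISSENSE, (True, True, False, False)),
                ("G1", EffectClass.NONSENSE, (True, False, False, False)),
                ("G2", EffectClass.SYNONYMOUS, (True, True, True, True)),
            ],
        )
        rows = gene_mutation_frequency(table)
        assert rows == [("G1", 2, 0.5)]  # synonymous-only G2 excluded

    def test_fifteen_of_twentytwo_is_682(self):
        lines = tuple(f"L{i}" for i in range(22))
        presence = tuple(i < 15 for i in range(22))
        table = _table(lines, [("TP53", EffectClass.MISSENSE, presence)])
        ((gene, n, frac),) = gene_mutation_frequency(table)
        assert (gene, n) == ("TP53", 15)
        assert round(100 * frac, 1) == 68.2

    def test_matches_bruteforce_per_line_counting(self, small_sim_config):
        from oncopanel.simulate import simulate_panel

        table, _, _, _ = simulate_panel(small_sim_config)
        rows = {g: (n, f) for g, n, f in gene_mutation_frequency(table)}
        expected = {}
        for li in range(table.n_lines):
            for rec in table.records:
                if rec.presence[li] and rec.annotation.effect_class is not EffectClass.SYNONYMOUS:
                    expected.setdefault(rec.annotation.gene_symbol, set()).add(li)
        assert rows == {g: (len(s), len(s) / table.n_lines) for g, s in expected.items()}

    def test_unknown_effect_class_rejected(self):
        table = _table(("L1",), [("G1", EffectClass.MISSENSE, (True,))])
        with pytest.raises(ValueError):
            gene_mutation_frequency(table, {"bogus"})
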