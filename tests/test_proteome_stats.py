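"""Aggregation, protein classification, timelines, gene sets, variants, Fisher."""

from __future__ import annotations

import math

import numpy as np
import pytest

from structcover.coverage_core import CategoryTrack, CoverageCategory
from structcover.io_formats import AlignmentHit, GeneSet, ProteinRecord, VariantRecord
from structcover.proteome_stats import (
    ProteinSummary,
    aggregate,
    classify_proteins,
    coverage_timeline,
    fisher_enrichment,
    fisher_test,
    gene_set_coverage,
    variant_coverage,
)

C = CoverageCategory


def _summary(pid="P1", gid=None, length=100, dark=1.0, exp=0.0, **flags):
    fractions = {c: 0.0 for c in C}
    fractions[C.DARK] = dark
    fractions[C.PDB_EXP] = exp
    defaults = dict(
        has_pdb=exp > 0, has_any_structure=exp > 0, hq_fraction=exp,
        af_high_fraction=0.0, plddt_high_fraction=0.0,
        af_only_covered_fraction=0.0, covered_fraction=exp,
    )
    defaults.update(flags)
    return ProteinSummary(pid, gid or pid, length, fractions, **defaults)


class TestAggregate:
    def test_residue_weighted_mean(self):
        s1 = _summary("P1", length=100, dark=1.0)
        s2 = _summary("P2", length=300, dark=0.0, exp=1.0)
        agg = aggregate([s1, s2])
        assert agg.fractions[C.DARK] == pytest.approx(0.25)
        assert agg.fractions[C.PDB_EXP] == pytest.approx(0.75)
        assert agg.total_residues == 400

    def test_single_protein_identity(self):
        s = _summary("P1", length=123, dark=0.4, exp=0.6)
        agg = aggregate([s])
        assert agg.fractions == s.fractions

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_matches_generator_bookkeeping(self, resolved_pipeline):
        _, _, summaries, truth = resolved_pipeline
        agg = aggregate(summaries)
        for c in C:
            assert agg.fractions[c] == truth.planted_aggregate[c]


class TestClassifyProteins:
    def test_structureless_contrast(self):
        # a protein with no template but a confident model counts as
        # structureless only before predictions are considered
        s = _summary("P1", has_pdb=False, has_any_structure=True,
                     covered_fraction=0.0, hq_fraction=0.0)
        counts = classify_proteins([s])
        assert counts["structureless_pre_af"] == 1
        assert counts["structureless_post_af"] == 0

    def test_fully_experimental_protein(self):
        s = _summary("P1", dark=0.0, exp=1.0)
        counts = classify_proteins([s])
        assert counts["near_complete"] == 1
        assert counts["af_majority_contributor"] == 0
        assert counts["covered_fraction_deciles"][9] == 1

    def test_unknown_rule_name_raises(self):
        with pytest.raises(ValueError, match="unknown rule"):
            classify_proteins([_summary()], rules=["no_such_rule"])

    def test_counts_match_plan_on_planted_cohort(self, resolved_pipeline):
        _, _, summaries, truth = resolved_pipeline
        counts = classify_proteins(summaries)
        # recompute the bins straight from the planted tracks
        expected_post = sum(
            1 for track in truth.planted.values()
            if set(track.codes) <= {C.IDR.value, C.DOMAIN_ONLY.value, C.DARK.value}
        )
        assert counts["structureless_post_af"] == expected_post
        assert counts["total_proteins"] == len(summaries)
        assert sum(counts["covered_fraction_deciles"]) == len(summaries)


def _dated_hit(qid, qstart, qend, pident, year):
    return AlignmentHit(qid, "S", pident, 1e-20, qstart, qend, year)


class TestTimeline:
    def test_future_hits_do_not_count(self):
        proteins = [ProteinRecord("P1", "G1", 100)]
        hits = {"P1": [_dated_hit("P1", 1, 100, 90.0, 2020)]}
        (point,) = coverage_timeline(hits, proteins, [20.0], [1995])
        assert point.fractions[20.0] == 0.0

    def test_monotone_in_year_and_threshold(self):
        rng = np.random.default_rng(23)
        proteins = [ProteinRecord(f"P{i}", f"G{i}", 200) for i in range(20)]
        hits = {}
        for p in proteins:
            rows = []
            for _ in range(rng.integers(0, 15)):
                qstart = int(rng.integers(1, 200))
                qend = int(rng.integers(qstart, 201))
                rows.append(_dated_hit(
                    p.protein_id, qstart, qend,
                    float(rng.uniform(20, 100)), int(rng.integers(1990, 2022)),
                ))
            hits[p.protein_id] = rows
        years = [1995, 2000, 2010, 2020]
        grid = [20.0, 50.0, 95.0]
        points = coverage_timeline(hits, proteins, grid, years)
        for a, b in zip(points, points[1:]):  # non-decreasing in year
            for t in grid:
                assert b.fractions[t] >= a.fractions[t]
        for point in points:  # non-increasing in identity threshold
            assert point.fractions[20.0] >= point.fractions[50.0] >= point.fractions[95.0]

    def test_matches_per_year_brute_force(self):
        rng = np.random.default_rng(31)
        proteins = [ProteinRecord("P1", "G1", 150)]
        rows = [
            _dated_hit("P1", int(s := rng.integers(1, 150)),
                       int(rng.integers(s, 151)),
                       float(rng.uniform(20, 100)), int(rng.integers(1995, 2021)))
            for _ in range(30)
        ]
        points = coverage_timeline({"P1": rows}, proteins, [50.0], [2000, 2010])
        for point in points:
            covered = np.zeros(150, dtype=bool)
            for h in rows:
                if h.subject_year <= point.year and h.percent_identity >= 50.0:
                    covered[h.qstart - 1 : h.qend] = True
            assert point.fractions[50.0] == pytest.approx(covered.mean())


class TestGeneSetCoverage:
    def test_full_set_equals_global_aggregate(self):
        summaries = [
            _summary("P1", "G1", 100, dark=1.0),
            _summary("P2", "G2", 300, dark=0.0, exp=1.0),
        ]
        per_set, baseline, unknown = gene_set_coverage(
            summaries, [GeneSet("all", frozenset({"G1", "G2"}))]
        )
        assert per_set["all"].fractions == baseline.fractions
        assert unknown["all"] == []

    def test_singleton_set(self):
        summaries = [_summary("P1", "G1", 100, dark=0.3, exp=0.7),
                     _summary("P2", "G2", 100)]
        per_set, _, _ = gene_set_coverage(
            summaries, [GeneSet("one", frozenset({"G1"}))]
        )
        assert per_set["one"].fractions == summaries[0].fractions

    def test_partition_recombines_to_global(self):
        rng = np.random.default_rng(13)
        summaries = []
        for i in range(10):
            exp = float(rng.random())
            summaries.append(_summary(f"P{i}", f"G{i}", int(rng.integers(50, 500)),
                                      dark=1 - exp, exp=exp))
        sets = [GeneSet("A", frozenset(f"G{i}" for i in range(5))),
                GeneSet("B", frozenset(f"G{i}" for i in range(5, 10)))]
        per_set, baseline, _ = gene_set_coverage(summaries, sets)
        for c in C:
            combined = sum(
                per_set[s.name].fractions[c] * per_set[s.name].total_residues
                for s in sets
            ) / baseline.total_residues
            assert combined == pytest.approx(baseline.fractions[c], abs=1e-12)

    def test_unresolvable_set_raises_unknown_members_reported(self):
        summaries = [_summary("P1", "G1")]
        with pytest.raises(ValueError, match="no resolvable members"):
            gene_set_coverage(summaries, [GeneSet("ghost", frozenset({"GX"}))])
        _, _, unknown = gene_set_coverage(
            summaries, [GeneSet("mixed", frozenset({"G1", "GX"}))]
        )
        assert unknown["mixed"] == ["GX"]


class TestVariantCoverage:
    def test_all_on_experimental_residues(self):
        track = CategoryTrack("P1", np.full(600, C.PDB_EXP.value, dtype=np.int8))
        variants = [VariantRecord("P1", p, "pathogenic") for p in range(1, 11)]
        result = variant_coverage(variants, {"P1": track})
        assert result.fractions["pathogenic"][C.PDB_EXP] == 1.0
        assert result.rollups["pathogenic"]["experimental"] == 1.0

    def test_out_of_range_and_unknown_protein_are_rejected(self):
        track = CategoryTrack("P1", np.zeros(50, dtype=np.int8))
        variants = [
            VariantRecord("P1", 55, "benign"),
            VariantRecord("P9", 1, "benign"),
            VariantRecord("P1", 50, "benign"),
        ]
        result = variant_coverage(variants, {"P1": track})
        assert len(result.rejects) == 2
        assert sum(result.counts["benign"].values()) == 1

    def test_fractions_sum_to_one_per_class(self, resolved_pipeline):
        from structcover.io_formats import read_variants

        _, tracks_by, _, truth = resolved_pipeline
        variants = [VariantRecord(*row) for row in truth.variant_rows]
        result = variant_coverage(variants, tracks_by)
        for label, fractions in result.fractions.items():
            assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)


def _enumerated_p(a, b, c, d):
    """Exact two-sided Fisher p by integer enumeration over the margins."""
    n1, n2, m = a + b, c + d, a + c
    w_obs = math.comb(n1, a) * math.comb(n2, c)
    total = math.comb(n1 + n2, m)
    acc = sum(
        math.comb(n1, k) * math.comb(n2, m - k)
        for k in range(max(0, m - n2), min(n1, m) + 1)
        if math.comb(n1, k) * math.comb(n2, m - k) <= w_obs
    )
    return acc / total if total else 1.0


class TestFisher:
    def test_perfect_separation_table(self):
        # both extreme tables of the (10,10,10,10)-margin family are equally
        # probable, so p = 2 / C(20,10); the OR uses the Haldane correction
        odds, p = fisher_test(10, 0, 0, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
        assert odds == pytest.approx(441.0)

    def test_balanced_table_is_null(self):
        odds, p = fisher_test(5, 5, 5, 5)
        assert odds == 1.0
        assert p == 1.0

    def test_random_small_tables_match_enumeration(self):
        rng = np.random.default_rng(29)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, size=4))
            if a + b + c + d == 0:
                continue
            _, p = fisher_test(a, b, c, d)
            assert p == pytest.approx(_enumerated_p(a, b, c, d), abs=1e-10)

    def test_set_trait_symmetry(self):
        universe = [f"G{i}" for i in range(40)]
        gene_set = GeneSet("s", frozenset(universe[:15]))
        trait = universe[10:22]
        forward = fisher_enrichment(universe, gene_set, trait)
        swapped = fisher_enrichment(
            universe, GeneSet("t", frozenset(trait)), list(gene_set.member_gene_ids)
        )
        assert forward.p_value == pytest.approx(swapped.p_value, rel=1e-12)
        assert forward.odds_ratio == pytest.approx(swapped.odds_ratio, rel=1e-12)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], GeneSet("s", frozenset({"G1"})), ["G1"])
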