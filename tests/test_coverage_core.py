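"""Evidence projection, tier classification and category resolution."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structcover.coverage_core import (
    CoverageCategory,
    ResidueTracks,
    Thresholds,
    build_tracks,
    classify_identity,
    classify_plddt,
    project_hits,
    resolve_categories,
    summarize_protein,
)
from structcover.io_formats import AlignmentHit, DomainHit, ProteinRecord

C = CoverageCategory


def _hit(qstart, qend, pident, qid="P1"):
    return AlignmentHit(qid, "S", pident, 1e-20, qstart, qend)


def _brute_force_projection(hits, length):
    out = np.full(length, np.nan)
    for r in range(1, length + 1):
        best = np.nan
        for h in hits:
            if h.qstart <= r <= h.qend:
                best = h.percent_identity if np.isnan(best) else max(best, h.percent_identity)
        out[r - 1] = best
    return out


class TestProjectHits:
    def test_max_over_overlapping_hits(self):
        ident = project_hits([_hit(10, 50, 60.0), _hit(40, 80, 96.0)], 100)
        assert np.all(ident[9:39] == 60.0)
        assert np.all(ident[39:80] == 96.0)
        assert np.all(np.isnan(ident[:9])) and np.all(np.isnan(ident[80:]))

    def test_no_hits_all_absent(self):
        assert np.all(np.isnan(project_hits([], 25)))

    def test_matches_per_residue_brute_force(self):
        rng = np.random.default_rng(42)
        length = 500
        hits = []
        for _ in range(200):
            qstart = int(rng.integers(1, length + 1))
            qend = int(rng.integers(qstart, length + 1))
            hits.append(_hit(qstart, qend, float(rng.uniform(20, 100))))
        fast = project_hits(hits, length)
        slow = _brute_force_projection(hits, length)
        np.testing.assert_array_equal(np.isnan(fast), np.isnan(slow))
        np.testing.assert_allclose(fast[~np.isnan(fast)], slow[~np.isnan(slow)])

    def test_hit_beyond_length_is_an_error(self):
        with pytest.raises(ValueError, match="beyond protein length"):
            project_hits([_hit(10, 120, 50.0)], 100)


class TestTierClassification:
    @pytest.mark.parametrize(
        "identity,expected",
        [
            (96.0, C.PDB_EXP),
            (95.0, C.PDB_HOMOLOGY),   # the experimental tier is strictly > 95
            (50.0, C.PDB_HOMOLOGY),   # boundary assigned upward
            (49.999, C.PDB_REMOTE),
            (20.0, C.PDB_REMOTE),
            (None, None),
        ],
    )
    def test_identity_tiers(self, identity, expected):
        assert classify_identity(identity) is expected

    def test_identity_below_filter_is_a_breach(self):
        with pytest.raises(ValueError, match="filter"):
            classify_identity(10.0)

    @pytest.mark.parametrize(
        "plddt,expected",
        [
            (90.0, C.AF_HIGH),
            (89.99, C.AF_MID),
            (70.0, C.AF_MID),
            (50.0, C.AF_LOW),
            (49.9, None),     # below 50 the model is disregarded
            (None, None),
        ],
    )
    def test_plddt_tiers(self, plddt, expected):
        assert classify_plddt(plddt) is expected

    def test_closure_flags_flip_the_boundaries(self):
        flipped = Thresholds(
            identity_exp_exclusive=False,
            identity_high_inclusive=False,
            plddt_inclusive=False,
        )
        assert classify_identity(95.0, flipped) is C.PDB_EXP
        assert classify_identity(50.0, flipped) is C.PDB_REMOTE
        assert classify_plddt(90.0, flipped) is C.AF_MID


def _single_residue_tracks(identity=np.nan, plddt=np.nan, disorder=np.nan,
                           in_domain=False):
    return ResidueTracks(
        "P1", 1,
        np.array([identity], dtype=float),
        np.array([plddt], dtype=float),
        np.array([disorder], dtype=float),
        np.array([in_domain]),
    )


class TestResolveCategories:
    @pytest.mark.parametrize(
        "identity,plddt,disorder,in_domain,expected",
        [
            (60.0, 95.0, np.nan, False, C.PDB_HOMOLOGY),  # template outranks model
            (25.0, 95.0, np.nan, False, C.AF_HIGH),       # high-confidence model outranks remote template
            (np.nan, 40.0, 0.9, False, C.IDR),
            (np.nan, 40.0, 0.1, True, C.DOMAIN_ONLY),
            (np.nan, np.nan, np.nan, False, C.DARK),
        ],
    )
    def test_precedence_examples(self, identity, plddt, disorder, in_domain, expected):
        track = resolve_categories(
            _single_residue_tracks(identity, plddt, disorder, in_domain)
        )
        assert track.categories == [expected]

    def test_fractions_partition_to_one(self):
        rng = np.random.default_rng(7)
        tracks = ResidueTracks(
            "P1", 400,
            np.where(rng.random(400) < 0.5, rng.uniform(20, 100, 400), np.nan),
            np.where(rng.random(400) < 0.5, rng.uniform(0, 100, 400), np.nan),
            np.where(rng.random(400) < 0.5, rng.uniform(0, 1, 400), np.nan),
            rng.random(400) < 0.3,
        )
        fractions = resolve_categories(tracks).fractions()
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_on_same_inputs(self):
        rng = np.random.default_rng(11)
        tracks = ResidueTracks(
            "P1", 200,
            np.where(rng.random(200) < 0.4, rng.uniform(20, 100, 200), np.nan),
            np.where(rng.random(200) < 0.4, rng.uniform(0, 100, 200), np.nan),
            np.where(rng.random(200) < 0.4, rng.uniform(0, 1, 200), np.nan),
            rng.random(200) < 0.2,
        )
        assert resolve_categories(tracks) == resolve_categories(tracks)

    @given(
        plddt=st.floats(0, 100),
        bump=st.floats(0, 50),
        identity=st.one_of(st.none(), st.floats(20, 100)),
        disorder=st.one_of(st.none(), st.floats(0, 1)),
        in_domain=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_plddt_never_lowers_precedence(
        self, plddt, bump, identity, disorder, in_domain
    ):
        """Category rank (0 = best) must not increase when pLDDT goes up."""
        def rank(p):
            t = _single_residue_tracks(
                np.nan if identity is None else identity,
                p,
                np.nan if disorder is None else disorder,
                in_domain,
            )
            return resolve_categories(t).codes[0]

        assert rank(min(plddt + bump, 100.0)) <= rank(plddt)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_adding_a_hit_never_decreases_identity(self, data):
        length = 50
        n_hits = data.draw(st.integers(0, 5))
        hits = []
        for _ in range(n_hits + 1):
            qstart = data.draw(st.integers(1, length))
            qend = data.draw(st.integers(qstart, length))
            hits.append(_hit(qstart, qend, data.draw(st.floats(20, 100))))
        before = project_hits(hits[:-1], length)
        after = project_hits(hits, length)
        ok = np.isnan(before) | (np.fmax(after, before) == after)
        assert ok.all()


class TestSummarizeProtein:
    def test_half_experimental_half_dark(self):
        protein = ProteinRecord("P1", "G1", 100)
        tracks = build_tracks(protein, [_hit(1, 50, 96.0)])
        summary = summarize_protein(resolve_categories(tracks), tracks)
        assert summary.fractions[C.PDB_EXP] == 0.5
        assert summary.fractions[C.DARK] == 0.5
        assert summary.hq_fraction == 0.5
        assert summary.covered_fraction == 0.5

    def test_model_only_protein(self):
        from structcover.io_formats import ResidueScoreTable

        protein = ProteinRecord("P1", "G1", 100)
        plddt = ResidueScoreTable(
            "P1", np.arange(1, 61), np.full(60, 95.0)
        )
        tracks = build_tracks(protein, [], plddt)
        summary = summarize_protein(resolve_categories(tracks), tracks)
        assert not summary.has_pdb
        assert summary.has_any_structure
        assert summary.af_high_fraction == 0.6

    def test_no_evidence_at_all(self):
        protein = ProteinRecord("P1", "G1", 40)
        tracks = build_tracks(protein)
        summary = summarize_protein(resolve_categories(tracks), tracks)
        assert not summary.has_any_structure
        assert summary.fractions[C.DARK] == 1.0
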