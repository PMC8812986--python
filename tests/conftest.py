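"""Shared fixtures: a full-size planted proteome (generated once per
session), its on-disk evidence files, and the pipeline re-resolution of
those files."""

from __future__ import annotations

import numpy as np
import pytest

from structcover.coverage_core import build_tracks, resolve_categories, summarize_protein
from structcover.io_formats import (
    read_alignment_hits,
    read_disorder,
    read_domains,
    read_plddt,
    read_proteins,
    read_variants,
)
from structcover.synthetic_data import GeneratorConfig, generate_proteome


@pytest.fixture(scope="session")
def default_truth():
    """The default planted proteome: 500 proteins, lengths 100-2000, seed 42."""
    return generate_proteome(GeneratorConfig())


@pytest.fixture(scope="session")
def truth_dir(default_truth, tmp_path_factory):
    """Evidence files emitted for the default planted proteome."""
    out = tmp_path_factory.mktemp("synth")
    paths = default_truth.write_files(out)
    return out, paths


@pytest.fixture(scope="session")
def resolved_pipeline(default_truth, truth_dir):
    """Read the emitted evidence back and resolve categories per protein.

    Returns (proteins, category tracks by id, protein summaries, truth).
    """
    _, paths = truth_dir
    proteins = read_proteins(paths["proteins"])
    hits = read_alignment_hits(paths["hits"])
    plddt = read_plddt(paths["plddt"])
    disorder = read_disorder(paths["disorder"])
    domains = read_domains(paths["domains"])
    tracks_by = {}
    summaries = []
    for p in proteins:
        evidence = build_tracks(
            p,
            hits.get(p.protein_id, ()),
            plddt.get(p.protein_id),
            disorder.get(p.protein_id),
            domains.get(p.protein_id, ()),
        )
        track = resolve_categories(evidence)
        tracks_by[p.protein_id] = track
        summaries.append(summarize_protein(track, evidence, gene_id=p.gene_id))
    return proteins, tracks_by, summaries, default_truth


@pytest.fixture(scope="session")
def plain_fold():
    """A 300-residue self-avoiding CA trace with no planted cluster."""
    from structcover.synthetic_data import generate_fold

    return generate_fold(300, seed=11)
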