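"""Frameshift-aware exon-guided alignment and disruption detection."""

import numpy as np
import pytest
from Bio.Seq import Seq

from unipseudo.disruption_align import (
    AlignConfig,
    _align_exon,
    align_exon_guided,
    detect_disruptions,
    gene_structure_similarity,
    _SCORES,
)
from unipseudo.io_model import GenomeSequence
from unipseudo.ortholog_screen import GenomicWindow, map_protein_to_genome
from unipseudo.synthetic_data import (
    GeneFate,
    evolve_query_genome,
    simulate_reference_geneset,
)


def _window_for(model, query, **kwargs):
    wins = map_protein_to_genome(model.protein, query, **kwargs)
    assert wins
    return wins[0]


def _one_gene_world(seed, kinds=None, **sim_kwargs):
    ref = simulate_reference_geneset(6, seed=seed, **sim_kwargs)
    gid = ref.models[0].gene_id
    query, truth = evolve_query_genome(
        ref,
        assignments={gid: GeneFate.UNITARY_PSEUDO} if kinds else None,
        disruption_kinds={gid: kinds} if kinds else None,
        seed=seed,
    )
    return ref, query, truth, ref.model(gid)


class TestAlignment:
    def test_exact_locus_is_perfect(self):
        ref, query, truth, model = _one_gene_world(1)
        aln = align_exon_guided(
            model, _window_for(model, query), query
        )
        assert aln.coverage == pytest.approx(1.0)
        assert all(b.identity == 1.0 for b in aln.blocks)
        assert all(not b.slips for b in aln.blocks)
        assert detect_disruptions(aln, model) == []

    def test_one_bp_deletion_single_slip_at_planted_offset(self):
        ref, query, truth, model = _one_gene_world(
            2, kinds=[("frameshift", "del1")]
        )
        gid = model.gene_id
        aln = align_exon_guided(
            model, _window_for(model, query), query
        )
        events = detect_disruptions(aln, model)
        assert [e.kind for e in events] == ["frameshift"]
        (planted,) = truth.records[gid].disruptions
        assert events[0].position == planted.position
        assert sum(len(b.slips) for b in aln.blocks) == 1

    def test_exon_score_matches_exhaustive_enumeration(self):
        # brute force over all move sequences for tiny exons
        config = AlignConfig()
        go, ge, fs = config.gap_open, config.gap_extend, \
            config.frameshift_penalty

        def brute(pseg, dna):
            best = 0.0

            def rec(i, j, score, gap_state):
                nonlocal best
                if j == len(pseg):
                    best = max(best, score)
                    return
                # codon match after optional slip of 1-2 nt
                for slip in (0, 1, 2):
                    i2 = i + slip + 3
                    if i2 <= len(dna):
                        codon = dna[i + slip : i2]
                        aa = str(Seq(codon).translate())
                        s = _SCORES.get((aa, pseg[j]), -4.0)
                        rec(i2, j + 1,
                            score + s - (fs if slip else 0), None)
                # protein gap
                cost = ge if gap_state == "y" else go
                rec(i, j + 1, score - cost, "y")
                # genome codon gap
                if i + 3 <= len(dna):
                    cost = ge if gap_state == "x" else go
                    rec(i + 3, j, score - cost, "x")

            for start in range(len(dna) + 1):
                rec(start, 0, 0.0, None)
            return best

        rng = np.random.default_rng(4)
        bases = list("ACGT")
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for trial in range(6):
            m = int(rng.integers(2, 5))
            n = int(rng.integers(6, 15))
            pseg = "".join(rng.choice(aas, size=m))
            dna = "".join(rng.choice(bases, size=n))
            result = _align_exon(pseg, dna, 0, n, config)
            got = result[2] if result is not None else 0.0
            assert got == pytest.approx(brute(pseg, dna))

    def test_score_monotone_in_frameshift_penalty(self):
        ref, query, truth, model = _one_gene_world(
            5, kinds=[("frameshift", "del2")]
        )
        prev = None
        for fs in (40.0, 20.0, 10.0, 5.0):
            aln = align_exon_guided(
                model, _window_for(model, query), query,
                AlignConfig(frameshift_penalty=fs),
            )
            if prev is not None:
                assert aln.score >= prev - 1e-9
            prev = aln.score

    def test_strand_symmetry_of_detected_events(self):
        ref, query, truth, model = _one_gene_world(
            6, kinds=[("premature_stop", "")], minus_strand_prob=0.0
        )
        aln = align_exon_guided(
            model, _window_for(model, query), query
        )
        events = detect_disruptions(aln, model)

        flipped = GenomeSequence(
            "chr1", "q", str(Seq(query.residues).reverse_complement())
        )
        model_rc = _mirror_model(model, len(query))
        aln_rc = align_exon_guided(
            model_rc, _window_for(model_rc, flipped), flipped
        )
        events_rc = detect_disruptions(aln_rc, model_rc)
        n = len(query)
        mirrored = sorted(
            n - e.position - 3 for e in events_rc
        )
        assert sorted(e.position for e in events) == mirrored


def _mirror_model(model, genome_len):
    from dataclasses import replace

    exons = sorted(
        (genome_len - e, genome_len - s) for s, e in model.exons
    )
    return replace(model, strand="-", exons=exons)


class TestDetection:
    def test_donor_gt_to_at_yields_splice_event(self):
        ref, query, truth, model = _one_gene_world(
            7, kinds=[("splice_site", "donor")]
        )
        aln = align_exon_guided(
            model, _window_for(model, query), query
        )
        events = detect_disruptions(aln, model)
        assert [e.kind for e in events] == ["splice_site"]
        assert events[0].detail == "AT"
        (planted,) = truth.records[model.gene_id].disruptions
        assert events[0].position == planted.position

    def test_eight_bp_deletion_yields_frameshift(self):
        ref, query, truth, model = _one_gene_world(
            8, kinds=[("frameshift", "del8")]
        )
        aln = align_exon_guided(
            model, _window_for(model, query), query
        )
        events = detect_disruptions(aln, model)
        assert [e.kind for e in events] == ["frameshift"]
        assert int(events[0].detail) % 3 == 2

    def test_in_frame_deletion_is_not_a_disruption(self):
        # deleting one whole codon leaves the frame intact
        ref = simulate_reference_geneset(4, seed=10)
        model = ref.models[0]
        query, _ = evolve_query_genome(ref, seed=10)
        s, e = model.exons[0]
        mid = s + 3 * ((e - s) // 6)
        residues = (
            query.residues[: mid] + query.residues[mid + 3 :]
        )
        mutated = GenomeSequence("chr1", "q", residues)
        aln = align_exon_guided(
            model, _window_for(model, mutated), mutated
        )
        assert detect_disruptions(aln, model) == []


class TestStructureSimilarity:
    def test_perfect_locus_scores_one(self):
        ref, query, truth, model = _one_gene_world(11)
        aln = align_exon_guided(
            model, _window_for(model, query), query
        )
        score, ok = gene_structure_similarity(aln, model)
        assert score == pytest.approx(1.0)
        assert ok

    def test_intronless_processed_copy_scores_half(self):
        ref = simulate_reference_geneset(
            6, exon_count_range=(4, 4), seed=12
        )
        gid = ref.models[0].gene_id
        query, truth = evolve_query_genome(
            ref, assignments={gid: GeneFate.PROCESSED_COPY}, seed=12
        )
        model = ref.model(gid)
        aln = align_exon_guided(
            model, _window_for(model, query), query
        )
        score, ok = gene_structure_similarity(aln, model)
        assert aln.coverage == pytest.approx(1.0)
        assert score == pytest.approx(0.5)
        assert not ok

    def test_unalignable_window_scores_zero(self):
        ref, query, truth, model = _one_gene_world(13)
        rng = np.random.default_rng(13)
        junk = GenomeSequence(
            "chr1", "q",
            "".join(rng.choice(list("ACGT"), size=2000)),
        )
        window = GenomicWindow("chr1", 0, 2000, "+", 0.0, 0.0)
        aln = align_exon_guided(model, window, junk)
        score, ok = gene_structure_similarity(aln, model)
        assert not ok

    def test_empty_window_scores_zero(self):
        ref, query, truth, model = _one_gene_world(14)
        tiny = GenomicWindow("chr1", 0, 10, "+", 0.0, 0.0)
        aln = align_exon_guided(model, tiny, query)
        assert aln.coverage == 0.0
        score, ok = gene_structure_similarity(aln, model)
        assert score == 0.0 and not ok
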