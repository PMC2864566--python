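"""Locus clustering, the filter cascade, synteny and polymorphic calls."""

import numpy as np
import pytest

from unipseudo.disruption_align import align_exon_guided, \
    detect_disruptions
from unipseudo.io_model import EvidenceClass, ValidationError
from unipseudo.locus_pipeline import (
    CandidateLocus,
    apply_evidence_filter,
    check_synteny,
    cluster_loci,
    detect_polymorphic,
    flag_tandem_family,
    run_pipeline,
)
from unipseudo.ortholog_screen import map_protein_to_genome
from unipseudo.synthetic_data import (
    GeneFate,
    build_ortholog_table,
    evolve_query_genome,
    simulate_reference_geneset,
)


def _locus(start, end, strand="+", chrom="chr1", gene="g", ev=None):
    return CandidateLocus(
        chrom=chrom, start=start, end=end, strand=strand,
        ref_gene_ids=[gene], alignment=_DUMMY, events=[],
        evidence_class=ev or EvidenceClass.NAMED_GENE,
    )


class _DummyAln:
    score = 0.0
    blocks = []
    wseq = ""

    def introns(self):
        return []


_DUMMY = _DummyAln()


class TestClusterLoci:
    def test_overlapping_pair_merges(self):
        out = cluster_loci(
            [_locus(100, 200, gene="a"), _locus(150, 250, gene="b")]
        )
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 250)
        assert out[0].ref_gene_ids == ["a", "b"]

    def test_disjoint_stay_separate(self):
        out = cluster_loci([_locus(0, 100), _locus(200, 300)])
        assert len(out) == 2

    def test_opposite_strands_stay_separate(self):
        out = cluster_loci(
            [_locus(0, 100, "+"), _locus(50, 150, "-")]
        )
        assert len(out) == 2

    def test_single_linkage_chain(self):
        out = cluster_loci(
            [
                _locus(0, 120, gene="a"),
                _locus(100, 220, gene="b"),
                _locus(200, 320, gene="c"),
            ]
        )
        assert len(out) == 1

    def test_matches_union_find_oracle_on_random_intervals(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 15))
            cands = []
            for i in range(n):
                s = int(rng.integers(0, 500))
                cands.append(
                    _locus(s, s + int(rng.integers(10, 120)),
                           gene=f"g{i}")
                )
            merged = cluster_loci(cands)
            # oracle: repeated pairwise merging to a fixed point
            spans = [(c.start, c.end) for c in cands]
            changed = True
            while changed:
                changed = False
                for i in range(len(spans)):
                    for j in range(i + 1, len(spans)):
                        a, b = spans[i], spans[j]
                        if a and b and a[0] < b[1] and b[0] < a[1]:
                            spans[i] = (min(a[0], b[0]),
                                        max(a[1], b[1]))
                            spans[j] = None
                            changed = True
                    spans = [s for s in spans if s]
            assert sorted((c.start, c.end) for c in merged) == \
                sorted(spans)
            assert len(merged) <= n


class TestEvidenceFilter:
    @pytest.mark.parametrize(
        "ev,kept",
        [
            (EvidenceClass.NAMED_GENE, True),
            (EvidenceClass.SPLICED_CDNA, True),
            (EvidenceClass.UNSPLICED_CDNA, False),
            (EvidenceClass.PREDICTED, False),
        ],
    )
    def test_class_gate(self, ev, kept):
        locus = _locus(0, 100, ev=ev)
        kept_list, dropped = apply_evidence_filter([locus])
        assert (locus in kept_list) == kept
        if not kept:
            assert dropped[0].classification == "REJECTED_EVIDENCE"


class TestTandemFamily:
    def test_planted_family_flagged_singleton_not(self, small_world):
        ref, query, truth, orthologs = small_world
        fam_gene = truth.genes_with_fate(GeneFate.FAMILY_PSEUDO)[0]
        single = truth.genes_with_fate(GeneFate.UNITARY_PSEUDO)[0]
        assert flag_tandem_family(
            _locus(0, 100, gene=fam_gene), ref.models,
            ref.paralog_families,
        )
        assert not flag_tandem_family(
            _locus(0, 100, gene=single), ref.models,
            ref.paralog_families,
        )

    def test_min_family_size_one_flags_everything(self, small_world):
        ref, *_ = small_world
        assert flag_tandem_family(
            _locus(0, 100, gene="g0005"), ref.models,
            ref.paralog_families, min_family_size=1,
        )


class TestSynteny:
    def _setup(self, shuffle=False):
        ref = simulate_reference_geneset(12, seed=21)
        gid = ref.models[5].gene_id
        query, truth = evolve_query_genome(
            ref,
            assignments={gid: GeneFate.UNITARY_PSEUDO},
            shuffle_synteny_for=(gid,) if shuffle else (),
            seed=21,
        )
        orth = build_ortholog_table(ref, truth)
        qann = {
            q.query_id: (q.chrom, q.start, q.end)
            for q in truth.query_genes
        }
        model = ref.model(gid)
        locus = _locus(model.start, model.end, gene=gid)
        return ref, orth, qann, locus

    def test_conserved_neighborhood_passes(self):
        ref, orth, qann, locus = self._setup()
        assert check_synteny(locus, ref.models, orth, qann, k=3)

    def test_shuffled_neighborhood_fails(self):
        ref, orth, qann, locus = self._setup(shuffle=True)
        assert not check_synteny(locus, ref.models, orth, qann, k=3)

    def test_k_zero_rejected(self):
        ref, orth, qann, locus = self._setup()
        with pytest.raises(ValidationError):
            check_synteny(locus, ref.models, orth, qann, k=0)


def _aligned_locus(ref, query, truth, gid):
    model = ref.model(gid)
    wins = map_protein_to_genome(model.protein, query)
    aln = align_exon_guided(model, wins[0], query)
    events = detect_disruptions(aln, model)
    return CandidateLocus(
        chrom=wins[0].chrom, start=wins[0].start, end=wins[0].end,
        strand=wins[0].strand, ref_gene_ids=[gid], alignment=aln,
        events=events, evidence_class=EvidenceClass.NAMED_GENE,
    )


class TestPolymorphic:
    @pytest.mark.parametrize(
        "kind", ["premature_stop", "frameshift", "splice_site"]
    )
    def test_functional_transcript_marks_polymorphic(self, kind):
        ref = simulate_reference_geneset(6, seed=31)
        gid = ref.models[0].gene_id
        detail = {"frameshift": "del2", "splice_site": "donor"}.get(
            kind, ""
        )
        query, truth = evolve_query_genome(
            ref,
            assignments={gid: GeneFate.UNITARY_PSEUDO},
            disruption_kinds={gid: [(kind, detail)]},
            polymorphic_genes=(gid,),
            seed=31,
        )
        locus = _aligned_locus(ref, query, truth, gid)
        assert locus.events, "disruption must be detected first"
        assert detect_polymorphic(locus, truth.transcripts)

    def test_disrupted_transcript_stays_fixed(self):
        ref = simulate_reference_geneset(6, seed=32)
        gid = ref.models[0].gene_id
        query, truth = evolve_query_genome(
            ref,
            assignments={gid: GeneFate.UNITARY_PSEUDO},
            disruption_kinds={gid: [("premature_stop", "")]},
            transcripts_for=(gid,),
            seed=32,
        )
        locus = _aligned_locus(ref, query, truth, gid)
        assert not detect_polymorphic(locus, truth.transcripts)

    def test_no_transcripts_default_fixed(self):
        ref = simulate_reference_geneset(6, seed=33)
        gid = ref.models[0].gene_id
        query, truth = evolve_query_genome(
            ref,
            assignments={gid: GeneFate.UNITARY_PSEUDO},
            seed=33,
        )
        locus = _aligned_locus(ref, query, truth, gid)
        assert not detect_polymorphic(locus, {})


@pytest.fixture(scope="module")
def pipeline_world():
    ref = simulate_reference_geneset(
        60, n_tandem_families=2, seed=17
    )
    fates = {
        GeneFate.UNITARY_PSEUDO: 6,
        GeneFate.FAMILY_PSEUDO: 2,
        GeneFate.PROCESSED_COPY: 2,
        GeneFate.DELETED_IN_QUERY: 2,
        GeneFate.GAIN_IN_REF: 2,
    }
    query, truth = evolve_query_genome(ref, fates=fates, seed=17)
    orth = build_ortholog_table(ref, truth)
    qann = {
        q.query_id: (q.chrom, q.start, q.end)
        for q in truth.query_genes
    }
    report = run_pipeline(
        ref.models, query, orth, query_annotation=qann,
        ref_paralog_families=ref.paralog_families,
    )
    return ref, query, truth, orth, qann, report


class TestRunPipeline:
    def test_bins_match_truth(self, pipeline_world):
        ref, query, truth, orth, qann, report = pipeline_world
        fixed = {g for l in report.fixed_unitary
                 for g in l.ref_gene_ids}
        fam = {g for l in report.tandem_family
               for g in l.ref_gene_ids}
        assert fixed == set(
            truth.genes_with_fate(GeneFate.UNITARY_PSEUDO)
        )
        assert fam == set(
            truth.genes_with_fate(GeneFate.FAMILY_PSEUDO)
        )
        assert set(report.structure_fail) == set(
            truth.genes_with_fate(GeneFate.PROCESSED_COPY)
        )
        assert set(report.unalignable) == set(
            truth.genes_with_fate(GeneFate.DELETED_IN_QUERY)
        ) | set(truth.genes_with_fate(GeneFate.GAIN_IN_REF))

    def test_every_unmatched_protein_in_exactly_one_bin(
        self, pipeline_world
    ):
        *_, report = pipeline_world
        bins = [
            set(report.unalignable),
            set(report.structure_fail),
            set(report.no_disruption),
        ]
        for group in (
            report.removed_evidence, report.tandem_family,
            report.removed_synteny, report.fixed_unitary,
            report.polymorphic,
        ):
            bins.append({g for l in group for g in l.ref_gene_ids})
        union = set().union(*bins)
        assert union == set(report.unmatched)
        assert sum(len(b) for b in bins) == len(union)

    def test_rerun_is_identical(self, pipeline_world):
        ref, query, truth, orth, qann, report = pipeline_world
        again = run_pipeline(
            ref.models, query, orth, query_annotation=qann,
            ref_paralog_families=ref.paralog_families,
        )
        assert again.counts() == report.counts()
        assert again.locus_table().equals(report.locus_table())

    def test_zero_planted_zero_loci(self):
        ref = simulate_reference_geneset(10, seed=19)
        query, truth = evolve_query_genome(ref, seed=19)
        orth = build_ortholog_table(ref, truth)
        report = run_pipeline(ref.models, query, orth)
        assert report.counts()["loci_after_clustering"] == 0
        assert report.unmatched == []
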