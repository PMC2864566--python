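"""Cluster candidate alignments into loci and apply the filter cascade.

The cascade mirrors a comparative pseudogene-discovery workflow: reference
proteins without query orthologs are mapped to the query genome; proteins
with no acceptable mapping are set aside as reference-lineage gains; mapped
candidates must reproduce the reference gene structure (which removes
intronless processed copies); disrupted candidates are clustered into loci
by coordinate overlap; loci supported only by unspliced or merely predicted
reference annotation are dropped; tandem-gene-family loci are reported
separately; synteny against the flanking orthologs is required; and loci
whose transcripts contradict the genomic disruptions are classified as
polymorphic rather than fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .disruption_align import (
    AlignConfig,
    DisruptionEvent,
    SplicedAlignment,
    align_exon_guided,
    detect_disruptions,
    gene_structure_similarity,
)
from .io_model import (
    EvidenceClass,
    GeneModel,
    GenomeSequence,
    OrthologTable,
    ValidationError,
)
from .ortholog_screen import (
    classify_mappability,
    find_unmatched_reference_proteins,
    map_protein_to_genome,
)

logger = logging.getLogger("unipseudo.pipeline")

__all__ = [
    "PipelineConfig",
    "CandidateLocus",
    "PipelineReport",
    "cluster_loci",
    "apply_evidence_filter",
    "flag_tandem_family",
    "check_synteny",
    "detect_polymorphic",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    seed_len: int = 5
    min_coverage: float = 0.5
    synteny_k: int = 3
    min_family_size: int = 2
    max_cluster_span: int = 10_000
    borderline_margin: float = 0.05  # structure scores this close to the
    # threshold are flagged as needing manual-style review
    align: AlignConfig = field(default_factory=AlignConfig)


@dataclass
class CandidateLocus:
    """A pseudogenic locus assembled from one or more protein alignments."""

    chrom: str
    start: int
    end: int
    strand: str
    ref_gene_ids: list[str]
    alignment: SplicedAlignment
    events: list[DisruptionEvent]
    evidence_class: EvidenceClass
    intronless: bool = False
    tandem_family: bool = False
    synteny_ok: bool = True
    polymorphic: bool = False
    needs_review: bool = False
    structure_score: float = 0.0
    classification: str = ""

    def interval(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class PipelineReport:
    """Fate of every unmatched reference protein, bin by bin."""

    n_reference: int
    unmatched: list[str]
    unalignable: list[str]
    structure_fail: list[str]
    no_disruption: list[str]
    n_candidates: int
    loci: list[CandidateLocus]
    removed_evidence: list[CandidateLocus]
    tandem_family: list[CandidateLocus]
    removed_synteny: list[CandidateLocus]
    fixed_unitary: list[CandidateLocus]
    polymorphic: list[CandidateLocus]

    def counts(self) -> dict[str, int]:
        return {
            "reference_genes": self.n_reference,
            "unmatched_proteins": len(self.unmatched),
            "unalignable": len(self.unalignable),
            "structure_fail": len(self.structure_fail),
            "no_disruption": len(self.no_disruption),
            "disrupted_candidates": self.n_candidates,
            "loci_after_clustering": len(self.loci),
            "removed_evidence": len(self.removed_evidence),
            "tandem_family": len(self.tandem_family),
            "removed_synteny": len(self.removed_synteny),
            "fixed_unitary": len(self.fixed_unitary),
            "polymorphic": len(self.polymorphic),
        }

    def locus_table(self) -> pd.DataFrame:
        rows = []
        for locus in (
            self.removed_evidence + self.tandem_family
            + self.removed_synteny + self.fixed_unitary + self.polymorphic
        ):
            rows.append(
                {
                    "chrom": locus.chrom,
                    "start": locus.start,
                    "end": locus.end,
                    "strand": locus.strand,
                    "ref_genes": ",".join(locus.ref_gene_ids),
                    "evidence": locus.evidence_class.name,
                    "n_events": len(locus.events),
                    "events": ";".join(
                        f"{e.kind}@{e.position}" for e in locus.events
                    ),
                    "structure_score": round(locus.structure_score, 3),
                    "intronless": locus.intronless,
                    "tandem_family": locus.tandem_family,
                    "synteny_ok": locus.synteny_ok,
                    "needs_review": locus.needs_review,
                    "classification": locus.classification,
                }
            )
        return pd.DataFrame(rows)


def cluster_loci(candidates: list[CandidateLocus]) -> list[CandidateLocus]:
    """Single-linkage merge of same-chromosome same-strand overlapping
    candidate loci; contributing reference genes are pooled."""
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = candidates[i], candidates[j]
            if (
                a.chrom == b.chrom
                and a.strand == b.strand
                and a.start < b.end
                and b.start < a.end
            ):
                parent[find(i)] = find(j)

    groups: dict[int, list[CandidateLocus]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(candidates[i])
    out = []
    for members in groups.values():
        best = max(members, key=lambda c: c.alignment.score)
        merged = CandidateLocus(
            chrom=best.chrom,
            start=min(c.start for c in members),
            end=max(c.end for c in members),
            strand=best.strand,
            ref_gene_ids=sorted(
                {g for c in members for g in c.ref_gene_ids}
            ),
            alignment=best.alignment,
            events=best.events,
            evidence_class=min(
                (c.evidence_class for c in members),
                key=lambda e: e.rank,
            ),
            intronless=best.intronless,
            structure_score=best.structure_score,
            needs_review=any(c.needs_review for c in members),
        )
        out.append(merged)
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


def apply_evidence_filter(
    loci: list[CandidateLocus],
) -> tuple[list[CandidateLocus], list[CandidateLocus]]:
    """Drop loci supported only by unspliced transcripts or predictions."""
    kept, discarded = [], []
    for locus in loci:
        if locus.evidence_class in (
            EvidenceClass.UNSPLICED_CDNA,
            EvidenceClass.PREDICTED,
        ):
            reason = (
                "unspliced transcribed sequence"
                if locus.evidence_class is EvidenceClass.UNSPLICED_CDNA
                else "modeled/predicted"
            )
            logger.info(
                "locus %s:%d-%d discarded (%s)",
                locus.chrom, locus.start, locus.end, reason,
            )
            locus.classification = "REJECTED_EVIDENCE"
            discarded.append(locus)
        else:
            kept.append(locus)
    return kept, discarded


def flag_tandem_family(
    locus: CandidateLocus,
    ref_models: list[GeneModel],
    ref_paralog_families: dict[str, str],
    min_family_size: int = 2,
    max_cluster_span: int = 10_000,
) -> bool:
    """True when the locus comes from a tandem gene family: the reference
    gene's family has >= min_family_size members of which >= 2 lie within
    max_cluster_span of each other in the reference genome."""
    by_id = {m.gene_id: m for m in ref_models}
    for gid in locus.ref_gene_ids:
        fam = ref_paralog_families.get(gid)
        if fam is None:
            if min_family_size <= 1:
                return True
            continue
        members = [
            g for g, f in ref_paralog_families.items() if f == fam
        ]
        if len(members) < min_family_size:
            continue
        positions = sorted(
            by_id[g].start for g in members if g in by_id
        )
        for a, b in zip(positions, positions[1:]):
            if b - a <= max_cluster_span:
                return True
    return min_family_size <= 1


def check_synteny(
    locus: CandidateLocus,
    ref_models: list[GeneModel],
    orthologs: OrthologTable,
    query_annotation: dict[str, tuple[str, int, int]],
    k: int = 3,
) -> bool:
    """Conserved flanking loci: on each side of the reference gene, at
    least one of the k nearest flanking genes must have its query ortholog
    on the locus chromosome and on the matching side of the locus.

    A side with no flanking genes (contig edge) passes vacuously.
    """
    if k < 1:
        raise ValidationError("synteny requires k >= 1 flanking genes")
    order = sorted(ref_models, key=lambda m: (m.chrom, m.start))
    ids = [m.gene_id for m in order]
    focal = locus.ref_gene_ids[0]
    try:
        i = ids.index(focal)
    except ValueError:
        raise ValidationError(f"unknown reference gene {focal!r}")

    def side_ok(neighbor_ids: list[str], left: bool) -> bool:
        if not neighbor_ids:
            logger.info(
                "locus %s:%d-%d: no %s flanking genes, side passes",
                locus.chrom, locus.start, locus.end,
                "left" if left else "right",
            )
            return True
        for gid in neighbor_ids:
            q = orthologs.query_ortholog_of(gid)
            if q is None or q not in query_annotation:
                continue
            chrom, start, end = query_annotation[q]
            if chrom != locus.chrom:
                continue
            if left and end <= locus.start:
                return True
            if not left and start >= locus.end:
                return True
        return False

    left_ids = ids[max(0, i - k) : i][::-1]
    right_ids = ids[i + 1 : i + 1 + k]
    return side_ok(left_ids, True) and side_ok(right_ids, False)


_FLANK = 12


def detect_polymorphic(
    locus: CandidateLocus,
    transcripts: dict[str, str] | list[str],
) -> bool:
    """True when a transcript spans a disruption and carries the
    functional state at every disruption it spans.

    Transcripts are matched against the spliced exon sequence of the locus
    by exact flank search (adequate at the near-identity of same-species
    mRNA); unmappable transcripts are ignored with a warning.
    """
    if not transcripts:
        return False
    if isinstance(transcripts, dict):
        transcripts = list(transcripts.values())
    aln = locus.alignment
    blocks = [b for b in aln.blocks if b.found]
    if not blocks:
        return False
    spliced_parts = []
    offsets = {}  # block index -> spliced offset of block start
    pos = 0
    for b in blocks:
        offsets[b.exon_index] = pos
        spliced_parts.append(aln.wseq[b.g_start : b.g_end])
        pos += b.g_end - b.g_start
    spliced = "".join(spliced_parts)

    def spliced_offset(window_off: int) -> int | None:
        for b in blocks:
            if b.g_start <= window_off <= b.g_end:
                return offsets[b.exon_index] + (window_off - b.g_start)
        return None

    for transcript in transcripts:
        spans, functional = 0, 0
        for event, w_off in _events_window_offsets(locus):
            o = spliced_offset(w_off)
            if o is None:
                continue
            verdict = _transcript_state(
                event, spliced, o, transcript
            )
            if verdict is None:
                continue
            spans += 1
            if verdict:
                functional += 1
        if spans == 0:
            logger.warning(
                "transcript does not span any disruption of locus "
                "%s:%d-%d; ignored", locus.chrom, locus.start, locus.end,
            )
            continue
        if spans == functional:
            return True
    return False


def _events_window_offsets(locus: CandidateLocus):
    """Pair each disruption event with its window coding-space offset."""
    aln = locus.alignment
    for e in locus.events:
        span = {"premature_stop": 3, "splice_site": 2}.get(e.kind, 0)
        if aln.window.strand == "+":
            w = e.position - aln.window.start
        else:
            w = aln.window.start + aln.window_len - e.position - span
        yield e, w


def _transcript_state(
    event: DisruptionEvent, spliced: str, o: int, transcript: str
) -> bool | None:
    """None if the transcript does not span the event; else True when it
    carries the functional (non-disrupted) state."""
    stops = {"TAA", "TAG", "TGA"}
    if event.kind == "premature_stop":
        left = spliced[max(0, o - _FLANK) : o]
        right = spliced[o + 3 : o + 3 + _FLANK]
        t = transcript.find(left)
        if t < 0 or not left or not right:
            return None
        codon_at = t + len(left)
        if not transcript[codon_at + 3 :].startswith(right):
            return None
        return transcript[codon_at : codon_at + 3] not in stops
    if event.kind == "frameshift":
        try:
            indel = abs(int(event.detail))
        except ValueError:
            return None
        left = spliced[max(0, o - _FLANK) : o]
        right = spliced[o : o + _FLANK]
        t = transcript.find(left)
        if t < 0 or not left or not right:
            return None
        after = t + len(left)
        window = transcript[after : after + indel + len(right)]
        d = window.find(right)
        if d < 0:
            return None
        return d == indel
    if event.kind == "splice_site":
        junction = spliced[max(0, o - _FLANK) : o + _FLANK]
        if len(junction) < _FLANK:
            return None
        return junction in transcript
    return None


def run_pipeline(
    ref_models: list[GeneModel],
    query_genome: GenomeSequence,
    orthologs: OrthologTable,
    query_annotation: dict[str, tuple[str, int, int]] | None = None,
    transcripts: dict[str, str] | None = None,
    ref_paralog_families: dict[str, str] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineReport:
    """Run the full cascade and account for every unmatched protein.

    *transcripts* maps reference gene ids to query mRNA sequences used for
    the polymorphic-locus contradiction check; *query_annotation* maps
    query gene ids to (chrom, start, end) for the synteny check (loci pass
    vacuously when it is absent).
    """
    by_id = {m.gene_id: m for m in ref_models}
    families = ref_paralog_families or {}
    unmatched = find_unmatched_reference_proteins(orthologs)
    logger.info("screen: %d unmatched reference proteins", len(unmatched))

    windows = {
        gid: map_protein_to_genome(
            by_id[gid].protein, query_genome,
            seed_len=config.seed_len, min_coverage=config.min_coverage,
        )
        for gid in unmatched
        if gid in by_id
    }
    mappability = classify_mappability(windows)
    unalignable = sorted(
        g for g, v in mappability.items() if v == "UNALIGNABLE"
    )
    logger.info("screen: %d unalignable (reference gains)",
                len(unalignable))

    candidates: list[CandidateLocus] = []
    structure_fail: list[str] = []
    no_disruption: list[str] = []
    for gid in unmatched:
        if mappability.get(gid) != "ALIGNABLE":
            continue
        model = by_id[gid]
        aln = align_exon_guided(
            model, windows[gid][0], query_genome, config.align
        )
        score, ok = gene_structure_similarity(aln, model, config.align)
        borderline = abs(
            score - config.align.structure_threshold
        ) <= config.borderline_margin
        if not ok:
            structure_fail.append(gid)
            continue
        events = detect_disruptions(aln, model, config.align)
        if not events:
            no_disruption.append(gid)
            continue
        found = [b for b in aln.blocks if b.found]
        w = aln.window
        if w.strand == "+":
            start = w.start + min(b.g_start for b in found)
            end = w.start + max(b.g_end for b in found)
        else:
            start = w.start + aln.window_len - max(
                b.g_end for b in found
            )
            end = w.start + aln.window_len - min(
                b.g_start for b in found
            )
        candidates.append(
            CandidateLocus(
                chrom=w.chrom,
                start=start,
                end=end,
                strand=w.strand,
                ref_gene_ids=[gid],
                alignment=aln,
                events=events,
                evidence_class=model.evidence_class,
                intronless=not aln.introns(),
                structure_score=score,
                needs_review=borderline,
            )
        )
    logger.info(
        "align: %d disrupted candidates, %d structure failures, "
        "%d without disruptions",
        len(candidates), len(structure_fail), len(no_disruption),
    )

    loci = cluster_loci(candidates)
    logger.info("cluster: %d loci", len(loci))
    kept, removed_evidence = apply_evidence_filter(loci)

    tandem, rest = [], []
    for locus in kept:
        if flag_tandem_family(
            locus, ref_models, families,
            config.min_family_size, config.max_cluster_span,
        ):
            locus.tandem_family = True
            locus.classification = "TANDEM_FAMILY"
            tandem.append(locus)
        else:
            rest.append(locus)

    removed_synteny, surviving = [], []
    for locus in rest:
        if query_annotation is not None:
            locus.synteny_ok = check_synteny(
                locus, ref_models, orthologs, query_annotation,
                config.synteny_k,
            )
        if not locus.synteny_ok:
            locus.classification = "REJECTED_SYNTENY"
            removed_synteny.append(locus)
        else:
            surviving.append(locus)

    fixed, poly = [], []
    for locus in surviving:
        locus_transcripts = {}
        if transcripts:
            locus_transcripts = {
                g: t for g, t in transcripts.items()
                if g in locus.ref_gene_ids
            }
        if detect_polymorphic(locus, locus_transcripts):
            locus.polymorphic = True
            locus.classification = "POLYMORPHIC"
            poly.append(locus)
        else:
            locus.classification = "FIXED_UNITARY"
            fixed.append(locus)
    logger.info(
        "classify: %d fixed unitary, %d polymorphic, %d tandem-family, "
        "%d rejected", len(fixed), len(poly), len(tandem),
        len(removed_evidence) + len(removed_synteny),
    )

    return PipelineReport(
        n_reference=len(ref_models),
        unmatched=unmatched,
        unalignable=unalignable,
        structure_fail=structure_fail,
        no_disruption=no_disruption,
        n_candidates=len(candidates),
        loci=loci,
        removed_evidence=removed_evidence,
        tandem_family=tandem,
        removed_synteny=removed_synteny,
        fixed_unitary=fixed,
        polymorphic=poly,
    )
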