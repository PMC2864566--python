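"""Synthetic pipeline inputs with known planted truth.

Every generator is a pure function of its seed and parameters. The genome
simulator writes multi-exon protein-coding genes separated by intergenic
spacers onto a single chromosome; the query evolver copies that genome and
plants gene fates (intact ortholog, unitary pseudogene, tandem-family
pseudogene, processed copy, deletion, reference-lineage gain) so that the
planted disruptions are the only ORF-breaking signal. Background divergence
is substitution-only (Jukes-Cantor-like) and never creates a stop codon or
touches a splice dinucleotide, so intact genes stay intact at any rate.

Introns are written with canonical GT..AG splice sites and exons fall on
codon boundaries (phase-0 introns); any deviation from GT..AG in the query
is therefore a planted disruption.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io_model import (
    EvidenceClass,
    GeneModel,
    GenomeSequence,
    GenotypeCounts,
    AnnotationDAG,
    OrthologTable,
    SpeciesTree,
    ValidationError,
    translate_cds,
)

__all__ = [
    "GeneFate",
    "PlantedDisruption",
    "TruthRecord",
    "TruthTable",
    "ReferenceGeneset",
    "QueryGene",
    "simulate_reference_geneset",
    "evolve_query_genome",
    "build_ortholog_table",
    "simulate_codon_phylogeny",
    "simulate_genotypes",
    "simulate_annotations",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


class GeneFate(enum.Enum):
    INTACT_ORTHOLOG = "INTACT_ORTHOLOG"
    UNITARY_PSEUDO = "UNITARY_PSEUDO"
    FAMILY_PSEUDO = "FAMILY_PSEUDO"
    PROCESSED_COPY = "PROCESSED_COPY"
    DELETED_IN_QUERY = "DELETED_IN_QUERY"
    GAIN_IN_REF = "GAIN_IN_REF"


@dataclass(frozen=True)
class PlantedDisruption:
    """One planted CDS disruption, located in query-genome coordinates.

    Position conventions (plus-strand chromosome coordinates of the query):
    premature_stop = leftmost base of the stop codon; frameshift = the
    insertion-point coordinate of the indel junction (bases to its left);
    splice_site = leftmost base of the altered dinucleotide.
    """

    kind: str  # premature_stop | frameshift | splice_site
    chrom: str
    position: int
    detail: str  # stop codon text, indel length, or observed dinucleotide


@dataclass
class TruthRecord:
    gene_id: str
    fate: GeneFate
    disruptions: list[PlantedDisruption] = field(default_factory=list)
    family_id: str | None = None
    branch: str | None = None  # planted pseudogenization branch (alignments)
    t_n: float | None = None  # planted nonfunctionalization time (MY)
    polymorphic: bool = False  # a functional allele still segregates

    def __post_init__(self) -> None:
        pseudo = self.fate in (
            GeneFate.UNITARY_PSEUDO,
            GeneFate.FAMILY_PSEUDO,
            GeneFate.PROCESSED_COPY,
        )
        if self.disruptions and not pseudo:
            raise ValidationError(
                f"{self.gene_id}: disruptions on non-pseudogenic fate"
            )


@dataclass
class QueryGene:
    """Location of an intact ortholog in the query genome (for synteny)."""

    query_id: str
    ref_id: str
    chrom: str
    start: int
    end: int


@dataclass
class TruthTable:
    records: dict[str, TruthRecord]
    query_genes: list[QueryGene] = field(default_factory=list)
    paralog_families: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tfate\tfamily\tpolymorphic\tdisruptions\n"
            )
            for gid in sorted(self.records):
                r = self.records[gid]
                dis = ";".join(
                    f"{d.kind}@{d.chrom}:{d.position}:{d.detail}"
                    for d in r.disruptions
                )
                fh.write(
                    f"{gid}\t{r.fate.value}\t{r.family_id or '.'}\t"
                    f"{int(r.polymorphic)}\t{dis or '.'}\n"
                )

    def fate_counts(self) -> dict[GeneFate, int]:
        out: dict[GeneFate, int] = {}
        for rec in self.records.values():
            out[rec.fate] = out.get(rec.fate, 0) + 1
        return out

    def genes_with_fate(self, fate: GeneFate) -> list[str]:
        return sorted(
            g for g, r in self.records.items() if r.fate is fate
        )


@dataclass
class ReferenceGeneset:
    genome: GenomeSequence
    models: list[GeneModel]
    paralog_families: dict[str, str] = field(default_factory=dict)

    def model(self, gene_id: str) -> GeneModel:
        for m in self.models:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# helpers

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    codons = [_SENSE_CODONS[i] for i in idx]
    codons[0] = "ATG"
    return "".join(codons)


def _random_intron(rng: np.random.Generator, length: int) -> str:
    interior = _random_dna(rng, max(0, length - 4))
    return "GT" + interior + "AG"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class _Blueprint:
    """A gene in coding orientation: exon CDS chunks and introns."""

    exon_cds: list[str]
    introns: list[str]
    strand: str

    def region(self) -> str:
        parts = []
        for i, ex in enumerate(self.exon_cds):
            parts.append(ex)
            if i < len(self.introns):
                parts.append(self.introns[i])
        coding = "".join(parts)
        return coding if self.strand == "+" else _revcomp(coding)

    def cds(self) -> str:
        return "".join(self.exon_cds)

    def exon_offsets(self) -> list[tuple[int, int]]:
        """Coding-orientation region offsets of each exon, in coding order."""
        out = []
        pos = 0
        for i, ex in enumerate(self.exon_cds):
            out.append((pos, pos + len(ex)))
            pos += len(ex)
            if i < len(self.introns):
                pos += len(self.introns[i])
        return out

    def intron_offsets(self) -> list[tuple[int, int]]:
        exo = self.exon_offsets()
        return [
            (exo[i][1], exo[i + 1][0]) for i in range(len(self.introns))
        ]


def _blueprint_from_model(
    model: GeneModel, genome: GenomeSequence
) -> _Blueprint:
    region = genome.residues[model.start : model.end]
    if model.strand == "-":
        region = _revcomp(region)
    exon_cds, introns = [], []
    pos = 0
    lengths = [(e - s) for s, e in model.exons_biological()]
    intron_lengths = [(e - s) for s, e in model.introns()]
    if model.strand == "-":
        intron_lengths = intron_lengths[::-1]
    for i, ln in enumerate(lengths):
        exon_cds.append(region[pos : pos + ln])
        pos += ln
        if i < len(intron_lengths):
            introns.append(region[pos : pos + intron_lengths[i]])
            pos += intron_lengths[i]
    return _Blueprint(exon_cds, introns, model.strand)


def _model_from_blueprint(
    gene_id: str,
    species: str,
    chrom: str,
    start: int,
    bp: _Blueprint,
    evidence: EvidenceClass,
) -> GeneModel:
    region_len = sum(map(len, bp.exon_cds)) + sum(map(len, bp.introns))
    exons = []
    for (a, b) in bp.exon_offsets():
        if bp.strand == "+":
            exons.append((start + a, start + b))
        else:
            exons.append((start + region_len - b, start + region_len - a))
    exons.sort()
    aa = translate_cds(bp.cds())
    return GeneModel(
        gene_id=gene_id,
        species=species,
        chrom=chrom,
        strand=bp.strand,
        exons=exons,
        protein=aa,
        evidence_class=evidence,
    )


# ---------------------------------------------------------------------------
# reference gene set

def simulate_reference_geneset(
    n_genes: int,
    exon_count_range: tuple[int, int] = (2, 5),
    exon_len_range: tuple[int, int] = (45, 150),
    intergenic_len: int = 300,
    intron_len_range: tuple[int, int] = (60, 200),
    n_tandem_families: int = 0,
    family_size: int = 3,
    minus_strand_prob: float = 0.3,
    evidence_mix: dict[EvidenceClass, float] | None = None,
    seed: int = 0,
    species: str = "reference",
    chrom: str = "chr1",
) -> ReferenceGeneset:
    """Simulate a single-chromosome genome with non-overlapping genes.

    Exon lengths are drawn in whole codons within *exon_len_range* nt, so
    every intron is phase 0. Tandem paralog families are emitted as
    *family_size* adjacent near-identical copies of a common ancestor and
    recorded in ``paralog_families``.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if exon_count_range[0] < 1 or exon_count_range[0] > exon_count_range[1]:
        raise ValidationError("invalid exon_count_range")
    lo_c = max(2, exon_len_range[0] // 3)
    hi_c = max(lo_c, exon_len_range[1] // 3)
    if exon_len_range[0] > exon_len_range[1] or exon_len_range[0] < 3:
        raise ValidationError("invalid exon_len_range")
    if n_tandem_families * family_size > n_genes:
        raise ValidationError("tandem families exceed n_genes")

    rng = _rng(seed, 1)

    # slot blocks occupied by families, placed deterministically
    family_of_slot: dict[int, str] = {}
    if n_tandem_families:
        stride = n_genes // n_tandem_families
        for f in range(n_tandem_families):
            base = f * stride
            for k in range(family_size):
                family_of_slot[base + k] = f"fam{f:03d}"

    blueprints: list[_Blueprint] = []
    fam_proto: dict[str, _Blueprint] = {}
    for slot in range(n_genes):
        fam = family_of_slot.get(slot)
        if fam is not None and fam in fam_proto:
            bp = _mutate_paralog(fam_proto[fam], rng)
        else:
            n_ex = int(rng.integers(exon_count_range[0],
                                    exon_count_range[1] + 1))
            exon_cds = [
                _random_cds(rng, int(rng.integers(lo_c, hi_c + 1)))
                if i == 0
                else "".join(
                    _SENSE_CODONS[j]
                    for j in rng.integers(
                        0, len(_SENSE_CODONS),
                        size=int(rng.integers(lo_c, hi_c + 1)),
                    )
                )
                for i in range(n_ex)
            ]
            introns = [
                _random_intron(
                    rng, int(rng.integers(*intron_len_range))
                )
                for _ in range(n_ex - 1)
            ]
            strand = "-" if rng.random() < minus_strand_prob else "+"
            bp = _Blueprint(exon_cds, introns, strand)
            if fam is not None:
                fam_proto[fam] = bp
        blueprints.append(bp)

    mix = evidence_mix or {EvidenceClass.NAMED_GENE: 1.0}
    classes = list(mix)
    weights = np.array([mix[c] for c in classes], dtype=float)
    weights /= weights.sum()

    parts: list[str] = []
    models: list[GeneModel] = []
    families: dict[str, str] = {}
    pos = 0
    for slot, bp in enumerate(blueprints):
        spacer = _random_dna(rng, intergenic_len)
        parts.append(spacer)
        pos += len(spacer)
        gid = f"g{slot:04d}"
        ev = classes[int(rng.choice(len(classes), p=weights))]
        if ev is EvidenceClass.UNSPLICED_CDNA and len(bp.exon_cds) > 1:
            bp = _Blueprint([bp.cds()], [], bp.strand)
        region = bp.region()
        models.append(
            _model_from_blueprint(gid, species, chrom, pos, bp, ev)
        )
        parts.append(region)
        pos += len(region)
        if slot in family_of_slot:
            families[gid] = family_of_slot[slot]
    parts.append(_random_dna(rng, intergenic_len))
    genome = GenomeSequence(chrom, species, "".join(parts))
    for m in models:
        if m.evidence_class is not EvidenceClass.PREDICTED:
            m.validate_functional(genome)
    return ReferenceGeneset(genome, models, families)


def _mutate_paralog(
    proto: _Blueprint, rng: np.random.Generator, rate: float = 0.06
) -> _Blueprint:
    """A tandem paralog: ~6% substitutions (~94% nt identity, in the range
    of real tandem receptor families), ORF preserved."""
    exon_cds = [
        _mutate_orf_safe(ex, rng, rate) for ex in proto.exon_cds
    ]
    introns = [
        _mutate_intron(intr, rng, rate) for intr in proto.introns
    ]
    return _Blueprint(exon_cds, introns, proto.strand)


def _mutate_orf_safe(
    cds: str, rng: np.random.Generator, rate: float,
    protected: set[int] | None = None,
) -> str:
    """Substitute bases at *rate*, never creating a stop codon."""
    out = list(cds)
    n_mut = rng.binomial(len(cds), rate)
    sites = rng.choice(len(cds), size=min(n_mut, len(cds)), replace=False)
    for i in sorted(int(s) for s in sites):
        if protected and i in protected:
            continue
        old = out[i]
        new = _BASES[int(rng.integers(4))]
        if new == old:
            continue
        c0 = 3 * (i // 3)
        codon = out[c0 : c0 + 3]
        codon[i - c0] = new
        if "".join(codon) in _STOPS:
            continue
        out[i] = new
    return "".join(out)


def _mutate_intron(
    intron: str, rng: np.random.Generator, rate: float
) -> str:
    """Substitute intron interior; GT..AG dinucleotides untouched."""
    if len(intron) <= 4:
        return intron
    body = list(intron[2:-2])
    n_mut = rng.binomial(len(body), rate)
    sites = rng.choice(len(body), size=min(n_mut, len(body)), replace=False)
    for i in sites:
        body[int(i)] = _BASES[int(rng.integers(4))]
    return intron[:2] + "".join(body) + intron[-2:]


# ---------------------------------------------------------------------------
# query genome evolution

_DISRUPTION_KINDS = ("premature_stop", "frameshift", "splice_site")


def evolve_query_genome(
    ref: ReferenceGeneset,
    neutral_sub_rate: float = 0.0,
    fates: dict[GeneFate, int] | None = None,
    assignments: dict[str, GeneFate] | None = None,
    disruption_kinds: dict[str, list[tuple[str, str]]] | None = None,
    shuffle_synteny_for: tuple[str, ...] = (),
    polymorphic_genes: tuple[str, ...] = (),
    transcripts_for: tuple[str, ...] = (),
    seed: int = 0,
    species: str = "query",
) -> tuple[GenomeSequence, TruthTable]:
    """Derive a query genome from the reference with planted gene fates.

    *fates* gives requested counts per fate (remaining genes stay intact);
    *assignments* pins specific genes instead. *disruption_kinds* optionally
    fixes the planted events per gene as (kind, detail) pairs, e.g.
    ``[("frameshift", "del8")]`` or ``[("splice_site", "donor")]``; by
    default one randomly chosen disruption is planted per pseudogene.
    FAMILY_PSEUDO fates are planted in distinct tandem families (one member
    disabled); DELETED_IN_QUERY and GAIN_IN_REF loci are replaced with
    random sequence; PROCESSED_COPY genes lose their spliced locus and gain
    an intronless (stop-disrupted) CDS copy at the chromosome end.

    Genes in *polymorphic_genes* (which must have a pseudogenic fate) keep
    their planted genomic disruptions but also emit a spliced mRNA of the
    functional allele — the transcript/genome contradiction that marks a
    segregating (polymorphic) pseudogene. Genes in *transcripts_for* emit
    a transcript of the disrupted allele instead (same state as genomic).
    """
    rng = _rng(seed, 2)
    fate_of = _assign_fates(ref, fates, assignments, rng)

    models = sorted(ref.models, key=lambda m: m.start)
    chrom = ref.genome.seq_id
    gseq = ref.genome.residues

    records: dict[str, TruthRecord] = {}
    out_parts: list[str] = []
    query_genes: list[QueryGene] = []
    transcripts: dict[str, str] = {}
    processed_tail: list[tuple[str, str]] = []  # (gene_id, cds_with_stop)

    cursor = 0
    qpos = 0
    for m in models:
        inter = gseq[cursor : m.start]
        out_parts.append(_mutate_free(inter, rng, neutral_sub_rate))
        qpos += len(inter)
        cursor = m.end

        fate = fate_of[m.gene_id]
        bp = _blueprint_from_model(m, ref.genome)
        rec = TruthRecord(
            m.gene_id, fate, family_id=ref.paralog_families.get(m.gene_id)
        )
        region_len = m.end - m.start
        if fate in (GeneFate.DELETED_IN_QUERY, GeneFate.GAIN_IN_REF):
            out_parts.append(_random_dna(rng, region_len))
            qpos += region_len
        elif fate is GeneFate.PROCESSED_COPY:
            out_parts.append(_random_dna(rng, region_len))
            qpos += region_len
            processed_tail.append((m.gene_id, bp.cds()))
        else:
            edits: list[_Edit] = []
            if fate in (GeneFate.UNITARY_PSEUDO, GeneFate.FAMILY_PSEUDO):
                plan = (disruption_kinds or {}).get(m.gene_id)
                edits = _plan_disruptions(bp, plan, rng)
            region_q, events, func_cds, dis_cds = _apply_gene_edits(
                bp, edits, rng, neutral_sub_rate, chrom, qpos
            )
            rec.disruptions = events
            if m.gene_id in polymorphic_genes:
                if not edits:
                    raise ValidationError(
                        f"{m.gene_id}: polymorphic gene needs a "
                        "pseudogenic fate"
                    )
                rec.polymorphic = True
                transcripts[m.gene_id] = func_cds
            elif m.gene_id in transcripts_for:
                transcripts[m.gene_id] = dis_cds
            out_parts.append(region_q)
            if fate is GeneFate.INTACT_ORTHOLOG:
                query_genes.append(
                    QueryGene(
                        f"q_{m.gene_id}", m.gene_id, chrom,
                        qpos, qpos + len(region_q),
                    )
                )
            qpos += len(region_q)
        records[m.gene_id] = rec

    tail = gseq[cursor:]
    out_parts.append(_mutate_free(tail, rng, neutral_sub_rate))
    qpos += len(tail)

    for gene_id, cds in processed_tail:
        spacer = _random_dna(rng, 200)
        out_parts.append(spacer)
        qpos += len(spacer)
        copy, events = _disrupted_cds_copy(cds, rng, chrom, qpos)
        records[gene_id].disruptions = events
        out_parts.append(copy)
        qpos += len(copy)
    if processed_tail:
        out_parts.append(_random_dna(rng, 200))

    _shuffle_synteny(
        query_genes, records, models, shuffle_synteny_for, rng
    )

    genome = GenomeSequence(chrom, species, "".join(out_parts))
    truth = TruthTable(
        records=records,
        query_genes=query_genes,
        paralog_families=dict(ref.paralog_families),
        transcripts=transcripts,
    )
    return genome, truth


def _assign_fates(
    ref: ReferenceGeneset,
    fates: dict[GeneFate, int] | None,
    assignments: dict[str, GeneFate] | None,
    rng: np.random.Generator,
) -> dict[str, GeneFate]:
    fate_of = {m.gene_id: GeneFate.INTACT_ORTHOLOG for m in ref.models}
    if assignments:
        for gid, fate in assignments.items():
            if gid not in fate_of:
                raise ValidationError(f"unknown gene {gid!r}")
            fate_of[gid] = fate
    if not fates:
        return fate_of
    family_ids = sorted(set(ref.paralog_families.values()))
    fam_members = {
        f: sorted(
            g for g, ff in ref.paralog_families.items() if ff == f
        )
        for f in family_ids
    }
    singles = sorted(
        g for g in fate_of
        if g not in ref.paralog_families
        and (not assignments or g not in assignments)
    )
    rng.shuffle(singles)
    n_fam = fates.get(GeneFate.FAMILY_PSEUDO, 0)
    if n_fam > len(family_ids):
        raise ValidationError(
            f"requested {n_fam} FAMILY_PSEUDO but only "
            f"{len(family_ids)} tandem families exist"
        )
    for f in family_ids[:n_fam]:
        victim = fam_members[f][int(rng.integers(len(fam_members[f])))]
        fate_of[victim] = GeneFate.FAMILY_PSEUDO
    idx = 0
    for fate, count in fates.items():
        if fate in (GeneFate.FAMILY_PSEUDO, GeneFate.INTACT_ORTHOLOG):
            continue
        if idx + count > len(singles):
            raise ValidationError("requested fate counts exceed n_genes")
        for _ in range(count):
            fate_of[singles[idx]] = fate
            idx += 1
    return fate_of


@dataclass(frozen=True)
class _Edit:
    """A planted edit at a coding-orientation region offset."""

    kind: str
    offset: int
    span: int  # bases removed (deletions) or replaced in place
    replacement: str
    detail: str


def _plan_disruptions(
    bp: _Blueprint,
    plan: list[tuple[str, str]] | None,
    rng: np.random.Generator,
) -> list[_Edit]:
    auto = plan is None
    if plan is None:
        kinds = [k for k in _DISRUPTION_KINDS
                 if k != "splice_site" or bp.introns]
        plan = [(kinds[int(rng.integers(len(kinds)))], "")]
    edits = []
    for kind, detail in plan:
        if kind == "premature_stop":
            edits.append(_plan_stop(bp, rng))
        elif kind == "frameshift":
            length = int(detail[3:]) if detail.startswith("del") else int(
                rng.choice([1, 2, 4, 5, 7, 8])
            )
            try:
                edits.append(_plan_frameshift(bp, length, rng))
            except ValidationError:
                if not auto:
                    raise
                # no unambiguous cut in this gene: plant a stop instead
                edits.append(_plan_stop(bp, rng))
        elif kind == "splice_site":
            if not bp.introns:
                raise ValidationError(
                    "splice_site disruption needs a multi-exon gene"
                )
            edits.append(_plan_splice(bp, detail or "donor", rng))
        else:
            raise ValidationError(f"unknown disruption kind {kind!r}")
    edits.sort(key=lambda e: e.offset)
    for a, b in zip(edits, edits[1:]):
        if b.offset < a.offset + max(a.span, 3) + 6:
            raise ValidationError("planted disruptions too close together")
    return edits


def _plan_stop(bp: _Blueprint, rng: np.random.Generator) -> _Edit:
    """Replace a mid-gene codon with TAA, away from the near-terminal
    tolerance zone (last 10 codons) and the start codon."""
    exo = bp.exon_offsets()
    total = sum(len(e) for e in bp.exon_cds) // 3
    lo, hi = 5, total - 12
    if hi <= lo:
        raise ValidationError("gene too short to plant a premature stop")
    for _ in range(100):
        codon_i = int(rng.integers(lo, hi + 1))
        acc = 0
        for (a, b), ex in zip(exo, bp.exon_cds):
            n_c = len(ex) // 3
            if codon_i < acc + n_c:
                off = a + 3 * (codon_i - acc)
                break
            acc += n_c
        if bp.cds()[3 * codon_i : 3 * codon_i + 3] != "TAA":
            return _Edit("premature_stop", off, 3, "TAA", "TAA")
    raise ValidationError("could not plant premature stop")


def _plan_frameshift(
    bp: _Blueprint, length: int, rng: np.random.Generator
) -> _Edit:
    if length % 3 == 0:
        raise ValidationError("frameshift indel length must be != 0 mod 3")
    exo = bp.exon_offsets()
    region = ""
    for i, ex in enumerate(bp.exon_cds):
        region += ex
        if i < len(bp.introns):
            region += bp.introns[i]
    # choose a codon-aligned cut in a long-enough exon, away from edges
    # (so a frameshift transition beats end-gapping in the aligner) and
    # with a junction whose position is unambiguous under optimal
    # alignment (no equal-scoring codon-shifted placement)
    margin = 5  # codons kept intact on each side of the cut
    candidates = [
        i for i, (a, b) in enumerate(exo)
        if b - a >= length + 3 * (2 * margin + 1)
    ]
    if not candidates:
        raise ValidationError("no exon long enough for frameshift")
    for _ in range(200):
        a, b = exo[candidates[int(rng.integers(len(candidates)))]]
        n_codons = (b - a) // 3
        ci = int(rng.integers(margin,
                              n_codons - (length // 3) - margin))
        off = a + 3 * ci
        if (
            region[off - 1] != region[off + length - 1]
            and region[off] != region[off + length]
            and _junction_unambiguous(region, off, length)
            and _boundary_slide_unambiguous(region, off, length, a, b)
            and _slip_detected_at(region, off, length, a, b)
        ):
            return _Edit("frameshift", off, length, "", str(length))
    raise ValidationError("could not place junction-distinct frameshift")


def _slip_detected_at(
    region: str, off: int, length: int, exon_start: int, exon_end: int
) -> bool:
    """Verify the post-condition directly: the optimal frameshift-aware
    alignment of the edited exon places exactly one slip at the junction.

    The cheap score checks above rule out the common ambiguities; this
    runs the actual exon DP once so that rarer equal-score paths (e.g.
    gap-placement swaps between identical residues) cannot displace the
    recorded junction."""
    from .disruption_align import AlignConfig, _align_exon

    after = region[:off] + region[off + length :]
    pseg = translate_cds(region[exon_start:exon_end])
    lo = max(0, exon_start - 40)
    hi = min(len(after), exon_end - length + 40)
    result = _align_exon(pseg, after, lo, hi, AlignConfig())
    if result is None:
        return False
    slips = result[5]
    return slips == [off]


def _junction_unambiguous(region: str, off: int, length: int) -> bool:
    """True when the deletion junction cannot shift by whole codons under
    optimal frameshift-aware alignment.

    After deleting region[off:off+length], the aligner realigns the frame
    by consuming s = (3 - length) mod 3 leftover bases at the junction.
    Sliding the junction k codons left (right) swaps k true codon matches
    for hybrid-codon matches; the placement is unique iff every such swap
    scores strictly worse under the substitution matrix.
    """
    from .disruption_align import _SCORES, _translate_codon

    after = region[:off] + region[off + length :]
    s = (3 - length % 3) % 3
    for direction in (-1, +1):
        cum = 0.0
        for k in range(1, 5):
            if direction < 0:
                if off - 3 * k < 0:
                    break
                true_c = after[off - 3 * k : off - 3 * k + 3]
                alt_c = after[off - 3 * k + s : off - 3 * k + s + 3]
            else:
                true_c = after[off + s + 3 * (k - 1) :
                               off + s + 3 * (k - 1) + 3]
                alt_c = after[off + 3 * (k - 1) : off + 3 * (k - 1) + 3]
            if len(true_c) < 3 or len(alt_c) < 3:
                break
            aa = _translate_codon(true_c)
            alt_aa = _translate_codon(alt_c)
            cum += _SCORES.get((alt_aa, aa), -4.0) - \
                _SCORES.get((aa, aa), 4.0)
            if cum >= 0:
                return False
    return True


def _boundary_slide_unambiguous(
    region: str, off: int, length: int, exon_start: int, exon_end: int,
    safety: float = 3.0,
) -> bool:
    """True when a frameshift transition at the junction strictly beats
    absorbing the deletion by sliding an exon-block boundary.

    A glocal exon alignment has free genomic ends, so a deletion of L nt
    can also be 'explained' slip-free by starting the block L nt early
    (reading L nt of upstream intron and mismatching every codon before
    the junction) or ending it L nt late (mismatching every codon after).
    Both alternatives are costed exactly with the substitution matrix and
    must lose to the slip path by more than *safety*.
    """
    from .disruption_align import _SCORES, _translate_codon

    fs, go, ge = 20.0, 11.0, 1.0  # aligner defaults
    L = length
    d_aa = -(-L // 3)
    slip_cost = fs + go + (d_aa - 1) * ge
    after = region[:off] + region[off + L :]
    es = exon_start
    t_left = (off - es) // 3
    m = (exon_end - es) // 3  # protein residues of this exon

    def aa_at(k: int) -> str:
        if k < t_left:
            return _translate_codon(after[es + 3 * k : es + 3 * k + 3])
        if k < t_left + d_aa:
            return _translate_codon(region[off + 3 * (k - t_left) :
                                           off + 3 * (k - t_left) + 3])
        return _translate_codon(after[es + 3 * k - L : es + 3 * k - L + 3])

    def junk_score(aa: str, pos: int) -> float:
        codon = after[max(0, pos) : pos + 3]
        if pos < 0 or len(codon) < 3:
            return -1.0  # unknown flank: average-junk assumption
        return _SCORES.get((_translate_codon(codon), aa), -4.0)

    def self_score(aa: str) -> float:
        return _SCORES.get((aa, aa), 4.0)

    # start-slide: block begins L nt early; every codon up to (and
    # including) the deleted residues is matched against shifted junk
    slip_left = sum(self_score(aa_at(k)) for k in range(t_left)) - slip_cost
    junk_left = sum(
        junk_score(aa_at(k), es - L + 3 * k)
        for k in range(t_left + d_aa)
    )
    if slip_left <= junk_left + safety:
        return False

    # end-slide: block stays in the original frame past the junction,
    # matching every remaining codon against junk read L nt ahead
    slip_right = sum(
        self_score(aa_at(k)) for k in range(t_left + d_aa, m)
    ) - slip_cost
    junk_right = sum(
        junk_score(aa_at(k), es + 3 * k) for k in range(t_left, m)
    )
    if slip_right <= junk_right + safety:
        return False
    return True


def _plan_splice(
    bp: _Blueprint, site: str, rng: np.random.Generator
) -> _Edit:
    intr_off = bp.intron_offsets()
    k = int(rng.integers(len(intr_off)))
    a, b = intr_off[k]
    if site == "donor":
        return _Edit("splice_site", a, 2, "AT", "AT")
    return _Edit("splice_site", b - 2, 2, "GG", "GG")


def _apply_gene_edits(
    bp: _Blueprint,
    edits: list[_Edit],
    rng: np.random.Generator,
    neutral_sub_rate: float,
    chrom: str,
    query_start: int,
) -> tuple[str, list[PlantedDisruption], str, str]:
    """Mutate background, apply planted edits, map events to query coords.

    Returns (query region, events, functional spliced CDS, disrupted
    spliced CDS); the last two are mRNA surrogates for the two alleles of
    a polymorphic locus (a splice-site edit leaves the affected intron
    retained in the disrupted transcript).
    """
    exo = bp.exon_offsets()
    mut_exons: list[str] = []
    mut_introns: list[str] = []
    parts = []
    for i, ex in enumerate(bp.exon_cds):
        mex = _mutate_orf_safe(
            ex, rng, neutral_sub_rate,
            protected=_protected_sites(edits, exo[i][0], len(ex)),
        )
        mut_exons.append(mex)
        parts.append(mex)
        if i < len(bp.introns):
            mintr = _mutate_intron(bp.introns[i], rng, neutral_sub_rate)
            mut_introns.append(mintr)
            parts.append(mintr)
    region = "".join(parts)
    functional_cds = "".join(mut_exons)

    out = region
    for e in sorted(edits, key=lambda x: -x.offset):
        out = out[: e.offset] + e.replacement + out[e.offset + e.span :]

    disrupted_cds = _disrupted_transcript(
        bp, exo, mut_exons, mut_introns, edits
    )

    final_len = len(out)
    events = []
    for e in edits:
        delta = sum(
            len(o.replacement) - o.span
            for o in edits
            if o.offset < e.offset
        )
        off_f = e.offset + delta
        span_f = len(e.replacement)
        if bp.strand == "+":
            pos = query_start + off_f
        else:
            pos = query_start + final_len - off_f - span_f
        events.append(
            PlantedDisruption(e.kind, chrom, pos, e.detail)
        )
    if bp.strand == "-":
        out = _revcomp(out)
    events.sort(key=lambda ev: ev.position)
    return out, events, functional_cds, disrupted_cds


def _disrupted_transcript(
    bp: _Blueprint,
    exo: list[tuple[int, int]],
    mut_exons: list[str],
    mut_introns: list[str],
    edits: list[_Edit],
) -> str:
    exons = list(mut_exons)
    introns = list(mut_introns)
    retained: set[int] = set()
    intr_off = bp.intron_offsets()
    for e in edits:
        if e.kind == "splice_site":
            for k, (a, b) in enumerate(intr_off):
                if a <= e.offset < b:
                    retained.add(k)
                    o = e.offset - a
                    introns[k] = (
                        introns[k][:o] + e.replacement
                        + introns[k][o + e.span :]
                    )
                    break
            continue
        for i, (a, b) in enumerate(exo):
            if a <= e.offset < b:
                o = e.offset - a
                exons[i] = (
                    exons[i][:o] + e.replacement + exons[i][o + e.span :]
                )
                break
    parts = []
    for i, ex in enumerate(exons):
        parts.append(ex)
        if i in retained:
            parts.append(introns[i])
    return "".join(parts)


def _protected_sites(
    edits: list[_Edit], exon_start: int, exon_len: int
) -> set[int]:
    out: set[int] = set()
    for e in edits:
        for p in range(e.offset - 3, e.offset + e.span + 3):
            q = p - exon_start
            if 0 <= q < exon_len:
                out.add(q)
    return out


def _mutate_free(
    seq: str, rng: np.random.Generator, rate: float
) -> str:
    if rate <= 0 or not seq:
        return seq
    out = list(seq)
    n_mut = rng.binomial(len(seq), rate)
    sites = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for i in sites:
        out[int(i)] = _BASES[int(rng.integers(4))]
    return "".join(out)


def _disrupted_cds_copy(
    cds: str, rng: np.random.Generator, chrom: str, query_start: int
) -> tuple[str, list[PlantedDisruption]]:
    """An intronless processed copy carrying one premature stop."""
    n_codons = len(cds) // 3
    ci = int(rng.integers(5, max(6, n_codons - 12)))
    out = cds[: 3 * ci] + "TAA" + cds[3 * ci + 3 :]
    ev = PlantedDisruption(
        "premature_stop", chrom, query_start + 3 * ci, "TAA"
    )
    return out, [ev]


def _shuffle_synteny(
    query_genes: list[QueryGene],
    records: dict[str, TruthRecord],
    models: list[GeneModel],
    shuffle_for: tuple[str, ...],
    rng: np.random.Generator,
    k: int = 3,
) -> None:
    """Relocate the query orthologs flanking chosen loci to a decoy
    chromosome, breaking their synteny signal."""
    if not shuffle_for:
        return
    order = [m.gene_id for m in models]
    by_ref = {q.ref_id: q for q in query_genes}
    for gid in shuffle_for:
        if gid not in order:
            raise ValidationError(f"unknown gene {gid!r}")
        i = order.index(gid)
        for j in range(max(0, i - k), min(len(order), i + k + 1)):
            q = by_ref.get(order[j])
            if q is not None:
                q.chrom = "chr_shuffled"
                q.start = int(rng.integers(0, 10_000))
                q.end = q.start + 100


def build_ortholog_table(
    ref: ReferenceGeneset, truth: TruthTable
) -> OrthologTable:
    """InParanoid-like table: intact orthologs paired, everything else not."""
    pairs = [(q.ref_id, q.query_id, 1.0) for q in truth.query_genes]
    ref_universe = {m.gene_id for m in ref.models}
    query_universe = {q.query_id for q in truth.query_genes}
    return OrthologTable(pairs, ref_universe, query_universe)


# ---------------------------------------------------------------------------
# codon phylogenies with a planted nonfunctionalization switch

_CODON_TABLE = {c: translate_cds(c) for c in
                [a + b + c for a in _BASES for b in _BASES for c in _BASES]}


def _syn_damp_factor(codon: str) -> float:
    """Synonymous-acceptance damping that keeps K_A/K_S = omega exact.

    Mutations to stop codons are rejected (the reading frame must
    survive), which removes part of the nonsynonymous opportunity that
    NG86-style counting includes in its site totals. Damping synonymous
    acceptance by (reachable nonsyn)/(all nonsyn) per codon equalizes
    the per-site realized rates, so a neutral simulation measures
    omega = 1 without bias.
    """
    syn9 = stop9 = 0
    aa = _CODON_TABLE[codon]
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in _STOPS:
                stop9 += 1
            elif _CODON_TABLE[mut] == aa:
                syn9 += 1
    return (9 - syn9 - stop9) / (9 - syn9)


_SYN_DAMP = {c: _syn_damp_factor(c) for c in _SENSE_CODONS}


def simulate_codon_phylogeny(
    tree: SpeciesTree,
    omega_constrained: float,
    codon_count: int,
    switch_branch: str | tuple[str, ...] | None = None,
    t_n: float | None = None,
    neutral_rate: float = 0.0011,
    n_disruptions: int = 1,
    seed: int = 0,
) -> tuple[dict[str, str], TruthRecord]:
    """Evolve a codon sequence along a dated species tree.

    Substitutions are attempted at *neutral_rate* per site per MY (uniform
    across target bases); synonymous changes are always accepted,
    nonsynonymous ones with probability omega (the branch's K_A/K_S), and
    changes creating stop codons are rejected. On the lineage identified by
    *switch_branch* (a leaf label, or a tuple of labels naming the stem of
    their minimal clade), omega switches to 1 at *t_n* MY before present and
    *n_disruptions* premature stop codons are planted at the switch,
    inherited by every descendant leaf.
    """
    if not 0 < omega_constrained <= 1:
        raise ValidationError("omega_constrained must be in (0, 1]")
    rng = _rng(seed, 3)
    root_cds = _random_cds(rng, codon_count)
    root_seq = [root_cds[i : i + 3] for i in range(0, len(root_cds), 3)]

    switch_node = None
    if switch_branch is not None:
        labels = (
            [switch_branch]
            if isinstance(switch_branch, str)
            else list(switch_branch)
        )
        switch_node = tree.mrca(labels)
        parent = switch_node.parent_node
        if parent is None:
            raise ValidationError("switch branch cannot be the root")
        top, bottom = tree.age_of(parent), tree.age_of(switch_node)
        if t_n is None or not bottom <= t_n <= top:
            raise ValidationError(
                f"t_n must lie within the switch branch "
                f"[{bottom}, {top}] MY"
            )

    planted_codons: list[int] = []
    leaves: dict[str, str] = {}

    def evolve_branch(seq: list[str], node, inactivated: bool) -> None:
        parent = node.parent_node
        seq = list(seq)
        if parent is not None:
            top, bottom = tree.age_of(parent), tree.age_of(node)
            if node is switch_node:
                _evolve_segment(seq, top - t_n, omega_constrained, rng,
                                neutral_rate)
                for _ in range(n_disruptions):
                    ci = int(rng.integers(5, codon_count - 5))
                    seq[ci] = "TAA"
                    planted_codons.append(ci)
                _evolve_segment(seq, t_n - bottom, 1.0, rng, neutral_rate,
                                allow_stop_context=True)
                inactivated = True
            else:
                om = 1.0 if inactivated else omega_constrained
                _evolve_segment(seq, top - bottom, om, rng, neutral_rate,
                                allow_stop_context=inactivated)
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(seq)
        else:
            for child in node.child_nodes():
                evolve_branch(seq, child, inactivated)

    evolve_branch(root_seq, tree.tree.seed_node, False)

    branch_label = None
    if switch_node is not None:
        branch_label = "+".join(sorted(tree.leaves_under(switch_node)))
    rec = TruthRecord(
        "locus", GeneFate.UNITARY_PSEUDO if switch_node is not None
        else GeneFate.INTACT_ORTHOLOG,
        disruptions=[
            PlantedDisruption("premature_stop", "aln", 3 * ci, "TAA")
            for ci in planted_codons
        ] if switch_node is not None else [],
        branch=branch_label,
        t_n=t_n if switch_node is not None else None,
    )
    return leaves, rec


def _evolve_segment(
    seq: list[str],
    duration: float,
    omega: float,
    rng: np.random.Generator,
    neutral_rate: float,
    allow_stop_context: bool = False,
) -> None:
    """Apply Poisson(rate * 3L * t) substitution attempts in place.

    Planted stop codons are frozen; point mutations never create stops so
    the open reading frame survives on functional lineages (and stays
    analyzable on dead ones).
    """
    if duration <= 0:
        return
    n_nt = 3 * len(seq)
    n_attempts = rng.poisson(neutral_rate * n_nt * duration)
    for _ in range(n_attempts):
        site = int(rng.integers(n_nt))
        ci, within = divmod(site, 3)
        codon = seq[ci]
        if codon in _STOPS:
            continue  # planted disruption is immutable
        new_base = _BASES[int(rng.integers(4))]
        if new_base == codon[within]:
            continue
        new_codon = codon[:within] + new_base + codon[within + 1 :]
        if new_codon in _STOPS:
            continue
        if _CODON_TABLE[new_codon] == _CODON_TABLE[codon]:
            if rng.random() < _SYN_DAMP[codon]:
                seq[ci] = new_codon
        elif rng.random() < omega:
            seq[ci] = new_codon


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(
    pops: list[str],
    allele_freqs: dict[str, float] | float,
    inbreeding_F: float = 0.0,
    n: int | dict[str, int] = 100,
    snp_id: str = "snp1",
    seed: int = 0,
) -> list[GenotypeCounts]:
    """Multinomial genotype counts under HWE with inbreeding F.

    Genotype probabilities are (p^2 + Fpq, 2pq(1 - F), q^2 + Fpq).
    """
    rng = _rng(seed, 4)
    out = []
    for pop in pops:
        p = allele_freqs[pop] if isinstance(allele_freqs, dict) \
            else float(allele_freqs)
        if not 0 <= p <= 1:
            raise ValidationError(f"{pop}: allele frequency outside [0,1]")
        q = 1 - p
        f_min = -min(p / q if q else np.inf, q / p if p else np.inf)
        if not f_min <= inbreeding_F <= 1:
            raise ValidationError(
                f"{pop}: F={inbreeding_F} outside [{f_min:.3f}, 1]"
            )
        probs = np.array([
            p * p + inbreeding_F * p * q,
            2 * p * q * (1 - inbreeding_F),
            q * q + inbreeding_F * p * q,
        ])
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        size = n[pop] if isinstance(n, dict) else int(n)
        counts = rng.multinomial(size, probs)
        out.append(GenotypeCounts(pop, snp_id, *map(int, counts)))
    return out


# ---------------------------------------------------------------------------
# annotation DAGs with planted enrichment

def simulate_annotations(
    n_genes: int = 1000,
    n_terms: int = 50,
    planted_term: str = "T0049",
    fold_enrichment: float = 5.0,
    study_size: int = 20,
    background_freq: float = 0.05,
    terms_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> tuple[AnnotationDAG, set[str], set[str]]:
    """An is_a DAG plus study/population gene sets with one planted
    over-represented term.

    The planted term is a leaf (no children) carried by
    round(background_freq * n_genes) population genes; the study set
    contains round(fold * background_freq * study_size) carriers, so its
    study-set frequency is fold_enrichment times the background frequency
    up to rounding.
    """
    if fold_enrichment < 1:
        raise ValidationError("fold_enrichment must be >= 1")
    rng = _rng(seed, 5)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    if planted_term not in terms:
        raise ValidationError(f"planted term {planted_term!r} not in DAG")
    parents: dict[str, set[str]] = {terms[0]: set()}
    namespace = {t: "molecular_function" for t in terms}
    for i, t in enumerate(terms[1:], start=1):
        pool = [x for x in terms[:i] if x != planted_term]
        parents[t] = {pool[int(rng.integers(len(pool)))]} if pool else set()
        if len(pool) > 1 and rng.random() < 0.2:
            extra = pool[int(rng.integers(len(pool)))]
            parents[t].add(extra)

    genes = [f"gene{i:04d}" for i in range(n_genes)]
    k_pop = round(background_freq * n_genes)
    k_study = round(fold_enrichment * background_freq * study_size)
    if k_study > min(k_pop, study_size) or \
            study_size - k_study > n_genes - k_pop:
        raise ValidationError(
            "fold_enrichment infeasible for the given set sizes"
        )
    carriers = set(
        str(g) for g in rng.choice(genes, size=k_pop, replace=False)
    )
    other_terms = [t for t in terms if t != planted_term]
    gene_terms: dict[str, set[str]] = {}
    for g in genes:
        k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
        chosen = rng.choice(other_terms, size=k, replace=False)
        gene_terms[g] = {str(t) for t in chosen}
        if g in carriers:
            gene_terms[g].add(planted_term)

    carrier_list = sorted(carriers)
    non_carrier_list = sorted(set(genes) - carriers)
    rng.shuffle(carrier_list)
    rng.shuffle(non_carrier_list)
    study = set(carrier_list[:k_study]) | set(
        non_carrier_list[: study_size - k_study]
    )
    dag = AnnotationDAG(parents, gene_terms, namespace)
    return dag, study, set(genes)
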