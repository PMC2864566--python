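"""Domain types and on-disk formats for the unitary-pseudogene pipeline.

Internal coordinates are 0-based half-open throughout the package. GFF3 I/O
converts to/from the format's 1-based closed convention; BED output stays
0-based half-open. Minus-strand genes are stored with ascending genomic exon
coordinates; biological (transcription) order is derived on demand.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "EvidenceClass",
    "GenomeSequence",
    "GeneModel",
    "OrthologTable",
    "SpeciesTree",
    "GenotypeCounts",
    "AnnotationDAG",
    "GffParseError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_newick_dated",
    "read_genotype_table",
    "write_genotype_table",
    "read_obo_lite",
    "write_obo_lite",
    "translate_cds",
]

_DNA_ALPHABET = frozenset("ACGTN")


class GffParseError(ValueError):
    """A malformed GFF3 line; message names the offending line number."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class EvidenceClass(enum.Enum):
    """Annotation support for a reference gene, best to worst."""

    NAMED_GENE = 0
    SPLICED_CDNA = 1
    UNSPLICED_CDNA = 2
    PREDICTED = 3

    @property
    def rank(self) -> int:
        return self.value


@dataclass(frozen=True)
class GenomeSequence:
    seq_id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"{self.seq_id}: empty sequence")
        bad = set(self.residues) - _DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.seq_id}: non-DNA characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code; '*' marks stop codons."""
    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


@dataclass
class GeneModel:
    """A multi-exon protein-coding gene with genomic coordinates.

    Exons are genomic intervals (0-based half-open), stored ascending and
    non-overlapping regardless of strand.
    """

    gene_id: str
    species: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    protein: str
    evidence_class: EvidenceClass = EvidenceClass.NAMED_GENE

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        for (s, e) in self.exons:
            if not 0 <= s < e:
                raise ValidationError(f"{self.gene_id}: bad exon ({s},{e})")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if b > c:
                raise ValidationError(
                    f"{self.gene_id}: exons not sorted/disjoint"
                )
        if (
            self.evidence_class is EvidenceClass.UNSPLICED_CDNA
            and len(self.exons) > 1
        ):
            raise ValidationError(
                f"{self.gene_id}: UNSPLICED_CDNA must be single-exon"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def intronless(self) -> bool:
        return len(self.exons) == 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_biological(self) -> list[tuple[int, int]]:
        """Exons in transcription order (reversed for minus strand)."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals, ascending."""
        return [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        ]

    def spliced_cds(self, genome: GenomeSequence) -> str:
        """Concatenated coding sequence in reading orientation."""
        chunks = [genome.residues[s:e] for s, e in self.exons]
        cds = "".join(chunks)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def validate_functional(self, genome: GenomeSequence) -> None:
        """Check the coding invariants of a functional gene."""
        cds = self.spliced_cds(genome)
        if len(cds) % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {len(cds)} not a multiple of 3"
            )
        aa = translate_cds(cds)
        if "*" in aa[:-1]:
            raise ValidationError(f"{self.gene_id}: internal stop codon")


@dataclass
class OrthologTable:
    """InParanoid-style pairwise ortholog assignments with id universes."""

    pairs: list[tuple[str, str, float]]
    ref_universe: set[str]
    query_universe: set[str]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for ref_id, query_id, score in self.pairs:
            if score < 0:
                raise ValidationError(f"negative score for {ref_id}")
            if ref_id not in self.ref_universe:
                raise ValidationError(f"unknown reference id {ref_id!r}")
            if query_id not in self.query_universe:
                raise ValidationError(f"unknown query id {query_id!r}")
            key = (ref_id, query_id)
            if key in seen:
                raise ValidationError(f"duplicate ortholog pair {key!r}")
            seen.add(key)

    def paired_ref_ids(self) -> set[str]:
        return {r for r, _, _ in self.pairs}

    def query_ortholog_of(self, ref_id: str) -> str | None:
        best = None
        best_score = -math.inf
        for r, q, s in self.pairs:
            if r == ref_id and s > best_score:
                best, best_score = q, s
        return best


@dataclass
class SpeciesTree:
    """Rooted ultrametric species tree; node ages in MY (leaves at 0)."""

    tree: dendropy.Tree
    ages: dict[dendropy.Node, float]

    def age_of(self, node: dendropy.Node) -> float:
        return self.ages[node]

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def mrca(self, labels: list[str]) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(x) for x in labels]
        missing = [l for l, t in zip(labels, taxa) if t is None]
        if missing:
            raise ValidationError(f"species not in tree: {missing}")
        if len(taxa) == 1:
            return self.tree.find_node_with_taxon_label(labels[0])
        return self.tree.mrca(taxa=taxa)

    def leaves_under(self, node: dendropy.Node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}


@dataclass(frozen=True)
class GenotypeCounts:
    """Biallelic genotype counts for one SNP in one population."""

    population: str
    snp_id: str
    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValidationError("negative genotype count")
        if self.n == 0:
            raise ValidationError(
                f"{self.population}/{self.snp_id}: zero individuals"
            )

    @property
    def n(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa

    @property
    def p_hat(self) -> float:
        """Sample frequency of the A allele."""
        return (2 * self.n_AA + self.n_Aa) / (2 * self.n)


@dataclass
class AnnotationDAG:
    """is_a term hierarchy plus direct gene-to-term assignments."""

    parents: dict[str, set[str]]
    gene_terms: dict[str, set[str]]
    namespace: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValidationError(
                        f"term {term}: unknown parent {p!r}"
                    )
        for gene, terms in self.gene_terms.items():
            for t in terms:
                if t not in self.parents:
                    raise ValidationError(
                        f"gene {gene}: annotated to unknown term {t!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.parents}
        for start in self.parents:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self.parents[start]))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    color[node] = BLACK
                    stack.pop()
                elif color[nxt] == GRAY:
                    raise ValidationError(f"cycle through term {nxt!r}")
                elif color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(self.parents[nxt])))

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of *term* (term itself excluded)."""
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, species: str = "") -> dict[str, GenomeSequence]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = GenomeSequence(rec.id, species, str(rec.seq).upper())
    return out


def write_fasta(path, seqs) -> None:
    """Write sequences wrapped at 60 columns.

    Accepts GenomeSequence values or (id, sequence) pairs.
    """
    records = []
    for item in seqs:
        if isinstance(item, GenomeSequence):
            records.append(
                SeqRecord(Seq(item.residues), id=item.seq_id, description="")
            )
        else:
            seq_id, residues = item
            records.append(
                SeqRecord(Seq(residues), id=seq_id, description="")
            )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 gene models

_GFF_COLS = 9


def read_gene_models(
    gff3_path, fasta_path, species: str = "reference"
) -> tuple[list[GeneModel], dict[str, GenomeSequence]]:
    """Read gene models (gene + CDS rows) and their genome.

    GFF3 is 1-based closed; coordinates are converted to 0-based half-open.
    Proteins are derived by translating the spliced CDS and genes flagged
    functional (any class except PREDICTED) are validated.
    """
    genome = read_fasta(fasta_path, species=species)
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise GffParseError(
                    f"line {lineno}: expected {_GFF_COLS} columns, "
                    f"got {len(cols)}"
                )
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GffParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from None
            if start1 < 1 or end1 < start1:
                raise GffParseError(f"line {lineno}: bad interval")
            attrs = _parse_attrs(attrs_s, lineno)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise GffParseError(f"line {lineno}: gene without ID")
                ev = attrs.get("evidence_class", "NAMED_GENE")
                try:
                    evc = EvidenceClass[ev]
                except KeyError:
                    raise GffParseError(
                        f"line {lineno}: unknown evidence_class {ev!r}"
                    ) from None
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "evidence": evc,
                    "exons": [],
                }
                order.append(gid)
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent is None or parent not in genes:
                    raise GffParseError(
                        f"line {lineno}: CDS without known Parent"
                    )
                genes[parent]["exons"].append((start1 - 1, end1))
    models = []
    for gid in order:
        info = genes[gid]
        if not info["exons"]:
            raise GffParseError(f"gene {gid}: no CDS rows")
        exons = sorted(info["exons"])
        chrom_seq = genome.get(info["chrom"])
        if chrom_seq is None:
            raise ValidationError(f"gene {gid}: chromosome not in FASTA")
        model = GeneModel(
            gene_id=gid,
            species=species,
            chrom=info["chrom"],
            strand=info["strand"],
            exons=exons,
            protein="",
            evidence_class=info["evidence"],
        )
        if info["evidence"] is not EvidenceClass.PREDICTED:
            model.validate_functional(chrom_seq)
        aa = translate_cds(model.spliced_cds(chrom_seq))
        model.protein = aa[:-1] if aa.endswith("*") else aa
        models.append(model)
    return models, genome


def write_gene_models(gff3_path, models: list[GeneModel]) -> None:
    """Write gene models back to GFF3 (1-based closed)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        "unipseudo",
                        "gene",
                        str(m.start + 1),
                        str(m.end),
                        ".",
                        m.strand,
                        ".",
                        f"ID={m.gene_id};"
                        f"evidence_class={m.evidence_class.name}",
                    ]
                )
                + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(
                        [
                            m.chrom,
                            "unipseudo",
                            "CDS",
                            str(s + 1),
                            str(e),
                            ".",
                            m.strand,
                            "0",
                            f"Parent={m.gene_id}",
                        ]
                    )
                    + "\n"
                )


def _parse_attrs(attrs_s: str, lineno: int) -> dict[str, str]:
    out = {}
    for part in attrs_s.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GffParseError(f"line {lineno}: bad attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


# ---------------------------------------------------------------------------
# Ortholog table (TSV)

def read_ortholog_table(
    tsv_path, ref_ids=None, query_ids=None
) -> OrthologTable:
    """Read a TSV of (ref_id, query_id, score) ortholog pairs.

    Universes default to the ids present in the table; pass explicit id
    collections to record genes outside any pair (the unmatched ones the
    screen is after).
    """
    pairs: list[tuple[str, str, float]] = []
    with open(tsv_path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                if cols[:3] != ["ref_id", "query_id", "score"]:
                    raise ValidationError(
                        f"line {lineno}: expected header "
                        "ref_id/query_id/score"
                    )
                continue
            if len(cols) != 3:
                raise ValidationError(f"line {lineno}: expected 3 columns")
            pairs.append((cols[0], cols[1], float(cols[2])))
    ref_universe = set(ref_ids) if ref_ids is not None else {
        r for r, _, _ in pairs
    }
    query_universe = set(query_ids) if query_ids is not None else {
        q for _, q, _ in pairs
    }
    return OrthologTable(pairs, ref_universe, query_universe)


def write_ortholog_table(tsv_path, table: OrthologTable) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("ref_id\tquery_id\tscore\n")
        for r, q, s in table.pairs:
            fh.write(f"{r}\t{q}\t{s:g}\n")


# ---------------------------------------------------------------------------
# Newick species tree with ages

def read_newick_dated(path, tolerance: float = 1e-6) -> SpeciesTree:
    """Read a Newick tree with branch lengths in MY and derive node ages.

    The tree must be ultrametric: all leaves equidistant from the root
    within *tolerance* MY. Ages are root-to-leaf depths subtracted from the
    maximum depth, so leaves sit at age 0 and the root at the tree height.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return species_tree_from_dendropy(tree, tolerance=tolerance)


def species_tree_from_dendropy(
    tree: dendropy.Tree, tolerance: float = 1e-6
) -> SpeciesTree:
    tree.is_rooted = True
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leaf_depths = {
        lf.taxon.label: depth[lf] for lf in tree.leaf_node_iter()
    }
    height = max(leaf_depths.values(), default=0.0)
    for label, d in leaf_depths.items():
        if abs(d - height) > tolerance:
            raise ValidationError(
                f"tree not ultrametric: leaf {label!r} at depth {d}, "
                f"height {height}"
            )
    ages = {node: height - d for node, d in depth.items()}
    for lf in tree.leaf_node_iter():
        ages[lf] = 0.0
    return SpeciesTree(tree=tree, ages=ages)


# ---------------------------------------------------------------------------
# Genotype tables (TSV)

_GENO_HEADER = ["population", "snp_id", "n_AA", "n_Aa", "n_aa"]


def read_genotype_table(tsv_path) -> list[GenotypeCounts]:
    out = []
    with open(tsv_path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                if cols != _GENO_HEADER:
                    raise ValidationError(
                        f"line {lineno}: expected header {_GENO_HEADER}"
                    )
                header = cols
                continue
            pop, snp, a, b, c = cols
            out.append(GenotypeCounts(pop, snp, int(a), int(b), int(c)))
    return out


def write_genotype_table(tsv_path, rows: list[GenotypeCounts]) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(_GENO_HEADER) + "\n")
        for r in rows:
            fh.write(
                f"{r.population}\t{r.snp_id}\t{r.n_AA}\t{r.n_Aa}\t{r.n_aa}\n"
            )


# ---------------------------------------------------------------------------
# OBO-lite annotation DAG

def read_obo_lite(obo_path, assoc_path) -> AnnotationDAG:
    """Read a minimal OBO (id / is_a / namespace lines) plus a gene→term TSV."""
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    current = None
    with open(obo_path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                current = None
            elif line.startswith("id:"):
                current = line[3:].strip()
                parents.setdefault(current, set())
            elif line.startswith("is_a:") and current is not None:
                parent = line[5:].split("!")[0].strip()
                parents[current].add(parent)
            elif line.startswith("namespace:") and current is not None:
                namespace[current] = line[10:].strip()
    gene_terms: dict[str, set[str]] = {}
    with open(assoc_path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            gene_terms.setdefault(gene, set()).add(term)
    return AnnotationDAG(parents, gene_terms, namespace)


def write_obo_lite(obo_path, assoc_path, dag: AnnotationDAG) -> None:
    with open(obo_path, "w") as fh:
        for term in sorted(dag.parents):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            if term in dag.namespace:
                fh.write(f"namespace: {dag.namespace[term]}\n")
            for p in sorted(dag.parents[term]):
                fh.write(f"is_a: {p}\n")
            fh.write("\n")
    with open(assoc_path, "w") as fh:
        for gene in sorted(dag.gene_terms):
            for term in sorted(dag.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
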