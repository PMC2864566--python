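"""Find reference proteins without query orthologs and map them to the
query genome.

The mapper is a deliberately small translated-search stand-in for BLAT:
exact amino-acid k-mer seeds over the six-frame translation of the genome,
chained colinearly per strand with an intron-sized gap bound, reported as
genomic windows ranked by chained protein coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io_model import GenomeSequence, OrthologTable, ValidationError

__all__ = [
    "GenomicWindow",
    "find_unmatched_reference_proteins",
    "map_protein_to_genome",
    "classify_mappability",
]

DEFAULT_SEED_LEN = 5
DEFAULT_MIN_COVERAGE = 0.5
DEFAULT_GAP_BOUND = 50_000
_WINDOW_PAD = 200
_MAX_WINDOWS = 5
# per excess nt beyond the protein's own length; introns cost little but
# chimeric chains across tandem paralogs are dominated by compact ones
_SPAN_PENALTY = 0.01


def find_unmatched_reference_proteins(
    orthologs: OrthologTable,
) -> list[str]:
    """Reference ids that appear in no ortholog pair, sorted."""
    return sorted(orthologs.ref_universe - orthologs.paired_ref_ids())


@dataclass
class GenomicWindow:
    """A candidate mapping of a protein onto the query genome."""

    chrom: str
    start: int
    end: int
    strand: str
    coverage: float
    score: float

    def as_tuple(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


def map_protein_to_genome(
    protein: str,
    genome: GenomeSequence,
    seed_len: int = DEFAULT_SEED_LEN,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    gap_bound: int = DEFAULT_GAP_BOUND,
) -> list[GenomicWindow]:
    """Candidate genomic windows for *protein*, best first.

    Seeds are exact amino-acid *seed_len*-mers between the protein and each
    of the six reading frames; same-strand seeds colinear in both protein
    and genome within *gap_bound* nt are chained by dynamic programming
    maximizing covered protein residues (with a tiny span penalty so
    compact chains win ties). Chains covering >= *min_coverage* of the
    protein become windows; ordering is (score desc, chrom, start).
    """
    if len(genome) == 0:
        raise ValidationError("empty genome")
    if len(protein) < seed_len:
        raise ValidationError("protein shorter than seed length")

    kmer_index: dict[str, list[int]] = {}
    for j in range(len(protein) - seed_len + 1):
        kmer_index.setdefault(protein[j : j + seed_len], []).append(j)

    windows: list[GenomicWindow] = []
    glen = len(genome)
    for strand in "+-":
        seq = genome.residues if strand == "+" else str(
            Seq(genome.residues).reverse_complement()
        )
        seeds: list[tuple[int, int]] = []  # (nt pos in strand space, aa pos)
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate())
            for i in range(len(aa) - seed_len + 1):
                for j in kmer_index.get(aa[i : i + seed_len], ()):
                    seeds.append((frame + 3 * i, j))
        windows.extend(
            _chain_windows(
                seeds, strand, glen, genome.seq_id, len(protein),
                seed_len, min_coverage, gap_bound,
            )
        )
    windows.sort(key=lambda w: (-w.score, w.chrom, w.start))
    return windows


def _chain_windows(
    seeds: list[tuple[int, int]],
    strand: str,
    glen: int,
    chrom: str,
    plen: int,
    k: int,
    min_coverage: float,
    gap_bound: int,
) -> list[GenomicWindow]:
    out: list[GenomicWindow] = []
    remaining = sorted(seeds)
    for _ in range(_MAX_WINDOWS):
        if not remaining:
            break
        chain = _best_chain(remaining, k, gap_bound)
        if not chain:
            break
        covered = _covered_residues(chain, k)
        coverage = covered / plen
        g_lo = chain[0][0]
        g_hi = chain[-1][0] + 3 * k
        if coverage >= min_coverage:
            if strand == "+":
                start, end = g_lo, g_hi
            else:
                start, end = glen - g_hi, glen - g_lo
            start = max(0, start - _WINDOW_PAD)
            end = min(glen, end + _WINDOW_PAD)
            span_excess = max(0, (g_hi - g_lo) - 3 * plen)
            out.append(
                GenomicWindow(
                    chrom, start, end, strand, coverage,
                    covered - _SPAN_PENALTY * span_excess,
                )
            )
        used = set(chain)
        remaining = [
            s for s in remaining
            if s not in used and not g_lo <= s[0] < g_hi
        ]
    return out


def _best_chain(
    seeds: list[tuple[int, int]], k: int, gap_bound: int
) -> list[tuple[int, int]]:
    """Highest-coverage colinear chain (O(n^2) DP over sorted seeds)."""
    n = len(seeds)
    val = [float(k)] * n  # penalized chain score ending at each seed
    back = [-1] * n
    best_i, best_score = -1, 0.0
    for i, (gi, pi) in enumerate(seeds):
        for j in range(i):
            gj, pj = seeds[j]
            if pj >= pi or gj >= gi:
                continue
            g_gap = gi - (gj + 3 * k)
            if g_gap > gap_bound:
                continue
            if gi - gj < 3 * (pi - pj) - 60:
                continue  # genome may lag the protein only by small indels
            gained = min(k, pi - pj)
            extra_span = max(0, (gi - gj) - 3 * (pi - pj))
            cand = val[j] + gained - _SPAN_PENALTY * extra_span
            if cand > val[i]:
                val[i] = cand
                back[i] = j
        if val[i] > best_score:
            best_score, best_i = val[i], i
    if best_i < 0:
        return []
    chain = []
    i = best_i
    while i >= 0:
        chain.append(seeds[i])
        i = back[i]
    return chain[::-1]


def _covered_residues(chain: list[tuple[int, int]], k: int) -> int:
    covered = 0
    prev_end = -1
    for _, p in chain:
        lo = max(p, prev_end)
        covered += max(0, p + k - lo)
        prev_end = max(prev_end, p + k)
    return covered


def classify_mappability(
    windows_per_protein: dict[str, list[GenomicWindow]],
) -> dict[str, str]:
    """ALIGNABLE iff at least one window passed the coverage gate."""
    return {
        pid: "ALIGNABLE" if windows else "UNALIGNABLE"
        for pid, windows in windows_per_protein.items()
    }
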