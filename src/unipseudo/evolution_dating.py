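"""Dating pseudogenization events.

Three ingredients: Fitch parsimony reconstruction of ancestral sequences on
a dated species tree; lineage-wise K_A/K_S via the Nei-Gojobori (1986)
method with Jukes-Cantor correction; and Dollo placement of shared
disruptive mutations (a derived disruption arises once and never reverts,
so the event sits on the stem of the minimal clade containing every species
that carries it).

The nonfunctionalization time T_N of a pseudogene assumes nonsynonymous
sites are constrained (K_A/K_S = omega_bar, the background ratio) until
inactivation and fully neutral afterwards. Over a focal branch of length T
this mixes into the observed focal-lineage ratio

    omega_1 = [omega_bar * (T - T_N) + T_N] / T

which solves to T_N = T * (omega_1 - omega_bar) / (1 - omega_bar).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy

from .io_model import SpeciesTree, ValidationError, translate_cds

__all__ = [
    "LineageRates",
    "NonfunctionalizationEstimate",
    "DolloPlacement",
    "fitch_ancestral_reconstruction",
    "nei_gojobori_kaks",
    "lineage_omega",
    "place_disruption",
    "estimate_tn",
    "HUMAN_CHIMP_SPLIT_MY",
]

HUMAN_CHIMP_SPLIT_MY = 6.6  # default calibration for the focal branch

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_AA = {
    c: translate_cds(c)
    for c in (a + b + d for a in _BASES for b in _BASES for d in _BASES)
}


# ---------------------------------------------------------------------------
# Fitch parsimony

def fitch_ancestral_reconstruction(
    alignment: dict[str, str], tree: SpeciesTree
) -> tuple[dict[str, str], int]:
    """Per-site Fitch parsimony ancestral states.

    Ties are broken by preferring the parent's state, then the
    alphabetically first state; the root takes the alphabetical minimum of
    its state set. Returns (node label -> sequence, parsimony count);
    internal nodes are labelled by the sorted '+'-joined labels of their
    leaves.

    Raises when an alignment species is missing from the tree or
    sequences are unequal in length.
    """
    if not alignment:
        raise ValidationError("empty alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValidationError("aligned sequences differ in length")
    n_sites = lengths.pop()
    tree_leaves = set(tree.leaf_labels())
    missing = set(alignment) - tree_leaves
    if missing:
        raise ValidationError(
            f"species not in tree: {sorted(missing)}"
        )

    nodes = list(tree.tree.postorder_node_iter())
    sets: dict[dendropy.Node, list[frozenset[str]]] = {}
    changes = 0
    for node in nodes:
        if node.is_leaf():
            seq = alignment[node.taxon.label]
            sets[node] = [frozenset(c) for c in seq]
        else:
            kids = node.child_nodes()
            merged = []
            for i in range(n_sites):
                inter = frozenset.intersection(
                    *(sets[k][i] for k in kids)
                )
                if inter:
                    merged.append(inter)
                else:
                    merged.append(
                        frozenset.union(*(sets[k][i] for k in kids))
                    )
                    changes += len(kids) - 1
            sets[node] = merged

    states: dict[dendropy.Node, list[str]] = {}
    out: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            states[node] = list(alignment[node.taxon.label])
            continue
        parent = node.parent_node
        assigned = []
        for i in range(n_sites):
            options = sets[node][i]
            if parent is not None and states[parent][i] in options:
                assigned.append(states[parent][i])
            else:
                assigned.append(min(options))
        states[node] = assigned
        label = "+".join(sorted(
            lf.taxon.label for lf in node.leaf_iter()
        ))
        out[label] = "".join(assigned)
    for label, seq in alignment.items():
        out[label] = seq
    return out, changes


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) K_A/K_S

_SITES_CACHE: dict[str, tuple[float, float]] = {}
_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a codon.

    Mutations to stop codons count as nonsynonymous, the standard NG86
    convention (also used by MEGA and Biopython).
    """
    cached = _SITES_CACHE.get(codon)
    if cached is not None:
        return cached
    aa = _AA[codon]
    per_pos_syn = []
    for pos in range(3):
        n_syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in _STOPS and _AA[mut] == aa:
                n_syn += 1
        per_pos_syn.append(n_syn / 3.0)
    syn = sum(per_pos_syn)
    _SITES_CACHE[codon] = (syn, 3.0 - syn)
    return _SITES_CACHE[codon]


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over all mutational
    pathways between two codons, weighted equally; a step to or through a
    stop codon counts as nonsynonymous (NG86 convention)."""
    cached = _PATH_CACHE.get((c1, c2))
    if cached is not None:
        return cached
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot, nonsyn_tot, n_paths = 0.0, 0.0, 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn, nonsyn = 0.0, 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if (
                cur not in _STOPS
                and nxt not in _STOPS
                and _AA[nxt] == _AA[cur]
            ):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        syn_tot += syn
        nonsyn_tot += nonsyn
        n_paths += 1
    out = (syn_tot / n_paths, nonsyn_tot / n_paths)
    _PATH_CACHE[(c1, c2)] = out
    return out


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    saturated: bool = False

    @property
    def omega(self) -> float | None:
        if self.ks <= 0:
            return None
        return self.ka / self.ks


def nei_gojobori_kaks(cds1: str, cds2: str) -> KaKsResult:
    """NG86 with Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p).

    Codon columns containing a stop or a gap in either sequence are
    excluded (disrupted positions are 'remote from' the rates of
    interest). Proportions above 3/4 are flagged saturated and left at
    the uncorrected proportion.
    """
    if len(cds1) != len(cds2):
        raise ValidationError("sequence length mismatch")
    if len(cds1) % 3 != 0:
        raise ValidationError("length not a multiple of 3")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for i in range(0, len(cds1), 3):
        c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
        if (
            c1 in _STOPS or c2 in _STOPS
            or "-" in c1 or "-" in c2
            or "N" in c1 or "N" in c2
        ):
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        sd, nd = _pathway_differences(c1, c2)
        s_diff += sd
        n_diff += nd

    def correct(p: float) -> tuple[float, bool]:
        if p <= 0:
            return 0.0, False
        if p >= 0.75:
            return p, True
        return -0.75 * math.log(1 - 4 * p / 3), False

    ps = s_diff / s_sites if s_sites > 0 else 0.0
    pn = n_diff / n_sites if n_sites > 0 else 0.0
    ks, sat_s = correct(ps)
    ka, sat_n = correct(pn)
    return KaKsResult(ka=ka, ks=ks, saturated=sat_s or sat_n)


# ---------------------------------------------------------------------------
# lineage rates

@dataclass
class BranchRate:
    child: str  # node label (leaf name or '+'-joined clade)
    parent: str
    ka: float
    ks: float
    saturated: bool = False

    @property
    def omega(self) -> float | None:
        """K_A/K_S; None (undefined) when K_S = 0."""
        if self.ks <= 0:
            return None
        return self.ka / self.ks


@dataclass
class LineageRates:
    branches: list[BranchRate]

    def branch_for(self, label: str) -> BranchRate:
        for b in self.branches:
            if b.child == label:
                return b
        raise KeyError(label)

    def mean_omega(self, exclude: tuple[str, ...] = ()) -> float | None:
        """Unweighted mean of defined branch omega values, excluding the
        named child labels (typically the focal lineage)."""
        vals = [
            b.omega for b in self.branches
            if b.child not in exclude and b.omega is not None
        ]
        if not vals:
            return None
        return sum(vals) / len(vals)


def lineage_omega(
    alignment: dict[str, str], tree: SpeciesTree
) -> LineageRates:
    """Per-branch K_A and K_S from Fitch-reconstructed ancestors."""
    seqs, _ = fitch_ancestral_reconstruction(alignment, tree)

    def label(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "+".join(sorted(
            lf.taxon.label for lf in node.leaf_iter()
        ))

    branches = []
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        res = nei_gojobori_kaks(seqs[label(parent)], seqs[label(node)])
        branches.append(
            BranchRate(
                child=label(node), parent=label(parent),
                ka=res.ka, ks=res.ks, saturated=res.saturated,
            )
        )
    return LineageRates(branches)


# ---------------------------------------------------------------------------
# Dollo placement

@dataclass(frozen=True)
class DolloPlacement:
    branch: str  # child-node label of the stem branch
    clade_leaves: tuple[str, ...]
    homoplasic: bool  # an 'absent' species falls inside the clade
    conflicting_species: tuple[str, ...] = ()


def place_disruption(
    pattern: dict[str, str], tree: SpeciesTree
) -> DolloPlacement:
    """Place a disruption on the stem of the minimal clade containing all
    species that carry it (single origin, no reversal).

    *pattern* maps species to 'present' / 'absent' / 'missing'; missing
    species are uninformative. If an 'absent' species falls inside the
    minimal clade the pattern is homoplasic under Dollo parsimony and the
    placement is returned with a conflict flag.
    """
    if not pattern:
        raise ValidationError("empty sharing pattern")
    present = sorted(s for s, v in pattern.items() if v == "present")
    absent = {s for s, v in pattern.items() if v == "absent"}
    if not present:
        raise ValidationError("no species carries the disruption")
    node = tree.mrca(present)
    clade = tuple(sorted(tree.leaves_under(node)))
    conflicts = tuple(sorted(absent & set(clade)))
    return DolloPlacement(
        branch="+".join(clade),
        clade_leaves=clade,
        homoplasic=bool(conflicts),
        conflicting_species=conflicts,
    )


# ---------------------------------------------------------------------------
# nonfunctionalization time

@dataclass
class NonfunctionalizationEstimate:
    t: float  # focal branch length, MY
    t_n: float  # estimated nonfunctionalization time, MY
    omega1: float
    omega_bar: float
    ka1: float | None = None
    ks1: float | None = None
    rs1: float | None = None  # K_S1 / T
    clamped: bool = False
    caution: bool = False  # few species used


def estimate_tn(
    omega1: float,
    omega_bar: float,
    t: float = HUMAN_CHIMP_SPLIT_MY,
    ka1: float | None = None,
    ks1: float | None = None,
    few_species: bool = False,
) -> NonfunctionalizationEstimate:
    """T_N = T (omega1 - omega_bar) / (1 - omega_bar), clamped to [0, T].

    omega_bar must be < 1 (a neutral background leaves no signal to date
    the inactivation); estimates from few species carry a caution flag.
    """
    if omega_bar >= 1:
        raise ValidationError(
            "omega_bar >= 1: nonfunctionalization time undefined"
        )
    if t <= 0:
        raise ValidationError("T must be positive")
    raw = t * (omega1 - omega_bar) / (1.0 - omega_bar)
    t_n = min(max(raw, 0.0), t)
    return NonfunctionalizationEstimate(
        t=t,
        t_n=t_n,
        omega1=omega1,
        omega_bar=omega_bar,
        ka1=ka1,
        ks1=ks1,
        rs1=(ks1 / t) if ks1 is not None else None,
        clamped=(t_n != raw),
        caution=few_species,
    )


def estimate_tn_from_alignment(
    alignment: dict[str, str],
    tree: SpeciesTree,
    focal: str,
    t: float | None = None,
    omega_bar_override: float | None = None,
) -> NonfunctionalizationEstimate:
    """Full dating workflow: reconstruct ancestors, measure lineage rates,
    and date the focal terminal branch.

    By default omega_bar is the unweighted mean omega over all non-focal
    branches; pass *omega_bar_override* to use an external constrained
    ratio (e.g. a genome-wide median).
    """
    rates = lineage_omega(alignment, tree)
    focal_branch = rates.branch_for(focal)
    omega1 = focal_branch.omega
    if omega1 is None:
        raise ValidationError(
            f"focal branch {focal!r} has K_S = 0; omega undefined"
        )
    omega_bar = (
        omega_bar_override
        if omega_bar_override is not None
        else rates.mean_omega(exclude=(focal,))
    )
    if omega_bar is None:
        raise ValidationError("no defined background omega")
    if t is None:
        node = tree.mrca([focal])
        t = tree.age_of(node.parent_node)
    return estimate_tn(
        omega1=omega1,
        omega_bar=omega_bar,
        t=t,
        ka1=focal_branch.ka,
        ks1=focal_branch.ks,
        few_species=len(alignment) < 4,
    )
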