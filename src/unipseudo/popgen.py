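"""Population-genetic analysis of polymorphic pseudogene loci.

Hardy-Weinberg goodness of fit per population (chi-square on the three
genotype classes), Nei-style G_ST as the F_ST estimator between
populations, UPGMA clustering of the pairwise F_ST matrix with a
largest-gap cut into subdivisions, and a label-permutation test for the
between-subdivision F_ST.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist

from .io_model import GenotypeCounts, ValidationError

__all__ = [
    "HWETestResult",
    "FstResult",
    "SubdivisionClustering",
    "hwe_chisq",
    "fst_pairwise",
    "fst_matrix",
    "cluster_populations",
    "fst_subdivision_permutation",
]


@dataclass(frozen=True)
class HWETestResult:
    chi2: float
    df: int
    p: float
    p_hat: float


def hwe_chisq(
    counts: GenotypeCounts, df_convention: str = "pearson2"
) -> HWETestResult:
    """Chi-square goodness of fit of genotype counts to p^2 / 2pq / q^2.

    'pearson2' uses 2 degrees of freedom (three classes minus one);
    'standard1' subtracts one more for the estimated allele frequency.
    A monomorphic sample leaves nothing to test.
    """
    if df_convention not in ("pearson2", "standard1"):
        raise ValidationError(f"unknown df convention {df_convention!r}")
    n = counts.n
    p = counts.p_hat
    if p in (0.0, 1.0):
        raise ValidationError(
            f"{counts.population}/{counts.snp_id}: monomorphic sample, "
            "HWE test undefined"
        )
    q = 1 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (counts.n_AA, counts.n_Aa, counts.n_aa)
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip(observed, expected)
    )
    df = 2 if df_convention == "pearson2" else 1
    return HWETestResult(
        chi2=chi2, df=df, p=float(chi2_dist.sf(chi2, df)), p_hat=p
    )


@dataclass(frozen=True)
class FstResult:
    h_s: float  # mean within-population expected heterozygosity
    h_t: float  # total expected heterozygosity at the mean frequency
    fst: float | None  # None when H_T = 0 (undefined)
    perm_p: float | None = None


def _fst_from_freqs(freqs: list[float]) -> FstResult:
    h_s = float(np.mean([2 * p * (1 - p) for p in freqs]))
    p_bar = float(np.mean(freqs))
    h_t = 2 * p_bar * (1 - p_bar)
    if h_t <= 0:
        return FstResult(h_s=h_s, h_t=h_t, fst=None)
    return FstResult(h_s=h_s, h_t=h_t, fst=(h_t - h_s) / h_t)


def fst_pairwise(a: GenotypeCounts, b: GenotypeCounts) -> FstResult:
    """Nei G_ST-style F_ST = (H_T - H_S)/H_T with unweighted means."""
    return _fst_from_freqs([a.p_hat, b.p_hat])


def fst_matrix(pops: list[GenotypeCounts]) -> np.ndarray:
    """Symmetric pairwise F_ST matrix (undefined pairs as 0)."""
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = fst_pairwise(pops[i], pops[j])
            out[i, j] = out[j, i] = r.fst if r.fst is not None else 0.0
    return out


@dataclass
class SubdivisionClustering:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (UPGMA)
    assignment: dict[str, int]  # population -> subdivision id (1-based)
    n_subdivisions: int


def cluster_populations(
    fst: np.ndarray, labels: list[str]
) -> SubdivisionClustering:
    """UPGMA dendrogram of the F_ST matrix, cut at the largest gap
    between successive merge heights.

    An all-zero matrix yields a single subdivision. Ties in the gap are
    broken toward the earlier (lower) cut; label order fixes any
    remaining ambiguity.
    """
    fst = np.asarray(fst, dtype=float)
    if fst.shape[0] != fst.shape[1] or not np.allclose(fst, fst.T):
        raise ValidationError("F_ST matrix must be symmetric")
    if np.any(np.diag(fst) != 0):
        raise ValidationError("F_ST matrix must have a zero diagonal")
    k = fst.shape[0]
    if len(labels) != k:
        raise ValidationError("label count does not match matrix size")
    if k == 1:
        return SubdivisionClustering(
            labels=list(labels), linkage=np.empty((0, 4)),
            assignment={labels[0]: 1}, n_subdivisions=1,
        )
    link = average(squareform(fst, checks=False))
    heights = link[:, 2]
    if np.allclose(heights, heights[0]):
        flat = np.ones(k, dtype=int)
    else:
        gaps = np.diff(heights)
        cut_idx = int(np.argmax(gaps))
        threshold = (heights[cut_idx] + heights[cut_idx + 1]) / 2
        flat = fcluster(link, t=threshold, criterion="distance")
    # renumber subdivisions deterministically by first label occurrence
    remap: dict[int, int] = {}
    assignment = {}
    for lab, cl in zip(labels, flat):
        if cl not in remap:
            remap[cl] = len(remap) + 1
        assignment[lab] = remap[cl]
    return SubdivisionClustering(
        labels=list(labels), linkage=link,
        assignment=assignment, n_subdivisions=len(remap),
    )


def _group_fst(
    group_a: list[GenotypeCounts], group_b: list[GenotypeCounts]
) -> float | None:
    """F_ST between two subdivisions, each summarized by the unweighted
    mean of its member population allele frequencies."""
    pa = float(np.mean([g.p_hat for g in group_a]))
    pb = float(np.mean([g.p_hat for g in group_b]))
    return _fst_from_freqs([pa, pb]).fst


def fst_subdivision_permutation(
    group_a: list[GenotypeCounts],
    group_b: list[GenotypeCounts],
    n_perm: int = 10_000,
    seed: int = 0,
) -> FstResult:
    """Permutation significance of the between-subdivision F_ST.

    Population labels are shuffled across the two subdivisions (sizes
    preserved); p = (1 + #{perm >= observed}) / (1 + n_perm). When fewer
    than 20 distinct label assignments exist, all of them are enumerated
    instead (and the add-one correction is dropped: the observed split is
    one of the enumerated ones).
    """
    if len(group_a) + len(group_b) < 2:
        raise ValidationError("need at least two populations")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    pooled = list(group_a) + list(group_b)
    n_a = len(group_a)
    observed = _group_fst(group_a, group_b)
    if observed is None:
        return FstResult(h_s=0.0, h_t=0.0, fst=None)

    n_distinct = math.comb(len(pooled), n_a)
    if n_distinct < 20:
        exceed = total = 0
        for combo in itertools.combinations(range(len(pooled)), n_a):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(len(pooled))
                  if i not in combo]
            f = _group_fst(ga, gb)
            if f is not None:
                total += 1
                if f >= observed - 1e-12:
                    exceed += 1
        p = exceed / total if total else 1.0
    else:
        rng = np.random.default_rng([int(seed) % (2**31), 6])
        exceed = 0
        idx = np.arange(len(pooled))
        for _ in range(n_perm):
            perm = rng.permutation(idx)
            ga = [pooled[i] for i in perm[:n_a]]
            gb = [pooled[i] for i in perm[n_a:]]
            f = _group_fst(ga, gb)
            if f is not None and f >= observed - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
    base = _fst_from_freqs([
        float(np.mean([g.p_hat for g in group_a])),
        float(np.mean([g.p_hat for g in group_b])),
    ])
    return FstResult(
        h_s=base.h_s, h_t=base.h_t, fst=observed, perm_p=p
    )
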