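"""Population genetics of a segregating (polymorphic) pseudogene allele.

Simulates genotype counts for a null allele at very different
frequencies in two groups of populations, tests Hardy-Weinberg
equilibrium in the pooled meta-population, clusters populations by
pairwise F_ST, and assesses the two-subdivision split by permutation.
"""

from unipseudo.io_model import GenotypeCounts
from unipseudo.popgen import (
    cluster_populations,
    fst_matrix,
    fst_subdivision_permutation,
    hwe_chisq,
)
from unipseudo.synthetic_data import simulate_genotypes

freqs = {
    "pop01": 0.15, "pop02": 0.2, "pop03": 0.25,
    "pop04": 0.7, "pop05": 0.72, "pop06": 0.75, "pop07": 0.78,
    "pop08": 0.8, "pop09": 0.82, "pop10": 0.85, "pop11": 0.88,
}
pops = simulate_genotypes(sorted(freqs), freqs, n=120, seed=11)

pooled = GenotypeCounts(
    "meta", "null_allele",
    sum(p.n_AA for p in pops),
    sum(p.n_Aa for p in pops),
    sum(p.n_aa for p in pops),
)
hwe = hwe_chisq(pooled)  # df = 2 convention
print(
    f"meta-population HWE: chi2 = {hwe.chi2:.3f}, "
    f"df = {hwe.df}, p = {hwe.p:.4f}"
)
# Pooling differentiated populations creates a heterozygote deficit
# (the Wahlund effect), so the meta-population departs from HWE.

clustering = cluster_populations(
    fst_matrix(pops), [p.population for p in pops]
)
print(f"subdivisions found: {clustering.n_subdivisions}")
for sub in range(1, clustering.n_subdivisions + 1):
    members = [
        l for l, c in clustering.assignment.items() if c == sub
    ]
    print(f"  subdivision {sub}: {members}")

group1 = [
    p for p in pops if clustering.assignment[p.population] == 1
]
group2 = [
    p for p in pops if clustering.assignment[p.population] == 2
]
res = fst_subdivision_permutation(group1, group2, n_perm=10000, seed=11)
print(
    f"between-subdivision F_ST = {res.fst:.4f}, "
    f"permutation p = {res.perm_p:.4g}"
)
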