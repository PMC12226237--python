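"""Generate a synthetic ancient-DNA cohort with known ground truth.

Draws allele frequencies for drift-related source and reference
populations, samples pseudo-haploid individuals plus two admixed
targets, and writes the cohort as an EIGENSTRAT triplet.
"""

from adnapop.eigenstrat import write_eigenstrat
from adnapop.pipeline import default_tree
from adnapop.synthetic import AdmixtureSpec, draw_frequencies, make_cohort, make_snp_table

tree = default_tree()
freqs = draw_frequencies(tree, n_snps=5000, seed=42)
snps = make_snp_table(5000)

targets = [
    AdmixtureSpec("west_med_mix", {"Sicily_EMBA": 0.7, "NorthAfrica_IA": 0.3}),
    AdmixtureSpec("levantine_like", {"Levant_MLBA": 1.0}),
]
table = make_cohort(
    freqs,
    {pop: 10 for pop in tree.proxy_sources + tree.right_set},
    snps,
    missing_rate=0.15,
    seed=43,
    admixed=targets,
)
write_eigenstrat(table, "scratch/example_cohort")

print(f"cohort: {table.n_snps} SNPs x {table.n_individuals} individuals")
print(f"pseudo-haploid: {table.pseudo_haploid}")
cov = table.individuals.set_index("individual_id")["n_snps_covered"]
print(f"coverage of 'west_med_mix': {cov['west_med_mix']} non-missing autosomal calls")
# The two targets are mixtures of the named sources with the stated
# weights -- downstream examples recover those weights from genotypes.
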