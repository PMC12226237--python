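"""Project ancient individuals onto a reference PCA and read ancestry
off the two-cluster cline.

Fits a PCA on diploid reference individuals from three populations,
projects pseudo-haploid admixed ancients with least squares plus
shrinkage correction, and estimates each ancient's North-African-like
fraction from its position along the cline between the two source
clusters.
"""

import numpy as np
import pandas as pd

from adnapop.eigenstrat import GenotypeTable
from adnapop.pca import cline_fraction, fit_pca, project, project_reference, site_diversity
from adnapop.synthetic import AdmixtureSpec, PopulationTree, draw_frequencies, make_cohort, make_snp_table

tree = PopulationTree.from_edges(
    [("root", "EUR", 0.02), ("EUR", "Sicilian", 0.05), ("EUR", "Iberian", 0.05),
     ("root", "NorthAfrican", 0.10)]
)
n_snps = 8000
freqs = draw_frequencies(tree, n_snps, seed=3)
snps = make_snp_table(n_snps)
rng = np.random.default_rng(4)

cols, groups = [], []
for pop in ("Sicilian", "NorthAfrican", "Iberian"):
    cols.append(rng.binomial(2, freqs[pop][:, None], size=(n_snps, 30)).astype(np.int8))
    groups += [pop] * 30
reference = GenotypeTable(
    snps=snps,
    individuals=pd.DataFrame(
        {"individual_id": [f"{g}{i}" for i, g in enumerate(groups)],
         "sex": "unknown", "group_label": groups}
    ),
    calls=np.hstack(cols),
)
model = fit_pca(reference, n_components=2, shrinkage="loo", loo_size=20, seed=5)
refs = project_reference(model, reference)
sicilian, north_african = refs[:30], refs[30:60]

alphas = [0.0, 0.25, 0.5, 0.75, 1.0]
specs = [AdmixtureSpec(f"anc{k}", {"NorthAfrican": a, "Sicilian": 1 - a}) for k, a in enumerate(alphas)]
ancients = make_cohort(freqs, {}, snps, seed=6, admixed=specs, admixed_missing_rate=0.3)

print("true_NA  estimated_NA   PC1      PC2")
for k, a in enumerate(alphas):
    proj = project(model, ancients, f"anc{k}", min_snps=1000)
    est = cline_fraction(proj, sicilian, north_african)
    print(f"  {a:4.2f}      {est.fraction_b:5.3f}     {proj.coordinates[0]:+7.2f} {proj.coordinates[1]:+7.2f}")
print("per-'site' PC diversity of the 5 ancients:",
      round(site_diversity([project(model, ancients, f"anc{k}", min_snps=1000) for k in range(5)],
                           min_individuals=5), 3))
# estimated_NA tracks the generating weight; the mean pairwise PC
# distance is the per-site diversity statistic used to compare sites.
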