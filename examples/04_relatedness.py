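"""Kinship, IBD classification, segment dating and ROH analytics on a
simulated pedigree.

Simulates meiosis through a sibling pedigree and a first-cousin-union
pedigree, classifies pairs from their true IBD segments, dates a 16 cM
segment, and summarizes the cousin offspring's runs of homozygosity.
"""

from adnapop.relatedness import (
    IbdSummary,
    classify_pair,
    expected_roh_total,
    kinship_r,
    roh_summarize,
    segment_age,
)
from adnapop.synthetic import cousin_offspring_pedigree, sibling_pedigree, simulate_pedigree

sibs = simulate_pedigree(sibling_pedigree(), seed=1)
segs = sibs.ibd_segments("S1", "S2")
summary = IbdSummary.from_segments("S1", "S2", [e - s for _, s, e in segs])
print(f"siblings: {len(segs)} IBD segments, {summary.sum_over_12cm:.0f} cM in segments >12 cM")
print("classified as:", classify_pair(summary))

post = segment_age(16.0, ne=1000)
print(f"a 16 cM segment dates to median {post.median:.1f} generations "
      f"(95th percentile {post.q95:.1f}) under Ne=1000")

cousins = simulate_pedigree(cousin_offspring_pedigree(1), seed=2)
roh = [e - s for _, s, e in cousins.roh_segments("O")]
s = roh_summarize("O", roh)
print(f"first-cousin offspring: {s.sum_over_20cm:.0f} cM in ROH >20 cM "
      f"(expected {expected_roh_total('first_cousins'):.1f} cM on average)"
      f" -> parental class {s.parental_class!r}")

# kinship from mismatch rates: at the unrelated baseline r=0, at half
# the baseline r=1 (identical genomes)
print("kinship at x=b:", kinship_r(0.24, 0.24).r, " at x=b/2:", kinship_r(0.12, 0.24).r)
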