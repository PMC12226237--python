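"""Y-haplogroup spectrum summaries and per-site Inverse Simpson
diversity.

The Inverse Simpson index is the reciprocal of the probability that
two randomly selected males from a site carry the same (truncated)
Y haplogroup — the effective number of equally frequent lineages.
Haplogroup labels are ISOGG strings truncated to a configurable depth
(default 4 characters, the figure convention; 3 is the coarser text
convention) before counting.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter

import numpy as np
import pandas as pd

MIN_MALES = 5
MALE_SNP_GATE = 100_000


def truncate_isogg(haplogroup: str, k: int = 4) -> str:
    """First ``k`` characters of an ISOGG label; shorter labels are
    returned whole."""
    if k < 1:
        raise ValueError("truncation depth must be >= 1")
    if not haplogroup:
        raise ValueError("empty haplogroup label")
    return haplogroup[:k]


def inverse_simpson(labels: list[str], estimator: str = "unbiased") -> float:
    """Effective number of types among ``labels``.

    ``plug_in``: 1 / sum(p_i^2) with sample proportions p_i.
    ``unbiased``: without-replacement match probability,
    1 / [sum n_i (n_i - 1) / (n (n - 1))]; infinite when every label is
    a singleton (no within-class pair exists).
    """
    if not labels:
        raise ValueError("no labels")
    counts = np.array(list(Counter(labels).values()), dtype=float)
    n = counts.sum()
    if estimator == "plug_in":
        return float(1.0 / np.sum((counts / n) ** 2))
    if estimator == "unbiased":
        if n < 2:
            raise ValueError("unbiased estimator needs at least 2 labels")
        match = np.sum(counts * (counts - 1.0)) / (n * (n - 1.0))
        return math.inf if match == 0 else float(1.0 / match)
    raise ValueError(f"unknown estimator {estimator!r}")


def site_haplogroup_diversity(
    table: pd.DataFrame,
    truncation: int = 4,
    estimator: str = "unbiased",
    min_males: int = MIN_MALES,
    snp_gate: int | None = MALE_SNP_GATE,
    exclude_lineages: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-site Inverse Simpson diversity of truncated Y haplogroups.

    Expects columns ``individual_id, site, sex, y_haplogroup`` and
    optionally ``n_snps_covered`` (gated at ``snp_gate`` when present).
    Sites with fewer than ``min_males`` qualifying males are skipped
    with a warning.  ``exclude_lineages`` drops males whose truncated
    label starts with any of the given prefixes (the filtered variant
    factoring out specific lineages).
    """
    males = table[(table["sex"] == "male") & table["y_haplogroup"].notna()].copy()
    if snp_gate is not None and "n_snps_covered" in males.columns:
        males = males[males["n_snps_covered"] > snp_gate]
    males["lineage"] = [truncate_isogg(h, truncation) for h in males["y_haplogroup"]]
    if exclude_lineages:
        males = males[~males["lineage"].str.startswith(tuple(exclude_lineages))]
    recs = []
    for site, sub in males.groupby("site"):
        labels = list(sub["lineage"])
        if len(labels) < min_males:
            warnings.warn(f"site {site}: only {len(labels)} qualifying males (< {min_males}); skipped")
            continue
        recs.append((site, len(labels), inverse_simpson(labels, estimator), estimator, truncation))
    return pd.DataFrame(recs, columns=["site", "n_males", "index", "estimator", "k"])
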