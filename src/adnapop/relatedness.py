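"""Pairwise kinship from mismatch rates, IBD-based relationship
classification, coalescent dating of shared segments, and ROH-based
parental-relatedness summaries.

Segment *detection* is out of scope: IBD/ROH segments are consumed as
tables (ancIBD/hapROH-compatible TSV columns) or taken as ground truth
from the pedigree simulator.  Everything downstream of detection —
summaries, degree bands, dating, expected autozygosity — lives here.

The kinship estimator follows the mismatch-rate convention for
pseudo-haploid data:

    r = 1 - 2 (x - b/2) / b

where x is the pairwise mismatch rate and b the rate expected for two
unrelated individuals of the same ancestral background, so r = 0 for
unrelated pairs and r = 1 for a pair of identical genomes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .eigenstrat import GenotypeTable, MISSING
from .fstats import BlockScheme, weighted_jackknife

DEFAULT_MAP_CM = 3540.0          # total diploid autosomal genetic map
IBD_SIGNIFICANCE_CM = 16.0       # a single segment above this implies relatedness
ROH_CLOSE_KIN_CM = 50.0          # total ROH>20cM implying ~cousin parents
ROH_SECOND_DEGREE_CM = 350.0     # total ROH>20cM implying second-degree parents
ROH_BIN_EDGES_CM = (4.0, 8.0, 12.0, 20.0)

RELATIONSHIP_F = {
    "unrelated": 0.0,
    "siblings": 0.25,
    "parent_offspring": 0.25,
    "second_degree": 0.125,
    "avuncular": 0.125,
    "half_siblings": 0.125,
    "first_cousins": 1.0 / 16.0,
    "second_cousins": 1.0 / 64.0,
    "third_cousins": 1.0 / 256.0,
}


@dataclass
class MismatchEstimate:
    x: float
    ci95: tuple[float, float]
    n_overlap: int


@dataclass
class KinshipEstimate:
    r: float
    b: float


def pairwise_mismatch(
    table: GenotypeTable, id1: str, id2: str, blocks: BlockScheme
) -> MismatchEstimate:
    """Fraction of jointly covered autosomal SNPs where the two
    pseudo-haploid calls differ, with a block-jackknife 95% CI."""
    c1 = table.calls[:, table.individual_index(id1)]
    c2 = table.calls[:, table.individual_index(id2)]
    for cid, c in ((id1, c1), (id2, c2)):
        if (c == 1).any():
            raise ValueError(f"{cid} has heterozygous calls; mismatch rates need pseudo-haploid data")
    ok = table.autosomal_mask() & (c1 != MISSING) & (c2 != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no overlapping covered SNPs between {id1} and {id2}")
    diff = (c1[ok] != c2[ok]).astype(float)
    ids = blocks.block_ids[ok]
    sums = np.bincount(ids, weights=diff, minlength=blocks.n_blocks)
    counts = np.bincount(ids, minlength=blocks.n_blocks).astype(float)
    x, se = weighted_jackknife(diff.sum(), float(n), sums, counts)
    return MismatchEstimate(x=x, ci95=(x - 1.96 * se, x + 1.96 * se), n_overlap=n)


def kinship_r(x: float, b: float) -> KinshipEstimate:
    """r = 1 - 2(x - b/2)/b; reported unclamped, with a warning outside
    [-1, 1] (raw estimates are informative at low coverage)."""
    if b <= 0:
        raise ValueError("baseline mismatch rate b must be positive")
    r = 1.0 - 2.0 * (x - b / 2.0) / b
    if not -1.0 <= r <= 1.0:
        warnings.warn(f"kinship estimate r = {r:.3f} outside [-1, 1]")
    return KinshipEstimate(r=r, b=b)


def baseline_b(
    table: GenotypeTable, pairs: list[tuple[str, str]], blocks: BlockScheme
) -> float:
    """Unweighted mean mismatch rate over presumed-unrelated pairs
    (the baseline b of the kinship formula); needs >= 3 pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 presumed-unrelated pairs for a baseline")
    return float(np.mean([pairwise_mismatch(table, a, b, blocks).x for a, b in pairs]))


# ---------------------------------------------------------------------------
# IBD-based relationship classification

RELATIONSHIP_CLASSES = (
    "identical/1st",
    "2nd-4th",
    "5th-7th",
    "unrelated-detectable",
    "unrelated",
)


@dataclass
class IbdSummary:
    """Per-pair summary of IBD segments (>8 cM input convention)."""

    iid1: str
    iid2: str
    lengths_cm: np.ndarray
    relationship_class: str | None = None

    @classmethod
    def from_segments(cls, iid1: str, iid2: str, lengths_cm) -> "IbdSummary":
        lengths = np.asarray(lengths_cm, dtype=float)
        if (lengths < 0).any():
            raise ValueError("negative segment length")
        return cls(iid1=iid1, iid2=iid2, lengths_cm=lengths)

    def n_over(self, threshold_cm: float) -> int:
        return int((self.lengths_cm > threshold_cm).sum())

    @property
    def n_over_12cm(self) -> int:
        return self.n_over(12.0)

    @property
    def n_over_16cm(self) -> int:
        return self.n_over(16.0)

    @property
    def n_over_20cm(self) -> int:
        return self.n_over(20.0)

    @property
    def sum_over_12cm(self) -> float:
        return float(self.lengths_cm[self.lengths_cm > 12.0].sum())


def _load_calibration() -> dict:
    path = resources.files("adnapop").joinpath("data/ibd_calibration.json")
    return json.loads(path.read_text())


_CALIBRATION_CACHE: dict | None = None


def ibd_calibration() -> dict:
    """Degree-band thresholds calibrated on pedigree simulations (see
    scripts/calibrate_relatedness.py)."""
    global _CALIBRATION_CACHE
    if _CALIBRATION_CACHE is None:
        _CALIBRATION_CACHE = _load_calibration()
    return _CALIBRATION_CACHE


def classify_pair(ibd: IbdSummary, calibration: dict | None = None) -> str:
    """Relationship band from segments >12 cM.

    Rules (thresholds from the shipped pedigree-simulation calibration):

    * no segment >16 cM                      -> unrelated
    * sum of >12 cM segments >= first-degree threshold -> identical/1st
    * sum >= 2nd-4th threshold               -> 2nd-4th
    * multiple long segments                 -> 5th-7th
    * single long segment, low total         -> unrelated-detectable
    """
    cal = calibration or ibd_calibration()
    if ibd.n_over(cal.get("min_detectable_cM", IBD_SIGNIFICANCE_CM)) == 0:
        cls = "unrelated"
    elif ibd.sum_over_12cm >= cal["first_degree_sum_cM"]:
        cls = "identical/1st"
    elif ibd.sum_over_12cm >= cal["second_fourth_sum_cM"]:
        cls = "2nd-4th"
    elif ibd.n_over_12cm >= cal.get("min_n_long", 2):
        cls = "5th-7th"
    else:
        cls = "unrelated-detectable"
    ibd.relationship_class = cls
    return cls


def read_segment_table(path: str | Path, roh: bool = False) -> pd.DataFrame:
    """Read an ancIBD/hapROH-style TSV (iid1[, iid2], chrom, start_cM,
    end_cM, length_cM)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"chrom", "start_cM", "end_cM"}
    if not needed <= set(df.columns):
        raise ValueError(f"segment table missing columns {sorted(needed - set(df.columns))}")
    if "length_cM" not in df.columns:
        df["length_cM"] = df["end_cM"] - df["start_cM"]
    return df


# ---------------------------------------------------------------------------
# Coalescent dating of an IBD segment


@dataclass
class SegmentAgePosterior:
    """Posterior over the age (generations) of the common ancestor of
    an observed long IBD segment."""

    length_cm: float
    ne: float
    t: np.ndarray
    pmf: np.ndarray
    median: float
    q95: float

    def quantile(self, q: float) -> float:
        """Interpolated quantile; the mass at integer t is treated as
        spread over (t - 1/2, t + 1/2], matching the continuous limit."""
        cdf = np.cumsum(self.pmf)
        idx = int(np.searchsorted(cdf, q))
        lo = cdf[idx - 1] if idx > 0 else 0.0
        frac = (q - lo) / (cdf[idx] - lo)
        return float(self.t[idx] - 0.5 + frac)


def segment_age(length_cm: float, ne: float = 1000.0, t_max: int | None = None) -> SegmentAgePosterior:
    """Posterior age of the pairwise common ancestor given an IBD
    segment of the stated length, under a panmictic diploid coalescent
    of constant size Ne.

    The prior on the coalescence time t (generations) is geometric,
    (1/2Ne)(1 - 1/2Ne)^(t-1); the probability that a segment of length
    l Morgans survives 2t meioses unbroken while both endpoints recombine
    contributes a density proportional to (2t)^2 exp(-2 t l).  The
    discrete posterior is normalized over t = 1..t_max, with t_max set
    so the truncated tail mass is below 1e-6.
    """
    if length_cm <= 0 or ne <= 0:
        raise ValueError("segment length and Ne must be positive")
    l_m = length_cm / 100.0
    lam = -np.log1p(-1.0 / (2.0 * ne))
    rate = 2.0 * l_m + lam
    if t_max is None:
        t_max = max(50, int(np.ceil(stats.gamma.isf(1e-9, 3, scale=1.0 / rate))))
    t = np.arange(1, t_max + 1, dtype=float)
    log_w = 2.0 * np.log(2.0 * t) - rate * t      # geometric prior * (2t)^2 e^(-2tl)
    log_w -= log_w.max()
    pmf = np.exp(log_w)
    pmf /= pmf.sum()
    post = SegmentAgePosterior(length_cm=length_cm, ne=ne, t=t, pmf=pmf, median=0.0, q95=0.0)
    post.median = post.quantile(0.5)
    post.q95 = post.quantile(0.95)
    return post


# ---------------------------------------------------------------------------
# ROH summaries

PARENTAL_CLASSES = ("outbred", "close-kin-union", "second-degree-parents")


@dataclass
class RohSummary:
    individual_id: str
    bin_totals_cm: dict[str, float]
    sum_over_20cm: float
    parental_class: str


def roh_summarize(individual_id: str, lengths_cm, min_snps_covered: int | None = None,
                  coverage_gate: int = 400_000) -> RohSummary:
    """Bin an individual's ROH segments by length and classify parental
    relatedness from the total in long (>20 cM) ROH.

    ``min_snps_covered`` applies the coverage gate used when segments
    come from a real caller; simulator-derived segments pass None.
    """
    if min_snps_covered is not None and min_snps_covered < coverage_gate:
        raise ValueError(
            f"{individual_id}: {min_snps_covered} covered SNPs below the "
            f"{coverage_gate} gate for ROH calling"
        )
    lengths = np.asarray(lengths_cm, dtype=float)
    if (lengths < 0).any():
        raise ValueError("negative ROH length")
    e = ROH_BIN_EDGES_CM
    bins = {
        f"[{e[0]:g},{e[1]:g})": float(lengths[(lengths >= e[0]) & (lengths < e[1])].sum()),
        f"[{e[1]:g},{e[2]:g})": float(lengths[(lengths >= e[1]) & (lengths < e[2])].sum()),
        f"[{e[2]:g},{e[3]:g})": float(lengths[(lengths >= e[2]) & (lengths < e[3])].sum()),
        f">={e[3]:g}": float(lengths[lengths >= e[3]].sum()),
    }
    long_total = bins[f">={e[3]:g}"]
    if long_total >= ROH_SECOND_DEGREE_CM:
        cls = "second-degree-parents"
    elif long_total >= ROH_CLOSE_KIN_CM:
        cls = "close-kin-union"
    else:
        cls = "outbred"
    return RohSummary(
        individual_id=individual_id,
        bin_totals_cm=bins,
        sum_over_20cm=long_total,
        parental_class=cls,
    )


def expected_roh_total(relationship: str | float, map_cm: float = DEFAULT_MAP_CM) -> float:
    """Expected total autozygous length (cM) for the offspring of
    parents with the given relationship: F x map length, with F the
    offspring's inbreeding coefficient (1/16 for first cousins)."""
    if isinstance(relationship, str):
        try:
            f_coef = RELATIONSHIP_F[relationship]
        except KeyError:
            raise ValueError(f"unknown relationship {relationship!r}") from None
    else:
        f_coef = float(relationship)
    if not 0.0 <= f_coef <= 0.25:
        raise ValueError("inbreeding coefficient must be in [0, 0.25]")
    return f_coef * map_cm
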