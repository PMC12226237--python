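"""Synthetic cohort generator: drift-related population frequencies,
admixed pseudo-haploid individuals, pedigrees with true IBD/ROH
segments, and per-site haplogroup tables.

The generator is the ground truth against which every downstream stage
(f4/admixture fitting, PCA clines, kinship analytics, diversity
indices) is validated.

Models
------
* Allele frequencies follow Balding-Nichols drift: along an edge with
  drift parameter F, a child's frequency given the parent frequency p
  is Beta(p(1-F)/F, (1-p)(1-F)/F), so E = p and Var = F p(1-p).
  Closed-form moments make exact oracles possible.
* Admixed targets draw two alleles Binomial(2, q) from the mixture
  frequency q = sum_k alpha_k p_k, then pseudo-haploidize.
* Meiosis places crossovers as a Poisson process with rate 1 per
  Morgan, no interference.  Founders carry two uniquely labeled
  haplotypes per chromosome; IBD/ROH are maximal intervals of shared
  founder-haplotype descent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eigenstrat import GenotypeTable, MISSING, SNP_COLUMNS, IND_COLUMNS

# 22 autosomes, human-like relative genetic lengths, total 35.0 Morgans
_RAW = np.array([
    2.84, 2.69, 2.23, 2.14, 2.04, 1.92, 1.87, 1.70, 1.68, 1.81, 1.58,
    1.75, 1.26, 1.19, 1.41, 1.34, 1.29, 1.18, 1.08, 1.08, 0.62, 0.74,
])
DEFAULT_CHROM_LENGTHS_M: np.ndarray = _RAW / _RAW.sum() * 35.0


class PedigreeError(ValueError):
    """Raised on malformed pedigrees (cycles, unknown parents)."""


@dataclass
class PopulationTree:
    """Rooted drift tree over named populations.

    ``parents`` maps node -> parent (root maps to None); ``drift`` maps
    node -> Balding-Nichols F of the edge above it, in [0, 1).
    """

    parents: dict[str, str | None]
    drift: dict[str, float]
    proxy_sources: tuple[str, ...] = ()
    right_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        for n, p in self.parents.items():
            if p is not None and p not in self.parents:
                raise ValueError(f"node {n} has unknown parent {p}")
        for n, f in self.drift.items():
            if not (0.0 <= f < 1.0):
                raise ValueError(f"drift F for {n} must be in [0, 1), got {f}")
        # acyclicity: walking up from every node must reach the root
        for n in self.parents:
            seen = set()
            while n is not None:
                if n in seen:
                    raise ValueError("tree contains a cycle")
                seen.add(n)
                n = self.parents[n]

    @property
    def root(self) -> str:
        return next(n for n, p in self.parents.items() if p is None)

    def topological_order(self) -> list[str]:
        order, placed = [], set()
        pending = list(self.parents)
        while pending:
            progressed = False
            for n in list(pending):
                p = self.parents[n]
                if p is None or p in placed:
                    order.append(n)
                    placed.add(n)
                    pending.remove(n)
                    progressed = True
            if not progressed:  # pragma: no cover - guarded in __post_init__
                raise ValueError("tree contains a cycle")
        return order

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str, float]],
        proxy_sources: tuple[str, ...] = (),
        right_set: tuple[str, ...] = (),
    ) -> "PopulationTree":
        """Build from (parent, child, F) triples; the one parent never
        appearing as a child becomes the root with F = 0."""
        parents: dict[str, str | None] = {}
        drift: dict[str, float] = {}
        for parent, child, f_drift in edges:
            parents[child] = parent
            drift[child] = f_drift
            parents.setdefault(parent, None)
            drift.setdefault(parent, 0.0)
        return cls(parents=parents, drift=drift, proxy_sources=proxy_sources, right_set=right_set)


@dataclass
class AdmixtureSpec:
    """Ground-truth mixture weights of one synthetic target."""

    target_id: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()))
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("admixture weights must be non-negative and sum to 1")


def draw_frequencies(
    tree: PopulationTree,
    n_snps: int,
    seed: int,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
) -> dict[str, np.ndarray]:
    """Per-node allele-frequency vectors under Balding-Nichols drift.

    The root frequency is Uniform over ``ancestral_range``; each child
    draws Beta(p(1-F)/F, (1-p)(1-F)/F) around its parent's p (F = 0
    copies p exactly).  Deterministic given ``seed``.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    freqs: dict[str, np.ndarray] = {}
    for node in tree.topological_order():
        parent = tree.parents[node]
        if parent is None:
            freqs[node] = rng.uniform(*ancestral_range, size=n_snps)
            continue
        p = freqs[parent]
        f_drift = tree.drift[node]
        if f_drift == 0.0:
            freqs[node] = p.copy()
        else:
            scale = (1.0 - f_drift) / f_drift
            freqs[node] = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1 - p) * scale, 1e-12))
    return freqs


def sample_pseudo_haploid_calls(
    freq: np.ndarray, n_individuals: int, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Pseudo-haploid 0/2 calls: one Bernoulli(freq) allele per
    individual per SNP, dropped to missing with ``missing_rate``."""
    calls = (rng.random((len(freq), n_individuals)) < freq[:, None]).astype(np.int8) * 2
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    return calls


def simulate_admixed(
    freqs: dict[str, np.ndarray],
    spec: AdmixtureSpec,
    n_individuals: int = 1,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Pseudo-haploid call columns for admixed target individuals.

    Per SNP the mixture frequency is q = sum_k alpha_k p_k; two alleles
    are drawn Binomial(2, q) and then pseudo-haploidized (one of the
    two sampled uniformly), which is marginally a single Bernoulli(q)
    allele per site.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    q = np.zeros_like(next(iter(freqs.values())))
    for source, alpha in spec.weights.items():
        q = q + alpha * freqs[source]
    diploid = rng.binomial(2, q[:, None], size=(len(q), n_individuals)).astype(np.int8)
    picked = np.where(diploid == 1, rng.integers(0, 2, size=diploid.shape, dtype=np.int8) * 2, diploid)
    if missing_rate > 0:
        picked[rng.random(picked.shape) < missing_rate] = MISSING
    return picked


def make_snp_table(n_snps: int, chrom_lengths_m: np.ndarray | None = None) -> pd.DataFrame:
    """Evenly spaced synthetic SNP map over the default 22-autosome,
    35-Morgan genome (counts allocated proportionally to map length)."""
    lengths = DEFAULT_CHROM_LENGTHS_M if chrom_lengths_m is None else np.asarray(chrom_lengths_m)
    per_chrom = np.maximum(1, np.round(lengths / lengths.sum() * n_snps).astype(int))
    # adjust rounding drift on the largest chromosome
    per_chrom[0] += n_snps - per_chrom.sum()
    recs = []
    for c, (n_c, length) in enumerate(zip(per_chrom, lengths), start=1):
        gpos = np.linspace(0, length, n_c, endpoint=False)
        for i, g in enumerate(gpos):
            recs.append((f"rs{c}_{i}", c, float(g), int(g * 1e8) + i + 1, "A", "C"))
    return pd.DataFrame(recs, columns=SNP_COLUMNS)


def make_cohort(
    freqs: dict[str, np.ndarray],
    group_sizes: dict[str, int],
    snps: pd.DataFrame,
    missing_rate: float = 0.0,
    seed: int = 0,
    admixed: list[AdmixtureSpec] | None = None,
    admixed_missing_rate: float | None = None,
) -> GenotypeTable:
    """Assemble a pseudo-haploid GenotypeTable: ``group_sizes``
    individuals sampled per population plus one column per admixed
    target spec (labelled by its target id)."""
    rng = np.random.default_rng(seed)
    columns, ids, groups = [], [], []
    for pop, n in group_sizes.items():
        columns.append(sample_pseudo_haploid_calls(freqs[pop], n, missing_rate, rng))
        ids += [f"{pop}_{i}" for i in range(n)]
        groups += [pop] * n
    for k, spec in enumerate(admixed or []):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        mr = missing_rate if admixed_missing_rate is None else admixed_missing_rate
        columns.append(simulate_admixed(freqs, spec, 1, mr, sub_seed))
        ids.append(spec.target_id)
        groups.append(spec.target_id)
    individuals = pd.DataFrame(
        {"individual_id": ids, "sex": "unknown", "group_label": groups}, columns=IND_COLUMNS
    )
    return GenotypeTable(
        snps=snps, individuals=individuals, calls=np.hstack(columns), pseudo_haploid=True
    )


# ---------------------------------------------------------------------------
# Pedigree simulation


@dataclass
class Pedigree:
    """Founders and matings; members map to (father, mother) or None."""

    members: dict[str, tuple[str, str] | None] = field(default_factory=dict)

    def add_founder(self, member_id: str) -> None:
        self.members[member_id] = None

    def add_child(self, member_id: str, father: str, mother: str) -> None:
        self.members[member_id] = (father, mother)

    def founders(self) -> list[str]:
        return [m for m, p in self.members.items() if p is None]

    def topological_order(self) -> list[str]:
        order, placed = [], set()
        pending = list(self.members)
        while pending:
            progressed = False
            for m in list(pending):
                parents = self.members[m]
                if parents is None or all(p in placed for p in parents):
                    order.append(m)
                    placed.add(m)
                    pending.remove(m)
                    progressed = True
            if not progressed:
                raise PedigreeError(f"pedigree has a cycle or missing parents: {pending}")
        return order


# a haplotype mosaic on one chromosome: (breakpoints ending at L, founder labels)
Mosaic = tuple[np.ndarray, np.ndarray]


def _meiose(hap_a: Mosaic, hap_b: Mosaic, length: float, rng: np.random.Generator) -> Mosaic:
    """Recombine two parental haplotypes: Poisson(L) crossovers,
    uniform positions, no interference."""
    n_x = rng.poisson(length)
    cuts = np.sort(rng.uniform(0.0, length, n_x)) if n_x else np.empty(0)
    source = int(rng.integers(2))
    haps = (hap_a, hap_b)
    breaks, labels = [], []
    start = 0.0
    for cut in np.append(cuts, length):
        if cut > start:
            b, l = haps[source]
            i0, i1 = np.searchsorted(b, start, side="right"), np.searchsorted(b, cut, side="left")
            for k in range(i0, i1 + 1):
                end = min(float(b[k]), cut)
                if labels and labels[-1] == l[k]:
                    breaks[-1] = end
                else:
                    breaks.append(end)
                    labels.append(l[k])
        source ^= 1
        start = cut
    return np.array(breaks), np.array(labels)


def _matching_intervals(m1: Mosaic, m2: Mosaic) -> list[tuple[float, float]]:
    """Intervals where two mosaics carry the same founder label."""
    b1, l1 = m1
    b2, l2 = m2
    edges = np.unique(np.concatenate([b1, b2]))
    out: list[tuple[float, float]] = []
    start = 0.0
    for end in edges:
        mid = (start + end) / 2.0
        lab1 = l1[np.searchsorted(b1, mid)]
        lab2 = l2[np.searchsorted(b2, mid)]
        if lab1 == lab2:
            if out and out[-1][1] == start:
                out[-1] = (out[-1][0], float(end))
            else:
                out.append((start, float(end)))
        start = float(end)
    return out


def _union_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class TrueSegments:
    """Ground-truth shared-haplotype segments, coordinates in cM."""

    ibd: pd.DataFrame  # iid1, iid2, chrom, start_cM, end_cM, length_cM
    roh: pd.DataFrame  # iid, chrom, start_cM, end_cM, length_cM

    def to_tsv(self, ibd_path, roh_path) -> None:
        self.ibd.to_csv(ibd_path, sep="\t", index=False)
        self.roh.to_csv(roh_path, sep="\t", index=False)


@dataclass
class PedigreeRealization:
    """Simulated haplotype mosaics for every pedigree member."""

    pedigree: Pedigree
    chrom_lengths_m: np.ndarray
    haplotypes: dict[str, list[tuple[Mosaic, Mosaic]]]

    def ibd_segments(self, a: str, b: str) -> list[tuple[int, float, float]]:
        """Maximal (chrom, start_cM, end_cM) intervals where any of the
        four haplotype pairings of a and b share founder descent."""
        out = []
        for c, (ha, hb) in enumerate(zip(self.haplotypes[a], self.haplotypes[b]), start=1):
            pairs = []
            for m1 in ha:
                for m2 in hb:
                    pairs.extend(_matching_intervals(m1, m2))
            for s, e in _union_intervals(pairs):
                out.append((c, s * 100.0, e * 100.0))
        return out

    def roh_segments(self, a: str) -> list[tuple[int, float, float]]:
        out = []
        for c, (m1, m2) in enumerate(self.haplotypes[a], start=1):
            for s, e in _matching_intervals(m1, m2):
                out.append((c, s * 100.0, e * 100.0))
        return out

    def true_segments(self, pairs: list[tuple[str, str]] | None = None) -> TrueSegments:
        members = list(self.pedigree.members)
        if pairs is None:
            pairs = [(a, b) for i, a in enumerate(members) for b in members[i + 1:]]
        ibd_recs = [
            (a, b, c, s, e, e - s) for a, b in pairs for c, s, e in self.ibd_segments(a, b)
        ]
        roh_recs = [(m, c, s, e, e - s) for m in members for c, s, e in self.roh_segments(m)]
        return TrueSegments(
            ibd=pd.DataFrame(ibd_recs, columns=["iid1", "iid2", "chrom", "start_cM", "end_cM", "length_cM"]),
            roh=pd.DataFrame(roh_recs, columns=["iid", "chrom", "start_cM", "end_cM", "length_cM"]),
        )


def simulate_pedigree(
    pedigree: Pedigree,
    seed: int,
    chrom_lengths_m: np.ndarray | None = None,
) -> PedigreeRealization:
    """Drop haplotypes through the pedigree by simulated meiosis.

    Founders receive two uniquely labeled haplotypes per chromosome;
    each child receives one recombined gamete from each parent.
    """
    lengths = DEFAULT_CHROM_LENGTHS_M if chrom_lengths_m is None else np.asarray(chrom_lengths_m, float)
    if (lengths <= 0).any():
        raise ValueError("chromosome map lengths must be positive")
    rng = np.random.default_rng(seed)
    haps: dict[str, list[tuple[Mosaic, Mosaic]]] = {}
    next_label = 0
    for member in pedigree.topological_order():
        parents = pedigree.members[member]
        if parents is None:
            haps[member] = [
                (
                    (np.array([length]), np.array([next_label])),
                    (np.array([length]), np.array([next_label + 1])),
                )
                for length in lengths
            ]
            next_label += 2
        else:
            father, mother = parents
            haps[member] = [
                (
                    _meiose(*haps[father][c], lengths[c], rng),
                    _meiose(*haps[mother][c], lengths[c], rng),
                )
                for c in range(len(lengths))
            ]
    return PedigreeRealization(pedigree=pedigree, chrom_lengths_m=lengths, haplotypes=haps)


def lineal_pedigree(n_meioses: int) -> Pedigree:
    """Ancestor 'G0' and lineal descendant 'G<n>' separated by
    ``n_meioses`` meioses, with unrelated founder mates."""
    ped = Pedigree()
    ped.add_founder("G0")
    ped.add_founder("M0")
    ped.add_child("G1", "G0", "M0")
    for g in range(2, n_meioses + 1):
        ped.add_founder(f"M{g - 1}")
        ped.add_child(f"G{g}", f"G{g - 1}", f"M{g - 1}")
    return ped


def sibling_pedigree() -> Pedigree:
    ped = Pedigree()
    ped.add_founder("F")
    ped.add_founder("M")
    ped.add_child("S1", "F", "M")
    ped.add_child("S2", "F", "M")
    return ped


def cousin_offspring_pedigree(degree: int = 1) -> Pedigree:
    """Offspring of cousins of the given degree (1 = first cousins,
    inbreeding coefficient F = 1/16)."""
    ped = Pedigree()
    ped.add_founder("GF")
    ped.add_founder("GM")
    ped.add_child("P1", "GF", "GM")
    ped.add_child("P2", "GF", "GM")
    left, right = "P1", "P2"
    for d in range(1, degree):
        ped.add_founder(f"ML{d}")
        ped.add_founder(f"MR{d}")
        ped.add_child(f"C1_{d}", left, f"ML{d}")
        ped.add_child(f"C2_{d}", right, f"MR{d}")
        left, right = f"C1_{d}", f"C2_{d}"
    ped.add_founder("SL")
    ped.add_founder("SR")
    ped.add_child("A", left, "SL")
    ped.add_child("B", right, "SR")
    ped.add_child("O", "A", "B")
    return ped


def second_degree_offspring_pedigree() -> Pedigree:
    """Offspring of half-siblings (parents are second-degree relatives;
    offspring inbreeding coefficient F = 1/8)."""
    ped = Pedigree()
    ped.add_founder("F")
    ped.add_founder("M1")
    ped.add_founder("M2")
    ped.add_child("H1", "F", "M1")
    ped.add_child("H2", "F", "M2")
    ped.add_child("O", "H1", "H2")
    return ped


def assign_haplogroups(
    sites: list[str],
    spectra: dict[str, dict[str, float]],
    counts: dict[str, int],
    seed: int,
) -> pd.DataFrame:
    """Multinomial per-site Y-haplogroup draws.

    ``spectra`` maps site -> {haplogroup: frequency} (each summing to
    1); ``counts`` gives the number of males per site.
    """
    rng = np.random.default_rng(seed)
    recs = []
    for site in sites:
        spectrum = spectra[site]
        n = counts[site]
        if n < 0:
            raise ValueError(f"negative male count for site {site}")
        total = sum(spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplogroup spectrum for {site} sums to {total}, not 1")
        labels = list(spectrum)
        draws = rng.multinomial(n, [spectrum[h] for h in labels])
        i = 0
        for label, k in zip(labels, draws):
            for _ in range(k):
                recs.append((f"{site}_m{i}", site, "male", label))
                i += 1
    return pd.DataFrame(recs, columns=["individual_id", "site", "sex", "y_haplogroup"])
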