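"""f4-statistics with block-jackknife uncertainty and qpAdm-style
admixture model fitting.

The f4-statistic between populations (A, B; C, D) is the average over
SNPs of (pA - pB)(pC - pD), where p are alternate-allele frequencies.
Standard errors come from a delete-one-block jackknife over contiguous
genomic blocks, which is robust to linkage disequilibrium.

Admixture models are fit in the established weighted-least-squares
formulation: with rights R1..Rm (R1 the fixed anchor) and lefts
S1..SL, the target T satisfies, under the model,

    f4(T, R1; Rj, R1) = sum_i w_i f4(Si, R1; Rj, R1)   for j = 2..m,

with sum_i w_i = 1.  Weights minimize the residual in the metric of the
block-jackknife covariance; the residual norm is chi-squared with
m - L degrees of freedom under the model, giving the model p-value.
A model is *feasible* when all weights are non-negative and *valid*
when additionally p >= 0.05.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .eigenstrat import GenotypeTable

RIDGE_CONDITION_LIMIT = 1e12
RIDGE_SCALE = 1e-10
FEASIBILITY_TOL = 1e-9


@dataclass(frozen=True)
class BlockScheme:
    """Assignment of SNPs to contiguous genomic blocks.

    ``block_ids`` maps each SNP (in table order) to a block index in
    ``0..n_blocks-1``; blocks never span chromosome boundaries.
    """

    block_ids: np.ndarray
    n_blocks: int

    @classmethod
    def contiguous(
        cls,
        snps: pd.DataFrame,
        n_blocks: int | None = None,
        block_morgans: float = 0.05,
        max_blocks: int = 700,
    ) -> "BlockScheme":
        """Equal-SNP-count contiguous blocks.

        The default block count targets ~0.05 Morgans per block, capped
        at ``max_blocks`` (the coarser of the two wins); pass
        ``n_blocks`` to override.  Blocks are allocated to chromosomes
        proportionally to their SNP counts, at least one per chromosome.
        """
        chrom = snps["chromosome"].to_numpy()
        if n_blocks is None:
            gpos = snps["genetic_pos"].to_numpy()
            total_m = sum(
                gpos[chrom == c].max() - gpos[chrom == c].min()
                for c in np.unique(chrom)
                if (chrom == c).sum() > 1
            )
            n_blocks = int(min(max_blocks, max(1, round(total_m / block_morgans))))
        n_blocks = max(n_blocks, len(np.unique(chrom)))
        ids = np.empty(len(snps), dtype=np.int64)
        # proportional allocation, then contiguous equal-count split per chromosome
        uniq, counts = np.unique(chrom, return_counts=True)
        alloc = np.maximum(1, np.round(counts / counts.sum() * n_blocks).astype(int))
        next_id = 0
        for c, k in zip(uniq, alloc):
            idx = np.flatnonzero(chrom == c)
            k = min(k, len(idx))
            edges = np.linspace(0, len(idx), k + 1).astype(int)
            for b in range(k):
                ids[idx[edges[b]:edges[b + 1]]] = next_id
                next_id += 1
        return cls(block_ids=ids, n_blocks=next_id)


@dataclass
class FStatEstimate:
    """A single f-statistic with its jackknife standard error."""

    value: float
    std_err: float
    n_snps_used: int


@dataclass
class AdmixtureModelFit:
    """One fitted admixture model for one target."""

    target: str
    left_set: tuple[str, ...]
    right_set: tuple[str, ...]
    weights: np.ndarray
    weight_ses: np.ndarray
    chi_square: float
    dof: int
    p_value: float
    feasible: bool
    valid: bool
    scheme: str | None = None

    def weight_of(self, source: str) -> float:
        """Weight of ``source``, 0.0 when the model omits it."""
        try:
            return float(self.weights[self.left_set.index(source)])
        except ValueError:
            return 0.0

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "left_set": list(self.left_set),
            "right_set": list(self.right_set),
            "weights": [float(w) for w in self.weights],
            "weight_ses": [float(s) for s in self.weight_ses],
            "chi_square": float(self.chi_square),
            "dof": self.dof,
            "p_value": float(self.p_value),
            "feasible": self.feasible,
            "valid": self.valid,
            "scheme": self.scheme,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def weighted_jackknife(
    total_sum: float, total_count: float, block_sums: np.ndarray, block_counts: np.ndarray
) -> tuple[float, float]:
    """Delete-one-block jackknife mean and SE for a ratio statistic
    sum/count, blocks weighted by their SNP counts (Busing et al. 1999).
    """
    use = block_counts > 0
    bs, bc = block_sums[use], block_counts[use]
    g = len(bs)
    theta = total_sum / total_count
    if g < 2:
        return theta, 0.0
    loo = (total_sum - bs) / (total_count - bc)
    h = total_count / bc
    theta_j = g * theta - np.sum((1.0 - bc / total_count) * loo)
    tau = h * theta - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return theta, float(np.sqrt(var))


class F4Engine:
    """Caches per-population frequencies and per-block cross-products so
    that many f4 statistics and model fits over the same table are cheap.

    All statistics here are of the anchored form f4(P, anchor; R, anchor);
    general quadruples go through :func:`f4`.
    """

    def __init__(self, table: GenotypeTable, blocks: BlockScheme):
        self.table = table
        self.blocks = blocks
        auto = table.autosomal_mask()
        self._auto = auto
        self._freqs: dict[str, np.ndarray] = {}
        self._sums_cache: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}

    def freq(self, label: str) -> np.ndarray:
        if label not in self._freqs:
            self._freqs[label] = self.table.allele_frequencies(label)
        return self._freqs[label]

    def anchored_block_sums(
        self, pop: str, right: str, anchor: str, mask: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Block sums and counts of (p_pop - p_anchor)(p_right - p_anchor).

        ``mask`` restricts the usable SNPs (intersection mode); by
        default every autosomal SNP covered in all three populations is
        used (allsnps mode), and the result is cached.
        """
        key = (pop, right, anchor)
        if mask is None and key in self._sums_cache:
            return self._sums_cache[key]
        fp, fr, fa = self.freq(pop), self.freq(right), self.freq(anchor)
        ok = self._auto & np.isfinite(fp) & np.isfinite(fr) & np.isfinite(fa)
        if mask is not None:
            ok = ok & mask
        prod = (fp[ok] - fa[ok]) * (fr[ok] - fa[ok])
        ids = self.blocks.block_ids[ok]
        sums = np.bincount(ids, weights=prod, minlength=self.blocks.n_blocks)
        counts = np.bincount(ids, minlength=self.blocks.n_blocks).astype(float)
        if mask is None:
            self._sums_cache[key] = (sums, counts)
        return sums, counts

    def coverage_mask(self, labels: list[str]) -> np.ndarray:
        ok = self._auto.copy()
        for lab in labels:
            ok &= np.isfinite(self.freq(lab))
        return ok


def f4(
    table: GenotypeTable,
    a: str,
    b: str,
    c: str,
    d: str,
    blocks: BlockScheme,
    use_all_snps: bool = True,
    _model_pops: list[str] | None = None,
) -> FStatEstimate:
    """f4(a, b; c, d) with weighted block-jackknife standard error.

    With ``use_all_snps`` (the *allsnps* convention) every autosomal SNP
    covered in all four populations of this statistic is used; otherwise
    the SNP set is the intersection across ``_model_pops`` (defaulting
    to the four populations themselves).
    """
    freqs = [table.allele_frequencies(x) for x in (a, b, c, d)]
    ok = table.autosomal_mask()
    for f in freqs:
        ok = ok & np.isfinite(f)
    if not use_all_snps:
        for lab in _model_pops or []:
            ok = ok & np.isfinite(table.allele_frequencies(lab))
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no usable SNPs for f4({a},{b};{c},{d})")
    prod = (freqs[0][ok] - freqs[1][ok]) * (freqs[2][ok] - freqs[3][ok])
    ids = blocks.block_ids[ok]
    sums = np.bincount(ids, weights=prod, minlength=blocks.n_blocks)
    counts = np.bincount(ids, minlength=blocks.n_blocks).astype(float)
    value, se = weighted_jackknife(prod.sum(), float(n), sums, counts)
    return FStatEstimate(value=value, std_err=se, n_snps_used=n)


def _constrained_wls(
    y: np.ndarray, x: np.ndarray, omega_inv: np.ndarray
) -> tuple[np.ndarray, float]:
    """Minimize (y - Xw)' Oi (y - Xw) subject to sum(w) = 1."""
    xt_oi = x.T @ omega_inv
    a = xt_oi @ x
    g = np.linalg.pinv(a)
    w_u = g @ (xt_oi @ y)
    ones = np.ones(x.shape[1])
    g1 = g @ ones
    w = w_u + g1 * (1.0 - ones @ w_u) / (ones @ g1)
    resid = y - x @ w
    return w, float(resid @ omega_inv @ resid)


def _regularized_inverse(omega: np.ndarray) -> np.ndarray:
    tr = np.trace(omega)
    if tr <= 0 or not np.isfinite(tr):
        omega = omega + np.eye(len(omega)) * 1e-30
        tr = np.trace(omega)
    if np.linalg.cond(omega) > RIDGE_CONDITION_LIMIT:
        warnings.warn("singular f4 covariance; applying ridge regularization")
        omega = omega + np.eye(len(omega)) * RIDGE_SCALE * tr
    return np.linalg.inv(omega)


def qpadm_fit(
    table: GenotypeTable,
    target: str,
    left_set: list[str],
    right_set: list[str],
    blocks: BlockScheme,
    use_all_snps: bool = True,
    validity_alpha: float = 0.05,
    scheme: str | None = None,
    engine: F4Engine | None = None,
    n_gls_iter: int = 4,
) -> AdmixtureModelFit:
    """Fit the target as a mixture of the left populations.

    ``right_set[0]`` is the anchor.  Requires
    ``len(right_set) >= len(left_set) + 2`` so the chi-squared test has
    at least one degree of freedom.
    """
    left_set = list(left_set)
    right_set = list(right_set)
    n_l, n_r = len(left_set), len(right_set)
    if n_r < n_l + 2:
        raise ValueError(f"need >= {n_l + 2} right populations for {n_l} lefts, got {n_r}")
    if engine is None:
        engine = F4Engine(table, blocks)
    anchor = right_set[0]
    rights = right_set[1:]
    pops = left_set + [target]

    mask = None
    if not use_all_snps:
        mask = engine.coverage_mask(pops + right_set)
        if not mask.any():
            raise ValueError("no SNPs covered across all model populations")

    n_b = blocks.n_blocks
    j, L = len(rights), n_l
    # stacked statistic vector v = [y ; X columns], plus leave-one-block-out values
    sums = np.empty((j, L + 1, n_b))
    counts = np.empty((j, L + 1, n_b))
    for jj, r in enumerate(rights):
        for pp, p in enumerate(pops):
            s, c = engine.anchored_block_sums(p, r, anchor, mask=mask)
            sums[jj, L if p == target else pp] = s
            counts[jj, L if p == target else pp] = c
    tot_s, tot_c = sums.sum(axis=2), counts.sum(axis=2)
    if (tot_c == 0).any():
        bad = [(rights[a], pops[b]) for a, b in zip(*np.nonzero(tot_c == 0))]
        raise ValueError(f"zero usable SNPs for statistics involving {bad}")
    full = tot_s / tot_c                            # (j, L+1)
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_s[:, :, None] - sums) / (tot_c[:, :, None] - counts)   # (j, L+1, n_b)
    # blocks empty for every statistic contribute nothing; restore full value
    loo = np.where(np.isfinite(loo), loo, full[:, :, None])

    x_full, y_full = full[:, :L], full[:, L]
    v_loo = np.moveaxis(loo, 2, 0).reshape(n_b, j * (L + 1))
    v_bar = v_loo.mean(axis=0)
    dev = v_loo - v_bar
    cov_v = (n_b - 1) / n_b * (dev.T @ dev)

    # covariance of the residual vector via linearity in the stacked stats
    cov_v4 = cov_v.reshape(j, L + 1, j, L + 1)

    def residual_cov(w: np.ndarray) -> np.ndarray:
        coef = np.append(-w, 1.0)                  # e_j = [X_j, y_j] . [-w, 1]
        return np.einsum("a,jakb,b->jk", coef, cov_v4, coef)

    w = np.full(L, 1.0 / L)
    for _ in range(n_gls_iter):
        omega_inv = _regularized_inverse(residual_cov(w))
        w, chi2 = _constrained_wls(y_full, x_full, omega_inv)

    # weight SEs: delete-one-block refits at the converged metric
    loo_w = np.empty((n_b, L))
    y_loo, x_loo = loo[:, L, :], loo[:, :L, :]
    for b in range(n_b):
        loo_w[b], _ = _constrained_wls(y_loo[:, b], x_loo[:, :, b], omega_inv)
    w_bar = loo_w.mean(axis=0)
    ses = np.sqrt((n_b - 1) / n_b * ((loo_w - w_bar) ** 2).sum(axis=0))

    dof = n_r - n_l
    p_value = float(stats.chi2.sf(chi2, dof))
    feasible = bool((w >= -FEASIBILITY_TOL).all())
    return AdmixtureModelFit(
        target=target,
        left_set=tuple(left_set),
        right_set=tuple(right_set),
        weights=w,
        weight_ses=ses,
        chi_square=chi2,
        dof=dof,
        p_value=p_value,
        feasible=feasible,
        valid=feasible and p_value >= validity_alpha,
        scheme=scheme,
    )


def lrt_nested(fit_restricted: AdmixtureModelFit, fit_full: AdmixtureModelFit) -> float:
    """Likelihood-ratio p-value between nested models differing by one
    source; the chi-square drop is referred to chi-squared(1), clamped at
    zero when the restricted model fits (numerically) better.
    """
    small, big = set(fit_restricted.left_set), set(fit_full.left_set)
    if not (small < big and len(big - small) == 1):
        raise ValueError(
            f"models are not nested with one extra source: {sorted(small)} vs {sorted(big)}"
        )
    if fit_restricted.right_set != fit_full.right_set:
        raise ValueError("nested models must share the same right set")
    statistic = max(0.0, fit_restricted.chi_square - fit_full.chi_square)
    return float(stats.chi2.sf(statistic, 1))
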