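"""Reference-panel PCA with least-squares projection of ancient
individuals, shrinkage correction, the PC-cline ancestry estimator,
and PC-space site diversity.

Ancient individuals are never included in the PCA itself: components
are computed from a (well-covered, typically modern) reference panel,
and each ancient individual is projected by least squares restricted
to its covered SNPs.  Because projected samples are pulled toward the
origin relative to the reference (the high-dimensional shrinkage
effect that smartpca's shrinkmode compensates), per-component
shrinkage factors are estimated by leave-one-out projection of
reference individuals and divided out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .eigenstrat import GenotypeTable, MISSING


@dataclass
class PcaModel:
    """Fitted reference PCA: per-SNP normalization plus K loading
    vectors, eigenvalues, and shrinkage factors."""

    snp_ids: np.ndarray
    mean: np.ndarray          # per-SNP mean dosage among reference calls
    norm: np.ndarray          # per-SNP sqrt(p(1-p)) scaling
    loadings: np.ndarray      # (n_snps, K), orthonormal columns
    eigenvalues: np.ndarray
    shrinkage: np.ndarray     # per-component factor in (0, 1]
    reference_scores: np.ndarray  # (n_ref, K)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        snps = pd.DataFrame({"snp_id": self.snp_ids, "mean": self.mean, "norm": self.norm})
        snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
        pd.DataFrame(self.loadings).to_csv(outdir / "loadings.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"eigenvalue": self.eigenvalues, "shrinkage": self.shrinkage}
        ).to_csv(outdir / "components.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "PcaModel":
        indir = Path(indir)
        snps = pd.read_csv(indir / "snps.tsv", sep="\t")
        loadings = pd.read_csv(indir / "loadings.tsv", sep="\t").to_numpy()
        comps = pd.read_csv(indir / "components.tsv", sep="\t")
        return cls(
            snp_ids=snps["snp_id"].to_numpy(),
            mean=snps["mean"].to_numpy(),
            norm=snps["norm"].to_numpy(),
            loadings=loadings,
            eigenvalues=comps["eigenvalue"].to_numpy(),
            shrinkage=comps["shrinkage"].to_numpy(),
            reference_scores=np.empty((0, loadings.shape[1])),
        )


@dataclass
class Projection:
    individual_id: str
    coordinates: np.ndarray


@dataclass
class ClineEstimate:
    fraction_b: float
    centroid_a: np.ndarray
    centroid_b: np.ndarray


def _normalized_reference(reference: GenotypeTable):
    calls = reference.calls.astype(float)
    calls[calls == MISSING] = np.nan
    n_called = np.isfinite(calls).sum(axis=1)
    dosage_sum = np.nansum(calls, axis=1)
    keep = n_called > 0
    mean = np.where(keep, dosage_sum / np.maximum(n_called, 1), 0.0)
    p_hat = (1.0 + dosage_sum) / (2.0 + 2.0 * n_called)   # shrunk frequency
    poly = keep & (mean > 0) & (mean < 2)
    n_dropped = int((~poly).sum())
    norm = np.sqrt(p_hat * (1.0 - p_hat))
    z = (calls - mean[:, None]) / norm[:, None]
    z[~np.isfinite(z)] = 0.0                               # mean-impute missing
    return z[poly].T, mean[poly], norm[poly], poly, n_dropped


def fit_pca(
    reference: GenotypeTable,
    n_components: int = 2,
    shrinkage: str = "loo",
    loo_size: int = 30,
    seed: int = 0,
) -> PcaModel:
    """PCA of a reference panel.

    SNPs are centered by reference mean dosage and scaled by
    sqrt(p(1-p)) with p the shrunk reference frequency; monomorphic
    SNPs are dropped (count reported in a warning); missing reference
    calls are mean-imputed.  ``shrinkage='loo'`` estimates per-component
    shrinkage factors from leave-one-out projections of up to
    ``loo_size`` reference individuals; ``'none'`` fixes them at 1.
    """
    if n_components < 2:
        raise ValueError("need at least 2 components")
    z, mean, norm, poly, n_dropped = _normalized_reference(reference)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} monomorphic/uncovered SNPs from the reference")
    n_ref = z.shape[0]
    rank = min(z.shape)
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is at most {rank}")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:n_components].T
    scores = u[:, :n_components] * s[:n_components]
    eigenvalues = s[:n_components] ** 2 / max(n_ref - 1, 1)

    factors = np.ones(n_components)
    if shrinkage == "loo" and n_ref > n_components + 1:
        rng = np.random.default_rng(seed)
        subset = rng.choice(n_ref, size=min(loo_size, n_ref), replace=False)
        loo_abs = np.zeros(n_components)
        for i in subset:
            z_i = np.delete(z, i, axis=0)
            _, _, vt_i = np.linalg.svd(z_i, full_matrices=False)
            v_i = vt_i[:n_components].T
            coords, *_ = np.linalg.lstsq(v_i, z[i], rcond=None)
            loo_abs += np.abs(coords)
        full_abs = np.abs(scores[subset]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.clip(loo_abs / full_abs, 1e-6, 1.0)
        factors[~np.isfinite(factors)] = 1.0
    return PcaModel(
        snp_ids=reference.snps["snp_id"].to_numpy()[poly],
        mean=mean,
        norm=norm,
        loadings=loadings,
        eigenvalues=eigenvalues,
        shrinkage=factors,
        reference_scores=scores,
    )


def project(
    model: PcaModel,
    table: GenotypeTable,
    individual_id: str,
    min_snps: int = 20000,
) -> Projection:
    """Least-squares projection of one individual onto the model's
    components, restricted to its covered SNPs and corrected by the
    per-component shrinkage factors.

    Refuses individuals with fewer than ``min_snps`` covered SNPs
    overlapping the model.
    """
    col = table.individual_index(individual_id)
    order = pd.Index(table.snps["snp_id"]).get_indexer(model.snp_ids)
    if (order < 0).any():
        raise ValueError("table does not contain all model SNPs")
    calls = table.calls[order, col].astype(float)
    covered = calls != MISSING
    n_cov = int(covered.sum())
    if n_cov < min_snps:
        raise ValueError(
            f"{individual_id}: only {n_cov} covered SNPs overlap the model "
            f"(minimum {min_snps})"
        )
    z = (calls[covered] - model.mean[covered]) / model.norm[covered]
    coords, *_ = np.linalg.lstsq(model.loadings[covered], z, rcond=None)
    return Projection(individual_id=individual_id, coordinates=coords / model.shrinkage)


def project_reference(model: PcaModel, reference: GenotypeTable) -> list[Projection]:
    """Native PCA coordinates of the reference individuals."""
    ids = reference.individuals["individual_id"]
    return [
        Projection(individual_id=i, coordinates=model.reference_scores[k])
        for k, i in enumerate(ids)
    ]


def cline_fraction(
    proj: Projection,
    cluster_a: list[Projection],
    cluster_b: list[Projection],
) -> ClineEstimate:
    """Position of a sample along the PC1-PC2 cline from cluster A's
    centroid to cluster B's centroid, clamped to [0, 1].

    This is the PCA-based ancestry-proportion estimator: 0 means the
    sample sits at the A centroid, 1 at the B centroid.
    """
    if len(cluster_a) < 2 or len(cluster_b) < 2:
        raise ValueError("each cline endpoint cluster needs at least 2 members")
    c_a = np.mean([p.coordinates[:2] for p in cluster_a], axis=0)
    c_b = np.mean([p.coordinates[:2] for p in cluster_b], axis=0)
    axis = c_b - c_a
    denom = float(axis @ axis)
    if denom == 0.0:
        raise ValueError("cline endpoints coincide")
    t = float((proj.coordinates[:2] - c_a) @ axis) / denom
    return ClineEstimate(fraction_b=float(np.clip(t, 0.0, 1.0)), centroid_a=c_a, centroid_b=c_b)


def site_diversity(projections: list[Projection], min_individuals: int = 10) -> float | None:
    """Mean pairwise Euclidean distance in (PC1, PC2) over all
    unordered pairs of one site's individuals; None (with a warning)
    for sites below the ``min_individuals`` gate."""
    n = len(projections)
    if n < min_individuals:
        warnings.warn(f"site has {n} projectable individuals (< {min_individuals}); skipped")
        return None
    coords = np.array([p.coordinates[:2] for p in projections])
    return float(pdist(coords).mean())
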