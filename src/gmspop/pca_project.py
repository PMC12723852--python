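"""PCA on a reference panel with least-squares projection of held-out samples.

Fitting standardizes each SNP by the reference mean call and by
sqrt(p(1-p)) with a pseudocount-regularized frequency
p = (1 + sum of calls) / (2 + 2 n_nonmissing); missing reference calls are
mean-imputed before the singular value decomposition. Held-out samples (for
example ancient or low-coverage individuals) are placed by solving the
least-squares problem restricted to their non-missing loci — the behaviour
that distinguishes proper projection from naive imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class PcaModel:
    snp_means: np.ndarray          # per-SNP reference mean call
    snp_scales: np.ndarray         # per-SNP sqrt(p(1-p)), > 0
    loadings: np.ndarray           # (snps, k), orthonormal columns
    eigenvalues: np.ndarray        # k, non-increasing
    reference_coords: np.ndarray   # (ref samples, k)
    reference_ids: list = field(default_factory=list)


@dataclass
class Projection:
    sample_id: str
    coords: np.ndarray
    n_snps_used: int


def fit_pca(
    G: GenotypeMatrix, reference_samples: list[str], k: int
) -> PcaModel:
    """Fit a k-component PCA model on the reference samples.

    Requires every SNP to have at least one non-missing reference call and
    ``k < min(n_reference, n_snps)``.
    """
    ids = G.samples["sample_id"].to_numpy()
    ref_set = set(reference_samples)
    ref_idx = np.nonzero(np.isin(ids, list(ref_set)))[0]
    missing_refs = ref_set - set(ids[ref_idx])
    if missing_refs:
        raise KeyError(f"reference samples not in dataset: {sorted(missing_refs)}")
    n_ref = len(ref_idx)
    if not k < min(n_ref, G.n_snps):
        raise ValueError(f"k={k} must be < min(n_ref={n_ref}, n_snps={G.n_snps})")

    calls = G.calls[ref_idx].astype(np.float64)
    nonmiss = calls != MISSING
    if not nonmiss.any(axis=0).all():
        raise ValueError("some SNPs have no non-missing reference calls")
    calls[~nonmiss] = 0.0
    n_nm = nonmiss.sum(axis=0)
    sums = calls.sum(axis=0)
    means = sums / n_nm
    p_hat = (1.0 + sums) / (2.0 + 2.0 * n_nm)  # pseudocount keeps scale > 0
    scales = np.sqrt(p_hat * (1.0 - p_hat))

    X = (calls - means) / scales
    X[~nonmiss] = 0.0  # mean imputation after centering

    # thin SVD of the standardized matrix
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:k].T
    eigenvalues = (S[:k] ** 2) / max(n_ref - 1, 1)
    coords = U[:, :k] * S[:k]
    return PcaModel(
        snp_means=means,
        snp_scales=scales,
        loadings=loadings,
        eigenvalues=eigenvalues,
        reference_coords=coords,
        reference_ids=ids[ref_idx].tolist(),
    )


def project(
    model: PcaModel, sample_calls: np.ndarray, sample_id: str = ""
) -> Projection:
    """Least-squares projection of one call vector onto the fitted components.

    Coordinates c minimize || x_obs - L_obs c ||^2 over the sample's
    non-missing loci, where x is the standardized call vector and L the
    loadings restricted to those loci.
    """
    calls = np.asarray(sample_calls, dtype=np.float64)
    if calls.shape != (model.loadings.shape[0],):
        raise ValueError("call vector length does not match the model")
    obs = calls != MISSING
    k = model.loadings.shape[1]
    n_used = int(obs.sum())
    if n_used < k:
        raise ValueError(f"only {n_used} usable loci for k={k} components")
    x = (calls[obs] - model.snp_means[obs]) / model.snp_scales[obs]
    L = model.loadings[obs]
    coords, *_ = np.linalg.lstsq(L, x, rcond=None)
    return Projection(sample_id=sample_id, coords=coords, n_snps_used=n_used)


def pca_coords_frame(
    model: PcaModel, projections: list[Projection] | None = None
) -> pd.DataFrame:
    """Reference and projected coordinates as a tidy table."""
    k = model.loadings.shape[1]
    cols = [f"PC{i + 1}" for i in range(k)]
    rows = []
    for sid, c in zip(model.reference_ids, model.reference_coords):
        rows.append({"sample_id": sid, **dict(zip(cols, c)),
                     "n_snps_used": model.loadings.shape[0], "projected_flag": 0})
    for proj in projections or []:
        rows.append({"sample_id": proj.sample_id, **dict(zip(cols, proj.coords)),
                     "n_snps_used": proj.n_snps_used, "projected_flag": 1})
    return pd.DataFrame(rows)
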