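"""Genotype-matrix computations: relatedness, LD, pruning, heterozygosity, PCs."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from arcticfit.panel import GenotypePanel

log = logging.getLogger(__name__)


class UndefinedLDError(ValueError):
    """LD is undefined (monomorphic marker or too few complete pairs)."""


@dataclass
class GRM:
    """Genomic relatedness matrix with the allele frequencies used to scale it."""

    matrix: np.ndarray
    ids: np.ndarray
    allele_freqs: np.ndarray
    snp_indices: np.ndarray
    method: str = "vanraden"

    def __post_init__(self) -> None:
        self.matrix = 0.5 * (self.matrix + self.matrix.T)  # enforce symmetry


def _imputed_centred(panel: GenotypePanel):
    """Mean-imputed, centred dosage matrix; returns (Z, freqs, kept indices).

    Monomorphic and all-missing SNPs are excluded (logged)."""
    X = panel.dosage.copy()
    n_called = (~np.isnan(X)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(X, axis=0) / 2.0
        col_var = np.nanvar(X, axis=0)
    keep = (n_called > 0) & (col_var > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("excluding %d monomorphic or all-missing SNPs", n_dropped)
    X = X[:, keep]
    p = p[keep]
    inds = np.where(np.isnan(X))
    X[inds] = 2.0 * p[inds[1]]
    Z = X - 2.0 * p[None, :]
    return Z, p, np.flatnonzero(keep)


def compute_grm(panel: GenotypePanel, method: str = "vanraden") -> GRM:
    """Centred, frequency-scaled genomic relatedness matrix.

    ``vanraden`` (default) scales the cross-product by 2Σp(1−p) pooled over
    SNPs; ``gcta`` scales each SNP by its own 2p(1−p) before averaging
    (identity-by-state kinship convention).  Missing dosages are mean-imputed
    per SNP before centring.
    """
    if panel.n_individuals < 2:
        raise ValueError("GRM needs at least two individuals")
    Z, p, kept = _imputed_centred(panel)
    if Z.shape[1] == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    het = 2.0 * p * (1.0 - p)
    if method == "vanraden":
        G = (Z @ Z.T) / het.sum()
    elif method == "gcta":
        Zs = Z / np.sqrt(het)[None, :]
        G = (Zs @ Zs.T) / Z.shape[1]
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    return GRM(matrix=G, ids=np.asarray(panel.ids), allele_freqs=p, snp_indices=kept, method=method)


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of dosages on pairwise-complete entries.

    Raises :class:`UndefinedLDError` when fewer than three complete pairs
    exist or either vector is monomorphic on the complete subset.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 3:
        raise UndefinedLDError("fewer than 3 pairwise-complete observations")
    a, b = g1[ok], g2[ok]
    if a.var() == 0 or b.var() == 0:
        raise UndefinedLDError("monomorphic marker on the complete subset")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _window_vifs(R: np.ndarray) -> np.ndarray:
    """VIF_j = [R⁻¹]_jj for a marker correlation matrix; inf when singular."""
    try:
        vifs = np.diag(np.linalg.inv(R)).copy()
    except np.linalg.LinAlgError:
        return np.full(R.shape[0], np.inf)
    if np.linalg.cond(R) > 1e10:
        # near-singular: flag the perfectly correlated markers
        close = (np.abs(R - np.eye(R.shape[0])) > 1 - 1e-9).any(axis=0)
        vifs[close] = np.inf
    return vifs


def ld_prune(
    panel: GenotypePanel,
    window_snps: int = 50,
    step_snps: int = 5,
    vif_threshold: float = 2.0,
) -> np.ndarray:
    """Sliding-window VIF pruning (PLINK ``indep`` semantics, defaults 50, 5, 2).

    Windows of ``window_snps`` markers advance by ``step_snps`` within each
    scaffold; inside a window the marker with the highest variance inflation
    factor is removed until all VIF < threshold (ties broken by removing the
    later marker in map order).  Returns the retained marker indices.
    """
    Z, _, kept = _imputed_centred(panel)
    sd = Z.std(axis=0)
    Zs = Z / sd[None, :]
    n = panel.dosage.shape[0]
    removed = np.zeros(len(kept), dtype=bool)
    scaffolds = panel.marker_map["scaffold"].to_numpy()[kept]

    for sc in pd.unique(scaffolds):
        cols = np.flatnonzero(scaffolds == sc)
        start = 0
        while True:
            window = cols[start : start + window_snps]
            active = window[~removed[window]]
            while active.size > 1:
                R = (Zs[:, active].T @ Zs[:, active]) / n
                vifs = _window_vifs(R)
                worst = vifs.max()
                if worst < vif_threshold:
                    break
                # later marker in map order among the argmax ties
                worst_local = np.flatnonzero(vifs == worst).max()
                removed[active[worst_local]] = True
                active = window[~removed[window]]
            if start + window_snps >= cols.size:
                break
            start += step_snps
    return kept[~removed]


def genomewide_heterozygosity(panel: GenotypePanel) -> pd.Series:
    """Per-individual proportion of heterozygous calls among non-missing calls."""
    het = (panel.dosage == 1).sum(axis=1)
    called = (~np.isnan(panel.dosage)).sum(axis=1)
    out = np.divide(het, called, out=np.full(len(het), np.nan), where=called > 0)
    if (called == 0).any():
        log.warning("%d individuals have zero non-missing calls", int((called == 0).sum()))
    return pd.Series(out, index=panel.ids, name="heterozygosity")


def principal_components(grm: GRM, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal coordinates of the GRM (classical MDS on relatedness).

    Returns (coordinates, variance fractions).  Coordinates are eigenvectors
    scaled by √eigenvalue; each column is signed so its largest-magnitude
    loading is positive.  Variance fraction is eigenvalue / trace.
    """
    if not np.allclose(grm.matrix, grm.matrix.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int((vals > 1e-10 * max(vals[0], 1.0)).sum())
    if k > rank:
        log.warning("requested %d components but GRM rank is %d", k, rank)
        k = rank
    vals_k = vals[:k]
    vecs_k = vecs[:, :k]
    flip = np.sign(vecs_k[np.abs(vecs_k).argmax(axis=0), np.arange(k)])
    vecs_k = vecs_k * flip[None, :]
    coords = vecs_k * np.sqrt(np.maximum(vals_k, 0.0))[None, :]
    var_frac = vals_k / np.trace(grm.matrix)
    return coords, var_frac
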