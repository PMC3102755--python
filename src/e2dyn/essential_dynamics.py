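"""Stage 2: essential dynamics.

PCA of the positional covariance matrix of a selection (typically all Cα
atoms), projections onto the leading eigenvectors, explained-variance
fractions, the cosine-content sampling diagnostic, and the 2D free-energy
landscape over the first two principal components,
ΔG(bin) = −kT ln(n_bin / n_max) in kJ/mol.

Mass weighting is supported (deviations scaled by √m); for an all-Cα
selection it is a uniform scalar and leaves eigenvectors and explained
fractions unchanged, so the default is unweighted coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structio import ConformerSet, superpose, align_frames

__all__ = [
    "PCAModel",
    "FELGrid",
    "fit_pca",
    "project",
    "explained_fraction",
    "cosine_content",
    "build_fel",
]

#: standard atomic masses (amu) for mass weighting
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

#: kT at 300 K in kJ/mol
KT_300K = 2.494


@dataclass
class PCAModel:
    """Eigendecomposition of the covariance of positional fluctuations.

    ``eigenvectors`` has orthonormal columns in descending-eigenvalue
    order; eigenvalues are in Ų (amu·Ų when mass-weighted).
    ``mean_coords`` is the self-consistent alignment target: frames are
    superposed onto it (over the selection) before deviations are taken.
    """

    mean_coords: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    selection: np.ndarray
    mass_weights: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")


def _align_deviations(cs: ConformerSet, model: PCAModel) -> np.ndarray:
    """(F, 3n) deviations of the selection from the model mean after
    superposing each frame (over the selection) onto the mean."""
    sel = model.selection
    mean = model.mean_coords
    w = np.sqrt(model.mass_weights)
    aligned = align_frames(cs.frames[:, sel, :], mean, None)
    return ((aligned - mean) * w[None, :, None]).reshape(cs.n_frames, -1)


def fit_pca(cs: ConformerSet, selection, mass_weighted: bool = False) -> PCAModel:
    """PCA of the selection's positional fluctuations.

    Frames are iteratively superposed onto their own average (starting
    from the two-pass rule and continued to a fixed point, so that the
    average of the aligned frames *is* the alignment target); the
    covariance C = ⟨Δx Δxᵀ⟩ of the aligned deviations is then
    eigendecomposed.  Eigenvector signs follow the convention that each
    column's largest-magnitude component is positive.
    """
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("selection is empty")
    if cs.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    X = cs.frames[:, selection, :]
    F, n, _ = X.shape
    superpose(X[0], X[0], None)  # contract checks (count, collinearity)

    # iterate align-to-mean to self-consistency, from an order-invariant start
    mean = X.mean(axis=0)
    for _ in range(20):
        aligned = align_frames(X, mean, None)
        new_mean = aligned.mean(axis=0)
        drift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if drift < 1e-10:
            break

    masses = np.ones(n)
    if mass_weighted:
        elements = cs.atoms["element"].to_numpy()[selection]
        masses = np.array([ATOMIC_MASSES.get(e, 12.011) for e in elements])
    model_stub = PCAModel(
        mean_coords=mean,
        eigenvectors=np.eye(3 * n),
        eigenvalues=np.zeros(3 * n),
        selection=selection,
        mass_weights=masses,
    )
    dev = _align_deviations(cs, model_stub)
    dev -= dev.mean(axis=0)
    C = dev.T @ dev / F
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-|component| positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip[None, :]
    return PCAModel(
        mean_coords=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        selection=selection,
        mass_weights=masses,
    )


def project(cs: ConformerSet, model: PCAModel, k: int) -> np.ndarray:
    """(F, k) projections p_i(t) = v_iᵀ Δx(t) onto the first k eigenvectors."""
    if not (1 <= k <= model.eigenvectors.shape[1]):
        raise ValueError(f"k must be in [1, {model.eigenvectors.shape[1]}]")
    # deviations are taken about the model mean; by construction of fit_pca
    # the aligned-frame average coincides with it for the fitting ensemble
    dev = _align_deviations(cs, model)
    return dev @ model.eigenvectors[:, :k]


def explained_fraction(model: PCAModel, k: int) -> float:
    """Fraction of total positional variance carried by the first k PCs."""
    total = float(model.eigenvalues.sum())
    if not (1 <= k <= model.eigenvalues.size):
        raise ValueError(f"k must be in [1, {model.eigenvalues.size}]")
    if total == 0:
        return 0.0
    return float(model.eigenvalues[:k].sum() / total)


def cosine_content(p: np.ndarray) -> float:
    """Cosine content of a projection series.

    c = (2/T) (Σ_t p(t) cos(πt/T))² / Σ_t p(t)², t = 0..T−1, with the
    series mean-centered first.  Values near 1 indicate random-diffusion-
    like (unconverged) sampling; an all-zero series returns 0 by
    convention.  Invariant to scaling of p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("cosine_content expects a 1D series")
    T = p.size
    if T < 4:
        raise ValueError("series too short")
    p = p - p.mean()
    denom = float(np.sum(p * p))
    if denom == 0.0:
        return 0.0
    t = np.arange(T)
    num = float(np.sum(p * np.cos(np.pi * t / T))) ** 2
    return float((2.0 / T) * num / denom)


@dataclass
class FELGrid:
    """2D free-energy surface over PC1/PC2, kJ/mol, empty bins masked."""

    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    energy: np.ndarray
    kT: float
    mask: np.ndarray  # True where the bin is empty
    counts: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.pc1_edges) - 1, len(self.pc2_edges) - 1)
        if self.energy.shape != shape or self.mask.shape != shape:
            raise ValueError("grid shape must match bin edges")

    def bin_of(self, p2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col bin index of each (PC1, PC2) point (clipped to range)."""
        i = np.clip(np.searchsorted(self.pc1_edges, p2[:, 0], side="right") - 1, 0, self.energy.shape[0] - 1)
        j = np.clip(np.searchsorted(self.pc2_edges, p2[:, 1], side="right") - 1, 0, self.energy.shape[1] - 1)
        return i, j

    def to_frame(self) -> pd.DataFrame:
        c1 = 0.5 * (self.pc1_edges[:-1] + self.pc1_edges[1:])
        c2 = 0.5 * (self.pc2_edges[:-1] + self.pc2_edges[1:])
        ii, jj = np.meshgrid(np.arange(c1.size), np.arange(c2.size), indexing="ij")
        return pd.DataFrame(
            {
                "pc1_center": c1[ii.ravel()],
                "pc2_center": c2[jj.ravel()],
                "dG_kJ_mol": self.energy.ravel(),
                "masked": self.mask.ravel(),
            }
        )


def build_fel(
    p2: np.ndarray,
    kT: float = KT_300K,
    bins: int | tuple[int, int] = 32,
    padding: float = 0.05,
) -> FELGrid:
    """Free-energy landscape from (F, 2) PC projections.

    ΔG_bin = −kT ln(n_bin / n_max); the modal bin sits at 0 and empty bins
    are masked.  The grid spans the data range padded by ``padding`` on
    each side.
    """
    p2 = np.asarray(p2, dtype=float)
    if p2.ndim != 2 or p2.shape[1] != 2:
        raise ValueError("p2 must be (F, 2)")
    if isinstance(bins, int):
        bins = (bins, bins)
    if min(bins) < 2:
        raise ValueError("need at least 2 bins per axis")
    edges = []
    for axis, nb in zip(range(2), bins):
        lo, hi = p2[:, axis].min(), p2[:, axis].max()
        span = hi - lo
        pad = padding * span if span > 0 else 0.5
        edges.append(np.linspace(lo - pad, hi + pad, nb + 1))
    counts, _, _ = np.histogram2d(p2[:, 0], p2[:, 1], bins=edges)
    mask = counts == 0
    nmax = counts.max()
    energy = np.zeros_like(counts)
    occupied = ~mask
    energy[occupied] = -kT * np.log(counts[occupied] / nmax)
    return FELGrid(
        pc1_edges=edges[0], pc2_edges=edges[1], energy=energy, kT=kT, mask=mask, counts=counts
    )
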