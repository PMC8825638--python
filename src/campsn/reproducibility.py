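"""Sampling-consistency analysis of conformational ensembles.

Replicated ensembles are compared through their essential dynamics: each
frame is least-squares superposed on a reference structure (Cα atoms), the
3N×3N covariance of the Cα coordinates is diagonalised, and the essential
subspace (ES) of the top S principal components is retained (S = 20 by
default). Two subspaces are compared with the root-mean-square inner
product,

    RMSIP = sqrt( (1/S) Σ_{n,m} (v_n^i · v_m^j)² ),

which is 1 for identical and 0 for mutually orthogonal subspaces.
Replicas are additionally projected onto the first two principal components
of the concatenated ensemble and subjected to linear discriminant analysis
with replica labels as classes: cross-validated accuracy near chance and
high density overlap indicate that the replicas sample the same
conformational space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .interactions import ConformationalEnsemble

__all__ = [
    "EssentialSubspace",
    "ReproducibilityReport",
    "superpose_frames",
    "superpose_and_covariance",
    "essential_subspace",
    "rmsip",
    "project_and_classify",
]


def superpose_frames(
    coords: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Least-squares (Kabsch) superposition of each frame onto a reference.

    ``coords``: (n_frames, n_points, 3); ``reference``: (n_points, 3).
    Rotation + translation only; returns the aligned copy.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.ndim != 3 or coords.shape[1:] != reference.shape:
        raise ValueError("coords and reference shapes are incompatible")
    ref_centered = reference - reference.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        frame = coords[f]
        centroid = frame.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, frame - centroid)
        out[f] = rot.apply(frame - centroid) + reference.mean(axis=0)
    return out


def superpose_and_covariance(
    ensemble: ConformationalEnsemble | Sequence[ConformationalEnsemble],
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Cα covariance matrix (3N×3N, Å²) after superposition.

    Accepts a single ensemble or a list of replicas (concatenated in order).
    The reference defaults to the first frame's Cα coordinates; the
    covariance is taken about the ensemble mean of the flattened 3N vector.
    """
    ca = _stack_ca(ensemble)
    if ca.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if reference is None:
        reference = ca[0]
    if reference.shape != ca.shape[1:]:
        raise ValueError("reference does not match the Cα atom count")
    aligned = superpose_frames(ca, reference)
    flat = aligned.reshape(aligned.shape[0], -1)
    return np.cov(flat, rowvar=False, ddof=1)


def _stack_ca(
    ensemble: ConformationalEnsemble | Sequence[ConformationalEnsemble],
) -> np.ndarray:
    if isinstance(ensemble, ConformationalEnsemble):
        return ensemble.ca_coordinates()
    parts = [e.ca_coordinates() for e in ensemble]
    if not parts:
        raise ValueError("no ensembles given")
    return np.concatenate(parts, axis=0)


@dataclass
class EssentialSubspace:
    """Top-S eigenpairs of a Cα covariance matrix.

    ``eigenvectors`` holds one orthonormal 3N-vector per row, sorted by
    descending eigenvalue; each vector's sign is fixed so its
    largest-magnitude component is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    s: int
    source: str = "concatenated"

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if self.eigenvectors.shape[0] != self.s:
            raise ValueError("S does not match the number of eigenvectors")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(self.s), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")

    def to_csv(self, path: str | Path) -> None:
        import json

        df = pd.DataFrame(self.eigenvectors.T)
        df.columns = [f"pc{i + 1}" for i in range(self.s)]
        df.to_csv(path, index=False)
        meta = Path(path).with_suffix(".json")
        meta.write_text(
            json.dumps(
                {
                    "eigenvalues": self.eigenvalues.tolist(),
                    "S": self.s,
                    "source": self.source,
                }
            )
        )


def essential_subspace(
    covariance: np.ndarray, s: int = 20, source: str = "concatenated"
) -> EssentialSubspace:
    """Diagonalise a covariance matrix and retain the top-S eigenpairs.

    When S exceeds the matrix rank the subspace is truncated to the rank
    with a warning.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    vals, vecs = np.linalg.eigh(cov)
    vals = vals[::-1]
    vecs = vecs[:, ::-1]
    rank = int(np.sum(vals > max(vals.max(), 0.0) * 1e-12 + 1e-300))
    if s > rank:
        warnings.warn(
            f"requested S={s} exceeds covariance rank {rank}; truncating",
            stacklevel=2,
        )
        s = max(rank, 1)
    vals = np.clip(vals[:s], 0.0, None)
    vecs = vecs[:, :s].T.copy()
    for row in vecs:  # reproducible sign convention
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return EssentialSubspace(vals, vecs, s, source=source)


def rmsip(es_i: EssentialSubspace, es_j: EssentialSubspace) -> float:
    """Root-mean-square inner product of two essential subspaces, in [0, 1]."""
    if es_i.s != es_j.s:
        raise ValueError("subspaces must retain the same number of components")
    if es_i.eigenvectors.shape[1] != es_j.eigenvectors.shape[1]:
        raise ValueError("subspaces live in different dimensionalities")
    overlap = es_i.eigenvectors @ es_j.eigenvectors.T
    return float(np.sqrt(np.sum(overlap**2) / es_i.s))


@dataclass
class ReproducibilityReport:
    """2-PC projections with LDA and density-overlap diagnostics."""

    projections: pd.DataFrame
    lda_accuracy: float
    chance_level: float
    overlap: pd.DataFrame
    pc_variances: tuple[float, float]

    def to_csv(self, path: str | Path) -> None:
        self.projections.to_csv(path, index=False)


def project_and_classify(
    ensembles: Sequence[ConformationalEnsemble],
    n_folds: int = 5,
    grid_bins: int = 50,
    random_state: int = 0,
) -> ReproducibilityReport:
    """Project replicas on the concatenated PC1/PC2 plane and classify.

    The covariance of the concatenated, superposed Cα coordinates defines
    PC1/PC2; every frame is projected and labelled with its replica. LDA
    accuracy is estimated with stratified K-fold cross-validation (chance
    is 1/n_replicas for balanced replicas); pairwise density overlap
    coefficients are computed on a shared 2-D histogram grid.
    """
    ensembles = list(ensembles)
    if len(ensembles) < 2:
        raise ValueError("need at least 2 replicas")
    for e in ensembles:
        if e.n_frames < 3:
            raise ValueError("each replica needs at least 3 frames")
    ca = _stack_ca(ensembles)
    reference = ca[0]
    aligned = superpose_frames(ca, reference)
    flat = aligned.reshape(aligned.shape[0], -1)
    mean = flat.mean(axis=0)
    cov = np.cov(flat, rowvar=False, ddof=1)
    es = essential_subspace(cov, s=2, source="concatenated")
    proj = (flat - mean) @ es.eigenvectors.T  # (n_frames_total, 2)
    labels = np.concatenate(
        [np.full(e.n_frames, e.replica, dtype=object) for e in ensembles]
    )
    df = pd.DataFrame(
        {
            "frame": np.arange(proj.shape[0]),
            "replica": labels,
            "pc1": proj[:, 0],
            "pc2": proj[:, 1],
        }
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                         random_state=random_state)
    scores = cross_val_score(
        LinearDiscriminantAnalysis(), proj, labels, cv=cv
    )
    accuracy = float(scores.mean())
    chance = 1.0 / len(ensembles)
    # density overlap on a shared grid
    xed = np.linspace(proj[:, 0].min(), proj[:, 0].max(), grid_bins + 1)
    yed = np.linspace(proj[:, 1].min(), proj[:, 1].max(), grid_bins + 1)
    densities = {}
    for e in ensembles:
        m = labels == e.replica
        h, _, _ = np.histogram2d(proj[m, 0], proj[m, 1], bins=[xed, yed])
        densities[e.replica] = h / h.sum()
    names = [e.replica for e in ensembles]
    ov = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            coeff = float(np.minimum(densities[a], densities[b]).sum())
            ov.loc[a, b] = ov.loc[b, a] = coeff
    return ReproducibilityReport(
        projections=df,
        lda_accuracy=accuracy,
        chance_level=chance,
        overlap=ov,
        pc_variances=(float(es.eigenvalues[0]), float(es.eigenvalues[1])),
    )
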