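"""Diketone-ligand conformer descriptors and clustering.

The two carbonyl oxygens' distance is the cis/trans descriptor: cis iff
d <= threshold (0.32 nm by default, inclusive).  Ligand frames can be
embedded with PCA after Kabsch alignment and partitioned with k-means;
cluster "centroid conformers" are medoids (real frames), so they are
always physically valid conformations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import Trajectory
from .superpose import kabsch

__all__ = [
    "ConformerSeries",
    "ClusterModel",
    "CIS_TRANS_THRESHOLD_NM",
    "oo_distance_series",
    "find_ligand_oxygens",
    "classify_cis_trans",
    "classify_series",
    "cis_fraction",
    "trans_fraction",
    "conformer_pca",
    "kmeans_cluster",
    "cluster_centroid_conformer",
]

#: Default O-O cis/trans boundary (nm); d <= threshold classifies as cis.
CIS_TRANS_THRESHOLD_NM = 0.32

DEFAULT_KMEANS_SEED = 1234
DEFAULT_KMEANS_RESTARTS = 50


@dataclass(frozen=True)
class ConformerSeries:
    oo_distance: np.ndarray  # nm, per frame
    labels: np.ndarray  # 'cis' / 'trans' per frame
    threshold: float  # nm

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.oo_distance.shape != self.labels.shape:
            raise ValueError("distance and label arrays must align")


@dataclass
class ClusterModel:
    """PCA embedding of aligned ligand frames, optionally with a k-means
    partition layered on top."""

    embedding: np.ndarray  # (n_frames, n_components)
    explained_variance: np.ndarray  # fractions, non-increasing
    ligand_atoms: np.ndarray  # atom indices the embedding was built from
    reference_frame: int
    k: int | None = None
    assignments: np.ndarray | None = None
    centroids: np.ndarray | None = None  # (k, n_components) in embedding space
    inertia: float | None = None


def find_ligand_oxygens(traj: Trajectory, ligand_residue=None) -> tuple[int, int]:
    """Atom indices of the two ligand oxygens (errors unless exactly two)."""
    top = traj.topology
    if ligand_residue is None:
        ligands = top.ligand_residues()
        if len(ligands) != 1:
            raise ValueError(f"expected exactly one ligand residue, found {len(ligands)}")
        ligand_residue = ligands[0]
    oxy = [i for i in top.atom_indices(ligand_residue)
           if top.atoms[i].element.upper() == "O"]
    if len(oxy) != 2:
        raise ValueError(f"ligand {ligand_residue} has {len(oxy)} oxygens, need 2")
    return oxy[0], oxy[1]


def oo_distance_series(traj: Trajectory, oxygen_atoms: tuple[int, int]) -> np.ndarray:
    """Per-frame Euclidean distance (nm) between the two oxygen atoms."""
    i, j = oxygen_atoms
    for idx in (i, j):
        if not 0 <= idx < traj.n_atoms:
            raise ValueError(f"atom index {idx} not in topology")
        if traj.topology.atoms[idx].element.upper() != "O":
            raise ValueError(f"atom {idx} ({traj.topology.atoms[idx].name}) is not oxygen")
    diff = traj.coords[:, i, :] - traj.coords[:, j, :]
    return np.sqrt(np.einsum("fi,fi->f", diff, diff))


def classify_cis_trans(d, threshold: float = CIS_TRANS_THRESHOLD_NM):
    """'cis' iff d <= threshold (inclusive), else 'trans'; vectorized."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    labels = np.where(arr <= threshold, "cis", "trans")
    if np.isscalar(d) or arr.ndim == 0:
        return str(labels)
    return labels


def classify_series(distances: np.ndarray, threshold: float = CIS_TRANS_THRESHOLD_NM) -> ConformerSeries:
    distances = np.asarray(distances, dtype=float)
    return ConformerSeries(oo_distance=distances,
                           labels=classify_cis_trans(distances, threshold),
                           threshold=threshold)


def cis_fraction(series: ConformerSeries) -> float:
    """Percentage of frames labelled cis."""
    if series.labels.size == 0:
        raise ValueError("empty conformer series")
    return 100.0 * float(np.count_nonzero(series.labels == "cis")) / series.labels.size


def trans_fraction(series: ConformerSeries) -> float:
    return 100.0 - cis_fraction(series)


def conformer_pca(
    traj: Trajectory,
    ligand_atoms: np.ndarray,
    reference_frame: int = 0,
    n_components: int | None = None,
) -> ClusterModel:
    """PCA of Kabsch-aligned, flattened ligand coordinates.

    Each frame's ligand is superposed on the reference frame first, so the
    embedding reflects internal conformational changes only (and is rigid-
    transform invariant up to component sign).
    """
    lig = np.asarray(ligand_atoms, dtype=int)
    if lig.size < 3:
        raise ValueError("need >= 3 ligand atoms for alignment")
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames")
    ref = traj.coords[reference_frame][lig]
    aligned = np.empty((traj.n_frames, lig.size, 3))
    for f in range(traj.n_frames):
        sup = kabsch(traj.coords[f][lig], ref)
        aligned[f] = sup.apply(traj.coords[f][lig])
    X = aligned.reshape(traj.n_frames, -1)
    X = X - X.mean(axis=0)
    total_var = float(np.sum(X * X) / (traj.n_frames - 1))
    max_comp = min(traj.n_frames - 1, X.shape[1])
    if total_var < 1e-24:
        warnings.warn("degenerate ensemble: all aligned frames identical")
        k = n_components or max_comp
        return ClusterModel(embedding=np.zeros((traj.n_frames, k)),
                            explained_variance=np.zeros(k),
                            ligand_atoms=lig, reference_frame=reference_frame)
    pca = PCA(n_components=n_components or max_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    return ClusterModel(embedding=scores,
                        explained_variance=pca.explained_variance_ratio_.copy(),
                        ligand_atoms=lig, reference_frame=reference_frame)


def kmeans_cluster(
    points: np.ndarray,
    k: int,
    seed: int = DEFAULT_KMEANS_SEED,
    restarts: int = DEFAULT_KMEANS_RESTARTS,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd k-means with k-means++ seeding, best of ``restarts`` runs.

    Deterministic for a given seed.  Returns (assignments, centroids,
    inertia).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > pts.shape[0]:
        raise ValueError(f"k={k} exceeds number of points ({pts.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    assignments = km.fit_predict(pts)
    return assignments, km.cluster_centers_, float(km.inertia_)


def attach_clusters(model: ClusterModel, k: int,
                    seed: int = DEFAULT_KMEANS_SEED,
                    restarts: int = DEFAULT_KMEANS_RESTARTS) -> ClusterModel:
    """Cluster the model's embedding in place and return it."""
    assignments, centroids, inertia = kmeans_cluster(model.embedding, k, seed, restarts)
    model.k = k
    model.assignments = assignments
    model.centroids = centroids
    model.inertia = inertia
    return model


def cluster_centroid_conformer(
    model: ClusterModel, traj: Trajectory, cluster: int
) -> tuple[int, np.ndarray]:
    """Medoid frame of a cluster: the real frame whose embedding is nearest
    the cluster centroid (ties -> lower frame index).

    Returns ``(frame_index, ligand_coordinates_nm)``.
    """
    if model.assignments is None or model.centroids is None:
        raise ValueError("model has no cluster assignments; run attach_clusters first")
    members = np.flatnonzero(model.assignments == cluster)
    if members.size == 0:
        raise ValueError(f"cluster {cluster} is empty")
    d = np.linalg.norm(model.embedding[members] - model.centroids[cluster], axis=1)
    frame = int(members[int(np.argmin(d))])  # argmin returns first minimum: low-index tie-break
    return frame, traj.coords[frame][model.ligand_atoms].copy()
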