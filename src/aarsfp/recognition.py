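"""Embedding of fingerprint distances and silhouette-based design comparison.

The pairwise Jaccard matrix over all complexes is embedded into two
dimensions with a pluggable neighbor-embedding backend (UMAP by default,
with the study parameters n_neighbors=60, min_dist=0.1).  The mean
silhouette coefficient over all points, with synthetase identity as the
cluster label, quantifies how well a fingerprint design separates the
recognition of different synthetases: values near one indicate clean
separation, zero random overlap, and negative values that foreign
synthetases look more similar than one's own group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np

from .core import AnalysisConfig, EditingTable, StructureComplex
from .fingerprints import Fingerprint, build_fingerprint, distance_matrix

__all__ = [
    "EmbeddingBackend",
    "UMAPBackend",
    "ClassicalMDSBackend",
    "EmbeddingResult",
    "embed",
    "silhouette_samples",
    "mean_silhouette",
    "DesignComparison",
    "compare_designs",
    "pca_variance_explained",
]


class EmbeddingBackend(Protocol):
    """Contract: precomputed distance matrix in, 2-D coordinates out."""

    def embed(self, dm: np.ndarray, seed: int) -> np.ndarray: ...


@dataclass
class UMAPBackend:
    """Default backend: UMAP on a precomputed distance matrix.

    ``n_neighbors`` is clamped to n - 1 with a warning when the dataset is
    smaller than the configured neighborhood.
    """

    n_neighbors: int = 60
    min_dist: float = 0.1
    n_components: int = 2

    def embed(self, dm: np.ndarray, seed: int) -> np.ndarray:
        import umap

        n = dm.shape[0]
        n_neighbors = self.n_neighbors
        if n_neighbors >= n:
            warnings.warn(
                f"n_neighbors={n_neighbors} >= n={n}; clamping to {n - 1}"
            )
            n_neighbors = max(2, n - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                metric="precomputed",
                n_neighbors=n_neighbors,
                min_dist=self.min_dist,
                n_components=self.n_components,
                random_state=seed,
            )
            return np.asarray(reducer.fit_transform(dm), dtype=float)


@dataclass
class ClassicalMDSBackend:
    """Deterministic classical scaling (PCoA) backend.

    Eigendecomposition of the double-centered squared distance matrix;
    useful for fast deterministic tests and degenerate inputs.  The seed
    is ignored (the solution is unique up to sign, which is fixed).
    """

    n_components: int = 2

    def embed(self, dm: np.ndarray, seed: int = 0) -> np.ndarray:
        n = dm.shape[0]
        j = np.eye(n) - np.full((n, n), 1.0 / n)
        b = -0.5 * j @ (dm ** 2) @ j
        eigvals, eigvecs = np.linalg.eigh(b)
        order = np.argsort(eigvals)[::-1][: self.n_components]
        coords = eigvecs[:, order] * np.sqrt(np.maximum(eigvals[order], 0.0))
        # fix sign: largest-magnitude coordinate positive per axis
        for k in range(coords.shape[1]):
            col = coords[:, k]
            if col[np.argmax(np.abs(col))] < 0:
                coords[:, k] = -col
        return coords


@dataclass(frozen=True)
class EmbeddingResult:
    coordinates: np.ndarray         # n x 2
    labels: tuple[str, ...]
    seed: int
    parameters: Mapping[str, object] = field(default_factory=dict)


def embed(
    dm: np.ndarray,
    labels: Sequence[str] | None = None,
    backend: Optional[EmbeddingBackend] = None,
    seed: int = 0,
    config: Optional[AnalysisConfig] = None,
) -> EmbeddingResult:
    """Embed a precomputed distance matrix into 2-D coordinates."""
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError(f"distance matrix must be square, got {dm.shape}")
    if backend is None:
        cfg = config or AnalysisConfig()
        backend = UMAPBackend(
            n_neighbors=cfg.n_neighbors,
            min_dist=cfg.min_dist,
            n_components=cfg.n_components,
        )
    coords = backend.embed(dm, seed)
    lbl = tuple(labels) if labels is not None else tuple("" for _ in range(dm.shape[0]))
    params = {k: getattr(backend, k) for k in ("n_neighbors", "min_dist", "n_components")
              if hasattr(backend, k)}
    params["backend"] = type(backend).__name__
    return EmbeddingResult(coordinates=coords, labels=lbl, seed=seed,
                          parameters=params)


def _pairwise_euclidean(x: np.ndarray) -> np.ndarray:
    # direct differences: numerically exact, embeddings are low-dimensional
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff * diff).sum(axis=-1))


def silhouette_samples(
    data: np.ndarray,
    labels: Sequence[str],
    metric: str = "euclidean",
) -> np.ndarray:
    """Per-point silhouette s(i) = (b(i) - a(i)) / max(a(i), b(i)).

    ``metric="euclidean"`` treats ``data`` as coordinates;
    ``metric="precomputed"`` as a distance matrix.  a(i) is the mean
    distance to the point's own cluster (excluding itself), b(i) the
    smallest mean distance to any other cluster.  Points in singleton
    clusters score 0, as do points where a and b are both zero.
    """
    labels = np.asarray(labels)
    if metric == "euclidean":
        dm = _pairwise_euclidean(np.asarray(data, dtype=float))
    elif metric == "precomputed":
        dm = np.asarray(data, dtype=float)
        if dm.shape[0] != dm.shape[1]:
            raise ValueError("precomputed matrix must be square")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("silhouette needs at least two distinct labels")
    n = dm.shape[0]
    masks = {lab: labels == lab for lab in unique}
    sizes = {lab: int(m.sum()) for lab, m in masks.items()}
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        a = (dm[i, masks[own]].sum()) / (sizes[own] - 1)
        b = min(
            dm[i, masks[lab]].mean() for lab in unique if lab != own
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def mean_silhouette(
    data: np.ndarray, labels: Sequence[str], metric: str = "euclidean"
) -> float:
    """Mean silhouette coefficient over all points."""
    return float(np.mean(silhouette_samples(data, labels, metric=metric)))


@dataclass(frozen=True)
class DesignComparison:
    """Silhouette comparison of fingerprint designs.

    ``per_seed[design]`` lists the mean silhouette of each embedding seed;
    ``mean``/``std`` summarise over seeds; ``samples[design]`` holds the
    per-point silhouettes of the first seed for dispersion plots.
    """

    designs: tuple[str, ...]
    per_seed: Mapping[str, tuple[float, ...]]
    mean: Mapping[str, float]
    std: Mapping[str, float]
    samples: Mapping[str, np.ndarray]


def compare_designs(
    complexes: Sequence[StructureComplex],
    designs: Sequence[str] = ("Seq_sim", "Seq+Int", "Seq+Int+Ed", "Seq+Int+Ed+Vol"),
    seeds: Sequence[int] = (0,),
    editing_table: Optional[EditingTable] = None,
    backend: Optional[EmbeddingBackend] = None,
    config: Optional[AnalysisConfig] = None,
) -> DesignComparison:
    """Fingerprint -> Jaccard -> embedding -> silhouette, per design.

    For each design the Jaccard matrix is embedded once per seed and the
    mean silhouette (synthetase labels, Euclidean metric on the embedded
    coordinates) is recorded.  The complexes must span at least two
    synthetases; a design that needs unavailable data (e.g. volumes)
    raises with the design's name.
    """
    if len(designs) < 1:
        raise ValueError("need at least one design")
    order = sorted(range(len(complexes)), key=lambda i: (complexes[i].aars,
                                                         complexes[i].structure_id))
    complexes = [complexes[i] for i in order]
    labels = [c.aars for c in complexes]
    if len(set(labels)) < 2:
        raise ValueError("complexes must span at least two aaRSs")
    per_seed: dict[str, tuple[float, ...]] = {}
    samples: dict[str, np.ndarray] = {}
    for design in designs:
        try:
            fps = [
                build_fingerprint(c, design, editing_table, config)
                for c in complexes
            ]
        except ValueError as err:
            raise ValueError(f"design {design!r}: {err}") from None
        dm = distance_matrix(fps)
        values = []
        for k, seed in enumerate(seeds):
            result = embed(dm, labels, backend=backend, seed=seed, config=config)
            sil = silhouette_samples(result.coordinates, labels)
            if k == 0:
                samples[design] = sil
            values.append(float(np.mean(sil)))
        per_seed[design] = tuple(values)
    mean = {d: float(np.mean(v)) for d, v in per_seed.items()}
    std = {d: float(np.std(v)) for d, v in per_seed.items()}
    return DesignComparison(
        designs=tuple(designs), per_seed=per_seed, mean=mean, std=std,
        samples=samples,
    )


def plot_embedding(result: EmbeddingResult, path: str) -> None:
    """Scatter plot of an embedding, coloured by synthetase label.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    labels = np.asarray(result.labels)
    for lab in np.unique(labels):
        mask = labels == lab
        ax.scatter(result.coordinates[mask, 0], result.coordinates[mask, 1],
                   s=12, label=str(lab))
    ax.set_xlabel("embedding 1")
    ax.set_ylabel("embedding 2")
    ax.legend(fontsize=5, ncol=2, markerscale=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_variance_explained(
    fps: Sequence[Fingerprint], n_components: int = 2
) -> np.ndarray:
    """Variance-explained ratios of the top principal components of the
    raw bit matrix (thin diagnostic of fingerprint dimensionality)."""
    x = np.stack([fp.bits for fp in fps]).astype(float)
    x = x - x.mean(axis=0)
    _, svals, _ = np.linalg.svd(x, full_matrices=False)
    var = svals ** 2
    total = var.sum()
    if total == 0:
        return np.zeros(n_components)
    return var[:n_components] / total
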