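"""Dimensionality reduction of incidence-age profiles.

Profiles (rows of the harmonized incidence table, one per dataset or per
stratum) are log10-transformed and embedded with PCA (column-centered,
no unit-variance scaling, so amplitude differences between disease tiers
are preserved) and with UMAP.  PC1 separates the non-multistep control
from the power-law diseases; PC2 tends to order the multistep strata by
their step tier.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

DEFAULT_UMAP_NEIGHBORS = 5
DEFAULT_UMAP_MIN_DIST = 0.3
DEFAULT_UMAP_SEED = 42


@dataclasses.dataclass(frozen=True)
class Embedding:
    """Coordinates of profiles in a low-dimensional space.

    ``coordinates``: DataFrame indexed by profile label with columns
    ``PC1, PC2, ...`` (PCA) or ``UMAP1, UMAP2`` (UMAP).
    ``explained_variance_pct`` is populated for PCA only (percent per
    component, non-increasing).
    """

    method: str
    coordinates: pd.DataFrame
    explained_variance_pct: tuple[float, ...] = ()
    seed: int | None = None
    params: dict = dataclasses.field(default_factory=dict)


def _validate_profiles(profiles: pd.DataFrame, min_rows: int) -> np.ndarray:
    if profiles.shape[0] < min_rows:
        raise ValueError(f"need >= {min_rows} profiles, got {profiles.shape[0]}")
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 age columns")
    arr = profiles.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError(
            "profiles contain missing cells; restrict to complete-case columns first"
        )
    if (arr <= 0).any():
        raise ValueError("profiles must be strictly positive (log10 is taken)")
    return np.log10(arr)


def pca_embed(profiles: pd.DataFrame, n_components: int = 2) -> Embedding:
    """PCA of log10 profiles (column-centered, unscaled).

    Components come from the singular value decomposition of the centered
    log-profile table; explained variance is reported in percent.
    """
    logp = _validate_profiles(profiles, min_rows=2)
    k = min(n_components, logp.shape[0] - 1, logp.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(logp)
    cols = [f"PC{i + 1}" for i in range(k)]
    return Embedding(
        method="pca",
        coordinates=pd.DataFrame(coords, index=profiles.index, columns=cols),
        explained_variance_pct=tuple(100.0 * pca.explained_variance_ratio_),
        params={
            "n_components": k,
            "components": pca.components_,  # for reconstruction diagnostics
            "mean": pca.mean_,
        },
    )


def umap_embed(
    profiles: pd.DataFrame,
    n_neighbors: int = DEFAULT_UMAP_NEIGHBORS,
    min_dist: float = DEFAULT_UMAP_MIN_DIST,
    seed: int = DEFAULT_UMAP_SEED,
) -> Embedding:
    """2-D UMAP of log10 profiles; deterministic for a fixed seed."""
    logp = _validate_profiles(profiles, min_rows=4)
    if n_neighbors >= profiles.shape[0]:
        raise ValueError(
            f"n_neighbors ({n_neighbors}) must be < number of profiles "
            f"({profiles.shape[0]})"
        )
    import umap  # deferred: numba-jitted import is slow

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(logp)
    return Embedding(
        method="umap",
        coordinates=pd.DataFrame(
            np.asarray(coords, dtype=float),
            index=profiles.index,
            columns=["UMAP1", "UMAP2"],
        ),
        seed=seed,
        params={"n_neighbors": n_neighbors, "min_dist": min_dist},
    )


def plot_embedding(embedding: Embedding, path, labels: dict[str, str] | None = None):
    """Scatter plot of an embedding, optionally colored by group label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coordinates
    fig, ax = plt.subplots(figsize=(6, 5))
    if labels:
        groups = sorted({labels.get(i, "other") for i in coords.index})
        for g in groups:
            idx = [i for i in coords.index if labels.get(i, "other") == g]
            ax.scatter(coords.loc[idx].iloc[:, 0], coords.loc[idx].iloc[:, 1], label=g, s=30)
        ax.legend(fontsize=8)
    else:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=30)
    for name, row in coords.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=6, alpha=0.7)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    if embedding.method == "pca" and len(embedding.explained_variance_pct) >= 2:
        ax.set_xlabel(f"PC1 ({embedding.explained_variance_pct[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({embedding.explained_variance_pct[1]:.0f}%)")
    ax.set_title(embedding.method.upper())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
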