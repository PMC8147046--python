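"""Gaussian class-separability indices and 2-D embedding of feature sets.

Classes are summarized by sample mean and covariance; separation between
the two class distributions is quantified by the Bhattacharyya distance B,
its bounded Jeffries-Matusita transform JM = 2(1 - e^-B), the symmetric
divergence D, and the bounded transformed divergence TD = 2(1 - e^(-D/8)).
Larger values mean better separation; JM and TD saturate at 2.  Raw D is
reported alongside TD because the two are often conflated in the remote
sensing literature from which these indices come.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GaussianClassStats:
    """Per-class mean vectors and ridge-regularized covariance matrices."""

    classes: tuple
    means: dict
    covs: dict
    counts: dict
    ridge: float


def fit_class_gaussians(features, labels, ridge: float = 1e-6) -> GaussianClassStats:
    """Sample mean and (n-1)-denominator covariance per class, plus ridge.

    Requires exactly two classes with at least 2 rows each; the ridge keeps
    covariances positive-definite when rows are fewer than dimensions.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    means, covs, counts = {}, {}, {}
    dim = x.shape[1]
    for c in classes:
        rows = x[y == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        means[c] = rows.mean(axis=0)
        covs[c] = np.cov(rows, rowvar=False).reshape(dim, dim) + ridge * np.eye(dim)
        counts[c] = rows.shape[0]
    return GaussianClassStats(classes=classes, means=means, covs=covs,
                              counts=counts, ridge=ridge)


def bhattacharyya_jm(stats: GaussianClassStats) -> tuple[float, float]:
    """Bhattacharyya distance and Jeffries-Matusita distance.

    B = 1/8 dm' S^-1 dm + 1/2 ln( det S / sqrt(det S1 det S2) ) with
    S = (S1 + S2)/2; JM = 2(1 - e^-B) in [0, 2].
    """
    c1, c2 = stats.classes
    dm = stats.means[c1] - stats.means[c2]
    s1, s2 = stats.covs[c1], stats.covs[c2]
    s = 0.5 * (s1 + s2)
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0:
        raise np.linalg.LinAlgError("pooled covariance is singular despite ridge")
    term_m = 0.125 * float(dm @ np.linalg.solve(s, dm))
    term_c = 0.5 * (logdet_s - 0.5 * (np.linalg.slogdet(s1)[1]
                                      + np.linalg.slogdet(s2)[1]))
    b = term_m + term_c
    return b, 2.0 * (1.0 - np.exp(-b))


def divergence_indices(stats: GaussianClassStats) -> tuple[float, float]:
    """Symmetric divergence D and transformed divergence TD = 2(1-e^(-D/8)).

    D = 1/2 tr[(S1-S2)(S2^-1 - S1^-1)] + 1/2 tr[(S1^-1+S2^-1) dm dm'].
    """
    c1, c2 = stats.classes
    dm = stats.means[c1] - stats.means[c2]
    s1, s2 = stats.covs[c1], stats.covs[c2]
    i1, i2 = np.linalg.inv(s1), np.linalg.inv(s2)
    d = 0.5 * float(np.trace((s1 - s2) @ (i2 - i1)))
    d += 0.5 * float(dm @ (i1 + i2) @ dm)
    return d, 2.0 * (1.0 - np.exp(-d / 8.0))


def separability_report(features, labels, ridge: float = 1e-6) -> dict[str, float]:
    """All four indices for one feature set."""
    stats = fit_class_gaussians(features, labels, ridge=ridge)
    b, jm = bhattacharyya_jm(stats)
    d, td = divergence_indices(stats)
    return {"bhattacharyya": b, "jeffries_matusita": jm,
            "divergence": d, "transformed_divergence": td}


def embed_2d(features, n_neighbors: int = 15, min_dist: float = 0.1,
             seed: int = 0) -> np.ndarray:
    """Seeded 2-D UMAP embedding of the feature rows (N x 2 coordinates)."""
    import umap  # heavy import kept local

    x = np.asarray(features, dtype=np.float64)
    if x.shape[0] < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} rows, "
                         f"have {x.shape[0]}")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    coords = reducer.fit_transform(x)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return np.asarray(coords, dtype=np.float64)


def plot_embedding(coords, labels, path) -> None:
    """Class-colored scatter of a 2-D embedding (AD red, CN blue)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, color in (("CN", "tab:blue"), ("AD", "tab:red")):
        sel = labels == cls if labels.dtype.kind in "US" else labels == (cls == "AD")
        ax.scatter(coords[sel, 0], coords[sel, 1], s=12, c=color, label=cls,
                   alpha=0.8)
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
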