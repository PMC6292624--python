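"""Principal components of the binary-encoded mtDNA SNP matrix.

Used for haplogroup-structure visualization and stratification checks: deep
clades separate on the leading components because their defining-SNP sets are
disjoint. Loci are column-centered but not variance-scaled (scaling binary
data would explode the influence of rare variants); a scaling flag is
provided. Signs are fixed by making the largest-magnitude loading of each
component positive, so output is reproducible bit-for-bit on fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ALT, MISSING, REF, GenotypeMatrix

__all__ = ["PCAResult", "encode_binary", "run_pca", "cluster_separation_report"]


@dataclass
class PCAResult:
    loadings: np.ndarray  # loci x k, orthonormal columns
    scores: np.ndarray  # samples x k
    explained_variance_fraction: np.ndarray  # length k, non-increasing
    zero_variance_components: list[int]  # component indices beyond rank


def encode_binary(g: GenotypeMatrix, missing_policy: str = "mean") -> np.ndarray:
    """REF→0, ALT→1; MISSING handled per policy.

    ``mean``: impute each missing call to its locus mean over non-missing
    calls (0 for all-missing loci). ``drop``: drop loci with any missing call.
    """
    if g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    x = g.calls.astype(float)
    miss = g.calls == MISSING
    if missing_policy == "mean":
        n_obs = (~miss).sum(axis=0)
        sums = np.where(miss, 0.0, x).sum(axis=0)
        col_mean = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), 0.0)
        idx = np.where(miss)
        x[idx] = col_mean[idx[1]]
    elif missing_policy == "drop":
        keep = ~miss.any(axis=0)
        x = x[:, keep]
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return x


def run_pca(m: np.ndarray, k: int) -> PCAResult:
    """Column-centered PCA via SVD; deterministic sign convention."""
    m = np.asarray(m, dtype=float)
    n, p = m.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k must be in [1, {min(n, p)}]")
    centered = m - m.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[:k].T
    # sign convention: largest-magnitude loading positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = centered @ loadings
    var = s**2 / max(n - 1, 1)
    total = var.sum()
    frac = var[:k] / total if total > 0 else np.zeros(k)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    zero = [j for j in range(k) if s[j] <= tol]
    return PCAResult(loadings, scores, frac, zero)


def cluster_separation_report(
    scores: np.ndarray,
    labels,
    component_pairs: list[tuple[int, int]] = [(0, 1), (0, 2)],
) -> dict[str, pd.DataFrame]:
    """Quantitative surrogate for visual cluster separation on PC planes.

    For each requested component pair, reports per-label centroids and RMS
    dispersion, plus pairwise centroid distances.
    """
    labels = np.asarray(labels)
    if len(labels) != len(scores):
        raise ValueError("labels must cover all samples")
    out: dict[str, pd.DataFrame] = {}
    uniq = sorted(set(labels.tolist()))
    for a, b in component_pairs:
        if max(a, b) >= scores.shape[1]:
            continue
        pts = scores[:, [a, b]]
        rows = []
        centroids = {}
        for lab in uniq:
            sub = pts[labels == lab]
            c = sub.mean(axis=0)
            centroids[lab] = c
            disp = float(np.sqrt(((sub - c) ** 2).sum(axis=1).mean()))
            rows.append((lab, len(sub), c[0], c[1], disp))
        key = f"PC{a + 1}/PC{b + 1}"
        out[key] = pd.DataFrame(
            rows, columns=["label", "n", "centroid_x", "centroid_y", "dispersion"]
        )
        pair_rows = [
            (la, lb, float(np.linalg.norm(centroids[la] - centroids[lb])))
            for i, la in enumerate(uniq)
            for lb in uniq[i + 1 :]
        ]
        out[key + "/pairs"] = pd.DataFrame(
            pair_rows, columns=["label_a", "label_b", "centroid_distance"]
        )
    return out
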