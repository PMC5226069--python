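"""Statistical shape atlas: PCA over corresponded shape vectors.

The atlas reduces each subject's 3456-entry shape vector to scores on
the K dominant anatomical modes (principal components of the pooled,
mean-centred coordinate covariance; K = 10 by default).  Modes are
reported by eigen-rank; reconstruction along a single mode at +/-k SD
visualizes the anatomical deformation it encodes, and per-mode one-way
ANOVA with Bonferroni correction across the K tested modes screens for
group differences in shape.

PCA is computed on raw mm coordinates without per-feature scaling:
units are homogeneous and overall size is genuine signal (ventricular
dilation is a finding, not a nuisance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ShapeAtlas:
    mean: np.ndarray  # (D,)
    modes: np.ndarray  # (D, K), orthonormal columns
    eigenvalues: np.ndarray  # (K,) variance per retained mode
    eigenvalues_all: np.ndarray  # full spectrum, for explained variance
    scores: np.ndarray  # (N, K) training-set mode scores
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def validate(self) -> None:
        gram = self.modes.T @ self.modes
        if not np.allclose(gram, np.eye(self.n_modes), atol=1e-8):
            raise AssertionError("modes are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-9) or np.any(self.eigenvalues < -1e-12):
            raise AssertionError("eigenvalues must be non-negative and non-increasing")
        if not np.allclose(self.scores.mean(axis=0), 0.0, atol=1e-8):
            raise AssertionError("mode scores must be centred")

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        np.savez(path, mean=self.mean, modes=self.modes,
                 eigenvalues=self.eigenvalues,
                 eigenvalues_all=self.eigenvalues_all, scores=self.scores)

    @classmethod
    def load(cls, path: str | Path) -> "ShapeAtlas":
        with np.load(path) as z:
            return cls(mean=z["mean"], modes=z["modes"],
                       eigenvalues=z["eigenvalues"],
                       eigenvalues_all=z["eigenvalues_all"], scores=z["scores"])


def build_atlas(shape_vectors: np.ndarray, k: int = 10) -> ShapeAtlas:
    """Mean-centred PCA of the (N, D) shape-vector matrix, top-``k`` modes.

    Mode signs are fixed deterministically: the largest-magnitude
    loading of each mode is made positive.  When the data rank is below
    ``k`` the atlas is truncated with a warning.
    """
    X = np.asarray(shape_vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("shape_vectors must be a 2D (subjects x variables) array")
    n = X.shape[0]
    if n < 3:
        raise ValueError("atlas requires at least 3 subjects")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig_all = s**2 / (n - 1)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if rank < k:
        warnings.warn(f"data rank {rank} < requested {k} modes; truncating")
        k = max(rank, 1)
    modes = vt[:k].T
    scores = u[:, :k] * s[:k]
    flip = modes[np.abs(modes).argmax(axis=0), np.arange(k)] < 0
    modes[:, flip] *= -1.0
    scores[:, flip] *= -1.0
    atlas = ShapeAtlas(mean=mean, modes=modes, eigenvalues=eig_all[:k],
                       eigenvalues_all=eig_all, scores=scores,
                       meta={"n_subjects": n})
    atlas.validate()
    return atlas


def explained_variance(atlas: ShapeAtlas, k: int) -> float:
    """Fraction of total shape variance captured by the first ``k`` modes."""
    if not 1 <= k <= atlas.eigenvalues_all.size:
        raise ValueError(f"k must lie in [1, {atlas.eigenvalues_all.size}]")
    total = atlas.eigenvalues_all.sum()
    if total == 0:
        return 1.0
    return float(atlas.eigenvalues_all[:k].sum() / total)


def project_shape(atlas: ShapeAtlas, shape_vector: np.ndarray) -> np.ndarray:
    """Mode scores of a shape vector: modes^T (x - mean)."""
    x = np.asarray(shape_vector, dtype=float).ravel()
    if x.size != atlas.mean.size:
        raise ValueError(f"shape vector length {x.size} != atlas dimension {atlas.mean.size}")
    return atlas.modes.T @ (x - atlas.mean)


def reconstruct_shape(atlas: ShapeAtlas, scores: np.ndarray | None = None,
                      mode: int | None = None, k_sd: float | None = None) -> np.ndarray:
    """Shape vector from mode scores, or from a single mode at ``k_sd`` SDs.

    ``reconstruct_shape(atlas, mode=m, k_sd=+3)`` gives the +3 SD extreme
    of anatomical mode ``m`` (0-based): mean + 3 sqrt(lambda_m) mode_m.
    """
    if scores is None:
        if mode is None or k_sd is None:
            raise ValueError("provide either scores or (mode, k_sd)")
        if not 0 <= mode < atlas.n_modes:
            raise ValueError(f"mode index {mode} out of range")
        if abs(k_sd) > 5:
            warnings.warn("|k_sd| > 5 extrapolates far outside the training data")
        scores = np.zeros(atlas.n_modes)
        scores[mode] = k_sd * np.sqrt(atlas.eigenvalues[mode])
    scores = np.asarray(scores, dtype=float)
    return atlas.mean + atlas.modes[:, : scores.size] @ scores


def _permutation_anova(groups: list[np.ndarray], n_perm: int = 10000,
                       seed: int = 0) -> tuple[float, float]:
    """Permutation one-way ANOVA for degenerate (zero-variance) inputs."""
    rng = np.random.default_rng(seed)
    values = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def f_stat(v):
        start, groups_v = 0, []
        for sz in sizes:
            groups_v.append(v[start:start + sz])
            start += sz
        grand = v.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups_v)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups_v)
        dfb, dfw = len(sizes) - 1, len(v) - len(sizes)
        if ssw == 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / dfb) / (ssw / dfw)

    f_obs = f_stat(values)
    count = sum(f_stat(rng.permutation(values)) >= f_obs for _ in range(n_perm))
    return f_obs, (count + 1) / (n_perm + 1)


def compare_modes(scores: np.ndarray, labels, alpha: float = 0.05,
                  n_comparisons: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-mode one-way ANOVA of scores across groups, Bonferroni-adjusted.

    Returns a table with one row per mode: F statistic, raw and adjusted
    p-values (adjusted = min(1, raw x K)), per-group score means and a
    significance flag at ``alpha``.  Zero-variance degeneracies fall back
    to a seeded permutation test.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("compare_modes needs at least two groups")
    if any((labels == g).sum() < 2 for g in groups):
        raise ValueError("each group needs at least two subjects")
    k = scores.shape[1]
    m = n_comparisons if n_comparisons is not None else k
    rows = []
    for j in range(k):
        per_group = [scores[labels == g, j] for g in groups]
        if any(np.ptp(g) == 0 for g in per_group):
            f, p = _permutation_anova(per_group, seed=seed + j)
        else:
            f, p = stats.f_oneway(*per_group)
        p_adj = min(1.0, p * m)
        row = {"mode": j + 1, "F": float(f), "p": float(p),
               "p_bonferroni": float(p_adj), "significant": p_adj < alpha}
        for g, vals in zip(groups, per_group):
            row[f"mean_{g}"] = float(vals.mean())
        rows.append(row)
    return pd.DataFrame(rows)
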