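"""Group-level permutation inference for decoding accuracies.

ROI level: category labels are shuffled within each run (preserving the
leave-one-run-out structure), the decoder is re-run on the shuffled labels
100 times per subject, and 1000 group-level null accuracies are formed by
averaging one sampled permuted accuracy per subject.  The observed group
mean is tested one-sided against this null with the +1-corrected count
convention, followed by Benjamini-Hochberg FDR across ROIs.  The
recognized-minus-unrecognized accuracy difference is tested against paired
permuted differences built the same way.

Whole-brain level: a searchlight (3-voxel-radius sphere, 123 voxels when
fully interior) maps balanced accuracy per voxel; group t-maps against
chance (25%) are enhanced with TFCE (E = 0.5, H = 2, 6-connectivity) and
family-wise error is controlled with the null distribution of the image-wide
maximum TFCE score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .decoding import cross_validate

CHANCE_4WAY = 0.25


# --------------------------------------------------------------------------
# label permutation and ROI-level group null


def permute_labels_within_run(
    labels: np.ndarray, runs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle labels independently within each run (multisets preserved)."""
    labels = np.asarray(labels)
    runs = np.asarray(runs)
    out = labels.copy()
    for r in np.unique(runs):
        idx = np.flatnonzero(runs == r)
        out[idx] = labels[idx[rng.permutation(len(idx))]]
    return out


def decode_with_permutations(
    X: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    *,
    n_perms: int = 100,
    rng: np.random.Generator,
    C: float = 1.0,
    decoder: str = "svm",
) -> tuple[float, np.ndarray]:
    """Observed balanced accuracy plus ``n_perms`` label-permuted accuracies."""
    obs = cross_validate(X, labels, runs, C=C, decoder=decoder).balanced_accuracy
    perms = np.empty(n_perms)
    for i in range(n_perms):
        y_perm = permute_labels_within_run(labels, runs, rng)
        perms[i] = cross_validate(X, y_perm, runs, C=C, decoder=decoder).balanced_accuracy
    return obs, perms


@dataclass
class PermutationNull:
    observed: np.ndarray  # per-subject observed accuracy
    subject_perms: np.ndarray  # n_subjects x n_subject_perms
    group_null: np.ndarray  # n_group samples of group-mean accuracy

    @property
    def group_observed(self) -> float:
        return float(self.observed.mean())


def sample_group_null(
    subject_perms: np.ndarray, n_group: int, rng: np.random.Generator
) -> np.ndarray:
    """Group null: mean of one sampled permuted accuracy per subject."""
    perms = np.asarray(subject_perms, dtype=float)
    n_sub, n_per = perms.shape
    picks = rng.integers(0, n_per, size=(n_group, n_sub))
    return perms[np.arange(n_sub), picks].mean(axis=1)


def build_group_null(
    subject_data: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    *,
    n_subject_perms: int = 100,
    n_group: int = 1000,
    rng: np.random.Generator,
    C: float = 1.0,
    decoder: str = "svm",
) -> PermutationNull:
    """Full pipeline: per-subject permuted decoding, then group resampling.

    ``subject_data`` holds one (X, labels, runs) triple per subject.
    """
    obs = np.empty(len(subject_data))
    perms = np.empty((len(subject_data), n_subject_perms))
    for s, (X, y, runs) in enumerate(subject_data):
        obs[s], perms[s] = decode_with_permutations(
            X, y, runs, n_perms=n_subject_perms, rng=rng, C=C, decoder=decoder
        )
    group = sample_group_null(perms, n_group, rng)
    return PermutationNull(obs, perms, group)


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """One-sided +1-corrected permutation p-value."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((1.0 + np.sum(null >= observed)) / (1.0 + null.size))


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def accuracy_difference_test(
    null_a: PermutationNull,
    null_b: PermutationNull,
    *,
    n_group: int = 1000,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One-sided test of the paired accuracy difference (a minus b).

    Both nulls must come from the same subjects in the same order.  The null
    difference resamples one permuted accuracy per subject per condition,
    keeping subjects paired.
    """
    if null_a.observed.shape != null_b.observed.shape:
        raise ValueError("subject sets must match between conditions")
    diff = float(null_a.observed.mean() - null_b.observed.mean())
    n_sub, n_per_a = null_a.subject_perms.shape
    n_per_b = null_b.subject_perms.shape[1]
    picks_a = rng.integers(0, n_per_a, size=(n_group, n_sub))
    picks_b = rng.integers(0, n_per_b, size=(n_group, n_sub))
    null_diff = (
        null_a.subject_perms[np.arange(n_sub), picks_a].mean(axis=1)
        - null_b.subject_perms[np.arange(n_sub), picks_b].mean(axis=1)
    )
    return diff, permutation_pvalue(diff, null_diff)


# --------------------------------------------------------------------------
# searchlight


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets with x^2 + y^2 + z^2 <= radius^2 (123 at radius 3)."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def searchlight_map(
    data: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    mask: np.ndarray,
    *,
    radius: int = 3,
    decoder: str = "svm",
    C: float = 1.0,
) -> np.ndarray:
    """Balanced-accuracy map from a sphere around every in-mask voxel.

    ``data`` is (n_samples, nx, ny, nz).  Spheres are truncated to in-mask
    voxels.  ``decoder`` is "svm" (the pairwise max-margin decoder, exact but
    slow) or "nearest_centroid" (a vectorized nearest-class-mean decoder
    whose per-voxel class scores are accumulated over the sphere with a
    sparse adjacency product — orders of magnitude faster, used for large
    calibration studies).  Voxels outside the mask are NaN.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    runs = np.asarray(runs)
    mask = np.asarray(mask, dtype=bool)
    if data.shape[1:] != mask.shape:
        raise ValueError("data grid and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    if decoder == "svm":
        return _searchlight_svm(data, labels, runs, mask, radius, C)
    if decoder == "nearest_centroid":
        return _searchlight_nearest_centroid(data, labels, runs, mask, radius)
    raise ValueError(f"unknown decoder {decoder!r}")


def _searchlight_svm(data, labels, runs, mask, radius, C):
    offsets = sphere_offsets(radius)
    dims = mask.shape
    out = np.full(dims, np.nan)
    centers = np.argwhere(mask)
    flat = data.reshape(data.shape[0], -1)
    for cx, cy, cz in centers:
        pts = offsets + (cx, cy, cz)
        ok = np.all((pts >= 0) & (pts < dims), axis=1)
        pts = pts[ok]
        pts = pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
        cols = np.ravel_multi_index((pts[:, 0], pts[:, 1], pts[:, 2]), dims)
        res = cross_validate(flat[:, cols], labels, runs, C=C)
        out[cx, cy, cz] = res.balanced_accuracy
    return out


def _searchlight_nearest_centroid(data, labels, runs, mask, radius):
    return searchlight_map_batch(data, [labels], runs, mask, radius=radius)[0]


def searchlight_map_batch(
    data: np.ndarray,
    label_sets: list[np.ndarray],
    runs: np.ndarray,
    mask: np.ndarray,
    *,
    radius: int = 3,
) -> np.ndarray:
    """Nearest-centroid searchlight maps for several label assignments at once.

    All label sets (e.g. the observed labels plus within-run permutations of
    them) share the data, so the per-sphere score sums are batched into a
    single sparse-matrix product per fold.  Returns (n_sets, nx, ny, nz)
    with NaN outside the mask.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    runs = np.asarray(runs)
    label_sets = [np.asarray(ls) for ls in label_sets]
    cats = tuple(sorted(np.unique(label_sets[0])))
    dims = mask.shape
    n_vox = int(np.prod(dims))
    S = _sphere_adjacency(mask, radius)  # (n_vox, n_vox) sparse, mask-truncated
    maskv = mask.ravel()
    data_flat = data.reshape(data.shape[0], n_vox) * maskv
    n_sets = len(label_sets)
    correct = np.zeros((n_sets, len(cats), n_vox))
    total = np.zeros((n_sets, len(cats)), dtype=int)
    for r in np.unique(runs):
        train = runs != r
        test = ~train
        Xte = data_flat[test]
        # per label set: class centroids on train, class scores on test;
        # score_c(v) = sum over sphere of (2 x mu_c - mu_c^2), in-mask only
        integrands = []
        for ls in label_sets:
            ytr = ls[train]
            mus = np.stack([data_flat[train][ytr == c].mean(axis=0) for c in cats])
            integrands.append(2.0 * Xte[:, None] * mus[None] - mus[None] ** 2)
        flat = np.concatenate(integrands).reshape(-1, n_vox)
        scores = (S @ flat.T).T.reshape(n_sets, len(Xte), len(cats), n_vox)
        pred = np.argmax(scores, axis=2)
        for s, ls in enumerate(label_sets):
            yte = ls[test]
            for i, yt in enumerate(yte):
                ci = cats.index(yt)
                total[s, ci] += 1
                correct[s, ci] += pred[s, i] == ci
    out = np.empty((n_sets, n_vox))
    for s in range(n_sets):
        per_cat = np.stack(
            [correct[s, ci] / total[s, ci] for ci in range(len(cats)) if total[s, ci] > 0]
        )
        out[s] = per_cat.mean(axis=0)
        out[s][~maskv] = np.nan
    return out.reshape(n_sets, *dims)


def _sphere_adjacency(mask: np.ndarray, radius: int):
    """Sparse matrix S with S[center, member] = 1 for in-mask sphere members."""
    from scipy import sparse

    dims = mask.shape
    n_vox = int(np.prod(dims))
    centers = np.argwhere(mask)
    offsets = sphere_offsets(radius)
    rows, cols = [], []
    for off in offsets:
        pts = centers + off
        ok = np.all((pts >= 0) & (pts < dims), axis=1)
        member = np.zeros(len(centers), dtype=bool)
        member[ok] = mask[pts[ok, 0], pts[ok, 1], pts[ok, 2]]
        rows.append(np.ravel_multi_index(tuple(centers[member].T), dims))
        cols.append(np.ravel_multi_index(tuple(pts[member].T), dims))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    return sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_vox, n_vox)
    )


# --------------------------------------------------------------------------
# TFCE and max-statistic FWE


_CONN6 = ndimage.generate_binary_structure(3, 1)


def tfce_transform(
    vals: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of ``vals``.

    out(v) = sum over thresholds h of extent(v, h)^E * h^H * dh, where
    extent(v, h) is the size of the 6-connected suprathreshold component
    containing v.  ``dh`` defaults to max/n_steps (adaptive step).
    """
    vals = np.asarray(vals, dtype=float)
    if mask is None:
        mask = np.isfinite(vals)
    mask = np.asarray(mask, dtype=bool)
    work = np.where(mask, vals, 0.0)
    work = np.where(np.isfinite(work), work, 0.0)
    vmax = work.max(initial=0.0)
    out = np.zeros_like(work)
    if vmax <= 0:
        return out
    if dh is None:
        dh = vmax / n_steps
    h = dh
    while h <= vmax + 1e-12:
        above = work >= h
        lab, n = ndimage.label(above, structure=_CONN6)
        if n == 0:
            break
        sizes = np.bincount(lab.ravel())
        out[above] += sizes[lab[above]] ** E * h**H * dh
        h += dh
    out[~mask] = 0.0
    return out


def group_t_map(
    subject_maps: np.ndarray, chance: float = CHANCE_4WAY
) -> np.ndarray:
    """One-sample t statistic across subjects against ``chance``, per voxel."""
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    return (mean - chance) / np.maximum(sd / np.sqrt(n), 1e-12)


def maxstat_fwe(
    true_map: np.ndarray,
    perm_maps: np.ndarray,
    *,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise FWE control via the null of image-wide maxima.

    Returns (p map, significance mask, null maxima).  p uses +1-corrected
    counts over the per-permutation maxima of ``perm_maps``.
    """
    true_map = np.asarray(true_map, dtype=float)
    perm_maps = np.asarray(perm_maps, dtype=float)
    if mask is None:
        mask = np.isfinite(true_map)
    mask = np.asarray(mask, dtype=bool)
    n_perm = perm_maps.shape[0]
    maxima = np.array(
        [np.nanmax(np.where(mask, pm, -np.inf)) for pm in perm_maps]
    )
    p = np.ones_like(true_map)
    counts = (maxima[:, None] >= true_map[mask][None, :]).sum(axis=0)
    p[mask] = (1.0 + counts) / (1.0 + n_perm)
    sig = mask & (p < alpha)
    return p, sig, maxima


@dataclass
class SearchlightGroupResult:
    t_map: np.ndarray
    tfce_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    null_maxima: np.ndarray


def group_searchlight_tfce(
    subject_maps: np.ndarray,
    subject_perm_maps: np.ndarray,
    mask: np.ndarray,
    *,
    n_group_perms: int = 50,
    alpha: float = 0.05,
    chance: float = CHANCE_4WAY,
    rng: np.random.Generator,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
) -> SearchlightGroupResult:
    """Group searchlight inference with TFCE and max-statistic FWE control.

    ``subject_maps`` is (n_subjects, nx, ny, nz); ``subject_perm_maps`` is
    (n_subjects, n_perms_per_subject, nx, ny, nz) from within-run label
    shuffles.  Each group permutation samples one permuted map per subject
    (with replacement), computes the t map against chance, and TFCE-enhances
    it; the image-wide maxima form the null.
    """
    mask = np.asarray(mask, dtype=bool)
    t_true = np.where(mask, group_t_map(subject_maps, chance), 0.0)
    tfce_true = tfce_transform(t_true, mask, E=E, H=H, n_steps=n_steps)
    n_sub, n_per = subject_perm_maps.shape[:2]
    null_tfce = np.empty((n_group_perms, *mask.shape))
    for g in range(n_group_perms):
        picks = rng.integers(0, n_per, size=n_sub)
        sample = subject_perm_maps[np.arange(n_sub), picks]
        t_null = np.where(mask, group_t_map(sample, chance), 0.0)
        null_tfce[g] = tfce_transform(t_null, mask, E=E, H=H, n_steps=n_steps)
    p, sig, maxima = maxstat_fwe(tfce_true, null_tfce, alpha=alpha, mask=mask)
    return SearchlightGroupResult(t_true, tfce_true, p, sig, maxima)
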