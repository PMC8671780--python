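"""Deception Detection Matrices: sliding-window single-trial decoding.

A DDM is an m-by-m lower-triangular matrix whose (i, j) cell is the
lie-vs-truth classification accuracy for the analysis window starting at
bin i (0-based) with length j bins (1-based), on a 1-s envelope epoch cut
into 10-ms bins (m = 100 at full scale).  Cells exist only where
i + j <= m, giving m(m+1)/2 defined cells (5050 at m = 100).

Per window the features (envelope samples, or per-bin means) are reduced
to two principal components fitted across all trials of the stage, and a
linear classifier is scored by repeated paired holdout: one lie and one
truth trial are left out at random, the classifier is trained on the rest
and scored on the two held-out trials; accuracy is the mean over all
held-out predictions.  When the number of distinct (lie, truth) holdout
pairs does not exceed ``n_iterations`` the enumeration is exhaustive.

The default classifier minimizes a regularized least-squares cost on +-1
labels (the linear "least-squares SVM" reading of the procedure); a
maximum-margin SVM (C = 1) is available via ``classifier="svm"``.  The
least-squares route admits exact rank-one downdating of the normal
equations, which is what makes shuffle-resolved DDMs tractable: the PCA
and the Gram matrix of every window are shared across all label
permutations, and all holdout refits are closed-form batched 3x3 solves.

Label-shuffled DDMs (the permutation null) rerun the identical pipeline on
permuted labels, preserving class counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .preprocess import EpochSet


class LowVarianceWarning(UserWarning):
    """Two components explain less than the expected variance fraction."""


@dataclass(frozen=True)
class DDMConfig:
    """Knobs of the DDM pipeline; defaults are the full-scale constants
    (m = 100 bins of 10 ms, 1000 holdout iterations)."""

    m_bins: int = 100
    bin_ms: float = 10.0
    n_iterations: int = 1000
    classifier: str = "lsq"  # "lsq" | "svm"
    features: str = "samples"  # "samples" | "binned"
    ridge: float = 1e-8
    leakage_free_pca: bool = False  # fit PCA on training folds only (slow path)
    explained_variance_floor: float = 0.95

    def samples_per_bin(self, fs: int) -> int:
        spb = self.bin_ms * fs / 1000.0
        if abs(spb - round(spb)) > 1e-9:
            raise ValueError("bin_ms must be an integer number of samples")
        return int(round(spb))


#: desk-scale defaults: 50-ms bins (m=20), 100 iterations
DESK_CONFIG = DDMConfig(m_bins=20, bin_ms=50.0, n_iterations=100)


@dataclass
class DDM:
    """One deception detection matrix with its provenance."""

    accuracy: np.ndarray  # [m x m]; [i, j-1] = accuracy(onset i, size j); NaN masked
    m: int
    bin_ms: float
    meta: dict = field(default_factory=dict)

    @property
    def defined_mask(self) -> np.ndarray:
        i = np.arange(self.m)[:, None]
        j = np.arange(1, self.m + 1)[None, :]
        return (i + j) <= self.m

    @property
    def defined_values(self) -> np.ndarray:
        return self.accuracy[self.defined_mask]

    def cell(self, onset_bin: int, size_bins: int) -> float:
        return float(self.accuracy[onset_bin, size_bins - 1])


def n_defined_cells(m: int) -> int:
    return m * (m + 1) // 2


def window_slice(
    epochs: EpochSet,
    onset_bin: int,
    size_bins: int,
    config: DDMConfig = DDMConfig(),
) -> np.ndarray:
    """Feature matrix [n_trials x features] for one (onset, size) window."""
    m = config.m_bins
    if size_bins < 1 or onset_bin < 0 or onset_bin + size_bins > m:
        raise ValueError(f"window ({onset_bin}, {size_bins}) outside the m={m} triangle")
    spb = config.samples_per_bin(epochs.fs)
    if m * spb != epochs.data.shape[1]:
        raise ValueError("bin grid does not tile the epoch")
    x = epochs.data[:, onset_bin * spb:(onset_bin + size_bins) * spb]
    if config.features == "binned":
        x = x.reshape(x.shape[0], size_bins, spb).mean(axis=2)
    return x


def reduce_dimensions(features: np.ndarray, ev_floor: float = 0.95):
    """Two leading principal components of the trial-by-feature matrix.

    Returns ``(components [n x 2], explained_variance_fraction)``; warns
    when the two components explain less than ``ev_floor`` of the variance.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 trials for PCA")
    xc = x - x.mean(axis=0, keepdims=True)
    total = float(np.sum(xc**2))
    if total <= 0:
        raise ValueError("zero-variance features")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, :2] * s[:2]
    if scores.shape[1] < 2:
        scores = np.column_stack([scores, np.zeros(x.shape[0])])
    ev = float(np.sum(s[:2] ** 2) / total)
    if ev < ev_floor:
        warnings.warn(
            f"two components explain only {ev:.2f} of the variance",
            LowVarianceWarning, stacklevel=2,
        )
    return scores, ev


# ---------------------------------------------------------------------------
# classifiers


def _solve3(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched closed-form solve of 3x3 systems via the adjugate."""
    a00, a01, a02 = A[..., 0, 0], A[..., 0, 1], A[..., 0, 2]
    a10, a11, a12 = A[..., 1, 0], A[..., 1, 1], A[..., 1, 2]
    a20, a21, a22 = A[..., 2, 0], A[..., 2, 1], A[..., 2, 2]
    c00 = a11 * a22 - a12 * a21
    c01 = a12 * a20 - a10 * a22
    c02 = a10 * a21 - a11 * a20
    det = a00 * c00 + a01 * c01 + a02 * c02
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    c10 = a02 * a21 - a01 * a22
    c11 = a00 * a22 - a02 * a20
    c12 = a01 * a20 - a00 * a21
    c20 = a01 * a12 - a02 * a11
    c21 = a02 * a10 - a00 * a12
    c22 = a00 * a11 - a01 * a10
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    x0 = (c00 * b0 + c10 * b1 + c20 * b2) / det
    x1 = (c01 * b0 + c11 * b1 + c21 * b2) / det
    x2 = (c02 * b0 + c12 * b1 + c22 * b2) / det
    return np.stack([x0, x1, x2], axis=-1)


def _augment(components: np.ndarray) -> np.ndarray:
    return np.column_stack([components, np.ones(components.shape[0])])


def _gram(Z: np.ndarray, ridge: float) -> np.ndarray:
    G = Z.T @ Z
    lam = ridge * max(np.trace(G[:2, :2]), 1.0)
    G = G.copy()
    G[0, 0] += lam
    G[1, 1] += lam
    return G


def _lsq_holdout_accuracy(Z, G, Zty, a_idx, b_idx) -> np.ndarray:
    """Per-prediction correctness for holdout pairs (a=lie, b=truth).

    Trains the least-squares classifier on all trials minus the pair via a
    rank-one downdate of the normal equations; returns a boolean array of
    length 2P (correctness of each held-out prediction, a's then b's,
    interleaved per pair).
    """
    za, zb = Z[a_idx], Z[b_idx]
    Gp = G[None] - np.einsum("pi,pj->pij", za, za) - np.einsum("pi,pj->pij", zb, zb)
    r = Zty[None] if Zty.ndim == 1 else Zty
    rp = r - za + zb  # remove y_a=+1 and y_b=-1 contributions
    w = _solve3(Gp, rp)
    sa = np.einsum("pi,pi->p", za, w)
    sb = np.einsum("pi,pi->p", zb, w)
    return np.column_stack([sa > 0, sb < 0])


def _svm_holdout_accuracy(components, y, a_idx, b_idx):
    from sklearn.svm import SVC

    out = np.empty((len(a_idx), 2), dtype=bool)
    n = components.shape[0]
    for k, (a, b) in enumerate(zip(a_idx, b_idx)):
        mask = np.ones(n, dtype=bool)
        mask[[a, b]] = False
        clf = SVC(kernel="linear", C=1.0).fit(components[mask], y[mask])
        out[k] = clf.predict(components[[a, b]]) == y[[a, b]]
    return out


def _holdout_pairs(lie_idx, truth_idx, n_iterations, rng):
    """Exhaustive enumeration when feasible, else sampling with replacement."""
    n_pairs = lie_idx.size * truth_idx.size
    if n_pairs <= n_iterations:
        a = np.repeat(lie_idx, truth_idx.size)
        b = np.tile(truth_idx, lie_idx.size)
    else:
        a = lie_idx[rng.integers(0, lie_idx.size, n_iterations)]
        b = truth_idx[rng.integers(0, truth_idx.size, n_iterations)]
    return a, b


def classify_window(
    components: np.ndarray,
    labels: np.ndarray,
    n_iterations: int = 1000,
    seed: int = 0,
    classifier: str = "lsq",
    ridge: float = 1e-8,
) -> float:
    """Paired-holdout accuracy of the linear classifier on one window.

    Returns NaN (the undefined-cell marker) when either class has fewer
    than 2 trials.  Seeded and reproducible; exhaustive over all
    (lie, truth) holdout pairs whenever their number does not exceed
    ``n_iterations``.
    """
    labels = np.asarray(labels, dtype=bool)
    lie_idx = np.flatnonzero(labels)
    truth_idx = np.flatnonzero(~labels)
    if lie_idx.size < 2 or truth_idx.size < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    a, b = _holdout_pairs(lie_idx, truth_idx, n_iterations, rng)
    y = np.where(labels, 1.0, -1.0)
    if classifier == "lsq":
        Z = _augment(np.asarray(components, dtype=np.float64))
        G = _gram(Z, ridge)
        correct = _lsq_holdout_accuracy(Z, G, Z.T @ y, a, b)
    elif classifier == "svm":
        correct = _svm_holdout_accuracy(np.asarray(components, float), y, a, b)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    return float(np.mean(correct))


# ---------------------------------------------------------------------------
# DDM construction


def _cumulative_gram(epochs: EpochSet, config: DDMConfig) -> np.ndarray:
    """K[k] = uncentered trial Gram matrix of features in bins [0, k)."""
    n = epochs.n_trials
    m = config.m_bins
    spb = config.samples_per_bin(epochs.fs)
    if m * spb != epochs.data.shape[1]:
        raise ValueError("bin grid does not tile the epoch")
    K = np.empty((m + 1, n, n))
    K[0] = 0.0
    data = np.asarray(epochs.data, dtype=np.float64)
    for k in range(m):
        xk = data[:, k * spb:(k + 1) * spb]
        if config.features == "binned":
            xb = xk.mean(axis=1)
            K[k + 1] = K[k] + np.outer(xb, xb)
        else:
            K[k + 1] = K[k] + xk @ xk.T
    return K


def _window_scores_from_gram(Kw: np.ndarray):
    """Top-2 PCA scores and explained variance from an uncentered Gram."""
    n = Kw.shape[0]
    rm = Kw.mean(axis=1, keepdims=True)
    Gc = Kw - rm - rm.T + rm.mean()
    Gc = 0.5 * (Gc + Gc.T)
    total = float(np.trace(Gc))
    if total <= 1e-12 * n:
        return None, 0.0
    vals, vecs = sla.eigh(Gc, subset_by_index=[n - 2, n - 1])
    vals = np.clip(vals[::-1], 0.0, None)  # descending
    vecs = vecs[:, ::-1]
    scores = vecs * np.sqrt(vals)
    return scores, float(vals.sum() / total)


def _cell_order(m: int):
    """Canonical traversal of defined cells: onset ascending, size ascending."""
    return [(i, j) for i in range(m) for j in range(1, m - i + 1)]


def _row_draws(seed: int, tag: int, n_cells: int, n_iter: int,
               n_lie: int, n_truth: int):
    """Holdout-pair index draws for one label row, all cells at once.

    One counter-based stream per (seed, row tag), consumed in canonical
    cell order, so a DDM built alone is identical to the same row inside a
    joint real-plus-shuffles run.
    """
    rng = np.random.default_rng(
        np.random.Philox(key=np.uint64(seed & 0xFFFFFFFFFFFFFFFF),
                         counter=[int(tag), 0, 0, 0])
    )
    d0 = rng.integers(0, n_lie, (n_cells, n_iter))
    d1 = rng.integers(0, n_truth, (n_cells, n_iter))
    return d0, d1


def _build_ddms_multi(
    epochs: EpochSet,
    label_rows: np.ndarray,
    row_tags: np.ndarray,
    config: DDMConfig,
    seed: int,
) -> np.ndarray:
    """Accuracy arrays for several label vectors over one epoch set.

    ``label_rows`` is [L x n_trials] boolean; ``row_tags`` distinguishes
    rows in the random stream (0 = real labels, r >= 1 = shuffle r), so a
    DDM built alone and as part of a joint real+shuffles run is identical.
    All rows must share their class counts (label shuffles do), which lets
    the holdout machinery run fully vectorized across rows.
    """
    if config.classifier != "lsq" or config.leakage_free_pca:
        return _build_ddms_multi_slow(epochs, label_rows, row_tags, config, seed)

    L, n = label_rows.shape
    m = config.m_bins
    acc = np.full((L, m, m), np.nan)
    n_lie = int(label_rows[0].sum())
    n_truth = n - n_lie
    if not np.all(label_rows.sum(axis=1) == n_lie):
        return _build_ddms_multi_slow(epochs, label_rows, row_tags, config, seed)
    if n_lie < 2 or n_truth < 2:
        return acc
    lie_mat = np.vstack([np.flatnonzero(row) for row in label_rows])
    truth_mat = np.vstack([np.flatnonzero(~row) for row in label_rows])

    cells = _cell_order(m)
    n_pairs = n_lie * n_truth
    exhaustive = n_pairs <= config.n_iterations
    if exhaustive:
        P = n_pairs
        base_a = np.repeat(np.arange(n_lie), n_truth)
        base_b = np.tile(np.arange(n_truth), n_lie)
        A_fixed = lie_mat[:, base_a]  # [L x P]
        B_fixed = truth_mat[:, base_b]
    else:
        P = config.n_iterations
        D0 = np.empty((L, len(cells), P), dtype=np.intp)
        D1 = np.empty((L, len(cells), P), dtype=np.intp)
        for r in range(L):
            D0[r], D1[r] = _row_draws(seed, row_tags[r], len(cells), P,
                                      n_lie, n_truth)

    r_cat = np.repeat(np.arange(L), P)
    K = _cumulative_gram(epochs, config)
    for c, (i, j) in enumerate(cells):
        scores, _ = _window_scores_from_gram(K[i + j] - K[i])
        if scores is None:
            continue
        Z = _augment(scores)
        G = _gram(Z, config.ridge)
        if exhaustive:
            A, B = A_fixed, B_fixed
        else:
            A = np.take_along_axis(lie_mat, D0[:, c, :], axis=1)
            B = np.take_along_axis(truth_mat, D1[:, c, :], axis=1)
        Zty_rows = np.where(label_rows, 1.0, -1.0) @ Z  # [L x 3]
        correct = _lsq_holdout_accuracy(Z, G, Zty_rows[r_cat],
                                        A.ravel(), B.ravel())
        acc[:, i, j - 1] = correct.reshape(L, P, 2).mean(axis=(1, 2))
    return acc


def _build_ddms_multi_slow(epochs, label_rows, row_tags, config, seed):
    """Reference path: per-cell, per-row classification (supports the SVM
    classifier and leakage-free PCA fitted on training folds only)."""
    L, n = label_rows.shape
    m = config.m_bins
    cells = _cell_order(m)
    acc = np.full((L, m, m), np.nan)
    draws = {}
    for r in range(L):
        lie_idx = np.flatnonzero(label_rows[r])
        truth_idx = np.flatnonzero(~label_rows[r])
        if (lie_idx.size >= 2 and truth_idx.size >= 2
                and lie_idx.size * truth_idx.size > config.n_iterations):
            draws[r] = _row_draws(seed, row_tags[r], len(cells),
                                  config.n_iterations, lie_idx.size,
                                  truth_idx.size)
    for c, (i, j) in enumerate(cells):
        feats = window_slice(epochs, i, j, config)
        if not config.leakage_free_pca:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", LowVarianceWarning)
                try:
                    comps, _ = reduce_dimensions(feats)
                except ValueError:
                    continue
        for r in range(L):
            labels = label_rows[r]
            lie_idx = np.flatnonzero(labels)
            truth_idx = np.flatnonzero(~labels)
            if lie_idx.size < 2 or truth_idx.size < 2:
                continue
            if r in draws:
                a = lie_idx[draws[r][0][c]]
                b = truth_idx[draws[r][1][c]]
            else:  # exhaustive enumeration
                a = np.repeat(lie_idx, truth_idx.size)
                b = np.tile(truth_idx, lie_idx.size)
            y = np.where(labels, 1.0, -1.0)
            if config.leakage_free_pca:
                correct = _leakage_free_correct(feats, y, a, b, config)
            elif config.classifier == "svm":
                correct = _svm_holdout_accuracy(comps, y, a, b)
            else:
                Z = _augment(comps)
                correct = _lsq_holdout_accuracy(Z, _gram(Z, config.ridge),
                                                Z.T @ y, a, b)
            acc[r, i, j - 1] = float(np.mean(correct))
    return acc


def _leakage_free_correct(feats, y, a_idx, b_idx, config):
    """PCA refit on the training fold of every holdout pair."""
    n = feats.shape[0]
    out = np.empty((len(a_idx), 2), dtype=bool)
    for k, (a, b) in enumerate(zip(a_idx, b_idx)):
        mask = np.ones(n, dtype=bool)
        mask[[a, b]] = False
        xtr = feats[mask]
        mu = xtr.mean(axis=0)
        xc = xtr - mu
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        V = vt[:2].T
        ctr = xc @ V
        cte = (feats[[a, b]] - mu) @ V
        if config.classifier == "svm":
            from sklearn.svm import SVC

            clf = SVC(kernel="linear", C=1.0).fit(ctr, y[mask])
            out[k] = clf.predict(cte) == y[[a, b]]
        else:
            Z = _augment(ctr)
            G = _gram(Z, config.ridge)
            w = np.linalg.solve(G, Z.T @ y[mask])
            sc = _augment(cte) @ w
            out[k] = (sc * y[[a, b]]) > 0
    return out


def _meta(epochs: EpochSet, config: DDMConfig, seed: int, **extra) -> dict:
    return {
        "muscle": epochs.muscle, "event": epochs.event, "stage": epochs.stage,
        "n_trials": epochs.n_trials, "n_iterations": config.n_iterations,
        "seed": seed, **extra,
    }


def build_ddm(epochs: EpochSet, config: DDMConfig = DDMConfig(), seed: int = 0) -> DDM:
    """The real-label DDM: every defined (onset, size) cell classified."""
    labels = np.asarray(epochs.labels, dtype=bool)[None, :]
    acc = _build_ddms_multi(epochs, labels, np.array([0]), config, seed)
    return DDM(accuracy=acc[0], m=config.m_bins, bin_ms=config.bin_ms,
               meta=_meta(epochs, config, seed, kind="real"))


def _shuffle_rows(labels: np.ndarray, n_shuffles: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A]))
    return np.vstack([labels[rng.permutation(labels.size)] for _ in range(n_shuffles)])


def build_shuffled_ddms(
    epochs: EpochSet,
    n_shuffles: int = 1000,
    seed: int = 0,
    config: DDMConfig = DDMConfig(),
) -> list[DDM]:
    """Label-shuffled DDMs: each permutes the labels once (class counts
    preserved) and reruns the identical pipeline."""
    labels = np.asarray(epochs.labels, dtype=bool)
    rows = _shuffle_rows(labels, n_shuffles, seed)
    tags = np.arange(1, n_shuffles + 1)
    acc = _build_ddms_multi(epochs, rows, tags, config, seed)
    return [
        DDM(accuracy=acc[r], m=config.m_bins, bin_ms=config.bin_ms,
            meta=_meta(epochs, config, seed, kind="shuffle", shuffle=r + 1))
        for r in range(n_shuffles)
    ]


def build_real_and_shuffled(
    epochs: EpochSet,
    n_shuffles: int,
    seed: int = 0,
    config: DDMConfig = DDMConfig(),
) -> tuple[DDM, list[DDM]]:
    """Joint construction of the real DDM and its permutation null, sharing
    the per-window PCA; bit-identical to the two separate calls."""
    labels = np.asarray(epochs.labels, dtype=bool)
    rows = np.vstack([labels[None, :], _shuffle_rows(labels, n_shuffles, seed)])
    tags = np.arange(0, n_shuffles + 1)
    acc = _build_ddms_multi(epochs, rows, tags, config, seed)
    real = DDM(accuracy=acc[0], m=config.m_bins, bin_ms=config.bin_ms,
               meta=_meta(epochs, config, seed, kind="real"))
    shuffled = [
        DDM(accuracy=acc[r + 1], m=config.m_bins, bin_ms=config.bin_ms,
            meta=_meta(epochs, config, seed, kind="shuffle", shuffle=r + 1))
        for r in range(n_shuffles)
    ]
    return real, shuffled
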