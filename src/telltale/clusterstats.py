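"""Cluster-based permutation significance on deception detection matrices.

The multiple-comparisons correction over the m(m+1)/2 window cells follows
the standard cluster-permutation recipe: (1) a statistical threshold is set
at the 95th percentile of accuracy over all defined cells of the shuffled
DDMs (linear interpolation between order statistics); (2) cells of each
DDM — real and shuffled — strictly exceeding the threshold are clustered
by temporal adjacency on the (onset, size) grid, with minimal cluster
size 2; (3) a cluster's statistic is the sum of its accuracies; (4) each
shuffled DDM contributes its best cluster statistic (0 when it has none)
to the null distribution; (5) a real cluster is significant when its
statistic exceeds every null value, which with 1000 shuffles bounds the
familywise significance level at p < .001 (add-one bound 1/1001).

Adjacency defaults to 4-connectivity (shared edge); 8-connectivity is
available.  Reported p-values use the add-one permutation convention
(1 + #{null >= stat}) / (1 + n_shuffles), so p is never zero, while the
exceed-all decision rule is preserved exactly in the ``significant`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ddm import DDM

#: fixed ordering of the six DDM slots per participant and stage
SLOT_ORDER = (
    ("ZM", "stimulus"), ("ZM", "speech"), ("ZM", "response"),
    ("CS", "stimulus"), ("CS", "speech"), ("CS", "response"),
)

MIN_CLUSTER_SIZE = 2


@dataclass
class ClusterResult:
    """One suprathreshold cluster of DDM cells."""

    cells: frozenset  # of (onset_bin 0-based, size_bins 1-based)
    stat: float  # sum of accuracies over the cells
    p_bound: float | None = None
    significant: bool | None = None


@dataclass
class NullDistribution:
    """Max-cluster statistics of the shuffled DDMs at a shared threshold."""

    max_stats: np.ndarray
    threshold: float

    def __post_init__(self):
        self.max_stats = np.asarray(self.max_stats, dtype=float)


def significance_threshold(shuffled: list[DDM], percentile: float = 95.0) -> float:
    """Percentile of accuracy pooled over all defined cells of all shuffles.

    Linear interpolation between order statistics (numpy's default), the
    convention under which every documented example is computed.
    """
    if not shuffled:
        raise ValueError("need at least one shuffled DDM")
    vals = np.concatenate([d.defined_values for d in shuffled])
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("shuffled DDMs contain no defined cells")
    return float(np.percentile(vals, percentile))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def find_clusters(
    ddm: DDM,
    threshold: float,
    connectivity: int = 4,
    min_size: int = MIN_CLUSTER_SIZE,
) -> list[ClusterResult]:
    """Connected components of cells strictly exceeding the threshold.

    Components smaller than ``min_size`` are discarded.  Returned clusters
    are sorted by descending statistic.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be an accuracy in [0, 1]")
    acc = ddm.accuracy
    mask = np.zeros_like(acc, dtype=bool)
    defined = ddm.defined_mask & ~np.isnan(acc)
    mask[defined] = acc[defined] > threshold
    labeled, n = ndimage.label(mask, structure=_structure(connectivity))
    clusters = []
    for lab in range(1, n + 1):
        ii, jj = np.nonzero(labeled == lab)
        if ii.size < min_size:
            continue
        cells = frozenset((int(i), int(j) + 1) for i, j in zip(ii, jj))
        clusters.append(ClusterResult(cells=cells, stat=float(acc[ii, jj].sum())))
    clusters.sort(key=lambda c: -c.stat)
    return clusters


def null_max_stats(
    shuffled: list[DDM],
    threshold: float,
    connectivity: int = 4,
    min_size: int = MIN_CLUSTER_SIZE,
) -> NullDistribution:
    """Best cluster statistic of each shuffled DDM (0 when none)."""
    stats = np.zeros(len(shuffled))
    for k, d in enumerate(shuffled):
        cl = find_clusters(d, threshold, connectivity, min_size)
        stats[k] = cl[0].stat if cl else 0.0
    return NullDistribution(max_stats=stats, threshold=threshold)


def significant_clusters(
    real: DDM,
    null: NullDistribution,
    connectivity: int = 4,
    min_size: int = MIN_CLUSTER_SIZE,
) -> list[ClusterResult]:
    """Score the real DDM's clusters against the permutation null.

    A cluster is significant iff its statistic exceeds every null maximum;
    its reported bound is the add-one permutation p-value.
    """
    n = null.max_stats.size
    if n == 0:
        raise ValueError("empty null distribution")
    out = []
    for c in find_clusters(real, null.threshold, connectivity, min_size):
        b = int(np.sum(null.max_stats >= c.stat))
        out.append(
            ClusterResult(
                cells=c.cells, stat=c.stat,
                p_bound=(1 + b) / (1 + n),
                significant=bool(c.stat > null.max_stats.max()),
            )
        )
    return out


def analyze_ddm_family(
    real: DDM,
    shuffled: list[DDM],
    percentile: float = 95.0,
    connectivity: int = 4,
    min_size: int = MIN_CLUSTER_SIZE,
) -> tuple[list[ClusterResult], NullDistribution]:
    """Threshold, cluster and score one (participant, muscle, event, stage)
    DDM against its own shuffles (per-family threshold pooling).

    A fully undefined family (a class with < 2 trials leaves every cell
    NaN) yields no clusters and an all-zero null rather than an error.
    """
    pooled = np.concatenate([d.defined_values for d in shuffled]) if shuffled else np.array([])
    if pooled.size == 0 or np.all(np.isnan(pooled)):
        return [], NullDistribution(max_stats=np.zeros(len(shuffled)),
                                    threshold=float("nan"))
    thr = significance_threshold(shuffled, percentile)
    null = null_max_stats(shuffled, thr, connectivity, min_size)
    return significant_clusters(real, null, connectivity, min_size), null


def count_vector(six_results: dict) -> np.ndarray:
    """Six-cell vector of significant-cluster counts, fixed slot order
    (ZM-stimulus, ZM-speech, ZM-response, CS-stimulus, CS-speech,
    CS-response)."""
    counts = np.zeros(6, dtype=int)
    for k, slot in enumerate(SLOT_ORDER):
        if slot not in six_results:
            raise KeyError(f"missing DDM slot {slot}")
        counts[k] = sum(1 for c in six_results[slot] if c.significant)
    return counts
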