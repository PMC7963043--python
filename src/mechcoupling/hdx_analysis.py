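"""Downstream statistics for hydrogen/deuterium-exchange (HDX-MS) uptake data.

The pipeline mirrors the experimental analysis used to validate the coupling
model: peptide deuterium counts are converted to %D against each peptide's
24-hour reference, pairwise |d_i − d_j| difference matrices capture which
peptides exchange alike, Pearson correlation of the difference profiles gives
a peptide–peptide similarity, and hierarchical clustering (distance 1 − corr,
complete linkage) groups peptides into dynamic "neighbourhoods". The cluster
count is chosen by maximizing the silhouette score of k-means partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "UptakeTable",
    "HDXDifferenceMatrix",
    "CorrelationClustering",
    "percent_uptake",
    "difference_matrix",
    "correlation_clusters",
]

#: hour count of the full-exchange reference timepoint
REFERENCE_HOURS = 24.0


@dataclass
class UptakeTable:
    """Peptide-level deuterium counts per (condition, timepoint).

    ``counts`` is a DataFrame indexed by peptide_id with a (condition,
    timepoint) column MultiIndex; ``peptides`` maps peptide_id to
    (chain, start, end) residue spans. The 24-hour column of each condition
    is the full-exchange reference D_max.
    """

    counts: pd.DataFrame
    peptides: pd.DataFrame  # columns: chain, start, end; index: peptide_id

    def __post_init__(self) -> None:
        bad = self.peptides[self.peptides["start"] > self.peptides["end"]]
        if len(bad):
            raise ValueError(f"invalid residue spans for peptides {list(bad.index)}")

    @classmethod
    def from_csv(cls, path) -> "UptakeTable":
        """Load the long-format CSV dialect.

        Expected columns: peptide_id, chain, start, end, condition,
        timepoint (hours), D_count — one row per measurement.
        """
        df = pd.read_csv(path)
        required = {"peptide_id", "chain", "start", "end", "condition", "timepoint", "D_count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing CSV columns: {sorted(missing)}")
        counts = df.pivot_table(
            index="peptide_id", columns=["condition", "timepoint"], values="D_count"
        )
        peptides = (
            df[["peptide_id", "chain", "start", "end"]]
            .drop_duplicates("peptide_id")
            .set_index("peptide_id")
        )
        return cls(counts=counts, peptides=peptides.loc[counts.index])

    def to_csv(self, path) -> None:
        long = self.counts.stack(["condition", "timepoint"], future_stack=True).rename("D_count").reset_index()
        long = long.merge(self.peptides, left_on="peptide_id", right_index=True)
        long[["peptide_id", "chain", "start", "end", "condition", "timepoint", "D_count"]].to_csv(
            path, index=False
        )

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.counts.columns.get_level_values("condition")))


def percent_uptake(table: UptakeTable, reference_hours: float = REFERENCE_HOURS) -> pd.DataFrame:
    """%D per peptide and (condition, timepoint): 100·#D / #D(24 h).

    The reference is per peptide and per condition. Raises, naming the
    peptide, if any 24-hour reference count is zero or absent.
    """
    out = {}
    for cond in table.conditions:
        block = table.counts[cond]
        if reference_hours not in block.columns:
            raise ValueError(f"condition {cond!r} lacks the {reference_hours} h reference timepoint")
        dmax = block[reference_hours]
        zero = dmax[(dmax == 0) | dmax.isna()]
        if len(zero):
            raise ValueError(f"zero 24 h reference uptake for peptide(s) {list(zero.index)}")
        for tp in block.columns:
            out[(cond, tp)] = 100.0 * block[tp] / dmax
    result = pd.DataFrame(out, index=table.counts.index)
    result.columns = pd.MultiIndex.from_tuples(result.columns, names=["condition", "timepoint"])
    return result


@dataclass
class HDXDifferenceMatrix:
    """Symmetric |d_i − d_j| matrix (%D units) for one condition/timepoint."""

    values: np.ndarray
    peptide_ids: list = field(default_factory=list)
    condition: str = ""


def difference_matrix(d, peptide_ids=None, condition: str = "") -> HDXDifferenceMatrix:
    """Pairwise absolute %D differences of one per-peptide uptake vector."""
    vec = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite %D values")
    mat = np.abs(vec[:, None] - vec[None, :])
    if peptide_ids is None:
        peptide_ids = list(range(vec.size))
    return HDXDifferenceMatrix(values=mat, peptide_ids=list(peptide_ids), condition=condition)


@dataclass
class CorrelationClustering:
    """Pearson correlation of difference profiles plus its hierarchical cut."""

    corr: np.ndarray
    linkage: np.ndarray
    k: int
    labels: np.ndarray  # per-peptide cluster id in 1..k
    peptide_ids: list
    silhouette_by_k: dict[int, float]
    excluded: list = field(default_factory=list)
    seed: int = 0


def correlation_clusters(
    m: HDXDifferenceMatrix, k_range=(2, 12), seed: int = 0, n_restarts: int = 50
) -> CorrelationClustering:
    """Cluster peptides by the correlation of their exchange-difference rows.

    Pearson correlation between rows of the difference matrix; hierarchical
    clustering on 1 − corr with complete linkage; the cluster count k is the
    silhouette-score maximizer over k-means partitions (``n_restarts``
    restarts, seeded) of the difference-profile rows for k in ``k_range``;
    the hierarchical tree is then cut at that k. Zero-variance rows are
    excluded with a warning.
    """
    rows = np.asarray(m.values, dtype=float)
    ids = list(m.peptide_ids)
    keep = rows.std(axis=1) > 0
    excluded = [ids[i] for i in np.flatnonzero(~keep)]
    if excluded:
        warnings.warn(f"excluding zero-variance peptides: {excluded}", stacklevel=2)
        rows = rows[keep][:, keep]
        ids = [p for p, k_ in zip(ids, keep) if k_]
    n = rows.shape[0]
    if n < 3:
        raise ValueError("need at least 3 peptides with variance to cluster")

    corr = np.corrcoef(rows)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    merge_tree = linkage(squareform(dist, checks=False), method="complete")

    lo, hi = int(k_range[0]), int(k_range[1])
    n_distinct = np.unique(rows, axis=0).shape[0]
    hi = min(hi, n - 1, n_distinct)  # duplicate profiles cannot split further
    scores: dict[int, float] = {}
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(rows)
        if len(set(km.labels_)) < 2:
            continue
        scores[k] = float(silhouette_score(rows, km.labels_))
    if not scores:
        raise ValueError("no admissible cluster count in range")
    best_k = max(scores, key=lambda k: (scores[k], -k))
    labels = fcluster(merge_tree, t=best_k, criterion="maxclust")
    return CorrelationClustering(
        corr=corr, linkage=merge_tree, k=best_k, labels=labels,
        peptide_ids=ids, silhouette_by_k=scores, excluded=excluded, seed=seed,
    )
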