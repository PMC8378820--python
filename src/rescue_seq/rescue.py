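"""Rescue clustering: k-means over dysregulated gene z-profiles and
classification of clusters whose treated-group expression reverses toward
control.

Disease-dysregulated genes (up- and down-regulated lists from the disease vs
control contrast) are clustered separately on their per-gene z-scored
expression profiles. A cluster is flagged *reversed* when its treated-class
centroid has moved at least a fraction ``theta`` of the way from the disease
centroid back toward the control centroid; members of reversed clusters form
the "partially corrected" gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .matrix import LOG2, ExpressionMatrix, StateError

DEFAULT_SEED = 17


def zscore_by_gene(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene row to mean 0 and scale to population SD 1.

    Rows with zero variance become all-zero (no information about direction).
    """
    if m.space != LOG2:
        raise StateError("z-scoring expects log2-space values")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population SD
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.repeat(sd == 0, arr.shape[1], axis=1)] = 0.0
    return m.with_values(pd.DataFrame(z, index=m.values.index, columns=m.values.columns))


@dataclass
class ClusterAssignment:
    """Per-gene cluster membership plus per-class centroids and reversal flags.

    ``assignments``: DataFrame indexed by gene with columns ``cluster_id``
    (strings like ``up_03``) and ``direction`` (up/down in disease vs
    control). ``centroids``: DataFrame indexed by cluster id, one column per
    class, holding the mean z-score of the cluster's genes over that class's
    samples. ``reversed_flags``: cluster id -> bool (empty until
    :func:`classify_reversed` runs).
    """

    assignments: pd.DataFrame
    centroids: pd.DataFrame
    k_up: int
    k_down: int
    seed: int
    theta: float | None = None
    reversed_flags: dict[str, bool] = field(default_factory=dict)


def _cluster_one_direction(z: ExpressionMatrix, genes: list[str], k: int,
                           direction: str, seed: int) -> pd.Series:
    if len(genes) == 0:
        return pd.Series(dtype=object)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} genes in the {direction} list")
    profiles = z.values.loc[list(genes)].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(profiles)
    width = max(2, len(str(k - 1)))
    return pd.Series([f"{direction}_{lab:0{width}d}" for lab in labels], index=list(genes))


def cluster_dysregulated(z: ExpressionMatrix, up_genes, down_genes,
                         k_up: int = 15, k_down: int = 15,
                         seed: int = DEFAULT_SEED) -> ClusterAssignment:
    """k-means (k-means++ init, 10 restarts, fixed seed) per direction list."""
    up_genes, down_genes = list(up_genes), list(down_genes)
    up = _cluster_one_direction(z, up_genes, k_up, "up", seed)
    down = _cluster_one_direction(z, down_genes, k_down, "down", seed + 1)
    assignments = pd.DataFrame({
        "cluster_id": pd.concat([up, down]) if (len(up) or len(down)) else pd.Series(dtype=object),
        "direction": pd.Series(
            ["up"] * len(up) + ["down"] * len(down),
            index=list(up.index) + list(down.index), dtype=object),
    })
    centroids = _class_centroids(z, assignments)
    return ClusterAssignment(assignments, centroids, k_up, k_down, seed)


def _class_centroids(z: ExpressionMatrix, assignments: pd.DataFrame) -> pd.DataFrame:
    classes = z.class_names
    rows = {}
    for cid, members in assignments.groupby("cluster_id").groups.items():
        block = z.values.loc[list(members)]
        rows[cid] = {cls: float(block[z.samples_of(cls)].to_numpy().mean())
                     for cls in classes}
    return pd.DataFrame.from_dict(rows, orient="index", columns=classes)


def classify_reversed(ca: ClusterAssignment, theta: float = 0.5,
                      control: str = "control", disease: str = "disease",
                      treated: str = "treated") -> ClusterAssignment:
    """Flag clusters whose treated centroid moved >= theta of the way back.

    Reversed iff |c_trt - c_ctrl| <= (1 - theta) * |c_dis - c_ctrl|. theta=0
    flags everything not past disease; theta=1 demands full return to control.
    """
    for cls in (control, disease, treated):
        if cls not in ca.centroids.columns:
            raise ValueError(f"class {cls!r} missing from centroid table")
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    flags = {}
    for cid, row in ca.centroids.iterrows():
        span = abs(row[disease] - row[control])
        flags[cid] = bool(abs(row[treated] - row[control]) <= (1.0 - theta) * span)
    ca.reversed_flags = flags
    ca.theta = theta
    return ca


def corrected_gene_list(ca: ClusterAssignment) -> dict:
    """Union of reversed-cluster members plus per-direction restored fractions.

    Fractions are reversed clusters over total clusters per direction (0 when
    a direction has no clusters).
    """
    if ca.theta is None:
        raise ValueError("classify_reversed must run before corrected_gene_list")
    reversed_ids = {cid for cid, flag in ca.reversed_flags.items() if flag}
    genes = sorted(ca.assignments.index[ca.assignments["cluster_id"].isin(reversed_ids)])
    fractions = {}
    for direction in ("up", "down"):
        ids = set(ca.assignments.loc[ca.assignments["direction"] == direction, "cluster_id"])
        fractions[direction] = len(ids & reversed_ids) / len(ids) if ids else 0.0
    return {
        "genes": genes,
        "fraction_restored_up": fractions["up"],
        "fraction_restored_down": fractions["down"],
    }
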