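"""Oxidative stress (GSH/GSSG) fold changes and secreted-protein analysis.

The reduced-to-oxidized glutathione ratio GSH/GSSG is the oxidative-stress
readout: a treated/control fold change below 1 means the cell's glutathione
pool shifted toward the oxidized form, i.e. oxidative stress.

Secreted proteins (cytokines, chemokines, growth factors from a multiplex
panel) are analyzed as fold changes versus control. Responders are proteins
shifted at least ``cutoff``-fold in either direction in at least one
treatment; responder profiles are grouped by agglomerative hierarchical
clustering of the log2 matrix, by default with Pearson correlation distance
(1 - r) and average linkage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DegenerateRowError, KeyingError, ValidationError


def gsh_gssg_fc(treated_gsh, treated_gssg, control_gsh, control_gssg) -> float:
    """Fold change of the GSH/GSSG ratio versus control; < 1 = oxidative stress."""
    vals = np.array(
        [treated_gsh, treated_gssg, control_gsh, control_gssg], dtype=float
    )
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValidationError("all four glutathione signals must be finite and > 0")
    return float((vals[0] / vals[1]) / (vals[2] / vals[3]))


def oxidative_stress_table(df: pd.DataFrame, control: str = "control") -> pd.DataFrame:
    """Per-treatment GSH/GSSG ratios and their fold change versus control.

    ``df`` needs columns treatment, gsh, gssg (one row per treatment, signals
    already averaged over replicates, or multiple rows which are averaged here).
    """
    for col in ("treatment", "gsh", "gssg"):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r}")
    means = df.groupby("treatment", as_index=False)[["gsh", "gssg"]].mean()
    if control not in set(means["treatment"]):
        raise KeyingError(f"control treatment {control!r} not found")
    if (means[["gsh", "gssg"]] <= 0).any().any():
        raise ValidationError("glutathione signals must be > 0")
    means["ratio"] = means["gsh"] / means["gssg"]
    ctrl_ratio = float(means.loc[means["treatment"] == control, "ratio"].iloc[0])
    means["ratio_fc"] = means["ratio"] / ctrl_ratio
    return means


def protein_fold_change(treated: pd.Series, control: pd.Series) -> pd.Series:
    """Per-protein treated/control ratio; index = protein labels."""
    treated, control = pd.Series(treated, dtype=float), pd.Series(control, dtype=float)
    missing = set(treated.index) ^ set(control.index)
    if missing:
        raise KeyingError(f"protein sets differ: {sorted(missing)}")
    control = control.reindex(treated.index)
    if (control <= 0).any():
        bad = control.index[control <= 0].tolist()
        raise ValidationError(f"non-positive control signals for: {bad}")
    return treated / control


def build_secretome_matrix(
    treated: pd.DataFrame, control: pd.Series
) -> pd.DataFrame:
    """Fold-change matrix (proteins x treatments) from raw signal columns."""
    cols = {t: protein_fold_change(treated[t], control) for t in treated.columns}
    return pd.DataFrame(cols)


def filter_responders(matrix: pd.DataFrame, cutoff: float = 1.5) -> pd.DataFrame:
    """Keep proteins changed >= cutoff-fold (either direction) in some treatment.

    Two-sided on the ratio scale: a protein passes if any fold change is
    >= cutoff or <= 1/cutoff; boundary values are included.
    """
    if not np.isfinite(cutoff) or cutoff <= 1:
        raise ValidationError("cutoff must be a finite number > 1")
    values = matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValidationError("fold changes must be finite and > 0")
    keep = ((values >= cutoff) | (values <= 1.0 / cutoff)).any(axis=1)
    return matrix.loc[keep]


class ClusterResult:
    """Row and column dendrograms of a fold-change matrix.

    Attributes
    ----------
    row_linkage, col_linkage : numpy.ndarray
        SciPy linkage matrices (step, members, merge height, cluster size).
    row_order, col_order : list of str
        Leaf labels in dendrogram order.
    """

    def __init__(self, row_linkage, col_linkage, row_labels, col_labels):
        self.row_linkage = row_linkage
        self.col_linkage = col_linkage
        self.row_labels = list(row_labels)
        self.col_labels = list(col_labels)
        self.row_order = [
            self.row_labels[i] for i in hierarchy.leaves_list(row_linkage)
        ]
        self.col_order = [
            self.col_labels[i] for i in hierarchy.leaves_list(col_linkage)
        ]

    def merge_table(self, axis: str = "rows") -> pd.DataFrame:
        """Agglomeration steps as a tidy frame: step, member_a, member_b, height, size."""
        linkage = self.row_linkage if axis == "rows" else self.col_linkage
        return pd.DataFrame(
            {
                "step": np.arange(1, linkage.shape[0] + 1),
                "member_a": linkage[:, 0].astype(int),
                "member_b": linkage[:, 1].astype(int),
                "height": linkage[:, 2],
                "size": linkage[:, 3].astype(int),
            }
        )

    def top_split(self, axis: str = "cols") -> tuple[set, set]:
        """Labels of the two subtrees under the final (root) merge."""
        linkage = self.row_linkage if axis == "rows" else self.col_linkage
        labels = self.row_labels if axis == "rows" else self.col_labels
        n = len(labels)
        members: dict[int, set] = {i: {labels[i]} for i in range(n)}
        for step, (a, b) in enumerate(linkage[:, :2].astype(int)):
            members[n + step] = members[a] | members[b]
        a, b = linkage[-1, 0].astype(int), linkage[-1, 1].astype(int)
        return members[a], members[b]


def _distance(data: np.ndarray, metric: str, axis_name: str, labels) -> np.ndarray:
    if metric == "pearson":
        spans = np.ptp(data, axis=1)
        if np.any(spans == 0):
            bad = [labels[i] for i in np.flatnonzero(spans == 0)]
            raise DegenerateRowError(
                f"constant {axis_name} under correlation distance: {bad}"
            )
        return pdist(data, metric="correlation")
    if metric == "euclidean":
        return pdist(data, metric="euclidean")
    raise ValidationError(f"unknown distance: {metric!r}")


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "pearson",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of the rows and columns of a fold-change matrix.

    Values are log2-transformed before distances are computed, so up- and
    down-regulation are symmetric about zero. Default distance is Pearson
    correlation distance (1 - r), default linkage is average (UPGMA); both are
    deterministic given the input ordering (SciPy breaks equal-distance ties by
    the lowest cluster index).
    """
    if linkage not in ("average", "complete"):
        raise ValidationError(f"unknown linkage: {linkage!r}")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError("need >= 2 rows and >= 2 columns to cluster")
    values = matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValidationError("fold changes must be finite and > 0")
    log2 = np.log2(values)
    row_d = _distance(log2, distance, "row(s)", list(matrix.index))
    col_d = _distance(log2.T, distance, "column(s)", list(matrix.columns))
    row_link = hierarchy.linkage(row_d, method=linkage)
    col_link = hierarchy.linkage(col_d, method=linkage)
    return ClusterResult(row_link, col_link, matrix.index, matrix.columns)
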