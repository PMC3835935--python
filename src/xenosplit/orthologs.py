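"""Joint human/mouse expression analysis over 1:1 orthologue pairs.

Each physical xenograft contributes two pseudo-samples to the joint matrix:
its human transcriptome (column suffix ``-H``) and its murine transcriptome
(``-M``); purely human samples contribute ``-H`` only.  Rows are 1:1
orthologue pairs, which places both species' expression on a common axis.

Sample clustering follows a correlation-of-correlations scheme: all-pairs
Pearson correlation between columns, Euclidean distance between the rows of
that correlation matrix, then agglomerative hierarchical clustering
(average linkage by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .quantify import CountMatrix

__all__ = [
    "OrthologMap",
    "load_ortholog_map",
    "build_joint_matrix",
    "pearson",
    "ClusteringResult",
    "cluster_samples",
]


@dataclass
class OrthologMap:
    """Strictly 1:1 human<->mouse gene pairing."""

    pairs: pd.DataFrame  # columns human_gene, mouse_gene
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.pairs["human_gene"].duplicated().any() or self.pairs[
            "mouse_gene"
        ].duplicated().any():
            raise ValueError("ortholog map is not 1:1")

    def __len__(self) -> int:
        return len(self.pairs)


def load_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV (human_gene, mouse_gene) and enforce 1:1.

    Every gene appearing more than once on either side is dropped entirely
    (all of its rows), with a warning carrying the dropped-row count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["human_gene", "mouse_gene"]
    if df.isna().any().any():
        raise ValueError(f"{path}: malformed rows with missing fields")
    dup_h = df["human_gene"].duplicated(keep=False)
    dup_m = df["mouse_gene"].duplicated(keep=False)
    keep = ~(dup_h | dup_m)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} ortholog rows violating 1:1 mapping")
    return OrthologMap(pairs=df[keep].reset_index(drop=True), n_dropped=n_dropped)


def _default_transform(x: pd.DataFrame) -> pd.DataFrame:
    return np.log2(x + 1.0)


def build_joint_matrix(
    human_counts: CountMatrix | None,
    mouse_counts: CountMatrix | None,
    ortholog_map: OrthologMap,
    transform="log2",
) -> pd.DataFrame:
    """Pair-indexed joint expression matrix of human and murine pseudo-samples.

    Human samples become ``<sample>-H`` columns, mouse samples ``<sample>-M``.
    Rows are restricted to orthologue pairs present in both annotations (or
    the human side only if no mouse counts are given).  Values are
    ``transform`` applied to CPM; ``"log2"`` (default) means log2(CPM + 1),
    ``"identity"`` leaves CPM untouched, and a callable is applied as is.
    """
    if transform == "log2":
        fn = _default_transform
    elif transform == "identity":
        fn = lambda x: x  # noqa: E731
    elif callable(transform):
        fn = transform
    else:
        raise ValueError(f"unknown transform {transform!r}")

    pairs = ortholog_map.pairs
    mask = np.ones(len(pairs), dtype=bool)
    if human_counts is not None:
        mask &= pairs["human_gene"].isin(human_counts.counts.index).to_numpy()
    if mouse_counts is not None:
        mask &= pairs["mouse_gene"].isin(mouse_counts.counts.index).to_numpy()
    pairs = pairs[mask]
    if pairs.empty:
        raise ValueError("no orthologue pairs overlap the count matrices")
    index = pd.Index(pairs["human_gene"], name="pair")

    cols: dict[str, np.ndarray] = {}
    if human_counts is not None:
        cpm = fn(human_counts.cpm())
        for s in human_counts.samples:
            cols[f"{s}-H"] = cpm.loc[pairs["human_gene"], s].to_numpy()
    if mouse_counts is not None:
        cpm = fn(mouse_counts.cpm())
        for s in mouse_counts.samples:
            cols[f"{s}-M"] = cpm.loc[pairs["mouse_gene"], s].to_numpy()
    joint = pd.DataFrame(cols, index=index)
    if joint.columns.duplicated().any():
        raise ValueError("duplicate pseudo-sample labels")
    return joint


def pearson(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    subset: np.ndarray | list | None = None,
) -> float:
    """Pearson correlation of two expression vectors.

    ``subset`` restricts the comparison to a gene subset: boolean mask or,
    when the inputs are Series, a list of index labels (e.g. housekeeping
    genes).  Zero variance raises rather than returning a silent NaN.
    """
    if subset is not None:
        if isinstance(x, pd.Series) and not isinstance(subset, np.ndarray):
            labels = [g for g in subset if g in x.index and g in y.index]
            x, y = x.loc[labels], y.loc[labels]
        else:
            x, y = np.asarray(x)[subset], np.asarray(y)[subset]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined: zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ClusteringResult:
    """Correlation matrix, linkage and Newick rendering of a sample tree."""

    correlation: pd.DataFrame
    distance: pd.DataFrame
    linkage: np.ndarray
    labels: list[str]

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            bl_l = node.dist - left.dist
            bl_r = node.dist - right.dist
            return f"({render(left)}:{bl_l:.6g},{render(right)}:{bl_r:.6g})"

        return render(tree) + ";"


def cluster_samples(joint: pd.DataFrame, linkage: str = "average") -> ClusteringResult:
    """Hierarchically cluster pseudo-samples of a joint matrix.

    Step 1: all-pairs Pearson correlation between columns.  Step 2: distance
    between two samples = Euclidean distance between their rows of the
    correlation matrix.  Step 3: agglomerative clustering with the given
    linkage (average by default).
    """
    if joint.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    labels = list(joint.columns)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(joint.to_numpy().T)
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)
    condensed = pdist(corr, metric="euclidean")
    Z = hierarchy.linkage(condensed, method=linkage)
    dist_df = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    return ClusteringResult(
        correlation=corr_df, distance=dist_df, linkage=Z, labels=labels
    )
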