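"""Co-expression structure of the DE miRNA list: pairwise correlation
matrix ordered by the first principal component, and genomic-cluster
statistics (a chromosomally contiguous, tightly co-expressed sub-group is
the signature of a transcribed miRNA cluster)."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ClusterReport:
    """Expression statistics of a chromosomally co-located miRNA sub-group."""

    members: list[str]
    chromosome: str
    span_start: int
    span_end: int
    mean_pairwise_r: float
    n_members: int

    def to_dict(self) -> dict:
        return asdict(self)


def correlation_matrix(
    expr: pd.DataFrame,
    feature_list: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Pearson correlations between features.

    Raises if a feature has zero variance (its correlation is undefined) or
    fewer than 3 samples are available.
    """
    features = list(feature_list) if feature_list is not None else list(expr.index)
    missing = [f for f in features if f not in expr.index]
    if missing:
        raise KeyError(f"features absent from the expression matrix: {missing}")
    sub = expr.loc[features]
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples for a correlation matrix")
    values = sub.to_numpy(dtype=float)
    sd = values.std(axis=1)
    dead = [f for f, s in zip(features, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead}")
    corr = np.corrcoef(values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=features, columns=features)


def pc_order(corr: pd.DataFrame) -> list[str]:
    """Feature ordering by loading on the first principal component.

    The first eigenvector of the correlation matrix is sign-fixed so its
    largest-magnitude entry is positive, making the ordering deterministic;
    loading ties break by feature id. Co-expressed blocks come out
    contiguous.
    """
    values = corr.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("pc_order expects a symmetric correlation matrix")
    eigval, eigvec = np.linalg.eigh(values)
    v1 = eigvec[:, np.argmax(eigval)]
    anchor = np.argmax(np.abs(v1))
    if v1[anchor] < 0:
        v1 = -v1
    ids = corr.index.to_numpy()
    order = np.lexsort((ids, v1))
    return list(ids[order])


def cluster_stats(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom: str,
    window: tuple[int, int] | None = None,
) -> ClusterReport:
    """Co-expression report for miRNAs annotated to one genomic region.

    Membership comes from annotation coordinates (chromosome plus optional
    [start, end) window), never from sequence re-alignment. The report
    carries the members, their genomic span and the mean pairwise Pearson
    correlation over all unordered member pairs.
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    ann = ann[ann.index.isin(expr.index)]
    sel = ann[ann["chrom"] == chrom]
    if window is not None:
        lo, hi = window
        sel = sel[(sel["start"] >= lo) & (sel["end"] <= hi)]
    members = sorted(sel.index)
    if len(members) < 2:
        raise ValueError(
            f"cluster on {chrom} needs >= 2 expressed members; found {len(members)}"
        )
    corr = correlation_matrix(expr, members)
    iu = np.triu_indices(len(members), k=1)
    mean_r = float(corr.to_numpy()[iu].mean())
    return ClusterReport(
        members=members,
        chromosome=chrom,
        span_start=int(sel["start"].min()),
        span_end=int(sel["end"].max()),
        mean_pairwise_r=mean_r,
        n_members=len(members),
    )


def plot_correlation_heatmap(corr: pd.DataFrame, path, order: Sequence[str] | None = None):
    """Optional static heatmap of the (PC-ordered) correlation matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if order is not None:
        corr = corr.loc[list(order), list(order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
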