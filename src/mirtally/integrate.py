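"""miRNA-mRNA integration: target-map parsing, miRNA-target correlation
profiling, the combinatorial (independent) target-count statistic, and the
DE-versus-control residual fold-change analysis.

The central idea: if a set of upregulated miRNAs contributes to global mRNA
downregulation, then the more *distinct* miRNAs from that set predictedly
target a gene, the more depressed its fold change should be — and the
depression should exceed what an equally sized list of non-differentially
expressed miRNAs produces, despite the heavy overlap between any two target
lists. Counts tally distinct miRNAs, never binding sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def canonical_gene(symbol: str) -> str:
    """Uppercase, whitespace-trimmed gene symbol (exact-match harmonization)."""
    return str(symbol).strip().upper()


@dataclass
class TargetMap:
    """Algorithm-tagged relation miRNA id -> set of predicted target genes."""

    algorithm: str
    targets: dict[str, frozenset[str]]

    @classmethod
    def from_edges(cls, algorithm: str, edges: Iterable[tuple[str, str]]) -> "TargetMap":
        acc: dict[str, set[str]] = {}
        for mirna, gene in edges:
            acc.setdefault(str(mirna), set()).add(canonical_gene(gene))
        return cls(algorithm, {m: frozenset(g) for m, g in acc.items()})

    def restrict(self, mirnas: Iterable[str]) -> "TargetMap":
        keep = set(mirnas)
        return TargetMap(self.algorithm, {m: g for m, g in self.targets.items() if m in keep})

    @property
    def n_edges(self) -> int:
        return sum(len(g) for g in self.targets.values())

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for g in self.targets.values():
            out |= g
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, g)
            for m in sorted(self.targets)
            for g in sorted(self.targets[m])
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id"])


# ---------------------------------------------------------------------------
# Parsers for prediction-file dialects
# ---------------------------------------------------------------------------

def _pick_column(columns: Sequence[str], candidates: Sequence[str], dialect: str) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    raise ValueError(
        f"{dialect} file is missing a required column; expected one of "
        f"{list(candidates)}, found {list(columns)}"
    )


def parse_target_map(
    path,
    format: str = "generic2col",
    mirna_filter: Iterable[str] | None = None,
) -> tuple[TargetMap, dict]:
    """Parse a target-prediction file into a deduplicated TargetMap.

    Dialects
    --------
    ``targetscan7``
        Tab-delimited with a gene-symbol column and a representative-miRNA
        (or miR-family) column; per-site columns are ignored, so a pair
        predicted at three sites contributes one edge.
    ``mirwalk3``
        Comma-separated with ``mirnaid`` and ``genesymbol`` columns;
        binding-region columns are ignored.
    ``generic2col``
        Two tab-separated columns (miRNA, gene), optional header.

    Returns the map plus a parse report: rows read, rows dropped (by the
    miRNA filter or malformed), edges kept after dedup.
    """
    keep = set(mirna_filter) if mirna_filter is not None else None
    if format == "targetscan7":
        df = pd.read_csv(path, sep="\t", dtype=str)
        gene_col = _pick_column(df.columns, ["gene symbol", "gene_symbol"], "targetscan7")
        mir_col = _pick_column(
            df.columns,
            ["representative mirna", "representative miRNA".lower(), "mir family", "mirna"],
            "targetscan7",
        )
    elif format == "mirwalk3":
        df = pd.read_csv(path, sep=",", dtype=str)
        gene_col = _pick_column(df.columns, ["genesymbol", "gene_symbol", "gene"], "mirwalk3")
        mir_col = _pick_column(df.columns, ["mirnaid", "mirna"], "mirwalk3")
    elif format == "generic2col":
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        if df.empty:
            df = pd.DataFrame(columns=[0, 1])
        if df.shape[1] < 2:
            raise ValueError("generic2col file must have two tab-separated columns")
        first = df.iloc[0] if len(df) else None
        if first is not None and str(first[0]).lower() in ("mirna", "mirna_id", "mir"):
            df = df.iloc[1:]
        mir_col, gene_col = df.columns[0], df.columns[1]
    else:
        raise ValueError(f"unknown target-map format {format!r}")

    n_read = len(df)
    df = df[[mir_col, gene_col]].dropna()
    df.columns = ["mirna_id", "gene_id"]
    df["mirna_id"] = df["mirna_id"].astype(str).str.strip()
    df["gene_id"] = df["gene_id"].map(canonical_gene)
    df = df[(df["mirna_id"] != "") & (df["gene_id"] != "")]
    if keep is not None:
        df = df[df["mirna_id"].isin(keep)]
    tmap = TargetMap.from_edges(format, zip(df["mirna_id"], df["gene_id"]))
    report = {
        "rows_read": int(n_read),
        "rows_dropped": int(n_read - len(df)),
        "edges_kept": tmap.n_edges,
    }
    if tmap.n_edges == 0:
        warnings.warn(f"parsed target map from {path} is empty", stacklevel=2)
    return tmap, report


# ---------------------------------------------------------------------------
# Pairwise miRNA-target correlations
# ---------------------------------------------------------------------------

def correlate_pairs(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    target_map: TargetMap,
    mirna_list: Sequence[str],
) -> tuple[pd.DataFrame, dict]:
    """Pearson correlation of each (miRNA, predicted target) pair.

    Correlations are computed across the samples shared by the two
    expression matrices; p-values come from the exact t transform
    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom (two-sided).
    Predicted targets without mRNA expression are tallied in the skip
    report; zero-variance vectors yield a flagged record with undefined p.

    Returns (pair table, skip report). Pair-table columns: mirna_id,
    gene_id, r, p, n, sign, flagged.
    """
    shared = [s for s in mirna_expr.columns if s in set(mrna_expr.columns)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    n = len(shared)
    mi = mirna_expr[shared]
    mr = mrna_expr[shared]
    mr_values = mr.to_numpy(dtype=float)
    mr_centered = mr_values - mr_values.mean(axis=1, keepdims=True)
    mr_norm = np.sqrt((mr_centered**2).sum(axis=1))
    gene_pos = {g: i for i, g in enumerate(mr.index)}

    records = []
    skipped_genes: set[str] = set()
    n_skipped_edges = 0
    for mirna in mirna_list:
        if mirna not in mi.index:
            raise KeyError(f"miRNA {mirna!r} absent from the miRNA expression matrix")
        genes = sorted(target_map.targets.get(mirna, frozenset()))
        idx = []
        for g in genes:
            if g in gene_pos:
                idx.append(gene_pos[g])
            else:
                skipped_genes.add(g)
                n_skipped_edges += 1
        if not idx:
            continue
        x = mi.loc[mirna].to_numpy(dtype=float)
        xc = x - x.mean()
        xn = np.sqrt((xc**2).sum())
        sub_c = mr_centered[idx]
        sub_n = mr_norm[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (sub_c @ xc) / (sub_n * xn)
        flagged = (xn == 0) | (sub_n == 0)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p = np.where(np.isnan(t) & ~flagged, 0.0, p)  # |r| == 1 exactly
        for k, gi in enumerate(idx):
            records.append(
                (
                    mirna,
                    mr.index[gi],
                    float("nan") if flagged[k] else float(r[k]),
                    float("nan") if flagged[k] else float(p[k]),
                    n,
                    "negative" if (not flagged[k] and r[k] < 0) else "positive",
                    bool(flagged[k]),
                )
            )
    pairs = pd.DataFrame(
        records,
        columns=["mirna_id", "gene_id", "r", "p", "n", "sign", "flagged"],
    ).astype({"r": float, "p": float, "n": int, "flagged": bool})
    report = {
        "n_pairs": len(pairs),
        "n_flagged": int(pairs["flagged"].sum()) if len(pairs) else 0,
        "n_genes_without_expression": len(skipped_genes),
        "n_edges_skipped": n_skipped_edges,
    }
    return pairs, report


def bin_pvalues(pairs: pd.DataFrame, mode: str = "coarse") -> pd.DataFrame:
    """Histogram of pair-correlation p-values, split by correlation sign.

    ``coarse``: 20 half-open bins of width 0.05 over [0, 1] (last bin closed
    at 1). ``fine``: 20 bins of width 0.000125 over [0, 0.0025), zooming
    into the most significant coarse sub-bin. Flagged pairs (undefined p)
    are excluded.
    """
    if mode == "coarse":
        edges = np.linspace(0.0, 1.0, 21)
        closed_right = True
    elif mode == "fine":
        edges = np.linspace(0.0, 0.0025, 21)
        closed_right = False
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    usable = pairs[~pairs["flagged"] & pairs["p"].notna()]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        if last and closed_right:
            mask = (usable["p"] >= lo) & (usable["p"] <= hi)
        else:
            mask = (usable["p"] >= lo) & (usable["p"] < hi)
        sel = usable[mask]
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_positive": int((sel["sign"] == "positive").sum()),
                "n_negative": int((sel["sign"] == "negative").sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Combinatorial target counts and residual fold changes
# ---------------------------------------------------------------------------

def count_targets(
    target_map: TargetMap,
    mirna_list: Sequence[str],
    gene_universe: Sequence[str],
) -> pd.Series:
    """Independent target count: distinct miRNAs of ``mirna_list`` predicted
    to target each gene of the universe.

    Genes targeted by no list member get count 0 and stay in the table —
    they form the "0 times targeted" category. Binding-site multiplicity
    never matters; the map already holds one edge per (miRNA, gene) pair.
    """
    counts = pd.Series(0, index=pd.Index(gene_universe, name="gene_id"), dtype=int)
    members = set(mirna_list)
    for mirna in members:
        genes = target_map.targets.get(mirna, frozenset())
        hit = counts.index.intersection(genes)
        counts.loc[hit] += 1
    return counts


def build_count_table(
    target_map: TargetMap,
    de_list: Sequence[str],
    control_list: Sequence[str],
    mrna_fc: pd.Series,
) -> pd.DataFrame:
    """TargetCountTable over the genes carrying fold-change data: per gene,
    count_de, count_control and log2fc_mrna."""
    universe = list(mrna_fc.index)
    return pd.DataFrame(
        {
            "count_de": count_targets(target_map, de_list, universe),
            "count_control": count_targets(target_map, control_list, universe),
            "log2fc_mrna": mrna_fc,
        }
    )


def group_fold_change(
    counts: pd.DataFrame,
    count_col: str = "count_de",
) -> tuple[pd.DataFrame, dict]:
    """Per-count-category fold-change summary plus the count-FC correlation.

    For every populated count category: number of genes, mean fold change
    and its standard error (sd/sqrt(n), the "standard deviation of the
    mean"). The correlation tests (Pearson and Spearman) run on the
    per-gene count and fold-change vectors, not on the category means.
    """
    grouped = counts.groupby(count_col)["log2fc_mrna"]
    summary = pd.DataFrame(
        {
            "n_genes": grouped.size(),
            "mean_fc": grouped.mean(),
            "sd_fc": grouped.std(ddof=1).fillna(0.0),
        }
    )
    summary["sem_fc"] = summary["sd_fc"] / np.sqrt(summary["n_genes"])
    summary.index.name = "count"

    x = counts[count_col].to_numpy(dtype=float)
    y = counts["log2fc_mrna"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        corr = {"pearson_r": None, "pearson_p": None,
                "spearman_rho": None, "spearman_p": None,
                "flag": "constant input, correlation undefined"}
    else:
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        corr = {
            "pearson_r": float(pr.statistic),
            "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic),
            "spearman_p": float(sr.pvalue),
            "flag": None,
        }
    return summary, corr


def residual_fold_change(
    summary_de: pd.DataFrame,
    summary_control: pd.DataFrame,
) -> tuple[pd.DataFrame, list[int]]:
    """Per-category residual: mean FC of DE-list-targeted genes minus mean
    FC of control-list-targeted genes, over categories populated on both
    sides. Negative residuals indicate DE-list-specific repression.

    Returns (residual table, categories omitted from either side).
    """
    shared = summary_de.index.intersection(summary_control.index)
    if len(shared) == 0:
        raise ValueError("DE and control summaries share no count categories")
    omitted = sorted(
        set(summary_de.index).symmetric_difference(summary_control.index)
    )
    table = pd.DataFrame(
        {
            "residual": summary_de.loc[shared, "mean_fc"]
            - summary_control.loc[shared, "mean_fc"],
            "n_genes_de": summary_de.loc[shared, "n_genes"],
            "n_genes_control": summary_control.loc[shared, "n_genes"],
        }
    )
    table.index.name = "count"
    return table, [int(c) for c in omitted]


def compare_fc_ttest(
    counts: pd.DataFrame,
    min_hits: int = 4,
) -> dict:
    """Welch t-test of fold changes: heavily DE-targeted vs heavily
    control-targeted genes.

    Groups are genes with count_de >= ``min_hits`` and genes with
    count_control >= ``min_hits``; a gene targeted that often by both lists
    appears in both groups. Returns both group means, t and the two-sided p.
    """
    de_fc = counts.loc[counts["count_de"] >= min_hits, "log2fc_mrna"]
    ctrl_fc = counts.loc[counts["count_control"] >= min_hits, "log2fc_mrna"]
    if len(de_fc) < 2 or len(ctrl_fc) < 2:
        raise ValueError(
            f"need >= 2 genes per group; got {len(de_fc)} DE-targeted and "
            f"{len(ctrl_fc)} control-targeted at min_hits={min_hits}"
        )
    res = stats.ttest_ind(de_fc, ctrl_fc, equal_var=False)
    return {
        "mean_de": float(de_fc.mean()),
        "mean_control": float(ctrl_fc.mean()),
        "n_de": int(len(de_fc)),
        "n_control": int(len(ctrl_fc)),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "min_hits": min_hits,
    }


def map_overlap_correlation(counts: pd.DataFrame) -> dict:
    """Pearson r between the DE-list and control-list target counts.

    A high r says frequently DE-targeted genes are also frequently targeted
    by the control list — the overlap the residual analysis must overcome.
    """
    if len(counts) < 3:
        raise ValueError("need >= 3 genes for the overlap correlation")
    x = counts["count_de"].to_numpy(dtype=float)
    y = counts["count_control"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": None, "p": None, "flag": "zero-variance count vector"}
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "flag": None}
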