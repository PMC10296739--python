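"""Per-feature two-factor differential expression for the 2x2 (age x
exposure) design: Type III ANOVA, unweighted-cell-mean fold changes, Storey
q-values, and DE / control-list selection.

The design is a full factorial with interaction, fit per feature by least
squares under sum-to-zero coding; main-effect and interaction F statistics
come from model comparison (Type III sums of squares), the convention for
unbalanced factorials. Fold changes are contrasts of unweighted cell means,
so imbalance (e.g. a 6/6/5/6 design after dropping a failed array) does not
bias them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

AGE_LEVELS = ("5mo", "2yr")
EXPOSURE_LEVELS = ("control", "PAE")

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.901, 0.05), 2)


def validate_design(design: pd.DataFrame, min_per_cell: int = 2) -> pd.DataFrame:
    """Check a sample design table (columns ``age``, ``exposure``).

    Every cell of the 2x2 must hold at least ``min_per_cell`` samples;
    unbalanced designs are allowed.
    """
    for col, levels in (("age", AGE_LEVELS), ("exposure", EXPOSURE_LEVELS)):
        if col not in design.columns:
            raise ValueError(f"design table lacks column {col!r}")
        bad = set(design[col]) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} levels: {sorted(bad)} (expected {levels})")
    counts = design.groupby(["age", "exposure"], observed=True).size()
    if len(counts) < 4 or (counts < min_per_cell).any():
        raise ValueError(
            "every age x exposure cell needs >= "
            f"{min_per_cell} samples; got {counts.to_dict()}"
        )
    return design


@dataclass
class AnovaFit:
    """Per-feature two-factor ANOVA results, q-values and DE classes.

    ``table`` columns: log2fc_alcohol, log2fc_age, p_alcohol, p_age,
    p_interaction, then (once filled) q_alcohol, q_age, q_interaction and
    de_class in {'up', 'down', 'none'}.
    """

    table: pd.DataFrame
    zero_variance: list[str] = field(default_factory=list)


def fit_two_factor_anova(expr: pd.DataFrame, design: pd.DataFrame) -> AnovaFit:
    """Fit the full-factorial age x exposure model to every feature.

    Parameters
    ----------
    expr
        log2 expression, features x samples; columns must match the design.
    design
        Sample table with ``age`` and ``exposure`` columns, indexed by
        sample id; every 2x2 cell needs >= 2 samples so residual degrees of
        freedom are guaranteed.

    Returns
    -------
    AnovaFit with per-feature fold changes (PAE - control, 2yr - 5mo, as
    unweighted means of cell means) and Type III p-values for both main
    effects and the interaction. Features with (numerically) zero residual
    variance get the limiting p (0 when the effect sum of squares is
    positive, else 1) and are listed in ``zero_variance``.
    """
    design = validate_design(design)
    if list(expr.columns) != list(design.index):
        if set(expr.columns) != set(design.index):
            raise ValueError("expression samples do not match the design table")
        design = design.loc[expr.columns]
    y = expr.to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("fit_two_factor_anova: non-finite expression values")

    a = np.where(design["exposure"].to_numpy() == "PAE", 1.0, -1.0)
    b = np.where(design["age"].to_numpy() == "2yr", 1.0, -1.0)
    n = a.size
    full = np.column_stack([np.ones(n), a, b, a * b])

    def rss(X: np.ndarray) -> np.ndarray:
        # residual sum of squares of every feature under design matrix X
        q, _ = np.linalg.qr(X)
        resid = y - (y @ q) @ q.T
        return np.einsum("ij,ij->i", resid, resid)

    sse_full = rss(full)
    df_resid = n - full.shape[1]
    mse = sse_full / df_resid

    pvals = {}
    ss_effect = {}
    for name, drop in (("alcohol", 1), ("age", 2), ("interaction", 3)):
        reduced = np.delete(full, drop, axis=1)
        ss = rss(reduced) - sse_full
        ss_effect[name] = ss
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ss / mse
        pvals[name] = stats.f.sf(f, 1, df_resid)

    # unweighted cell means for fold changes
    cell_mean = {}
    for age in AGE_LEVELS:
        for expo in EXPOSURE_LEVELS:
            mask = (design["age"] == age).to_numpy() & (design["exposure"] == expo).to_numpy()
            cell_mean[(age, expo)] = y[:, mask].mean(axis=1)
    lfc_alcohol = 0.5 * (
        cell_mean[("5mo", "PAE")] + cell_mean[("2yr", "PAE")]
        - cell_mean[("5mo", "control")] - cell_mean[("2yr", "control")]
    )
    lfc_age = 0.5 * (
        cell_mean[("2yr", "control")] + cell_mean[("2yr", "PAE")]
        - cell_mean[("5mo", "control")] - cell_mean[("5mo", "PAE")]
    )

    table = pd.DataFrame(
        {
            "log2fc_alcohol": lfc_alcohol,
            "log2fc_age": lfc_age,
            "p_alcohol": pvals["alcohol"],
            "p_age": pvals["age"],
            "p_interaction": pvals["interaction"],
        },
        index=expr.index,
    )

    zero_var = mse <= 1e-12 * np.maximum(1.0, np.abs(y).max(axis=1))
    zero_ids: list[str] = []
    if zero_var.any():
        for name in ("alcohol", "age", "interaction"):
            col = f"p_{name}"
            lim = np.where(ss_effect[name][zero_var] > 1e-12, 0.0, 1.0)
            table.loc[zero_var, col] = lim
        zero_ids = list(table.index[zero_var])
    return AnovaFit(table=table, zero_variance=zero_ids)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 by the smoothing approach.

    Computes pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid,
    fits a cubic smoothing spline, and evaluates it at the largest lambda;
    estimates above 1 (or unusable fits) fall back to 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    grid = np.asarray(lambda_grid, dtype=float)
    raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if grid.size < 4 or np.allclose(raw, raw[0]):
        pi0 = float(raw[-1])
    else:
        try:
            spline = make_smoothing_spline(grid, raw)
            pi0 = float(spline(grid.max()))
        except Exception:  # degenerate grid; fall back to the last raw value
            pi0 = float(raw[-1])
    if not np.isfinite(pi0) or pi0 > 1.0:
        pi0 = 1.0
    return max(pi0, 1.0 / m)


def storey_qvalues(
    p: np.ndarray | pd.Series,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    pi0: float | None = None,
) -> np.ndarray | pd.Series:
    """Convert p-values to q-values (FDR scale) with an estimated pi0.

    q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j), clipped to 1.
    With ``pi0=1`` this reduces exactly to the Benjamini-Hochberg adjusted
    p-values. The mapping is order-preserving.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("storey_qvalues expects a non-empty 1-D p-value vector")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    if pi0 is None:
        pi0 = estimate_pi0(arr, lambda_grid)
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index)
    return q


def add_qvalues(fit: AnovaFit, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> AnovaFit:
    """Attach q_alcohol / q_age / q_interaction columns to an AnovaFit."""
    for factor in ("alcohol", "age", "interaction"):
        fit.table[f"q_{factor}"] = storey_qvalues(
            fit.table[f"p_{factor}"], lambda_grid=lambda_grid
        )
    return fit


# ---------------------------------------------------------------------------
# DE and control-list selection
# ---------------------------------------------------------------------------

def select_de(
    fit: AnovaFit,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    factor: str = "alcohol",
) -> tuple[list[str], list[str]]:
    """Split features into up/down DE lists for one factor.

    The cut is strict on both axes — p < ``p_thresh`` and log2 fold change
    strictly beyond ``lfc_thresh`` — and lists are sorted by ascending p.
    ``de_class`` is stamped onto the result table for the alcohol factor.
    """
    t = fit.table
    pcol, fcol = f"p_{factor}", f"log2fc_{factor}"
    sig = t[pcol] < p_thresh
    up = t[sig & (t[fcol] > lfc_thresh)].sort_values(pcol)
    down = t[sig & (t[fcol] < -lfc_thresh)].sort_values(pcol)
    if factor == "alcohol":
        t["de_class"] = "none"
        t.loc[up.index, "de_class"] = "up"
        t.loc[down.index, "de_class"] = "down"
    return list(up.index), list(down.index)


def select_control_list(
    fit: AnovaFit,
    k: int = 24,
    interaction_alpha: float = 0.05,
    factor: str = "alcohol",
) -> list[str]:
    """Pick the k non-DE features with p-values nearest 1 for ``factor``.

    Features showing a strong interaction effect (p_interaction below
    ``interaction_alpha``) are excluded first; the survivors are ranked by
    descending p for the factor, ties broken by feature id.
    """
    t = fit.table
    eligible = t[t["p_interaction"] >= interaction_alpha]
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} features pass the interaction screen; {k} requested"
        )
    # descending p, deterministic tie-break on id within equal p
    ranked = eligible.iloc[
        np.lexsort((eligible.index.to_numpy(), -eligible[f"p_{factor}"].to_numpy()))
    ]
    return list(ranked.index[:k])


def expected_null_count(n_tests: int, alpha: float) -> int:
    """Features expected below ``alpha`` were the factor truly null:
    floor(alpha * n_tests)."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return int(np.floor(alpha * n_tests))


def write_results(fit: AnovaFit, path) -> None:
    """Write the per-feature result table as tab-delimited text."""
    fit.table.rename_axis("feature_id").to_csv(path, sep="\t")


def summarize_counts(fit: AnovaFit, alpha: float = 0.05) -> dict:
    """Headline counts per factor: sub-alpha features and the null expectation."""
    out = {}
    m = len(fit.table)
    for factor in ("alcohol", "age", "interaction"):
        out[f"n_p_lt_alpha_{factor}"] = int((fit.table[f"p_{factor}"] < alpha).sum())
    out["n_features"] = m
    out["expected_under_null"] = expected_null_count(m, alpha)
    return out
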