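"""Probe-level preprocessing: detection calls, normalization, summarization,
and the species/uniqueness annotation funnel.

The processing chain mirrors the standard robust multi-array average (RMA)
convention for a PM-only miRNA array: optional background correction,
quantile normalization across arrays, log2 transform, then median-polish
summarization of each probe set. Detection ("present/absent") calls are a
rank test of a probe set's intensities against the array's background
probes, the MAS5-style contract adapted to a platform without mismatch
probes.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: miRBase species prefixes accepted by the annotation funnel: human, great
#: apes and gibbons, and Old World monkeys (incl. macaques and the vervet).
DEFAULT_ALLOWED_SPECIES = frozenset(
    {"hsa", "ptr", "ppa", "ggo", "ppy", "nle", "ssy", "mml", "mne", "sab", "pha"}
)

#: Default offset for the detection rank test (on the same scale as the
#: intensities after any transform the caller applies).
DEFAULT_DETECTION_TAU = 0.015


# ---------------------------------------------------------------------------
# Detection calls
# ---------------------------------------------------------------------------

def detection_pvalue(
    probe_values: Sequence[float],
    background_values: Sequence[float],
    tau: float = DEFAULT_DETECTION_TAU,
    probe_set_id: str | None = None,
) -> float:
    """One-sided rank-sum p-value that a probe set exceeds background.

    A Wilcoxon rank-sum (Mann-Whitney) test of the probe intensities against
    the background-probe intensities shifted up by ``tau``; small p means the
    probe set is detected ("present") on this array. Exact tail probabilities
    are used whenever SciPy can enumerate them (small samples, no ties).

    Parameters
    ----------
    probe_values
        Intensities of the probes in one probe set on one array (>= 4).
    background_values
        Background-probe intensities on the same array (>= 4).
    tau
        Small positive offset added to the background before ranking, so a
        probe set must exceed background by a margin to look present.
    probe_set_id
        Used only to name the probe set in error messages.
    """
    probe = np.asarray(probe_values, dtype=float)
    background = np.asarray(background_values, dtype=float)
    label = f" for probe set {probe_set_id!r}" if probe_set_id else ""
    if probe.size < 4:
        raise ValueError(
            f"detection_pvalue needs >= 4 probe values{label}, got {probe.size}"
        )
    if background.size < 4:
        raise ValueError(
            f"detection_pvalue needs >= 4 background values{label}, "
            f"got {background.size}"
        )
    res = stats.mannwhitneyu(
        probe, background + tau, alternative="greater", method="auto"
    )
    return float(res.pvalue)


def detection_pvalue_table(
    probe_table: pd.DataFrame,
    background: pd.DataFrame,
    tau: float = DEFAULT_DETECTION_TAU,
) -> pd.DataFrame:
    """Detection p-values for every (probe set, array) combination.

    ``probe_table`` is tab-format probe-level data: columns ``probe_set_id``,
    ``probe_index``, then one column per array. ``background`` holds the
    background probes with the same array columns.
    """
    sample_cols = [c for c in probe_table.columns if c not in ("probe_set_id", "probe_index")]
    missing = [c for c in sample_cols if c not in background.columns]
    if missing:
        raise ValueError(f"background table lacks array columns: {missing}")
    rows = {}
    for pset, grp in probe_table.groupby("probe_set_id", sort=True):
        rows[pset] = [
            detection_pvalue(grp[c].to_numpy(), background[c].to_numpy(), tau, pset)
            for c in sample_cols
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=sample_cols)


def filter_expressed(
    detection_p: pd.DataFrame,
    min_arrays: int = 6,
    alpha: float = 0.05,
) -> list[str]:
    """Feature ids detected (p < alpha) on at least ``min_arrays`` arrays.

    Input row order is preserved in the output. An empty table yields an
    empty list with a warning rather than an error.
    """
    if detection_p.shape[1] and min_arrays > detection_p.shape[1]:
        raise ValueError(
            f"min_arrays={min_arrays} exceeds the {detection_p.shape[1]} arrays present"
        )
    if detection_p.empty:
        warnings.warn("filter_expressed: empty detection table", stacklevel=2)
        return []
    n_detected = (detection_p < alpha).sum(axis=1)
    return list(detection_p.index[n_detected >= min_arrays])


# ---------------------------------------------------------------------------
# Normalization and summarization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every array (column) onto the mean empirical distribution.

    After normalization each column's sorted values equal the across-column
    mean of sorted values (the reference distribution). Tied values within a
    column receive the mean of the reference values at their rank positions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile_normalize needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile_normalize: missing values are not supported")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = reference
        # average the reference over tie groups
        ser = pd.Series(mapped)
        out[:, j] = ser.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish_summarize(
    probe_level: pd.DataFrame | np.ndarray,
    max_iter: int = 10,
    tol: float = 0.01,
) -> np.ndarray | pd.Series:
    """Summarize one probe set's log2 probe-by-array matrix by median polish.

    Fits the additive decomposition ``value[i, j] ~ overall + probe[i] +
    array[j]`` by alternating median sweeps over rows and columns, and
    returns the per-array expression ``overall + array_effect`` — the Tukey
    median-polish summarization step of RMA. Iteration stops when neither
    sweep moves any residual median by ``tol`` or more.
    """
    is_frame = isinstance(probe_level, pd.DataFrame)
    z = np.asarray(probe_level, dtype=float).copy()
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish_summarize expects a non-empty 2-D matrix")
    if not np.isfinite(z).all():
        raise ValueError("median_polish_summarize: non-finite input")
    overall = 0.0
    row_eff = np.zeros(z.shape[0])
    col_eff = np.zeros(z.shape[1])
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row_eff += rmed
        delta = np.median(col_eff)
        overall += delta
        col_eff -= delta

        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col_eff += cmed
        delta = np.median(row_eff)
        overall += delta
        row_eff -= delta
        if np.abs(rmed).max() < tol and np.abs(cmed).max() < tol:
            break
    expression = overall + col_eff
    if is_frame:
        return pd.Series(expression, index=probe_level.columns)
    return expression


def summarize_probe_sets(
    probe_table: pd.DataFrame,
    max_iter: int = 10,
    tol: float = 0.01,
) -> pd.DataFrame:
    """Median-polish every probe set of a log2 probe-level table into an
    expression matrix (features x arrays)."""
    sample_cols = [c for c in probe_table.columns if c not in ("probe_set_id", "probe_index")]
    rows = {
        pset: median_polish_summarize(grp[sample_cols], max_iter=max_iter, tol=tol)
        for pset, grp in probe_table.groupby("probe_set_id", sort=True)
    }
    return pd.DataFrame.from_dict(rows, orient="index")[sample_cols]


def rma_background_correct(matrix: pd.DataFrame) -> pd.DataFrame:
    """Convolution background adjustment (exponential signal + Gaussian noise).

    Models each observed intensity as S + N with S ~ Exp(alpha) and
    N ~ Normal(mu, sigma^2), and replaces it with E[S | observed]. The
    parameters are estimated per array from the intensity mode (kernel
    density peak), the spread of the sub-mode tail, and the mean excess
    above the mode. Optional; the summarization contract downstream does
    not depend on it.
    """
    values = matrix.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("rma_background_correct expects strictly positive intensities")
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        x = values[:, j]
        kde = stats.gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 512)
        mu = grid[np.argmax(kde(grid))]
        below = x[x < mu]
        sigma = np.sqrt(np.mean((below - mu) ** 2) * 2.0) if below.size else x.std()
        above = x[x > mu]
        alpha = 1.0 / max(np.mean(above - mu), 1e-9) if above.size else 1.0
        a = x - mu - sigma**2 * alpha
        b = sigma
        num = stats.norm.pdf(a / b) - stats.norm.pdf((x - a) / b)
        den = stats.norm.cdf(a / b) + stats.norm.cdf((x - a) / b) - 1.0
        out[:, j] = a + b * num / np.maximum(den, 1e-12)
    out = np.maximum(out, 1e-6)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Annotation funnel
# ---------------------------------------------------------------------------

def annotate_and_dedupe(
    retained_ids: Iterable[str],
    annotation: pd.DataFrame,
    allowed_species: frozenset[str] | set[str] = DEFAULT_ALLOWED_SPECIES,
) -> tuple[pd.DataFrame, list[dict]]:
    """Species-filter and sequence-deduplicate detected features.

    Applies the funnel: (1) drop features whose ``species_tag`` is outside
    ``allowed_species``; (2) group the survivors by identical mature sequence
    (U/T insensitive); (3) keep one representative per group, carrying the
    human miRBase name when a human record is in the group, else the
    lexicographically smallest name.

    Returns the representative table (feature_id, mirbase_name, sequence,
    n_probes, plus the representative's annotation columns) and the funnel
    report, a list of ``{"step": ..., "retained": ...}`` records.

    Every retained id must have an annotation row; missing ids raise.
    """
    retained = list(retained_ids)
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    missing = [i for i in retained if i not in ann.index]
    if missing:
        raise ValueError(f"annotation missing for ids: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    funnel = [{"step": "detected", "retained": len(retained)}]
    sub = ann.loc[retained].copy()
    sub = sub[sub["species_tag"].isin(allowed_species)]
    funnel.append({"step": "species_filter", "retained": len(sub)})

    sub["_seq"] = sub["sequence"].str.upper().str.replace("U", "T")
    reps = []
    for _, grp in sub.groupby("_seq", sort=True):
        human = grp[grp["species_tag"] == "hsa"]
        if len(human):
            pick = human.sort_values("mirbase_name").iloc[0]
        else:
            pick = grp.sort_values("mirbase_name").iloc[0]
        rec = pick.drop(labels="_seq").to_dict()
        rec["feature_id"] = pick.name
        rec["n_probes"] = len(grp)
        reps.append(rec)
    unique = pd.DataFrame(reps)
    if len(unique):
        unique = unique.sort_values("feature_id").reset_index(drop=True)
        cols = ["feature_id"] + [c for c in unique.columns if c != "feature_id"]
        unique = unique[cols]
    funnel.append({"step": "unique_sequence", "retained": len(unique)})
    return unique, funnel


# ---------------------------------------------------------------------------
# Array-level QC report
# ---------------------------------------------------------------------------

def array_qc_report(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-array screening statistics: mean, boxplot five-number summary and
    the array's coordinates on the first two principal components.

    Outlier arrays (e.g. one with a depressed mean expression level) are
    surfaced here for the analyst; exclusion is always a configuration
    decision, never automatic.
    """
    values = expr.to_numpy(dtype=float)
    q = np.percentile(values, [0, 25, 50, 75, 100], axis=0)
    centered = values - values.mean(axis=1, keepdims=True)
    # samples as observations: PCA of the sample-by-feature matrix
    u, s, vt = np.linalg.svd(centered.T - centered.T.mean(axis=0), full_matrices=False)
    pcs = u[:, :2] * s[:2]
    return pd.DataFrame(
        {
            "mean": values.mean(axis=0),
            "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
            "pc1": pcs[:, 0], "pc2": pcs[:, 1] if pcs.shape[1] > 1 else 0.0,
        },
        index=expr.columns,
    )
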