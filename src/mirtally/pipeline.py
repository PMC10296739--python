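"""End-to-end pipeline: preprocess -> differential expression -> miRNA-mRNA
integration (once per target map) -> co-expression, with every intermediate
table written to the output directory and a run log capturing versions,
thresholds, the filtering funnel and any stage notices.

Re-running with the same configuration reproduces byte-identical outputs;
nothing in the bundle depends on wall-clock state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from . import coexpr as cx
from . import diffexpr as dx
from . import integrate as ig
from . import preprocess as pp


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and mode flags for one pipeline run.

    Either ``expression`` (a pre-summarized log2 matrix; the
    skip-preprocess path) or ``probe_table``+``background`` (raw
    intensities for the detection/RMA chain) must be given. ``target_maps``
    entries are ``{"path": ..., "format": targetscan7|mirwalk3|generic2col,
    "tag": ...}``. A missing mRNA fold-change table downgrades the
    integration stage to a notice instead of an error.
    """

    design: str = ""
    expression: str | None = None
    probe_table: str | None = None
    background: str | None = None
    annotation: str | None = None
    mrna_fc: str | None = None
    mrna_expression: str | None = None
    target_maps: list[dict] = field(default_factory=list)

    detection_alpha: float = 0.05
    min_arrays: int = 6
    detection_tau: float = pp.DEFAULT_DETECTION_TAU
    background_correct: bool = False
    exclude_arrays: list[str] = field(default_factory=list)

    p_thresh: float = 0.05
    lfc_thresh: float = 1.0
    k_control: int = 24
    interaction_alpha: float = 0.05
    min_hits: int = 4
    lambda_grid: list[float] = field(
        default_factory=lambda: list(dx.DEFAULT_LAMBDA_GRID)
    )

    cluster_chrom: str | None = None
    cluster_window: tuple[int, int] | None = None

    seed: int = 0
    out_dir: str = "mirtally_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.cluster_window is not None:
            cfg.cluster_window = tuple(cfg.cluster_window)
        return cfg

    def validate(self) -> "PipelineConfig":
        if not self.design:
            raise ValueError("config needs a design table path")
        if self.expression is None and self.probe_table is None:
            raise ValueError("config needs either an expression matrix or probe-level data")
        for key in ("design", "expression", "probe_table", "background",
                    "annotation", "mrna_fc", "mrna_expression"):
            val = getattr(self, key)
            if val and not Path(val).exists():
                raise FileNotFoundError(f"{key} path does not exist: {val}")
        for entry in self.target_maps:
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(f"target map missing: {entry['path']}")
        if not 0 < self.p_thresh < 1 or not 0 < self.detection_alpha < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.lfc_thresh < 0 or self.min_hits < 0 or self.k_control <= 0:
            raise ValueError("lfc_thresh/min_hits/k_control out of range")
        return self


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write the report bundle to ``out_dir``.

    Returns a dict with the key objects (expression matrix, fit, lists,
    per-map statistics, cluster report) and the paths written. Any stage
    error aborts with the stage name; an ``INCOMPLETE`` marker is left in
    the output directory so partial bundles are recognizable.
    """
    config = config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    notices: list[str] = []
    log: dict = {
        "versions": {
            "mirtally": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config": {k: v for k, v in asdict(config).items()},
        "notices": notices,
    }
    result: dict = {"out_dir": str(out)}
    try:
        design = pd.read_csv(config.design, sep="\t", index_col=0)

        # ---- preprocess ------------------------------------------------
        stage = "preprocess"
        try:
            annotation = (
                pd.read_csv(config.annotation, sep="\t") if config.annotation else None
            )
            if config.probe_table is not None:
                probe = pd.read_csv(config.probe_table, sep="\t")
                background = pd.read_csv(config.background, sep="\t")
                sample_cols = [
                    c for c in probe.columns if c not in ("probe_set_id", "probe_index")
                ]
                detect_p = pp.detection_pvalue_table(
                    probe, background, tau=config.detection_tau
                )
                retained = pp.filter_expressed(
                    detect_p, min_arrays=config.min_arrays, alpha=config.detection_alpha
                )
                intens = probe[sample_cols]
                if config.background_correct:
                    intens = pp.rma_background_correct(intens)
                norm = pp.quantile_normalize(intens)
                log2_probe = pd.concat(
                    [probe[["probe_set_id", "probe_index"]], np.log2(norm)], axis=1
                )
                expr = pp.summarize_probe_sets(log2_probe)
                expr = expr.loc[[i for i in expr.index if i in set(retained)]]
                log["funnel"] = [
                    {"step": "probe_sets", "retained": int(probe["probe_set_id"].nunique())},
                    {"step": "detected_min_arrays", "retained": len(retained)},
                ]
            else:
                expr = pd.read_csv(config.expression, sep="\t", index_col=0)
                notices.append("preprocess: pre-summarized matrix supplied; "
                               "detection/normalization skipped")
            if annotation is not None:
                unique, funnel = pp.annotate_and_dedupe(list(expr.index), annotation)
                expr = expr.loc[unique["feature_id"]]
                log.setdefault("funnel", []).extend(funnel)
                unique.to_csv(out / "features.tsv", sep="\t", index=False)
            if config.exclude_arrays:
                keep = [c for c in expr.columns if c not in set(config.exclude_arrays)]
                notices.append(f"preprocess: excluded arrays {config.exclude_arrays}")
                expr = expr[keep]
                design = design.loc[keep]
            qc = pp.array_qc_report(expr)
            qc.rename_axis("sample_id").to_csv(out / "array_qc.tsv", sep="\t")
            expr.rename_axis("feature_id").to_csv(out / "expression_processed.tsv", sep="\t")
            result["expression"] = expr
        except (PipelineError,):
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        # ---- differential expression ------------------------------------
        stage = "diffexpr"
        try:
            design = design.loc[expr.columns]
            fit = dx.fit_two_factor_anova(expr, design)
            dx.add_qvalues(fit, lambda_grid=np.asarray(config.lambda_grid))
            de_up, de_down = dx.select_de(
                fit, p_thresh=config.p_thresh, lfc_thresh=config.lfc_thresh
            )
            control = dx.select_control_list(
                fit, k=config.k_control, interaction_alpha=config.interaction_alpha
            )
            dx.write_results(fit, out / "diffexpr.tsv")
            (out / "de_up.txt").write_text("\n".join(de_up) + "\n")
            (out / "de_down.txt").write_text("\n".join(de_down) + "\n")
            (out / "control_list.txt").write_text("\n".join(control) + "\n")
            stats = {"diffexpr": dx.summarize_counts(fit, alpha=config.p_thresh)}
            stats["diffexpr"]["n_de_up"] = len(de_up)
            stats["diffexpr"]["n_de_down"] = len(de_down)
            result.update(fit=fit, de_up=de_up, de_down=de_down, control_list=control)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        # ---- integration (per target map) -------------------------------
        stage = "integrate"
        try:
            if config.mrna_fc is None:
                notices.append("integrate: no mRNA fold-change table; stage skipped")
            elif not config.target_maps:
                notices.append("integrate: no target maps configured; stage skipped")
            else:
                mrna_fc = pd.read_csv(config.mrna_fc, sep="\t", index_col=0).iloc[:, 0]
                mrna_fc.index = mrna_fc.index.map(ig.canonical_gene)
                mrna_expr = None
                if config.mrna_expression:
                    mrna_expr = pd.read_csv(
                        config.mrna_expression, sep="\t", index_col=0
                    )
                    mrna_expr.index = mrna_expr.index.map(ig.canonical_gene)
                stats["integrate"] = {}
                for entry in config.target_maps:
                    tag = entry.get("tag") or entry["format"]
                    tmap, parse_report = ig.parse_target_map(
                        entry["path"], format=entry["format"]
                    )
                    tmap.algorithm = tag
                    counts = ig.build_count_table(tmap, de_up, control, mrna_fc)
                    counts.rename_axis("gene_id").to_csv(
                        out / f"counts_{tag}.tsv", sep="\t"
                    )
                    sum_de, corr_de = ig.group_fold_change(counts, "count_de")
                    sum_ct, corr_ct = ig.group_fold_change(counts, "count_control")
                    sum_de.to_csv(out / f"groups_de_{tag}.tsv", sep="\t")
                    sum_ct.to_csv(out / f"groups_control_{tag}.tsv", sep="\t")
                    residuals, omitted = ig.residual_fold_change(sum_de, sum_ct)
                    residuals.to_csv(out / f"residuals_{tag}.tsv", sep="\t")
                    try:
                        ttest = ig.compare_fc_ttest(counts, min_hits=config.min_hits)
                    except ValueError as exc:
                        # e.g. an empty DE list leaves no >= min_hits genes
                        ttest = None
                        notices.append(f"integrate[{tag}]: t-test skipped ({exc})")
                    overlap = ig.map_overlap_correlation(counts)
                    map_stats = {
                        "parse_report": parse_report,
                        "count_fc_correlation": corr_de,
                        "count_fc_correlation_control": corr_ct,
                        "residual_categories_omitted": omitted,
                        "n_negative_residuals": int((residuals["residual"] < 0).sum()),
                        "n_residual_categories": int(len(residuals)),
                        "ttest_min_hits": ttest,
                        "overlap_correlation": overlap,
                    }
                    if mrna_expr is not None:
                        pairs, skip = ig.correlate_pairs(expr, mrna_expr, tmap, de_up)
                        pairs.to_csv(out / f"pairs_{tag}.tsv", sep="\t", index=False)
                        ig.bin_pvalues(pairs, "coarse").to_csv(
                            out / f"hist_coarse_{tag}.tsv", sep="\t", index=False
                        )
                        ig.bin_pvalues(pairs, "fine").to_csv(
                            out / f"hist_fine_{tag}.tsv", sep="\t", index=False
                        )
                        map_stats["pair_report"] = skip
                        usable = pairs[~pairs["flagged"]]
                        map_stats["n_pairs_negative"] = int(
                            (usable["sign"] == "negative").sum()
                        )
                        map_stats["n_pairs_positive"] = int(
                            (usable["sign"] == "positive").sum()
                        )
                    else:
                        notices.append(
                            f"integrate[{tag}]: no mRNA expression matrix; "
                            "pair correlations skipped"
                        )
                    stats["integrate"][tag] = map_stats
                    result.setdefault("counts", {})[tag] = counts
                    result.setdefault("residuals", {})[tag] = residuals
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        # ---- co-expression ----------------------------------------------
        stage = "coexpr"
        try:
            if len(de_up) >= 2:
                corr = cx.correlation_matrix(expr, de_up)
                order = cx.pc_order(corr)
                corr.loc[order, order].rename_axis("feature_id").to_csv(
                    out / "de_corr_matrix.tsv", sep="\t"
                )
                (out / "pc_order.txt").write_text("\n".join(order) + "\n")
                result["pc_order"] = order
                if config.cluster_chrom and annotation is not None:
                    report = cx.cluster_stats(
                        expr.loc[de_up],
                        annotation,
                        config.cluster_chrom,
                        config.cluster_window,
                    )
                    _json_dump(report.to_dict(), out / "cluster_report.json")
                    stats["coexpr"] = {"cluster": report.to_dict()}
                    result["cluster_report"] = report
            else:
                notices.append("coexpr: fewer than 2 upregulated DE miRNAs; stage skipped")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        _json_dump(stats, out / "stats.json")
        _json_dump(log, out / "run_log.json")
        result["stats"] = stats
        marker.unlink()
        return result
    except PipelineError:
        raise
    except Exception as exc:  # input reading and other pre-stage errors
        raise PipelineError(f"pipeline setup failed: {exc}") from exc
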