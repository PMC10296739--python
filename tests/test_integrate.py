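"""Target-map parsing, pair correlations, the independent target-count
statistic and the residual fold-change analysis, with hand-worked and
closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from mirtally import (
    TargetMap,
    bin_pvalues,
    build_count_table,
    compare_fc_ttest,
    correlate_pairs,
    count_targets,
    group_fold_change,
    map_overlap_correlation,
    parse_target_map,
    residual_fold_change,
)


class TestParsing:
    def test_targetscan_duplicate_sites_become_one_edge(self, tmp_path):
        f = tmp_path / "ts.txt"
        f.write_text(
            "Gene Symbol\tRepresentative miRNA\tSite type\n"
            "Nfia\thsa-miR-1\t8mer\n"
            "NFIA\thsa-miR-1\t7mer-m8\n"
            "nfia \thsa-miR-1\t7mer-a1\n"
            "GRIN2B\thsa-miR-1\t8mer\n"
        )
        tmap, report = parse_target_map(f, format="targetscan7")
        assert tmap.targets == {"hsa-miR-1": frozenset({"NFIA", "GRIN2B"})}
        assert report["rows_read"] == 4
        assert report["edges_kept"] == 2

    def test_mirwalk_csv_dialect(self, tmp_path):
        f = tmp_path / "mw.csv"
        f.write_text(
            "mirnaid,refseqid,genesymbol,position\n"
            "hsa-miR-2,NM_1,bdnf,3utr\n"
            "hsa-miR-2,NM_2,BDNF,5utr\n"
            "hsa-miR-3,NM_3,FMR1,3utr\n"
        )
        tmap, _ = parse_target_map(f, format="mirwalk3")
        assert tmap.targets == {
            "hsa-miR-2": frozenset({"BDNF"}),
            "hsa-miR-3": frozenset({"FMR1"}),
        }

    def test_generic_two_column_hand_parse(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text(
            "mirna_id\tgene_id\n"
            "m1\tg1\nm1\tg2\nm2\tg1\nm2\tg3\nm1\tg1\n"
        )
        tmap, report = parse_target_map(f, format="generic2col")
        assert tmap.targets == {
            "m1": frozenset({"G1", "G2"}),
            "m2": frozenset({"G1", "G3"}),
        }
        assert report["edges_kept"] == 4

    def test_mirna_filter_restricts(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("m1\tg1\nm2\tg2\n")
        tmap, _ = parse_target_map(f, format="generic2col", mirna_filter=["m1"])
        assert set(tmap.targets) == {"m1"}

    def test_missing_column_named_in_error(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("Wrong\tColumns\nx\ty\n")
        with pytest.raises(ValueError, match="targetscan7"):
            parse_target_map(f, format="targetscan7")

    def test_unknown_format_rejected(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("m1\tg1\n")
        with pytest.raises(ValueError, match="unknown"):
            parse_target_map(f, format="mystery")

    def test_empty_file_with_header_warns(self, tmp_path):
        f = tmp_path / "e.csv"
        f.write_text("mirnaid,genesymbol\n")
        with pytest.warns(UserWarning):
            tmap, _ = parse_target_map(f, format="mirwalk3")
        assert tmap.n_edges == 0


def t_tail_oracle(t_obs, df):
    """Two-sided t tail by numerical integration of the density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    dens = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = quad(dens, abs(t_obs), np.inf)
    return 2 * tail


class TestCorrelatePairs:
    def make_exprs(self, x, genes):
        samples = [f"s{i}" for i in range(len(x))]
        mirna = pd.DataFrame([x], index=["m1"], columns=samples)
        mrna = pd.DataFrame(genes, index=samples).T
        return mirna, mrna

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        mirna, mrna = self.make_exprs(x, {"G1": 2 * x + 1})
        tmap = TargetMap("t", {"m1": frozenset({"G1"})})
        pairs, _ = correlate_pairs(mirna, mrna, tmap, ["m1"])
        row = pairs.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(0.0, abs=1e-12)
        assert row["sign"] == "positive"

    def test_negation_flips_sign_keeps_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        g = 2.0 * x + 0.3 * rng.normal(size=10)
        mirna, mrna = self.make_exprs(x, {"G1": g, "G2": -g})
        tmap = TargetMap("t", {"m1": frozenset({"G1", "G2"})})
        pairs, _ = correlate_pairs(mirna, mrna, tmap, ["m1"])
        pairs = pairs.set_index("gene_id")
        assert pairs.loc["G1", "r"] == pytest.approx(-pairs.loc["G2", "r"])
        assert pairs.loc["G1", "p"] == pytest.approx(pairs.loc["G2", "p"])
        assert pairs.loc["G2", "sign"] == "negative"

    def test_p_matches_numerically_integrated_t_tail(self):
        # construct a pair with r very near 0.632 at n = 10 and check the
        # p-value against direct integration of the t density with 8 df
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        g = rng.normal(size=10)
        mirna, mrna = self.make_exprs(x, {"G1": g})
        tmap = TargetMap("t", {"m1": frozenset({"G1"})})
        pairs, _ = correlate_pairs(mirna, mrna, tmap, ["m1"])
        r = pairs.iloc[0]["r"]
        t_obs = r * math.sqrt(8 / (1 - r * r))
        assert pairs.iloc[0]["p"] == pytest.approx(t_tail_oracle(t_obs, 8), rel=1e-6)
        # and the exact textbook point: r = 0.632, n = 10
        t632 = 0.632 * math.sqrt(8 / (1 - 0.632**2))
        assert 2 * stats.t.sf(t632, 8) == pytest.approx(t_tail_oracle(t632, 8), rel=1e-9)

    def test_too_few_shared_samples(self):
        mirna = pd.DataFrame([[1.0, 2.0]], index=["m1"], columns=["s1", "s2"])
        mrna = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["s1", "s2"])
        tmap = TargetMap("t", {"m1": frozenset({"G1"})})
        with pytest.raises(ValueError, match="shared"):
            correlate_pairs(mirna, mrna, tmap, ["m1"])

    def test_zero_variance_gene_flagged_and_skip_report(self):
        x = np.arange(5.0)
        mirna, mrna = self.make_exprs(x, {"G1": np.ones(5), "G2": x.copy()})
        tmap = TargetMap("t", {"m1": frozenset({"G1", "G2", "ABSENT"})})
        pairs, report = correlate_pairs(mirna, mrna, tmap, ["m1"])
        flagged = pairs.set_index("gene_id")["flagged"]
        assert bool(flagged["G1"]) and not bool(flagged["G2"])
        assert report["n_genes_without_expression"] == 1
        assert report["n_flagged"] == 1


class TestBinPvalues:
    def hand_pairs(self):
        return pd.DataFrame(
            {
                "p": [0.01, 0.05, 0.049, 0.12, 0.97, 1.0, 0.0],
                "sign": ["positive", "negative", "negative", "positive",
                         "positive", "negative", "negative"],
                "flagged": [False] * 7,
            }
        )

    def test_hand_tally_and_edge_rule(self):
        h = bin_pvalues(self.hand_pairs(), mode="coarse")
        first = h.iloc[0]   # [0, 0.05): p=0.01, 0.049, 0.0
        assert (first["n_positive"], first["n_negative"]) == (1, 2)
        second = h.iloc[1]  # [0.05, 0.10): the p = 0.05 pair lands here
        assert (second["n_positive"], second["n_negative"]) == (0, 1)
        last = h.iloc[-1]   # [0.95, 1.0] closed: 0.97 and 1.0
        assert (last["n_positive"], last["n_negative"]) == (1, 1)

    def test_conservation(self):
        h = bin_pvalues(self.hand_pairs(), mode="coarse")
        assert (h["n_positive"] + h["n_negative"]).sum() == 7

    def test_fine_mode_window(self):
        pairs = pd.DataFrame(
            {
                "p": [0.0, 0.0001, 0.0024, 0.0025, 0.5],
                "sign": ["negative"] * 5,
                "flagged": [False] * 5,
            }
        )
        h = bin_pvalues(pairs, mode="fine")
        assert len(h) == 20
        assert h["bin_hi"].iloc[-1] == pytest.approx(0.0025)
        # p = 0.0025 falls outside the half-open fine window
        assert (h["n_positive"] + h["n_negative"]).sum() == 3

    def test_null_shape_roughly_flat(self):
        rng = np.random.default_rng(2)
        pairs = pd.DataFrame(
            {
                "p": rng.uniform(size=4000),
                "sign": rng.choice(["positive", "negative"], size=4000),
                "flagged": [False] * 4000,
            }
        )
        h = bin_pvalues(pairs, mode="coarse")
        totals = h["n_positive"] + h["n_negative"]
        assert totals.min() > 140 and totals.max() < 260


class TestCounts:
    def toy_map(self):
        return TargetMap(
            "toy",
            {
                "m1": frozenset({"G1", "G2", "G3"}),
                "m2": frozenset({"G1", "G4"}),
                "m3": frozenset({"G1", "G2"}),
            },
        )

    def test_brute_force_oracle(self):
        universe = ["G1", "G2", "G3", "G4", "G5", "G6"]
        counts = count_targets(self.toy_map(), ["m1", "m2", "m3"], universe)
        tmap = self.toy_map()
        for g in universe:
            expected = sum(g in tmap.targets[m] for m in ("m1", "m2", "m3"))
            assert counts[g] == expected
        assert counts["G5"] == 0  # untargeted genes retained at zero

    def test_empty_list_all_zero(self):
        counts = count_targets(self.toy_map(), [], ["G1", "G2"])
        assert (counts == 0).all()

    def test_distinct_mirna_counting_not_sites(self, tmp_path):
        # one miRNA predicted at 4 sites still contributes a single count
        f = tmp_path / "sites.tsv"
        lines = ["m1\tG1"] * 4 + ["m2\tG1", "m3\tG1"]
        f.write_text("\n".join(lines) + "\n")
        tmap, _ = parse_target_map(f, format="generic2col")
        counts = count_targets(tmap, ["m1", "m2", "m3"], ["G1"])
        assert counts["G1"] == 3


class TestGroupFoldChange:
    def test_hand_averages(self):
        counts = pd.DataFrame(
            {
                "count_de": [0, 0, 1, 1, 1, 2, 2, 5],
                "count_control": [0] * 8,
                "log2fc_mrna": [0.1, -0.1, -0.2, -0.4, -0.3, -0.5, -0.7, -1.0],
            },
            index=[f"G{i}" for i in range(8)],
        )
        summary, corr = group_fold_change(counts)
        assert summary.loc[0, "mean_fc"] == pytest.approx(0.0)
        assert summary.loc[1, "mean_fc"] == pytest.approx(-0.3)
        assert summary.loc[2, "mean_fc"] == pytest.approx(-0.6)
        assert summary.loc[5, "n_genes"] == 1
        assert summary.loc[1, "sem_fc"] == pytest.approx(0.1 / np.sqrt(3))
        r, p = stats.pearsonr(counts["count_de"], counts["log2fc_mrna"])
        assert corr["pearson_r"] == pytest.approx(r)
        assert corr["pearson_p"] == pytest.approx(p)

    def test_constant_fold_changes_flagged(self):
        counts = pd.DataFrame(
            {"count_de": [0, 1, 2], "count_control": [0, 0, 0],
             "log2fc_mrna": [0.3, 0.3, 0.3]}
        )
        summary, corr = group_fold_change(counts)
        assert (summary["mean_fc"] == 0.3).all()
        assert corr["pearson_r"] is None and corr["flag"] is not None

    def test_planted_slope_recovered(self):
        from mirtally import SynthConfig, generate_paired_dataset

        cfg = SynthConfig(n_gene=5000, targets_per_mirna=600.0, seed=23)
        ds = generate_paired_dataset(cfg)
        counts = build_count_table(
            ds.maps["synthA"], ds.truth.de_up_ids, [], ds.mrna_fc
        )
        _, corr = group_fold_change(counts)
        assert corr["pearson_r"] < 0
        assert corr["pearson_p"] < 1e-3
        # per-gene slope of fc on the *true* hit count recovers -beta
        slope = np.polyfit(ds.truth.hit_count.to_numpy(dtype=float),
                           ds.mrna_fc.to_numpy(), 1)[0]
        assert slope == pytest.approx(-cfg.suppression_beta, abs=0.01)


class TestResiduals:
    def test_hand_subtraction_and_omission(self):
        de = pd.DataFrame({"n_genes": [10, 5], "mean_fc": [-0.5, -0.8]},
                          index=[0, 1])
        ct = pd.DataFrame({"n_genes": [9, 4, 2], "mean_fc": [-0.1, -0.2, -0.3]},
                          index=[0, 1, 2])
        table, omitted = residual_fold_change(de, ct)
        assert table.loc[0, "residual"] == pytest.approx(-0.4)
        assert table.loc[1, "residual"] == pytest.approx(-0.6)
        assert omitted == [2]

    def test_identical_maps_zero_residuals(self):
        counts = pd.DataFrame(
            {"count_de": [0, 1, 1, 2], "count_control": [0, 1, 1, 2],
             "log2fc_mrna": [0.1, -0.2, -0.4, -0.6]}
        )
        sde, _ = group_fold_change(counts, "count_de")
        sct, _ = group_fold_change(counts, "count_control")
        table, _ = residual_fold_change(sde, sct)
        assert np.allclose(table["residual"], 0.0)

    def test_disjoint_categories_error(self):
        de = pd.DataFrame({"n_genes": [1], "mean_fc": [0.0]}, index=[0])
        ct = pd.DataFrame({"n_genes": [1], "mean_fc": [0.0]}, index=[5])
        with pytest.raises(ValueError, match="categories"):
            residual_fold_change(de, ct)

    def test_planted_suppression_gives_negative_residuals(self, default_dataset):
        ds = default_dataset
        ctrl_pool = [m for m in ds.mirna_expr.index
                     if m not in set(ds.truth.de_up_ids + ds.truth.de_down_ids)]
        counts = build_count_table(
            ds.maps["synthA"], ds.truth.de_up_ids, ctrl_pool[:24], ds.mrna_fc
        )
        sde, _ = group_fold_change(counts, "count_de")
        sct, _ = group_fold_change(counts, "count_control")
        table, _ = residual_fold_change(sde, sct)
        frac_neg = (table.loc[table.index >= 1, "residual"] < 0).mean()
        assert frac_neg > 0.5


class TestWelch:
    def test_identical_groups(self):
        counts = pd.DataFrame(
            {"count_de": [4, 5, 6], "count_control": [4, 5, 6],
             "log2fc_mrna": [-0.1, -0.2, -0.3]}
        )
        out = compare_fc_ttest(counts)
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_closed_form_welch(self):
        counts = pd.DataFrame(
            {
                "count_de": [4, 4, 4, 0, 0, 0],
                "count_control": [0, 0, 0, 4, 4, 4],
                "log2fc_mrna": [-1.0, -2.0, -3.0, 1.0, 2.0, 3.0],
            }
        )
        out = compare_fc_ttest(counts)
        # closed form: means -2 and 2, s1^2 = s2^2 = 1, n = 3
        t = (-2.0 - 2.0) / math.sqrt(1 / 3 + 1 / 3)
        df = (1 / 3 + 1 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (1 / 3) ** 2 / 2)
        assert out["t"] == pytest.approx(t)
        assert out["p"] == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-9)
        assert out["mean_de"] == pytest.approx(-2.0)
        assert out["mean_control"] == pytest.approx(2.0)

    def test_planted_direction_significant(self, default_dataset):
        ds = default_dataset
        ctrl_pool = [m for m in ds.mirna_expr.index
                     if m not in set(ds.truth.de_up_ids + ds.truth.de_down_ids)]
        counts = build_count_table(
            ds.maps["synthA"], ds.truth.de_up_ids, ctrl_pool[:24], ds.mrna_fc
        )
        out = compare_fc_ttest(counts)
        assert out["mean_de"] < out["mean_control"]
        assert out["p"] < 0.01

    def test_small_group_rejected(self):
        counts = pd.DataFrame(
            {"count_de": [4, 0], "count_control": [0, 4],
             "log2fc_mrna": [0.0, 0.0]}
        )
        with pytest.raises(ValueError, match="genes per group"):
            compare_fc_ttest(counts)


class TestOverlapCorrelation:
    def test_identity(self):
        counts = pd.DataFrame(
            {"count_de": [0, 1, 3], "count_control": [0, 1, 3],
             "log2fc_mrna": [0.0] * 3}
        )
        assert map_overlap_correlation(counts)["r"] == pytest.approx(1.0)

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            {"count_de": rng.poisson(3, 4000),
             "count_control": rng.poisson(3, 4000),
             "log2fc_mrna": np.zeros(4000)}
        )
        assert abs(map_overlap_correlation(counts)["r"]) < 0.05

    def test_zero_variance_flagged(self):
        counts = pd.DataFrame(
            {"count_de": [1, 1, 1], "count_control": [0, 1, 2],
             "log2fc_mrna": [0.0] * 3}
        )
        out = map_overlap_correlation(counts)
        assert out["r"] is None and out["flag"] is not None

    def test_overlap_band_across_seeds(self):
        """With map_overlap = 0.7 the DE-vs-control count correlation falls
        in a narrow band (empirical over seeded replicates)."""
        from mirtally import SynthConfig, generate_paired_dataset

        rs = []
        for seed in (31, 32, 33):
            cfg = SynthConfig(n_mirna=120, n_gene=4000, targets_per_mirna=500.0,
                              seed=seed)
            ds = generate_paired_dataset(cfg)
            ctrl_pool = [m for m in ds.mirna_expr.index
                         if m not in set(ds.truth.de_up_ids + ds.truth.de_down_ids)]
            counts = build_count_table(
                ds.maps["synthA"], ds.truth.de_up_ids, ctrl_pool[:24], ds.mrna_fc
            )
            rs.append(map_overlap_correlation(counts)["r"])
        assert 0.55 < np.mean(rs) < 0.85
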