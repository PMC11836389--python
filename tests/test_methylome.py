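"""oxBS beta subtraction, DMP calling, annotation, expression correlation."""

import numpy as np
import pandas as pd
import pytest

from notet import (
    annotate_sites,
    call_dmps,
    compute_betas,
    methylation_expression_correlation,
    summarize_by_annotation,
)
from notet.errors import InsufficientDataError, InvalidParameterError


def _counts(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "condition", "replicate",
                 "assay", "meth", "total"],
    )


class TestComputeBetas:
    def test_subtraction_arithmetic(self):
        counts = _counts([
            ("chr1", 10, "+", "c", 1, "BS", 30, 60),
            ("chr1", 10, "+", "c", 1, "oxBS", 15, 50),
        ])
        b = compute_betas(counts).iloc[0]
        assert b.beta_bs == pytest.approx(0.5)
        assert b.beta_5mc == pytest.approx(0.3)
        assert b.beta_5hmc == pytest.approx(0.2)
        assert not b.clipped and not b.masked

    def test_negative_5hmc_clipped_and_flagged(self):
        counts = _counts([
            ("chr1", 10, "+", "c", 1, "BS", 10, 50),
            ("chr1", 10, "+", "c", 1, "oxBS", 20, 50),
        ])
        b = compute_betas(counts).iloc[0]
        assert b.beta_5hmc == 0.0
        assert b.clipped

    def test_low_coverage_masked(self):
        counts = _counts([
            ("chr1", 10, "+", "c", 1, "BS", 2, 5),
            ("chr1", 10, "+", "c", 1, "oxBS", 20, 50),
        ])
        b = compute_betas(counts, min_coverage=10).iloc[0]
        assert b.masked
        assert np.isnan(b.beta_5mc)

    def test_pooling_commutes_with_beta_for_equal_totals(self):
        # beta of pooled counts == mean of per-replicate betas when totals match
        counts = _counts([
            ("chr1", 10, "+", "c", r, assay, m, 50)
            for r, m_bs, m_ox in ((1, 20, 10), (2, 30, 20))
            for assay, m in (("BS", m_bs), ("oxBS", m_ox))
        ])
        betas = compute_betas(counts)
        pooled = counts.groupby("assay")[["meth", "total"]].sum()
        beta_pooled = pooled.loc["oxBS", "meth"] / pooled.loc["oxBS", "total"]
        assert betas["beta_5mc"].mean() == pytest.approx(beta_pooled)


class TestCallDmps:
    def test_welch_hand_example_is_hyper(self, tiny_counts):
        # control betas (0.20, 0.22) vs treated (0.50, 0.52): delta 0.30,
        # Welch t = 21.2 on ~2 df, p ~ 0.002
        out = call_dmps(tiny_counts, "control", "treated", mark="5mC",
                        test="welch")
        row = out.iloc[0]
        assert row.delta_beta == pytest.approx(0.30, abs=1e-9)
        assert row.p_value < 0.05
        assert row.call == "hyper"

    def test_small_delta_never_called(self):
        rows = []
        for cond, betas in (("control", [0.40, 0.42]), ("treated", [0.44, 0.46])):
            for rep, b in enumerate(betas, 1):
                rows.append(("chr1", 5, ".", cond, rep, "BS", int(b * 200), 200))
                rows.append(("chr1", 5, ".", cond, rep, "oxBS", int(b * 200), 200))
        out = call_dmps(_counts(rows), "control", "treated", mark="5mC",
                        test="welch")
        assert abs(out.iloc[0].delta_beta) < 0.1
        assert out.iloc[0].call == "none"

    def test_identical_groups_give_zero_delta_and_no_call(self, tiny_counts):
        out = call_dmps(tiny_counts, "control", "control", mark="5mC",
                        test="welch")
        assert out.iloc[0].delta_beta == 0.0
        assert out.iloc[0].call == "none"

    def test_pooled_test_agrees_on_strong_effect(self, tiny_counts):
        out = call_dmps(tiny_counts, "control", "treated", mark="5mC")
        assert out.iloc[0].call == "hyper"

    def test_no_overlap_returns_empty_with_warning(self, tiny_counts):
        with pytest.warns(UserWarning):
            out = call_dmps(tiny_counts, "a", "b", mark="5mC")
        assert out.empty

    def test_unknown_mark_rejected(self, tiny_counts):
        with pytest.raises(InvalidParameterError):
            call_dmps(tiny_counts, "control", "treated", mark="6mA")


class TestAnnotate:
    islands = pd.DataFrame(
        [("chr1", 1000, 2000, "island")],
        columns=["chrom", "start", "end", "label"],
    )
    features = pd.DataFrame(
        [("chr1", 1500, 1600, "promoter"), ("chr1", 1500, 1600, "exon"),
         ("chr1", 7000, 7100, "enhancer")],
        columns=["chrom", "start", "end", "label"],
    )

    def _annotate(self, positions, chrom="chr1"):
        sites = pd.DataFrame({"chrom": chrom, "pos": positions})
        return annotate_sites(sites, self.islands, self.features)

    @pytest.mark.parametrize("pos,cls", [
        (1500, "island"),
        (2500, "shore"),      # 501 bp from island edge
        (4999, "shelf"),      # 3 kb from island edge
        (50_000, "open_sea"),
    ])
    def test_cpg_class_by_distance(self, pos, cls):
        assert self._annotate([pos]).iloc[0].cpg_class == cls

    def test_distance_band_edges(self):
        # end-exclusive island, shore out to 2 kb, shelf to 4 kb
        out = self._annotate([1999, 2000, 3999, 4000, 5999, 6000])
        assert list(out.cpg_class) == [
            "island", "shore", "shore", "shelf", "shelf", "open_sea"]

    def test_feature_precedence_promoter_over_exon(self):
        assert self._annotate([1550]).iloc[0].feature == "promoter"

    def test_no_overlap_is_intergenic_open_sea(self):
        row = self._annotate([50_000]).iloc[0]
        assert row.cpg_class == "open_sea" and row.feature == "intergenic"

    def test_enhancer_overlap_flagged(self):
        row = self._annotate([7050]).iloc[0]
        assert row.feature == "enhancer" and row.in_enhancer

    def test_unknown_chromosome_flagged_unannotated(self):
        row = self._annotate([1500], chrom="chrUn").iloc[0]
        assert not row.annotated

    def test_every_site_gets_exactly_one_class(self, null_methylome):
        ann = annotate_sites(null_methylome.truth[["chrom", "pos"]],
                             null_methylome.islands, null_methylome.features)
        assert ann.cpg_class.isin(
            ["island", "shore", "shelf", "open_sea"]).all()


class TestSummarize:
    def test_hand_counted_fractions(self):
        dmps = pd.DataFrame({
            "call": ["hyper"] * 6 + ["none"] * 4,
            "cpg_class": ["open_sea"] * 3 + ["island", "shore", "shelf"]
            + ["open_sea"] * 4,
            "feature": ["intron"] * 10,
        })
        summ = summarize_by_annotation(dmps)
        row = summ[(summ.category_type == "cpg_class")
                   & (summ.category == "open_sea")].iloc[0]
        assert row.n_hyper == 3
        assert row.fraction == pytest.approx(0.5)

    def test_no_calls_gives_zero_table(self):
        dmps = pd.DataFrame({"call": ["none"], "cpg_class": ["open_sea"],
                             "feature": ["intron"]})
        summ = summarize_by_annotation(dmps)
        assert (summ.n_hyper == 0).all() and (summ.fraction == 0).all()

    def test_cpg_class_fractions_partition_calls(self, planted_methylome):
        dmps = call_dmps(planted_methylome.counts, "control", "treated")
        dmps = annotate_sites(dmps, planted_methylome.islands,
                              planted_methylome.features)
        summ = summarize_by_annotation(dmps)
        cpg = summ[summ.category_type == "cpg_class"]
        if dmps.call.isin(["hyper", "hypo"]).any():
            assert cpg.fraction.sum() == pytest.approx(1.0)


class TestExpressionCorrelation:
    def test_exact_monotone_map_gives_minus_one(self):
        betas = {f"g{i}": b for i, b in enumerate(np.linspace(0.05, 0.95, 20))}
        expr = {g: np.exp(-b) for g, b in betas.items()}
        res = methylation_expression_correlation(betas, expr)
        assert res.rho == pytest.approx(-1.0)

    def test_permuted_pairing_is_null(self):
        rng = np.random.default_rng(3)
        betas = pd.Series(rng.uniform(0, 1, 200),
                          index=[f"g{i}" for i in range(200)])
        expr = pd.Series(rng.permutation(np.exp(-betas.values)),
                         index=betas.index)
        res = methylation_expression_correlation(betas, expr)
        assert abs(res.rho) < 0.2
        assert res.p_value > 0.05

    def test_too_few_shared_genes_rejected(self):
        betas = {f"g{i}": 0.5 for i in range(5)}
        with pytest.raises(InsufficientDataError):
            methylation_expression_correlation(betas, betas)
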