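"""Spearman machinery, DMF-DEG attribution geometry, panels and the MFI
fold-change formula."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conmeth.annotation import GeneRecord, GeneTable
from conmeth.integration import (
    FlowMeasurement,
    correlate_genes,
    integrate_dmf_deg,
    mfi_log2fc,
    panel_matrix,
    read_enhancers,
    regulator_correlogram,
    spearman,
)

from oracles import brute_force_spearman


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, x[::-1]).rho == pytest.approx(-1.0)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            spearman([1.0, 2.0], [2.0, 1.0])

    def test_matches_brute_force_with_ties(self, rng):
        """rho equals rank-then-Pearson with average ties on small fixtures."""
        for _ in range(200):
            n = int(rng.integers(3, 9))
            x = list(rng.integers(0, 4, size=n).astype(float))  # heavy ties
            y = list(rng.integers(0, 4, size=n).astype(float))
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            got = spearman(x, y).rho
            assert got == pytest.approx(brute_force_spearman(x, y), abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        # perfect monotone at n=5: only identity and reversal reach |rho|=1
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = spearman(x, [2.0, 4.0, 6.0, 8.0, 10.0])
        assert res.p == pytest.approx(2 / 120)

    def test_null_rho_spread_at_n12(self, rng):
        """With no planted correlation at n=12, |rho| rarely exceeds 0.58."""
        hits = 0
        for _ in range(200):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            if abs(spearman(x, y).rho) < 0.58:
                hits += 1
        assert hits >= 0.95 * 200


class TestCorrelogram:
    def test_symmetry_and_unit_diagonal(self, rng):
        expr = pd.DataFrame(
            rng.random((5, 12)),
            index=["DNMT3A", "UHRF2", "TET1", "CD274", "other"],
            columns=[f"s{i}" for i in range(12)],
        )
        meth = pd.Series(rng.random(12), index=expr.columns)
        cg = regulator_correlogram(expr, ["DNMT3A", "UHRF2", "TET1"], "CD274", meth)
        np.testing.assert_allclose(cg.rho.to_numpy(), cg.rho.to_numpy().T)
        np.testing.assert_allclose(np.diag(cg.rho.to_numpy()), 1.0)
        assert "global_methylation" in cg.rho.index

    def test_missing_regulator_warns_and_drops(self, rng):
        expr = pd.DataFrame(
            rng.random((2, 12)),
            index=["DNMT3A", "CD274"],
            columns=[f"s{i}" for i in range(12)],
        )
        with pytest.warns(UserWarning, match="UHRF2"):
            cg = regulator_correlogram(expr, ["DNMT3A", "UHRF2"], "CD274", None)
        assert "UHRF2" not in cg.rho.index

    def test_anticorrelated_planted_pair(self, rng):
        z = rng.normal(size=12)
        expr = pd.DataFrame(
            [5 + z + 0.1 * rng.normal(size=12), 5 - z + 0.1 * rng.normal(size=12)],
            index=["DNMT3A", "UHRF2"],
            columns=[f"s{i}" for i in range(12)],
        )
        cg = regulator_correlogram(expr, ["DNMT3A", "UHRF2"], None, None)
        assert cg.rho.loc["DNMT3A", "UHRF2"] < -0.5


class TestCorrelateGenes:
    def test_anchor_excluded_and_signs(self, rng):
        meth = pd.Series(np.linspace(0.4, 0.7, 12), index=[f"s{i}" for i in range(12)])
        anchor = -meth.to_numpy() + 0.01 * rng.normal(size=12)
        expr = pd.DataFrame(
            {"CD274": anchor, "tracker": meth.to_numpy()}, index=meth.index
        ).T
        out = correlate_genes(expr, "CD274", meth)
        assert "CD274" not in out.index
        assert out.loc["tracker", "rho_methylome"] == pytest.approx(1.0)
        assert out.loc["tracker", "rho_anchor"] < -0.9

    def test_too_few_samples(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["CD274"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="common samples"):
            correlate_genes(expr, "CD274", pd.Series([0.5, 0.6], index=["s1", "s2"]))


def make_genes():
    return GeneTable(
        [
            # + strand: promoter [5000, 11000), body [11000, 20000)
            GeneRecord("gX", "chr1", "+", 10_000, 20_000, (10_000,), (20_000,)),
            # - strand: TSS at 40000, promoter [39000, 45000), body [30000, 39000)
            GeneRecord("gY", "chr1", "-", 30_000, 40_000, (30_000,), (40_000,)),
        ]
    )


def dmf_frame(rows):
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "diff", "direction", "is_dmf"]
    )
    df.index = [f"{r[0]}:{r[1]}-{r[2]}" for r in rows]
    return df


def deg_frame(entries):
    return pd.DataFrame(
        {
            "lfc": [e[1] for e in entries],
            "direction": [e[2] for e in entries],
        },
        index=[e[0] for e in entries],
    )


class TestIntegrate:
    def test_body_hypo_down_concordance(self):
        dmfs = dmf_frame([("chr1", 15_000, 15_100, -0.4, "hypo", True)])
        degs = deg_frame([("gX", -3.0, "down")])
        rec, conc = integrate_dmf_deg(dmfs, degs, make_genes())
        assert len(rec) == 1
        assert rec.iloc[0]["context"] == "gene_body"
        assert rec.iloc[0]["concordance"] == "body-hypo/down"
        assert conc.iloc[0]["n"] == 1

    def test_deg_without_dmf_absent(self):
        dmfs = dmf_frame([("chr1", 25_000, 25_100, -0.4, "hypo", True)])
        degs = deg_frame([("gX", -3.0, "down")])
        rec, _ = integrate_dmf_deg(dmfs, degs, make_genes())
        assert len(rec) == 0

    def test_shared_dmf_attributed_to_both_genes(self):
        # [39500, 39600) lies in gY's promoter; with gX's promoter shifted it
        # is cleaner to use a fragment in gX promoter AND gY body overlap zone
        dmfs = dmf_frame([("chr1", 38_000, 39_200, -0.4, "hypo", True)])
        degs = deg_frame([("gY", 2.5, "up")])
        rec, _ = integrate_dmf_deg(dmfs, degs, make_genes())
        # fragment spans gY body [30000,39000) and gY promoter [39000,45000)
        contexts = set(rec["context"])
        assert contexts == {"gene_body", "promoter"}

    def test_promoter_and_body_of_different_genes(self):
        genes = GeneTable(
            [
                GeneRecord("gA", "chr1", "+", 10_000, 20_000, (10_000,), (20_000,)),
                # gB promoter [15000, 21000) overlaps gA body
                GeneRecord("gB", "chr1", "+", 20_000, 30_000, (20_000,), (30_000,)),
            ]
        )
        dmfs = dmf_frame([("chr1", 16_000, 16_100, 0.3, "hyper", True)])
        degs = deg_frame([("gA", -2.5, "down"), ("gB", 3.0, "up")])
        rec, _ = integrate_dmf_deg(dmfs, degs, genes)
        by_gene = rec.set_index("gene")["context"].to_dict()
        assert by_gene == {"gA": "gene_body", "gB": "promoter"}

    def test_multi_dmf_flag(self):
        dmfs = dmf_frame(
            [
                ("chr1", 12_000, 12_100, -0.4, "hypo", True),
                ("chr1", 18_000, 18_100, -0.5, "hypo", True),
            ]
        )
        degs = deg_frame([("gX", -3.0, "down")])
        rec, _ = integrate_dmf_deg(dmfs, degs, make_genes())
        assert rec["multi_dmf"].all()
        assert len(rec) == 2

    def test_enhancer_attribution(self, tmp_path):
        bed = tmp_path / "enh.bed"
        bed.write_text("chr1\t50000\t51000\tgX\n")
        enhancers = read_enhancers(bed)
        dmfs = dmf_frame([("chr1", 50_400, 50_500, -0.6, "hypo", True)])
        degs = deg_frame([("gX", 4.0, "up")])
        rec, _ = integrate_dmf_deg(dmfs, degs, make_genes(), enhancers)
        assert rec.iloc[0]["context"] == "enhancer"
        assert rec.iloc[0]["concordance"] == "enhancer-hypo/up"

    def test_enhancer_without_link_rejected(self, tmp_path):
        bed = tmp_path / "enh.bed"
        bed.write_text("chr1\t50000\t51000\n")
        with pytest.raises(ValueError, match="gene link"):
            read_enhancers(bed)

    def test_overlaps_verified_by_interval_oracle(self, rng):
        """Every emitted record corresponds to a genuine interval overlap."""
        genes = make_genes()
        rows = []
        for i in range(60):
            s = int(rng.integers(0, 60_000))
            rows.append(("chr1", s, s + 120, -0.3, "hypo", True))
        dmfs = dmf_frame(rows)
        dmfs = dmfs[~dmfs.index.duplicated()]
        degs = deg_frame([("gX", -3.0, "down"), ("gY", 2.0, "up")])
        rec, _ = integrate_dmf_deg(dmfs, degs, genes)
        windows = {
            ("gX", "promoter"): (5_000, 11_000),
            ("gX", "gene_body"): (11_000, 20_000),
            ("gY", "promoter"): (39_000, 45_000),
            ("gY", "gene_body"): (30_000, 39_000),
        }
        emitted = {
            (r.gene, r.context, r.fragment) for r in rec.itertuples(index=False)
        }
        for frag in dmfs.index:
            s, e = dmfs.loc[frag, "start"], dmfs.loc[frag, "end"]
            for (gene_id, context), (lo, hi) in windows.items():
                expected = max(lo, s) < min(hi, e)
                assert ((gene_id, context, frag) in emitted) == expected


class TestPanels:
    def test_missing_genes_reported(self, rng):
        expr = pd.DataFrame(
            rng.random((2, 6)) * 10, index=["IFI44", "OASL"],
            columns=[f"s{i}" for i in range(6)],
        )
        scaled, missing = panel_matrix(expr)
        assert set(scaled.data.index) == {"IFI44", "OASL"}
        assert "IRF7" in missing

    def test_empty_intersection_rejected(self, rng):
        expr = pd.DataFrame(rng.random((1, 4)), index=["g"], columns=list("abcd"))
        with pytest.raises(ValueError, match="panel"):
            panel_matrix(expr, panel=["IFI44"])

    def test_constant_panel_gene_zscore_flag(self):
        expr = pd.DataFrame(
            [[3.0] * 4], index=["IFI44"], columns=list("abcd")
        )
        scaled, _ = panel_matrix(expr, panel=["IFI44"], mode="zscore")
        assert scaled.zero_variance_rows == ["IFI44"]


class TestMFI:
    @pytest.mark.parametrize(
        "m, expected",
        [
            ((200, 10, 100, 5), 1.0),
            ((100, 5, 100, 5), 0.0),
            ((390, 10, 100, 5), 2.0),
        ],
    )
    def test_formula(self, m, expected):
        assert mfi_log2fc(FlowMeasurement(*m)) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_difference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mfi_log2fc(FlowMeasurement(10, 20, 100, 5))
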