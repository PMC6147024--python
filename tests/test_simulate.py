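"""Generator properties: determinism, clipping, noise-model limits and
truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from conmeth.diffexpr import call_degs
from conmeth.rrbs import mspi_digest, quantify_fragments
from conmeth.simulate import (
    SimConfig,
    make_expression,
    make_genome,
    make_methylome,
    sample_counts,
    simulate_bundle,
    synthetic_fragment_set,
    write_bundle,
)

SMALL = dict(n_chrom=1, chrom_length=60_000, n_genes=50, n_deg=5)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(chrom_length=5_000), "chrom_length"),
            (dict(dispersion=0.0), "dispersion"),
            (dict(dispersion=1.0), "dispersion"),
            (dict(coupling_rho=1.5), "coupling_rho"),
            (dict(n_deg=10, n_genes=5), "n_deg"),
            (dict(repeat_density={"LINE:L1": 0.95}), "repeat_density"),
            (dict(baseline_meth={"promoter": 1.2}), "baseline_meth"),
            (dict(coverage_mean=0.5), "coverage_mean"),
        ],
    )
    def test_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            SimConfig(**kwargs).validate()


class TestGenome:
    def test_deterministic_outputs(self, tmp_path):
        c = SimConfig(seed=5, **SMALL)
        b1 = simulate_bundle(c)
        b2 = simulate_bundle(SimConfig(seed=5, **SMALL))
        assert dict(b1.genome) == dict(b2.genome)
        pd.testing.assert_frame_equal(b1.calls.frame, b2.calls.frame)
        pd.testing.assert_frame_equal(b1.expression, b2.expression)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_bundle(b1, d1)
        write_bundle(b2, d2)
        for rel in ("genome.fa", "repeats.bed", "expression.tsv"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_zero_repeat_density_empty_annotation(self):
        _, _, repeats = make_genome(SimConfig(repeat_density={}, **SMALL))
        assert len(repeats) == 0

    def test_all_element_classes_reachable(self, default_bundle):
        """Digestion of the default genome hits every element class."""
        classes = set(default_bundle.classification["element_class"])
        assert classes == {"promoter", "exon", "intron", "intergenic"}
        fams = {
            f
            for cell in default_bundle.classification["repeat_families"]
            for f in str(cell).split(",")
            if f
        }
        assert len(fams) >= 5


class TestMethylome:
    def test_null_effect_groups_identical(self):
        cfg = SimConfig(
            baseline_meth={"x": 0.5}, group_effect={"x": 0.0}, sample_sd=0.0, seed=3
        )
        fs = synthetic_fragment_set(100)
        truth = make_methylome(fs, {f.name: "x" for f in fs}, cfg)
        ga, gb = truth.design.groups
        np.testing.assert_array_equal(
            truth.true_frag_meth[ga], truth.true_frag_meth[gb]
        )

    def test_calibrated_intergenic_shift(self):
        cfg = SimConfig(
            baseline_meth={"intergenic": 0.66},
            group_effect={"intergenic": -0.19},
            frag_noise_sd=0.0,
            seed=3,
        )
        fs = synthetic_fragment_set(10)
        truth = make_methylome(fs, {f.name: "intergenic" for f in fs}, cfg)
        assert truth.true_frag_meth[truth.design.groups[1]].mean() == pytest.approx(
            0.47, abs=1e-9
        )

    def test_clipping_floor(self):
        cfg = SimConfig(
            baseline_meth={"x": 0.05}, group_effect={"x": -0.2}, frag_noise_sd=0.0,
            seed=3,
        )
        fs = synthetic_fragment_set(5)
        truth = make_methylome(fs, {f.name: "x" for f in fs}, cfg)
        assert (truth.true_frag_meth[truth.design.groups[1]] == 0.01).all()

    def test_unlabeled_fragment_rejected(self):
        cfg = SimConfig(baseline_meth={"x": 0.5}, group_effect={})
        fs = synthetic_fragment_set(3)
        with pytest.raises(ValueError, match="unlabeled"):
            make_methylome(fs, {fs[0].name: "x"}, cfg)


class TestCounts:
    def test_low_dispersion_high_coverage_recovers_truth(self):
        """phi -> 0 with depth 1e4 gives proportions within 0.02 of truth."""
        cfg = SimConfig(
            baseline_meth={"x": 0.6},
            group_effect={"x": -0.2},
            sample_sd=0.0,
            dispersion=1e-12,
            coverage_mean=2500.0,  # x 4 CpGs = 1e4 reads per fragment
            seed=7,
        )
        fs = synthetic_fragment_set(50)
        truth = make_methylome(fs, {f.name: "x" for f in fs}, cfg)
        calls = sample_counts(truth, fs, cfg)
        meth = quantify_fragments(calls, fs, 10, 2, truth.design)
        est = meth.meth[truth.design.samples].to_numpy()
        true = truth.sample_meth.loc[meth.meth.index].to_numpy()
        assert np.abs(est - true).max() < 0.02

    def test_seed_changes_counts_not_means(self):
        cfg = dict(
            baseline_meth={"x": 0.5}, group_effect={"x": 0.0}, sample_sd=0.0
        )
        fs = synthetic_fragment_set(1000)
        labels = {f.name: "x" for f in fs}
        out = []
        for seed in (1, 2):
            c = SimConfig(seed=seed, **cfg)
            truth = make_methylome(fs, labels, c)
            calls = sample_counts(truth, fs, c)
            out.append(calls)
        assert not out[0].frame["n_meth"].equals(out[1].frame["n_meth"])
        for calls in out:
            overall = calls.frame["n_meth"].sum() / (
                calls.frame["n_meth"].sum() + calls.frame["n_unmeth"].sum()
            )
            assert overall == pytest.approx(0.5, abs=0.01)

    def test_dispersion_bounds_enforced(self):
        cfg = SimConfig(baseline_meth={"x": 0.5}, group_effect={})
        cfg.dispersion = 2.0
        fs = synthetic_fragment_set(2)
        truth = make_methylome(fs, {f.name: "x" for f in fs}, SimConfig(baseline_meth={"x": 0.5}, group_effect={}))
        with pytest.raises(ValueError, match="dispersion"):
            sample_counts(truth, fs, cfg)


class TestExpression:
    def _truth(self, cfg, n_frag=50):
        fs = synthetic_fragment_set(n_frag)
        return make_methylome(fs, {f.name: "x" for f in fs}, cfg)

    def test_noiseless_limit_exact_lfc(self):
        cfg = SimConfig(
            baseline_meth={"x": 0.6}, group_effect={"x": -0.2},
            n_genes=50, n_deg=10, lfc_scale=2.0, expr_log2_sd=0.0, seed=9,
        )
        truth = self._truth(cfg)
        expr, truth = make_expression(truth, cfg)
        ga, gb = truth.design.groups
        sa = truth.design.samples_of(ga)
        sb = truth.design.samples_of(gb)
        for gene, planted in truth.true_deg.items():
            lfc = np.log2(expr.loc[gene, sb].mean() / expr.loc[gene, sa].mean())
            assert lfc == pytest.approx(planted, abs=1e-9)
            assert abs(planted) == 2.0

    def test_null_expression_type_one_error(self):
        cfg = SimConfig(
            baseline_meth={"x": 0.6}, group_effect={"x": -0.2},
            n_genes=2000, n_deg=0, seed=9,
        )
        truth = self._truth(cfg)
        expr, truth = make_expression(truth, cfg)
        res = call_degs(expr, truth.design)
        # regulator genes are coupled, not null; exclude them
        null_genes = res.table.index.difference(truth.true_regulator_rho)
        frac = (res.table.loc[null_genes, "p"] <= 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_anchor_higher_in_hypomethylated_group(self):
        cfg = SimConfig(baseline_meth={"x": 0.6}, group_effect={"x": -0.2},
                        n_genes=20, n_deg=0, seed=11)
        truth = self._truth(cfg)
        expr, truth = make_expression(truth, cfg)
        ga, gb = truth.design.groups
        anchor = expr.loc["CD274"]
        assert (
            anchor[truth.design.samples_of(gb)].mean()
            > anchor[truth.design.samples_of(ga)].mean()
        )

    def test_truth_tables_reference_emitted_entities(self, default_bundle, tmp_path):
        write_bundle(default_bundle, tmp_path)
        truth_frag = pd.read_csv(tmp_path / "truth_fragments.tsv", sep="\t", index_col=0)
        assert list(truth_frag.index) == default_bundle.fragments.names
        truth_deg = pd.read_csv(tmp_path / "truth_degs.tsv", sep="\t")
        assert set(truth_deg["gene_id"]).issubset(set(default_bundle.expression.index))


class TestEndToEnd:
    def test_hypomethylation_drives_anchor_and_integration(
        self, default_bundle, default_meth
    ):
        """Planted global hypomethylation yields a negative anchor-methylome
        correlation, hypo-dominant DMFs, and recoverable body-hypo/down
        coupled genes."""
        from conmeth.diffexpr import call_degs
        from conmeth.diffmeth import call_dmfs
        from conmeth.integration import integrate_dmf_deg, spearman

        b = default_bundle
        res = call_dmfs(default_meth, b.design)
        assert res.hypo_fraction >= 0.95

        global_meth = default_meth.meth.median(axis=0)[b.design.samples]
        anchor = b.expression.loc["CD274", global_meth.index]
        assert spearman(anchor, global_meth.values).rho < 0

        degs = call_degs(b.expression, b.design).degs
        rec, conc = integrate_dmf_deg(res.table, degs, b.genes)
        body_down = rec[(rec["context"] == "gene_body") & (rec["concordance"] == "body-hypo/down")]
        recovered = set(body_down["gene"]) & set(b.truth.true_coupled)
        assert len(recovered) >= 0.8 * len(b.truth.true_coupled)
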