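import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gexpipe import proteomics, simulate
from gexpipe.simulate import ConfigError, SimConfig

from .conftest import ratio_table_from_frame


def venn_counts(flags: pd.DataFrame) -> dict[tuple[str, ...], int]:
    """Independent oracle: brute-force region counting of boolean vectors."""
    counts: dict[tuple[str, ...], int] = {}
    for _, row in flags.iterrows():
        members = tuple(sorted(c for c in flags.columns if row[c]))
        if members:
            counts[members] = counts.get(members, 0) + 1
    return counts


class TestOverlapFlags:
    def test_triple_region_only(self):
        cfg = SimConfig(
            n_genes=100, n_proteins=10, conditions=("wt", "a", "b", "c"),
            overlap_spec={("a", "b", "c"): 5}, de_fraction=1.0, seed=1,
        )
        flags = simulate.gen_overlap_flags(cfg)
        triple = flags.all(axis=1)
        assert triple.sum() == 5
        assert flags.sum().tolist() == [5, 5, 5]

    def test_all_regions_zero(self):
        cfg = SimConfig(
            n_genes=50, n_proteins=10, conditions=("wt", "a", "b", "c"),
            overlap_spec={}, seed=1,
        )
        flags = simulate.gen_overlap_flags(cfg)
        assert not flags.any().any()

    def test_pairwise_arithmetic(self):
        cfg = SimConfig(
            n_genes=10, n_proteins=5, conditions=("wt", "a", "b"),
            overlap_spec={("a",): 2, ("b",): 3, ("a", "b"): 1},
            de_fraction=1.0, seed=2,
        )
        flags = simulate.gen_overlap_flags(cfg)
        assert flags["a"].sum() == 3
        assert flags["b"].sum() == 4
        assert (flags["a"] & flags["b"]).sum() == 1

    def test_infeasible_total_raises(self):
        cfg = SimConfig(
            n_genes=10, n_proteins=5, conditions=("wt", "a", "b"),
            overlap_spec={("a",): 8, ("b",): 8}, de_fraction=1.0, seed=1,
        )
        with pytest.raises(ConfigError, match="16"):
            simulate.gen_overlap_flags(cfg)

    def test_marginal_violation_names_condition(self):
        cfg = SimConfig(
            n_genes=100, n_proteins=5, conditions=("wt", "a", "b"),
            overlap_spec={("a",): 30}, de_fraction=0.1, seed=1,
        )
        with pytest.raises(ConfigError, match="'a'"):
            simulate.gen_overlap_flags(cfg)

    @settings(max_examples=25, deadline=None)
    @given(
        only_a=st.integers(0, 10),
        only_b=st.integers(0, 10),
        ab=st.integers(0, 10),
        abc=st.integers(0, 10),
        seed=st.integers(0, 10_000),
    )
    def test_region_counts_exact(self, only_a, only_b, ab, abc, seed):
        spec = {("a",): only_a, ("b",): only_b, ("a", "b"): ab, ("a", "b", "c"): abc}
        cfg = SimConfig(
            n_genes=60, n_proteins=5, conditions=("wt", "a", "b", "c"),
            overlap_spec=spec, de_fraction=1.0, seed=seed,
        )
        flags = simulate.gen_overlap_flags(cfg)
        observed = venn_counts(flags)
        expected = {k: v for k, v in spec.items() if v > 0}
        assert observed == expected


class TestSilacTable:
    def _cfg(self, **kw):
        defaults = dict(
            n_genes=40, n_proteins=40, conditions=("wt", "mutA"),
            overlap_spec={("mutA",): 8}, de_fraction=0.5,
            ratio_noise_sd=0.0, missing_rate=0.0, seed=5,
            n_decoy_rows=0, n_contaminant_rows=0,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_noise_free_null_ratios_equal(self):
        cfg = self._cfg(overlap_spec={})
        truth = simulate.gen_truth(cfg)
        table = simulate.gen_silac_table(cfg, truth)
        ratio_cols = [c for c in table.columns if c.startswith("Ratio H/L")]
        arr = table[ratio_cols].to_numpy()
        assert np.allclose(arr, arr[:, [0]])

    def test_fold_change_by_construction(self):
        cfg = self._cfg(effect_size_log2=1.0)
        truth = simulate.gen_truth(cfg)
        table = simulate.gen_silac_table(cfg, truth).set_index("Protein IDs")
        de_protein = truth.true_de.index[truth.true_de["mutA"]][0]
        wt = table.loc[de_protein, "Ratio H/L normalized wt_r1"]
        mut = table.loc[de_protein, "Ratio H/L normalized mutA_r1"]
        fc = truth.true_log2fc.loc[de_protein, "mutA"]
        assert wt / mut == pytest.approx(2.0**fc)
        assert abs(fc) == 1.0

    def test_all_missing_drops_everything_downstream(self):
        cfg = self._cfg(missing_rate=1.0)
        truth = simulate.gen_truth(cfg)
        table = ratio_table_from_frame(simulate.gen_silac_table(cfg, truth))
        d = proteomics.deconvolute(
            table.condition_ratios("wt"), table.condition_ratios("mutA")
        )
        assert len(d) == 0

    def test_decoy_contaminant_rows_appended(self):
        cfg = self._cfg(n_decoy_rows=3, n_contaminant_rows=2)
        truth = simulate.gen_truth(cfg)
        raw = simulate.gen_silac_table(cfg, truth)
        assert (raw["Reverse"] == "+").sum() == 3
        assert (raw["Potential contaminant"] == "+").sum() == 2
        parsed = ratio_table_from_frame(raw)
        assert len(parsed.ratios) == cfg.n_proteins

    def test_noise_free_recovery_to_machine_precision(self):
        cfg = self._cfg(effect_size_log2=1.7)
        truth = simulate.gen_truth(cfg)
        table = ratio_table_from_frame(simulate.gen_silac_table(cfg, truth))
        res = proteomics.scale_and_test(
            proteomics.deconvolute(
                table.condition_ratios("wt"), table.condition_ratios("mutA")
            )
        )
        true_fc = truth.true_log2fc.loc[res.index, "mutA"]
        # noise-free: median over proteins is 0 on log2 scale (more non-DE
        # than DE), so scaling is exact and recovery is to machine precision
        np.testing.assert_allclose(res["log2fc_mean"], true_fc, atol=1e-12)


class TestCounts:
    def test_poisson_limit(self):
        cfg = SimConfig(
            n_genes=3000, n_proteins=5, conditions=("wt", "mutA"),
            overlap_spec={}, nb_dispersion=0.0, seed=11,
            libsize_factor_range=(1.0, 1.0), replicates_per_condition=3,
        )
        truth = simulate.gen_truth(cfg)
        cm = simulate.gen_counts(cfg, truth)
        m = cm.counts.mean(axis=1)
        v = cm.counts.var(axis=1, ddof=1)
        # variance/mean ratio -> 1 over many genes within MC error
        assert np.mean(v / m) == pytest.approx(1.0, abs=0.03)

    def test_null_cpm_ratio_centred_on_zero(self):
        from gexpipe import rnaseq

        cfg = SimConfig(
            n_genes=1000, n_proteins=5, conditions=("wt", "mutA"),
            overlap_spec={}, nb_dispersion=0.02, seed=12,
        )
        truth = simulate.gen_truth(cfg)
        cm = simulate.gen_counts(cfg, truth)
        c = rnaseq.cpm(cm.counts)
        wt = c[[s for s in c if s.startswith("wt")]].to_numpy()
        mut = c[[s for s in c if s.startswith("mutA")]].to_numpy()
        ratio = np.log2(mut.mean(axis=1) / wt.mean(axis=1))
        assert abs(ratio.mean()) < 0.02

    def test_marked_gene_ratio_mc(self):
        # DERIVED Monte-Carlo oracle: a gene with true log2 FC = 2 at high
        # baseline and dispersion 0.01 shows an empirical CPM ratio in [3, 5]
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            base = 800.0
            shape = 1 / 0.01
            wt = rng.poisson(rng.gamma(shape, base * 0.01, size=3))
            mut = rng.poisson(rng.gamma(shape, base * 4 * 0.01, size=3))
            ratio = mut.mean() / wt.mean()
            hits += 3.0 <= ratio <= 5.0
        assert hits >= 0.99 * n_seeds

    def test_marked_gene_ratio_through_generator(self):
        from gexpipe import rnaseq

        cfg = SimConfig(
            n_genes=100, n_proteins=5, conditions=("wt", "mutA"),
            overlap_spec={("mutA",): 5}, de_fraction=0.1,
            effect_size_log2=2.0, nb_dispersion=0.01,
            baseline_range=(500.0, 1000.0), seed=13,
        )
        truth = simulate.gen_truth(cfg)
        cm = simulate.gen_counts(cfg, truth)
        c = rnaseq.cpm(cm.counts)
        gene = truth.true_de.index[
            truth.true_de["mutA"] & (truth.true_log2fc["mutA"] > 0)
        ][0]
        wt = c.loc[gene, [s for s in c if s.startswith("wt")]].mean()
        mut = c.loc[gene, [s for s in c if s.startswith("mutA")]].mean()
        assert 3.0 <= mut / wt <= 5.0

    def test_library_factors_recorded(self, small_cfg, small_truth):
        cm = simulate.gen_counts(small_cfg, small_truth)
        lo, hi = small_cfg.libsize_factor_range
        assert ((cm.samples["lib_factor"] >= lo) & (cm.samples["lib_factor"] <= hi)).all()


class TestAnnotations:
    def test_single_term_is_root_annotated_to_all(self):
        cfg = SimConfig(
            n_genes=30, n_proteins=5, conditions=("wt", "a"),
            overlap_spec={}, go_terms=1, ontologies=("BP",), seed=3,
        )
        dag, ann, _ = simulate.gen_annotations(cfg)
        assert dag.terms() == ["BP:0000"]
        assert set(ann["gene"]) == set(cfg.gene_ids)
        assert (ann["term"] == "BP:0000").all()

    def test_all_neutral(self):
        cfg = SimConfig(
            n_genes=50, n_proteins=5, conditions=("wt", "a"),
            overlap_spec={}, class_proportions=(0.0, 0.0, 1.0), seed=3,
        )
        _, _, labels = simulate.gen_annotations(cfg)
        assert (labels == "neutral").all()

    def test_label_counts_within_binomial_bounds(self):
        # DERIVED oracle: 99% binomial quantile bounds at n=1000
        cfg = SimConfig(
            n_genes=1000, n_proteins=5, conditions=("wt", "a"),
            overlap_spec={}, class_proportions=(0.2, 0.1, 0.7), seed=99,
        )
        labels = simulate.gen_class_labels(cfg)
        for cls, p in zip(simulate.CLASS_LABELS, (0.2, 0.1, 0.7)):
            lo = stats.binom.ppf(0.005, 1000, p)
            hi = stats.binom.ppf(0.995, 1000, p)
            assert lo <= (labels == cls).sum() <= hi

    def test_dag_acyclic_single_root(self, small_cfg):
        dag, _, _ = simulate.gen_annotations(small_cfg)
        dag.validate()  # raises on cycle or multiple roots
        assert set(dag.ontologies()) == set(small_cfg.ontologies)

    def test_class_labels_match_truth(self, small_cfg, small_truth):
        _, _, labels = simulate.gen_annotations(small_cfg)
        assert labels.equals(small_truth.class_label)


class TestReproducibility:
    def test_byte_identical_outputs(self, small_cfg, tmp_path):
        p1 = simulate.write_dataset(small_cfg, tmp_path / "a")
        p2 = simulate.write_dataset(small_cfg, tmp_path / "b")
        assert set(p1) == set(p2)
        for name in p1:
            with open(p1[name], "rb") as f1, open(p2[name], "rb") as f2:
                assert f1.read() == f2.read(), name

    def test_adding_output_does_not_perturb_others(self, small_cfg, small_truth):
        counts_before = simulate.gen_counts(small_cfg, small_truth)
        simulate.gen_silac_table(small_cfg, small_truth)  # unrelated stream
        counts_after = simulate.gen_counts(small_cfg, small_truth)
        assert counts_before.counts.equals(counts_after.counts)


class TestConfigValidation:
    def test_class_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="class_proportions"):
            SimConfig(class_proportions=(0.5, 0.5, 0.1))

    def test_yaml_roundtrip(self, small_cfg, tmp_path):
        import yaml

        simulate.write_dataset(small_cfg, tmp_path)
        data = yaml.safe_load((tmp_path / "config.yaml").read_text())
        cfg2 = simulate.config_from_dict(data)
        assert cfg2 == small_cfg
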