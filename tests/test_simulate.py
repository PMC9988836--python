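"""Generator correctness: marginal statistics match closed-form expectations."""

import numpy as np
import pytest

from modmap.datatypes import MISSING
from modmap.simulate import (
    BackcrossSimConfig,
    NetworkSimConfig,
    PanelSimConfig,
    ParentalHaplotypes,
    TwoLocusTraitModel,
    assign_trait_alleles,
    haldane,
    simulate_backcross,
    simulate_dose_response,
    simulate_network,
    simulate_strain_panel,
    susceptibility_probability,
)


class TestPanel:
    def test_zero_divergence_monomorphic_errors(self):
        cfg = PanelSimConfig(
            between_group_divergence=0.0, within_group_diversity=0.0, n_snps=100, seed=1
        )
        with pytest.raises(ValueError, match="polymorphic"):
            simulate_strain_panel(cfg)

    def test_missing_rate_within_binomial_bound(self):
        cfg = PanelSimConfig(
            n_groups=4, strains_per_group=5, n_snps=2000, missing_rate_range=(0.1, 0.1), seed=2
        )
        gm = simulate_strain_panel(cfg)
        frac = gm.missing_fraction()
        sd = np.sqrt(0.1 * 0.9 / 2000)
        assert ((frac - 0.1).abs() <= 3 * sd).all()

    def test_seed_determinism(self):
        cfg = PanelSimConfig(n_groups=3, strains_per_group=3, n_snps=200, seed=7)
        a, b = simulate_strain_panel(cfg), simulate_strain_panel(cfg)
        assert a == b

    def test_group_structure(self):
        """Within-group strain pairs are far more concordant than between."""
        cfg = PanelSimConfig(
            n_groups=2, strains_per_group=3, n_snps=1000, missing_rate_range=(0, 0), seed=3
        )
        gm = simulate_strain_panel(cfg)
        within = (gm.calls[:, 0] == gm.calls[:, 1]).mean()
        between = (gm.calls[:, 0] == gm.calls[:, 3]).mean()
        assert within > between + 0.1


class TestTraitModel:
    @pytest.mark.parametrize(
        "primary, enhancer, expect",
        [("s", "e", 0.9), ("r", "e", 0.0), ("r", "E", 0.9), ("ko", "E", 0.0), ("s", "E", 0.9)],
    )
    def test_rule_table(self, primary, enhancer, expect):
        model = TwoLocusTraitModel(penetrance=0.9)
        assert susceptibility_probability(primary, enhancer, model) == expect

    def test_alleles_embedded_as_genotype_columns(self):
        cfg = PanelSimConfig(n_groups=2, strains_per_group=2, n_snps=50, seed=4)
        panel = simulate_strain_panel(cfg)
        plan = {"G1": ("s", "e"), "G2": ("r", "E")}
        ann = assign_trait_alleles(panel, TwoLocusTraitModel(), plan)
        assert ann.genotypes.n_variants == 52
        v = ann.genotypes.variants
        prow = v.index[v["snp_id"] == "primary_locus"][0]
        assert ann.genotypes.calls[prow].tolist() == [1, 1, 0, 0]
        erow = v.index[v["snp_id"] == "enhancer_locus"][0]
        assert ann.genotypes.calls[erow].tolist() == [0, 0, 1, 1]


class TestDoseResponse:
    def _annotated(self, seed=5):
        cfg = PanelSimConfig(n_groups=2, strains_per_group=2, n_snps=50, seed=seed)
        panel = simulate_strain_panel(cfg)
        return assign_trait_alleles(
            panel, TwoLocusTraitModel(penetrance=0.9), {"G1": ("s", "e"), "G2": ("r", "e")}
        )

    def test_resistant_strain_all_zero(self):
        table = simulate_dose_response(self._annotated(), [100, 50], 10, seed=1)
        rows = table.rows[table.rows["strain"].str.startswith("G2")]
        assert (rows["affected"] == 0).all()

    def test_susceptible_fraction_within_binomial_bound(self):
        table = simulate_dose_response(self._annotated(), [100], 1000, seed=2)
        rows = table.rows[table.rows["strain"] == "G1S1"]
        frac = rows["affected"].sum() / rows["tested"].sum()
        assert abs(frac - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / 1000)

    def test_determinism(self):
        a = simulate_dose_response(self._annotated(), [100, 50], 5, seed=3)
        b = simulate_dose_response(self._annotated(), [100, 50], 5, seed=3)
        assert a.rows.equals(b.rows)


class TestBackcross:
    MODEL = TwoLocusTraitModel(primary_locus_pos=55_100_000, enhancer_locus_pos=52_000_000)

    def test_no_recombination_at_zero_rate(self):
        cfg = BackcrossSimConfig(
            n_animals=100, marker_positions=(1_000_000, 51_000_000), cm_per_mb=0.0, seed=6
        )
        bc = simulate_backcross(cfg, self.MODEL)
        assert (bc.genotypes[0] == bc.genotypes[1]).all()

    def test_haldane_recombinant_fraction(self):
        """Markers 50 Mb apart at 0.5 cM/Mb: 25 cM, r = (1-e^-0.5)/2 = 0.1967."""
        cfg = BackcrossSimConfig(
            n_animals=5000, marker_positions=(1_000_000, 51_000_000), cm_per_mb=0.5, seed=7
        )
        bc = simulate_backcross(cfg, self.MODEL)
        rec = (bc.genotypes[0] != bc.genotypes[1]).mean()
        r = haldane(0.25)
        assert abs(rec - r) <= 3 * np.sqrt(r * (1 - r) / 5000)

    def test_knockout_recurrent_half_affected(self):
        """Donor (r, E) x knockout recurrent: only animals inheriting both a
        functional primary allele and the enhancer can be affected."""
        cfg = BackcrossSimConfig(n_animals=3000, seed=8)
        model = TwoLocusTraitModel(
            primary_locus_pos=55_100_000, enhancer_locus_pos=55_200_000, penetrance=1.0
        )
        bc = simulate_backcross(cfg, model, ParentalHaplotypes(("r", "E"), ("ko", "e")))
        # tightly linked loci: affected fraction ~ 1/2 (co-inherited donor gamete)
        assert abs(bc.animals["phenotype"].mean() - 0.5) < 0.05

    def test_determinism(self):
        cfg = BackcrossSimConfig(n_animals=30, seed=9)
        a, b = simulate_backcross(cfg, self.MODEL), simulate_backcross(cfg, self.MODEL)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.animals.equals(b.animals)


class TestNetwork:
    def test_symmetry_and_range(self):
        net, _ = simulate_network(NetworkSimConfig(seed=10))
        assert np.allclose(net.weights, net.weights.T)
        assert net.weights.min() >= 0 and net.weights.max() <= 1
        assert np.allclose(np.diag(net.weights), 0)

    def test_planted_contrast(self):
        cfg = NetworkSimConfig(
            n_genes=100, module_sizes=(30,), within_weight_mean=0.8, between_weight_mean=0.1, seed=11
        )
        net, modules = simulate_network(cfg)
        idx = [net.index(g) for g in modules["module1"]]
        sub = net.weights[np.ix_(idx, idx)]
        within = sub[np.triu_indices(30, 1)].mean()
        out = net.weights[np.ix_(idx, range(60, 100))].mean()
        assert within > 0.7 and out < 0.2

    def test_degenerate_concentration(self):
        cfg = NetworkSimConfig(
            n_genes=40, module_sizes=(10,), weight_concentration=1e9, seed=12,
            within_weight_mean=0.8, between_weight_mean=0.1,
        )
        net, modules = simulate_network(cfg)
        idx = [net.index(g) for g in modules["module1"]]
        sub = net.weights[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(10, 1)]
        assert np.allclose(vals, 0.8, atol=1e-3)

    def test_determinism(self):
        cfg = NetworkSimConfig(seed=13)
        a, _ = simulate_network(cfg)
        b, _ = simulate_network(cfg)
        assert np.array_equal(a.weights, b.weights)
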