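"""Segregation testing, haplotype inference and trait localization."""

import math

import numpy as np
import pytest

from woolmap import mapping as mp
from woolmap.errors import ValidationError
from woolmap.fixtures import replica_snp_markers, replica_snp_typing
from woolmap.genetics import (
    BackcrossPanel,
    Marker,
    Progeny,
    TraitLocus,
    make_marker_map,
    simulate_backcross,
)


def panel_from_counts(n_mut, n_norm):
    gmap = make_marker_map(2, 1000)
    progeny = [
        Progeny(f"m{i}", "mutant", {"M1": "N", "M2": "N"}) for i in range(n_mut)
    ] + [Progeny(f"n{i}", "normal", {"M1": "H", "M2": "H"}) for i in range(n_norm)]
    return BackcrossPanel(map=gmap, trait="t", progeny=progeny)


class TestSegregation:
    def test_published_family_size_split(self):
        seg = mp.test_segregation(panel_from_counts(840, 839))
        assert seg.chi2 == pytest.approx(1 / 1679)  # (0.5^2 + 0.5^2) / 839.5
        assert seg.p_value > 0.98

    def test_equal_split_is_exactly_zero(self):
        seg = mp.test_segregation(panel_from_counts(50, 50))
        assert seg.chi2 == 0.0
        assert seg.p_value == 1.0

    def test_total_distortion(self):
        seg = mp.test_segregation(panel_from_counts(100, 0))
        assert seg.chi2 == pytest.approx(100.0)
        assert seg.p_value < 1e-22

    def test_empty_panel_rejected(self):
        gmap = make_marker_map(2, 1000)
        with pytest.raises(ValidationError):
            mp.test_segregation(BackcrossPanel(map=gmap, trait="t", progeny=[]))

    def test_null_p_values_uniform(self):
        # KS test on segregation p-values under 1:1 truth, alpha = 0.01
        from scipy.stats import kstest

        gmap = make_marker_map(2, 1_000_000)
        trait = TraitLocus("t", 500_000, 0.25)
        pvals = []
        for seed in range(2000):
            panel = simulate_backcross(gmap, trait, 1679, seed=seed)
            pvals.append(mp.test_segregation(panel).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestHaplotypeInference:
    gmap = make_marker_map(6, 5_000_000)

    def make(self, phenotype, codes):
        genos = dict(zip(self.gmap.names, codes))
        panel = BackcrossPanel(
            map=self.gmap, trait="t",
            progeny=[Progeny("p1", phenotype, genos)],
        )
        return mp.infer_transmitted_haplotypes(panel)[0]

    def test_all_het_mutant_is_double_recombinant_pattern(self):
        h = self.make("mutant", ["H"] * 6)
        assert all(h.alleles[n] == "A" for n in self.gmap.names)
        assert h.trait_allele == "N"

    def test_all_hom_normal(self):
        h = self.make("normal", ["N"] * 6)
        assert all(h.alleles[n] == "N" for n in self.gmap.names)
        assert h.trait_allele == "A"

    def test_missing_propagates_to_unknown(self):
        h = self.make("mutant", ["-"] * 6)
        assert all(h.alleles[n] is None for n in self.gmap.names)

    def test_unknown_code_rejected(self):
        panel = BackcrossPanel(
            map=self.gmap, trait="t",
            progeny=[Progeny("p1", "mutant", dict.fromkeys(self.gmap.names, "N"))],
        )
        panel.progeny[0].genotypes["M1"] = "X"
        with pytest.raises(ValidationError, match="genotype code"):
            mp.infer_transmitted_haplotypes(panel)


class TestHaplotypeClasses:
    def test_partition_and_conservation(self):
        gmap = make_marker_map(3, 1000)
        progeny = (
            [Progeny(f"a{i}", "mutant", {"M1": "N", "M2": "N", "M3": "N"}) for i in range(3)]
            + [Progeny(f"b{i}", "normal", {"M1": "H", "M2": "H", "M3": "H"}) for i in range(2)]
        )
        panel = BackcrossPanel(map=gmap, trait="t", progeny=progeny)
        classes = mp.count_haplotype_classes(mp.infer_transmitted_haplotypes(panel))
        assert [c.count for c in classes] == [3, 2]
        assert sum(c.count for c in classes) == 5

    def test_random_panel_counts_sum_to_panel_size(self):
        gmap = make_marker_map(5, 5_000_000)
        trait = TraitLocus("t", 2_500_000, 1.25)
        panel = simulate_backcross(gmap, trait, 500, seed=9)
        classes = mp.count_haplotype_classes(mp.infer_transmitted_haplotypes(panel))
        assert sum(c.count for c in classes) == 500


class TestRecombinationEstimate:
    def test_eleven_of_1679(self, replica_haplotypes):
        est = mp.estimate_recombination(replica_haplotypes, "D11Mit208", "wly")
        assert est.n_recombinant == 11
        assert est.r == pytest.approx(11 / 1679)
        assert est.se == pytest.approx(math.sqrt(est.r * (1 - est.r) / 1679))
        assert est.r == pytest.approx(0.00655, abs=5e-5)
        assert est.se == pytest.approx(0.00197, abs=5e-5)

    def test_nineteen_of_1679(self, replica_haplotypes):
        est = mp.estimate_recombination(replica_haplotypes, "wly", "D11Mit242")
        assert est.n_recombinant == 19
        assert est.r == pytest.approx(0.01132, abs=5e-5)

    def test_zero_recombinants(self, replica_haplotypes):
        est = mp.estimate_recombination(replica_haplotypes, "wly", "D11Mit260")
        assert est.r == 0.0 and est.se == 0.0

    def test_se_matches_bootstrap_within_ten_percent(self):
        rng = np.random.default_rng(5)
        gmap = make_marker_map(2, 10_000_000)  # 5 cM
        trait = TraitLocus("t", 0, 0.0)
        panel = simulate_backcross(gmap, trait, 1000, seed=2)
        haps = mp.infer_transmitted_haplotypes(panel)
        est = mp.estimate_recombination(haps, "M1", "M2")
        flags = np.array(
            [h.alleles["M1"] != h.alleles["M2"] for h in haps], dtype=float
        )
        boots = [
            rng.choice(flags, size=len(flags), replace=True).mean()
            for _ in range(2000)
        ]
        assert est.se == pytest.approx(np.std(boots), rel=0.10)

    def test_no_informative_progeny_rejected(self):
        gmap = make_marker_map(2, 1000)
        panel = BackcrossPanel(
            map=gmap, trait="t",
            progeny=[Progeny("p", "mutant", {"M1": "-", "M2": "N"})],
        )
        haps = mp.infer_transmitted_haplotypes(panel)
        with pytest.raises(ValidationError, match="informative"):
            mp.estimate_recombination(haps, "M1", "M2")


class TestLocalization:
    def test_replica_flanks_and_counts(self, replica_haplotypes, replica_panel):
        loc = mp.localize_trait(replica_haplotypes, replica_panel.map)
        assert (loc.proximal_flank, loc.distal_flank) == ("D11Mit208", "D11Mit242")
        assert loc.n_proximal_recombinants == 11
        assert loc.n_distal_recombinants == 19
        assert loc.interval_bp == 4_800_000

    def test_zero_recombinant_marker_lies_inside_interval(self, replica_haplotypes,
                                                          replica_panel):
        loc = mp.localize_trait(replica_haplotypes, replica_panel.map)
        gmap = replica_panel.map
        m = gmap.marker("D11Mit260")
        assert gmap.marker(loc.proximal_flank).pos_bp < m.pos_bp
        assert m.pos_bp < gmap.marker(loc.distal_flank).pos_bp

    def test_interval_contains_truth_across_seeds(self):
        gmap = make_marker_map(7, 4_800_000)
        trait = TraitLocus("wly", 2_000_000, 1.0)
        for seed in range(30):
            panel = simulate_backcross(gmap, trait, 400, seed=seed)
            loc = mp.localize_trait(mp.infer_transmitted_haplotypes(panel), gmap)
            lo = gmap.marker(loc.proximal_flank).pos_bp
            hi = gmap.marker(loc.distal_flank).pos_bp
            assert lo <= trait.pos_bp <= hi

    def test_all_trait_unknown_rejected(self):
        gmap = make_marker_map(2, 1000)
        haps = [
            mp.TransmittedHaplotype("p", {"M1": "A", "M2": "A"}, "t", None)
        ]
        with pytest.raises(ValidationError, match="pseudo-locus"):
            mp.localize_trait(haps, gmap)

    def test_double_recombinant_flagged_not_bounding(self, replica_panel):
        # an all-A mutant would need a double crossover around the trait
        gmap = replica_panel.map
        bad = Progeny("dbl", "mutant", dict.fromkeys(gmap.names, "H"))
        panel = BackcrossPanel(
            map=gmap, trait="wly", progeny=replica_panel.progeny + [bad]
        )
        loc = mp.localize_trait(mp.infer_transmitted_haplotypes(panel), gmap)
        assert "dbl" in loc.flagged_ids
        assert (loc.proximal_flank, loc.distal_flank) == ("D11Mit208", "D11Mit242")


class TestRefinement:
    def test_replica_snp_refinement(self, replica_haplotypes, replica_panel):
        loc = mp.localize_trait(replica_haplotypes, replica_panel.map)
        refined = mp.refine_interval(
            loc, replica_panel, replica_snp_markers(), replica_snp_typing()
        )
        assert (refined.proximal_flank, refined.distal_flank) == ("SNP2", "SNP6")
        assert refined.n_proximal_recombinants == 2
        assert refined.n_distal_recombinants == 1
        assert refined.interval_bp == 750_000
        assert refined.interval_bp <= loc.interval_bp

    def test_no_extra_markers_is_identity(self, replica_haplotypes, replica_panel):
        loc = mp.localize_trait(replica_haplotypes, replica_panel.map)
        assert mp.refine_interval(loc, replica_panel, [], {}) is loc

    def test_extra_marker_outside_interval_rejected(self, replica_haplotypes,
                                                    replica_panel):
        loc = mp.localize_trait(replica_haplotypes, replica_panel.map)
        outside = Marker("bad", "chr11", 8_000_000, 4.0)
        with pytest.raises(ValidationError, match="outside"):
            mp.refine_interval(loc, replica_panel, [outside], replica_snp_typing())

    def test_missing_recombinant_typing_rejected(self, replica_haplotypes,
                                                 replica_panel):
        loc = mp.localize_trait(replica_haplotypes, replica_panel.map)
        typing = dict(replica_snp_typing())
        typing.pop("RP-AN-01")
        with pytest.raises(ValidationError, match="missing"):
            mp.refine_interval(loc, replica_panel, replica_snp_markers(), typing)

    def test_refinement_never_widens_on_simulated_panels(self):
        # simulate on a dense map, localize on a sparse view, then refine
        # with the withheld markers typed on the interval recombinants
        dense = make_marker_map(11, 5_000_000)
        trait = TraitLocus("wly", 2_600_000, 1.3)
        for seed in range(10):
            full = simulate_backcross(dense, trait, 600, seed=seed)
            sparse_names = dense.names[::2]  # M1 M3 M5 M7 M9 M11
            sparse = make_marker_map(
                len(sparse_names), 5_000_000,
                positions_bp=[dense.marker(n).pos_bp for n in sparse_names],
                names=sparse_names,
            )
            view = BackcrossPanel(
                map=sparse, trait="wly",
                progeny=[
                    Progeny(p.id, p.phenotype,
                            {n: p.genotypes[n] for n in sparse_names})
                    for p in full.progeny
                ],
            )
            loc = mp.localize_trait(mp.infer_transmitted_haplotypes(view), sparse)
            extra = [
                m for m in dense.markers
                if sparse.marker(loc.proximal_flank).pos_bp < m.pos_bp
                < sparse.marker(loc.distal_flank).pos_bp
                and m.name not in sparse_names
            ]
            recs = set(loc.proximal_recombinant_ids) | set(loc.distal_recombinant_ids)
            typing = {
                p.id: {m.name: p.genotypes[m.name] for m in extra}
                for p in full.progeny if p.id in recs
            }
            refined = mp.refine_interval(loc, view, extra, typing)
            assert refined.interval_bp <= loc.interval_bp
            lo = {m.name: m.pos_bp for m in dense.markers}.get(
                refined.proximal_flank,
                sparse.marker(loc.proximal_flank).pos_bp,
            )
            assert lo <= trait.pos_bp


class TestMonotonicity:
    def test_expected_interval_width_shrinks_with_panel_size(self):
        gmap = make_marker_map(9, 4_800_000)
        trait = TraitLocus("wly", 2_400_000, 1.2)
        widths = {}
        for n in (100, 400, 1600):
            ws = []
            for seed in range(25):
                panel = simulate_backcross(gmap, trait, n, seed=seed)
                loc = mp.localize_trait(
                    mp.infer_transmitted_haplotypes(panel), gmap
                )
                ws.append(loc.interval_bp)
            widths[n] = np.mean(ws)
        assert widths[100] >= widths[400] >= widths[1600]
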