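"""Founder haplotype panel, gamete formation, and file round-trips."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from surrosim.founder_genomes import (
    FEMALE,
    MALE,
    Cohort,
    Gamete,
    GeneticMap,
    HaplotypePanel,
    Individual,
    attach_map,
    export_haplotypes,
    generate_base_haplotypes,
    import_haplotypes,
    make_gamete,
    mate,
    sample_crossover_positions,
    sample_founder,
    sample_founder_cohort,
    spectrum_density,
)


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------


class TestPanelGeneration:
    def test_default_dimensions(self, desk_panel):
        assert desk_panel.n_haplotypes == 400
        assert desk_panel.n_chromosomes == 10
        assert desk_panel.loci_per_chromosome == (200,) * 10
        assert desk_panel.n_loci == 2000

    def test_alleles_binary_int8(self, desk_panel):
        for a in desk_panel.alleles:
            assert a.dtype == np.int8
            assert np.isin(a, (0, 1)).all()

    def test_every_locus_segregates(self, desk_panel):
        for a in desk_panel.alleles:
            counts = a.sum(axis=0)
            assert (counts > 0).all() and (counts < desk_panel.n_haplotypes).all()
        desk_panel.validate()

    def test_map_positions_sorted_in_range(self, desk_panel):
        for pos in desk_panel.gmap.positions:
            assert (np.diff(pos) > 0).all()
            assert pos[0] >= 0.0 and pos[-1] <= desk_panel.gmap.chromosome_length

    def test_deterministic_given_seed(self):
        a = generate_base_haplotypes(40, 2, 25, seed=5)
        b = generate_base_haplotypes(40, 2, 25, seed=5)
        for x, y in zip(a.alleles, b.alleles):
            assert np.array_equal(x, y)
        for x, y in zip(a.gmap.positions, b.gmap.positions):
            assert np.array_equal(x, y)

    def test_two_haplotype_panel_is_complementary(self):
        # with two haplotypes, segregation forces exactly one "1" per locus
        panel = generate_base_haplotypes(2, 2, 40, seed=3)
        for a in panel.alleles:
            assert np.array_equal(a.sum(axis=0), np.ones(a.shape[1]))

    def test_unknown_spectrum_rejected(self):
        with pytest.raises(ValueError, match="frequency model"):
            generate_base_haplotypes(10, 1, 10, frequency_model="zipf", seed=0)

    @pytest.mark.parametrize("model", ["uniform", "beta(2,2)", "neutral-sfs"])
    def test_frequency_spectrum_calibration(self, model):
        """Central-bin allele-frequency histogram matches the configured law.

        Oracle: bin probabilities recomputed here from the model definition
        (1/x for the neutral SFS, flat for uniform, beta pdf otherwise),
        restricted to frequencies in [0.1, 0.9] where the segregation
        conditioning of the generator is negligible for n=200 haplotypes.
        """
        from scipy import stats

        n_hap, n_loci = 200, 4000
        panel = generate_base_haplotypes(n_hap, 2, n_loci // 2, frequency_model=model, seed=17)
        freqs = np.concatenate([a.mean(axis=0) for a in panel.alleles])

        grid = np.arange(1, n_hap) / n_hap
        if model == "neutral-sfs":
            w = 1.0 / grid
        elif model == "uniform":
            w = np.ones_like(grid)
        else:
            w = stats.beta.pdf(grid, 2.0, 2.0)
        central = (grid >= 0.1) & (grid <= 0.9)
        edges = np.linspace(0.1, 0.9, 9)
        expected = np.array(
            [
                w[central & (grid >= lo) & (grid < hi)].sum()
                for lo, hi in zip(edges[:-1], edges[1:])
            ]
        )
        expected /= w[central].sum()

        in_central = (freqs >= 0.1) & (freqs < 0.9)
        observed = np.array(
            [
                ((freqs >= lo) & (freqs < hi)).sum()
                for lo, hi in zip(edges[:-1], edges[1:])
            ],
            dtype=float,
        )
        observed /= in_central.sum()
        # 4-sigma multinomial tolerance per bin
        se = np.sqrt(expected * (1 - expected) / in_central.sum())
        assert (np.abs(observed - expected) < 4 * se + 1e-9).all()

        # the package's own density helper agrees with the recomputed law
        g2, p2 = spectrum_density(model, n_hap)
        assert np.allclose(g2, grid)
        assert np.allclose(p2, w / w.sum())


# ---------------------------------------------------------------------------
# file round-trips
# ---------------------------------------------------------------------------


class TestImportExport:
    def test_matrix_round_trip(self, tiny_panel, tmp_path):
        path = str(tmp_path / "panel.txt")
        export_haplotypes(tiny_panel, path)
        back = import_haplotypes(path)
        assert back.n_haplotypes == tiny_panel.n_haplotypes
        for a, b in zip(back.alleles, tiny_panel.alleles):
            assert np.array_equal(a, b)
        for p, q in zip(back.gmap.positions, tiny_panel.gmap.positions):
            assert np.allclose(p, q, atol=1e-10)

    def test_monomorphic_loci_dropped_and_logged(self, tmp_path, caplog):
        path = str(tmp_path / "mono.txt")
        with open(path, "w") as fh:
            fh.write("l0 l1 l2\n0 1 1\n0 0 0\n0 1 1\n")
        with open(path + ".map", "w") as fh:
            fh.write("0 l0 1.0\n0 l1 2.0\n0 l2 3.0\n")
        with caplog.at_level(logging.INFO, logger="surrosim.founder_genomes"):
            panel = import_haplotypes(path)
        assert panel.n_loci == 2  # the all-zero column is gone
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_bad_allele_code_rejected(self, tmp_path):
        path = str(tmp_path / "bad.txt")
        with open(path, "w") as fh:
            fh.write("l0 l1\n0 2\n1 0\n")
        with open(path + ".map", "w") as fh:
            fh.write("0 l0 1.0\n0 l1 2.0\n")
        with pytest.raises(ValueError, match="allele code"):
            import_haplotypes(path)

    def test_missing_map_entry_rejected(self, tmp_path):
        path = str(tmp_path / "nomap.txt")
        with open(path, "w") as fh:
            fh.write("l0 l1\n0 1\n1 0\n")
        with open(path + ".map", "w") as fh:
            fh.write("0 l0 1.0\n")
        with pytest.raises(ValueError, match="l1"):
            import_haplotypes(path)

    def _write_vcf(self, path, records):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=100000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for pos, g1, g2 in records:
                fh.write(f"1\t{pos}\t.\tA\tC\t.\tPASS\t.\tGT\t{g1}\t{g2}\n")

    def test_vcf_round_trip(self, tmp_path):
        path = str(tmp_path / "p.vcf")
        self._write_vcf(
            path,
            [(1000, "0|1", "1|0"), (2000, "1|1", "0|0"), (3000, "0|0", "0|1")],
        )
        panel = import_haplotypes(path, format="vcf")
        # 4 haplotypes (2 samples x 2), all three sites segregate
        assert panel.n_haplotypes == 4
        assert panel.n_loci == 3
        assert np.array_equal(panel.alleles[0][:, 0], [0, 1, 1, 0])
        # physical positions mapped at 1 cM/Mb
        assert np.allclose(panel.gmap.positions[0], [1e-5, 2e-5, 3e-5])

    def test_vcf_unphased_names_site(self, tmp_path):
        path = str(tmp_path / "u.vcf")
        self._write_vcf(path, [(1000, "0|1", "1|0"), (2000, "0/1", "1|0")])
        with pytest.raises(ValueError, match="unphased.*1:2000"):
            import_haplotypes(path, format="vcf")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            import_haplotypes(str(tmp_path / "x"), format="plink")


# ---------------------------------------------------------------------------
# founders and cohorts
# ---------------------------------------------------------------------------


class TestFounders:
    def test_single_haplotype_panel_gives_homozygous_founder(self):
        hap = np.array([[1, 0, 1, 0, 1]], dtype=np.int8)
        panel = HaplotypePanel(
            [hap], GeneticMap((np.linspace(0.1, 0.9, 5),), 1.0)
        )
        ind = sample_founder(panel, id=0, sex=MALE, rng=np.random.default_rng(0))
        for m, p in zip(ind.maternal_gamete.haplotypes, ind.paternal_gamete.haplotypes):
            assert np.array_equal(m, p)

    def test_founder_cohort_alternating_sexes(self, tiny_panel):
        cohort = sample_founder_cohort(tiny_panel, 10, np.random.default_rng(1))
        assert cohort.n_males == cohort.n_females == 5
        assert list(cohort.sex[:4]) == [MALE, FEMALE, MALE, FEMALE]
        assert cohort.generation == -22
        assert cohort.maternal.shape == (10, tiny_panel.n_loci)

    def test_founder_rows_come_from_panel(self, tiny_panel):
        cohort = sample_founder_cohort(tiny_panel, 6, np.random.default_rng(2))
        off = tiny_panel.gmap.offsets
        for c, a in enumerate(tiny_panel.alleles):
            block = cohort.maternal[:, off[c] : off[c + 1]]
            for row in block:
                assert any(np.array_equal(row, h) for h in a)

    def test_cohort_individual_round_trip(self, tiny_panel):
        cohort = sample_founder_cohort(tiny_panel, 4, np.random.default_rng(3))
        ind = cohort.individual(2)
        assert ind.id == cohort.ids[2]
        assert np.array_equal(ind.maternal_gamete.concatenated(), cohort.maternal[2])
        back = Cohort.from_individuals(
            [cohort.individual(i) for i in range(4)], tiny_panel.gmap
        )
        assert np.array_equal(back.maternal, cohort.maternal)
        assert np.array_equal(back.paternal, cohort.paternal)
        assert list(back.sex) == list(cohort.sex)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


class TestMeiosis:
    def test_crossover_counts_poisson_dispersion(self):
        rng = np.random.default_rng(11)
        counts, positions = sample_crossover_positions(100_000, 1.0, rng)
        mean = counts.mean()
        assert abs(mean - 1.0) < 0.02
        assert 0.9 < counts.var() / mean < 1.1

    def test_crossover_positions_uniform(self):
        rng = np.random.default_rng(12)
        counts, positions = sample_crossover_positions(50_000, 1.0, rng)
        flat = positions[np.isfinite(positions)]
        assert flat.size == counts.sum()
        assert (flat >= 0).all() and (flat <= 1).all()
        # first two moments of Uniform(0,1), 4-sigma tolerance
        n = flat.size
        assert abs(flat.mean() - 0.5) < 4 / np.sqrt(12 * n)
        assert abs(np.mean(flat**2) - 1 / 3) < 4 * np.sqrt(4 / 45 / n)

    def test_longer_chromosome_more_crossovers(self):
        rng = np.random.default_rng(13)
        c2, _ = sample_crossover_positions(20_000, 2.0, rng)
        assert abs(c2.mean() - 2.0) < 0.05

    def test_mendelian_transmission_heterozygous_locus(self, tiny_panel):
        """A heterozygous parent transmits each allele half the time."""
        n_loci = tiny_panel.gmap.loci_per_chromosome
        ones = Gamete(tuple(np.ones(k, dtype=np.int8) for k in n_loci))
        zeros = Gamete(tuple(np.zeros(k, dtype=np.int8) for k in n_loci))
        parent = Individual(0, MALE, ones, zeros, generation=0)
        attach_map(parent, tiny_panel.gmap)
        rng = np.random.default_rng(14)
        n = 4000
        transmitted = np.array(
            [make_gamete(parent, rng).concatenated()[0] for _ in range(n)]
        )
        p = transmitted.mean()
        assert abs(p - 0.5) < 4 * 0.5 / np.sqrt(n)

    def test_gamete_alleles_come_from_parent(self, tiny_panel):
        cohort = sample_founder_cohort(tiny_panel, 2, np.random.default_rng(15))
        parent = cohort.individual(0)
        rng = np.random.default_rng(16)
        for _ in range(20):
            g = make_gamete(parent, rng).concatenated()
            m = parent.maternal_gamete.concatenated()
            p = parent.paternal_gamete.concatenated()
            assert np.all((g == m) | (g == p))

    def test_no_recombination_on_point_chromosome(self, tiny_panel):
        """With ~0 map length each chromosome is transmitted intact."""
        gmap = GeneticMap(
            tuple(pos * 1e-9 for pos in tiny_panel.gmap.positions),
            chromosome_length=1e-9,
        )
        panel = HaplotypePanel(tiny_panel.alleles, gmap)
        cohort = sample_founder_cohort(panel, 2, np.random.default_rng(17))
        parent = cohort.individual(0)
        off = gmap.offsets
        rng = np.random.default_rng(18)
        for _ in range(10):
            g = make_gamete(parent, rng)
            for c, h in enumerate(g.haplotypes):
                m = parent.maternal_gamete.haplotypes[c]
                p = parent.paternal_gamete.haplotypes[c]
                assert np.array_equal(h, m) or np.array_equal(h, p)

    @given(st.integers(0, 2**31 - 1))
    def test_meiosis_deterministic_given_seed(self, seed):
        panel = generate_base_haplotypes(10, 2, 15, seed=99)
        cohort = sample_founder_cohort(panel, 2, np.random.default_rng(100))
        parent = cohort.individual(0)
        g1 = make_gamete(parent, np.random.default_rng(seed))
        g2 = make_gamete(parent, np.random.default_rng(seed))
        assert np.array_equal(g1.concatenated(), g2.concatenated())


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------


class TestMating:
    def test_mate_produces_alternating_sexes(self, tiny_panel):
        cohort = sample_founder_cohort(tiny_panel, 4, np.random.default_rng(20))
        dam, sire = cohort.individual(1), cohort.individual(0)
        kids = mate(dam, sire, 6, rng=np.random.default_rng(21))
        assert [k.sex for k in kids] == [MALE, FEMALE] * 3
        assert all(k.generation == dam.generation + 1 for k in kids)

    def test_mate_requires_correct_sexes(self, tiny_panel):
        cohort = sample_founder_cohort(tiny_panel, 4, np.random.default_rng(22))
        with pytest.raises(ValueError, match="dam"):
            mate(cohort.individual(0), cohort.individual(0), 2)
        with pytest.raises(ValueError, match="sire"):
            mate(cohort.individual(1), cohort.individual(1), 2)

    def test_offspring_mean_near_mid_parent(self, desk_panel, desk_arch):
        """Additive trait: mean offspring TBV ~ mid-parent TBV."""
        from surrosim.trait_architecture import true_breeding_value

        cohort = sample_founder_cohort(desk_panel, 2, np.random.default_rng(23))
        dam, sire = cohort.individual(1), cohort.individual(0)
        mid = 0.5 * (
            true_breeding_value(dam, desk_arch) + true_breeding_value(sire, desk_arch)
        )
        kids = mate(dam, sire, 400, rng=np.random.default_rng(24))
        tbvs = np.array([true_breeding_value(k, desk_arch) for k in kids])
        se = tbvs.std(ddof=1) / np.sqrt(tbvs.size)
        assert abs(tbvs.mean() - mid) < 4 * se + 1e-12
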