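import numpy as np
import pytest
from scipy import stats

from introscan import simulate as sim
from introscan.simulate import (
    DONOR,
    RECIPIENT,
    GenomeModel,
    Haplotype,
    PopulationCrashed,
    SelectionScheme,
    SterilityModel,
    TraitArchitecture,
    TraitLocus,
    backcross,
    donor_allele_freq,
    emit_nochoice_counts,
    emit_phenotypes,
    emit_sync,
    emit_twochoice_counts,
    make_f1,
    make_introgressed_strain,
    make_pure,
    plant_tract,
)


def all_tile(pop, genome):
    return all(
        h.tiles(genome.chrom_lengths[c])
        for ind in pop
        for c, haps in ind.haplotypes.items()
        for h in haps
    )


class TestF1:
    def test_f1_female_autosomes_exactly_half_donor(self, toy_genome, toy_sterility):
        f1 = make_f1(toy_genome, n=20, seed=1, sterility=toy_sterility)
        for ind in f1:
            if ind.sex == "F":
                assert ind.donor_fraction(toy_genome) == pytest.approx(0.5)

    def test_f1_male_x_is_maternal_species(self, toy_genome, toy_sterility):
        f1 = make_f1(toy_genome, maternal="yak", n=30, seed=2, sterility=toy_sterility)
        for ind in f1:
            if ind.sex == "M":
                (x,) = ind.haplotypes["X"]
                assert list(x.anc) == [RECIPIENT]

    def test_f1_males_all_sterile(self, toy_genome, toy_sterility):
        f1 = make_f1(toy_genome, n=50, seed=3, sterility=toy_sterility)
        males = [i for i in f1 if i.sex == "M"]
        assert males and all(not m.fertile for m in males)

    def test_invalid_n(self, toy_genome):
        with pytest.raises(ValueError):
            make_f1(toy_genome, n=0)


class TestBackcross:
    def _bc1(self, toy_genome, toy_sterility, n=2000, seed=4):
        f1 = make_f1(toy_genome, n=60, seed=seed, sterility=toy_sterility)
        mothers = [i for i in f1 if i.sex == "F"]
        fathers = [make_pure(toy_genome, "yak", "M") for _ in range(10)]
        return backcross(
            mothers, fathers, toy_genome, seed=seed, n_offspring=n, sterility=toy_sterility
        )

    def test_autosomal_donor_fraction_mendelian(self, toy_genome, toy_sterility):
        bc1 = self._bc1(toy_genome, toy_sterility)
        fracs = []
        for ind in bc1:
            donor = sum(h.donor_bp() for h in ind.haplotypes["2L"])
            fracs.append(donor / (2 * toy_genome.chrom_lengths["2L"]))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.25) < 3 * se + 1e-9

    def test_son_x_donor_fraction_half(self, toy_genome, toy_sterility):
        """Sons carry only the recombinant maternal X (yak/san heterozygous
        mother), so their expected X donor fraction is 0.5."""
        bc1 = self._bc1(toy_genome, toy_sterility)
        sons = [i for i in bc1 if i.sex == "M"]
        fracs = [
            i.haplotypes["X"][0].donor_bp() / toy_genome.chrom_lengths["X"]
            for i in sons
        ]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) < 3 * se + 1e-9

    def test_zero_recombination_unbroken_parental_x(self, toy_sterility):
        genome = GenomeModel(
            chrom_lengths={"X": 3_000_000, "2L": 2_000_000}, recomb_rate=0.0
        )
        bc1 = self._bc1(genome, toy_sterility, n=200, seed=5)
        for ind in bc1:
            for h in ind.haplotypes["X"]:
                assert len(h.anc) == 1  # pure yak or pure san, never recombinant

    def test_segments_tile_after_meiosis(self, toy_genome, toy_sterility):
        bc1 = self._bc1(toy_genome, toy_sterility, n=300, seed=6)
        assert all_tile(bc1, toy_genome)

    def test_sex_validation(self, toy_genome):
        m = make_pure(toy_genome, "yak", "M")
        f = make_pure(toy_genome, "yak", "F")
        with pytest.raises(ValueError):
            backcross([m], [m], toy_genome)
        with pytest.raises(ValueError):
            backcross([f], [f], toy_genome)


class TestEvolve:
    def _start(self, toy_genome, toy_sterility, n=120, seed=7):
        f1 = make_f1(toy_genome, n=60, seed=seed, sterility=toy_sterility)
        mothers = [i for i in f1 if i.sex == "F"]
        fathers = [make_pure(toy_genome, "yak", "M") for _ in range(10)]
        return backcross(
            mothers, fathers, toy_genome, seed=seed, n_offspring=n, sterility=toy_sterility
        )

    def test_vacuous_selection_reproduces_no_selection_run(
        self, toy_genome, toy_sterility
    ):
        start = self._start(toy_genome, toy_sterility)
        _, s1 = sim.evolve(
            start, 4, toy_genome, sterility=toy_sterility,
            selection=SelectionScheme(select_n=10**9), census=120, seed=42,
        )
        _, s2 = sim.evolve(
            start, 4, toy_genome, sterility=toy_sterility,
            selection=SelectionScheme(select_n=120), census=120, seed=42,
        )
        assert s1 == s2

    def test_selection_enriches_donor_at_trait_loci(self, toy_genome, toy_sterility):
        """Truncation selection for light pigmentation raises donor
        frequency at the lightening loci above the genome-wide mean by
        generation 15 in >=95% of 20 seeded replicates."""
        locus = TraitLocus("X", 500_000, (0, 0, -1.0, -1.5, -2.0, -2.0))
        arch = TraitArchitecture(loci=[locus])
        hits = 0
        for seed in range(20):
            start = self._start(toy_genome, toy_sterility, n=120, seed=100 + seed)
            _, summ = sim.evolve(
                start, 15, toy_genome, arch, toy_sterility,
                SelectionScheme(select_n=20), census=120, seed=100 + seed,
            )
            final = summ[-1]
            hits += (
                final["donor_freq_X:500000"] > final["mean_donor_fraction"]
            )
        assert hits >= 19

    def test_population_crash_diagnostic(self, toy_genome):
        # every male sterile: sterility locus where all are donor
        genome = toy_genome
        pop = [make_pure(genome, "san", "F") for _ in range(5)] + [
            make_pure(genome, "san", "M") for _ in range(5)
        ]
        ster = SterilityModel(loci=[("2L", 1_000_000)])
        for ind in pop:
            ster.apply(ind)
        with pytest.raises(PopulationCrashed):
            sim.evolve(pop, 1, genome, sterility=ster, census=10, seed=1)


class TestEmitSync:
    def test_fixed_donor_no_error_pure_counts(self, toy_genome):
        pop = [make_pure(toy_genome, "san", "F") for _ in range(4)]
        lines, pools = emit_sync({"adm": pop}, toy_genome, depth=40, error_rate=0.0, seed=9)
        assert pools == ["yak", "san", "adm"]
        for line in lines:
            fields = line.split("\t")
            san_col = [int(x) for x in fields[4].split(":")[:4]]
            adm_col = [int(x) for x in fields[5].split(":")[:4]]
            assert san_col == adm_col  # admixed pool fixed donor == donor parent
            assert sum(adm_col) == 40 and max(adm_col) == 40

    def test_binomial_sampling_matches_exact_pmf(self):
        """Donor counts at freq 0.5, depth 10 follow Binomial(10, .5) over
        10,000 sites (chi-squared goodness of fit, p > .01)."""
        genome = GenomeModel(chrom_lengths={"2L": 10_000_000}, divergent_density=1.0)
        pop = [make_pure(genome, "san", "F"), make_pure(genome, "yak", "F")]
        positions = {"2L": np.arange(1000, 10_000_000, 999)[:10_000]}
        lines, _ = emit_sync(
            {"adm": pop}, genome, depth=10, error_rate=0.0, seed=11, positions=positions
        )
        assert len(lines) == 10_000
        donor_counts = []
        for line in lines:
            fields = line.split("\t")
            ref = fields[2]
            adm = {b: int(x) for b, x in zip("ATCG", fields[5].split(":")[:4])}
            donor_counts.append(10 - adm[ref])  # non-reference = donor allele
        obs = np.bincount(donor_counts, minlength=11)
        expected = stats.binom.pmf(np.arange(11), 10, 0.5) * len(donor_counts)
        _, p = stats.chisquare(obs, expected)
        assert p > 0.01

    def test_bitwise_reproducible(self, toy_genome):
        pop = make_introgressed_strain(toy_genome, 10, seed=3)
        a, _ = emit_sync({"s": pop}, toy_genome, depth=30, seed=77)
        b, _ = emit_sync({"s": pop}, toy_genome, depth=30, seed=77)
        assert a == b

    def test_depth_must_be_positive(self, toy_genome):
        with pytest.raises(ValueError):
            emit_sync({}, toy_genome, depth=0)


class TestEmitPhenotypes:
    def test_zero_effects_zero_noise_gives_baseline(self, toy_genome):
        arch = TraitArchitecture(
            loci=[], baseline={"F": (3,) * 6, "M": (3,) * 6}, noise_sd=0.0
        )
        pop = [make_pure(toy_genome, "yak", "F"), make_pure(toy_genome, "yak", "M")]
        for r in emit_phenotypes(pop, arch, seed=1):
            assert r.scores == (3,) * 6

    def test_male_hemizygous_x_counts_double_dose(self, toy_genome):
        locus = TraitLocus("X", 500_000, (1, 1, 1, 1, 1, 1), sex_factor={"F": 1.0, "M": 1.0})
        arch = TraitArchitecture(loci=[locus], baseline={"F": (2,) * 6, "M": (2,) * 6}, noise_sd=0.0)
        female_hom = make_pure(toy_genome, "san", "F")
        male_hemi = make_pure(toy_genome, "san", "M")
        rf = emit_phenotypes([female_hom], arch, seed=1)[0]
        rm = emit_phenotypes([male_hemi], arch, seed=1)[0]
        assert rf.scores == rm.scores == (4,) * 6
        arch_off = TraitArchitecture(
            loci=[locus], baseline={"F": (2,) * 6, "M": (2,) * 6},
            noise_sd=0.0, x_dosage_compensation=False,
        )
        assert emit_phenotypes([male_hemi], arch_off, seed=1)[0].scores == (3,) * 6

    def test_observed_sd_matches_rounded_gaussian(self, toy_genome):
        """With noise sd 0.5 at mid-scale, the observed score sd matches
        the analytic sd of a rounded Gaussian within 15%."""
        arch = TraitArchitecture(loci=[], baseline={"F": (5,) * 6, "M": (5,) * 6}, noise_sd=0.5)
        pop = [make_pure(toy_genome, "yak", "F") for _ in range(200)]
        recs = emit_phenotypes(pop, arch, seed=21)
        scores = np.array([r.scores for r in recs], dtype=float).ravel()
        # analytic variance of round(N(5, 0.5^2)) by direct summation
        ks = np.arange(0, 11)
        pk = stats.norm.cdf(ks + 0.5, 5, 0.5) - stats.norm.cdf(ks - 0.5, 5, 0.5)
        mean = (ks * pk).sum()
        analytic_sd = np.sqrt(((ks - mean) ** 2 * pk).sum())
        assert abs(scores.std(ddof=1) - analytic_sd) / analytic_sd < 0.15

    def test_n_per_sex_sampling(self, toy_genome):
        arch = TraitArchitecture()
        pop = [make_pure(toy_genome, "yak", "F") for _ in range(30)] + [
            make_pure(toy_genome, "yak", "M") for _ in range(30)
        ]
        recs = emit_phenotypes(pop, arch, seed=2, n_per_sex=10)
        assert sum(r.sex == "F" for r in recs) == 10
        assert sum(r.sex == "M" for r in recs) == 10


class TestEmitMatingCounts:
    def test_total_preference_all_homogamic(self):
        pref = sim.PreferenceMatrix({("A", "A"): 1.0, ("A", "B"): 0.0})
        own, other = emit_twochoice_counts(pref, "A", "A", "B", n_trials=50, seed=1)
        assert other == 0 and own > 0  # every realised choice is homogamic

    def test_uniform_preferences_near_parity(self):
        pref = sim.PreferenceMatrix({("A", "A"): 0.8, ("A", "B"): 0.8})
        own, other = emit_twochoice_counts(pref, "A", "A", "B", n_trials=1000, seed=2)
        frac = own / (own + other)
        se = 0.5 / np.sqrt(own + other)
        assert abs(frac - 0.5) < 3 * se

    def test_preference_ratio_detected_by_fisher(self):
        """A 3:1 acceptance ratio with 40 trials per focal strain is
        detected at alpha = .05 by the Fisher test in most seeds."""
        from introscan.mating import twochoice_fisher

        pref = sim.PreferenceMatrix(
            {("A", "A"): 0.9, ("A", "B"): 0.3, ("B", "B"): 0.9, ("B", "A"): 0.3}
        )
        hits = 0
        for seed in range(100):
            a = emit_twochoice_counts(pref, "A", "A", "B", n_trials=40, seed=seed)
            b = emit_twochoice_counts(pref, "B", "B", "A", n_trials=40, seed=seed + 500)
            # rows: focal A (own, other), focal B (other, own) as assay table
            r = twochoice_fisher(a, (b[1], b[0]))
            hits += r.p < 0.05
        assert hits > 50

    def test_nochoice_binomial(self):
        pref = sim.PreferenceMatrix({("A", "A"): 0.85, ("A", "B"): 0.1})
        counts = emit_nochoice_counts(pref, [("A", "A"), ("A", "B")], trials=20, seed=3)
        assert counts[("A", "A")][1] == 20
        assert counts[("A", "B")][0] <= counts[("A", "A")][0]

    def test_invalid_preference_rejected(self):
        with pytest.raises(ValueError):
            sim.PreferenceMatrix({("A", "A"): 1.2})


class TestPlantedStrain:
    def test_fixed_tracts_present_in_all_copies(self, toy_genome):
        pop = make_introgressed_strain(
            toy_genome, 20, fixed_tracts=[("X", 100_000, 400_000)],
            residual_per_hap=0.0, seed=5,
        )
        assert donor_allele_freq(pop, "X", 250_000) == 1.0
        assert all_tile(pop, toy_genome)

    def test_intermediate_tract_frequency(self, toy_genome):
        pop = make_introgressed_strain(
            toy_genome, 200, intermediate_tracts=[("2L", 100_000, 600_000, 0.5)],
            residual_per_hap=0.0, seed=6,
        )
        f = donor_allele_freq(pop, "2L", 300_000)
        assert 0.35 < f < 0.65

    def test_plant_tract_overrides_background(self, toy_genome):
        pop = [make_pure(toy_genome, "yak", "F") for _ in range(5)]
        planted = plant_tract(pop, "X", 1_000_000, 2_000_000)
        assert donor_allele_freq(planted, "X", 1_500_000) == 1.0
        assert donor_allele_freq(planted, "X", 500_000) == 0.0
        assert all_tile(planted, toy_genome)
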