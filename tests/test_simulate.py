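"""Synthetic-genome generator: determinism, divergence, planting invariants."""

import math

import numpy as np
import pytest
from scipy import stats

from repeatscape.simulate import (
    SimulationConfig,
    TruthRecord,
    evolve_ltr_pair,
    evolve_sequence,
    generate_background,
    plant_ltr_element,
    plant_satellite_array,
    simulate_genome,
    simulate_reads,
    build_ltr_element,
)
from repeatscape.references import default_library

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class TestBackground:
    def test_length_and_gc_concentration(self):
        seq = generate_background(1000, 0.5, seed=1)
        assert len(seq) == 1000
        gc = (seq.count("G") + seq.count("C")) / 1000
        assert 0.40 <= gc <= 0.60

    def test_gc_zero_gives_at_only(self):
        assert set(generate_background(10, 1e-12, seed=3)) <= {"A", "T"}

    def test_deterministic_under_seed(self):
        assert generate_background(500, 0.4, seed=7) == generate_background(500, 0.4, seed=7)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            generate_background(0, 0.5, seed=1)


class TestEvolution:
    def test_age_zero_is_identity(self):
        anc = generate_background(300, 0.4, seed=2)
        ltr5, ltr3 = evolve_ltr_pair(anc, 0.0, 1.3e-8, 2.0, seed=5)
        assert ltr5 == ltr3 == anc

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            evolve_ltr_pair("ACGT" * 50, -1.0, 1.3e-8, 2.0, seed=1)

    def test_pairwise_k2p_distance_matches_2rt(self):
        # Monte-Carlo oracle: count substitutions by hand and invert with
        # the closed form; 500 replicate 500-bp pairs at T=1 My.
        anc = generate_background(500, 0.36, seed=9)
        rng = np.random.default_rng(17)
        ts = tv = sites = 0
        for _ in range(500):
            a, b = evolve_ltr_pair(anc, 1.0e6, 1.3e-8, 2.0, rng)
            for x, y in zip(a, b):
                sites += 1
                if x != y:
                    if (x, y) in TRANSITIONS:
                        ts += 1
                    else:
                        tv += 1
        P, Q = ts / sites, tv / sites
        k = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert abs(k - 0.026) / 0.026 < 0.05

    def test_extreme_ts_tv_ratio_suppresses_transversions(self):
        anc = generate_background(2000, 0.4, seed=4)
        mutated = evolve_sequence(anc, 0.05, 1e6, seed=8)
        changed = [(x, y) for x, y in zip(anc, mutated) if x != y]
        assert changed, "expected substitutions at distance 0.05"
        assert all(pair in TRANSITIONS for pair in changed)


class TestPlanting:
    def test_tsd_flanks_element_by_construction(self, refs, rng):
        genome = generate_background(20000, 0.4, rng)
        element = build_ltr_element(rng, refs, ltr_length=300, internal_length=2500,
                                    age=0.0, superfamily="Copia", lineage="Angela",
                                    tsd="GATCA")
        genome2, truth = plant_ltr_element(genome, 10000, element)
        assert genome2[truth.start - 5 : truth.start] == "GATCA"
        assert genome2[truth.end : truth.end + 5] == "GATCA"
        assert genome2[truth.ltr5_start : truth.ltr5_start + 2] == "TG"
        assert genome2[truth.ltr3_end - 2 : truth.ltr3_end] == "CA"
        assert len(genome2) == len(genome) + (truth.end - truth.start) + 10

    def test_position_out_of_range_rejected(self, refs, rng):
        element = build_ltr_element(rng, refs, ltr_length=300, internal_length=2500,
                                    age=0.0, superfamily="Copia", lineage="Angela")
        with pytest.raises(ValueError):
            plant_ltr_element("ACGT" * 100, 10_000, element)

    def test_satellite_exact_duplication_when_divergence_zero(self):
        genome = "A" * 200
        genome2, truth = plant_satellite_array(genome, 100, 60, 2, 0.0, seed=3)
        array = genome2[truth.start : truth.end]
        assert len(array) == 120
        assert array[:60] == array[60:]
        assert truth.monomer_length == 60

    def test_satellite_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            plant_satellite_array("A" * 2000, 500, 60, 3, 0.0, seed=1,
                                  occupied=[(400, 700)])

    def test_truth_record_interval_nesting_enforced(self):
        with pytest.raises(ValueError):
            TruthRecord(element_id="x", element_class="LTR-RE", contig="chr1",
                        start=100, end=200, ltr5_start=150, ltr5_end=140,
                        ltr3_start=160, ltr3_end=190)


class TestGenomeAssembly:
    def test_truth_intervals_disjoint_and_length_conserved(self, small_sim):
        truth = small_sim.truth.sort_values("start")
        starts, ends = truth["start"].to_numpy(), truth["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()
        inserted = 0
        for _, row in truth.iterrows():
            inserted += row.end - row.start
            if row.element_class in ("LTR-RE", "TIR"):
                inserted += 2 * len(str(row.tsd))
        assert len(small_sim.genome) == small_sim.config.genome_length + inserted

    def test_seed_determinism(self):
        config = SimulationConfig(genome_length=50_000, n_ltr_elements=2, seed=5)
        a, b = simulate_genome(config), simulate_genome(config)
        assert a.genome == b.genome
        assert a.truth.equals(b.truth)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=0)
        with pytest.raises(ValueError):
            SimulationConfig(age_range=(0.0, 1e9))
        with pytest.raises(ValueError):
            SimulationConfig(satellite_specs=((60, 1, 0.0),))


class TestReads:
    def test_coverage_arithmetic(self):
        genome = generate_background(100_000, 0.4, seed=2)
        reads = simulate_reads(genome, 200, 301, seed=3)
        assert len(reads) == 200
        assert all(len(seq) == 301 for _, seq in reads)
        coverage = 200 * 301 / len(genome)
        assert abs(coverage - 0.602) < 1e-9

    def test_determinism(self):
        genome = generate_background(10_000, 0.4, seed=2)
        assert simulate_reads(genome, 50, 100, seed=9) == simulate_reads(genome, 50, 100, seed=9)

    def test_read_length_exceeding_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads("ACGT" * 10, 5, 100, seed=1)

    def test_start_positions_uniform_chi_square(self):
        genome = generate_background(200_000, 0.4, seed=6)
        reads = simulate_reads(genome, 50_000, 301, seed=7)
        starts = np.array([int(rid.split("|")[1]) for rid, _ in reads])
        counts, _ = np.histogram(starts, bins=20, range=(0, len(genome) - 301 + 1))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=19)

    def test_satellite_read_fraction_matches_array_fraction(self):
        config = SimulationConfig(genome_length=500_000, n_ltr_elements=0,
                                  satellite_specs=((60, 500, 0.0),),
                                  n_reads=20_000, read_length=100, seed=21)
        sim = simulate_genome(config)
        truth = sim.truth.iloc[0]
        frac = (truth.end - truth.start) / len(sim.genome)
        inside = sum(1 for rid, _ in sim.reads
                     if truth.start <= int(rid.split("|")[1]) < truth.end - 100)
        expected = frac * len(sim.reads)
        # binomial oracle: 4-sigma band around the expectation
        sigma = math.sqrt(len(sim.reads) * frac * (1 - frac))
        assert abs(inside - expected) < 4 * sigma + 10
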