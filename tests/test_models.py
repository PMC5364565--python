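import numpy as np
import pytest

from zwdistort import (
    ExtinctionError,
    ModelSpec,
    OverdominanceModel,
    PseudoOverdominanceModel,
    closed_form_recessive_lethal,
    recombine_gamete_distribution,
    run_scenario,
    run_trajectory,
    step_overdominance,
    step_pseudooverdominance,
    viability,
)
from zwdistort.models import _initial_state


class TestViability:
    def test_overdominance_homozygote_lethal(self):
        assert not viability(("a", "a"), "overdominance")
        assert viability(("a", "b"), "overdominance")

    def test_pseudooverdominance_disjoint_lethals_viable(self):
        assert viability(("1000", "0100"), "pseudooverdominance")

    def test_pseudooverdominance_shared_locus_lethal(self):
        assert not viability(("1010", "0010"), "pseudooverdominance")

    def test_harmless_homozygote_viable(self):
        assert viability(("0000", "0000"), "pseudooverdominance")


class TestOverdominanceStep:
    def test_two_allele_dependent_equilibrium(self):
        state = _initial_state(("A1", "A2"), [0.5, 0.5], "dependent", "overdominance")
        nxt = step_overdominance(state, "dependent")
        assert nxt.survivor_fraction == pytest.approx(0.5, abs=1e-15)
        assert nxt.female_fraction == pytest.approx(2 / 3, abs=1e-15)
        np.testing.assert_allclose(nxt.combined_Z_frequencies, [0.5, 0.5], atol=1e-15)

    def test_ten_allele_dependent_equilibrium(self):
        init = [0.1] * 10
        state = _initial_state(tuple(f"A{i}" for i in range(10)), init,
                               "dependent", "overdominance")
        nxt = step_overdominance(state, "dependent")
        assert nxt.survivor_fraction == pytest.approx(0.9, abs=1e-15)
        assert nxt.female_fraction == pytest.approx(1 / 1.9, abs=1e-15)

    def test_neutral_unequal_frequencies_equalize_in_one_step(self):
        state = _initial_state(("A1", "A2"), [0.3, 0.7], "neutral", "overdominance")
        nxt = step_overdominance(state, "neutral")
        np.testing.assert_allclose(nxt.combined_Z_frequencies, [0.5, 0.5], atol=1e-15)

    def test_single_allele_extinct(self):
        state = _initial_state(("A1", "A2"), [1.0, 0.0], "neutral", "overdominance")
        with pytest.raises(ExtinctionError):
            step_overdominance(step_overdominance(state, "neutral"), "neutral")


class TestRecombineGameteDistribution:
    def test_no_recombination_transmits_parentals(self):
        g = recombine_gamete_distribution({("1000", "0001"): 1.0}, 0.0, 4)
        assert g == {0b0001: 0.5, 0b1000: 0.5}

    def test_free_recombination_two_loci(self):
        g = recombine_gamete_distribution({("10", "01"): 1.0}, 0.5, 2)
        for mask in (0b00, 0b01, 0b10, 0b11):
            assert g[mask] == pytest.approx(0.25, abs=1e-15)

    def test_single_interval_crossover_algebra(self):
        g = recombine_gamete_distribution({("10", "01"): 1.0}, 0.1, 2)
        # '10' = mask 1, '01' = mask 2; recombinants '11' = 3 and '00' = 0
        assert g[1] == pytest.approx(0.45, abs=1e-15)
        assert g[2] == pytest.approx(0.45, abs=1e-15)
        assert g[3] == pytest.approx(0.05, abs=1e-15)
        assert g[0] == pytest.approx(0.05, abs=1e-15)

    def test_distribution_sums_to_one(self):
        g = recombine_gamete_distribution(
            {("110010", "001100"): 0.7, ("000000", "111111"): 0.3}, 0.07, 6)
        assert sum(g.values()) == pytest.approx(1.0, abs=1e-12)


class TestPseudoOverdominance:
    def test_single_locus_matches_recessive_lethal_closed_form(self):
        traj = PseudoOverdominanceModel(["1", "0"], sex_mode="neutral",
                                        initial_frequencies=[0.5, 0.5]).run(100)
        for t, state in enumerate(traj.states):
            q = state.combined_Z_frequencies[list(state.alleles).index("1")]
            assert q == pytest.approx(closed_form_recessive_lethal(0.5, t), abs=1e-12)

    def test_closed_form_values(self):
        assert closed_form_recessive_lethal(0.5, 0) == 0.5
        assert closed_form_recessive_lethal(0.5, 1) == pytest.approx(1 / 3, abs=1e-15)
        assert closed_form_recessive_lethal(0.5, 100) == pytest.approx(0.5 / 51, abs=1e-15)

    def test_harmless_haplotype_frequency_strictly_increases(self):
        haps = PseudoOverdominanceModel.default_haplotypes(10)
        traj = PseudoOverdominanceModel(haps, sex_mode="neutral",
                                        recombination_rate=0.0).run(30)
        harmless = traj.combined_frequency("0" * 9)
        assert np.all(np.diff(harmless) > 0)

    def test_disjoint_lethals_without_harmless_equals_overdominance(self):
        # pairwise-disjoint single lethals, no harmless haplotype, r = 0:
        # the viability pattern coincides with 4-allele overdominance
        haps = ["1000", "0100", "0010", "0001"]
        init = [0.4, 0.3, 0.2, 0.1]
        pseudo = PseudoOverdominanceModel(haps, sex_mode="dependent",
                                          initial_frequencies=init,
                                          recombination_rate=0.0).run(20)
        over = OverdominanceModel(4, sex_mode="dependent",
                                  initial_frequencies=init).run(20)
        for sp, so in zip(pseudo.states, over.states):
            freqs = dict(zip(sp.alleles, sp.combined_Z_frequencies))
            got = [freqs.get(h, 0.0) for h in haps]
            np.testing.assert_allclose(got, so.combined_Z_frequencies, atol=1e-12)
            assert sp.female_fraction == pytest.approx(so.female_fraction, abs=1e-12)

    def test_recombination_erodes_lethals_dependent_model(self):
        haps = PseudoOverdominanceModel.default_haplotypes(10)
        traj = PseudoOverdominanceModel(haps, sex_mode="dependent",
                                        recombination_rate=0.01).run(100)
        ff = traj.female_fractions()
        assert np.all(np.diff(ff) <= 1e-15)          # monotone decline
        assert ff[0] > 0.52 and ff[-1] > 0.5         # towards, never past, 1:1
        assert ff[-1] < ff[0]


class TestTrajectories:
    def test_two_allele_overdominance_preserves_frequencies(self):
        traj = OverdominanceModel(2, sex_mode="dependent",
                                  initial_frequencies=[0.5, 0.5]).run(100)
        assert len(traj) == 101
        for state in traj.states:
            np.testing.assert_allclose(state.combined_Z_frequencies, [0.5, 0.5],
                                       atol=1e-12)

    def test_frequencies_renormalized_every_generation(self):
        traj = run_scenario("fig3b")["pseudooverdominance_dependent"]
        for state in traj.states:
            assert abs(state.combined_Z_frequencies.sum() - 1.0) < 1e-12
            assert abs(state.maternal_Z_frequencies.sum() - 1.0) < 1e-12

    def test_sex_neutral_female_fraction_always_half(self):
        traj = OverdominanceModel(5, sex_mode="neutral").run(20)
        assert np.all(traj.female_fractions() == 0.5)

    def test_sex_dependent_female_fraction_identity(self):
        traj = OverdominanceModel(10, sex_mode="dependent").run(20)
        np.testing.assert_allclose(
            traj.female_fractions(), 1.0 / (1.0 + traj.survivor_fractions()),
            atol=1e-15)

    def test_neutral_and_dependent_identical_at_symmetric_init(self):
        n = OverdominanceModel(10, sex_mode="neutral").run(50)
        d = OverdominanceModel(10, sex_mode="dependent").run(50)
        for sn, sd in zip(n.states, d.states):
            np.testing.assert_allclose(sn.combined_Z_frequencies,
                                       sd.combined_Z_frequencies, atol=1e-12)

    def test_varied_init_stays_positive_and_converges(self):
        traj = run_scenario("fig3c", generations=2000)["overdominance_varied_init"]
        freqs = np.array([s.combined_Z_frequencies for s in traj.states])
        assert (freqs > 0).all()  # no allele is ever lost
        # per-generation movement shrinks monotonically in the long run and
        # the trajectory settles at the symmetric fixed point 1/K
        step = np.abs(np.diff(freqs, axis=0)).max(axis=1)
        assert step[-1] < step[100] < step[1]
        np.testing.assert_allclose(traj.states[-1].combined_Z_frequencies,
                                   0.1, atol=1e-6)

    def test_trajectory_frame_layout(self):
        traj = OverdominanceModel(2).run(5)
        f = traj.to_frame()
        assert list(f["t"]) == list(range(6))
        assert {"survivor_fraction", "female_fraction", "freq_A1"} <= set(f.columns)

    def test_initial_state_recorded(self):
        traj = OverdominanceModel(4, initial_frequencies=[0.4, 0.3, 0.2, 0.1]).run(3)
        np.testing.assert_allclose(traj.states[0].maternal_Z_frequencies,
                                   [0.4, 0.3, 0.2, 0.1])


class TestModelSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(model="overdominance", n_alleles=1),
        dict(model="pseudooverdominance", haplotypes=("10", "10")),
        dict(model="pseudooverdominance", haplotypes=("10", "0")),
        dict(model="overdominance", n_alleles=2, initial_frequencies=(0.6, 0.6)),
        dict(model="pseudooverdominance", haplotypes=("1", "0"),
             recombination_rate=0.7),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)

    def test_extinction_reports_generation(self):
        spec = ModelSpec(model="pseudooverdominance", sex_mode="neutral",
                         haplotypes=("1",) * 1 + ("0",), generations=5,
                         initial_frequencies=(1.0, 0.0), recombination_rate=0.0)
        with pytest.raises(ExtinctionError):
            run_trajectory(spec)
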