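"""Generator determinism, telegraph statistics, and planted ground truth."""

import numpy as np
import pytest

from loopscan import occupancy
from loopscan.errors import ScenarioError
from loopscan.synthetic import (
    ContactPairScenario,
    ContactScenario,
    SequenceScenario,
    aac_like,
    effective_sample_size,
    gen_contact_trajectory,
    gen_family,
    gen_tripartite_sequence,
    simulate_telegraph,
)


class TestContactGenerator:
    def test_fully_bound_pair_is_always_in_contact(self):
        scenario = ContactScenario(
            pairs=(ContactPairScenario(p=1.0, sigma_nm=0.0),), n_frames=50, seed=1
        )
        traj, truth = gen_contact_trajectory(scenario)
        assert truth.realized_occupancy(0) == 100.0
        assert occupancy(traj, truth.specs[0]) == 100.0

    def test_iid_occupancy_within_binomial_bound(self):
        n = 10_000
        scenario = ContactScenario(
            pairs=(ContactPairScenario(p=0.5, phi=0.0),), n_frames=n, seed=123
        )
        _, truth = gen_contact_trajectory(scenario)
        assert abs(truth.realized_occupancy(0) - 50.0) <= 300 * np.sqrt(0.25 / n)

    def test_same_seed_is_byte_identical(self):
        scenario = ContactScenario(
            pairs=(ContactPairScenario(p=0.4, phi=0.6),), n_frames=200, seed=77
        )
        t1, truth1 = gen_contact_trajectory(scenario)
        t2, truth2 = gen_contact_trajectory(scenario)
        assert t1.coordinates.tobytes() == t2.coordinates.tobytes()
        assert (truth1.states == truth2.states).all()

    def test_different_seeds_differ(self):
        mk = lambda s: gen_contact_trajectory(
            ContactScenario(pairs=(ContactPairScenario(p=0.5),), n_frames=100, seed=s)
        )[0]
        assert mk(1).coordinates.tobytes() != mk(2).coordinates.tobytes()

    @pytest.mark.parametrize(
        "pair",
        [
            ContactPairScenario(p=0.5, bound_nm=0.30, sigma_nm=0.02),  # bound too close
            ContactPairScenario(p=0.5, unbound_nm=0.35, sigma_nm=0.02),  # unbound too close
            ContactPairScenario(p=1.5),
            ContactPairScenario(p=0.5, phi=1.0),
        ],
    )
    def test_invalid_scenarios_rejected(self, pair):
        with pytest.raises(ScenarioError):
            ContactScenario(pairs=(pair,), n_frames=10, seed=0).validate()

    def test_duplicate_residue_numbers_rejected(self):
        scenario = ContactScenario(
            pairs=(
                ContactPairScenario(p=0.5, resid_a=7, resid_b=8),
                ContactPairScenario(p=0.5, resid_a=7, resid_b=9),
            ),
            n_frames=10,
            seed=0,
        )
        with pytest.raises(ScenarioError, match="used twice"):
            scenario.validate()


class TestTelegraph:
    @pytest.mark.parametrize("p,phi", [(0.3, 0.8), (0.67, 0.5), (0.5, 0.0)])
    def test_stationary_distribution_matches_closed_form(self, p, phi):
        rng = np.random.default_rng(99)
        n = 100_000
        states = simulate_telegraph(p, phi, n, rng)
        sigma = np.sqrt(p * (1 - p) / effective_sample_size(n, phi))
        assert abs(states.mean() - p) <= 4 * sigma

    def test_lag1_autocorrelation_matches_phi(self):
        rng = np.random.default_rng(5)
        states = simulate_telegraph(0.5, 0.7, 200_000, rng).astype(float)
        r = np.corrcoef(states[:-1], states[1:])[0, 1]
        assert r == pytest.approx(0.7, abs=0.02)


class TestSequenceGenerators:
    def test_planted_deg_letters_direct(self):
        truth = gen_tripartite_sequence(
            SequenceScenario(seed=3, deg_letters=("E", "D", "E"))
        )
        for d, letter in zip((1, 2, 3), ("E", "D", "E")):
            pos = truth.motif_starts[("[DE]G", d)]
            assert truth.sequence[pos - 1] == letter
            assert truth.sequence[pos] == "G"

    def test_motif_starts_are_non_overlapping(self):
        truth = gen_tripartite_sequence(SequenceScenario(seed=11))
        spans = []
        lengths = {"Px[DE]xx[KR]xRxQxQ": 12, "[YF]xG": 3, "DCxx[RK]": 5, "[DE]G": 2, "[YWF][KR]G": 3}
        for (motif, _), start in truth.motif_starts.items():
            spans.append((start, start + lengths[motif] - 1))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_alignment_is_gap_free_with_constant_offsets(self):
        truth = gen_tripartite_sequence(SequenceScenario(seed=1, domain_length=55))
        tmap = truth.triplet_map()
        for t in tmap.triplets:
            d1, d2, d3 = tmap.triplet_partners(t)
            assert (d2 - d1, d3 - d1) == (55, 110)

    def test_determinism(self):
        a = gen_tripartite_sequence(SequenceScenario(seed=10))
        b = gen_tripartite_sequence(SequenceScenario(seed=10))
        assert a.sequence == b.sequence

    def test_short_domains_rejected(self):
        with pytest.raises(ScenarioError, match="collide"):
            gen_tripartite_sequence(SequenceScenario(seed=0, domain_length=30))


class TestFamilyGenerator:
    def test_all_e_probs_give_all_e(self):
        truth = gen_family(SequenceScenario(seed=4, family_size=6, e_probs=(1, 1, 1)))
        assert (truth.table[["d1", "d2", "d3"]] == "E").all().all()

    def test_empirical_frequencies_within_binomial_bound(self):
        n = 500
        probs = (0.8, 0.3, 0.9)
        truth = gen_family(SequenceScenario(seed=21, family_size=n, e_probs=probs))
        for d, p in enumerate(probs, start=1):
            freq = (truth.table[f"d{d}"] == "E").mean()
            assert abs(freq - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_names_override(self):
        truth = gen_family(
            SequenceScenario(seed=2, family_size=2), names=["MTCH1", "OTHER"]
        )
        assert [i for i, _ in truth.entries] == ["MTCH1", "OTHER"]


class TestCarrierFixture:
    def test_sequence_honours_stated_identities(self):
        fx = aac_like()
        seq = fx.sequence
        expectations = {
            30: "R", 139: "R", 236: "R",  # capping arginines
            37: "V", 142: "A", 239: "M",  # hydrophobic plug
            38: "Q", 143: "D", 240: "Q",  # loop N-ends
            50: "Y", 153: "F", 250: "Y",  # beta-turn aromatics
            167: "D", 264: "E",           # [DE]G first residues
            232: "T",                     # theta reference
        }
        for pos, letter in expectations.items():
            assert seq[pos - 1] == letter, pos

    def test_rrrmmm_run(self):
        assert aac_like().sequence[233:239] == "RRRMMM"

    def test_fixture_is_deterministic(self):
        assert aac_like().sequence == aac_like().sequence
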