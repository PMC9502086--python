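"""[DE]G family survey: calls, exclusions, E frequencies, PFMs."""

import numpy as np
import pytest
from scipy.stats import entropy

from loopscan import synthetic
from loopscan.errors import AlignmentError
from loopscan.survey import (
    CHARGED_SECOND_POSITION,
    OUTSIDE_IMM,
    CarrierEntry,
    apply_exclusions,
    build_pfm,
    call_entries,
    e_frequency,
    locate_deg,
    survey_table,
)


def entry(ident, calls):
    return CarrierEntry(identifier=ident, sequence="", calls=calls)


class TestLocateDEG:
    def test_carrier_domains_2_and_3(self, carrier, carrier_elements):
        windows = [carrier_elements.range(d, "matrix_helix") for d in (1, 2, 3)]
        calls = locate_deg(carrier.sequence, windows)
        assert calls[1] == "D"  # D167
        assert calls[2] == "E"  # E264

    def test_planted_family_calls_recovered(self):
        truth = synthetic.gen_family(
            synthetic.SequenceScenario(seed=31, family_size=20, e_probs=(0.7, 0.2, 0.5))
        )
        entries = [CarrierEntry(i, s) for i, s in truth.entries]
        called = call_entries(entries, truth.deg_windows)
        for e, (_, row) in zip(called, truth.table.iterrows()):
            assert e.calls == (row.d1, row.d2, row.d3)

    def test_charged_second_position_flagged_as_other(self):
        # G replaced by lysine: no G-anchored candidate at the motif site
        seq = "AAAAAEKAAAA"
        with pytest.warns(UserWarning):
            calls = locate_deg(seq, [(1, 11), (1, 11), (1, 11)])
        assert calls == ("other", "other", "other")

    def test_candidate_nearest_c_end_wins(self):
        seq = "AADGAAAAEGAA"
        calls = locate_deg(seq, [(1, 12), (1, 12), (1, 12)])
        assert calls[0] == "E"  # EG at 9-10 beats DG at 3-4

    def test_wrong_window_count_rejected(self):
        with pytest.raises(ValueError):
            locate_deg("AAEG", [(1, 4)])


class TestApplyExclusions:
    def test_reference_counts_53_to_46(self):
        names = list(OUTSIDE_IMM) + list(CHARGED_SECOND_POSITION)
        names += [f"MC{i:03d}" for i in range(53 - len(names))]
        truth = synthetic.gen_family(
            synthetic.SequenceScenario(seed=8, family_size=53), names=names
        )
        entries = [CarrierEntry(i, s) for i, s in truth.entries]
        retained, excluded = apply_exclusions(entries)
        assert len(entries) == 53
        assert len(retained) == 46
        assert len(excluded) == 7

    def test_empty_lists_are_identity(self):
        entries = [entry("A", ("E", "D", "E")), entry("B", ("D", "D", "D"))]
        retained, excluded = apply_exclusions(entries, (), ())
        assert retained == entries
        assert excluded == []

    def test_entry_on_both_lists_excluded_once_with_both_flags(self):
        entries = [entry("DUAL", ("E", "E", "E"))]
        retained, excluded = apply_exclusions(entries, ("DUAL",), ("DUAL",))
        assert retained == []
        assert len(excluded) == 1
        assert set(excluded[0].flags) == {"outside-IMM", "charged-second-position"}

    def test_missing_listed_name_warns(self):
        with pytest.warns(UserWarning, match="MTCH1"):
            apply_exclusions([entry("A", ("E", "E", "E"))])

    def test_no_entry_lost(self):
        entries = [entry(f"C{i}", ("E", "D", "E")) for i in range(10)]
        retained, excluded = apply_exclusions(entries, ("C3",), ("C7",))
        assert len(retained) + len(excluded) == len(entries)
        assert {e.identifier for e in retained} | {e.identifier for e in excluded} == {
            e.identifier for e in entries
        }


class TestEFrequency:
    def test_direct_count(self):
        table = e_frequency([entry("A", ("E", "D", "E")), entry("B", ("E", "E", "E"))])
        assert table.loc[0, "domain1_E_freq"] == pytest.approx(1.0)
        assert table.loc[0, "domain2_E_freq"] == pytest.approx(0.5)
        assert table.loc[0, "domain3_E_freq"] == pytest.approx(1.0)

    def test_all_d_family_is_zero(self):
        table = e_frequency([entry(str(i), ("D", "D", "D")) for i in range(5)])
        for d in (1, 2, 3):
            assert table.loc[0, f"domain{d}_E_freq"] == 0.0

    def test_planted_frequencies_recovered_exactly(self):
        truth = synthetic.gen_family(
            synthetic.SequenceScenario(seed=5, family_size=40, e_probs=(0.9, 0.1, 0.5))
        )
        entries = call_entries(
            [CarrierEntry(i, s) for i, s in truth.entries], truth.deg_windows
        )
        table = e_frequency(entries)
        for d in (1, 2, 3):
            planted = (truth.table[f"d{d}"] == "E").mean()
            assert table.loc[0, f"domain{d}_E_freq"] == pytest.approx(planted)

    def test_group_stratification(self):
        entries = [entry("A", ("E", "D", "D")), entry("B", ("D", "D", "D"))]
        table = e_frequency(entries, groups={"A": "g1", "B": "g2"})
        assert set(table.group) == {"g1", "g2"}
        assert table.set_index("group").loc["g1", "domain1_E_freq"] == 1.0


class TestPFM:
    def test_conserved_column_has_full_information(self):
        pfm = build_pfm(["A"] * 10)
        assert pfm.information[0] == pytest.approx(np.log2(20), abs=1e-9)

    def test_uniform_column_has_zero_information(self):
        pfm = build_pfm([aa for aa in "ACDEFGHIKLMNPQRSTVWY"])
        assert pfm.information[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_entropy_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFG-"), 30)) for _ in range(25)]
        pfm = build_pfm(seqs)
        for pos in range(30):
            col = [s[pos] for s in seqs if s[pos] != "-"]
            if not col:
                continue
            _, counts = np.unique(col, return_counts=True)
            expected = np.log2(20) - entropy(counts / counts.sum(), base=2)
            assert pfm.information[pos] == pytest.approx(expected, abs=1e-9)

    def test_column_counts_sum_to_sequence_count(self, rng):
        seqs = ["".join(rng.choice(list("ACD-"), 12)) for _ in range(9)]
        pfm = build_pfm(seqs)
        sums = pfm.counts.sum(axis=0)
        assert (sums == 9).all()

    def test_information_bounds(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 15)) for _ in range(8)]
        pfm = build_pfm(seqs)
        assert (pfm.information >= -1e-12).all()
        assert (pfm.information <= np.log2(20) + 1e-12).all()

    def test_ragged_alignment_rejected(self):
        with pytest.raises(AlignmentError, match="ragged"):
            build_pfm(["AAA", "AA"])


class TestSurveyTable:
    def test_retained_and_excluded_all_present(self):
        entries = [entry("A", ("E", "D", "E")), entry("MTCH1", ("D", "D", "D"))]
        retained, excluded = apply_exclusions(entries, ("MTCH1",), ())
        table = survey_table(retained, excluded)
        assert set(table.carrier) == {"A", "MTCH1"}
        assert table.set_index("carrier").loc["MTCH1", "exclusion"] == "outside-IMM"
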