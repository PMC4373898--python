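"""Motif engine: pattern compilation, CCM scanning, cohort screening."""

import itertools

import numpy as np
import pytest

from cotscan.core import DEFAULT_SCHEME, STANDARD_AA, ResidueClassScheme, ValidationError
from cotscan.motif import (
    FlankRule,
    PatternSyntaxError,
    ccm_pattern_family,
    compile_pattern,
    find_pattern,
    scan_sequence,
    screen_cohort,
)
from cotscan.synthetic import GeneratorConfig, generate_sas


class TestCompilePattern:
    def test_three_element_pattern(self):
        p = compile_pattern("[GASTC](2)-x(2,3)-[GASTC](1,2)")
        assert [(lo, hi) for _, lo, hi in p.elements] == [(2, 2), (2, 3), (1, 2)]
        assert p.elements[0][0] == frozenset("GASTC")
        assert p.elements[1][0] == STANDARD_AA

    def test_negated_set_is_complement_over_20(self):
        p = compile_pattern("{GASTC}(2)")
        assert p.elements[0][0] == STANDARD_AA - frozenset("GASTC")
        assert len(p.elements[0][0]) == 15

    @pytest.mark.parametrize(
        "bad", ["[GASTC](3,2)", "[GAST", "[GASTC](0)", "", "[J]", "[GASTC]--x"]
    )
    def test_malformed_patterns_raise(self, bad):
        with pytest.raises(PatternSyntaxError):
            compile_pattern(bad)

    def test_find_pattern_greedy_spans(self):
        p = compile_pattern("K-[GA](1,2)")
        assert find_pattern("KGGL", p) == [(1, 3)]


class TestFamily:
    def test_family_has_12_concrete_variants(self, family):
        assert len(family) == 12
        geometries = {
            (
                sum(lo for (_, lo, _), role in zip(p.elements, p.roles) if role == "separator"),
                sum(lo for (_, lo, _), role in zip(p.elements, p.roles) if role == "patch2"),
                p.flank_rule,
            )
            for p in family
        }
        assert len(geometries) == 12

    def test_empty_flank_set_rejected(self):
        with pytest.raises(ValidationError):
            ccm_pattern_family(
                ResidueClassScheme(small=frozenset("GASTC"), bulky=frozenset("LIV"), flank=frozenset())
            )

    def test_both_required_rule_gives_4_variants(self, scheme):
        assert len(ccm_pattern_family(scheme, FlankRule.BOTH_REQUIRED)) == 4


class TestScanSequence:
    def test_kgglla_match_anatomy(self, family):
        (m,) = scan_sequence("KGGLLA", family)
        assert (m.start, m.end) == (1, 6)
        assert m.left_flank_pos == 1 and m.right_flank_pos is None
        assert m.patch1_span == (2, 3)
        assert m.separator_span == (4, 5)
        assert m.patch2_span == (6, 6)

    def test_no_flank_no_match(self, family):
        assert scan_sequence("GGLLA", family) == []

    def test_empty_sequence_raises(self, family):
        with pytest.raises(ValidationError):
            scan_sequence("", family)

    def test_region_out_of_bounds_raises(self, family):
        with pytest.raises(ValidationError):
            scan_sequence("KGGLLA", family, region=(2, 7))

    def test_region_restricts_flank_too(self, family):
        # Without position 1 in the region the K flank cannot be used.
        assert scan_sequence("KGGLLA", family, region=(2, 6)) == []

    def test_shorter_separator_preferred(self, family):
        # KGG LLL A: separator could be LL (patch2 L? no) — build a case where
        # both sep=2 (patch2 at 6) and sep=3 (patch2 at 7) parse.
        seq = "KGGLLAA"
        (m,) = scan_sequence(seq, family)
        assert m.separator_span == (4, 5)
        assert m.patch2_span == (6, 7)  # longest patch2 at the short separator

    def test_verbose_reports_alternatives(self, family):
        alts = scan_sequence("KGGLLAA", family, verbose=True)
        assert len(alts) > 1

    def test_ambiguous_residues_never_match(self, family):
        # X belongs to no residue class, so it breaks any required element.
        assert scan_sequence("KGXLLA", family) == []


class TestOracleEquivalence:
    """scan_sequence must agree exactly with the brute-force definition."""

    def _assert_same(self, seq, family, oracle_scan):
        got = [
            {
                "patch1": m.patch1_span,
                "separator": m.separator_span,
                "patch2": m.patch2_span,
                "left_flank": m.left_flank_pos,
                "right_flank": m.right_flank_pos,
            }
            for m in scan_sequence(seq, family)
        ]
        assert got == oracle_scan(seq), seq

    def test_exhaustive_small_alphabet(self, family, oracle_scan):
        for length in range(5, 8):
            for letters in itertools.product("GLKA", repeat=length):
                self._assert_same("".join(letters), family, oracle_scan)

    def test_sampled_longer_sequences(self, family, oracle_scan):
        rng = np.random.default_rng(2024)
        alphabet = np.array(list("GLKA"))
        for _ in range(3000):
            length = int(rng.integers(8, 13))
            seq = "".join(rng.choice(alphabet, size=length))
            self._assert_same(seq, family, oracle_scan)

    def test_sampled_full_alphabet(self, family, oracle_scan):
        rng = np.random.default_rng(7)
        alphabet = np.array(sorted(STANDARD_AA))
        for _ in range(2000):
            length = int(rng.integers(5, 16))
            seq = "".join(rng.choice(alphabet, size=length))
            self._assert_same(seq, family, oracle_scan)


def test_monotonicity_enlarging_small_set(family):
    """With the separator set held fixed, growing the small set can only
    add matched sequences in a fixed cohort."""
    bulky = frozenset("LIVFMWP")
    base = ResidueClassScheme(frozenset("GAST"), bulky, DEFAULT_SCHEME.flank, "base")
    bigger = ResidueClassScheme(frozenset("GASTC"), bulky, DEFAULT_SCHEME.flank, "big")
    even_bigger = ResidueClassScheme(frozenset("GASTCDN"), bulky, DEFAULT_SCHEME.flank, "bigger")
    records, _ = generate_sas(150, GeneratorConfig(seed=11), motif_prevalence=0.3)
    counts = []
    for sch in (base, bigger, even_bigger):
        fam = ccm_pattern_family(sch)
        counts.append(
            sum(bool(scan_sequence(r.full_sequence, fam)) for r in records)
        )
    assert counts == sorted(counts)


class TestScreenCohort:
    def test_planted_cohort_counts(self, family):
        with_motif, _ = generate_sas(2, GeneratorConfig(seed=1), motif_prevalence=1.0, prefix="W")
        without, _ = generate_sas(1, GeneratorConfig(seed=2), motif_prevalence=0.0, prefix="N")
        # Guard: the no-motif record must not carry an accidental match.
        summary = screen_cohort(with_motif + without, family)
        counts = summary.counts()
        assert counts["with"] >= 2 and counts["with"] + counts["without"] == 3

    def test_empty_cohort(self, family):
        summary = screen_cohort([], family)
        assert summary.counts() == {"with": 0, "without": 0}
        assert summary.n_skipped == 0

    def test_poly_l_with_flank_never_matches(self, family):
        from cotscan.core import ProteinClass, SignalSequenceRecord, SignalType

        records = [
            SignalSequenceRecord(
                accession=f"L{i}",
                full_sequence="K" + "L" * 20,
                protein_class=ProteinClass.MEMBRANE,
                signal_type=SignalType.SAS,
                signal_start=2,
                signal_end=21,
            )
            for i in range(3)
        ]
        summary = screen_cohort(records, family)
        assert summary.counts() == {"with": 0, "without": 3}

    def test_missing_boundaries_skipped(self, family):
        from cotscan.core import ProteinClass, SignalSequenceRecord, SignalType

        rec = SignalSequenceRecord(
            accession="NB",
            full_sequence="KGGLLA",
            protein_class=ProteinClass.MEMBRANE,
            signal_type=SignalType.SAS,
        )
        summary = screen_cohort([rec], family)
        assert summary.n_skipped == 1
        assert summary.rows[0].skipped


def test_planted_motif_recall_is_total(family):
    """Every planted motif is found at its planted first-patch position:
    zero false negatives across 1000 independently seeded sequences."""
    records, truth = generate_sas(1000, GeneratorConfig(seed=99), motif_prevalence=1.0)
    for rec in records:
        planted = truth[rec.accession]
        region = (
            max(1, rec.signal_start - 2),
            min(len(rec.full_sequence), rec.signal_end + 2),
        )
        matches = scan_sequence(rec.full_sequence, family, region=region)
        assert any(m.patch1_start == planted.patch1_start for m in matches), rec.accession
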