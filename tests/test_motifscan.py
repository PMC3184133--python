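import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtcre import (PWM, parse_matrix_library, scan_group, scan_promoter,
                    simulate_promoters, write_matrix_library)
from emtcre.errors import ConfigurationError, ParseError
from emtcre.motifscan import MotifLibrary, default_library
from emtcre.promoters import PromoterRecord, revcomp
from emtcre.simulate import PromoterSimConfig

from conftest import consensus_pwm
from helpers import brute_force_scan

dna = st.text(alphabet="ACGT", min_size=30, max_size=80)


class TestLibraryParsing:
    def test_simple_dialect_consensus(self, tmp_path):
        (tmp_path / "m.txt").write_text(
            ">polyA\n10 0 0 0\n10 0 0 0\n10 0 0 0\n10 0 0 0\n")
        lib = parse_matrix_library(tmp_path / "m.txt")
        assert lib["polyA"].consensus == "AAAA"

    def test_round_trip_is_lossless(self, toy_library, tmp_path):
        write_matrix_library(toy_library, tmp_path / "lib.txt")
        back = parse_matrix_library(tmp_path / "lib.txt")
        assert back.names == toy_library.names
        for name in back.names:
            assert np.array_equal(back[name].counts, toy_library[name].counts)

    def test_bundled_mixed_dialect_directory(self):
        lib = default_library()
        assert len(lib) == 6
        assert {"SRY", "FTS-1", "Evi-1", "GC-Box", "Elk-1", "CREB"} == \
            set(lib.names)
        assert lib["FTS-1"].consensus == "TGATTGATCCT"

    def test_malformed_row_reports_line(self, tmp_path):
        (tmp_path / "bad.txt").write_text(">m\n1 2 3 4\n1 2 3\n")
        with pytest.raises(ParseError, match="line 3"):
            parse_matrix_library(tmp_path / "bad.txt")

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ConfigurationError):
            PWM("neg", np.full((4, 3), -1.0))
        with pytest.raises(ConfigurationError):
            PWM("bad-bg", np.ones((4, 3)), background=np.array([1, 1, 1, 1.0]))


class TestScanPromoter:
    def test_planted_literal_found_once_at_threshold_one(self):
        rng = np.random.default_rng(0)
        pwm = consensus_pwm("FTS-1", "TGATTGATCCT", strength=1000.0)
        seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)]))
        # scrub spurious occurrences, then plant one copy
        background = "".join(seq).replace("TGATTGATCCT", "TGATTGATCCA")
        planted_at = 123
        seq = background[:planted_at] + "TGATTGATCCT" + \
            background[planted_at + 11:]
        hits = scan_promoter(seq, pwm, threshold_fraction=1.0)
        plus = [h for h in hits if h.strand == "+"]
        assert [h.offset for h in plus] == [planted_at]

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(1)
        pwm = consensus_pwm("SRY", "AACAATG")
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        fwd = scan_promoter(seq, pwm, threshold_fraction=0.8)
        rev = scan_promoter(revcomp(seq), pwm, threshold_fraction=0.8)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted((len(seq) - h.offset - len(pwm), flip[h.strand],
                           round(h.score, 9)) for h in fwd)
        observed = sorted((h.offset, h.strand, round(h.score, 9))
                          for h in rev)
        assert mirrored == observed

    def test_all_n_promoter_has_no_hits(self):
        pwm = consensus_pwm("SRY", "AACAATG")
        rec = PromoterRecord("g", "N" * 100, tss_index=50)
        assert scan_promoter(rec, pwm) == []

    def test_offsets_are_tss_relative(self):
        pwm = consensus_pwm("X", "TGATTGATCCT", strength=1000.0)
        seq = "A" * 40 + "TGATTGATCCT" + "A" * 49
        rec = PromoterRecord("g", seq, tss_index=60)
        (hit,) = [h for h in scan_promoter(rec, pwm, 1.0) if h.strand == "+"]
        assert hit.offset == 40 - 60

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(dna)
    def test_matches_exhaustive_oracle(self, seq):
        pwm = consensus_pwm("SRY", "AACAATG", strength=9.0)
        thr = 0.7
        hits = scan_promoter(seq, pwm, threshold_fraction=thr)
        oracle = brute_force_scan(seq, pwm.log_odds, thr * pwm.max_score)
        got = sorted((h.offset, h.strand, round(h.score, 9)) for h in hits)
        want = sorted((o, s, round(sc, 9)) for o, s, sc in oracle)
        assert got == want

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(dna)
    def test_hit_count_monotone_in_threshold(self, seq):
        pwm = consensus_pwm("GC-Box", "GGGGCGGGG", strength=5.0)
        counts = [len(scan_promoter(seq, pwm, threshold_fraction=f))
                  for f in (0.6, 0.75, 0.9, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_palindromic_pwm_is_strand_symmetric(self):
        rng = np.random.default_rng(5)
        pwm = consensus_pwm("CREB", "TGACGTCA", strength=8.0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        hits = scan_promoter(seq, pwm, threshold_fraction=0.75)
        plus = {h.offset for h in hits if h.strand == "+"}
        minus = {h.offset for h in hits if h.strand == "-"}
        assert plus == minus

    def test_short_promoter_rejected(self):
        pwm = consensus_pwm("SRY", "AACAATG")
        with pytest.raises(ConfigurationError):
            scan_promoter("ACG", pwm)


class TestScanGroup:
    def test_recovers_planted_sites(self, toy_library):
        cfg = PromoterSimConfig(n_genes=40, gc_content=0.5,
                                planted_freq={"FTS-1": 1.0, "GC-Box": 0.5},
                                seed=21)
        ps, truth = simulate_promoters(cfg, toy_library)
        hits = scan_group(ps, toy_library, threshold_fraction=0.95)
        found = {(r.gene_id, r.element, r.offset + ps[r.gene_id].tss_index)
                 for r in hits.itertuples()}
        planted = [(g, e, off) for (g, e), sites in truth.planted_sites.items()
                   for off, _ in sites]
        recall = np.mean([(g, e, o) in found for g, e, o in planted])
        assert recall >= 0.95

    def test_false_hit_rate_bounded_by_oracle(self, toy_library):
        cfg = PromoterSimConfig(n_genes=10, gc_content=0.5,
                                planted_freq={}, seed=22)
        ps, _ = simulate_promoters(cfg, toy_library)
        hits = scan_group(ps, toy_library, threshold_fraction=0.95)
        pwm = toy_library["FTS-1"]
        oracle_total = sum(
            len(brute_force_scan(r.sequence, pwm.log_odds,
                                 0.95 * pwm.max_score)) for r in ps)
        assert len(hits[hits["element"] == "FTS-1"]) == oracle_total

    def test_empty_library_gives_empty_table(self, toy_library):
        cfg = PromoterSimConfig(n_genes=3, planted_freq={}, seed=2)
        ps, _ = simulate_promoters(cfg, toy_library)
        hits = scan_group(ps, MotifLibrary([]))
        assert hits.empty
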