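import numpy as np
import pandas as pd
import pytest

from emtcre import (frequency_timecourse, simulate_promoters,
                    tabulate_frequencies, top_k_elements)
from emtcre.errors import ConfigurationError, DataError
from emtcre.motifscan import scan_group
from emtcre.simulate import PromoterSimConfig


def _hits(rows):
    return pd.DataFrame(rows, columns=["gene_id", "element", "offset",
                                       "strand", "score"])


class TestTabulateFrequencies:
    def test_clustered_elements_exceed_100_percent(self):
        genes = [f"g{i}" for i in range(10)]
        hits = _hits([(g, "FTS-1", o, "+", 1.0)
                      for g in genes for o in (-100, 200)])
        prof = tabulate_frequencies(hits, genes, "T6", "up")
        assert prof.iloc[0]["freq_percent"] == 200.0

    def test_zero_hits_is_zero_percent(self):
        prof = tabulate_frequencies(_hits([]), ["g1", "g2"], "T6", "up",
                                    elements=["SRY"])
        assert prof.iloc[0]["freq_percent"] == 0.0
        assert prof.iloc[0]["total_hits"] == 0

    def test_recovers_planted_frequency_ranking(self, toy_library):
        cfg = PromoterSimConfig(
            n_genes=200, gc_content=0.5, seed=31,
            planted_freq={"FTS-1": 2.0, "GC-Box": 0.5, "SRY": 0.1})
        ps, _ = simulate_promoters(cfg, toy_library)
        hits = scan_group(ps, toy_library, threshold_fraction=0.95)
        prof = tabulate_frequencies(hits, ps.gene_ids, "T6", "up",
                                    elements=toy_library.names)
        ranked = prof.sort_values("rank")["element"].tolist()
        assert ranked == ["FTS-1", "GC-Box", "SRY"]

    def test_empty_group_rejected(self):
        with pytest.raises(DataError, match="empty"):
            tabulate_frequencies(_hits([]), [], "T6", "up")

    def test_invariance_and_linearity(self):
        genes = ["g1", "g2", "g3"]
        rows = [("g1", "A", 0, "+", 1.0), ("g2", "A", 5, "-", 1.0),
                ("g1", "B", 9, "+", 1.0)]
        prof = tabulate_frequencies(_hits(rows), genes, "s", "up")
        shuffled = tabulate_frequencies(_hits(rows[::-1]), genes[::-1],
                                        "s", "up")
        pd.testing.assert_frame_equal(prof, shuffled)
        doubled = tabulate_frequencies(_hits(rows + rows), genes, "s", "up")
        assert np.array_equal(doubled["freq_percent"],
                              2 * prof["freq_percent"])

    def test_hit_conservation(self):
        genes = ["g1", "g2"]
        rows = [("g1", "A", 0, "+", 1.0), ("g2", "B", 1, "+", 1.0),
                ("g2", "A", 2, "-", 1.0), ("gX", "A", 3, "+", 1.0)]
        prof = tabulate_frequencies(_hits(rows), genes, "s", "up")
        in_group = sum(1 for r in rows if r[0] in genes)
        assert prof["total_hits"].sum() == in_group


class TestTopK:
    @staticmethod
    def _profile(freqs: dict[str, float], stage="T6", group="up"):
        hits = _hits([(f"g{i}", e, i, "+", 1.0)
                      for e, f in freqs.items()
                      for i in range(int(f))])
        return tabulate_frequencies(hits, [f"g{i}" for i in range(10)],
                                    stage, group, elements=list(freqs))

    def test_fewer_elements_than_k_warns(self):
        prof = self._profile({"A": 3, "B": 2, "C": 1})
        with pytest.warns(UserWarning, match="returning all"):
            tops = top_k_elements(prof, k=6)
        assert tops[("T6", "up")] == ["A", "B", "C"]

    def test_order_matches_sort_oracle(self):
        freqs = {"E1": 9, "E2": 3, "E3": 7, "E4": 1, "E5": 5}
        prof = self._profile(freqs)
        tops = top_k_elements(prof, k=3)
        oracle = sorted(freqs, key=lambda e: (-freqs[e], e))[:3]
        assert tops[("T6", "up")] == oracle

    def test_tie_at_rank_k_resolved_lexicographically(self):
        prof = self._profile({"B": 5, "A": 3, "C": 3})
        with pytest.warns(UserWarning, match="tie"):
            tops = top_k_elements(prof, k=2)
        assert tops[("T6", "up")] == ["B", "A"]

    def test_common_mode_intersects_stages(self):
        p1 = self._profile({"A": 5, "B": 4, "C": 1}, stage="T6")
        p2 = self._profile({"A": 5, "C": 4, "B": 1}, stage="T18")
        prof = pd.concat([p1, p2], ignore_index=True)
        tops = top_k_elements(prof, k=2, common=True)
        assert tops[("T6", "up")] == ["A"]
        assert tops[("T18", "up")] == ["A"]


class TestTimecourse:
    def test_constant_element_has_zero_trend(self):
        rows = []
        for s in ("T6", "T18", "T96"):
            rows.append(TestTopK._profile({"A": 4}, stage=s))
        tc = frequency_timecourse(pd.concat(rows, ignore_index=True),
                                  stage_order=["T6", "T18", "T96"])
        assert (tc["trend"] == 0.0).all()
        assert len(tc) == 3  # one element x three stages

    def test_declining_plant_yields_negative_trend(self, toy_library):
        rows = []
        for stage, freq in (("T6", 2.0), ("T96", 0.8)):
            cfg = PromoterSimConfig(n_genes=80, gc_content=0.5,
                                    planted_freq={"FTS-1": freq},
                                    seed=40 + len(rows))
            ps, _ = simulate_promoters(cfg, toy_library)
            hits = scan_group(ps, toy_library, threshold_fraction=0.95)
            rows.append(tabulate_frequencies(hits, ps.gene_ids, stage, "up",
                                             elements=["FTS-1"]))
        tc = frequency_timecourse(pd.concat(rows, ignore_index=True),
                                  stage_order=["T6", "T96"])
        assert (tc["trend"] < 0).all()

    def test_single_stage_rejected(self):
        prof = TestTopK._profile({"A": 2})
        with pytest.raises(ConfigurationError):
            frequency_timecourse(prof)

    def test_misaligned_stage_labels_rejected(self):
        p1 = TestTopK._profile({"A": 2}, stage="T6")
        p2 = TestTopK._profile({"B": 2}, stage="T18")
        prof = pd.concat([p1, p2], ignore_index=True)
        with pytest.raises(DataError, match="misaligned|missing"):
            frequency_timecourse(prof, stage_order=["T6", "T18"])
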