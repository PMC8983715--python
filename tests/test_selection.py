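"""Toggle-selection rules, fold change, enrichment report and the
cross-strategy merge — each checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from aptaselex import (CandidateRecord, FrequencyMatrix, SelectionThresholds,
                       enrichment_report, fold_change, merge_strategies,
                       toggle_candidates)

T = SelectionThresholds()


def matrix_from_counts(counts_b, counts_a, extracted_b, extracted_a):
    seqs = sorted(set(counts_b) | set(counts_a))
    counts = pd.DataFrame({
        "M8": [counts_b.get(s, 0) for s in seqs],
        "M8H2": [counts_a.get(s, 0) for s in seqs],
    }, index=seqs)
    extracted = pd.Series({"M8": extracted_b, "M8H2": extracted_a})
    return FrequencyMatrix(counts, extracted)


def brute_force_rules(matrix, t=T, preset="methods"):
    """Per-row if/else re-statement of the three rules (oracle)."""
    out = {}
    for seq in matrix.sequences:
        cb = matrix.counts.loc[seq, "M8"]
        fb = matrix.freq.loc[seq, "M8"]
        fa = matrix.freq.loc[seq, "M8H2"]
        fc = fa / max(fb, t.fold_floor)
        if cb == 0 and fa >= t.high_freq:
            out[seq] = "R1"
        elif preset == "methods" and fb > t.mid_freq and fa > t.min_detect \
                and fc > t.fold_rule2:
            out[seq] = "R2"
        elif preset == "results" and cb > 0 and fa >= t.high_freq \
                and fc >= t.fold_rule2:
            out[seq] = "R2"
        elif fb > t.high_freq and fc >= t.fold_rule3:
            out[seq] = "R3"
    return out


class TestFoldChange:
    def test_equal_frequencies(self):
        assert fold_change(1e-4, 1e-4) == 1.0

    def test_floor_convention_for_undetected(self):
        assert fold_change(0.0, 1e-4, floor=1e-6) == pytest.approx(100.0)

    def test_monotone_in_after(self):
        vals = [fold_change(1e-5, fa) for fa in (1e-6, 1e-5, 1e-4, 1e-3)]
        assert vals == sorted(vals)

    def test_invalid_floor(self):
        with pytest.raises(ValueError):
            fold_change(1e-5, 1e-4, floor=0.0)


class TestToggleCandidates:
    def test_empty_matrix(self):
        m = matrix_from_counts({}, {}, 10, 10)
        assert toggle_candidates(m, "M8", "M8H2") == []

    def test_hand_built_boundary_table(self):
        """Twelve rows exercising every rule and near-threshold boundary,
        at denominator 1e6 so frequencies are exact decimals."""
        E = 10**6
        rows = {
            "s01": (0, 100),     # R1: undetected -> 1e-4
            "s02": (0, 99),      # just below theta_H: no rule
            "s03": (5, 99),      # f_b = 5e-6 exactly: fails R2's strict >
            "s04": (6, 99),      # R2: 6e-6 -> 9.9e-5, FC 16.5 > 10
            "s05": (6, 60),      # FC = 10 exactly: fails strict >
            "s06": (6, 61),      # R2: FC just above 10
            "s07": (101, 202),   # R3: >1e-4 and exactly doubling (>=)
            "s08": (101, 201),   # FC < 2: no rule
            "s09": (100, 200),   # f_b = 1e-4 exactly: fails R3's strict >
            "s10": (101, 2000),  # satisfies R2 and R3 -> reported once, R2
            "s11": (0, 50),      # undetected, below theta_H: no rule
            "s12": (1, 100),     # R2: 1e-6 -> 1e-4? f_b=1e-6 fails > 5e-6
        }
        m = matrix_from_counts({k: v[0] for k, v in rows.items()},
                               {k: v[1] for k, v in rows.items()}, E, E)
        got = {c.sequence: c.rule_id for c in toggle_candidates(m, "M8", "M8H2")}
        assert got == {"s01": "R1", "s04": "R2", "s06": "R2",
                       "s07": "R3", "s10": "R2"}
        assert got == brute_force_rules(m)

    def test_oracle_equivalence_randomized(self, rng):
        """Randomized count tables (with threshold-boundary values mixed
        in) match the brute-force rule enumeration exactly."""
        special = [0, 1, 4, 5, 6, 50, 99, 100, 101, 200, 1000, 5000]
        for _ in range(50):
            n = int(rng.integers(5, 400))
            cb = {f"q{i}": int(rng.choice(special)) for i in range(n)}
            ca = {f"q{i}": int(rng.choice(special)) for i in range(n)}
            m = matrix_from_counts(cb, ca, 10**6, 10**6)
            got = {c.sequence: c.rule_id
                   for c in toggle_candidates(m, "M8", "M8H2")}
            assert got == brute_force_rules(m)

    def test_results_preset_oracle(self, rng):
        special = [0, 1, 5, 6, 50, 99, 100, 101, 1000, 5000]
        for _ in range(20):
            n = int(rng.integers(5, 200))
            cb = {f"q{i}": int(rng.choice(special)) for i in range(n)}
            ca = {f"q{i}": int(rng.choice(special)) for i in range(n)}
            m = matrix_from_counts(cb, ca, 10**6, 10**6)
            got = {c.sequence: c.rule_id
                   for c in toggle_candidates(m, "M8", "M8H2",
                                              preset="results")}
            assert got == brute_force_rules(m, preset="results")

    def test_each_sequence_reported_once_lowest_rule(self, rng):
        m = matrix_from_counts({"s": 101}, {"s": 2000}, 10**6, 10**6)
        out = toggle_candidates(m, "M8", "M8H2")
        assert len(out) == 1 and out[0].rule_id == "R2"

    def test_relaxing_thresholds_is_monotone(self, rng):
        cb = {f"q{i}": int(rng.integers(0, 300)) for i in range(100)}
        ca = {f"q{i}": int(rng.integers(0, 300)) for i in range(100)}
        m = matrix_from_counts(cb, ca, 10**5, 10**5)
        strict = {c.sequence for c in toggle_candidates(m, "M8", "M8H2", T)}
        relaxed = SelectionThresholds(high_freq=5e-5, mid_freq=2e-6,
                                      min_detect=5e-7, fold_rule2=5.0,
                                      fold_rule3=1.5)
        loose = {c.sequence
                 for c in toggle_candidates(m, "M8", "M8H2", relaxed)}
        assert strict <= loose

    def test_missing_cycle_errors(self):
        m = matrix_from_counts({"s": 1}, {"s": 1}, 10, 10)
        with pytest.raises(KeyError):
            toggle_candidates(m, "M8", "M9")

    def test_sorted_by_after_frequency(self, rng):
        cb = {f"q{i}": 0 for i in range(20)}
        ca = {f"q{i}": int(rng.integers(100, 10**4)) for i in range(20)}
        m = matrix_from_counts(cb, ca, 10**6, 10**6)
        out = toggle_candidates(m, "M8", "M8H2")
        freqs = [c.f_after for c in out]
        assert freqs == sorted(freqs, reverse=True)


class TestEnrichmentReport:
    def test_toy_counts_match_brute_force(self):
        E = 10**6
        cb = {"a": 0, "b": 0, "c": 10, "d": 500, "e": 3}
        ca = {"a": 5, "b": 0, "c": 400, "d": 600, "e": 49}
        m = matrix_from_counts(cb, ca, E, E)
        rep = enrichment_report(m, "M8", "M8H2", T, fold=16.0)
        # brute force: new = detected after, not before, fa > 1e-6
        new = sum(1 for s in ca if ca[s] > 0 and cb.get(s, 0) == 0
                  and ca[s] / E > 1e-6)
        exp = sum(1 for s in ca if ca[s] / E > 1e-6
                  and (ca[s] / E) / max(cb.get(s, 0) / E, 1e-6) > 16)
        assert rep["new_detected"] == new
        assert rep["expanded"] == exp

    def test_neutral_table_near_zero(self, rng):
        counts = {f"q{i}": int(rng.integers(90, 110)) for i in range(200)}
        m = matrix_from_counts(counts, counts, 10**5, 10**5)
        rep = enrichment_report(m, "M8", "M8H2")
        assert rep["new_detected"] == 0 and rep["expanded"] == 0

    def test_counts_non_increasing_in_epsilon(self, rng):
        cb = {f"q{i}": int(rng.integers(0, 50)) for i in range(300)}
        ca = {f"q{i}": int(rng.integers(0, 50)) for i in range(300)}
        m = matrix_from_counts(cb, ca, 10**6, 10**6)
        reps = [enrichment_report(m, "M8", "M8H2",
                                  SelectionThresholds(background=e))
                for e in (1e-7, 1e-6, 1e-5)]
        news = [r["new_detected"] for r in reps]
        exps = [r["expanded"] for r in reps]
        assert news == sorted(news, reverse=True)
        assert exps == sorted(exps, reverse=True)


def _cand(seq, strategy, f_after=1e-3):
    rule = "family" if strategy == "cluster" else "R1"
    return CandidateRecord(seq, strategy, rule, 0.0, f_after, 1.0)


class TestMergeStrategies:
    def test_disjoint_dissimilar_sets(self, rng):
        a = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(3)]
        b = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(3)]
        merged = merge_strategies([_cand(s, "cluster") for s in a],
                                  [_cand(s, "toggle") for s in b])
        assert all(not m.convergent for m in merged)
        assert len(merged) == 6

    def test_identical_sequence_in_both(self):
        s = "ACGT" * 10
        merged = merge_strategies([_cand(s, "cluster")], [_cand(s, "toggle")])
        assert len(merged) == 1
        assert set(merged[0].strategies) == {"cluster", "toggle"}
        assert merged[0].convergent

    def test_similar_pair_flagged(self):
        s = "ACGT" * 10
        s2 = "T" + s[1:]  # 39/40 identity
        merged = merge_strategies([_cand(s, "cluster")],
                                  [_cand(s2, "toggle")],
                                  identity_threshold=0.9)
        assert all(m.convergent for m in merged)

    def test_simulated_cross_reactive_convergence(self, small_sim,
                                                  small_matrix):
        """On the simulated toggle protocol, convergence flags land on the
        planted cross-reactive families' sequences."""
        from aptaselex import cluster_families, select_family_candidates
        _, libs, truth = small_sim
        fams = cluster_families(small_matrix, "M8H2", min_freq=1e-6)
        cl = select_family_candidates(fams, 1e-4)
        tg = toggle_candidates(small_matrix, "M8", "M8H2")
        merged = merge_strategies(cl, tg)
        fam_of = truth.family_id
        convergent_fams = {fam_of.get(m.sequence, -1) for m in merged
                          if m.convergent}
        # background is never flagged convergent
        assert -1 not in convergent_fams
        # the convergent set is dominated by planted cross-reactive families
        assert convergent_fams & set(truth.cross_reactive)
        top = max(merged, key=lambda m: m.f_after)
        assert fam_of.get(top.sequence, -1) in truth.cross_reactive
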