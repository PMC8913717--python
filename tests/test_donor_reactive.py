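"""donor_reactive: fold-change calling, tracking, delta tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allotrace.donor_reactive import (
    call_donor_reactive,
    delta_table,
    delta_summary,
    track_donor_reactive,
)
from allotrace.exceptions import ConfigError, ContractError

from conftest import build_repertoire


def make_pair(unstim_reads: dict, stim_reads: dict):
    unstim = build_repertoire(unstim_reads, condition="bulk")
    stim = build_repertoire(stim_reads, condition="stimulated")
    return unstim, stim


def fold_oracle(unstim_reads: dict, stim_reads: dict, threshold: float,
                total_u: int | None = None, total_s: int | None = None,
                min_stim: float = 2.0, include_absent: bool = True) -> set:
    """Brute-force recomputation of every fold on depth-normalized reads."""
    total_u = total_u or sum(unstim_reads.values())
    total_s = total_s or sum(stim_reads.values())
    depth = min(total_u, total_s)
    called = set()
    for key, s_reads in stim_reads.items():
        s_norm = s_reads * depth / total_s
        if key in unstim_reads:
            u_norm = unstim_reads[key] * depth / total_u
            if s_norm / u_norm >= threshold:
                called.add(key)
        elif include_absent and s_norm >= min_stim:
            called.add(key)
    return called


def called_nts(result) -> set:
    return {k[0] for k in result.keys}


class TestCallDonorReactive:
    def test_fold_exactly_five_is_called(self):
        # equal depths, unstim 2 vs stim 10 -> fold 5 (threshold at equality)
        unstim, stim = make_pair({"TGTAAA": 2, "TGTCCC": 98},
                                 {"TGTAAA": 10, "TGTCCC": 90})
        result = call_donor_reactive(unstim, stim, 5.0, absent_rule="exclude")
        assert called_nts(result) == {"TGTAAA"}

    def test_fold_below_threshold_not_called(self):
        unstim, stim = make_pair({"TGTAAA": 2, "TGTCCC": 98},
                                 {"TGTAAA": 9, "TGTCCC": 91})
        result = call_donor_reactive(unstim, stim, 5.0, absent_rule="exclude")
        assert called_nts(result) == set()

    def test_planted_folds_match_oracle(self):
        # 30-clonotype pair with planted folds including {1, 4.9, 5, 5.1, inf}
        unstim_reads = {f"TGTPLANT{i:02d}": 100 for i in range(29)}
        stim_reads = dict(unstim_reads)
        stim_reads["TGTPLANT00"] = 100     # fold 1
        stim_reads["TGTPLANT01"] = 490     # fold 4.9
        stim_reads["TGTPLANT02"] = 500     # fold 5.0
        stim_reads["TGTPLANT03"] = 510     # fold 5.1
        stim_reads["TGTABSENT"] = 5000     # absent in unstim (infinite fold)
        # pad unstim so depths are equal -> normalization is the identity
        unstim_reads["TGTPADDING"] = sum(stim_reads.values()) - sum(unstim_reads.values())
        unstim, stim = make_pair(unstim_reads, stim_reads)

        result = call_donor_reactive(unstim, stim, 5.0)
        expected = fold_oracle(unstim_reads, stim_reads, 5.0)
        assert called_nts(result) == expected
        assert {"TGTPLANT02", "TGTPLANT03", "TGTABSENT"} <= called_nts(result)
        assert "TGTPLANT01" not in called_nts(result)

    def test_monotone_in_threshold(self, rng):
        unstim_reads = {f"TGTK{i:03d}": int(rng.integers(1, 50)) for i in range(40)}
        stim_reads = {k: int(rng.integers(1, 400)) for k in unstim_reads}
        unstim, stim = make_pair(unstim_reads, stim_reads)
        previous = None
        for threshold in (1.5, 2, 3, 5, 8, 13, 50):
            called = called_nts(call_donor_reactive(unstim, stim, threshold))
            if previous is not None:
                assert called <= previous
            previous = called

    def test_normalized_vs_raw_mode(self):
        # stim sequenced twice as deep: raw folds inflate, normalized corrects
        unstim_reads = {"TGTAAA": 10, "TGTCCC": 90}
        stim_reads = {"TGTAAA": 60, "TGTCCC": 140}
        unstim, stim = make_pair(unstim_reads, stim_reads)
        raw = call_donor_reactive(unstim, stim, 5.0, mode="raw",
                                  absent_rule="exclude")
        norm = call_donor_reactive(unstim, stim, 5.0, mode="normalized",
                                   absent_rule="exclude")
        assert called_nts(raw) == {"TGTAAA"}       # raw fold 6
        assert called_nts(norm) == set()           # normalized fold 3
        expected = fold_oracle(unstim_reads, stim_reads, 5.0, include_absent=False)
        assert called_nts(norm) == expected

    def test_absent_rule_floor(self):
        unstim_reads = {"TGTCCC": 100}
        stim_reads = {"TGTCCC": 97, "TGTAAA": 2, "TGTGGG": 1}
        unstim, stim = make_pair(unstim_reads, stim_reads)
        included = call_donor_reactive(unstim, stim, 5.0, absent_rule="include",
                                       min_stim_reads=2.0)
        assert called_nts(included) == {"TGTAAA"}
        excluded = call_donor_reactive(unstim, stim, 5.0, absent_rule="exclude")
        assert called_nts(excluded) == set()

    def test_contract_errors(self):
        unstim, stim = make_pair({"TGTAAA": 5}, {"TGTAAA": 5})
        with pytest.raises(ConfigError):
            call_donor_reactive(unstim, stim, threshold=1.0)
        bad = build_repertoire({"TGTAAA": 5}, condition="stimulated", timepoint="M1")
        with pytest.raises(ContractError):
            call_donor_reactive(unstim, bad)
        with pytest.raises(ContractError):
            call_donor_reactive(stim, unstim)  # conditions swapped


class TestTracking:
    def test_empty_intersection(self):
        unstim, stim = make_pair({"TGTAAA": 1, "TGTCCC": 9},
                                 {"TGTAAA": 50, "TGTCCC": 9})
        reactive = call_donor_reactive(unstim, stim, 5.0)
        bulk = build_repertoire({"TGTGGG": 5, "TGTTTT": 5})
        record = track_donor_reactive(reactive, bulk)
        assert record.pct_clonotypes_donor_reactive == 0.0
        assert record.cum_freq_donor_reactive == 0.0

    def test_all_reactive(self):
        unstim, stim = make_pair({"TGTAAA": 1, "TGTCCC": 1, "TGTGGG": 98},
                                 {"TGTAAA": 40, "TGTCCC": 40, "TGTGGG": 20})
        reactive = call_donor_reactive(unstim, stim, 5.0)
        assert called_nts(reactive) == {"TGTAAA", "TGTCCC"}
        bulk = build_repertoire({"TGTAAA": 3, "TGTCCC": 7})
        record = track_donor_reactive(reactive, bulk)
        assert record.pct_clonotypes_donor_reactive == 100.0
        assert record.cum_freq_donor_reactive == pytest.approx(100.0)

    def test_constructed_fixture_1p5_2p1(self):
        # 200-clonotype bulk, 3 reactive keys carrying summed frequency
        # 21/1000 = 0.021 -> (pct, cum_freq) = (1.5, 2.1)
        reactive_nts = ["TGTR00", "TGTR01", "TGTR02"]
        bulk_reads = {nt: r for nt, r in zip(reactive_nts, [10, 6, 5])}
        remaining = 1000 - 21
        for i in range(197):
            bulk_reads[f"TGTB{i:03d}"] = remaining // 197 + (1 if i < remaining % 197 else 0)
        unstim = build_repertoire({**{nt: 1 for nt in reactive_nts}, "TGTPAD": 147},
                                  condition="bulk")
        stim = build_repertoire({nt: 50 for nt in reactive_nts},
                                condition="stimulated")
        reactive = call_donor_reactive(unstim, stim, 5.0, mode="raw")
        assert called_nts(reactive) == set(reactive_nts)
        bulk = build_repertoire(bulk_reads)
        record = track_donor_reactive(reactive, bulk)
        assert record.pct_clonotypes_donor_reactive == pytest.approx(1.5)
        assert record.cum_freq_donor_reactive == pytest.approx(2.1)


class TestDeltaTable:
    @staticmethod
    def records(rows):
        return pd.DataFrame(
            rows, columns=["patient_id", "group", "phenotype", "timepoint", "value"]
        )

    def test_simple_subtraction(self):
        table = self.records([
            ("P1", "ATLG", "CD4", "preTx", 1.0),
            ("P1", "ATLG", "CD4", "M1", 1.67),
        ])
        out = delta_table(table, value="value")
        assert out["delta"].iloc[0] == pytest.approx(0.67)

    def test_first_post_policy_prefers_m1(self):
        table = self.records([
            ("P1", "ATLG", "CD4", "M3", 9.0),
            ("P1", "ATLG", "CD4", "preTx", 1.0),
            ("P1", "ATLG", "CD4", "M1", 2.0),
        ])
        out = delta_table(table, value="value", post_policy="first_post")
        assert out["post"].iloc[0] == 2.0
        out = delta_table(table, value="value", post_policy="mean_post")
        assert out["post"].iloc[0] == pytest.approx(5.5)

    def test_zero_cohort(self):
        rows = []
        for p in ("P1", "P2", "P3"):
            for tp in ("preTx", "M1"):
                rows.append((p, "ATLG", "CD4", tp, 2.5))
        out = delta_table(self.records(rows), value="value")
        summary = delta_summary(out.assign(group="ATLG"))
        assert (out["delta"] == 0).all()
        assert summary["delta_mean"].iloc[0] == 0.0
        assert summary["delta_std"].iloc[0] == 0.0

    def test_missing_pretx_excluded(self):
        table = self.records([
            ("P1", "ATLG", "CD4", "M1", 2.0),
            ("P2", "ATLG", "CD4", "preTx", 1.0),
            ("P2", "ATLG", "CD4", "M1", 3.0),
        ])
        out = delta_table(table, value="value")
        assert list(out["patient_id"]) == ["P2"]

    def test_programmed_delta_recovered(self, rng):
        # n=5 patients, true delta 0.9, noise SD 0.2 on each measurement
        true_delta, noise_sd, n = 0.9, 0.2, 5
        n_sim = 200
        means = []
        for _ in range(n_sim):
            rows = []
            for i in range(n):
                pre = 1.0 + rng.normal(0, noise_sd)
                post = 1.0 + true_delta + rng.normal(0, noise_sd)
                rows.append((f"P{i}", "ATLG", "CD4", "preTx", pre))
                rows.append((f"P{i}", "ATLG", "CD4", "M1", post))
            out = delta_table(self.records(rows), value="value")
            means.append(out["delta"].mean())
        se = np.std(means) / np.sqrt(n_sim)
        assert abs(np.mean(means) - true_delta) <= 3 * se
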