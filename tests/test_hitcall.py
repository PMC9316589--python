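import numpy as np
import pandas as pd
import pytest

from chronoscreen.hitcall import (
    HitcallError,
    HitcallParams,
    guide_gates,
    prepare_datasets,
    run_hitcall,
)
from chronoscreen.library import NONTARGETING_LABEL, make_library
from chronoscreen.normalize import median_normalize
from chronoscreen.simulate import SimulationConfig, simulate_counts

from conftest import SCREEN_DESIGN, make_normalized, random_screen_values
from oracle import naive_hitcall


def normalized_from_rows(rows):
    """rows: list of (guide_id, gene, a, b, c, d)."""
    index = pd.Index([r[0] for r in rows], name="guide_id")
    values = pd.DataFrame(
        [r[2:] for r in rows],
        index=index,
        columns=["ZT16_vehicle", "ZT16_drug", "ZT28_vehicle", "ZT28_drug"],
    )
    genes = pd.Series([r[1] for r in rows], index=index, name="gene")
    return make_normalized(values, genes)


def ledger_as_oracle_dict(ledger):
    gt = ledger.guide_table
    out = {
        "index": set(gt.index),
        "a1": gt["a1"].to_dict(),
        "b1": gt["b1"].to_dict(),
        "c1": gt["c1"].to_dict(),
        "d1": gt["d1"].to_dict(),
        "r16": gt["r16"].to_dict(),
        "r28": gt["r28"].to_dict(),
        "guide_sets": {name: set(ledger.guide_set(name))
                       for name in ("A2", "B2", "C2", "D2")},
        "gene_sets": {},
    }
    for name in ("A2_primed", "B2_primed", "C2_primed", "D2_primed",
                 "A2_strong", "B2_strong", "C2_strong", "D2_strong",
                 "A3", "B3", "C3", "D3", "A4", "B4", "C4", "D4"):
        out["gene_sets"][name] = set(ledger.gene_set(name))
    return out


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"up_threshold": 0.9},
            {"down_threshold": 1.5},
            {"strong_up": 1.5},          # below up_threshold
            {"strong_down": 0.6},        # above down_threshold
            {"min_concordant_guides": 1},
            {"pseudocount": 0},
            {"zero_filter_scope": "sometimes"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(HitcallError):
            HitcallParams(**kwargs)


class TestPrepare:
    def test_all_zero_guide_removed_either_scope(self):
        for scope in ("any_sample", "all_samples"):
            norm = normalized_from_rows(
                [("k_1", "K", 5, 5, 5, 5), ("z_1", "Z", 0, 0, 0, 0)]
            )
            prepared = prepare_datasets(norm, HitcallParams(zero_filter_scope=scope))
            assert list(prepared.index) == ["k_1"]

    def test_single_zero_guide_scope_dependent(self):
        rows = [("k_1", "K", 5, 5, 5, 5), ("p_1", "P", 10, 20, 10, 0)]
        any_scope = prepare_datasets(
            normalized_from_rows(rows), HitcallParams(zero_filter_scope="any_sample")
        )
        assert "p_1" not in any_scope.index
        all_scope = prepare_datasets(
            normalized_from_rows(rows), HitcallParams(zero_filter_scope="all_samples")
        )
        assert all_scope.loc["p_1", "d1"] == pytest.approx(1.0)  # 0 + pseudocount

    def test_nontargeting_removed_regardless_of_counts(self):
        norm = normalized_from_rows(
            [("k_1", "K", 5, 5, 5, 5),
             ("ntc_1", NONTARGETING_LABEL, 50, 50, 50, 50)]
        )
        prepared = prepare_datasets(norm, HitcallParams())
        assert "ntc_1" not in prepared.index

    def test_missing_design_cell_named_in_error(self):
        norm = normalized_from_rows([("k_1", "K", 5, 5, 5, 5)])
        norm.values = norm.values.drop(columns="ZT28_drug")
        norm.design = SCREEN_DESIGN.drop(index="ZT28_drug")
        with pytest.raises(HitcallError, match="ZT28 x drug"):
            prepare_datasets(norm, HitcallParams())

    def test_empty_after_filter_raises(self):
        norm = normalized_from_rows([("z_1", "Z", 0, 0, 0, 0)])
        with pytest.raises(HitcallError, match="no guides remain"):
            prepare_datasets(norm, HitcallParams())


class TestGates:
    def test_threshold_inclusivity(self):
        # pseudocounted ratios: 20/10 = 2 exactly; 5/10 = 0.5 exactly; 10/10 = 1
        norm = normalized_from_rows(
            [("x_1", "X", 9, 19, 9, 9),   # r16 = 2.0 -> in B2 (inclusive)
             ("y_1", "Y", 9, 4, 9, 9),    # r16 = 0.5 -> not in A2 (strict)
             ("w_1", "W", 9, 9, 9, 9)]    # r16 = 1.0 -> neither
        )
        params = HitcallParams()
        gated = guide_gates(prepare_datasets(norm, params), params)
        assert bool(gated.loc["x_1", "in_b2"]) is True
        assert bool(gated.loc["y_1", "in_a2"]) is False
        assert not gated.loc["w_1", ["in_a2", "in_b2"]].any()
        # a ratio cannot satisfy both gates
        assert not (gated["in_a2"] & gated["in_b2"]).any()

    def test_strong_thresholds_inclusivity(self):
        norm = normalized_from_rows(
            [("s_1", "S", 9, 49, 9, 9),   # r16 = 5.0 -> strong (inclusive)
             ("t_1", "T", 9, 9, 49, 9)]   # r28 = 0.2 -> not strong (strict)
        )
        ledger = run_hitcall(norm)
        assert "S" in ledger.gene_set("B2_strong")
        assert "T" not in ledger.gene_set("C2_strong")


class TestWorkedExample:
    def test_full_hand_trace(self, toy_screen):
        ledger = run_hitcall(median_normalize(toy_screen))
        assert ledger.guide_set("B2") == {"g1_1", "g1_2", "g2_1"}
        assert ledger.guide_set("A2") == {"g3_1", "g3_2"}
        assert ledger.gene_set("B2_primed") == {"g1"}
        assert ledger.gene_set("B2_strong") == {"g2"}
        assert ledger.gene_set("B3") == {"g1", "g2"}
        assert ledger.gene_set("A2_primed") == {"g3"}
        assert ledger.gene_set("A2_strong") == set()
        assert ledger.gene_set("A3") == {"g3"}
        assert ledger.gene_set("D3") == {"g1"}
        assert ledger.gene_set("D2_primed") == {"g1"}
        assert ledger.gene_set("D2_strong") == set()
        assert ledger.gene_set("C3") == {"g3"}
        assert ledger.gene_set("C2_primed") == set()
        assert ledger.gene_set("C2_strong") == {"g3"}
        assert ledger.gene_set("B4") == {"g2"}
        assert ledger.gene_set("D4") == set()
        assert ledger.gene_set("A4") == set()
        assert ledger.gene_set("C4") == set()
        assert ledger.shared_resistance == {"g1"}
        assert ledger.shared_sensitivity == {"g3"}

    def test_admitting_rules_recorded(self, toy_screen):
        ledger = run_hitcall(median_normalize(toy_screen))
        assert ledger.gene_table.loc["g1", "b3_rule"] == "concordant"
        assert ledger.gene_table.loc["g2", "b3_rule"] == "strong"
        assert ledger.gene_table.loc["g3", "c3_rule"] == "strong"


class TestSetIdentities:
    def test_identical_per_timepoint_calls_empty_specific_sets(self):
        # same strong enrichment at both timepoints for gene E
        norm = normalized_from_rows(
            [("e_1", "E", 9, 99, 9, 99), ("k_1", "K", 9, 9, 9, 9)]
        )
        ledger = run_hitcall(norm)
        assert ledger.gene_set("B3") == ledger.gene_set("D3") == {"E"}
        assert ledger.gene_set("B4") == ledger.gene_set("D4") == set()

    def test_disjoint_calls_pass_through(self):
        norm = normalized_from_rows(
            [("e_1", "E", 9, 99, 9, 9), ("f_1", "F", 9, 9, 9, 99)]
        )
        ledger = run_hitcall(norm)
        assert ledger.gene_set("B4") == {"E"}
        assert ledger.gene_set("D4") == {"F"}

    def test_subset_and_disjointness_invariants(self):
        rng = np.random.default_rng(11)
        values, genes = random_screen_values(rng)
        ledger = run_hitcall(make_normalized(values, genes))
        assert ledger.gene_set("B4") <= ledger.gene_set("B3")
        assert ledger.gene_set("D4") <= ledger.gene_set("D3")
        assert not ledger.gene_set("B4") & ledger.gene_set("D4")
        assert not ledger.gene_set("A4") & ledger.gene_set("C4")


class TestOracleEquivalence:
    def test_matches_naive_reimplementation(self):
        """Pipeline vs straight-line loop oracle on 150 random matrices,
        across both zero-filter scopes and non-default thresholds."""
        rng = np.random.default_rng(42)
        param_choices = [
            HitcallParams(),
            HitcallParams(zero_filter_scope="all_samples"),
            HitcallParams(up_threshold=3.0, down_threshold=0.4,
                          strong_up=6.0, strong_down=0.15,
                          min_concordant_guides=3, pseudocount=0.5),
        ]
        for i in range(150):
            values, genes = random_screen_values(rng)
            params = param_choices[i % len(param_choices)]
            rows = [
                (gid, genes[gid], *values.loc[gid])
                for gid in values.index
            ]
            expected = naive_hitcall(rows, params)
            if not expected["index"]:
                continue
            ledger = run_hitcall(make_normalized(values, genes), params)
            got = ledger_as_oracle_dict(ledger)
            assert got["index"] == expected["index"]
            for col in ("a1", "b1", "c1", "d1", "r16", "r28"):
                for gid in expected["index"]:
                    assert got[col][gid] == expected[col][gid], (i, col, gid)
            assert got["guide_sets"] == expected["guide_sets"], i
            assert got["gene_sets"] == expected["gene_sets"], i


class TestMonotonicityAndPermutation:
    def test_raising_up_threshold_never_enlarges_enrichment_sets(self):
        rng = np.random.default_rng(7)
        values, genes = random_screen_values(rng)
        norm = make_normalized(values, genes)
        loose = run_hitcall(norm, HitcallParams(up_threshold=2.0, strong_up=5.0))
        tight = run_hitcall(norm, HitcallParams(up_threshold=3.0, strong_up=5.0))
        assert tight.guide_set("B2") <= loose.guide_set("B2")
        assert tight.gene_set("B2_primed") <= loose.gene_set("B2_primed")
        assert tight.gene_set("B3") <= loose.gene_set("B3")

    def test_lowering_down_threshold_never_enlarges_depletion_sets(self):
        rng = np.random.default_rng(8)
        values, genes = random_screen_values(rng)
        norm = make_normalized(values, genes)
        loose = run_hitcall(norm, HitcallParams(down_threshold=0.5))
        tight = run_hitcall(norm, HitcallParams(down_threshold=0.3))
        assert tight.guide_set("A2") <= loose.guide_set("A2")
        assert tight.gene_set("A3") <= loose.gene_set("A3")

    def test_guide_order_permutation_invariance(self):
        rng = np.random.default_rng(9)
        values, genes = random_screen_values(rng)
        norm = make_normalized(values, genes)
        perm = rng.permutation(values.index)
        norm_perm = make_normalized(values.loc[perm], genes.loc[perm])
        a = run_hitcall(norm)
        b = run_hitcall(norm_perm)
        for name in ("A3", "B3", "C3", "D3", "A4", "B4", "C4", "D4"):
            assert a.gene_set(name) == b.gene_set(name)


class TestOnSimulatedScreens:
    def test_no_nontargeting_label_in_any_output(self):
        cfg = SimulationConfig(library=make_library(200, 80, seed=1),
                               mean_coverage=100.0, n_zt16_specific=5,
                               n_zt28_specific=5, n_shared=2, seed=2)
        cm, _ = simulate_counts(cfg)
        ledger = run_hitcall(median_normalize(cm))
        assert NONTARGETING_LABEL not in set(ledger.guide_table["gene"])
        assert NONTARGETING_LABEL not in set(ledger.gene_table.index)

    def test_null_false_call_rate_matches_generative_oracle(self):
        """On null screens, the pipeline's gene false-call rate agrees with
        an independent Monte-Carlo estimate from the naive-loop oracle run
        on separately simulated screens (noisy regime so calls do occur)."""
        lib = make_library(100, 20, seed=3)

        def false_calls(seeds, use_oracle):
            total = 0
            for seed in seeds:
                cfg = SimulationConfig(
                    library=lib, mean_coverage=30.0, dispersion=0.3,
                    effect_multiplier=1.0, n_zt16_specific=0,
                    n_zt28_specific=0, n_shared=0, seed=seed,
                )
                cm, _ = simulate_counts(cfg)
                if use_oracle:
                    rows = [
                        (gid, cm.genes[gid], *cm.counts.loc[
                            gid, ["ZT16_vehicle", "ZT16_drug",
                                  "ZT28_vehicle", "ZT28_drug"]].astype(float))
                        for gid in cm.counts.index
                    ]
                    result = naive_hitcall(rows, HitcallParams())
                    sets = result["gene_sets"]
                    total += sum(len(sets[n]) for n in ("A4", "B4", "C4", "D4"))
                else:
                    ledger = run_hitcall(median_normalize(cm))
                    total += sum(
                        len(ledger.gene_set(n)) for n in ("A4", "B4", "C4", "D4")
                    )
            return total

        n_reps = 100
        pipeline_total = false_calls(range(1000, 1000 + n_reps), use_oracle=False)
        oracle_total = false_calls(range(5000, 5000 + n_reps), use_oracle=True)
        trials = n_reps * 100  # gene-level Bernoulli trials per arm
        p_pool = (pipeline_total + oracle_total) / (2 * trials)
        assert p_pool > 0, "regime must produce some false calls to compare"
        se = np.sqrt(2 * p_pool * (1 - p_pool) / trials)
        diff = abs(pipeline_total - oracle_total) / trials
        assert diff < 5 * se
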