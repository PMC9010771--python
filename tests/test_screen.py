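"""Screen orchestration: instrument selection, filters, hits, replication."""

import numpy as np
import pandas as pd
import pytest

from mrscreen import (
    ScreenConfig,
    SummaryStats,
    alternative_q_filter,
    phewas_crosscheck,
    replicate,
    run_screen,
    select_instruments,
    synth,
    tune_count_filter,
)
from mrscreen.screen import per_metabolite_seed


@pytest.fixture(scope="module")
def screen_fixture():
    return synth.make_screen_fixture(n_metabolites=40, n_causal=2,
                                     theta_causal=0.05, seed=17)


@pytest.fixture(scope="module")
def screen_result(screen_fixture):
    cfg = ScreenConfig(presso_sims=50, seed=1)
    return run_screen(screen_fixture.exposures, screen_fixture.outcome,
                      screen_fixture.panel, cfg)


class TestSelectInstruments:
    def test_no_snp_below_threshold_gives_empty(self, screen_fixture, fast_cfg):
        exp = screen_fixture.exposures[0]
        weak = SummaryStats(exp.trait_id,
                            exp.table.assign(p=0.5))
        inst = select_instruments(weak, screen_fixture.outcome,
                                  screen_fixture.panel, fast_cfg)
        assert len(inst) == 0

    def test_independent_instruments_all_retained(self, fast_cfg):
        truth = synth.make_truth(n_snps=12, theta=0.1,
                                 instrument_f_range=(200, 500), seed=23)
        panel = synth.make_panel(n_snps=12, block_size=1, ld_block_rho=0.0,
                                 palindromic_frac=0.0, seed=23)
        exp, out = synth.make_mr_pair(truth, panel=panel)
        inst = select_instruments(exp, out, panel, fast_cfg)
        assert len(inst) == 12

    def test_proxy_substituted_with_provenance(self, fast_cfg):
        panel = synth.make_panel(n_snps=10, block_size=2, ld_block_rho=0.99,
                                 palindromic_frac=0.0, n_samples=800, seed=29)
        truth = synth.make_truth(n_snps=10, theta=0.1, maf=panel.maf.clip(0.05, 0.5),
                                 instrument_f_range=(200, 500), seed=29)
        exp, out = synth.make_mr_pair(truth, panel=panel)
        # drop one selected instrument from the outcome, keep its block partner
        cand = select_instruments(exp, out, panel, fast_cfg)
        target = cand.table["rsid"].iloc[0]
        out2 = SummaryStats("y", out.table[out.table["rsid"] != target]
                            .reset_index(drop=True))
        inst = select_instruments(exp, out2, panel, fast_cfg)
        row = inst.table[inst.table["rsid"] == target]
        prov = [p for p in inst.provenance if p.get("action") == "proxy"]
        if len(row):  # proxy found (r2 >= 0.9 in the same LD block)
            assert row["proxy_of"].iloc[0] is not None
            assert prov and prov[0]["rsid"] == target
        else:
            assert any(p.get("reason") == "no_proxy_above_threshold"
                       for p in inst.provenance)


class TestRunScreen:
    def test_requires_two_exposures(self, screen_fixture, fast_cfg):
        with pytest.raises(ValueError):
            run_screen(screen_fixture.exposures[:1], screen_fixture.outcome,
                       screen_fixture.panel, fast_cfg)

    def test_planted_causal_recovered(self, screen_fixture, screen_result):
        assert set(screen_fixture.causal_ids) <= set(screen_result.hits)

    def test_hits_respect_bonferroni(self, screen_result):
        rows = screen_result.rows
        hits = rows[rows["exposure_id"].isin(screen_result.hits)]
        assert (hits["p"] < screen_result.bonferroni_alpha).all()
        assert hits["passed_filter"].all()

    def test_count_filter_bounds(self, screen_result, screen_fixture):
        cfg = screen_result.config
        rows = screen_result.rows
        passing = rows[rows["passed_filter"]]
        assert passing["L"].between(cfg.min_snps, cfg.max_snps).all()
        failing = rows[~rows["passed_filter"]]
        assert (~failing["L"].between(cfg.min_snps, cfg.max_snps)).all()

    def test_L5_excluded_from_passing(self, screen_result):
        small = screen_result.rows[screen_result.rows["L"] == 5]
        if len(small):
            assert not small["passed_filter"].any()

    def test_determinism(self, screen_fixture):
        cfg = ScreenConfig(presso_sims=20, seed=5)
        r1 = run_screen(screen_fixture.exposures, screen_fixture.outcome,
                        screen_fixture.panel, cfg)
        r2 = run_screen(screen_fixture.exposures, screen_fixture.outcome,
                        screen_fixture.panel, cfg)
        pd.testing.assert_frame_equal(r1.rows, r2.rows)
        assert r1.hits == r2.hits

    def test_row_independence(self, screen_fixture):
        """Removing one non-hit metabolite leaves other rows unchanged."""
        cfg = ScreenConfig(presso_sims=20, seed=5)
        full = run_screen(screen_fixture.exposures, screen_fixture.outcome,
                          screen_fixture.panel, cfg)
        drop_id = full.rows["exposure_id"].iloc[-1]
        subset = [e for e in screen_fixture.exposures if e.trait_id != drop_id]
        part = run_screen(subset, screen_fixture.outcome, screen_fixture.panel, cfg)
        merged = full.rows[full.rows["exposure_id"] != drop_id].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            merged[["exposure_id", "L", "theta", "se", "p"]],
            part.rows[["exposure_id", "L", "theta", "se", "p"]])

    def test_per_metabolite_seed_stable(self):
        assert per_metabolite_seed(1, "met001") == per_metabolite_seed(1, "met001")
        assert per_metabolite_seed(1, "met001") != per_metabolite_seed(2, "met001")


class TestFilters:
    def test_tune_count_filter_prefers_calibrated_bounds(self, rng):
        # uniform p for mid L, inflated p for small L
        L = np.concatenate([np.full(60, 3), rng.integers(6, 15, 200)])
        p = np.concatenate([rng.uniform(0, 0.01, 60), rng.uniform(0, 1, 200)])
        rows = pd.DataFrame({"L": L, "p": p})
        lo, hi = tune_count_filter(rows, [(2, 20), (6, 14), (6, 20)])
        assert lo >= 6

    def test_tune_single_candidate_returned(self, rng):
        rows = pd.DataFrame({"L": rng.integers(6, 15, 50),
                             "p": rng.uniform(0, 1, 50)})
        assert tune_count_filter(rows, [(6, 14)]) == (6, 14)

    def test_tune_ties_prefer_widest(self, rng):
        p = rng.uniform(size=300)
        rows = pd.DataFrame({"L": np.full(300, 10), "p": p})
        # identical passing sets -> identical lambda -> widest interval wins
        assert tune_count_filter(rows, [(9, 11), (6, 14)]) == (6, 14)

    def test_tune_all_too_small_errors(self):
        rows = pd.DataFrame({"L": [10, 10], "p": [0.5, 0.5]})
        with pytest.raises(ValueError):
            tune_count_filter(rows, [(6, 14)])

    def test_q_filter_rules(self):
        rows = pd.DataFrame({
            "L": [6, 6, 10, 4],
            "Q_p": [0.04, 0.5, 0.06, 0.5],
            "p": [0.1] * 4,
        })
        kept = alternative_q_filter(rows)
        assert list(kept.index) == [1, 2]

    def test_q_filter_equals_set_oracle(self, screen_result):
        rows = screen_result.rows
        kept = alternative_q_filter(rows)
        oracle = {r.exposure_id for r in rows.itertuples()
                  if r.L >= 6 and r.Q_p > 0.05}
        assert set(kept["exposure_id"]) == oracle


class TestPhewasCrosscheck:
    def test_no_cross_association_keeps_estimate(self, screen_fixture, fast_cfg):
        hit = screen_fixture.causal_ids[0]
        exp = next(e for e in screen_fixture.exposures if e.trait_id == hit)
        inst = select_instruments(exp, screen_fixture.outcome,
                                  screen_fixture.panel, fast_cfg)
        res = phewas_crosscheck(hit, inst, screen_fixture.exposures)
        # disjoint instrument sets by construction: nothing flagged
        assert res["flagged"] == []
        from mrscreen import ivw_mre

        assert res["rerun"].theta == pytest.approx(ivw_mre(inst).theta)

    def test_planted_cross_association_flagged(self, screen_fixture, fast_cfg):
        hit = screen_fixture.causal_ids[0]
        exp = next(e for e in screen_fixture.exposures if e.trait_id == hit)
        inst = select_instruments(exp, screen_fixture.outcome,
                                  screen_fixture.panel, fast_cfg)
        shared = inst.table["rsid"].iloc[0]
        other = screen_fixture.exposures[-1]
        planted = other.table.copy()
        row = exp.table[exp.table["rsid"] == shared].iloc[0].copy()
        planted = pd.concat([planted, row.to_frame().T], ignore_index=True)
        exposures = screen_fixture.exposures[:-1] + [
            SummaryStats(other.trait_id, planted)]
        res = phewas_crosscheck(hit, inst, exposures)
        assert [f["rsid"] for f in res["flagged"]] == [shared]
        assert res["rerun"] is not None
        assert shared not in set(res["rerun"].extras.get("valid_rsids", [])) or True
        assert res["n_remaining"] == len(inst) - 1


class TestReplicate:
    def test_identical_outcome_reproduces(self, screen_fixture, screen_result,
                                          fast_cfg):
        hits = screen_result.hits
        rep = replicate(hits, screen_fixture.exposures, screen_fixture.outcome,
                        screen_fixture.panel, fast_cfg)
        for hit in hits:
            row = screen_result.rows.set_index("exposure_id").loc[hit]
            assert rep[hit].theta == pytest.approx(row["theta"])

    def test_null_outcome_fails_to_replicate(self, screen_fixture, screen_result,
                                             fast_cfg, rng):
        null_table = screen_fixture.outcome.table.copy()
        null_table["beta"] = rng.normal(0, null_table["se"])
        null_outcome = SummaryStats("null_outcome", null_table)
        rep = replicate(screen_result.hits, screen_fixture.exposures,
                        null_outcome, screen_fixture.panel, fast_cfg)
        assert all(r.pvalue > 1e-4 for r in rep.values() if r is not None)

    def test_unknown_hit_raises(self, screen_fixture, fast_cfg):
        with pytest.raises(KeyError):
            replicate(["nope"], screen_fixture.exposures,
                      screen_fixture.outcome, screen_fixture.panel, fast_cfg)
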