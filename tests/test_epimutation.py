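"""Variance F-scan, candidate filters, deviation and outlier calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methvar import (call_epimutations, compute_deviations,
                     load_epimutation_panel, scan_variances,
                     select_candidates, summarize_calls, variance_ftest)
from methvar.core import BetaMatrix, ValidationError
from .conftest import make_betas, make_paired_sheet, random_betas


class TestVarianceFtest:
    def test_identical_samples_give_F1_p1(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        res = variance_ftest(x, x)
        assert res.F == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.df1 == res.df2 == 3

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_two_sided_p_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0, 2, 11)
        assert variance_ftest(x, y).p_two_sided == pytest.approx(
            variance_ftest(y, x).p_two_sided)

    def test_both_constant_is_uninformative(self):
        res = variance_ftest([0.5, 0.5, 0.5], [0.2, 0.2])
        assert res.p_two_sided == 1.0
        assert res.degenerate == "constant"
        assert np.isnan(res.F)

    def test_one_zero_variance_flagged_degenerate(self):
        res = variance_ftest([0.1, 0.9, 0.4], [0.25, 0.25, 0.25])
        assert res.p_two_sided == 0.0
        assert res.degenerate == "zero_variance"

    def test_needs_two_observations(self):
        with pytest.raises(ValidationError):
            variance_ftest([0.1], [0.2, 0.3])

    def test_unbiased_variance_ratio(self):
        x = [0.0, 1.0, 2.0]          # var 1.0 (ddof=1)
        y = [0.0, 0.5, 1.0, 1.5]     # var 0.4166...
        res = variance_ftest(x, y)
        assert res.F == pytest.approx(np.var(x, ddof=1) / np.var(y, ddof=1))


class TestScanVariances:
    def test_extreme_case_minimal_p_and_group(self):
        sheet = make_paired_sheet(n_conv=4, n_nonc=4)
        vals = np.full((3, 16), 0.5)
        betas = make_betas(vals, samples=list(sheet.data["sample_id"]))
        # probe 0: converters alternate 0/1 at MF, nonconverters near-constant
        for i, s in enumerate(["C0_MF", "C1_MF", "C2_MF", "C3_MF"]):
            betas.data.loc["cg00000000", s] = float(i % 2)
        for i, s in enumerate(["N0_MF", "N1_MF", "N2_MF", "N3_MF"]):
            betas.data.loc["cg00000000", s] = 0.5 + 1e-4 * i
        # make the remaining probes non-degenerate
        rng = np.random.default_rng(0)
        for probe in ["cg00000001", "cg00000002"]:
            betas.data.loc[probe] = rng.uniform(0.4, 0.6, 16)
        scan = scan_variances(betas, sheet, "MF")
        assert scan.at["cg00000000", "higher_variance_group"] == "converters"
        assert scan.at["cg00000000", "p"] == scan["p"].min()

    def test_absent_timepoint_errors(self, rng):
        sheet = make_paired_sheet()
        sheet.data.drop(sheet.data[sheet.data.timepoint == "MF"].index,
                        inplace=True)
        betas = random_betas(rng, 5, sheet)
        with pytest.raises(ValidationError, match="MF"):
            scan_variances(betas, sheet, "MF")

    def test_bh_q_matches_independent_step_up_oracle(self, rng):
        """q-values from the scan equal a hand-rolled BH step-up on its
        p-values (1000 random probes)."""
        sheet = make_paired_sheet(n_conv=5, n_nonc=6)
        betas = random_betas(rng, 1000, sheet)
        scan = scan_variances(betas, sheet, "MF")
        p = scan["p"].to_numpy()

        def bh_step_up(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            q = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, pvals[i] * m / rank)
                q[i] = running
            return q

        assert np.allclose(scan["q"].to_numpy(), bh_step_up(p))

    def test_degenerate_probe_excluded_from_fdr(self):
        sheet = make_paired_sheet(n_conv=3, n_nonc=3)
        vals = np.random.default_rng(0).uniform(0.3, 0.7, (4, 12))
        vals[0] = 0.5  # constant probe
        betas = make_betas(vals, samples=list(sheet.data["sample_id"]))
        scan = scan_variances(betas, sheet, "MF")
        assert scan.at["cg00000000", "degenerate"] == "constant"
        assert np.isnan(scan.at["cg00000000", "q"])
        assert scan.loc[scan["degenerate"].isna(), "q"].notna().all()

    def test_q_at_least_p(self, rng):
        sheet = make_paired_sheet(n_conv=4, n_nonc=5)
        betas = random_betas(rng, 300, sheet)
        scan = scan_variances(betas, sheet, "M0")
        ok = scan["degenerate"].isna()
        assert (scan.loc[ok, "q"] >= scan.loc[ok, "p"] - 1e-12).all()


class TestSelectCandidates:
    def fake_scan(self, probes, q, var_c, var_n, higher):
        return pd.DataFrame({"q": q, "var_converters": var_c,
                             "var_nonconverters": var_n,
                             "higher_variance_group": higher},
                            index=pd.Index(probes, name="probe_id"))

    def test_all_three_filters_needed(self):
        probes = ["cgA", "cgB", "cgC", "cgD"]
        m0 = self.fake_scan(probes, [0.9, 0.9, 0.9, 0.01],
                            [1e-4] * 4, [1e-4] * 4,
                            ["tie", "tie", "tie", "nonconverters"])
        mf = self.fake_scan(probes,
                            [0.001, 0.001, 0.5, 0.001],
                            [1e-2, 1e-4, 1e-2, 1e-2],  # cgB: no variance increase
                            [1e-4] * 4,
                            ["converters"] * 4)
        out = select_candidates(m0, mf)
        assert bool(out.at["cgA", "is_candidate"])
        assert not out.at["cgB", "is_candidate"]   # variance not increased
        assert not out.at["cgC", "is_candidate"]   # not significant at MF
        assert not out.at["cgD", "is_candidate"]   # significant in nonconverters

    def test_equal_variance_boundary_rejected(self):
        """Strict increase: var(MF) == var(M0) fails filter (i)."""
        m0 = self.fake_scan(["cgA"], [0.9], [1e-3], [1e-4], ["converters"])
        mf = self.fake_scan(["cgA"], [0.001], [1e-3], [1e-4], ["converters"])
        out = select_candidates(m0, mf)
        assert not out.at["cgA", "passes_variance_increase"]
        assert not out.at["cgA", "is_candidate"]

    def test_sorted_by_mf_q(self):
        m0 = self.fake_scan(["cgA", "cgB"], [0.9, 0.9], [1e-4, 1e-4],
                            [1e-4, 1e-4], ["tie", "tie"])
        mf = self.fake_scan(["cgA", "cgB"], [0.04, 0.01], [1e-2, 1e-2],
                            [1e-4, 1e-4], ["converters", "converters"])
        out = select_candidates(m0, mf)
        assert list(out.index) == ["cgB", "cgA"]


class TestComputeDeviations:
    def test_symmetric_example(self):
        sheet = make_paired_sheet(n_conv=3, n_nonc=3)
        betas = make_betas(np.full((1, 12), 0.5),
                           samples=list(sheet.data["sample_id"]))
        betas.data.loc["cg00000000", ["C0_MF", "C1_MF", "C2_MF"]] = [0.2, 0.3, 0.4]
        dev = compute_deviations(betas, sheet, "converter", "MF")
        assert list(dev.data.loc["cg00000000"]) == pytest.approx([-0.1, 0.0, 0.1])

    def test_reconstructed_betas_recover_panel(self):
        """Betas rebuilt as (per-probe constant) + panel deviations give back
        the panel exactly at its printed precision: the deviations are
        invariant to the group median they were measured against."""
        from methvar import SampleSheet
        _, after, _ = load_epimutation_panel()
        sheet = SampleSheet(pd.DataFrame(
            [{"sample_id": f"{s}_MF", "subject_id": s,
              "group": "converter", "timepoint": "MF"}
             for s in after.subject_ids]))
        # center each probe so every reconstructed beta lands in [0, 1]
        base = (1.0 - after.data.min(axis=1) - after.data.max(axis=1)) / 2.0
        data = after.data.add(base, axis=0)
        data.columns = [f"{s}_MF" for s in after.subject_ids]
        betas = BetaMatrix(data)
        dev = compute_deviations(betas, sheet, "converter", "MF",
                                 probes=after.probe_ids)
        assert np.allclose(dev.data.to_numpy(), after.data.to_numpy(),
                           atol=5e-3)

    def test_matches_loop_oracle(self, rng):
        sheet = make_paired_sheet(n_conv=5, n_nonc=3)
        betas = random_betas(rng, 40, sheet)
        dev = compute_deviations(betas, sheet, "converter", "M0")
        samples = [f"C{i}_M0" for i in range(5)]
        for probe in betas.probe_ids:
            row = [betas.data.at[probe, s] for s in samples]
            med = np.median(row)
            for subj, s in zip([f"C{i}" for i in range(5)], samples):
                assert dev.data.at[probe, subj] == pytest.approx(
                    betas.data.at[probe, s] - med)

    def test_missing_probe_named(self, rng):
        sheet = make_paired_sheet()
        betas = random_betas(rng, 5, sheet)
        with pytest.raises(ValidationError, match="cgMISSING"):
            compute_deviations(betas, sheet, "converter", "M0",
                               probes=["cgMISSING"])

    def test_group_too_small(self, rng):
        sheet = make_paired_sheet(n_conv=2, n_nonc=3)
        betas = random_betas(rng, 5, sheet)
        with pytest.raises(ValidationError, match="need >= 3"):
            compute_deviations(betas, sheet, "converter", "M0")

    def test_shift_invariance(self, rng):
        """Adding a constant per probe to all group members leaves
        deviations unchanged."""
        sheet = make_paired_sheet(n_conv=4, n_nonc=3)
        betas = make_betas(rng.uniform(0.2, 0.6, (20, 14)),
                           samples=list(sheet.data["sample_id"]))
        shifted = BetaMatrix(betas.data + 0.3)
        a = compute_deviations(betas, sheet, "converter", "MF")
        b = compute_deviations(shifted, sheet, "converter", "MF")
        assert np.allclose(a.data.to_numpy(), b.data.to_numpy())


@pytest.fixture(scope="module")
def panel_calls():
    _, after, _ = load_epimutation_panel()
    return after, call_epimutations(after, 0.10, strict=True)


class TestCallsOnPanel:
    """The packaged after-transition panel is the worked example."""

    def test_threshold_is_strict(self, panel_calls):
        """Deviations printed as exactly 0.10 (PELI1 and GAS1 rows) must
        not produce calls."""
        _, calls = panel_calls
        keyed = set(zip(calls["probe_id"], calls["subject_id"]))
        assert ("cg17364044", "IC01.105") not in keyed
        assert ("cg26447413", "IC01.151") not in keyed

    def test_hyper_and_hypo_extremes_called(self, panel_calls):
        _, calls = panel_calls
        rac1 = calls[(calls.probe_id == "cg18404925")
                     & (calls.subject_id == "IC01.055")]
        astn2 = calls[(calls.probe_id == "cg13978347")
                      & (calls.subject_id == "IC01.178")]
        assert rac1["direction"].iloc[0] == "hyper"
        assert rac1["deviation"].iloc[0] == pytest.approx(0.63)
        assert astn2["direction"].iloc[0] == "hypo"
        assert astn2["deviation"].iloc[0] == pytest.approx(-0.71)

    def test_before_block_yields_no_calls(self):
        before, _, _ = load_epimutation_panel()
        assert len(call_epimutations(before, 0.10)) == 0


class TestSummarizeCalls:
    def test_empty_calls_all_zero_histogram(self):
        calls = pd.DataFrame(columns=["probe_id", "subject_id", "timepoint",
                                      "deviation", "direction"])
        summary = summarize_calls(calls, [f"S{i}" for i in range(5)])
        assert summary.histogram == {0: 5}
        assert summary.n_calls == 0

    def test_unknown_subject_rejected(self):
        calls = pd.DataFrame({"probe_id": ["cgA"], "subject_id": ["ghost"],
                              "deviation": [0.5], "direction": ["hyper"],
                              "timepoint": ["MF"]})
        with pytest.raises(ValidationError, match="ghost"):
            summarize_calls(calls, ["S1"])
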