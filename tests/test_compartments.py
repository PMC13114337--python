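"""Bin aggregation, orientation, stratified testing and block merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regarch import compartments as comp
from regarch.utils import InputError


def _bins(n, chrom="chr1", width=100_000):
    starts = np.arange(n) * width
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width})
    df.index.name = "bin_id"
    return df


class TestAggregate:
    def test_mean_of_probes(self):
        bins = _bins(2)
        probes = pd.DataFrame({"chrom": "chr1", "start": [10, 20], "end": [11, 21]},
                              index=["p1", "p2"])
        beta = pd.DataFrame({"s1": [0.2, 0.4]}, index=["p1", "p2"])
        out = comp.aggregate_probes_to_bins(beta, probes, bins, min_probes=1)
        assert out.loc[0, "s1"] == pytest.approx(0.3)

    def test_min_probes_filter(self):
        bins = _bins(1)
        probes = pd.DataFrame({"chrom": "chr1", "start": [10, 20], "end": [11, 21]},
                              index=["p1", "p2"])
        beta = pd.DataFrame({"s1": [0.2, 0.4]}, index=["p1", "p2"])
        out = comp.aggregate_probes_to_bins(beta, probes, bins, min_probes=3)
        assert out.empty

    def test_missing_values_ignored_per_cell(self):
        bins = _bins(1)
        probes = pd.DataFrame({"chrom": "chr1", "start": [1, 2, 3], "end": [2, 3, 4]},
                              index=list("abc"))
        beta = pd.DataFrame({"s1": [0.1, np.nan, 0.5], "s2": [np.nan] * 3},
                            index=list("abc"))
        out = comp.aggregate_probes_to_bins(beta, probes, bins, min_probes=3)
        assert out.loc[0, "s1"] == pytest.approx(0.3)
        assert np.isnan(out.loc[0, "s2"])

    def test_probe_outside_bins_warns_and_skips(self):
        bins = _bins(1)
        probes = pd.DataFrame({"chrom": "chr1", "start": [10, 250_000], "end": [11, 250_001]},
                              index=["p1", "p2"])
        beta = pd.DataFrame({"s1": [0.2, 0.9]}, index=["p1", "p2"])
        with pytest.warns(UserWarning, match="outside"):
            out = comp.aggregate_probes_to_bins(beta, probes, bins, min_probes=1)
        assert out.loc[0, "s1"] == pytest.approx(0.2)

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            comp.aggregate_probes_to_bins(pd.DataFrame(), pd.DataFrame(), _bins(1))

    def test_matches_bruteforce_group_mean(self, rng):
        n_probes, n_samples, n_bins = 50, 6, 8
        bins = _bins(n_bins)
        pos = rng.integers(0, n_bins * 100_000, size=n_probes)
        probes = pd.DataFrame({"chrom": "chr1", "start": pos, "end": pos + 1},
                              index=[f"p{i}" for i in range(n_probes)])
        beta = pd.DataFrame(rng.random((n_probes, n_samples)), index=probes.index,
                            columns=[f"s{j}" for j in range(n_samples)])
        out = comp.aggregate_probes_to_bins(beta, probes, bins, min_probes=1)
        for b in out.index:
            members = probes.index[(pos // 100_000) == b]
            expected = beta.loc[members].mean(axis=0)
            pd.testing.assert_series_equal(out.loc[b], expected, check_names=False)


class TestOrientAndCall:
    def test_orientation_invariance(self, comp_dataset):
        binmat = comp.aggregate_probes_to_bins(comp_dataset.beta, comp_dataset.probes,
                                               comp_dataset.bins)
        calls = comp.orient_and_call(binmat, comp_dataset.reference)
        flipped = comp.orient_and_call(1.0 - binmat, comp_dataset.reference)
        pd.testing.assert_frame_equal(calls.call, flipped.call)

    def test_constant_sample_gets_missing_calls(self, comp_dataset):
        binmat = comp.aggregate_probes_to_bins(comp_dataset.beta, comp_dataset.probes,
                                               comp_dataset.bins)
        binmat = binmat.copy()
        binmat.iloc[:, 0] = 0.5
        with pytest.warns(UserWarning, match="zero MAD"):
            calls = comp.orient_and_call(binmat, comp_dataset.reference)
        assert calls.call.iloc[:, 0].isna().all()
        assert calls.call.iloc[:, 1].notna().any()

    def test_calls_recover_latent_state(self, comp_dataset, comp_calls):
        latent = comp_dataset.latent_open.loc[comp_calls.retained_bins]
        acc = ((comp_calls.call == "A") == latent).to_numpy().mean()
        assert acc >= 0.90

    def test_no_reference_overlap_is_an_error(self, comp_dataset):
        binmat = comp.aggregate_probes_to_bins(comp_dataset.beta, comp_dataset.probes,
                                               comp_dataset.bins)
        ref = comp_dataset.reference.copy()
        ref.index = ref.index + 10_000
        with pytest.raises(InputError):
            comp.orient_and_call(binmat, ref)


def _callset(call_df):
    bins = _bins(len(call_df))
    return comp.CompartmentCallSet(score=pd.DataFrame(np.where(call_df == "A", 1.0, -1.0),
                                                      index=call_df.index,
                                                      columns=call_df.columns),
                                   call=call_df, retained_bins=list(call_df.index),
                                   bins=bins.loc[call_df.index])


def _strata(n_high, n_low):
    cols = [f"h{i}" for i in range(n_high)] + [f"l{i}" for i in range(n_low)]
    return cols, pd.Series(["high"] * n_high + ["low"] * n_low, index=cols)


class TestStratifiedFractions:
    def test_all_a_versus_all_b(self):
        cols, strata = _strata(3, 3)
        call = pd.DataFrame([["A"] * 3 + ["B"] * 3], columns=cols, index=[0])
        frac = comp.stratified_open_fraction(_callset(call), strata)
        assert frac.loc[0, "p_open_high"] == 1.0
        assert frac.loc[0, "p_open_low"] == 0.0
        assert frac.loc[0, "delta_p_open"] == 1.0

    def test_identical_distributions_give_zero_delta(self):
        cols, strata = _strata(4, 4)
        call = pd.DataFrame([["A", "A", "B", "B"] * 2], columns=cols, index=[0])
        frac = comp.stratified_open_fraction(_callset(call), strata)
        assert frac.loc[0, "delta_p_open"] == 0.0

    def test_unknown_stratum_label_rejected(self):
        cols, strata = _strata(2, 2)
        strata.iloc[0] = "mid"
        call = pd.DataFrame([["A"] * 4], columns=cols, index=[0])
        with pytest.raises(InputError, match="unknown stratum"):
            comp.stratified_open_fraction(_callset(call), strata)

    def test_matches_direct_counting(self, rng):
        cols, strata = _strata(10, 10)
        call = pd.DataFrame(rng.choice(["A", "B", None], size=(6, 20), p=[0.45, 0.45, 0.1]),
                            columns=cols, index=range(6))
        frac = comp.stratified_open_fraction(_callset(call), strata)
        for b in range(6):
            for grp, col in (("high", "p_open_high"), ("low", "p_open_low")):
                vals = [call.loc[b, c] for c in cols if strata[c] == grp
                        and call.loc[b, c] is not None]
                expected = sum(v == "A" for v in vals) / len(vals)
                assert frac.loc[b, col] == pytest.approx(expected)
            # complementarity: open + closed fractions sum to one
            assert frac.loc[b, "p_open_high"] + (1 - frac.loc[b, "p_open_high"]) == 1.0


class TestTestBins:
    def test_perfect_separation_matches_enumeration(self):
        cols, strata = _strata(10, 10)
        call = pd.DataFrame([["A"] * 10 + ["B"] * 10], columns=cols, index=[0])
        res = comp.test_bins(_callset(call), strata)
        # two-sided Fisher p by hypergeometric enumeration over the margin
        pmf = [stats.hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        p_obs = pmf[10]
        expected = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
        assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)
        assert res.loc[0, "q_value"] >= res.loc[0, "p_value"]

    def test_identical_strata_give_p_one(self):
        cols, strata = _strata(5, 5)
        call = pd.DataFrame([["A", "A", "B", "B", "A"] * 2], columns=cols, index=[0])
        res = comp.test_bins(_callset(call), strata)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_unsupported_method_rejected(self, comp_calls, comp_dataset):
        with pytest.raises(Exception, match="method"):
            comp.test_bins(comp_calls, comp_dataset.strata, method="anova")

    def test_q_at_least_p(self, comp_results):
        ok = comp_results.dropna(subset=["p_value"])
        assert (ok["q_value"] >= ok["p_value"] - 1e-12).all()


def _results_from_sig(sig, chrom="chr1", width=100_000, gaps=()):
    """Build a results frame from a 0/1 significance vector; listed gap
    positions are dropped entirely (untested bins)."""
    rows = []
    for i, s in enumerate(sig):
        if i in gaps:
            continue
        rows.append({"bin_id": i, "chrom": chrom, "start": i * width,
                     "end": (i + 1) * width, "delta_p_open": 0.2,
                     "p_value": 0.001 if s else 0.5,
                     "q_value": 0.01 if s else 0.9})
    return pd.DataFrame(rows).set_index("bin_id")


def _bruteforce_blocks(sig, min_run=3):
    """Independent run scanner over a contiguous 0/1 vector."""
    runs, start = [], None
    for i, s in enumerate(list(sig) + [0]):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    return runs


class TestMergeBlocks:
    def test_three_consecutive_form_one_block(self):
        blocks = comp.merge_significant_blocks(_results_from_sig([1, 1, 1, 0, 1, 1]))
        assert len(blocks) == 1
        assert blocks.loc[0, "n_bins"] == 3
        assert blocks.loc[0, "member_bin_ids"] == [0, 1, 2]

    def test_short_runs_discarded(self):
        blocks = comp.merge_significant_blocks(_results_from_sig([1, 1, 0, 1, 1]))
        assert blocks.empty

    def test_untested_bin_breaks_a_run(self):
        # six significant bins with bin 2 untested: runs of 2 and 3
        res = _results_from_sig([1, 1, 1, 1, 1, 1], gaps={2})
        blocks = comp.merge_significant_blocks(res)
        assert len(blocks) == 1
        assert blocks.loc[0, "member_bin_ids"] == [3, 4, 5]

    def test_matches_bruteforce_scanner(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            sig = rng.random(n) < 0.5
            blocks = comp.merge_significant_blocks(_results_from_sig(sig))
            expected = _bruteforce_blocks(sig)
            got = [(b.member_bin_ids[0], b.member_bin_ids[-1])
                   for b in blocks.itertuples()]
            assert got == expected

    def test_blocks_are_sound_and_maximal(self, comp_results):
        blocks = comp.merge_significant_blocks(comp_results)
        sig_ids = set(comp_results.index[comp_results["q_value"] < 0.05])
        for b in blocks.itertuples():
            members = b.member_bin_ids
            assert set(members) <= sig_ids
            assert len(members) >= 3
            assert members == list(range(members[0], members[-1] + 1))
            assert members[0] - 1 not in sig_ids
            assert members[-1] + 1 not in sig_ids


class TestSummarize:
    def test_constant_delta_gives_zero_iqr(self):
        res = _results_from_sig([1, 1, 1])
        out = comp.summarize_compartment_shift(res, comp.merge_significant_blocks(res))
        assert out["delta_p_open_q75"] - out["delta_p_open_q25"] == 0.0
        assert out["n_blocks"] == 1

    def test_zero_significant_reports_missing_percent(self):
        res = _results_from_sig([0, 0, 0])
        out = comp.summarize_compartment_shift(res, comp.merge_significant_blocks(res))
        assert out["n_significant"] == 0
        assert np.isnan(out["percent_direction_positive"])
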