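"""Differential-expression stage: BH against a brute-force oracle, dispersion
recovery on simulated truth, NB-test behavior and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imcorr.diffexpr import (
    _conditional_two_sided_p,
    bh_adjust,
    call_degs,
    deg_directions,
    estimate_dispersion,
    filter_detectable,
    log2_fold_change,
    nb_exact_test,
    size_factors,
)


def bh_oracle(p):
    """Literal step-up: q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12, atol=1e-12)


class TestFoldChange:
    def _frame(self, a, b):
        return pd.DataFrame(
            {"a1": a, "a2": a, "b1": b, "b2": b}, index=["g"]
        )

    def test_equal_means_zero(self):
        counts = self._frame(8, 8)
        sf = pd.Series(1.0, index=counts.columns)
        assert log2_fold_change(counts, ["a1", "a2"], ["b1", "b2"], sf)["g"] == 0.0

    def test_four_fold_at_vanishing_prior(self):
        counts = self._frame(8, 2)
        sf = pd.Series(1.0, index=counts.columns)
        fc = log2_fold_change(counts, ["a1", "a2"], ["b1", "b2"], sf, prior_count=1e-9)
        assert fc["g"] == pytest.approx(2.0, abs=1e-6)

    def test_zero_group_finite(self):
        counts = self._frame(0, 1000)
        sf = pd.Series(1.0, index=counts.columns)
        fc = log2_fold_change(counts, ["a1", "a2"], ["b1", "b2"], sf)["g"]
        assert np.isfinite(fc) and fc < -5


class TestFilterDetectable:
    @pytest.mark.parametrize(
        "means,expected",
        [((0.4, 0.8), False), ((0.0, 1.2), True), ((0.0, 0.0), False), ((1.0, 1.0), False)],
    )
    def test_max_group_mean_rule(self, means, expected):
        rpkm = pd.DataFrame(
            {"a1": means[0], "a2": means[0], "b1": means[1], "b2": means[1]}, index=["g"]
        )
        kept = filter_detectable(rpkm, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert ("g" in kept) is expected

    def test_empty_group_rejected(self):
        rpkm = pd.DataFrame({"a1": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="empty"):
            filter_detectable(rpkm, {"A": ["a1"], "B": []})


class TestDispersion:
    def test_constant_counts_zero(self):
        counts = pd.DataFrame(50, index=[f"g{i}" for i in range(10)],
                              columns=["a1", "a2", "b1", "b2"])
        phi = estimate_dispersion(counts, {"A": ["a1", "a2"], "B": ["b1", "b2"]},
                                  pd.Series(1.0, index=counts.columns))
        assert (phi == 0).all()

    def test_poisson_truth_recovered_near_zero(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(np.log(500), 1.0, 2000)
        counts = pd.DataFrame(
            rng.poisson(mu[:, None] * np.ones(4)), columns=["a1", "a2", "b1", "b2"]
        )
        phi = estimate_dispersion(counts, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert np.median(phi) < 0.05

    def test_nb_dispersion_04_recovered(self):
        rng = np.random.default_rng(1)
        mu = rng.lognormal(np.log(200), 0.8, 2000)
        r = 1 / 0.4
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 8)),
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        groups = {"A": [f"a{i}" for i in range(4)], "B": [f"b{i}" for i in range(4)]}
        phi = estimate_dispersion(counts, groups)
        assert 0.2 <= np.median(phi) <= 0.6

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2]}, index=["g"])
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(counts, {"A": ["a1"], "B": ["b1"]})


class TestNbExactTest:
    def _run(self, a, b, phi=0.0):
        counts = pd.DataFrame(
            {"a1": a[0], "a2": a[1], "b1": b[0], "b2": b[1]}, index=["g"]
        )
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(phi, index=["g"])
        return nb_exact_test(counts, ["a1", "a2"], ["b1", "b2"], disp, sf)["g"]

    def test_no_signal_large_p(self):
        assert self._run((500, 500), (500, 500)) > 0.5

    def test_planted_eight_fold_significant(self):
        assert self._run((400, 400), (50, 50), phi=0.01) < 0.01

    def test_relabeling_within_group_invariant(self):
        assert self._run((300, 500), (100, 120)) == self._run((500, 300), (120, 100))

    def test_monotone_in_fold_change(self):
        """Increasing the planted fold change never increases the p-value."""
        previous = 1.1
        for fold in (1, 2, 4, 8):
            p = self._run((100 * fold, 100 * fold), (100, 100), phi=0.05)
            assert p <= previous + 1e-12
            previous = p

    def test_windowed_support_matches_full(self, monkeypatch):
        full = _conditional_two_sided_p(5200, 9700, 2, 2, 0.03)
        import imcorr.diffexpr as de

        monkeypatch.setattr(de, "_FULL_SUPPORT_MAX", 100)
        windowed = _conditional_two_sided_p(5200, 9700, 2, 2, 0.03)
        assert windowed == pytest.approx(full, rel=1e-6)

    def test_zero_size_factor_rejected(self):
        counts = pd.DataFrame({"a1": [1], "a2": [1], "b1": [1], "b2": [1]}, index=["g"])
        sf = pd.Series([1.0, 1.0, 0.0, 1.0], index=counts.columns)
        with pytest.raises(ValueError, match="size factors"):
            nb_exact_test(counts, ["a1", "a2"], ["b1", "b2"], pd.Series(0.1, index=["g"]), sf)


class TestSizeFactors:
    def test_geometric_mean_normalized(self):
        counts = pd.DataFrame({"s1": [100], "s2": [400]}, index=["g"])
        sf = size_factors(counts)
        assert np.prod(sf.to_numpy()) == pytest.approx(1.0)
        assert sf["s2"] / sf["s1"] == pytest.approx(4.0)


class TestCallDegs:
    def test_missing_comparison_rejected(self, default_de):
        results, _ = default_de
        partial = {k: v for k, v in results.items() if k != ("media", "BT")}
        with pytest.raises(ValueError, match="missing comparison"):
            call_degs(partial)

    def test_planted_signals_called_and_fdr_respected(self, default_dataset, default_de):
        _, _, truth = default_dataset
        _, degs = default_de
        intimal = set(degs.union["intima"])
        assert set(truth.signal_genes) <= intimal
        nulls = set(truth.null_genes)
        false_rate = len(nulls & intimal) / len(nulls)
        assert false_rate < 0.05  # q<0.05 across mostly-null genes

    def test_overlap_set_semantics(self, default_de):
        results, degs = default_de
        for tissue in ("intima", "media"):
            ba = set(degs.per_comparison[(tissue, "BA")].index)
            bt = set(degs.per_comparison[(tissue, "BT")].index)
            assert degs.overlap[tissue] == len(ba & bt)
            assert len(degs.union[tissue]) == len(ba | bt)
            assert degs.counts[(tissue, "BA")]["total"] == len(ba)

    def test_direction_counts_sum(self, default_de):
        _, degs = default_de
        for key, c in degs.counts.items():
            assert c["up"] + c["down"] == c["total"]

    def test_planted_directions_recovered(self, default_dataset, default_de):
        _, _, truth = default_dataset
        results, _ = default_de
        genes = sorted(truth.signal_genes)
        directions = deg_directions(results, "intima", genes)
        for gene in genes:
            assert directions[gene] == truth.signal_genes[gene]["direction"]
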