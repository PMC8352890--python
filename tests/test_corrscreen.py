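"""Correlation screen: matched-vector assembly, Pearson r/p against
independent oracles, brute-force screen equivalence and candidate selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from imcorr.corrscreen import (
    assemble_matched_vectors,
    check_count_identity,
    count_correlates,
    matched_design,
    pearson_with_p,
    screen_pairs,
    select_candidates,
)
from imcorr.reference_tables import correlate_count_table


class TestMatchedVectors:
    def test_default_design_eight_aligned_slots(self, default_dataset, default_rpkm):
        _, samples, truth = default_dataset
        gene = sorted(truth.signal_genes)[0]
        vi = assemble_matched_vectors(default_rpkm, samples, gene, "intima")
        vm = assemble_matched_vectors(default_rpkm, samples, gene, "media")
        assert len(vi) == len(vm) == 8
        assert list(vi.index) == list(vm.index)

    def test_missing_media_sample_names_slot(self, default_dataset):
        _, samples, _ = default_dataset
        media_row = samples[samples.tissue == "media"].index[:1]
        with pytest.raises(ValueError, match="missing its media"):
            matched_design(samples.drop(index=media_row))

    def test_duplicate_slot_rejected(self, default_dataset):
        _, samples, _ = default_dataset
        dup = samples.iloc[[0]].rename(index={samples.index[0]: "dup_sample"})
        with pytest.raises(ValueError, match="duplicate"):
            matched_design(pd.concat([samples, dup]))

    def test_input_order_irrelevant(self, default_dataset, default_rpkm):
        _, samples, truth = default_dataset
        gene = sorted(truth.signal_genes)[0]
        v1 = assemble_matched_vectors(default_rpkm, samples, gene, "intima")
        v2 = assemble_matched_vectors(
            default_rpkm, samples.sample(frac=1.0, random_state=0), gene, "intima"
        )
        pd.testing.assert_series_equal(v1, v2)


class TestPearsonWithP:
    def test_perfect_line(self):
        x = np.arange(8.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == 1.0 and p == 0.0

    def test_antisymmetric(self):
        x = np.arange(1.0, 9.0)
        r, _ = pearson_with_p(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_p_matches_t_density_integration(self):
        """Two-sided p at n=8, r=0.95 equals numerically integrating the
        t density with 6 df beyond |t| = r sqrt(6)/sqrt(1-r^2)."""
        rng = np.random.default_rng(4)
        # construct a vector pair with r very close to 0.95
        x = np.arange(8.0)
        y = 0.95 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.95**2) * rng.normal(size=8)
        r, p = pearson_with_p(x, y)
        t_obs = abs(r) * np.sqrt(6) / np.sqrt(1 - r**2)
        density = lambda u: stats.t.pdf(u, 6)  # noqa: E731
        tail, _ = integrate.quad(density, t_obs, np.inf)
        assert p == pytest.approx(2 * tail, rel=1e-6)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert pearson_with_p(x, y) == pearson_with_p(y, x)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r1, p1 = pearson_with_p(x, y)
        r2, p2 = pearson_with_p(3.0 * x + 10.0, 0.5 * y - 2.0)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_with_p(np.ones(8), np.arange(8.0))


class TestScreenPairs:
    def _toy(self, n_i=6, n_m=8, seed=0):
        rng = np.random.default_rng(seed)
        samples = _design_frame()
        genes_i = [f"I{k}" for k in range(n_i)]
        genes_m = [f"M{k}" for k in range(n_m)]
        rpkm = pd.DataFrame(
            rng.lognormal(2.0, 1.0, size=(n_i + n_m, 16)),
            index=genes_i + genes_m, columns=samples.index,
        )
        return rpkm, samples, genes_i, genes_m

    def test_matches_brute_force_enumeration(self):
        """Vectorized screen equals looping scipy.stats.pearsonr per pair."""
        for scale in ("rpkm", "log2_rpkm"):
            rpkm, samples, genes_i, genes_m = self._toy()
            got = screen_pairs(rpkm, samples, genes_i, genes_m,
                               r_threshold=0.3, p_threshold=0.5, scale=scale)
            design = matched_design(samples)
            expected = []
            for gi in sorted(genes_i):
                for gm in sorted(genes_m):
                    x = rpkm.loc[gi, design["intima"]].to_numpy()
                    y = rpkm.loc[gm, design["media"]].to_numpy()
                    if scale == "log2_rpkm":
                        x, y = np.log2(x + 1), np.log2(y + 1)
                    res = stats.pearsonr(x, y)
                    if abs(res.statistic) > 0.3 and res.pvalue < 0.5:
                        expected.append((gi, gm, res.statistic, res.pvalue))
            assert len(got) == len(expected)
            for row, (gi, gm, r, p) in zip(got.itertuples(), expected):
                assert (row.intimal_gene, row.medial_gene) == (gi, gm)
                assert row.r == pytest.approx(r, rel=1e-9)
                assert row.p_value == pytest.approx(p, rel=1e-6)

    def test_constant_shift_pair_found_with_positive_sign(self):
        rpkm, samples, genes_i, genes_m = self._toy()
        design = matched_design(samples)
        # medial gene's matched vector = intimal gene's vector + constant
        rpkm.loc["M0", design["media"]] = rpkm.loc["I0", design["intima"]].to_numpy() + 7.0
        pairs = screen_pairs(rpkm, samples, ["I0"], ["M0"], scale="rpkm")
        assert len(pairs) == 1 and pairs.iloc[0]["sign"] == 1

    def test_null_pass_rate_below_1e3(self):
        """1000 independent gene pairs at n=8: expected pass rate ~1e-4."""
        rng = np.random.default_rng(12)
        samples = _design_frame()
        gi = [f"I{k}" for k in range(50)]
        gm = [f"M{k}" for k in range(20)]
        rpkm = pd.DataFrame(rng.lognormal(2, 1, size=(70, 16)),
                            index=gi + gm, columns=samples.index)
        pairs = screen_pairs(rpkm, samples, gi, gm)
        assert len(pairs) / 1000 <= 1e-3

    def test_zero_variance_gene_skipped_not_fatal(self):
        rpkm, samples, genes_i, genes_m = self._toy()
        rpkm.loc["I0"] = 5.0
        pairs = screen_pairs(rpkm, samples, genes_i, genes_m, r_threshold=0.0, p_threshold=1.0)
        assert "I0" not in set(pairs["intimal_gene"])
        assert set(pairs["intimal_gene"]) == set(genes_i) - {"I0"}

    def test_empty_deg_set_returns_empty(self, default_dataset, default_rpkm):
        _, samples, _ = default_dataset
        pairs = screen_pairs(default_rpkm, samples, [], ["NULL0001"])
        assert pairs.empty

    def test_deterministic_lexicographic_order(self):
        rpkm, samples, genes_i, genes_m = self._toy()
        pairs = screen_pairs(rpkm, samples, genes_i, genes_m, r_threshold=0.0, p_threshold=1.0)
        keys = list(zip(pairs["intimal_gene"], pairs["medial_gene"]))
        assert keys == sorted(keys)


class TestCountsAndCandidates:
    def _pairs(self, gene, n_pos, n_neg):
        rows = [{"intimal_gene": gene, "medial_gene": f"P{i}", "r": 0.99,
                 "p_value": 1e-6, "sign": 1, "n_points": 8} for i in range(n_pos)]
        rows += [{"intimal_gene": gene, "medial_gene": f"N{i}", "r": -0.99,
                  "p_value": 1e-6, "sign": -1, "n_points": 8} for i in range(n_neg)]
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("n_pos,n_neg,total", [(182, 105, 287), (106, 177, 283)])
    def test_reported_tallies_reproduced(self, n_pos, n_neg, total):
        counts = count_correlates(self._pairs("G", n_pos, n_neg))
        row = counts.loc["G"]
        assert (row["n_pos"], row["n_neg"], row["n_total"]) == (n_pos, n_neg, total)

    def test_gene_without_pairs_omitted(self):
        counts = count_correlates(self._pairs("G", 3, 2))
        assert list(counts.index) == ["G"]

    def test_identity_enforced_on_imports(self):
        """The published candidate table itself violates the tally identity
        for exactly two genes; the checker flags them."""
        assert check_count_identity(correlate_count_table()) == ["IL15", "NDP"]

    def test_candidate_rule_boundaries(self):
        counts = pd.DataFrame(
            {"n_total": [200, 250, 300], "n_pos": [100, 150, 200], "n_neg": [100, 100, 100]},
            index=pd.Index(["AT_BOUNDARY", "EXTRA", "NOT_EXTRA"], name="intimal_gene"),
        )
        annotation = pd.DataFrame(
            {"is_extracellular": [True, True, False], "product_class": ["other"] * 3},
            index=["AT_BOUNDARY", "EXTRA", "NOT_EXTRA"],
        )
        directions = pd.Series("up", index=counts.index)
        out = select_candidates(counts, annotation, directions, min_correlates=200)
        assert list(out["intimal_gene"]) == ["EXTRA"]

    def test_missing_annotation_treated_non_extracellular(self):
        counts = pd.DataFrame(
            {"n_total": [300], "n_pos": [200], "n_neg": [100]},
            index=pd.Index(["UNKNOWN"], name="intimal_gene"),
        )
        annotation = pd.DataFrame(columns=["is_extracellular", "product_class"])
        out = select_candidates(counts, annotation, pd.Series("up", index=counts.index))
        assert out.empty


def _design_frame():
    rows = []
    for animal, condition in (("L1", "ligated"), ("L2", "ligated"), ("S1", "sham"), ("S2", "sham")):
        for tissue in ("intima", "media"):
            for location, wss in (("BA", 10.0), ("BT", 20.0)):
                rows.append(
                    {
                        "sample_id": f"{animal}_{tissue}_{location}",
                        "animal_id": animal,
                        "tissue": tissue,
                        "location": location,
                        "condition": condition,
                        "wss_pa": wss * (4 if condition == "ligated" else 1),
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")
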