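import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio.stats.composition import clr as skbio_clr

from benthos16s.community import (
    OUTSIDE_DOMAIN,
    ClrMatrix,
    RegionScheme,
    aggregate_nested,
    aggregate_taxa,
    classify_depth,
    classify_region,
    clr_transform,
    correlation_grid,
    prevalence_filter,
)
from benthos16s.io_model import Lineage, OtuTable, TaxonomyAssignment, ValidationError


def make_assignment(otu, names):
    lin = Lineage(tuple(names))
    return TaxonomyAssignment(
        otu_id=otu, lineage=lin, assigned_rank=lin.deepest_rank,
        n_hits_input=1, n_hits_after_threshold=1, n_hits_after_margin=1,
        max_identity=90.0, lca_rank=lin.deepest_rank,
    )


class TestDepthClassification:
    @pytest.mark.parametrize(
        "depth,expected",
        [
            (20.0, "epibenthic"),
            (150.0, "epibenthic"),
            (199.99, "epibenthic"),
            (200.0, "mesobenthic"),   # 200 m belongs to the mesobenthic band
            (1000.0, "mesobenthic"),  # closed upper bound
            (1000.01, "bathybenthic"),
            (2415.0, "bathybenthic"),
        ],
    )
    def test_band_boundaries(self, depth, expected):
        assert classify_depth(depth) == expected

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValidationError):
            classify_depth(0.0)
        with pytest.raises(ValidationError):
            classify_depth(-5.0)

    @given(st.floats(min_value=1e-6, max_value=1e5, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_partition_is_total_and_exclusive(self, depth):
        cat = classify_depth(depth)
        assert cat in ("epibenthic", "mesobenthic", "bathybenthic")
        assert (cat == "epibenthic") == (depth < 200)
        assert (cat == "bathybenthic") == (depth > 1000)


class TestRegionClassification:
    scheme = RegionScheme()

    def test_below_lowest_cut_is_southern(self):
        assert classify_region(16.0, self.scheme) == "Southern Red Sea"

    def test_cut_belongs_to_band_it_opens(self):
        for cut, label in zip(self.scheme.cuts, self.scheme.labels[1:]):
            assert classify_region(cut, self.scheme) == label

    def test_monotone_latitudes_give_monotone_regions(self):
        lats = np.linspace(self.scheme.lat_min, self.scheme.lat_max, 50)
        idx = [self.scheme.labels.index(classify_region(v, self.scheme)) for v in lats]
        assert idx == sorted(idx)

    def test_outside_domain_label(self):
        assert classify_region(5.0, self.scheme) == OUTSIDE_DOMAIN
        assert classify_region(45.0, self.scheme) == OUTSIDE_DOMAIN

    def test_unsorted_cuts_rejected(self):
        with pytest.raises(ValidationError):
            RegionScheme(cuts=(21.0, 19.0, 24.0, 27.0))


class TestPrevalenceFilter:
    def _table(self, rows):
        counts = pd.DataFrame(
            rows, index=[f"o{i}" for i in range(len(rows))],
            columns=["a", "b", "c", "d"],
        )
        return OtuTable(counts, {c: "true_sample" for c in counts.columns})

    def test_prevalence_boundary(self):
        table = self._table(
            [
                [5, 9, 0, 0],   # prevalence 2 -> removed
                [1, 1, 1, 0],   # prevalence 3 -> retained
                [0, 0, 0, 0],   # all-zero -> removed
                [2, 2, 2, 2],
            ]
        )
        kept = prevalence_filter(table, min_prevalence=3)
        assert kept.otu_ids == ["o1", "o3"]

    def test_prevalence_counts_presence_not_abundance(self):
        table = self._table([[1000, 0, 0, 0]])
        assert prevalence_filter(table).otu_ids == []


class TestAggregation:
    def _table(self):
        counts = pd.DataFrame(
            [[4, 1], [6, 2], [5, 3], [1, 7], [2, 0]],
            index=["o0", "o1", "o2", "o3", "o4"],
            columns=["s1", "s2"],
        )
        return OtuTable(counts, {"s1": "true_sample", "s2": "true_sample"})

    def test_same_phylum_otus_sum_to_one_row(self):
        asg = [make_assignment(f"o{i}", ("d", "pA")) for i in range(5)]
        agg = aggregate_taxa(self._table(), asg, "phylum")
        assert agg.shape == (1, 2)
        assert agg.loc["pA"].tolist() == [18, 13]

    def test_column_sums_conserved_and_unassigned_pooled(self):
        asg = [
            make_assignment("o0", ("d", "pA")),
            make_assignment("o1", ("d", "pB")),
            make_assignment("o2", ("d",)),  # named only at domain
        ]  # o3, o4 have no assignment at all
        table = self._table()
        agg = aggregate_taxa(table, asg, "phylum")
        assert agg.sum(axis=0).tolist() == table.counts.sum(axis=0).tolist()
        assert agg.loc["Unassigned"].tolist() == [8, 10]

    def test_top_k_pools_remainder_into_other(self):
        asg = [make_assignment(f"o{i}", ("d", f"p{i}")) for i in range(5)]
        table = self._table()
        agg = aggregate_taxa(table, asg, "phylum", top_k=2)
        assert "other" in agg.index and len(agg) == 3
        assert agg.sum(axis=0).tolist() == table.counts.sum(axis=0).tolist()

    def test_top_k_larger_than_taxa_has_no_other(self):
        asg = [make_assignment(f"o{i}", ("d", f"p{i}")) for i in range(5)]
        agg = aggregate_taxa(self._table(), asg, "phylum", top_k=10)
        assert "other" not in agg.index

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_taxa(self._table(), [], "kingdom")

    def test_nested_phylum_class_view_conserves_totals(self):
        asg = [
            make_assignment("o0", ("d", "pA", "c1")),
            make_assignment("o1", ("d", "pA", "c2")),
            make_assignment("o2", ("d", "pA", "c3")),
            make_assignment("o3", ("d", "pB", "c4")),
            make_assignment("o4", ("d", "pC", "c5")),
        ]
        table = self._table()
        nested = aggregate_nested(table, asg, top_phyla=2, top_classes=2)
        assert nested.sum(axis=0).tolist() == table.counts.sum(axis=0).tolist()
        # pA keeps its top 2 classes, third pools into pA;other
        assert "pA;other" in nested.index
        # pC is outside the top 2 phyla -> plain "other"
        assert "other" in nested.index


class TestClrTransform:
    def _table(self, rows, cols=None):
        cols = cols or [f"s{i}" for i in range(len(rows[0]))]
        counts = pd.DataFrame(
            rows, index=[f"t{i}" for i in range(len(rows))], columns=cols
        )
        return OtuTable(counts, {c: "true_sample" for c in cols})

    def test_uniform_composition_maps_to_zero(self):
        clr = clr_transform(self._table([[1], [1], [1], [1]]), "none")
        assert np.allclose(clr.values.to_numpy(), 0.0)

    def test_closed_form_no_pseudocount(self):
        clr = clr_transform(self._table([[2], [4], [8]]), "none")
        expected = [math.log(0.5), 0.0, math.log(2.0)]
        assert np.allclose(clr.values.iloc[0].to_numpy(), expected)

    def test_scale_invariance_for_positive_rows(self):
        base = self._table([[2], [4], [8]])
        scaled = self._table([[20], [40], [80]])
        a = clr_transform(base, "none").values.to_numpy()
        b = clr_transform(scaled, "none").values.to_numpy()
        assert np.allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize(
        "mode", ["add_one", "add_half_min", "multiplicative_replacement"]
    )
    def test_row_sums_are_zero_for_all_modes(self, mode):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 50, size=(12, 8))
        rows[0, :] = 1  # keep all samples nonzero-total
        clr = clr_transform(self._table(rows.tolist()), mode)
        assert np.abs(clr.values.sum(axis=1).to_numpy()).max() < 1e-9

    def test_matches_skbio_on_positive_data(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(1, 100, size=(6, 5))
        ours = clr_transform(self._table(rows.tolist()), "none").values.to_numpy()
        theirs = skbio_clr(rows.T.astype(float))
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValidationError, match="zero total"):
            clr_transform(self._table([[0, 1], [0, 2]]), "add_one")

    def test_none_mode_requires_positive_counts(self):
        with pytest.raises(ValidationError):
            clr_transform(self._table([[0, 1], [3, 2]]), "none")


class TestCorrelationGrid:
    def _clr(self, values, samples, taxa):
        return ClrMatrix(
            values=pd.DataFrame(values, index=samples, columns=taxa),
            pseudocount_mode="none", pseudocount=0.0,
        )

    def test_affine_relation_gives_r_one(self):
        x = np.linspace(0, 1, 10)
        clr = self._clr(
            np.column_stack([2.0 * x + 3.0]), [f"s{i}" for i in range(10)], ["t"]
        )
        env = pd.DataFrame({"cov": x}, index=clr.values.index)
        grid = correlation_grid(clr, env, ["cov"])
        assert grid.r.loc["t", "cov"] == pytest.approx(1.0)

    def test_matches_naive_pairwise_oracle_with_missingness(self):
        rng = np.random.default_rng(7)
        taxa_vals = rng.normal(size=(20, 8))
        env = pd.DataFrame(
            {
                "a": rng.normal(size=20),
                "b": rng.normal(size=20),
            },
            index=[f"s{i}" for i in range(20)],
        )
        env.loc[env.index[:6], "b"] = np.nan
        clr = self._clr(taxa_vals, list(env.index), [f"t{j}" for j in range(8)])
        grid = correlation_grid(clr, env, ["a", "b"])
        for j in range(8):
            for cov in ("a", "b"):
                x = taxa_vals[:, j]
                y = env[cov].to_numpy()
                ok = ~np.isnan(y)
                num = np.sum(
                    (x[ok] - x[ok].mean()) * (y[ok] - y[ok].mean())
                )
                den = math.sqrt(
                    np.sum((x[ok] - x[ok].mean()) ** 2)
                    * np.sum((y[ok] - y[ok].mean()) ** 2)
                )
                assert grid.r.loc[f"t{j}", cov] == pytest.approx(
                    num / den, abs=1e-12
                )
                assert grid.n.loc[f"t{j}", cov] == ok.sum()

    def test_two_level_category_matches_point_biserial(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        cat = ["lo"] * 4 + ["hi"] * 4
        clr = self._clr(vals[:, None], [f"s{i}" for i in range(8)], ["t"])
        env = pd.DataFrame({"grp": cat}, index=clr.values.index)
        grid = correlation_grid(clr, env, [], categories=["grp"])
        # point-biserial closed form: r = (m1-m0)/s_n * sqrt(p*q)
        m1, m0 = vals[4:].mean(), vals[:4].mean()
        s = vals.std()
        expected = (m1 - m0) / s * math.sqrt(0.5 * 0.5)
        assert grid.r.loc["t", "grp=hi"] == pytest.approx(expected, abs=1e-12)
        assert grid.r.loc["t", "grp=lo"] == pytest.approx(-expected, abs=1e-12)

    def test_constant_column_is_missing_and_flagged(self):
        clr = self._clr(
            np.random.default_rng(0).normal(size=(5, 1)),
            [f"s{i}" for i in range(5)], ["t"],
        )
        env = pd.DataFrame({"const": [1.0] * 5}, index=clr.values.index)
        grid = correlation_grid(clr, env, ["const"])
        assert np.isnan(grid.r.loc["t", "const"])
        assert ("t", "const") in grid.flagged_constant

    def test_fewer_than_three_pairs_is_missing(self):
        clr = self._clr(
            np.arange(5, dtype=float)[:, None], [f"s{i}" for i in range(5)], ["t"]
        )
        env = pd.DataFrame(
            {"sparse": [1.0, 2.0, np.nan, np.nan, np.nan]}, index=clr.values.index
        )
        grid = correlation_grid(clr, env, ["sparse"])
        assert np.isnan(grid.r.loc["t", "sparse"])
        assert grid.n.loc["t", "sparse"] == 2
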