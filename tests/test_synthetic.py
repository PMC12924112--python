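import numpy as np
import pandas as pd
import pytest

from benthos16s.community import (
    aggregate_taxa,
    clr_transform,
    correlation_grid,
    derive_env_labels,
    prevalence_filter,
)
from benthos16s.decontam import remove_contaminants
from benthos16s.io_model import RANKS, FilterConfig
from benthos16s.synthetic import (
    CommunityDesign,
    gen_community,
    gen_hits,
    gen_reference,
    gen_survey,
)
from benthos16s.taxonomy import assign_taxonomy, lowest_common_ancestor, trim_by_identity

from _oracles import brute_force_lca


class TestGenReference:
    def test_seeded_determinism(self):
        a = gen_reference(50, seed=3)
        b = gen_reference(50, seed=3)
        assert a == b
        assert len(a) == 50
        assert len(set(a.values())) == 50  # unique lineages

    def test_different_seed_differs(self):
        assert gen_reference(50, seed=3) != gen_reference(50, seed=4)

    def test_hierarchy_consistency(self):
        """Two species sharing a genus share every rank above it, and so on
        up the hierarchy (no rank clashes across branches)."""
        lineages = list(gen_reference(200, seed=1).values())
        parent_of = {}
        for lin in lineages:
            assert lin.depth == len(RANKS)
            for d in range(1, lin.depth):
                child, parent = lin.names[d], lin.names[d - 1]
                assert parent_of.setdefault(child, parent) == parent

    def test_branching_produces_congeneric_species(self):
        lineages = list(gen_reference(200, seed=1).values())
        genera = {}
        for lin in lineages:
            genera.setdefault(lin.names[5], []).append(lin)
        assert any(len(v) > 1 for v in genera.values())

    def test_requested_phyla_are_exactly_used(self):
        phyla = ["p__A", "p__B", "p__C"]
        ref = gen_reference(60, seed=2, phyla=phyla)
        assert {lin.names[1] for lin in ref.values()} == set(phyla)


class TestGenHits:
    def test_seeded_determinism(self):
        lm = gen_reference(60, seed=0)
        h1, p1 = gen_hits(lm, 30, seed=5)
        h2, p2 = gen_hits(lm, 30, seed=5)
        assert p1 == p2
        assert h1 == h2

    def test_assignments_match_plan_derived_expectations(self):
        """The pipeline output on generated hits equals the expectation
        computed from the generator's plan by the documented rules: LCA of
        the within-margin subjects trimmed at the planted identity."""
        lm = gen_reference(120, seed=6)
        hits_by_otu, plans = gen_hits(lm, 500, seed=6)
        config = FilterConfig()
        results = {a.otu_id: a for a in assign_taxonomy(hits_by_otu, config)}
        for plan in plans:
            expected_lca = brute_force_lca(
                [lm[s] for s in plan.margin_subjects]
            )
            expected = trim_by_identity(expected_lca, plan.identity, config)
            assert results[plan.query_id].lineage == expected
            assert results[plan.query_id].max_identity == plan.identity

    def test_single_source_at_high_identity_reaches_species(self):
        lm = gen_reference(40, seed=7)
        hits_by_otu, plans = gen_hits(
            lm, 50, seed=7, p_multi_margin=0.0, identity_levels=(99.5,)
        )
        for a in assign_taxonomy(hits_by_otu):
            assert a.assigned_rank == "species"

    def test_within_margin_congeners_drive_lca_up(self):
        lm = gen_reference(60, seed=8)
        hits_by_otu, plans = gen_hits(
            lm, 80, seed=8, p_multi_margin=1.0, identity_levels=(99.5,)
        )
        results = {a.otu_id: a for a in assign_taxonomy(hits_by_otu)}
        for plan in plans:
            if len(plan.margin_subjects) > 1:
                lca = lowest_common_ancestor([lm[s] for s in plan.margin_subjects])
                assert results[plan.query_id].lineage.depth <= lca.depth


class TestGenCommunity:
    def test_seeded_determinism(self):
        t1, e1, tr1 = gen_community(seed=9)
        t2, e2, tr2 = gen_community(seed=9)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        pd.testing.assert_frame_equal(e1.df, e2.df)
        assert tr1.to_dict() == tr2.to_dict()

    def test_design_shape(self):
        design = CommunityDesign(samples_per_cell=2)
        table, env, truth = gen_community(design, seed=1)
        assert len(table.true_sample_ids) == 2 * 5 * 3
        assert len(table.control_ids) == 18
        strata = set(truth.stratum_of_sample.values())
        assert strata == {"epibenthic", "mesobenthic", "bathybenthic"}

    def test_oxygen_missingness_fraction(self):
        table, env, _ = gen_community(seed=2)
        frac = env.df["oxygen_saturation"].isna().mean()
        assert 0.05 < frac < 0.30

    def test_infeasible_design_rejected(self):
        with pytest.raises(ValueError):
            CommunityDesign(samples_per_cell=0)
        with pytest.raises(ValueError):
            CommunityDesign(n_otus=50, base_richness=140)

    def test_null_design_correlations_centre_on_zero(self):
        phyla = [f"p__SimPhylum{i:02d}" for i in range(15)]
        null_eff = pd.DataFrame(
            0.0, index=phyla, columns=["latitude", "depth_m", "oxygen_saturation"]
        )
        rs = []
        for seed in range(8):
            design = CommunityDesign(effects=null_eff, richness_slopes={
                "epibenthic": 0.0, "mesobenthic": 0.0, "bathybenthic": 0.0})
            table, env, truth = gen_community(design, seed=seed)
            clean, _ = remove_contaminants(table)
            filt = prevalence_filter(clean)
            labels = {
                o: truth.phylum_of_otu[o]
                for o in filt.otu_ids if o in truth.phylum_of_otu
            }
            agg = filt.counts.groupby(
                pd.Index([labels.get(o, "x") for o in filt.otu_ids])
            ).sum()
            clr = clr_transform(agg, "add_one")
            env_df = env.aligned_to(clr.sample_ids)
            grid = correlation_grid(clr, env_df, ["latitude", "depth_m"])
            rs.append(grid.r.to_numpy(dtype=float))
        mean_r = np.nanmean(np.concatenate([r.ravel() for r in rs]))
        assert abs(mean_r) < 0.05

    def test_planted_oxygen_loading_recovered_with_negative_sign(self):
        hits = 0
        reps = 10
        for seed in range(reps):
            table, env, truth = gen_community(seed=100 + seed)
            clean, _ = remove_contaminants(table)
            filt = prevalence_filter(clean)
            labels = {
                o: truth.phylum_of_otu[o]
                for o in filt.otu_ids if o in truth.phylum_of_otu
            }
            agg = filt.counts.groupby(
                pd.Index([labels.get(o, "x") for o in filt.otu_ids])
            ).sum()
            clr = clr_transform(agg, "add_one")
            grid = correlation_grid(
                clr, env.aligned_to(clr.sample_ids), ["oxygen_saturation"]
            )
            # p__SimPhylum00 is the Chloroflexi-like phylum: planted b_oxy < 0
            hits += grid.r.loc["p__SimPhylum00", "oxygen_saturation"] < 0
        assert hits >= 0.95 * reps

    def test_planted_contaminants_recovered_in_report(self):
        table, _, truth = gen_community(seed=3)
        _, report = remove_contaminants(table)
        for otu in truth.contaminant_otus:
            assert report.contamination_proportion.get(otu, 0) > 0

    def test_planted_richness_close_to_realised(self):
        table, _, truth = gen_community(seed=4)
        samples = table.true_sample_ids
        community = [o for o in table.otu_ids if o in truth.phylum_of_otu]
        realised = (table.counts.loc[community, samples] > 0).sum(axis=0)
        planted = pd.Series(truth.planted_richness)
        diff = (realised - planted.loc[samples]).abs()
        assert diff.median() <= 5


class TestGenSurvey:
    def test_pipeline_taxonomy_recovers_planted_phyla(self):
        survey = gen_survey(seed=5)
        truth = survey["truth"]
        assignments = assign_taxonomy(survey["hits_by_otu"])
        for a in assignments:
            assert a.lineage.depth >= 2  # at least phylum resolves
            assert a.lineage.names[1] == truth.phylum_of_otu[a.otu_id]

    def test_headline_structures_reproduced_end_to_end(self):
        """The default design reproduces the three headline patterns:
        depth-stratified composition, a latitudinal composition gradient,
        and sloped epibenthic but flat bathybenthic richness."""
        from benthos16s.trends import otu_richness, stratified_regression

        survey = gen_survey(seed=5)
        assignments = assign_taxonomy(survey["hits_by_otu"])
        clean, _ = remove_contaminants(survey["table"])
        filt = prevalence_filter(clean)
        agg = aggregate_taxa(filt, assignments, "phylum", top_k=12)
        clr = clr_transform(agg)
        env_df = derive_env_labels(survey["env"].aligned_to(clr.sample_ids))
        grid = correlation_grid(
            clr, env_df, ["latitude", "depth_m", "oxygen_saturation"]
        )
        # latitudinal + bathymetric composition gradients: at least one
        # strong association each among the planted phyla
        assert grid.r["latitude"].abs().max() > 0.5
        assert grid.r["depth_m"].abs().max() > 0.5
        rich = otu_richness(filt)
        fits = {
            f.stratum: f
            for f in stratified_regression(
                rich, env_df["latitude"], env_df["depth_category"]
            )
        }
        assert fits["epibenthic"].slope < 0
        assert fits["epibenthic"].p_value <= 0.05
        assert fits["bathybenthic"].p_value > 0.05
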