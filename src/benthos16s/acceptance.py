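"""Replicated simulation protocols behind the package's validation suite.

Each function runs one self-contained property or recovery protocol — the
taxonomy brute-force comparison, margin monotonicity, decontamination
recovery, clr closure, the RDA linear-algebra oracle, forward-selection
driver recovery, permutation-test null calibration, regression CI coverage,
the stratified richness-slope qualitative check, and pipeline determinism —
and returns plain numbers. The test suite asserts on them; the acceptance
script reports them.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kstest

from . import community, decontam, ordination, trends
from .io_model import RANKS, FilterConfig, Lineage
from .synthetic import (
    CommunityDesign,
    gen_community,
    gen_hits,
    gen_rda_problem,
    gen_reference,
    gen_survey,
)
from .taxonomy import assign_taxonomy


# -- taxonomy ----------------------------------------------------------------


def _oracle_lca(lineages) -> Lineage:
    for depth in range(len(RANKS), 0, -1):
        prefixes = {
            lin.names[:depth] if lin.depth >= depth else None for lin in lineages
        }
        if None not in prefixes and len(prefixes) == 1:
            return Lineage(next(iter(prefixes)))
    return Lineage(())


def _oracle_assign(hits, config: FilterConfig) -> Lineage:
    """Rank-by-rank brute-force application of the filtering rules, written
    independently of the taxonomy module's code path."""
    usable = [h for h in hits if h.lineage is not None]
    if config.low_score_rule == "or":
        kept = [
            h
            for h in usable
            if h.bitscore >= config.bitscore_min
            and h.alignment_length >= config.alen_min
        ]
    else:
        kept = [
            h
            for h in usable
            if h.bitscore >= config.bitscore_min
            or h.alignment_length >= config.alen_min
        ]
    if not kept:
        return Lineage(())
    best = max(h.bitscore for h in kept)
    kept = [h for h in kept if h.bitscore >= (1 - config.margin_fraction) * best]
    lca = _oracle_lca([h.lineage for h in kept])
    identity = max(h.pct_identity for h in kept)
    permitted = 1 if config.retain_domain else 0
    for rank in ("species", "genus", "family", "order", "class", "phylum"):
        if identity > config.identity_cutoffs[rank]:
            permitted = RANKS.index(rank) + 1
            break
    return Lineage(lca.names[:permitted])


def taxonomy_oracle_agreement(n_sets: int = 1000, seed: int = 0) -> float:
    """Percent of random hit sets on which the pipeline assignment equals
    the brute-force oracle."""
    lineage_map = gen_reference(150, seed=seed)
    hits_by_otu, _ = gen_hits(lineage_map, n_sets, seed=seed + 1)
    config = FilterConfig()
    results = assign_taxonomy(hits_by_otu, config)
    agree = sum(
        a.lineage == _oracle_assign(hits_by_otu[a.otu_id], config) for a in results
    )
    return 100.0 * agree / len(results)


def margin_monotonicity_violations(
    n_sets: int = 200,
    margins: tuple[float, ...] = (0.0, 0.02, 0.05, 0.1),
    seed: int = 0,
) -> int:
    """Number of (hit set, margin step) pairs where widening the bitscore
    margin deepened the assignment. Zero by the ancestor-or-equal property."""
    lineage_map = gen_reference(150, seed=seed)
    hits_by_otu, _ = gen_hits(lineage_map, n_sets, seed=seed + 1)
    depth_by_margin = []
    for m in margins:
        cfg = FilterConfig(margin_fraction=m)
        depth_by_margin.append(
            {a.otu_id: a.lineage.depth for a in assign_taxonomy(hits_by_otu, cfg)}
        )
    violations = 0
    for prev, nxt in zip(depth_by_margin, depth_by_margin[1:]):
        violations += sum(nxt[o] > prev[o] for o in prev)
    return violations


# -- decontamination ---------------------------------------------------------


def decontam_recovery(seed: int = 0) -> dict[str, float]:
    """Planted-read removal fraction and the count-monotonicity check on the
    default synthetic design."""
    table, _, truth = gen_community(CommunityDesign(), seed=seed)
    clean, _ = decontam.remove_contaminants(table)
    residual = sum(
        int(clean.counts.loc[o].sum())
        for o in truth.contaminant_otus
        if o in clean.counts.index
    )
    planted = truth.planted_contaminant_sample_reads
    inp = table.counts.loc[clean.otu_ids, clean.sample_ids].to_numpy()
    exceed = int((clean.counts.to_numpy() > inp).sum())
    return {
        "removed_pct": 100.0 * (planted - residual) / planted,
        "counts_exceeding_input": exceed,
    }


# -- clr ---------------------------------------------------------------------


def clr_invariants(seed: int = 0) -> dict[str, float]:
    """Worst row-sum deviation across every transformed sample of the
    default survey, and the worst scale-invariance error at delta = 0."""
    table, _, _ = gen_community(seed=seed)
    clean, _ = decontam.remove_contaminants(table)
    filt = community.prevalence_filter(clean)
    worst = 0.0
    for mode in ("add_one", "add_half_min", "multiplicative_replacement"):
        clr = community.clr_transform(filt, mode)
        worst = max(worst, float(np.abs(clr.values.sum(axis=1)).max()))
    rng = np.random.default_rng(seed)
    pos = pd.DataFrame(
        rng.integers(1, 200, size=(10, 6)),
        index=[f"t{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(6)],
    )
    a = community.clr_transform(pos, "none").values.to_numpy()
    b = community.clr_transform(pos * 17, "none").values.to_numpy()
    return {
        "max_abs_row_sum": worst,
        "scale_invariance_max_err": float(np.abs(a - b).max()),
    }


# -- ordination --------------------------------------------------------------


def rda_oracle_max_error(
    n_problems: int = 50, n: int = 15, p: int = 6, m: int = 3, seed: int = 0
) -> dict[str, float]:
    """Worst eigenvalue discrepancy against an explicit projection +
    eigendecomposition oracle, plus the PCA-equivalence error under a
    saturated constraint basis."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        Y = rng.normal(size=(n, p))
        X = rng.normal(size=(n, m))
        res = ordination.rda(pd.DataFrame(Y), pd.DataFrame(X))
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        Yhat = Xc @ beta
        lam_c = np.linalg.eigvalsh(Yhat.T @ Yhat / (n - 1))[::-1]
        lam_c = lam_c[: len(res.constrained_eigenvalues)]
        worst = max(worst, float(np.abs(res.constrained_eigenvalues - lam_c).max()))
        lam_r = np.linalg.eigvalsh((Yc - Yhat).T @ (Yc - Yhat) / (n - 1))[::-1]
        lam_r = lam_r[: len(res.unconstrained_eigenvalues)]
        worst = max(
            worst, float(np.abs(res.unconstrained_eigenvalues - lam_r).max())
        )
    # PCA equivalence under a saturated full-rank basis
    Y = rng.normal(size=(10, 4))
    res = ordination.rda(pd.DataFrame(Y), pd.DataFrame(np.eye(10)[:, :9]))
    Yc = Y - Y.mean(axis=0)
    pca = np.linalg.eigvalsh(Yc.T @ Yc / 9)[::-1]
    pca = pca[: len(res.constrained_eigenvalues)]
    pca_err = float(np.abs(res.constrained_eigenvalues - pca).max())
    return {"max_eigenvalue_error": worst, "pca_equivalence_error": pca_err}


def forward_selection_recovery(
    n_replicates: int = 100, n_perm: int = 199, seed: int = 0
) -> float:
    """Percent of replicates in which forward selection picks exactly the
    three planted drivers out of eight candidates."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_replicates):
        s = int(rng.integers(2**31))
        Y, X, drivers = gen_rda_problem(seed=s)
        res = ordination.forward_select(
            Y,
            ordination.expand_candidates(X, list(X.columns)),
            alpha=0.05,
            n_perm=n_perm,
            seed=s % (2**31 - 1),
        )
        exact += sorted(res.selected) == sorted(drivers)
    return 100.0 * exact / n_replicates


def permutation_null_ks(
    n_replicates: int = 1000, n_perm: int = 199, seed: int = 0
) -> float:
    """Kolmogorov-Smirnov distance of null permutation p-values from
    uniform."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_replicates)
    for i in range(n_replicates):
        Y = rng.normal(size=(30, 5))
        x = rng.normal(size=30)
        _, ps[i] = ordination.permutation_test(
            Y, x, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
    return float(kstest(ps, "uniform").statistic)


# -- trends ------------------------------------------------------------------


def regression_ci_coverage(
    n_sims: int = 1000, n: int = 40, slope: float = -300.0, noise_sd: float = 200.0,
    seed: int = 0,
) -> float:
    """Percent of simulations in which the slope's 95% CI covers the planted
    slope under correctly specified Gaussian noise."""
    rng = np.random.default_rng(seed)
    covered = 0
    from scipy.stats import t as t_dist

    tcrit = t_dist.ppf(0.975, n - 2)
    for _ in range(n_sims):
        lat = rng.uniform(16, 29.5, size=n)
        rich = 8000 + slope * lat + rng.normal(0, noise_sd, size=n)
        [fit] = trends.stratified_regression(
            pd.Series(rich), pd.Series(lat), pd.Series(["s"] * n)
        )
        covered += abs(fit.slope - slope) <= tcrit * fit.slope_se
    return 100.0 * covered / n_sims


def richness_slope_qualitative(
    n_replicates: int = 100, seed: int = 0
) -> dict[str, float]:
    """On the default design: percent of replicates with a detected negative
    epibenthic slope (p <= 0.05) and percent with the flat bathybenthic
    slope not rejected (p > 0.05)."""
    rng = np.random.default_rng(seed)
    epi_detected = bathy_flat = 0
    for _ in range(n_replicates):
        s = int(rng.integers(2**31))
        table, env, _ = gen_community(seed=s)
        clean, _ = decontam.remove_contaminants(table)
        filt = community.prevalence_filter(clean)
        env_df = community.derive_env_labels(env.aligned_to(filt.sample_ids))
        rich = trends.otu_richness(filt)
        fits = {
            f.stratum: f
            for f in trends.stratified_regression(
                rich, env_df["latitude"], env_df["depth_category"]
            )
        }
        epi = fits["epibenthic"]
        epi_detected += epi.slope < 0 and epi.p_value <= 0.05
        bathy_flat += fits["bathybenthic"].p_value > 0.05
    return {
        "epibenthic_detected_pct": 100.0 * epi_detected / n_replicates,
        "bathybenthic_not_rejected_pct": 100.0 * bathy_flat / n_replicates,
    }


# -- pipeline ----------------------------------------------------------------


def pipeline_determinism(work_dir: str | Path, seed: int = 0) -> bool:
    """Run the end-to-end pipeline twice on identical inputs and config;
    True when every TSV/JSON artifact is byte-identical."""
    from .io_model import (
        write_env_table,
        write_hits,
        write_lineage_map,
        write_otu_table,
    )
    from .pipeline import PipelineConfig, run_all

    work = Path(work_dir)
    data = work / "data"
    data.mkdir(parents=True, exist_ok=True)
    survey = gen_survey(CommunityDesign(samples_per_cell=3), seed=seed)
    write_lineage_map(survey["lineage_map"], data / "lineages.tsv")
    write_hits(
        [h for hs in survey["hits_by_otu"].values() for h in hs], data / "hits.tsv"
    )
    write_otu_table(survey["table"], data / "otu.tsv", data / "roles.tsv")
    write_env_table(survey["env"], data / "meta.csv")

    runs = []
    for tag in ("r1", "r2"):
        config = PipelineConfig(
            hits_path=str(data / "hits.tsv"),
            lineages_path=str(data / "lineages.tsv"),
            otu_table_path=str(data / "otu.tsv"),
            roles_path=str(data / "roles.tsv"),
            metadata_path=str(data / "meta.csv"),
            out_dir=str(work / tag),
            n_perm=99,
            seed=seed,
        )
        runs.append(run_all(config))
    identical = True
    for p in sorted(runs[0].iterdir()):
        # the resolved config legitimately differs in its out_dir field
        if p.suffix in (".tsv", ".json") and p.name != "run.log":
            identical &= filecmp.cmp(p, runs[1] / p.name, shallow=False)
    return identical
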