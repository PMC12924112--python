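"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure of a Red Sea benthic 16S
survey without any sequence data:

* :func:`gen_reference` builds a hierarchy-consistent reference taxonomy
  (several species per genus, several genera per family, ...).
* :func:`gen_hits` emits tabular similarity hits per query OTU — a true
  source hit at a planted identity plus decoys (within-margin relatives,
  off-margin hits, sub-threshold hits) — such that the expected consensus
  assignment is computable from the plan by the documented filtering rules.
* :func:`gen_community` draws an OTU-by-sample count table over a region x
  depth-stratum sampling design with planted compositional gradients
  (phylum log-abundance linear in latitude, depth and oxygen), planted
  per-stratum richness-latitude slopes (negative epibenthic, zero
  bathybenthic), contaminant OTUs present in every library including blanks,
  and matching environmental metadata with partially missing oxygen.

Counts follow a log-normal-Poisson compound (per-OTU log-normal noise on the
expected relative abundance, then a Poisson draw), giving the
overdispersion real amplicon libraries show. Every generator is bit-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .community import RegionScheme, classify_depth, classify_region
from .io_model import (
    EnvTable,
    Lineage,
    OtuTable,
    RANKS,
    SimilarityHit,
)

__all__ = [
    "HitPlan",
    "CommunityDesign",
    "SyntheticTruth",
    "gen_reference",
    "gen_hits",
    "gen_community",
    "gen_survey",
    "gen_rda_problem",
    "default_effects",
]

_RANK_PREFIX = ("d", "p", "c", "o", "f", "g", "s")

#: depth ranges (m) sampled per stratum
_STRATUM_DEPTH = {
    "epibenthic": (20.0, 199.0),
    "mesobenthic": (200.0, 1000.0),
    "bathybenthic": (1000.5, 2415.0),
}

#: identity levels a query may be planted at, spanning every trimming band
_IDENTITY_LEVELS = (99.5, 98.0, 96.5, 93.0, 87.5, 82.0, 77.0, 70.0)


# ---------------------------------------------------------------------------
# Reference taxonomy
# ---------------------------------------------------------------------------


def gen_reference(
    n_taxa: int, seed: int = 0, phyla: list[str] | None = None
) -> dict[str, Lineage]:
    """Generate ``n_taxa`` unique, hierarchy-consistent species lineages.

    New lineages diverge from a randomly chosen existing lineage at a random
    rank, biased deep so genera hold several species. With ``phyla`` given,
    every named phylum is seeded with its own subtree (divergence then stays
    at class level or below, so the phylum set is exactly as requested).
    Returns a mapping of reference subject id -> full 7-rank lineage.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if phyla is not None and n_taxa < len(phyla):
        raise ValueError("n_taxa must cover every requested phylum")
    rng = np.random.default_rng(seed)
    counters = [0] * len(RANKS)

    def fresh(rank_idx: int) -> str:
        counters[rank_idx] += 1
        return f"{_RANK_PREFIX[rank_idx]}__Taxon{counters[rank_idx]:04d}"

    lineages: list[Lineage] = []
    if phyla is None:
        lineages.append(Lineage(tuple(fresh(i) for i in range(len(RANKS)))))
        # divergence depth 0 = new domain ... 6 = new species under same genus
        depth_probs = np.array([0.01, 0.05, 0.08, 0.10, 0.16, 0.25, 0.35])
    else:
        domain = fresh(0)
        for p in phyla:
            lineages.append(
                Lineage((domain, p) + tuple(fresh(i) for i in range(2, len(RANKS))))
            )
        # never diverge above class, keeping the requested phylum set intact
        depth_probs = np.array([0.0, 0.0, 0.14, 0.10, 0.16, 0.25, 0.35])
    depth_probs = depth_probs / depth_probs.sum()
    while len(lineages) < n_taxa:
        template = lineages[rng.integers(len(lineages))]
        d = int(rng.choice(len(RANKS), p=depth_probs))
        names = template.names[:d] + tuple(
            fresh(i) for i in range(d, len(RANKS))
        )
        lineages.append(Lineage(names))
    return {f"ref_{i:05d}": lin for i, lin in enumerate(lineages)}


# ---------------------------------------------------------------------------
# Similarity hits
# ---------------------------------------------------------------------------


@dataclass
class HitPlan:
    """Planted structure behind one query's hit list.

    ``margin_subjects`` are the subjects intended to survive the bitscore
    margin; the expected assignment is the LCA of their lineages trimmed by
    ``identity`` under the default cutoffs.
    """

    query_id: str
    source_subject: str
    identity: float
    margin_subjects: list[str]
    n_decoys_off_margin: int
    n_decoys_subthreshold: int


def _relative_subject(
    lineage_map: Mapping[str, Lineage],
    subject: str,
    max_shared: int,
    rng,
    min_shared: int = 0,
) -> str | None:
    """Pick another subject sharing between ``min_shared`` and ``max_shared``
    leading ranks with ``subject``."""
    base = lineage_map[subject]
    ids = list(lineage_map)
    for _ in range(50):
        cand = ids[rng.integers(len(ids))]
        if cand == subject:
            continue
        shared = 0
        other = lineage_map[cand]
        for a, b in zip(base.names, other.names):
            if a == b:
                shared += 1
            else:
                break
        if min_shared <= shared <= max_shared:
            return cand
    return None


def gen_hits(
    lineage_map: Mapping[str, Lineage],
    n_queries: int | None = None,
    seed: int = 0,
    p_multi_margin: float = 0.4,
    max_decoys: int = 4,
    source_of_query: Mapping[str, str] | None = None,
    identity_levels: tuple[float, ...] = _IDENTITY_LEVELS,
    identity_probs: tuple[float, ...] | None = None,
    min_shared_margin: int = 0,
) -> tuple[dict[str, list[SimilarityHit]], list[HitPlan]]:
    """Emit hit lists with known expected assignments.

    Each query gets a top hit at a planted identity against its true source
    subject; with probability ``p_multi_margin`` additional relatives land
    within the 2% bitscore margin (driving the LCA above species); further
    decoys fall off-margin or below the score thresholds and must not affect
    the assignment. With ``source_of_query`` the queries and their source
    subjects are fixed by the caller (used to tie hits to a planted
    community); ``min_shared_margin`` keeps within-margin relatives at or
    below a shared rank depth (2 = same phylum).
    """
    rng = np.random.default_rng(seed)
    subjects = list(lineage_map)
    if source_of_query is None:
        if n_queries is None:
            raise ValueError("pass n_queries or source_of_query")
        source_of_query = {
            f"otu_{qi:05d}": subjects[rng.integers(len(subjects))]
            for qi in range(n_queries)
        }
    probs = None if identity_probs is None else np.asarray(identity_probs)
    hits_by_otu: dict[str, list[SimilarityHit]] = {}
    plans: list[HitPlan] = []
    for query, source in source_of_query.items():
        identity = float(rng.choice(identity_levels, p=probs))
        alen = int(rng.integers(250, 460))
        top_bs = float(np.round(1.8 * alen * identity / 100.0, 1))
        hits = [
            SimilarityHit(
                query_id=query,
                subject_id=source,
                pct_identity=identity,
                alignment_length=alen,
                evalue=1e-30,
                bitscore=top_bs,
                lineage=lineage_map[source],
            )
        ]
        margin_subjects = [source]
        if rng.random() < p_multi_margin:
            # relatives within the margin sharing a random number of ranks
            for _ in range(int(rng.integers(1, 3))):
                max_shared = int(rng.integers(min_shared_margin, len(RANKS)))
                rel = _relative_subject(
                    lineage_map, source, max_shared, rng,
                    min_shared=min_shared_margin,
                )
                if rel is None:
                    continue
                bs = float(np.round(top_bs * (1.0 - 0.019 * rng.random()), 1))
                ident = float(
                    np.round(max(50.0, identity - 3.0 * rng.random()), 1)
                )
                hits.append(
                    SimilarityHit(
                        query_id=query,
                        subject_id=rel,
                        pct_identity=ident,
                        alignment_length=alen,
                        evalue=1e-25,
                        bitscore=bs,
                        lineage=lineage_map[rel],
                    )
                )
                margin_subjects.append(rel)
        n_off = int(rng.integers(0, max_decoys + 1))
        for _ in range(n_off):
            decoy = subjects[rng.integers(len(subjects))]
            bs = float(np.round(top_bs * (0.90 - 0.3 * rng.random()), 1))
            hits.append(
                SimilarityHit(
                    query_id=query,
                    subject_id=decoy,
                    pct_identity=float(np.round(70 + 20 * rng.random(), 1)),
                    alignment_length=alen,
                    evalue=1e-10,
                    bitscore=max(bs, 151.0),
                    lineage=lineage_map[decoy],
                )
            )
        n_sub = int(rng.integers(0, max_decoys + 1))
        for _ in range(n_sub):
            decoy = subjects[rng.integers(len(subjects))]
            if rng.random() < 0.5:
                bs, dec_alen = float(rng.integers(60, 150)), alen  # low bitscore
            else:
                bs, dec_alen = 200.0, int(rng.integers(30, 100))  # short alignment
            hits.append(
                SimilarityHit(
                    query_id=query,
                    subject_id=decoy,
                    pct_identity=float(np.round(75 + 20 * rng.random(), 1)),
                    alignment_length=dec_alen,
                    evalue=1e-6,
                    bitscore=bs,
                    lineage=lineage_map[decoy],
                )
            )
        order = rng.permutation(len(hits))
        hits_by_otu[query] = [hits[i] for i in order]
        plans.append(
            HitPlan(
                query_id=query,
                source_subject=source,
                identity=identity,
                margin_subjects=margin_subjects,
                n_decoys_off_margin=n_off,
                n_decoys_subthreshold=n_sub,
            )
        )
    return hits_by_otu, plans


# ---------------------------------------------------------------------------
# Community counts + environment
# ---------------------------------------------------------------------------


def default_effects(phyla: list[str]) -> pd.DataFrame:
    """Planted phylum-by-covariate log-abundance loadings.

    The first phyla mimic the survey's headline taxa: a Chloroflexi-like
    phylum loading negatively on oxygen and latitude, a Proteobacteria-like
    phylum loading positively on both, depth-loving Gemmatimonadota/
    Acidobacteriota analogues, and a shallow-loving Planctomycetota analogue.
    Remaining phyla carry no planted effect.
    """
    eff = pd.DataFrame(
        0.0, index=phyla, columns=["latitude", "depth_m", "oxygen_saturation"]
    )
    patterns = [
        (-1.1, 0.0, -0.9),  # Chloroflexi-like: southern, low oxygen
        (0.9, -0.4, 0.9),  # Proteobacteria-like: northern, oxygenated, shallow
        (0.8, 1.0, 0.0),  # Gemmatimonadota-like: deep, northern
        (0.7, 0.9, 0.0),  # Acidobacteriota-like: deep, northern
        (0.0, -1.0, 0.0),  # Planctomycetota-like: shallow
        (-0.8, -0.6, 0.0),  # Desulfobacterota-like: southern, shallow
        (0.0, 1.0, 0.0),  # Methylomirabilota-like: deep
    ]
    for (b_lat, b_dep, b_oxy), phylum in zip(patterns, phyla):
        eff.loc[phylum] = [b_lat, b_dep, b_oxy]
    return eff


@dataclass
class CommunityDesign:
    """Sampling design and planted parameters of the synthetic survey.

    Defaults give 5 regions x 3 depth strata x 6 samples = 90 true samples
    plus 6 field + 6 extraction + 6 PCR blanks, 400 community OTUs in 15
    phyla, and richness declining northwards in the epibenthic stratum while
    flat in the bathybenthic stratum.
    """

    samples_per_cell: int = 6
    n_otus: int = 400
    n_phyla: int = 15
    n_contaminants: int = 6
    contaminant_load: float = 300.0
    contaminant_smear: float = 0.5
    carryover_rate: float = 0.3
    library_size: float = 30000.0
    library_sigma: float = 0.35
    overdispersion_sigma: float = 0.5
    base_richness: int = 140
    richness_slopes: dict = field(
        default_factory=lambda: {
            "epibenthic": -6.0,
            "mesobenthic": -3.5,
            "bathybenthic": 0.0,
        }
    )
    richness_noise_sd: float = 6.0
    oxygen_missing_fraction: float = 0.15
    oxygen_noise_sd: float = 8.0
    n_controls_per_role: int = 6
    region_scheme: RegionScheme = field(default_factory=RegionScheme)
    lat_range: tuple[float, float] = (16.0, 29.5)
    effects: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.samples_per_cell < 1 or self.n_otus < self.base_richness:
            raise ValueError("infeasible design: empty cells or too few OTUs")


@dataclass
class SyntheticTruth:
    """Planted parameters serialised alongside every generated dataset."""

    seed: int
    phylum_of_otu: dict[str, str]
    effects: dict
    richness_slopes: dict[str, float]
    contaminant_otus: list[str]
    planted_contaminant_sample_reads: int
    planted_richness: dict[str, int]
    stratum_of_sample: dict[str, str]
    region_of_sample: dict[str, str]

    def to_dict(self) -> dict:
        return asdict(self)


def _band_bounds(scheme: RegionScheme, idx: int, lat_range) -> tuple[float, float]:
    lo = lat_range[0] if idx == 0 else scheme.cuts[idx - 1]
    hi = lat_range[1] if idx == len(scheme.cuts) else scheme.cuts[idx]
    return lo, hi


def gen_community(
    design: CommunityDesign | None = None, seed: int = 0
) -> tuple[OtuTable, EnvTable, SyntheticTruth]:
    """Draw the full synthetic survey: counts, metadata, and ground truth."""
    design = design or CommunityDesign()
    rng = np.random.default_rng(seed)
    scheme = design.region_scheme
    strata = list(_STRATUM_DEPTH)

    phyla = [f"p__SimPhylum{i:02d}" for i in range(design.n_phyla)]
    effects = design.effects if design.effects is not None else default_effects(phyla)
    phylum_of_otu = {
        f"otu_{i:05d}": phyla[int(rng.integers(design.n_phyla))]
        for i in range(design.n_otus)
    }
    otu_ids = list(phylum_of_otu)
    baseline = rng.normal(0.0, 1.2, size=design.n_otus)  # OTU commonness

    # --- samples and environment -----------------------------------------
    rows = []
    sample_ids = []
    k = 0
    for ri in range(len(scheme.labels)):
        lo, hi = _band_bounds(scheme, ri, design.lat_range)
        for stratum in strata:
            dlo, dhi = _STRATUM_DEPTH[stratum]
            for _ in range(design.samples_per_cell):
                sid = f"S{k:03d}"
                k += 1
                lat = float(rng.uniform(lo, hi))
                depth = float(rng.uniform(dlo, dhi))
                temp = 30.0 - 0.004 * depth - 0.3 * (lat - 16.0) + rng.normal(0, 1.5)
                sal = 36.0 + 0.35 * (lat - 16.0) + rng.normal(0, 0.4)
                oxy = float(
                    np.clip(
                        30.0
                        + 2.2 * (lat - 16.0)
                        - 0.012 * depth
                        + rng.normal(0, design.oxygen_noise_sd),
                        1.0,
                        120.0,
                    )
                )
                sample_ids.append(sid)
                rows.append((sid, lat, 38.5 + rng.normal(0, 0.8), depth, temp, sal, oxy, stratum))
    env = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "latitude",
            "longitude",
            "depth_m",
            "temperature",
            "salinity",
            "oxygen_saturation",
            "stratum",
        ],
    )
    n_missing = int(round(design.oxygen_missing_fraction * len(env)))
    if n_missing:
        miss_idx = rng.choice(len(env), size=n_missing, replace=False)
        env.loc[env.index[miss_idx], "oxygen_saturation"] = np.nan

    # --- counts ------------------------------------------------------------
    z_lat = (env["latitude"].to_numpy() - 23.0) / 4.0
    z_dep = (env["depth_m"].to_numpy() - 800.0) / 700.0
    oxy_filled = env["oxygen_saturation"].to_numpy(dtype=float)
    # planted effects act on the measured value; where oxygen goes unmeasured
    # the latent value still acts, so fill from the systematic part
    latent_oxy = (
        30.0 + 2.2 * (env["latitude"].to_numpy() - 16.0) - 0.012 * env["depth_m"].to_numpy()
    )
    oxy_eff = np.where(np.isnan(oxy_filled), latent_oxy, oxy_filled)
    z_oxy = (oxy_eff - 50.0) / 25.0

    B = effects.to_numpy()  # phyla x 3
    phylum_idx = np.array([phyla.index(phylum_of_otu[o]) for o in otu_ids])
    Zcov = np.column_stack([z_lat, z_dep, z_oxy])  # samples x 3
    phylum_effect = Zcov @ B.T  # samples x phyla

    counts = np.zeros((design.n_otus, len(sample_ids)), dtype=int)
    planted_richness: dict[str, int] = {}
    lat_mid = 23.0
    for si, sid in enumerate(sample_ids):
        stratum = env.loc[si, "stratum"]
        slope = design.richness_slopes[stratum]
        target = design.base_richness + slope * (env.loc[si, "latitude"] - lat_mid)
        target += rng.normal(0, design.richness_noise_sd)
        target = int(np.clip(round(target), 20, design.n_otus))
        planted_richness[sid] = target
        # weighted sampling without replacement via Gumbel-max on commonness
        keys = baseline + rng.gumbel(size=design.n_otus)
        present = np.argsort(keys)[::-1][:target]
        logw = (
            baseline[present]
            + phylum_effect[si, phylum_idx[present]]
            + rng.normal(0, design.overdispersion_sigma, size=target)
        )
        p = np.exp(logw - logw.max())
        p /= p.sum()
        n_lib = rng.lognormal(np.log(design.library_size), design.library_sigma)
        counts[present, si] = rng.poisson(n_lib * p)

    count_df = pd.DataFrame(counts, index=otu_ids, columns=sample_ids)

    # --- contaminants and controls ----------------------------------------
    contam_ids = [f"contam_{i:02d}" for i in range(design.n_contaminants)]
    contam_load = design.contaminant_load * np.exp(
        rng.normal(0, 0.3, size=design.n_contaminants)
    )
    control_ids, roles = [], {s: "true_sample" for s in sample_ids}
    for role in ("field_control", "extraction_control", "pcr_control"):
        for j in range(design.n_controls_per_role):
            cid = f"{role[:3]}_ctrl_{j}"
            control_ids.append(cid)
            roles[cid] = role

    contam_sample = rng.poisson(
        np.outer(contam_load * design.contaminant_smear, np.ones(len(sample_ids)))
    )
    contam_control = rng.poisson(np.outer(contam_load, np.ones(len(control_ids))))
    contam_df = pd.DataFrame(
        np.hstack([contam_sample, contam_control]),
        index=contam_ids,
        columns=sample_ids + control_ids,
    )

    # trace carry-over of genuinely present OTUs into blanks
    common = np.argsort(baseline)[::-1][:20]
    carry = rng.poisson(
        design.carryover_rate, size=(len(common), len(control_ids))
    )
    control_block = pd.DataFrame(
        0, index=otu_ids, columns=control_ids, dtype=int
    )
    control_block.iloc[common, :] = carry

    full = pd.concat(
        [pd.concat([count_df, control_block], axis=1), contam_df], axis=0
    )
    table = OtuTable(full, roles)
    env_table = EnvTable(env.drop(columns=["stratum"]))

    truth = SyntheticTruth(
        seed=seed,
        phylum_of_otu=phylum_of_otu,
        effects={p: effects.loc[p].to_dict() for p in effects.index},
        richness_slopes=dict(design.richness_slopes),
        contaminant_otus=contam_ids,
        planted_contaminant_sample_reads=int(contam_sample.sum()),
        planted_richness=planted_richness,
        stratum_of_sample={
            s: classify_depth(env.loc[i, "depth_m"]) for i, s in enumerate(sample_ids)
        },
        region_of_sample={
            s: classify_region(env.loc[i, "latitude"], scheme)
            for i, s in enumerate(sample_ids)
        },
    )
    return table, env_table, truth


# ---------------------------------------------------------------------------
# Full survey: community + matching reference and hits
# ---------------------------------------------------------------------------

#: identity levels for survey queries, all above the phylum cutoff so every
#: OTU with resolvable hits keeps its planted phylum
_SURVEY_IDENTITY_LEVELS = (99.5, 97.0, 93.0, 87.5, 82.0, 78.0)
_SURVEY_IDENTITY_PROBS = (0.30, 0.25, 0.15, 0.12, 0.10, 0.08)


def gen_survey(
    design: CommunityDesign | None = None,
    seed: int = 0,
    ref_species_per_phylum: int = 20,
) -> dict:
    """Generate a coherent survey: counts + metadata + reference + hits.

    Every community OTU's hit source is a reference species inside its
    planted phylum, at an identity above the phylum cutoff, with
    within-margin relatives confined to the same phylum — so the pipeline's
    own taxonomy stage recovers the planted phylum structure that the
    downstream ordination and correlation stages are meant to detect.
    Returns a dict with keys lineage_map, hits_by_otu, plans, table, env,
    truth.
    """
    design = design or CommunityDesign()
    table, env, truth = gen_community(design, seed=seed)
    phyla = sorted({p for p in truth.phylum_of_otu.values()})
    lineage_map = gen_reference(
        n_taxa=ref_species_per_phylum * len(phyla), seed=seed + 1, phyla=phyla
    )
    subjects_by_phylum: dict[str, list[str]] = {}
    for sid, lin in lineage_map.items():
        subjects_by_phylum.setdefault(lin.names[1], []).append(sid)
    rng = np.random.default_rng(seed + 2)
    source_of_query = {
        otu: subjects_by_phylum[phylum][
            rng.integers(len(subjects_by_phylum[phylum]))
        ]
        for otu, phylum in truth.phylum_of_otu.items()
    }
    hits_by_otu, plans = gen_hits(
        lineage_map,
        seed=seed + 3,
        source_of_query=source_of_query,
        identity_levels=_SURVEY_IDENTITY_LEVELS,
        identity_probs=_SURVEY_IDENTITY_PROBS,
        min_shared_margin=2,
    )
    return {
        "lineage_map": lineage_map,
        "hits_by_otu": hits_by_otu,
        "plans": plans,
        "table": table,
        "env": env,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Generic driver-recovery problem (ordination calibration)
# ---------------------------------------------------------------------------


def gen_rda_problem(
    n_samples: int = 90,
    n_taxa: int = 12,
    n_drivers: int = 3,
    n_noise: int = 5,
    effect: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Multivariate response driven by ``n_drivers`` of the covariates; the
    remaining ``n_noise`` covariates are pure noise. Returns (response,
    covariates, driver names)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_drivers + n_noise))
    names = [f"driver_{i}" for i in range(n_drivers)] + [
        f"noise_{i}" for i in range(n_noise)
    ]
    B = rng.normal(0, effect, size=(n_drivers, n_taxa))
    Y = X[:, :n_drivers] @ B + rng.normal(size=(n_samples, n_taxa))
    response = pd.DataFrame(Y, columns=[f"taxon_{j}" for j in range(n_taxa)])
    covariates = pd.DataFrame(X, columns=names)
    return response, covariates, names[:n_drivers]
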