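"""Sample classification, prevalence filtering, taxonomic aggregation,
centred log-ratio transformation, and taxon-environment correlation grids.

All downstream community statistics operate on clr-transformed abundances:
for a sample x with pseudocount d, clr(x)_i = ln(x_i + d) - mean_j ln(x_j + d),
which maps compositions to unconstrained real space where Euclidean geometry
and Pearson correlation are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.stats.composition import multi_replace

from .io_model import (
    RANK_INDEX,
    OtuTable,
    TaxonomyAssignment,
    ValidationError,
)

__all__ = [
    "RegionScheme",
    "classify_depth",
    "classify_region",
    "derive_env_labels",
    "prevalence_filter",
    "aggregate_taxa",
    "aggregate_nested",
    "clr_transform",
    "correlation_grid",
    "ClrMatrix",
    "CorrelationGrid",
]

OUTSIDE_DOMAIN = "outside-domain"


def classify_depth(depth_m: float) -> str:
    """Assign a seafloor depth (m, positive down) to its benthic stratum:
    epibenthic < 200 m, mesobenthic 200-1000 m (closed), bathybenthic > 1000 m.
    """
    if not depth_m > 0:
        raise ValidationError(f"depth must be positive, got {depth_m}")
    if depth_m < 200:
        return "epibenthic"
    if depth_m <= 1000:
        return "mesobenthic"
    return "bathybenthic"


@dataclass(frozen=True)
class RegionScheme:
    """Latitudinal banding of the Red Sea into five regions.

    ``cuts`` are the four interior boundaries (degrees N, ascending); bands
    are lower-bound inclusive. The published banding scheme does not print
    coordinates, so these defaults span the basin's latitudinal range and are
    meant to be overridden per study.
    """

    cuts: tuple[float, float, float, float] = (19.0, 21.5, 24.5, 27.5)
    labels: tuple[str, str, str, str, str] = (
        "Southern Red Sea",
        "South-Central Red Sea",
        "North-Central Red Sea",
        "Northern Red Sea",
        "Gulf of Aqaba",
    )
    lat_min: float = 12.0
    lat_max: float = 30.0

    def __post_init__(self) -> None:
        if list(self.cuts) != sorted(self.cuts):
            raise ValidationError("region cuts must be ascending")
        if len(self.labels) != len(self.cuts) + 1:
            raise ValidationError("need exactly one more label than cuts")


def classify_region(latitude: float, scheme: RegionScheme | None = None) -> str:
    """Map a latitude to its region band (lower bound inclusive); latitudes
    outside the scheme's domain get the explicit outside-domain label."""
    scheme = scheme or RegionScheme()
    if not scheme.lat_min <= latitude <= scheme.lat_max:
        return OUTSIDE_DOMAIN
    idx = int(np.searchsorted(np.asarray(scheme.cuts), latitude, side="right"))
    return scheme.labels[idx]


def derive_env_labels(env_df: pd.DataFrame, scheme: RegionScheme | None = None) -> pd.DataFrame:
    """Attach derived region_label and depth_category columns to metadata."""
    out = env_df.copy()
    out["region_label"] = [classify_region(v, scheme) for v in out["latitude"]]
    out["depth_category"] = [classify_depth(v) for v in out["depth_m"]]
    return out


def prevalence_filter(table: OtuTable, min_prevalence: int = 3) -> OtuTable:
    """Discard OTUs with nonzero counts in fewer than ``min_prevalence``
    samples (prevalence is presence, not abundance)."""
    prevalence = (table.counts > 0).sum(axis=1)
    keep = prevalence >= min_prevalence
    return OtuTable(table.counts.loc[keep], table.sample_roles)


def _rank_labels(
    otu_ids: Sequence[str],
    assignments: Mapping[str, TaxonomyAssignment] | Sequence[TaxonomyAssignment],
    rank: str,
) -> list[str]:
    if rank not in RANK_INDEX:
        raise ValidationError(f"unknown rank {rank!r}")
    if not isinstance(assignments, Mapping):
        assignments = {a.otu_id: a for a in assignments}
    labels = []
    for otu in otu_ids:
        a = assignments.get(otu)
        name = a.lineage.name_at(rank) if a is not None else None
        labels.append(name if name is not None else "Unassigned")
    return labels


def aggregate_taxa(
    table: OtuTable,
    assignments: Mapping[str, TaxonomyAssignment] | Sequence[TaxonomyAssignment],
    rank: str = "phylum",
    top_k: int | None = None,
) -> pd.DataFrame:
    """Sum counts by taxon at ``rank``; per-sample totals are conserved.

    OTUs unnamed at that rank pool into "Unassigned". With ``top_k``, taxa
    outside the k most abundant (by total reads, Unassigned not competing)
    pool into "other".
    """
    labels = _rank_labels(table.otu_ids, assignments, rank)
    agg = table.counts.groupby(pd.Index(labels, name=rank)).sum()
    if top_k is not None:
        named = agg.drop(index="Unassigned", errors="ignore")
        top = named.sum(axis=1).sort_values(ascending=False).index[:top_k]
        rows = {t: agg.loc[t] for t in top}
        rest = named.index.difference(top)
        if len(rest):
            rows["other"] = agg.loc[rest].sum()
        if "Unassigned" in agg.index:
            rows["Unassigned"] = agg.loc["Unassigned"]
        agg = pd.DataFrame(rows).T
        agg.index.name = rank
    return agg


def aggregate_nested(
    table: OtuTable,
    assignments: Mapping[str, TaxonomyAssignment] | Sequence[TaxonomyAssignment],
    top_phyla: int = 12,
    top_classes: int = 2,
) -> pd.DataFrame:
    """Phylum/class two-level aggregation: the ``top_phyla`` most abundant
    phyla each keep their ``top_classes`` most abundant classes, everything
    else pools into "other" at the respective level (rows labelled
    "Phylum;Class")."""
    phyla = _rank_labels(table.otu_ids, assignments, "phylum")
    classes = _rank_labels(table.otu_ids, assignments, "class")
    df = table.counts.copy()
    key = pd.DataFrame({"phylum": phyla, "class": classes}, index=df.index)

    phylum_tot = df.groupby(key["phylum"].values).sum().sum(axis=1)
    named = phylum_tot.drop(index="Unassigned", errors="ignore")
    keep_phyla = set(named.sort_values(ascending=False).index[:top_phyla])

    rows: dict[str, pd.Series] = {}
    for phylum, grp in df.groupby(key["phylum"].values):
        if phylum != "Unassigned" and phylum not in keep_phyla:
            label = "other"
            rows[label] = rows.get(label, 0) + grp.sum()
            continue
        cls = key.loc[grp.index, "class"]
        cls_tot = grp.groupby(cls.values).sum().sum(axis=1)
        cls_named = cls_tot.drop(index="Unassigned", errors="ignore")
        keep_cls = set(cls_named.sort_values(ascending=False).index[:top_classes])
        for c, sub in grp.groupby(cls.values):
            c_label = c if (c in keep_cls or c == "Unassigned") else "other"
            label = f"{phylum};{c_label}"
            rows[label] = rows.get(label, 0) + sub.sum()
    out = pd.DataFrame(rows).T
    out.index.name = "phylum;class"
    return out


@dataclass
class ClrMatrix:
    """clr-transformed abundances, rows = samples, columns = taxa."""

    values: pd.DataFrame
    pseudocount_mode: str
    pseudocount: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)


def clr_transform(
    table: OtuTable | pd.DataFrame, pseudocount_mode: str = "add_one"
) -> ClrMatrix:
    """Centred log-ratio transform of a count table (rows taxa, cols samples).

    Zero replacement modes: ``add_one`` (d = 1), ``add_half_min`` (d = half
    the smallest nonzero count), ``multiplicative_replacement`` (simplex-aware
    zero replacement on proportions), or ``none`` (d = 0; requires strictly
    positive counts). Output rows (samples) sum to zero by construction.
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    X = counts.to_numpy(dtype=float).T  # samples x taxa
    if X.shape[1] == 0:
        raise ValidationError("cannot clr-transform an empty table")
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        bad = [counts.columns[i] for i in np.flatnonzero(totals <= 0)]
        raise ValidationError(f"samples with zero total reads: {bad}")

    if pseudocount_mode == "add_one":
        delta = 1.0
        Z = X + delta
    elif pseudocount_mode == "add_half_min":
        delta = 0.5 * X[X > 0].min()
        Z = X + delta
    elif pseudocount_mode == "none":
        delta = 0.0
        if (X <= 0).any():
            raise ValidationError("pseudocount_mode='none' requires positive counts")
        Z = X
    elif pseudocount_mode == "multiplicative_replacement":
        delta = float("nan")
        props = X / totals[:, None]
        Z = multi_replace(props) if (props == 0).any() else props
    else:
        raise ValidationError(f"unknown pseudocount mode {pseudocount_mode!r}")

    logs = np.log(Z)
    clr = logs - logs.mean(axis=1, keepdims=True)
    values = pd.DataFrame(clr, index=counts.columns, columns=counts.index)
    return ClrMatrix(values=values, pseudocount_mode=pseudocount_mode, pseudocount=delta)


@dataclass
class CorrelationGrid:
    """Pearson correlations of clr taxa against environmental covariates.

    ``r`` holds the coefficient per (taxon, covariate) pair on
    pairwise-complete observations; ``n`` the observation count per cell.
    Cells with fewer than 3 complete pairs, or a constant column, are NaN.
    """

    r: pd.DataFrame
    n: pd.DataFrame
    flagged_constant: list[tuple[str, str]] = field(default_factory=list)


def _pairwise_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return float("nan"), n
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return float("nan"), n
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, n


def correlation_grid(
    clr: ClrMatrix,
    env: pd.DataFrame,
    continuous: Sequence[str],
    categories: Sequence[str] = (),
) -> CorrelationGrid:
    """Correlate every clr taxon with continuous covariates and the one-hot
    indicators of categorical covariates.

    Rows of ``clr.values`` and ``env`` must align by sample. Missingness
    (e.g., oxygen available only for a sample subset) is handled per cell via
    pairwise-complete observations.
    """
    env = env.loc[clr.values.index]
    cov = {c: env[c].to_numpy(dtype=float) for c in continuous}
    for cat in categories:
        for level in pd.unique(env[cat].astype(str)):
            cov[f"{cat}={level}"] = (env[cat].astype(str) == level).to_numpy(float)

    taxa = clr.taxa
    r = pd.DataFrame(index=taxa, columns=list(cov), dtype=float)
    n = pd.DataFrame(0, index=taxa, columns=list(cov), dtype=int)
    flagged: list[tuple[str, str]] = []
    for taxon in taxa:
        tv = clr.values[taxon].to_numpy(dtype=float)
        for name, cv in cov.items():
            rij, nij = _pairwise_pearson(tv, cv)
            r.loc[taxon, name] = rij
            n.loc[taxon, name] = nij
            if nij >= 3 and np.isnan(rij):
                flagged.append((taxon, name))
    return CorrelationGrid(r=r, n=n, flagged_constant=flagged)
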