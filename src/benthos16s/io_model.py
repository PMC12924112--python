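"""Domain types, file readers/writers, and validation shared by all stages.

The on-disk dialect is deliberately plain text: tab-separated similarity hit
tables in BLAST outfmt-6 column order, OTU count tables as TSV (rows = OTUs,
columns = samples), sample metadata as CSV, and SILVA-style semicolon-delimited
seven-rank lineage strings. Validation is total: nothing is silently coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Fixed rank hierarchy, root first. Lineages may terminate early but never
#: skip a rank (no named genus under an unnamed family).
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

SAMPLE_ROLES: tuple[str, ...] = (
    "true_sample",
    "field_control",
    "extraction_control",
    "pcr_control",
)

CONTROL_ROLES: tuple[str, ...] = (
    "field_control",
    "extraction_control",
    "pcr_control",
)

#: Columns of a BLAST tabular (outfmt 6) hit file, in order.
OUTFMT6_COLUMNS: tuple[str, ...] = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

DEPTH_CATEGORIES: tuple[str, ...] = ("epibenthic", "mesobenthic", "bathybenthic")


class ValidationError(ValueError):
    """Raised when an input file or value violates a domain invariant."""


@dataclass(frozen=True)
class Lineage:
    """An ordered, gap-free-from-the-top taxonomic lineage.

    ``names`` holds taxon names from domain downwards; a lineage may stop at
    any rank (partial lineage) and the empty lineage means "unassigned".
    """

    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) > len(RANKS):
            raise ValidationError(
                f"lineage has {len(self.names)} ranks, hierarchy has {len(RANKS)}"
            )
        for name in self.names:
            if not isinstance(name, str) or name == "":
                raise ValidationError(
                    "lineage names must be non-empty strings with no internal "
                    f"gaps; got {self.names!r}"
                )

    @property
    def depth(self) -> int:
        """Number of named ranks (0 for an unassigned lineage)."""
        return len(self.names)

    @property
    def deepest_rank(self) -> str:
        """Name of the deepest named rank, or ``"unassigned"``."""
        return RANKS[self.depth - 1] if self.names else "unassigned"

    def truncate(self, depth: int) -> "Lineage":
        """Return the lineage cut to at most ``depth`` ranks."""
        if depth < 0:
            raise ValidationError("depth must be >= 0")
        return Lineage(self.names[:depth])

    def name_at(self, rank: str) -> str | None:
        i = RANK_INDEX[rank]
        return self.names[i] if i < self.depth else None

    def is_prefix_of(self, other: "Lineage") -> bool:
        return self.names == other.names[: self.depth]

    def to_string(self) -> str:
        """SILVA-style semicolon string, padded with empty trailing fields."""
        padded = list(self.names) + [""] * (len(RANKS) - self.depth)
        return ";".join(padded)

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a semicolon-delimited lineage; trailing empties are legal,
        internal gaps are not."""
        parts = [p.strip() for p in text.split(";")]
        if len(parts) > len(RANKS):
            raise ValidationError(f"lineage string has {len(parts)} fields: {text!r}")
        # trim trailing empties, then reject any internal empty
        while parts and parts[-1] == "":
            parts.pop()
        if any(p == "" for p in parts):
            raise ValidationError(f"lineage has a gap below a named rank: {text!r}")
        return cls(tuple(parts))


@dataclass(frozen=True)
class SimilarityHit:
    """One query-vs-reference alignment record with its subject's lineage.

    ``lineage`` is None when the subject was absent from the lineage map; such
    hits are flagged, never silently dropped (see :func:`read_hits`).
    """

    query_id: str
    subject_id: str
    pct_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    lineage: Lineage | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(
                f"pct_identity {self.pct_identity} outside [0, 100] "
                f"(query {self.query_id})"
            )
        if self.alignment_length < 1:
            raise ValidationError(
                f"alignment_length {self.alignment_length} < 1 (query {self.query_id})"
            )
        if self.evalue < 0:
            raise ValidationError(f"negative evalue (query {self.query_id})")
        if self.bitscore < 0:
            raise ValidationError(f"negative bitscore (query {self.query_id})")

    @property
    def lineage_missing(self) -> bool:
        return self.lineage is None


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the hit-filtering and rank-trimming scheme.

    ``identity_cutoffs`` maps rank name to the strict percent-identity floor a
    hit must exceed for an assignment at that rank; cutoffs must strictly
    decrease from species to phylum. ``low_score_rule`` chooses whether a hit
    is excluded when either score fails ("or", default) or only when both fail
    ("and").
    """

    evalue_max: float = 1e-5
    bitscore_min: float = 150.0
    alen_min: int = 100
    margin_fraction: float = 0.02
    identity_cutoffs: Mapping[str, float] = field(
        default_factory=lambda: {
            "species": 98.0,
            "genus": 95.0,
            "family": 90.0,
            "order": 85.0,
            "class": 80.0,
            "phylum": 75.0,
        }
    )
    low_score_rule: str = "or"
    #: below the phylum cutoff the assignment is wholly unassigned by default;
    #: set True to retain a bare domain label instead.
    retain_domain: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.margin_fraction < 1.0:
            raise ValidationError("margin_fraction must be in [0, 1)")
        if self.low_score_rule not in ("and", "or"):
            raise ValidationError("low_score_rule must be 'and' or 'or'")
        ordered = ["species", "genus", "family", "order", "class", "phylum"]
        missing = [r for r in ordered if r not in self.identity_cutoffs]
        if missing:
            raise ValidationError(f"identity_cutoffs missing ranks: {missing}")
        vals = [self.identity_cutoffs[r] for r in ordered]
        if not all(a > b for a, b in zip(vals, vals[1:])):
            raise ValidationError(
                "identity cutoffs must strictly decrease from species to phylum"
            )


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Per-OTU consensus lineage with audit fields.

    ``lca_rank`` records the rank at which the lowest common ancestor resolved
    before identity trimming; ``assigned_rank`` is never deeper than either
    the LCA or the rank permitted by ``max_identity``.
    """

    otu_id: str
    lineage: Lineage
    assigned_rank: str
    n_hits_input: int
    n_hits_after_threshold: int
    n_hits_after_margin: int
    max_identity: float
    lca_rank: str

    def __post_init__(self) -> None:
        if not (
            self.n_hits_input
            >= self.n_hits_after_threshold
            >= self.n_hits_after_margin
            >= 0
        ):
            raise ValidationError(
                f"hit audit counts not monotone for OTU {self.otu_id}"
            )


class OtuTable:
    """Integer OTU-by-sample count matrix with per-sample role labels."""

    def __init__(self, counts: pd.DataFrame, sample_roles: Mapping[str, str]):
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        arr = counts.to_numpy()
        if arr.size and not ((arr == arr.astype(int)).all() and (arr >= 0).all()):
            raise ValidationError("counts must be nonnegative integers")
        missing = [s for s in counts.columns if s not in sample_roles]
        if missing:
            raise ValidationError(f"samples missing a role: {missing}")
        bad = {s: r for s, r in sample_roles.items() if r not in SAMPLE_ROLES}
        if bad:
            raise ValidationError(f"unknown sample roles: {bad}")
        self.counts = counts.astype(int)
        self.sample_roles = {s: sample_roles[s] for s in counts.columns}

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def true_sample_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.sample_roles[s] == "true_sample"]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.sample_roles[s] != "true_sample"]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(
            self.counts.loc[:, list(sample_ids)],
            {s: self.sample_roles[s] for s in sample_ids},
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.counts.equals(other.counts)
            and self.sample_roles == other.sample_roles
        )


ENV_REQUIRED = ("sample_id", "latitude", "longitude", "depth_m", "temperature", "salinity")


class EnvTable:
    """Per-sample environmental and spatial covariates.

    ``oxygen_saturation`` (percent air saturation) may be missing for a subset
    of samples and is represented as NaN, never 0. ``region_label`` and
    ``depth_category`` are derived downstream (community module).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ENV_REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        if (df["depth_m"] <= 0).any():
            raise ValidationError("depth_m must be > 0 (positive down)")
        self.df = df.set_index("sample_id", drop=False)
        if "oxygen_saturation" not in self.df.columns:
            self.df["oxygen_saturation"] = math.nan

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        return self.df.loc[list(sample_ids)]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_lineage_map(path: str | Path) -> dict[str, Lineage]:
    """Read a two-column TSV of subject_id and lineage string."""
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            sid, lin = parts
            if sid in out:
                raise ValidationError(f"{path}:{lineno}: duplicate subject {sid}")
            out[sid] = Lineage.from_string(lin)
    return out


def write_lineage_map(lineage_map: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lin in lineage_map.items():
            fh.write(f"{sid}\t{lin.to_string()}\n")


def read_hits(
    path: str | Path, lineage_map: Mapping[str, Lineage]
) -> list[SimilarityHit]:
    """Parse a 12-column outfmt-6 hit table and attach subject lineages.

    Rows whose subject has no lineage in ``lineage_map`` come back with
    ``lineage=None`` (flagged, not dropped). Malformed rows are a hard error
    naming the line number.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(OUTFMT6_COLUMNS):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(OUTFMT6_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            try:
                pident = float(parts[2])
                alen = int(parts[3])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric score field: {exc}")
            try:
                hit = SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=pident,
                    alignment_length=alen,
                    evalue=evalue,
                    bitscore=bitscore,
                    lineage=lineage_map.get(parts[1]),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}")
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits back out in outfmt-6 column order (alignment coordinate
    columns not modelled here are emitted as zeros)."""
    with open(path, "w") as fh:
        for h in hits:
            row = [
                h.query_id,
                h.subject_id,
                f"{h.pct_identity:g}",
                str(h.alignment_length),
                "0",
                "0",
                "0",
                "0",
                "0",
                "0",
                f"{h.evalue:g}",
                f"{h.bitscore:g}",
            ]
            fh.write("\t".join(row) + "\n")


def read_otu_table(path: str | Path, roles_path: str | Path) -> OtuTable:
    """Read an OTU count TSV (rows OTUs, columns samples) plus a roles TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    for col in counts.columns:
        series = counts[col]
        if not pd.api.types.is_integer_dtype(series):
            if pd.api.types.is_float_dtype(series) and (series % 1 == 0).all():
                counts[col] = series.astype(int)
            else:
                raise ValidationError(f"non-integer counts in sample {col}")
        if (counts[col] < 0).any():
            raise ValidationError(f"negative counts in sample {col}")
    roles: dict[str, str] = {}
    with open(roles_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{roles_path}:{lineno}: expected sample_id<TAB>role"
                )
            roles[parts[0]] = parts[1]
    return OtuTable(counts, roles)


def write_otu_table(table: OtuTable, path: str | Path, roles_path: str | Path | None = None) -> None:
    table.counts.to_csv(path, sep="\t", index_label="otu_id")
    if roles_path is not None:
        with open(roles_path, "w") as fh:
            fh.write("sample_id\trole\n")
            for s in table.sample_ids:
                fh.write(f"{s}\t{table.sample_roles[s]}\n")


def read_env_table(path: str | Path) -> EnvTable:
    df = pd.read_csv(path)
    df["sample_id"] = df["sample_id"].astype(str)
    return EnvTable(df)


def write_env_table(env: EnvTable, path: str | Path) -> None:
    env.df.to_csv(path, index=False)


ASSIGNMENT_COLUMNS = (
    ("otu_id",)
    + RANKS
    + ("assigned_rank", "lca_rank", "n_hits_input", "n_hits_after_threshold",
       "n_hits_after_margin", "max_identity")
)


def write_assignments(
    assignments: Sequence[TaxonomyAssignment], path: str | Path
) -> None:
    """Write assignments as TSV, one rank per column, blank past the assigned
    rank; round-trips losslessly through :func:`read_assignments`."""
    with open(path, "w") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for a in assignments:
            ranks = list(a.lineage.names) + [""] * (len(RANKS) - a.lineage.depth)
            row = (
                [a.otu_id]
                + ranks
                + [
                    a.assigned_rank,
                    a.lca_rank,
                    str(a.n_hits_input),
                    str(a.n_hits_after_threshold),
                    str(a.n_hits_after_margin),
                    repr(a.max_identity),
                ]
            )
            fh.write("\t".join(row) + "\n")


def read_assignments(path: str | Path) -> list[TaxonomyAssignment]:
    out: list[TaxonomyAssignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ASSIGNMENT_COLUMNS:
            raise ValidationError(f"unexpected assignment header in {path}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(ASSIGNMENT_COLUMNS):
                raise ValidationError(f"{path}:{lineno}: wrong field count")
            names = [p for p in parts[1 : 1 + len(RANKS)]]
            while names and names[-1] == "":
                names.pop()
            out.append(
                TaxonomyAssignment(
                    otu_id=parts[0],
                    lineage=Lineage(tuple(names)),
                    assigned_rank=parts[8],
                    lca_rank=parts[9],
                    n_hits_input=int(parts[10]),
                    n_hits_after_threshold=int(parts[11]),
                    n_hits_after_margin=int(parts[12]),
                    max_identity=float(parts[13]),
                )
            )
    return out
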