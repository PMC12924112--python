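"""Blank-based decontamination of OTU count tables.

Negative field, extraction, and PCR controls capture reagent and handling
contamination. The default ``subtract_scaled`` method implements a
transparent constant-anchor subtraction contract: the OTU most abundant in
the blanks is assumed to be pure contamination, each true sample's
contamination level is scaled off that anchor, and every control OTU's
expected contribution is subtracted, floored at zero, and rounded down so no
fractional reads are ever manufactured. ``prevalence_zero`` is a blunter
alternative that zeroes any OTU seen in blanks above a count threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import CONTROL_ROLES, OtuTable, ValidationError

__all__ = ["DecontamReport", "remove_contaminants"]


@dataclass
class DecontamReport:
    """Accounting of what decontamination removed."""

    method: str
    otus_removed: list[str]
    reads_removed_per_sample: dict[str, int]
    contamination_proportion: dict[str, float]
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "otus_removed": self.otus_removed,
            "n_otus_removed": len(self.otus_removed),
            "reads_removed_per_sample": self.reads_removed_per_sample,
            "reads_removed_total": int(sum(self.reads_removed_per_sample.values())),
            "contamination_proportion": self.contamination_proportion,
            "params": self.params,
        }


def _control_profile(controls: pd.DataFrame) -> pd.Series:
    """Mean proportional abundance of each OTU across control libraries.

    Empty control libraries (zero total) contribute nothing rather than NaN.
    """
    totals = controls.sum(axis=0)
    nonempty = controls.loc[:, totals > 0]
    if nonempty.shape[1] == 0:
        return pd.Series(0.0, index=controls.index)
    props = nonempty.div(nonempty.sum(axis=0), axis=1)
    return props.mean(axis=1)


def _subtract_scaled(
    samples: pd.DataFrame, controls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    profile = _control_profile(controls)
    if (profile <= 0).all():
        return samples.copy(), profile
    anchor = profile.idxmax()
    # per-sample contamination scale, anchored on the most control-abundant
    # OTU: removal[o, s] = count[anchor, s] * profile[o] / profile[anchor]
    scale = samples.loc[anchor].astype(float) / profile[anchor]
    removal = pd.DataFrame(
        np.outer(profile.to_numpy(), scale.to_numpy()),
        index=samples.index,
        columns=samples.columns,
    )
    cleaned = np.floor((samples - removal).clip(lower=0)).astype(int)
    return cleaned, profile


def _prevalence_zero(
    samples: pd.DataFrame, controls: pd.DataFrame, control_count_min: int
) -> tuple[pd.DataFrame, pd.Series]:
    profile = _control_profile(controls)
    flagged = controls.max(axis=1) >= control_count_min
    cleaned = samples.copy()
    cleaned.loc[flagged] = 0
    return cleaned, profile


def remove_contaminants(
    table: OtuTable,
    method: str = "subtract_scaled",
    control_count_min: int = 1,
    pool_controls: bool = True,
) -> tuple[OtuTable, DecontamReport]:
    """Remove the contamination signal seen in blanks from true samples.

    Returns a table of true samples only (control columns dropped, all-zero
    OTUs dropped) plus a :class:`DecontamReport`. Output counts never exceed
    input counts. With ``pool_controls=False`` the three control roles are
    applied sequentially (field, then extraction, then PCR) instead of as one
    pooled blank set.
    """
    control_ids = table.control_ids
    sample_ids = table.true_sample_ids
    if not control_ids:
        raise ValidationError(
            "table has no control columns; decontamination is undefined "
            "(pass the table through unchanged if no blanks were sequenced)"
        )
    if not sample_ids:
        raise ValidationError("table has no true-sample columns")
    if method not in ("subtract_scaled", "prevalence_zero"):
        raise ValidationError(f"unknown decontamination method {method!r}")

    samples = table.counts[sample_ids]
    input_totals = samples.sum(axis=0)

    if pool_controls:
        control_sets = [table.counts[control_ids]]
    else:
        control_sets = [
            table.counts[[s for s in control_ids if table.sample_roles[s] == role]]
            for role in CONTROL_ROLES
        ]
        control_sets = [c for c in control_sets if c.shape[1] > 0]

    cleaned = samples
    profile_acc = pd.Series(0.0, index=table.counts.index)
    for controls in control_sets:
        if method == "subtract_scaled":
            cleaned, profile = _subtract_scaled(cleaned, controls)
        else:
            cleaned, profile = _prevalence_zero(cleaned, controls, control_count_min)
        profile_acc = profile_acc.combine(profile, max)

    keep = cleaned.sum(axis=1) > 0
    removed_otus = [str(o) for o in cleaned.index[~keep]]
    cleaned = cleaned.loc[keep]

    reads_removed = (input_totals - cleaned.sum(axis=0)).astype(int)
    report = DecontamReport(
        method=method,
        otus_removed=removed_otus,
        reads_removed_per_sample={s: int(v) for s, v in reads_removed.items()},
        contamination_proportion={
            str(o): float(v) for o, v in profile_acc.items() if v > 0
        },
        params={
            "pool_controls": pool_controls,
            "control_count_min": control_count_min,
            "n_controls": len(control_ids),
        },
    )
    out = OtuTable(cleaned, {s: "true_sample" for s in sample_ids})
    return out, report
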