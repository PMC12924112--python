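"""OTU richness and its latitudinal/bathymetric trends.

Richness is the per-sample count of OTUs with nonzero reads, computed on the
decontaminated, prevalence-filtered table. Per depth stratum an ordinary
least squares regression of richness on latitude gives the slope (OTUs per
degree latitude), its two-sided t-test p-value, and a pointwise 95%
confidence band for the conditional mean. A separate asymptotic saturation
model of OTUs against sequencing depth (Michaelis-Menten a*x/(b+x) or
exponential a*(1-exp(-x/b))) checks whether libraries were sequenced deep
enough to plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .io_model import OtuTable

__all__ = [
    "RegressionFit",
    "SaturationFit",
    "otu_richness",
    "stratified_regression",
    "saturation_fit",
]


@dataclass
class RegressionFit:
    stratum: str
    n: int
    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    p_value: float
    ci_grid: pd.DataFrame  # columns: latitude, mean, ci_low, ci_high

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "ci_grid": self.ci_grid.to_dict(orient="list"),
        }


@dataclass
class SaturationFit:
    model_form: str
    asymptote: float
    half_saturation: float
    rss: float
    converged: bool

    def predict(self, reads: np.ndarray) -> np.ndarray:
        x = np.asarray(reads, dtype=float)
        if self.model_form == "michaelis_menten":
            return self.asymptote * x / (self.half_saturation + x)
        return self.asymptote * (1.0 - np.exp(-x / self.half_saturation))

    def to_dict(self) -> dict:
        return {
            "model_form": self.model_form,
            "asymptote": self.asymptote,
            "half_saturation": self.half_saturation,
            "rss": self.rss,
            "converged": self.converged,
        }


def otu_richness(table: OtuTable | pd.DataFrame) -> pd.Series:
    """Number of OTUs with count > 0 per sample (presence only, so invariant
    to sequencing depth scaling)."""
    counts = table.counts if isinstance(table, OtuTable) else table
    return (counts > 0).sum(axis=0).rename("richness")


def stratified_regression(
    richness: pd.Series,
    latitude: pd.Series,
    depth_category: pd.Series,
    grid_points: int = 50,
) -> list[RegressionFit]:
    """Per-depth-stratum OLS of richness on latitude.

    Strata with fewer than 3 samples are skipped with a warning. The CI band
    is the pointwise 95% interval for the conditional mean, evaluated on an
    even latitude grid spanning the stratum's observed range.
    """
    df = pd.DataFrame(
        {
            "richness": richness,
            "latitude": latitude,
            "stratum": depth_category,
        }
    ).dropna()
    fits: list[RegressionFit] = []
    for stratum, grp in df.groupby("stratum", sort=False):
        if len(grp) < 3:
            warnings.warn(
                f"stratum {stratum!r} has {len(grp)} samples (< 3); skipped"
            )
            continue
        X = sm.add_constant(grp["latitude"].to_numpy(dtype=float))
        model = sm.OLS(grp["richness"].to_numpy(dtype=float), X).fit()
        grid = np.linspace(grp["latitude"].min(), grp["latitude"].max(), grid_points)
        pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
        ci = pd.DataFrame(
            {
                "latitude": grid,
                "mean": pred["mean"].to_numpy(),
                "ci_low": pred["mean_ci_lower"].to_numpy(),
                "ci_high": pred["mean_ci_upper"].to_numpy(),
            }
        )
        fits.append(
            RegressionFit(
                stratum=str(stratum),
                n=int(len(grp)),
                slope=float(model.params[1]),
                intercept=float(model.params[0]),
                slope_se=float(model.bse[1]),
                t_stat=float(model.tvalues[1]),
                p_value=float(model.pvalues[1]),
                ci_grid=ci,
            )
        )
    return fits


def _mm(x, a, b):
    return a * x / (b + x)


def _expsat(x, a, b):
    return a * (1.0 - np.exp(-x / b))


def saturation_fit(
    reads: np.ndarray | pd.Series,
    otus: np.ndarray | pd.Series,
    model_form: str = "michaelis_menten",
) -> SaturationFit:
    """Least-squares fit of an asymptotic saturation curve of OTUs vs reads.

    Self-starting initial values: asymptote a0 = max(otus), half-saturation
    b0 = median(reads). Non-convergence raises with the optimizer's message.
    """
    x = np.asarray(reads, dtype=float)
    y = np.asarray(otus, dtype=float)
    if (x <= 0).any() or (y < 0).any():
        raise ValueError("reads must be positive and otus nonnegative")
    forms = {"michaelis_menten": _mm, "exponential": _expsat}
    if model_form not in forms:
        raise ValueError(f"unknown model form {model_form!r}")
    f = forms[model_form]
    p0 = (max(y.max(), 1.0), max(float(np.median(x)), 1e-6))
    try:
        popt, _ = curve_fit(
            f,
            x,
            y,
            p0=p0,
            bounds=([1e-9, 1e-9], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"saturation fit did not converge: {exc}") from exc
    resid = y - f(x, *popt)
    return SaturationFit(
        model_form=model_form,
        asymptote=float(popt[0]),
        half_saturation=float(popt[1]),
        rss=float((resid**2).sum()),
        converged=True,
    )
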