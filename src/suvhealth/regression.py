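"""OLS models linking vehicle characteristics to tailpipe emissions.

Two fits mirror the study design: WLTP CO2 (g/km) on WLTP test mass, engine
capacity, wheelbase and a diesel indicator over all internal-combustion
models, and RDE NOx (mg/km) on test mass and engine capacity fitted
separately for diesel and petrol models.  Fits are unweighted across vehicle
models (each model one observation) with classical homoskedastic standard
errors and t-based 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fleet import VehicleModelRecord

__all__ = ["OlsResult", "fit_co2_model", "fit_nox_model", "write_report"]

CO2_PREDICTORS = ("wltp_test_mass", "engine_capacity", "wheelbase", "diesel")
NOX_PREDICTORS = ("wltp_test_mass", "engine_capacity")


@dataclass(frozen=True)
class OlsResult:
    """Coefficients with 95% CIs and p-values, plus fit statistics."""

    coefficients: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    f_statistic: float
    n_obs: int

    def __post_init__(self) -> None:
        for name, est in self.coefficients.items():
            if not self.ci_lower[name] <= est <= self.ci_upper[name]:
                raise ValueError(f"CI does not bracket estimate for {name}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 outside [0, 1]")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coefficient": self.coefficients,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_values,
        })


def _check_design(X: pd.DataFrame) -> None:
    zero_cols = [c for c in X.columns if np.allclose(X[c], 0.0)]
    if zero_cols:
        raise ValueError(f"all-zero predictor column(s): {zero_cols}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the smallest collinear subset greedily
        cols = list(X.columns)
        collinear = [c for c in cols
                     if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank]
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")


def _fit(y: pd.Series, X: pd.DataFrame) -> OlsResult:
    _check_design(X)
    Xc = sm.add_constant(X, prepend=False)
    res = sm.OLS(y, Xc).fit()
    ci = res.conf_int(alpha=0.05)
    return OlsResult(
        coefficients=res.params.to_dict(),
        ci_lower=ci[0].to_dict(),
        ci_upper=ci[1].to_dict(),
        p_values=res.pvalues.to_dict(),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        n_obs=int(res.nobs),
    )


def fit_co2_model(records: Iterable[VehicleModelRecord]) -> OlsResult:
    """Regress WLTP CO2 on mass, engine capacity, wheelbase and diesel dummy.

    Battery-electric models are excluded; hybrids carry their base fuel's
    indicator and plug-in hybrids count as petrol.  Requires at least 10
    internal-combustion observations.
    """
    rows = [
        {
            "co2_wltp": r.co2_wltp,
            "wltp_test_mass": r.wltp_test_mass,
            "engine_capacity": r.engine_capacity,
            "wheelbase": r.wheelbase,
            "diesel": 1.0 if r.is_diesel else 0.0,
        }
        for r in records if r.fuel != "bev"
    ]
    if len(rows) < 10:
        raise ValueError(f"need >= 10 ICE records for the CO2 fit, got {len(rows)}")
    df = pd.DataFrame(rows)
    return _fit(df["co2_wltp"], df[list(CO2_PREDICTORS)])


def fit_nox_model(records: Iterable[VehicleModelRecord], fuel: str) -> OlsResult:
    """Regress RDE NOx on mass and engine capacity for one fuel family.

    ``fuel`` is "diesel" or "petrol"; hybrids follow their base fuel and
    plug-in hybrids count as petrol.  Models without a reported NOx value are
    excluded.
    """
    if fuel not in ("diesel", "petrol"):
        raise ValueError(f"fuel must be 'diesel' or 'petrol', got {fuel!r}")
    want_diesel = fuel == "diesel"
    rows = [
        {
            "nox_rde": r.nox_rde,
            "wltp_test_mass": r.wltp_test_mass,
            "engine_capacity": r.engine_capacity,
        }
        for r in records
        if r.fuel != "bev" and r.nox_rde is not None and r.is_diesel == want_diesel
    ]
    if len(rows) < 10:
        raise ValueError(f"need >= 10 {fuel} records with NOx for the fit, got {len(rows)}")
    df = pd.DataFrame(rows)
    return _fit(df["nox_rde"], df[list(NOX_PREDICTORS)])


def write_report(results: dict[str, OlsResult], path: str | Path) -> None:
    """Write a delimited regression summary (one block per fitted model)."""
    frames = []
    for name, res in results.items():
        f = res.frame().reset_index(names="predictor")
        f.insert(0, "model", name)
        f["r_squared"] = res.r_squared
        f["f_statistic"] = res.f_statistic
        f["n_obs"] = res.n_obs
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
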