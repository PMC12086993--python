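"""Outlier filtering and construction of the log-scale model response.

Per-plant biomass from dense pots is strongly right-skewed and occasional
recording errors produce extreme values, so biomass is screened with Tukey
fences (Q1 - k*IQR, Q3 + k*IQR, default k = 1.5) before model fitting.
Fences are computed on the raw gram scale, pooled within each
species x experiment (monoculture vs biculture) group, and quartiles use the
linear-interpolation convention (positions p*(n-1) between order
statistics).  Fitting then happens on natural-log biomass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_is_fitted

from .data import ExperimentTable


class InsufficientDataError(ValueError):
    """Too few values to form quartiles."""


def tukey_fences(values, k: float = 1.5) -> tuple[float, float]:
    """Lower and upper Tukey fences of ``values``.

    Requires at least 4 values and ``k > 0``.  Quartiles are computed by
    linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientDataError(f"need >= 4 values, got {v.size}")
    if k <= 0:
        raise ValueError("k must be > 0")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # linear interpolation default
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


class TukeyOutlierFilter(OutlierMixin, BaseEstimator):
    """Interquartile-range outlier detector in the scikit-learn idiom.

    ``fit`` learns the fences from a 1-d sample; ``predict`` labels values
    ``1`` (inlier) or ``-1`` (outlier), as scikit-learn outlier detectors do.

    Parameters
    ----------
    k : float, default 1.5
        Fence multiplier: fences are ``Q1 - k*IQR`` and ``Q3 + k*IQR``.
    """

    def __init__(self, k: float = 1.5):
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).ravel()
        self.lower_, self.upper_ = tukey_fences(X, self.k)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float).ravel()
        inlier = (X >= self.lower_) & (X <= self.upper_)
        return np.where(inlier, 1, -1)


@dataclass(frozen=True)
class FilterReport:
    """Per-group accounting of the outlier screen."""

    species: str
    experiment: str  # "monoculture" or "biculture"
    n_total: int
    n_removed: int
    lower: float
    upper: float
    quantile_convention: str = "linear"

    @property
    def n_final(self) -> int:
        return self.n_total - self.n_removed


def _experiment_label(df: pd.DataFrame) -> pd.Series:
    is_bi = (df["planted_n_brte"] > 0) & (df["planted_n_vedu"] > 0)
    return pd.Series(np.where(is_bi, "biculture", "monoculture"), index=df.index)


def filter_outliers(
    table: ExperimentTable, k: float = 1.5
) -> tuple[ExperimentTable, list[FilterReport]]:
    """Remove biomass values outside their group's Tukey fences.

    Groups are species x {monoculture, biculture}, fences pooled across
    densities within a group and computed on raw grams.  Groups with fewer
    than 4 rows are passed through unfiltered (fences undefined) and
    reported with NaN fences.  No field other than row membership changes.
    """
    df = table.frame
    experiment = _experiment_label(df)
    keep = pd.Series(True, index=df.index)
    reports: list[FilterReport] = []
    for (sp, exp), idx in df.groupby([df["species"], experiment]).groups.items():
        values = df.loc[idx, "biomass_g"]
        if len(idx) < 4:
            reports.append(
                FilterReport(sp, exp, len(idx), 0, float("nan"), float("nan"))
            )
            continue
        lower, upper = tukey_fences(values, k)
        inside = (values >= lower) & (values <= upper)
        keep.loc[idx] = inside
        reports.append(
            FilterReport(sp, exp, len(idx), int((~inside).sum()), lower, upper)
        )
    reports.sort(key=lambda r: (r.species, r.experiment))
    filtered = ExperimentTable(df.loc[keep].copy(), dict(table.metadata))
    return filtered, reports


def null_filter_reports(table: ExperimentTable) -> list[FilterReport]:
    """Accounting rows for a run with the outlier screen disabled."""
    df = table.frame
    experiment = _experiment_label(df)
    reports = [
        FilterReport(sp, exp, len(idx), 0, float("nan"), float("nan"), "disabled")
        for (sp, exp), idx in df.groupby([df["species"], experiment]).groups.items()
    ]
    reports.sort(key=lambda r: (r.species, r.experiment))
    return reports


def reports_frame(reports: list[FilterReport]) -> pd.DataFrame:
    """Tabulate filter reports (species, experiment, totals, removed, final)."""
    return pd.DataFrame(
        {
            "species": [r.species for r in reports],
            "experiment": [r.experiment for r in reports],
            "total_observations": [r.n_total for r in reports],
            "outliers_removed": [r.n_removed for r in reports],
            "final_observations": [r.n_final for r in reports],
            "fence_lower": [r.lower for r in reports],
            "fence_upper": [r.upper for r in reports],
        }
    )


def prepare_log_response(table: ExperimentTable) -> pd.DataFrame:
    """Build the modelling frame: ln biomass plus realized-density covariates.

    Columns: ``species``, ``log_biomass``, ``n_total`` (realized pot total),
    ``n_self`` and ``n_other`` (realized density of the record's own and of
    the other species).
    """
    df = table.frame
    if len(df) == 0:
        return pd.DataFrame(
            columns=["species", "log_biomass", "n_total", "n_self", "n_other"]
        )
    if (df["biomass_g"] <= 0).any():
        raise ValueError("biomass_g must be > 0 for the log transform")
    is_brte = df["species"] == "BRTE"
    n_self = np.where(is_brte, df["realized_n_brte"], df["realized_n_vedu"])
    n_other = np.where(is_brte, df["realized_n_vedu"], df["realized_n_brte"])
    return pd.DataFrame(
        {
            "species": df["species"].to_numpy(),
            "log_biomass": np.log(df["biomass_g"].to_numpy()),
            "n_total": (df["realized_n_brte"] + df["realized_n_vedu"]).to_numpy(),
            "n_self": n_self.astype(float),
            "n_other": n_other.astype(float),
        }
    )
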