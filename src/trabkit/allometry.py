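"""Body-mass estimation from femoral-head calipers and allometric residuals.

Trabecular variables scale allometrically with body size, so before any
group comparison each variable is residualized: log10 of the variable is
regressed on log10 body mass by OLS across all specimens pooled, and the
unstandardized residuals are the size-corrected traits.

Body mass itself is estimated from femoral-head caliper dimensions using
published taxon-specific regressions: a linear anteroposterior-breadth
equation for humans (sex-specific, with the 0.9 downward adjustment for
skeletal samples) and log-form superoinferior-height equations for the
other groups, each with its ratio correction for back-transformation bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["SpecimenRecord", "EQUATION_SETS", "GENUS_EQUATION_SET",
           "LOCOMOTOR_GROUPS", "estimate_body_mass",
           "AllometricScaling", "AllometryResults", "size_residuals"]

#: fixed locomotor vocabulary (seven categories)
LOCOMOTOR_GROUPS = [
    "biped",
    "terrestrial quad",
    "arboreal quad",
    "arboreal quad-climber",
    "quadrumanous climber",
    "brachiator",
    "terrestrial quad-climber",
]

#: log-form sets: ln(BM) = a·ln(FemHeadSI) + c, BM ×= ratio; ``unit`` is the
#: unit the source regression predicts (grams are converted to kg).
EQUATION_SETS = {
    "haplorhine": {"form": "log", "a": 2.729, "c": 1.42, "ratio": 1.0,
                   "unit": "g"},
    "cercopithecine": {"form": "log", "a": 2.389, "c": -4.541, "ratio": 1.014,
                       "unit": "kg"},
    "hominoid": {"form": "log", "a": 3.019, "c": -6.668, "ratio": 1.006,
                 "unit": "kg"},
    "asian_ape": {"form": "log", "a": 3.024, "c": -6.718, "ratio": 1.008,
                  "unit": "kg"},
    "colobine": {"form": "log", "a": 2.424, "c": -4.684, "ratio": 1.01,
                 "unit": "kg"},
    # human: BM = (a·FemHeadAP − b) · 0.9, kg, sex-specific
    "human": {"form": "linear",
              "M": {"a": 2.741, "b": 54.9},
              "F": {"a": 2.426, "b": 35.1},
              "shrink": 0.9, "unit": "kg"},
}

#: default genus → equation-set assignment
GENUS_EQUATION_SET = {
    "Alouatta": "haplorhine",
    "Homo": "human",
    "Macaca": "cercopithecine",
    "Papio": "cercopithecine",
    "Pan": "hominoid",
    "Pongo": "asian_ape",
    "Symphalangus": "asian_ape",
    "Trachypithecus": "colobine",
}


@dataclass
class SpecimenRecord:
    """One specimen's metadata row (calipers in mm)."""

    id: str
    genus: str
    locomotor_group: str
    element: str = "femur"
    sex: str = "I"
    fem_head_SI_mm: float | None = None
    fem_head_AP_mm: float | None = None
    fem_head_ML_mm: float | None = None
    body_mass_kg: float | None = None

    def __post_init__(self):
        if self.locomotor_group not in LOCOMOTOR_GROUPS:
            raise ValueError(f"unknown locomotor group {self.locomotor_group!r}")
        for f in ("fem_head_SI_mm", "fem_head_AP_mm", "fem_head_ML_mm"):
            v = getattr(self, f)
            if v is not None and not v > 0:
                raise ValueError(f"{f} must be positive")


def estimate_body_mass(record: SpecimenRecord,
                       equation_set: str | None = None) -> float:
    """Predicted body mass in kg for one specimen.

    ``equation_set`` defaults to the genus assignment in
    :data:`GENUS_EQUATION_SET`.  The human equations require a determined
    sex and the anteroposterior caliper; log-form sets require the
    superoinferior caliper.
    """
    name = equation_set or GENUS_EQUATION_SET.get(record.genus)
    if name is None:
        raise ValueError(f"no equation set for genus {record.genus!r}")
    eq = EQUATION_SETS[name]
    if eq["form"] == "linear":
        if record.sex not in ("M", "F"):
            raise ValueError("human equations require sex M or F")
        if record.fem_head_AP_mm is None:
            raise ValueError("human equations require fem_head_AP_mm")
        coefs = eq[record.sex]
        bm = (coefs["a"] * record.fem_head_AP_mm - coefs["b"]) * eq["shrink"]
    else:
        if record.fem_head_SI_mm is None:
            raise ValueError(f"{name} equations require fem_head_SI_mm")
        bm = float(np.exp(eq["a"] * np.log(record.fem_head_SI_mm) + eq["c"]))
        bm *= eq["ratio"]
    if eq["unit"] == "g":
        bm /= 1000.0
    if bm <= 0:
        raise ValueError(f"non-positive predicted mass ({bm:.2f} kg) for "
                         f"specimen {record.id}")
    return float(bm)


@dataclass
class AllometryResults:
    """Per-variable log-log OLS fits and the residual table.

    ``coefficients`` rows are variables with columns (intercept, slope,
    slope_se, r2); ``residuals`` has one column per variable, in log10 units.
    """

    coefficients: pd.DataFrame
    residuals: pd.DataFrame

    def summary(self) -> str:
        lines = ["Allometric scaling (log10 variable ~ log10 body mass)",
                 "-" * 56,
                 f"{'variable':<16}{'intercept':>10}{'slope':>9}"
                 f"{'SE':>8}{'R2':>8}"]
        for var, row in self.coefficients.iterrows():
            lines.append(f"{var:<16}{row['intercept']:>10.4f}"
                         f"{row['slope']:>9.4f}{row['slope_se']:>8.4f}"
                         f"{row['r2']:>8.3f}")
        return "\n".join(lines)


class AllometricScaling:
    """OLS residualization model: one pooled regression per trabecular variable.

    Parameters
    ----------
    features : DataFrame
        Specimens × variables, strictly positive values.
    body_mass_kg : Series
        Per-specimen body mass, aligned with ``features``.
    """

    def __init__(self, features: pd.DataFrame, body_mass_kg: pd.Series):
        features = features.astype(float)
        mass = pd.Series(body_mass_kg, index=features.index).astype(float)
        if (features <= 0).any().any():
            bad = features.index[(features <= 0).any(axis=1)].tolist()
            raise ValueError(f"non-positive feature values (log-undefined) "
                             f"in rows {bad}")
        if (mass <= 0).any():
            raise ValueError("non-positive body mass")
        if np.ptp(np.log10(mass.to_numpy())) == 0:
            raise ValueError("constant body mass: regression is degenerate")
        self.features = features
        self.body_mass_kg = mass

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mass_col: str = "body_mass_kg",
                       feature_cols: list[str] | None = None):
        cols = feature_cols or [c for c in df.columns if c != mass_col]
        return cls(df[cols], df[mass_col])

    def fit(self) -> AllometryResults:
        logm = np.log10(self.body_mass_kg.to_numpy())
        X = sm.add_constant(logm)
        coefs, resid = {}, {}
        for var in self.features.columns:
            y = np.log10(self.features[var].to_numpy())
            res = sm.OLS(y, X).fit()
            coefs[var] = {"intercept": res.params[0], "slope": res.params[1],
                          "slope_se": res.bse[1], "r2": res.rsquared}
            resid[var] = res.resid
        return AllometryResults(
            pd.DataFrame(coefs).T[["intercept", "slope", "slope_se", "r2"]],
            pd.DataFrame(resid, index=self.features.index))


def size_residuals(features: pd.DataFrame, body_mass_kg: pd.Series) -> pd.DataFrame:
    """Convenience wrapper: the residual table from :class:`AllometricScaling`."""
    return AllometricScaling(features, body_mass_kg).fit().residuals
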