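"""Normative W-score maps for baseline atrophy.

A W-score is a covariate-adjusted z-score: per region, a least-squares
regression of the deformation measure on age and sex is fit on healthy
control *baseline* scans, and any scan is then scored as

    W = (observed - predicted(age, sex)) / residual SD

so W is in control-SD units with mean 0 / SD 1 in the reference population.
A higher W means more baseline atrophy than expected for that age and sex
(the deformation measure is oriented at load time so this sign convention
holds).  W is invariant to affine rescaling of the raw measure, since scale
cancels between numerator and residual SD after refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import LongitudinalDataset, RegionalMap, check_same_regions

#: sex coding used in the reference design (recorded in the model artifact)
SEX_CODING = {"M": 0.0, "F": 1.0}

_N_PARAMS = 3  # intercept, age, sex


@dataclass
class ReferenceModel:
    """Per-region normative regression fitted on HC baseline scans."""

    region_ids: Sequence[str]
    intercept: np.ndarray
    age_coef: np.ndarray
    sex_coef: np.ndarray
    residual_sd: np.ndarray
    n_controls: int
    age_min: float
    age_max: float
    sex_coding: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sex_coding is None:
            self.sex_coding = dict(SEX_CODING)

    @property
    def zero_variance_mask(self) -> np.ndarray:
        """Regions whose residual SD collapsed to ~0 (flagged, not scored)."""
        return ~(self.residual_sd > 1e-12)

    def predict(self, age: np.ndarray, sex_code: np.ndarray) -> np.ndarray:
        age = np.asarray(age, dtype=float)[:, None]
        sex_code = np.asarray(sex_code, dtype=float)[:, None]
        return self.intercept[None, :] + age * self.age_coef[None, :] + sex_code * self.sex_coef[None, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": list(self.region_ids),
                "intercept": self.intercept,
                "age_coef": self.age_coef,
                "sex_coef": self.sex_coef,
                "residual_sd": self.residual_sd,
            }
        )

    def save(self, path) -> None:
        df = self.to_frame()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(
                f"# n_controls={self.n_controls} age_min={self.age_min!r} "
                f"age_max={self.age_max!r} sex_coding=M:0,F:1\n"
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header if "=" in kv)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        return cls(
            df["region_id"].astype(str).tolist(),
            df["intercept"].to_numpy(),
            df["age_coef"].to_numpy(),
            df["sex_coef"].to_numpy(),
            df["residual_sd"].to_numpy(),
            n_controls=int(meta["n_controls"]),
            age_min=float(meta["age_min"]),
            age_max=float(meta["age_max"]),
        )


def _design(meta: pd.DataFrame) -> np.ndarray:
    sex = meta["sex"].map(SEX_CODING)
    if sex.isna().any():
        raise ValueError(f"unknown sex labels {meta.loc[sex.isna(), 'sex'].unique()}")
    return np.column_stack(
        [np.ones(len(meta)), meta["age"].to_numpy(float), sex.to_numpy(float)]
    )


def fit_reference(dataset: LongitudinalDataset) -> ReferenceModel:
    """Fit the per-region normative model on HC baseline scans.

    The input is restricted to group HC at visit 0; anything less than
    ``n_params + 5`` controls is refused.  Residual SD uses the unbiased
    (n - 3) denominator.  Regions with (numerically) zero residual variance
    are flagged rather than dropped.
    """
    hc = dataset.restrict_group("HC").baseline()
    n = hc.n_scans
    if n < _N_PARAMS + 5:
        raise ValueError(
            f"need at least {_N_PARAMS + 5} HC baseline scans to fit the "
            f"reference model, got {n}"
        )
    if n < 20:
        warnings.warn(
            f"only {n} HC baseline scans; normative estimates will be noisy",
            stacklevel=2,
        )
    X = _design(hc.meta)
    Y = hc.values
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    residual_sd = np.sqrt((resid**2).sum(axis=0) / (n - _N_PARAMS))
    model = ReferenceModel(
        list(hc.region_ids),
        coef[0],
        coef[1],
        coef[2],
        residual_sd,
        n_controls=n,
        age_min=float(hc.meta["age"].min()),
        age_max=float(hc.meta["age"].max()),
    )
    if model.zero_variance_mask.any():
        flagged = np.asarray(model.region_ids)[model.zero_variance_mask]
        warnings.warn(
            f"{model.zero_variance_mask.sum()} regions have ~zero residual "
            f"variance (e.g. {flagged[:3].tolist()}); their W-scores are NaN",
            stacklevel=2,
        )
    return model


@dataclass
class WScoreResult:
    subject_ids: list[str]
    groups: list[str]
    wscores: np.ndarray  # (n_subjects, R)
    region_ids: Sequence[str]

    def subject_map(self, subject_id: str) -> RegionalMap:
        i = self.subject_ids.index(subject_id)
        return RegionalMap(list(self.region_ids), self.wscores[i], "w")

    def group_mean_maps(self) -> dict[str, RegionalMap]:
        groups = np.asarray(self.groups)
        return {
            g: RegionalMap(
                list(self.region_ids),
                self.wscores[groups == g].mean(axis=0),
                "w",
            )
            for g in dict.fromkeys(self.groups)
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.wscores, columns=list(self.region_ids))
        df.insert(0, "group", self.groups)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def compute_wscores(
    dataset: LongitudinalDataset, model: ReferenceModel, visit: int = 0
) -> WScoreResult:
    """Score every subject's scan at ``visit`` against the normative model.

    Ages more than 10 years outside the reference fitting range trigger an
    extrapolation warning.  Regions flagged as zero-variance score NaN.
    """
    check_same_regions(dataset.region_ids, model.region_ids, "dataset vs reference model")
    at_visit = dataset.select((dataset.meta["visit"] == visit).to_numpy())
    if at_visit.n_scans == 0:
        raise ValueError(f"no scans at visit {visit}")
    meta = at_visit.meta
    ages = meta["age"].to_numpy(float)
    out_of_range = (ages < model.age_min - 10) | (ages > model.age_max + 10)
    if out_of_range.any():
        warnings.warn(
            f"{out_of_range.sum()} subjects outside the reference age range "
            f"by >10 y; W-scores are extrapolations",
            stacklevel=2,
        )
    sex_code = meta["sex"].map(model.sex_coding).to_numpy(float)
    predicted = model.predict(ages, sex_code)
    sd = np.where(model.zero_variance_mask, np.nan, model.residual_sd)
    W = (at_visit.values - predicted) / sd[None, :]
    return WScoreResult(
        meta["subject_id"].tolist(),
        meta["group"].tolist(),
        W,
        list(dataset.region_ids),
    )
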