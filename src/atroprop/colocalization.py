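"""Spatial colocalization of regional maps and correlation-strength tests.

Atrophy/progression maps are correlated region-wise against PET binding
maps and against neurotransmitter receptor/transporter density maps, with
significance from the shared variogram-matched surrogate machinery in
:mod:`atroprop.spatial_nulls` and BH-FDR across the candidate set.

Correlation *strengths* are compared two ways:

* independent samples (e.g. the same pair of maps in two groups):
  Fisher's z test, z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3));
* dependent correlations sharing a sample (e.g. tau-vs-atrophy against
  Abeta-vs-atrophy within one group): Zou's modified-asymptotic confidence
  interval for r1 - r2, combining single-correlation Fisher-z CIs with a
  dependence-adjusted corner formula, for both the overlapping (one shared
  variable) and non-overlapping cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ReceptorAtlas, RegionalMap, check_same_regions
from .progression import bh_fdr
from .spatial_nulls import (
    SurrogateParams,
    generate_surrogates,
    spin_correlation_test,
)


def standardize_receptors(atlas: ReceptorAtlas) -> dict[str, RegionalMap]:
    """One z-scored map per target.

    Each contributing tracer map is z-scored across regions; targets with
    several tracer studies combine them as a weighted average with weights
    proportional to study sample size.  Single-tracer targets pass through
    z-scored.
    """
    out: dict[str, RegionalMap] = {}
    for target, maps in atlas.entries.items():
        zs = []
        weights = []
        for m, w in maps:
            v = m.values
            ok = np.isfinite(v)
            sd = v[ok].std(ddof=0)
            if sd == 0:
                raise ValueError(f"zero-variance tracer map for target {target!r}")
            z = (v - v[ok].mean()) / sd
            zs.append(z)
            weights.append(w)
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
        combined = np.einsum("t,tr->r", weights, np.vstack(zs))
        out[target] = RegionalMap(atlas.region_ids, combined, "receptor_z")
    return out


def colocalize(
    target_maps: Mapping[str, RegionalMap],
    candidate_maps: Mapping[str, RegionalMap],
    D: np.ndarray,
    n_surr: int = 1000,
    rng_seed: int = 0,
    method: str = "pearson",
    params: SurrogateParams | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """All target x candidate spatial correlations with spin p-values.

    The target map is the one surrogated; its ensemble is generated once and
    reused across every candidate, so the null is identical within a target.
    BH-FDR is applied across the candidate set separately per target.
    """
    rows = []
    ss = np.random.SeedSequence(rng_seed)
    target_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(target_maps, ss.spawn(len(target_maps)))
    }
    for t_name, t_map in target_maps.items():
        ok_t = np.isfinite(t_map.values)
        ensemble = None
        for c_name, c_map in candidate_maps.items():
            check_same_regions(
                t_map.region_ids, c_map.region_ids, f"{t_name} vs {c_name}"
            )
            ok = ok_t & np.isfinite(c_map.values)
            if ensemble is None or not np.array_equal(ok, ensemble_mask):
                ensemble_mask = ok
                ensemble = generate_surrogates(
                    t_map.values[ok], D[np.ix_(ok, ok)], n_surr,
                    target_seeds[t_name], params,
                )
            res = spin_correlation_test(
                t_map.values[ok],
                c_map.values[ok],
                D[np.ix_(ok, ok)],
                n_surr=n_surr,
                rng_seed=target_seeds[t_name],
                method=method,
                ensemble=ensemble,
            )
            rows.append(
                {
                    "target": t_name,
                    "candidate": c_name,
                    "r": res.r_emp,
                    "p_spin": res.p_spin,
                    "n_regions": int(ok.sum()),
                }
            )
    table = pd.DataFrame(rows)
    table["p_spin_fdr"] = np.nan
    for t_name in target_maps:
        ix = table["target"] == t_name
        table.loc[ix, "p_spin_fdr"] = bh_fdr(table.loc[ix, "p_spin"].to_numpy(), q).adjusted_p
    table["significant"] = table["p_spin_fdr"] < q
    return table


# ---------------------------------------------------------------------------
# correlation-strength comparisons
# ---------------------------------------------------------------------------


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    comparison: str  # independent | dependent-overlapping | dependent-nonoverlapping
    n1: int
    n2: int
    statistic: float | None = None
    p_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    cross_correlations: dict | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("CI low must be <= high")


def _check_r(*rs: float) -> None:
    for r in rs:
        if not -1.0 < r < 1.0:
            raise ValueError(f"correlation {r} must lie strictly inside (-1, 1)")


def compare_independent(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Fisher-z comparison of two correlations from independent samples."""
    _check_r(r1, r2)
    if n1 < 10 or n2 < 10:
        raise ValueError("need n >= 10 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return CorrelationComparison(
        r1=r1, r2=r2, comparison="independent", n1=n1, n2=n2,
        statistic=float(z), p_value=p,
    )


def _fisher_ci(r: float, n: int, conf: float) -> tuple[float, float]:
    zc = stats.norm.ppf(0.5 + conf / 2)
    se = 1 / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(r) - zc * se), np.tanh(np.arctanh(r) + zc * se)
    return float(lo), float(hi)


def _corr_overlapping(r12: float, r13: float, r23: float) -> float:
    """Correlation between the sampling errors of r12 and r13 (shared variable 1)."""
    num = (r23 - 0.5 * r12 * r13) * (1 - r12**2 - r13**2 - r23**2) + r23**3
    den = (1 - r12**2) * (1 - r13**2)
    return num / den


def _corr_nonoverlapping(
    r12: float, r34: float, r13: float, r14: float, r23: float, r24: float
) -> float:
    """Correlation between the sampling errors of r12 and r34 (no shared variable)."""
    num = (
        0.5 * r12 * r34 * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - (r12 * r13 * r14 + r12 * r23 * r24 + r13 * r23 * r34 + r14 * r24 * r34)
    )
    den = (1 - r12**2) * (1 - r34**2)
    return num / den


def compare_dependent(
    r1: float,
    r2: float,
    cross_correlations: float | Mapping[str, float],
    n: int,
    conf: float = 0.95,
) -> CorrelationComparison:
    """Zou's modified-asymptotic CI for the difference of two dependent
    correlations measured on the same ``n`` subjects (or regions).

    Overlapping case (r1 = corr(x, y1), r2 = corr(x, y2)): pass the single
    cross-correlation corr(y1, y2) as a float.  Non-overlapping case
    (r1 = corr(x1, y1), r2 = corr(x2, y2)): pass a mapping with keys
    ``x1x2, x1y2, y1x2, y1y2`` for the four cross correlations.

    With zero dependence the interval reduces exactly to the independent
    corner combination L = r1 - r2 - sqrt((r1-l1)^2 + (u2-r2)^2).
    """
    _check_r(r1, r2)
    if n < 10:
        raise ValueError("need n >= 10")
    l1, u1 = _fisher_ci(r1, n, conf)
    l2, u2 = _fisher_ci(r2, n, conf)
    if isinstance(cross_correlations, Mapping):
        needed = {"x1x2", "x1y2", "y1x2", "y1y2"}
        if set(cross_correlations) != needed:
            raise ValueError(f"non-overlapping case needs keys {sorted(needed)}")
        cc = {k: float(v) for k, v in cross_correlations.items()}
        _check_r(*[v for v in cc.values() if abs(v) < 1.0] or [0.0])
        full = np.array(
            [
                [1, r1, cc["x1x2"], cc["x1y2"]],
                [r1, 1, cc["y1x2"], cc["y1y2"]],
                [cc["x1x2"], cc["y1x2"], 1, r2],
                [cc["x1y2"], cc["y1y2"], r2, 1],
            ]
        )
        if np.linalg.eigvalsh(full).min() < -1e-8:
            raise ValueError("cross-correlation structure is not positive semidefinite")
        c = _corr_nonoverlapping(
            r12=r1, r34=r2,
            r13=cc["x1x2"], r14=cc["x1y2"], r23=cc["y1x2"], r24=cc["y1y2"],
        )
        kind = "dependent-nonoverlapping"
        cross = cc
    else:
        r23 = float(cross_correlations)
        full = np.array([[1, r1, r2], [r1, 1, r23], [r2, r23, 1]])
        if np.linalg.eigvalsh(full).min() < -1e-8:
            raise ValueError("cross-correlation structure is not positive semidefinite")
        c = _corr_overlapping(r1, r2, r23)
        kind = "dependent-overlapping"
        cross = {"y1y2": r23}
    lo = r1 - r2 - np.sqrt(
        max((r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2), 0.0)
    )
    hi = r1 - r2 + np.sqrt(
        max((u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2), 0.0)
    )
    return CorrelationComparison(
        r1=r1, r2=r2, comparison=kind, n1=n, n2=n,
        ci_low=float(lo), ci_high=float(hi), cross_correlations=cross,
    )
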