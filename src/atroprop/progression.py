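"""Region-wise and network-wise longitudinal models of atrophy progression.

The central model is a linear mixed-effects regression fit per region:

    y ~ group + age + group:age + sex + education + BMI + APOE4 + APOE4:age
    random effects: intercept and age slope per subject, unstructured 2x2
    covariance, REML estimation.

The group x age interaction coefficient ("beta") is the atrophy-progression
estimate: positive beta means faster deformation change with age than the
healthy-control reference.  Age is centered at the pooled baseline mean
before entering the model (units of beta unchanged) for conditioning.

Because hundreds of independent regional fits need an automated policy,
non-convergence falls down a ladder — unstructured covariance, then
independent (diagonal) random effects, then random intercept only — each
step flagged in the result.

Also here: the Benjamini-Hochberg FDR step-up, the PET group comparison
(ordinary least squares per region, one baseline scan per subject), partial
Spearman correlations, and the small categorical tests (Pearson chi-square
without continuity correction; tie-corrected Kruskal-Wallis on per-subject
scan counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.stats.multitest import multipletests

from .core_data import (
    CategoricalTestResult,
    LongitudinalDataset,
    NetworkPartition,
    RegionalMap,
)

CONTRASTS = ("FHAD-HC", "AD-HC", "AD-FHAD")

#: covariate columns every longitudinal model adjusts for
_COVARIATES = ("sex", "education_y", "bmi", "apoe4")


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


@dataclass
class FdrResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    reject: np.ndarray
    q: float

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Adjusted p-values are min over j>=i of m*p_(j)/j, capped at 1; NaN
    entries (e.g. failed fits) are excluded from the correction and stay NaN.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan)
    reject = np.zeros_like(p, dtype=bool)
    if ok.sum():
        rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adjusted[ok] = adj
        reject[ok] = rej
    return FdrResult(p, adjusted, reject, q)


# ---------------------------------------------------------------------------
# design construction (shared across all regional fits)
# ---------------------------------------------------------------------------


@dataclass
class _Design:
    X: np.ndarray
    names: list[str]
    groups: np.ndarray
    age_c: np.ndarray
    keep: np.ndarray  # scan-row mask after covariate-completeness filtering
    n_subjects: int
    interaction_ix: list[int]  # columns of the two group x age terms


def _build_design(dataset: LongitudinalDataset, sex_terms: bool = False) -> _Design:
    meta = dataset.meta
    keep = (
        meta[list(_COVARIATES) + ["age", "group", "subject_id"]].notna().all(axis=1)
    ).to_numpy()
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} scans with missing covariates", stacklevel=3
        )
    meta = meta.loc[keep]
    baseline_mean_age = meta.loc[meta["visit"] == 0, "age"].mean()
    age_c = (meta["age"] - baseline_mean_age).to_numpy(float)
    g_f = (meta["group"] == "FHAD").to_numpy(float)
    g_a = (meta["group"] == "AD").to_numpy(float)
    sex = (meta["sex"] == "F").to_numpy(float)
    cols = {
        "const": np.ones(len(meta)),
        "g_fhad": g_f,
        "g_ad": g_a,
        "age_c": age_c,
        "g_fhad:age_c": g_f * age_c,
        "g_ad:age_c": g_a * age_c,
        "sex": sex,
        "education_y": meta["education_y"].to_numpy(float),
        "bmi": meta["bmi"].to_numpy(float),
        "apoe4": meta["apoe4"].to_numpy(float),
        "apoe4:age_c": meta["apoe4"].to_numpy(float) * age_c,
    }
    if sex_terms:
        cols["g_fhad:sex"] = g_f * sex
        cols["g_ad:sex"] = g_a * sex
        cols["sex:age_c"] = sex * age_c
        cols["g_fhad:sex:age_c"] = g_f * sex * age_c
        cols["g_ad:sex:age_c"] = g_a * sex * age_c
    names = list(cols)
    X = np.column_stack(list(cols.values()))
    return _Design(
        X=X,
        names=names,
        groups=meta["subject_id"].to_numpy(),
        age_c=age_c,
        keep=keep,
        n_subjects=meta["subject_id"].nunique(),
        interaction_ix=[names.index("g_fhad:age_c"), names.index("g_ad:age_c")],
    )


# ---------------------------------------------------------------------------
# single-region LMM
# ---------------------------------------------------------------------------


@dataclass
class LmmRegionResult:
    region_id: str
    beta: dict[str, float]  # per contrast, deformation units / year
    se: dict[str, float]
    wald_z: dict[str, float]
    p: dict[str, float]
    f_stat: float  # Wald F (chi2/2) on the two group x age coefficients
    p_omnibus: float
    re_cov: np.ndarray  # 2x2 random intercept/slope covariance (or 1x1)
    converged: bool
    covariance_structure: str  # unstructured | diagonal | intercept-only
    n_obs: int
    n_subjects: int


def _fit_ladder(y: np.ndarray, design: _Design):
    """Fit with unstructured random effects; fall back to diagonal, then to
    random intercept only.  Returns (result, structure_label, clean_converged)."""
    exog_re = np.column_stack([np.ones_like(design.age_c), design.age_c])
    attempts = [
        ("unstructured", exog_re, None),
        (
            "diagonal",
            exog_re,
            MixedLMParams.from_components(
                fe_params=np.ones(design.X.shape[1]), cov_re=np.eye(2)
            ),
        ),
        ("intercept-only", exog_re[:, :1], None),
    ]
    last = None
    for label, xre, free in attempts:
        model = MixedLM(y, design.X, groups=design.groups, exog_re=xre)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(
                    reml=True, method=["lbfgs", "cg"], free=free, maxiter=200
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
        ok = (
            res.converged
            and np.isfinite(res.fe_params).all()
            and np.isfinite(np.asarray(res.bse_fe)).all()
        )
        last = (res, label)
        if ok:
            return res, label, label == "unstructured"
    if last is None:
        raise np.linalg.LinAlgError("all mixed-model fits failed")
    return last[0], last[1], False


def _extract_result(res, structure: str, clean: bool, design: _Design, region_id: str) -> LmmRegionResult:
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(params), : len(params)]
    i_f, i_a = design.interaction_ix
    b_f, b_a = params[i_f], params[i_a]
    v_f, v_a = cov[i_f, i_f], cov[i_a, i_a]
    c_fa = cov[i_f, i_a]
    ests = {
        "FHAD-HC": (b_f, np.sqrt(v_f)),
        "AD-HC": (b_a, np.sqrt(v_a)),
        "AD-FHAD": (b_a - b_f, np.sqrt(max(v_a + v_f - 2 * c_fa, 0.0))),
    }
    beta, se, wz, p = {}, {}, {}, {}
    for name, (b, s) in ests.items():
        beta[name] = float(b)
        se[name] = float(s)
        z = b / s if s > 0 else np.nan
        wz[name] = float(z)
        p[name] = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    # omnibus Wald test on the two interaction coefficients
    V = cov[np.ix_(design.interaction_ix, design.interaction_ix)]
    b2 = params[design.interaction_ix]
    try:
        w = float(b2 @ np.linalg.solve(V, b2))
        p_omni = float(stats.chi2.sf(w, df=2))
    except np.linalg.LinAlgError:
        w, p_omni = np.nan, np.nan
    return LmmRegionResult(
        region_id=region_id,
        beta=beta,
        se=se,
        wald_z=wz,
        p=p,
        f_stat=w / 2 if np.isfinite(w) else np.nan,
        p_omnibus=p_omni,
        re_cov=np.atleast_2d(np.asarray(res.cov_re)),
        converged=clean,
        covariance_structure=structure,
        n_obs=len(design.groups),
        n_subjects=design.n_subjects,
    )


def fit_region_lmm(
    dataset: LongitudinalDataset, region_id: str, _design_cache: _Design | None = None
) -> LmmRegionResult:
    """Fit the longitudinal mixed model for one region and return the three
    pairwise group x age contrasts plus the omnibus interaction test."""
    groups_present = dataset.meta["group"].nunique()
    if groups_present < 2:
        raise ValueError("need at least two groups to estimate progression contrasts")
    if dataset.n_subjects < 30:
        raise ValueError(
            f"need at least 30 subjects for a stable mixed model, got {dataset.n_subjects}"
        )
    design = _design_cache or _build_design(dataset)
    ids = list(dataset.region_ids)
    j = ids.index(str(region_id))
    y = dataset.values[design.keep, j]
    res, structure, clean = _fit_ladder(y, design)
    return _extract_result(res, structure, clean, design, str(region_id))


# ---------------------------------------------------------------------------
# all-region maps
# ---------------------------------------------------------------------------


@dataclass
class ProgressionResult:
    table: pd.DataFrame  # one row per region
    beta_maps: dict[str, RegionalMap]
    fdr: FdrResult  # omnibus p over regions
    posthoc_fdr: dict[str, FdrResult]
    significant_positive: dict[str, list[str]]
    significant_negative: dict[str, list[str]]
    failed_regions: list[str]


def progression_maps(
    dataset: LongitudinalDataset,
    q: float = 0.05,
    posthoc_scope: str = "significant",
) -> ProgressionResult:
    """Run the regional mixed model over every region.

    Omnibus group x age p-values are BH-FDR corrected at ``q``; post hoc
    contrast p-values are FDR-corrected within the omnibus-significant set
    (``posthoc_scope="all"`` corrects over every region instead).  Regions
    where every fit attempt fails are excluded and reported.
    """
    if posthoc_scope not in ("significant", "all"):
        raise ValueError("posthoc_scope must be 'significant' or 'all'")
    design = _build_design(dataset)
    rows = []
    failed: list[str] = []
    results: list[LmmRegionResult] = []
    for j, rid in enumerate(dataset.region_ids):
        y = dataset.values[design.keep, j]
        try:
            res, structure, clean = _fit_ladder(y, design)
        except np.linalg.LinAlgError:
            failed.append(str(rid))
            continue
        results.append(_extract_result(res, structure, clean, design, str(rid)))
    for r in results:
        row = {"region_id": r.region_id, "f_stat": r.f_stat, "p_omnibus": r.p_omnibus,
               "converged": r.converged, "covariance_structure": r.covariance_structure}
        for c in CONTRASTS:
            row[f"beta_{c}"] = r.beta[c]
            row[f"se_{c}"] = r.se[c]
            row[f"p_{c}"] = r.p[c]
        rows.append(row)
    table = pd.DataFrame(rows)
    fdr = bh_fdr(table["p_omnibus"].to_numpy(), q)
    table["p_omnibus_fdr"] = fdr.adjusted_p
    table["significant"] = fdr.reject
    posthoc_fdr: dict[str, FdrResult] = {}
    sig_pos: dict[str, list[str]] = {}
    sig_neg: dict[str, list[str]] = {}
    scope = fdr.reject if posthoc_scope == "significant" else np.ones(len(table), bool)
    for c in CONTRASTS:
        p_scope = np.where(scope, table[f"p_{c}"].to_numpy(), np.nan)
        pf = bh_fdr(p_scope, q)
        posthoc_fdr[c] = pf
        table[f"p_{c}_fdr"] = pf.adjusted_p
        beta = table[f"beta_{c}"].to_numpy()
        sig_pos[c] = table.loc[pf.reject & (beta > 0), "region_id"].tolist()
        sig_neg[c] = table.loc[pf.reject & (beta < 0), "region_id"].tolist()
    ids_done = table["region_id"].tolist()
    beta_maps = {}
    all_ids = [str(r) for r in dataset.region_ids]
    for c in CONTRASTS:
        vals = pd.Series(
            table[f"beta_{c}"].to_numpy(), index=ids_done
        ).reindex(all_ids).to_numpy()
        beta_maps[c] = RegionalMap(all_ids, vals, "beta")
    return ProgressionResult(
        table=table,
        beta_maps=beta_maps,
        fdr=fdr,
        posthoc_fdr=posthoc_fdr,
        significant_positive=sig_pos,
        significant_negative=sig_neg,
        failed_regions=failed,
    )


def sex_interaction_scan(dataset: LongitudinalDataset, q: float = 0.05) -> pd.DataFrame:
    """Secondary scan adding group x sex x age, group x sex and sex x age
    terms; returns per-region Wald p-values for each term set, FDR-corrected
    across regions within each set."""
    design = _build_design(dataset, sex_terms=True)
    term_sets = {
        "group_sex_age": ["g_fhad:sex:age_c", "g_ad:sex:age_c"],
        "group_sex": ["g_fhad:sex", "g_ad:sex"],
        "sex_age": ["sex:age_c"],
    }
    ix_sets = {k: [design.names.index(n) for n in v] for k, v in term_sets.items()}
    rows = []
    for j, rid in enumerate(dataset.region_ids):
        y = dataset.values[design.keep, j]
        try:
            res, structure, clean = _fit_ladder(y, design)
        except np.linalg.LinAlgError:
            rows.append({"region_id": str(rid), **{f"p_{k}": np.nan for k in term_sets}})
            continue
        params = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: len(params), : len(params)]
        row = {"region_id": str(rid)}
        for k, ix in ix_sets.items():
            V = cov[np.ix_(ix, ix)]
            b = params[ix]
            try:
                w = float(b @ np.linalg.solve(V, b))
                row[f"p_{k}"] = float(stats.chi2.sf(w, df=len(ix)))
            except np.linalg.LinAlgError:
                row[f"p_{k}"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    for k in term_sets:
        table[f"p_{k}_fdr"] = bh_fdr(table[f"p_{k}"].to_numpy(), q).adjusted_p
    return table


def network_progression(
    dataset: LongitudinalDataset, partition: NetworkPartition, q: float = 0.05
) -> ProgressionResult:
    """Average regional values within each network per scan, then run the
    same mixed model on the network means; FDR over the (7) networks."""
    idx = partition.indices_by_label(dataset.region_ids)
    empty = [lab for lab, ix in idx.items() if len(ix) == 0]
    if empty:
        raise ValueError(f"empty networks: {empty}")
    labels = list(idx)
    net_values = np.column_stack(
        [dataset.values[:, ix].mean(axis=1) for ix in idx.values()]
    )
    net_ds = LongitudinalDataset(dataset.meta.copy(), net_values, labels)
    return progression_maps(net_ds, q=q, posthoc_scope="all")


# ---------------------------------------------------------------------------
# partial Spearman correlations
# ---------------------------------------------------------------------------


def partial_spearman(
    score: np.ndarray,
    network_w: np.ndarray,
    covariates: np.ndarray,
    q: float = 0.05,
    network_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Partial Spearman correlation of a subject-level score with per-network
    baseline atrophy, adjusting for covariates (canonically baseline age,
    BMI and APOE4 count).

    All variables are rank-transformed, ranks are residualized on the
    covariate ranks, and Pearson correlation is taken on the residuals;
    two-sided p from the t distribution with n - 2 - k df, BH-FDR across
    networks.  Rows with any missing value are dropped pairwise-complete.
    """
    score = np.asarray(score, dtype=float)
    W = np.atleast_2d(np.asarray(network_w, dtype=float))
    if W.shape[0] == score.shape[0] and W.ndim == 2:
        pass
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != score.shape[0]:
        C = C.T
    n_networks = W.shape[1]
    if network_labels is None:
        network_labels = [f"network_{i}" for i in range(n_networks)]
    k = C.shape[1]
    rows = []
    for j in range(n_networks):
        cols = np.column_stack([score, W[:, j], C])
        ok = np.isfinite(cols).all(axis=1)
        n = int(ok.sum())
        if n < 20:
            raise ValueError(f"need >= 20 pairwise-complete subjects, got {n}")
        sub = cols[ok]
        if np.ptp(sub[:, 0]) == 0 or np.ptp(sub[:, 1]) == 0:
            raise ValueError("constant score or atrophy vector")
        ranks = np.column_stack([stats.rankdata(sub[:, i]) for i in range(sub.shape[1])])
        Z = np.column_stack([np.ones(n), ranks[:, 2:]])
        resid = ranks[:, :2] - Z @ np.linalg.lstsq(Z, ranks[:, :2], rcond=None)[0]
        r = float(np.corrcoef(resid[:, 0], resid[:, 1])[0, 1])
        df = n - 2 - k
        t = r * np.sqrt(df / max(1e-300, 1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
        rows.append({"network": network_labels[j], "rho": r, "p": p, "n": n})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy(), q).adjusted_p
    return out


# ---------------------------------------------------------------------------
# PET group comparison (baseline, one scan per subject)
# ---------------------------------------------------------------------------


def compare_pet_groups(
    pet_dataset: LongitudinalDataset,
    q: float = 0.05,
    group_a: str = "AD",
    group_b: str = "FHAD",
) -> pd.DataFrame:
    """Region-wise OLS of baseline SUVR on group plus covariates (age, sex,
    education, BMI, APOE4); reports the group coefficient t-test with BH-FDR
    over regions.  Positive t means higher binding in ``group_a``."""
    ds = pet_dataset.restrict_group(group_a, group_b).baseline()
    meta = ds.meta
    keep = meta[list(_COVARIATES) + ["age"]].notna().all(axis=1).to_numpy()
    meta = meta.loc[keep]
    Y = ds.values[keep]
    g = (meta["group"] == group_a).to_numpy(float)
    X = np.column_stack(
        [
            np.ones(len(meta)),
            g,
            meta["age"].to_numpy(float),
            (meta["sex"] == "F").to_numpy(float),
            meta["education_y"].to_numpy(float),
            meta["bmi"].to_numpy(float),
            meta["apoe4"].to_numpy(float),
        ]
    )
    n, p_cols = X.shape
    if np.linalg.matrix_rank(X) < p_cols:
        raise ValueError("rank-deficient PET design matrix")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / (n - p_cols)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = B[1] / se
    p = 2 * stats.t.sf(np.abs(t), df=n - p_cols)
    fdr = bh_fdr(p, q)
    return pd.DataFrame(
        {
            "region_id": list(ds.region_ids),
            "group_coef": B[1],
            "t": t,
            "p": p,
            "p_fdr": fdr.adjusted_p,
            "significant": fdr.reject,
        }
    )


# ---------------------------------------------------------------------------
# categorical / nonparametric tests
# ---------------------------------------------------------------------------


def chi_square_2x2(a: int, b: int, c: int, d: int) -> CategoricalTestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any() or not np.array_equal(table, np.round(table)):
        raise ValueError("cell counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be > 0")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return CategoricalTestResult(float(stat), int(df), float(p))


def scan_count_test(dataset: LongitudinalDataset) -> CategoricalTestResult:
    """Tie-corrected Kruskal-Wallis H on per-subject scan counts by group."""
    counts = dataset.scan_counts()
    samples = [
        sub["n_scans"].to_numpy() for _, sub in counts.groupby("group", sort=False)
    ]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 subjects")
    stat, p = stats.kruskal(*samples)
    return CategoricalTestResult(float(stat), len(samples) - 1, float(p))
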