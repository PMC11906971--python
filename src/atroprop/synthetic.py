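"""Synthetic cohort generator with known ground truth.

Real deformation/PET/connectivity releases for this kind of study are
access-restricted, so every pipeline stage here is exercised on simulated
data whose generating parameters are known exactly.  The generator emulates
the statistical structure the analysis assumes:

* region coordinates on two mirrored hemispheric shells (mm scale);
* a distance-dependent binary connectome (edge probability decaying
  exponentially with Euclidean distance);
* a ground-truth pathology pattern produced by degree-normalized diffusion
  from a small set of seed regions — the generative counterpart of the
  network-spread hypothesis that pathology propagates along connections;
* longitudinal regional deformation that is linear in age within subject,
  with a group-specific extra slope proportional to the pattern, subject
  random intercepts/slopes, small covariate effects, optional site shifts,
  and a spatially autocorrelated regional intercept field;
* PET-like SUVR maps coupled to the pattern with group-dependent gain;
* receptor maps partially correlated with the pattern;
* per-subject connectomes as edge-flip perturbations of the group graph.

Everything is reproducible bit-for-bit from ``rng_seed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .core_data import (
    Connectome,
    GROUPS,
    LongitudinalDataset,
    META_COLUMNS,
    NetworkPartition,
    ReceptorAtlas,
    RegionalMap,
    default_region_ids,
)

import pandas as pd

#: default receptor/transporter targets and their coupling to the pattern;
#: weights mirror typical multi-tracer meta-analytic sample sizes
DEFAULT_RECEPTOR_COUPLING: dict[str, float] = {
    "5-HT6": 0.5,
    "5-HT1B": 0.3,
    "mGluR5": 0.4,
    "D2": 0.0,
    "VAchT": 0.0,
    "H3": 0.0,
    "NET": 0.0,
}

#: targets represented by more than one synthetic tracer study (weight = n)
MULTI_TRACER_WEIGHTS: dict[str, tuple[float, ...]] = {
    "5-HT1B": (65.0, 23.0),
    "NET": (46.0, 10.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Scales mirror the design of the emulated study where stated (three
    groups, baseline ages around 72-73 y, 1-year visit spacing with up to
    four years of follow-up); deformation effect sizes have no published
    scale and are calibrated for test power, not realism.
    """

    R: int = 200
    n_per_group: int = 50
    visits: int = 4
    dropout_prob: float = 0.2
    age_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "HC": (60.0, 83.4),
            "FHAD": (66.0, 87.8),
            "AD": (55.2, 83.7),
        }
    )
    slope_base: float = 0.01
    slope_effect: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "FHAD": 0.015, "AD": 0.04}
    )
    #: explicit seed-region indices; default None draws an epicenter-like
    #: cluster (a random region plus its nearest neighbors, 10% of R total)
    pattern_seeds: Sequence[int] | None = None
    diffusion_steps: int = 8
    diffusion_decay: float = 0.9
    spatial_corr_length: float = 20.0
    noise_sd: float = 0.005
    intercept_sd: float = 0.01
    slope_sd: float = 0.001
    intercept_field_sd: float = 0.05
    sex_effect: float = 0.01
    education_effect: float = 0.001
    bmi_effect: float = 0.0005
    apoe4_effect: float = 0.005
    pet_gain: Mapping[str, float] = field(
        default_factory=lambda: {"FHAD": 0.15, "AD": 0.30}
    )
    pet_noise_sd: float = 0.05
    receptor_coupling: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RECEPTOR_COUPLING)
    )
    site_count: int = 1
    site_shift_sd: float = 0.0
    target_density: float = 0.15
    decay_mm: float = 30.0
    n_connectome_subjects: int = 20
    edge_flip_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "intercept_sd", "slope_sd", "intercept_field_sd",
                     "pet_noise_sd", "site_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if not 0.0 < self.diffusion_decay < 1.0:
            raise ValueError("diffusion_decay must lie in (0, 1)")
        for c in self.receptor_coupling.values():
            if not -1.0 <= c <= 1.0:
                raise ValueError("receptor_coupling values must lie in [-1, 1]")


@dataclass
class GroundTruth:
    """Generating parameters actually used for one simulated cohort."""

    pattern: RegionalMap
    true_beta: dict[str, np.ndarray]
    slope_base: float
    receptor_coupling: dict[str, float]
    pet_gain: dict[str, float]
    connectome: Connectome
    pattern_seed_indices: np.ndarray
    rng_seed: int


@dataclass
class SimulatedCohort:
    dataset: LongitudinalDataset
    tau_maps: dict[str, RegionalMap]
    abeta_maps: dict[str, RegionalMap]
    receptor_atlas: ReceptorAtlas
    subject_connectomes: dict[str, list[Connectome]]
    network_partition: NetworkPartition
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry / connectome / pattern
# ---------------------------------------------------------------------------


def make_geometry(
    R: int, rng_seed: int, radius: float = 65.0, jitter: float = 5.0
) -> np.ndarray:
    """R points (mm) on two mirrored hemispheric shells, left x<0, right x>0.

    For even R the hemispheres hold exactly R/2 points each; for odd R the
    right shell carries the extra point.  Deterministic given ``rng_seed``.
    """
    if R < 10:
        raise ValueError(f"need at least 10 regions, got {R}")
    rng = np.random.default_rng(rng_seed)
    n_right = R // 2 + R % 2
    dirs = rng.standard_normal((n_right, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs[:, 0] = np.abs(dirs[:, 0]) + 1e-3  # keep strictly right of midline
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = rng.uniform(radius - jitter, radius + jitter, size=n_right)
    right = dirs * radii[:, None]
    left = right[: R // 2].copy()
    left[:, 0] *= -1.0
    return np.vstack([left, right])


def make_connectome(
    coordinates: np.ndarray,
    target_density: float,
    decay_mm: float,
    rng_seed: int,
    region_ids: Sequence[str] | None = None,
    max_attempts: int = 10,
) -> Connectome:
    """Distance-dependent random binary graph.

    Edge probability is proportional to ``exp(-d / decay_mm)``, rescaled so
    the expected density matches ``target_density``; the realized graph must
    land within +/-20% of the target and keep a giant component covering at
    least 90% of regions (redrawn up to ``max_attempts`` times).
    """
    if not 0.0 < target_density <= 0.5:
        raise ValueError("target_density must lie in (0, 0.5]")
    coords = np.asarray(coordinates, dtype=float)
    R = len(coords)
    if region_ids is None:
        region_ids = default_region_ids(R)
    D = squareform(pdist(coords))
    kernel = np.exp(-D / decay_mm)
    iu = np.triu_indices(R, k=1)
    scale = target_density / kernel[iu].mean()
    P = np.clip(scale * kernel, 0.0, 1.0)
    achievable = P[iu].mean()
    if achievable < 0.8 * target_density:
        raise ValueError(
            f"target density {target_density} infeasible with decay_mm="
            f"{decay_mm} (achievable ~{achievable:.3f}); increase decay_mm "
            "or lower target_density"
        )
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_attempts):
        A = np.zeros((R, R), dtype=np.int8)
        A[iu] = rng.random(len(iu[0])) < P[iu]
        A = A + A.T
        realized = A[iu].sum() / len(iu[0])
        if not (0.8 * target_density <= realized <= 1.2 * target_density):
            continue
        n_comp, labels = connected_components(A, directed=False)
        giant = np.bincount(labels).max()
        if giant >= 0.9 * R:
            return Connectome(region_ids, A, coords)
    raise ValueError(
        "could not realize a graph meeting density/connectedness constraints; "
        "try a larger decay_mm or target_density"
    )


def make_pattern(
    connectome: Connectome,
    pattern_seeds: Sequence[int],
    steps: int,
    decay: float,
    normalize: bool = True,
) -> RegionalMap:
    """Ground-truth pathology pattern by degree-normalized network diffusion.

    pattern = sum_{k=0..steps} decay^k (D^-1 A)^k s with one-hot seeds s,
    then rescaled to unit maximum (so ``slope_effect`` is the full extra
    slope at the most affected region).  Degree normalization keeps values
    bounded and hub-independent.
    """
    A = connectome.adjacency.astype(float)
    R = connectome.n_regions
    seeds = np.asarray(pattern_seeds, dtype=int)
    if seeds.size == 0:
        raise ValueError("need at least one pattern seed")
    if seeds.min() < 0 or seeds.max() >= R:
        raise ValueError(f"seed indices out of range for R={R}")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    deg = A.sum(axis=1)
    if steps > 0 and np.any(deg[seeds] == 0):
        warnings.warn(
            f"isolated seed region(s) {seeds[deg[seeds] == 0].tolist()}: "
            "diffusion leaves them in place",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    T = A * inv_deg[:, None]  # row-normalized: (D^-1 A)
    s = np.zeros(R)
    s[seeds] = 1.0
    acc = s.copy()
    v = s.copy()
    w = 1.0
    for _ in range(steps):
        v = T @ v
        w *= decay
        acc = acc + w * v
    if normalize:
        acc = acc / acc.max()
    return RegionalMap(list(connectome.region_ids), acc, "pattern")


# ---------------------------------------------------------------------------
# spatially autocorrelated fields
# ---------------------------------------------------------------------------


def smooth_field(
    D: np.ndarray,
    corr_length: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field(s) with covariance exp(-d/lambda).

    Returns shape (size, R); Cholesky factorization with a tiny jitter on the
    diagonal for numerical positive-definiteness.
    """
    R = D.shape[0]
    cov = np.exp(-D / corr_length) + 1e-8 * np.eye(R)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((size, R))
    return z @ L.T


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

_APOE4_PROBS = {
    # P(0, 1, 2 alleles); marginals follow the emulated cohort descriptives
    "HC": (0.741, 0.25, 0.009),
    "FHAD": (0.644, 0.27, 0.086),
    "AD": (0.30, 0.49, 0.21),
}


def _perturb_connectome(
    base: Connectome, flip_rate: float, rng: np.random.Generator, subject_id: str
) -> Connectome:
    """Subject-level graph: each edge dropped w.p. flip_rate, matched by an
    equal expected number of spurious edges so density stays calibrated."""
    A = base.adjacency.copy()
    R = base.n_regions
    iu = np.triu_indices(R, k=1)
    upper = A[iu].astype(bool)
    drop = upper & (rng.random(upper.size) < flip_rate)
    n_edges = upper.sum()
    n_non = (~upper).sum()
    add_rate = flip_rate * n_edges / max(n_non, 1)
    add = ~upper & (rng.random(upper.size) < add_rate)
    new_upper = (upper & ~drop) | add
    B = np.zeros((R, R), dtype=np.int8)
    B[iu] = new_upper
    B = B + B.T
    return Connectome(list(base.region_ids), B, base.coordinates, subject_id=subject_id)


#: labels emulating the canonical 7 resting-state networks
NETWORK_LABELS = (
    "visual", "somatomotor", "dorsal_attention", "ventral_attention",
    "limbic", "frontoparietal", "default_mode",
)


def make_partition(
    coordinates: np.ndarray,
    region_ids: Sequence[str],
    rng_seed: int,
    labels: Sequence[str] = NETWORK_LABELS,
) -> NetworkPartition:
    """Spatially coherent partition of the regions into len(labels) networks,
    mirrored across hemispheres (k-means on |x|,y,z coordinates)."""
    from scipy.cluster.vq import kmeans2

    coords = np.asarray(coordinates, dtype=float).copy()
    coords[:, 0] = np.abs(coords[:, 0])  # homologous regions share a network
    # mirrored regions duplicate feature rows; cluster the unique rows and
    # propagate labels so the '++' init never sees zero total distance
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    _, uniq_assign = kmeans2(uniq, min(len(labels), len(uniq)), minit="++",
                             seed=np.random.default_rng(rng_seed))
    assign = uniq_assign[inverse]
    # guard against empty clusters: reassign from the largest
    for k in range(len(labels)):
        if not (assign == k).any():
            donor = np.argmax(np.bincount(assign, minlength=len(labels)))
            assign[np.flatnonzero(assign == donor)[0]] = k
    return NetworkPartition(
        {str(r): labels[k] for r, k in zip(region_ids, assign)}
    )


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort: longitudinal deformation data,
    PET-like maps, a receptor atlas, subject connectomes and ground truth."""
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(cfg.rng_seed)
    (s_geo, s_conn, s_seeds, s_field, s_cohort, s_pet,
     s_recept, s_subj, s_part) = [np.random.default_rng(c) for c in ss.spawn(9)]

    coords = make_geometry(cfg.R, s_geo.integers(2**31))
    conn = make_connectome(
        coords, cfg.target_density, cfg.decay_mm, s_conn.integers(2**31)
    )
    region_ids = list(conn.region_ids)
    D = squareform(pdist(coords))

    if cfg.pattern_seeds is None:
        # epicenter-like nucleation: a random connected region and its
        # nearest connected neighbors, so pathology starts focally and can
        # actually diffuse
        n_seeds = max(1, int(round(0.1 * cfg.R)))
        connected = np.flatnonzero(conn.degree > 0)
        center = int(s_seeds.choice(connected))
        order = connected[np.argsort(D[center, connected])]
        seed_idx = np.sort(order[:n_seeds])
    else:
        seed_idx = np.asarray(cfg.pattern_seeds, dtype=int)
    pattern_map = make_pattern(conn, seed_idx, cfg.diffusion_steps, cfg.diffusion_decay)
    pattern = pattern_map.values

    intercept_field = cfg.intercept_field_sd * smooth_field(
        D, cfg.spatial_corr_length, s_field
    )[0]

    # --- longitudinal deformation records --------------------------------
    rows: list[dict] = []
    value_rows: list[np.ndarray] = []
    site_shifts = cfg.site_shift_sd * s_cohort.standard_normal(max(cfg.site_count, 1))
    for group in GROUPS:
        lo, hi = cfg.age_range[group]
        slope_g = cfg.slope_effect.get(group, 0.0)
        p0, p1, p2 = _APOE4_PROBS[group]
        for j in range(cfg.n_per_group):
            sid = f"{group}{j:03d}"
            # baseline drawn so all follow-ups stay inside the configured range
            a0 = s_cohort.uniform(lo, hi - (cfg.visits - 1))
            sex = "F" if s_cohort.random() < 0.5 else "M"
            edu = float(np.clip(s_cohort.normal(16.0, 2.5), 8.0, 20.0))
            bmi = float(np.clip(s_cohort.normal(26.5, 4.0), 17.0, 45.0))
            apoe4 = int(s_cohort.choice(3, p=(p0, p1, p2)))
            site = int(s_cohort.integers(cfg.site_count)) if cfg.site_count > 1 else 0
            u_j = s_cohort.normal(0.0, cfg.intercept_sd) if cfg.intercept_sd else 0.0
            v_j = s_cohort.normal(0.0, cfg.slope_sd) if cfg.slope_sd else 0.0
            slope_j = cfg.slope_base + slope_g * pattern + v_j
            covar = (
                cfg.sex_effect * (sex == "F")
                + cfg.education_effect * edu
                + cfg.bmi_effect * bmi
                + cfg.apoe4_effect * apoe4
                + site_shifts[site]
            )
            n_visits = 1
            while n_visits < cfg.visits and s_cohort.random() >= cfg.dropout_prob:
                n_visits += 1
            for t in range(n_visits):
                age = a0 + t
                eps = (
                    cfg.noise_sd * s_cohort.standard_normal(cfg.R)
                    if cfg.noise_sd
                    else np.zeros(cfg.R)
                )
                y = intercept_field + u_j + slope_j * age + covar + eps
                rows.append(
                    dict(
                        subject_id=sid,
                        group=group,
                        age=age,
                        sex=sex,
                        education_y=edu,
                        bmi=bmi,
                        apoe4=apoe4,
                        site=site,
                        visit=t,
                    )
                )
                value_rows.append(y)
    dataset = LongitudinalDataset(
        pd.DataFrame(rows, columns=META_COLUMNS), np.vstack(value_rows), region_ids
    )

    # --- PET-like maps ----------------------------------------------------
    tau_maps: dict[str, RegionalMap] = {}
    abeta_maps: dict[str, RegionalMap] = {}
    for group in ("FHAD", "AD"):
        gain = cfg.pet_gain.get(group, 0.0)
        for store, label in ((tau_maps, "suvr_tau"), (abeta_maps, "suvr_abeta")):
            noise = cfg.pet_noise_sd * smooth_field(D, cfg.spatial_corr_length, s_pet)[0]
            store[group] = RegionalMap(
                region_ids, 1.0 + gain * pattern + noise, label
            )

    # --- receptor atlas ---------------------------------------------------
    pattern_z = _zscore(pattern)
    entries: dict[str, list[tuple[RegionalMap, float]]] = {}
    for target, coupling in cfg.receptor_coupling.items():
        base = coupling * pattern_z + math.sqrt(
            max(0.0, 1.0 - coupling**2)
        ) * smooth_field(D, cfg.spatial_corr_length, s_recept)[0]
        weights = MULTI_TRACER_WEIGHTS.get(target, (30.0,))
        tracer_maps = []
        for w in weights:
            tracer = base if len(weights) == 1 else base + 0.2 * s_recept.standard_normal(cfg.R)
            tracer_maps.append(
                (RegionalMap(region_ids, _zscore(tracer), "receptor_z"), w)
            )
        entries[target] = tracer_maps
    atlas = ReceptorAtlas(entries)

    # --- subject-level connectomes ---------------------------------------
    subject_connectomes = {
        group: [
            _perturb_connectome(
                conn, cfg.edge_flip_rate, s_subj, f"{group}-conn{j:03d}"
            )
            for j in range(cfg.n_connectome_subjects)
        ]
        for group in ("FHAD", "AD")
    }

    partition = make_partition(coords, region_ids, int(s_part.integers(2**31)))

    truth = GroundTruth(
        pattern=pattern_map,
        true_beta={g: cfg.slope_effect.get(g, 0.0) * pattern for g in GROUPS},
        slope_base=cfg.slope_base,
        receptor_coupling=dict(cfg.receptor_coupling),
        pet_gain=dict(cfg.pet_gain),
        connectome=conn,
        pattern_seed_indices=seed_idx,
        rng_seed=cfg.rng_seed,
    )
    return SimulatedCohort(
        dataset=dataset,
        tau_maps=tau_maps,
        abeta_maps=abeta_maps,
        receptor_atlas=atlas,
        subject_connectomes=subject_connectomes,
        network_partition=partition,
        ground_truth=truth,
    )
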