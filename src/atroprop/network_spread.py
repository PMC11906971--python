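"""Neighbor-spread statistics on structural connectomes.

If pathology spreads along axonal connections, a region's atrophy (or its
progression, or its tracer binding) should correlate with the mean value of
its structurally connected neighbors — and, as a specificity contrast,
*anti*-correlate with the mean over the regions it is *not* connected to.
Both correlations are tested against variogram-matched surrogate maps: each
surrogate is pushed through the same neighbor-averaging operator before
correlating, so the null preserves the joint spatial structure being tested.

Regions with no connected neighbor are excluded listwise from both the
connected and the non-connected correlation, keeping the two contrasts on
identical samples.

Also here: group-consensus connectome construction from subject-level
binary matrices (edge retained when present in a configurable fraction of
subjects, with an optional distance-binned variant that preserves the
subject-mean edge-length distribution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import Connectome, RegionalMap, check_same_regions
from .spatial_nulls import (
    SurrogateParams,
    SpinTestResult,
    _rowwise_pearson,
    _summarize_null,
    distance_matrix,
    generate_surrogates,
)


def consensus_connectome(
    subject_connectomes: Sequence[Connectome],
    retain_fraction: float = 0.5,
    distance_binned: bool = False,
    n_bins: int = 10,
) -> Connectome:
    """Group-consensus binary connectome.

    Default rule: an edge is retained iff it is present in at least
    ``retain_fraction`` of subjects.  The distance-binned variant instead
    retains, within each edge-length bin, the most consistently observed
    edges up to the subject-mean edge count for that bin, preserving the
    mean edge-length distribution.
    """
    if len(subject_connectomes) < 2:
        raise ValueError("need at least 2 subject connectomes")
    if not 0.0 < retain_fraction <= 1.0:
        raise ValueError("retain_fraction must lie in (0, 1]")
    ref = subject_connectomes[0]
    for c in subject_connectomes[1:]:
        check_same_regions(ref.region_ids, c.region_ids, "subject connectomes")
    stack = np.stack([c.adjacency for c in subject_connectomes])
    freq = stack.mean(axis=0)
    R = ref.n_regions
    if not distance_binned:
        A = (freq >= retain_fraction).astype(np.int8)
        np.fill_diagonal(A, 0)
        return Connectome(list(ref.region_ids), A, ref.coordinates)
    D = distance_matrix(ref.coordinates)
    iu = np.triu_indices(R, k=1)
    d = D[iu]
    f = freq[iu]
    mean_edges_per_subject = stack[:, iu[0], iu[1]].sum(axis=1).mean()
    edges_lengths = np.concatenate(
        [d[stack[s, iu[0], iu[1]] > 0] for s in range(len(subject_connectomes))]
    )
    bins = np.quantile(edges_lengths, np.linspace(0, 1, n_bins + 1))
    bins[0], bins[-1] = 0.0, d.max() + 1.0
    keep = np.zeros(len(d), dtype=bool)
    for b in range(n_bins):
        in_bin = (d >= bins[b]) & (d < bins[b + 1])
        n_lengths = ((edges_lengths >= bins[b]) & (edges_lengths < bins[b + 1])).sum()
        quota = int(round(n_lengths / len(subject_connectomes)))
        if quota == 0 or not in_bin.any():
            continue
        order = np.argsort(-f[in_bin])
        chosen = np.flatnonzero(in_bin)[order[:quota]]
        keep[chosen[f[chosen] > 0]] = True
    A = np.zeros((R, R), dtype=np.int8)
    A[iu] = keep
    A = A + A.T
    return Connectome(list(ref.region_ids), A, ref.coordinates)


def _neighbor_means_matrix(
    V: np.ndarray, A: np.ndarray, mode: str
) -> np.ndarray:
    """Neighbor means for rows of V (m, R) under adjacency A; NaN-aware.

    connected:    mean of v over {j != i : A_ij = 1}
    nonconnected: mean of v over {j != i : A_ij = 0}
    Regions whose neighbor set is empty (or all-missing) come out NaN.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    finite = np.isfinite(V)
    Vz = np.where(finite, V, 0.0)
    Af = A.astype(float)
    if mode == "connected":
        sums = Vz @ Af.T
        counts = finite.astype(float) @ Af.T
    elif mode == "nonconnected":
        total = Vz.sum(axis=1, keepdims=True)
        ntot = finite.sum(axis=1, keepdims=True)
        sums = total - Vz - Vz @ Af.T
        counts = ntot - finite - finite.astype(float) @ Af.T
    else:
        raise ValueError("mode must be 'connected' or 'nonconnected'")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts <= 0] = np.nan
    return out


def neighbor_mean(
    regional_map: RegionalMap,
    connectome: Connectome,
    mode: str = "connected",
    edge_weights: np.ndarray | None = None,
) -> RegionalMap:
    """Per-region mean of the map over (non-)connected neighbors.

    Regions with an empty neighbor set get NaN; missing input values simply
    drop out of the averages.  ``edge_weights`` (an R x R nonnegative
    symmetric matrix, e.g. streamline counts) switches the connected mode to
    a weighted average over the same binary neighbor sets; the default — and
    the convention used throughout the analyses — is the unweighted mean
    over the binary adjacency.
    """
    check_same_regions(
        regional_map.region_ids, connectome.region_ids, "map vs connectome"
    )
    A = connectome.adjacency
    if edge_weights is None:
        nm = _neighbor_means_matrix(regional_map.values[None, :], A, mode)[0]
    else:
        W = np.asarray(edge_weights, dtype=float)
        if W.shape != A.shape or (W < 0).any() or not np.allclose(W, W.T):
            raise ValueError("edge_weights must be a nonnegative symmetric R x R matrix")
        if mode != "connected":
            raise ValueError("edge_weights apply to the connected mode only")
        W = W * A  # weights only act on existing edges
        v = regional_map.values
        finite = np.isfinite(v)
        num = W @ np.where(finite, v, 0.0)
        den = W @ finite.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            nm = num / den
        nm[den <= 0] = np.nan
    return regional_map.with_values(nm, f"{regional_map.measure_label}_nbr")


@dataclass
class SpreadResult:
    connected: SpinTestResult
    nonconnected: SpinTestResult
    connected_neighbor_means: RegionalMap
    nonconnected_neighbor_means: RegionalMap
    excluded_regions: list[str]
    map_label: str
    connectome_id: str | None


def spread_test(
    regional_map: RegionalMap,
    connectome: Connectome,
    D: np.ndarray | None = None,
    n_surr: int = 1000,
    rng_seed: int = 0,
    params: SurrogateParams | None = None,
) -> SpreadResult:
    """Neighbor-spread test of one map on one connectome.

    Pearson r between the map and its connected-neighbor means, and between
    the map and its non-connected means, each against a surrogate null in
    which the *map* is replaced by a variogram-matched surrogate and the
    neighbor means are recomputed from the surrogate (the neighbor operator
    is part of the statistic, so it is applied inside the null too).
    """
    check_same_regions(
        regional_map.region_ids, connectome.region_ids, "map vs connectome"
    )
    if D is None:
        D = distance_matrix(connectome.coordinates)
    A = connectome.adjacency
    x = regional_map.values
    deg = A.sum(axis=1)
    retained = (deg > 0) & np.isfinite(x)
    excluded = [
        str(r) for r, ok in zip(regional_map.region_ids, retained) if not ok
    ]
    if retained.sum() < 20:
        raise ValueError(
            f"need >= 20 regions with connected neighbors, got {int(retained.sum())}"
        )
    nm_con = _neighbor_means_matrix(x[None, :], A, "connected")[0]
    nm_non = _neighbor_means_matrix(x[None, :], A, "nonconnected")[0]
    # identical samples for both contrasts
    ok = retained & np.isfinite(nm_con) & np.isfinite(nm_non)
    for nm, what in ((nm_con, "connected"), (nm_non, "non-connected")):
        if np.ptp(nm[ok]) == 0:
            raise ValueError(f"constant {what} neighbor-mean vector")
    xs = x[ok]
    Ds = D[np.ix_(ok, ok)]
    ensemble = generate_surrogates(xs, Ds, n_surr, rng_seed, params)
    # embed surrogates back into the full region set so neighbor means see
    # the observed values of excluded regions
    S_full = np.tile(x, (ensemble.n_surrogates, 1))
    S_full[:, ok] = ensemble.surrogates
    results = {}
    for mode, nm in (("connected", nm_con), ("nonconnected", nm_non)):
        r_emp = float(np.corrcoef(xs, nm[ok])[0, 1])
        NM = _neighbor_means_matrix(S_full, A, mode)[:, ok]
        # rowwise correlation surrogate vs its own neighbor means
        Sc = ensemble.surrogates - ensemble.surrogates.mean(axis=1, keepdims=True)
        Nc = NM - NM.mean(axis=1, keepdims=True)
        denom = np.sqrt((Sc**2).sum(axis=1) * (Nc**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            null_r = (Sc * Nc).sum(axis=1) / np.maximum(denom, 1e-300)
        results[mode] = _summarize_null(
            r_emp, null_r, ensemble.n_surrogates, rng_seed, "pearson"
        )
    ids = list(regional_map.region_ids)
    return SpreadResult(
        connected=results["connected"],
        nonconnected=results["nonconnected"],
        connected_neighbor_means=RegionalMap(ids, nm_con, "nbr_connected"),
        nonconnected_neighbor_means=RegionalMap(ids, nm_non, "nbr_nonconnected"),
        excluded_regions=excluded,
        map_label=regional_map.measure_label,
        connectome_id=connectome.subject_id,
    )


def spread_tests(
    maps: Mapping[str, RegionalMap],
    connectomes: Mapping[str, Connectome],
    n_surr: int = 1000,
    rng_seed: int = 0,
    params: SurrogateParams | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Neighbor-spread tests for every map x connectome combination, with
    BH-FDR over the family of connected (and, separately, non-connected)
    spin p-values."""
    from .progression import bh_fdr

    ss = np.random.SeedSequence(rng_seed)
    seeds = iter(ss.spawn(len(maps) * len(connectomes)))
    rows = []
    for m_name, m in maps.items():
        for c_name, conn in connectomes.items():
            seed = int(next(seeds).generate_state(1)[0] % (2**31))
            res = spread_test(m, conn, n_surr=n_surr, rng_seed=seed, params=params)
            rows.append(
                {
                    "map": m_name,
                    "connectome": c_name,
                    "r_connected": res.connected.r_emp,
                    "p_spin_connected": res.connected.p_spin,
                    "r_nonconnected": res.nonconnected.r_emp,
                    "p_spin_nonconnected": res.nonconnected.p_spin,
                    "n_excluded": len(res.excluded_regions),
                }
            )
    table = pd.DataFrame(rows)
    for side in ("connected", "nonconnected"):
        fdr = bh_fdr(table[f"p_spin_{side}"].to_numpy(), q)
        table[f"p_spin_{side}_fdr"] = fdr.adjusted_p
    return table
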