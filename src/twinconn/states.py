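"""Network-level dynamic brain states.

Windowed ROI connectivity matrices are averaged into Yeo-7 network blocks,
the unique network-matrix entries (7 within-network diagonals plus 21
between-network values) are z-scored over the pooled windows of all
subjects, and k-means (k = 2) partitions the windows into two recurring
connectivity states.  States are characterized per subject by occupancy
(fraction of windows), mean dwell time (consecutive windows), transition
count, and within/between-network connectivity; State 1 is by convention
the state with the lower group-mean occupancy (the transient state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .connectivity import ConnMatrix, WindowedConnStack
from .genetics import fit_variance_components, heritability_percent, twin_iccs
from .io import NetworkMap, TwinManifest


class StateError(ValueError):
    pass


@dataclass
class NetworkMatrix:
    """n_networks x n_networks matrix of network-averaged correlations.

    Diagonal entries are within-network means (NaN when a network has a
    single ROI), not forced to 1.
    """

    values: np.ndarray
    networks: Sequence[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or len(self.networks) != v.shape[0]:
            raise StateError("network matrix shape/label mismatch")
        self.values = (v + v.T) / 2.0
        self.networks = list(self.networks)


def network_average(conn: ConnMatrix, nmap: Mapping[str, str]) -> NetworkMatrix:
    """Average a ROI connectivity matrix within network blocks.

    Entry (m, n) is the mean of conn(i, j) over ROI pairs with i in m and
    j in n, excluding the self-pairs i == j on the diagonal blocks.  Every
    ROI must be mapped; a network with fewer than 2 ROIs has an undefined
    (NaN) within-network mean.
    """
    nmap = NetworkMap(nmap)
    labels = list(conn.roi_labels)
    missing = [l for l in labels if l not in nmap]
    if missing:
        raise StateError(f"ROI(s) not in network map: {missing}")
    networks = sorted({nmap[l] for l in labels})
    members = {n: [i for i, l in enumerate(labels) if nmap[l] == n]
               for n in networks}
    k = len(networks)
    out = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a, k):
            ia, ib = members[networks[a]], members[networks[b]]
            if a == b:
                if len(ia) >= 2:
                    sub = conn.values[np.ix_(ia, ia)]
                    iu = np.triu_indices(len(ia), k=1)
                    out[a, a] = sub[iu].mean()
            else:
                out[a, b] = out[b, a] = conn.values[np.ix_(ia, ib)].mean()
    return NetworkMatrix(out, networks)


def _feature_vector(nm: NetworkMatrix) -> np.ndarray:
    """Within-network diagonal followed by upper off-diagonal entries."""
    k = len(nm.networks)
    iu = np.triu_indices(k, k=1)
    return np.concatenate([np.diag(nm.values), nm.values[iu]])


def feature_names(networks: Sequence[str]) -> list[str]:
    names = [f"within:{n}" for n in networks]
    names += [f"between:{a}|{b}" for i, a in enumerate(networks)
              for b in list(networks)[i + 1:]]
    return names


def state_features(stacks: Mapping[str, WindowedConnStack],
                   nmap: Mapping[str, str],
                   ) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Pooled, z-scored window features for clustering.

    For every subject's windows, the network-averaged matrix is reduced to a
    vector of k within-network and k(k-1)/2 between-network values (28 for
    the full Yeo-7 set).  Features undefined for every window (networks with
    a single ROI) are dropped; each remaining feature is z-scored over the
    pooled (all subjects x all windows) sample.

    Returns ``(features, window_subjects, networks, kept_feature_names)``
    where ``window_subjects[i]`` is the subject owning pooled window i.
    """
    rows: list[np.ndarray] = []
    owners: list[str] = []
    networks: list[str] | None = None
    for subject, stack in stacks.items():
        for m in stack.matrices:
            nm = network_average(m, nmap)
            if networks is None:
                networks = list(nm.networks)
            elif list(nm.networks) != networks:
                raise StateError("subjects disagree on network set")
            rows.append(_feature_vector(nm))
            owners.append(subject)
    if len(rows) < 2:
        raise StateError("need at least 2 pooled windows")
    feats = np.vstack(rows)
    names = feature_names(networks)
    keep = ~np.all(np.isnan(feats), axis=0)
    feats, names = feats[:, keep], [n for n, k in zip(names, keep) if k]
    if np.isnan(feats).any():
        raise StateError("feature matrix contains partial missing values")
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [n for n, s in zip(names, sd) if s == 0]
        raise StateError(f"constant feature(s) across pooled windows: {bad}")
    return (feats - mu) / sd, owners, networks, names


def cluster_states(features: np.ndarray, k: int = 2, seed: int = 0,
                   n_init: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """k-means over pooled window features (k-means++, best of n_init).

    Returns raw ``(labels, centroids)``; relabeling to the occupancy
    convention happens in :func:`decompose_states`.
    """
    if features.shape[0] < k:
        raise StateError(f"cannot form {k} clusters from {features.shape[0]} windows")
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                random_state=seed)
    labels = km.fit_predict(features)
    return labels, km.cluster_centers_


def occupancy_dwell(labels: Sequence[int], n_states: int = 2,
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """Occupancy, mean dwell and transition count of one label sequence.

    Occupancy is the fraction of windows in each state; dwell is the mean
    length of maximal consecutive runs of the state, in windows (NaN for a
    never-visited state); the transition count is the number of label
    changes between consecutive windows.
    """
    labels = np.asarray(list(labels), dtype=int)
    if labels.size == 0:
        raise StateError("empty label sequence")
    occ = np.array([(labels == s).mean() for s in range(n_states)])
    runs: dict[int, list[int]] = {s: [] for s in range(n_states)}
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs[labels[start]].append(i - start)
            start = i
    dwell = np.array([float(np.mean(runs[s])) if runs[s] else np.nan
                      for s in range(n_states)])
    transitions = int(np.sum(labels[1:] != labels[:-1]))
    return occ, dwell, transitions


@dataclass
class StateDecomposition:
    """Pooled two-state decomposition with per-subject temporal metrics.

    States are numbered 1..k with State 1 the lowest group-mean occupancy
    (the transient state).  ``metrics`` holds one row per subject with
    occupancy/dwell per state and the transition count; ``state_matrices``
    maps subject -> state -> within/between NetworkMatrix averaged over the
    subject's windows in that state (absent when never visited).
    """

    labels: dict[str, np.ndarray]
    centroids: np.ndarray
    networks: list[str]
    metrics: pd.DataFrame
    state_matrices: dict[str, dict[int, NetworkMatrix]] = field(default_factory=dict)

    @property
    def group_occupancy(self) -> np.ndarray:
        cols = [c for c in self.metrics.columns if c.startswith("occupancy_state")]
        return self.metrics[cols].mean(axis=0).to_numpy()


def decompose_states(stacks: Mapping[str, WindowedConnStack],
                     nmap: Mapping[str, str], k: int = 2, seed: int = 0,
                     n_init: int = 20) -> StateDecomposition:
    """Full state analysis: features, clustering, relabeling, metrics.

    One k-means model is fit across the pooled windows of all subjects.
    Cluster ids are relabeled by ascending group-mean occupancy, so State 1
    is the transient state regardless of the k-means seed; the relabeling is
    idempotent and seed-independent for identical partitions (ties break by
    ascending raw cluster id).
    """
    feats, owners, networks, _ = state_features(stacks, nmap)
    raw_labels, centroids = cluster_states(feats, k=k, seed=seed, n_init=n_init)
    # group occupancy of each raw cluster over pooled windows
    occ = np.array([(raw_labels == c).mean() for c in range(k)])
    order = np.argsort(occ, kind="stable")  # ascending: transient first
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    owners_arr = np.asarray(owners)
    labels: dict[str, np.ndarray] = {}
    rows = []
    state_matrices: dict[str, dict[int, NetworkMatrix]] = {}
    for subject, stack in stacks.items():
        lab = remap[raw_labels[owners_arr == subject]]
        labels[subject] = lab
        occ_s, dwell_s, transitions = occupancy_dwell(lab - 1, n_states=k)
        row: dict[str, float] = {"subject": subject, "transitions": transitions}
        for s in range(k):
            row[f"occupancy_state{s + 1}"] = occ_s[s]
            row[f"dwell_state{s + 1}"] = dwell_s[s]
        rows.append(row)
        per_state: dict[int, NetworkMatrix] = {}
        arrs = stack.as_array()
        for s in range(1, k + 1):
            mask = lab == s
            if mask.any():
                mean_conn = ConnMatrix(
                    np.clip(arrs[mask].mean(axis=0), -1, 1), stack.roi_labels)
                per_state[s] = network_average(mean_conn, nmap)
        state_matrices[subject] = per_state
    metrics = pd.DataFrame(rows).set_index("subject")
    return StateDecomposition(labels, centroids[order], networks, metrics,
                              state_matrices)


def within_between_connectivity(nm: NetworkMatrix) -> tuple[pd.Series, float, float]:
    """(per-network within values, within mean, between mean) of one matrix."""
    k = len(nm.networks)
    within = pd.Series(np.diag(nm.values), index=list(nm.networks))
    iu = np.triu_indices(k, k=1)
    between = float(np.nanmean(nm.values[iu]))
    return within, float(np.nanmean(within.to_numpy())), between


def compare_states(decomp: StateDecomposition) -> pd.DataFrame:
    """Paired t-tests of State 1 vs State 2 connectivity across subjects.

    One row per network (within-network connectivity) plus a ``between``
    row (mean between-network connectivity).  Subjects missing a state are
    excluded from that contrast.  Zero-variance differences are reported as
    degenerate: t is NaN and the row is flagged.
    """
    rows = []
    metrics: dict[str, list[tuple[float, float]]] = {
        n: [] for n in decomp.networks}
    metrics["between"] = []
    for subject, per_state in decomp.state_matrices.items():
        if 1 not in per_state or 2 not in per_state:
            continue
        for name in decomp.networks:
            i = decomp.networks.index(name)
            v1 = per_state[1].values[i, i]
            v2 = per_state[2].values[i, i]
            if np.isfinite(v1) and np.isfinite(v2):
                metrics[name].append((v1, v2))
        _, _, b1 = within_between_connectivity(per_state[1])
        _, _, b2 = within_between_connectivity(per_state[2])
        metrics["between"].append((b1, b2))
    for name, vals in metrics.items():
        if len(vals) < 2:
            raise StateError(
                f"fewer than 2 subjects with both states for {name!r}")
        arr = np.asarray(vals)
        diff = arr[:, 0] - arr[:, 1]
        degenerate = bool(np.allclose(diff.std(ddof=1), 0.0))
        if degenerate and not np.allclose(diff, 0.0):
            t, p = np.nan, 0.0  # identical nonzero differences
        elif degenerate:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(arr[:, 0], arr[:, 1])
        n = len(vals)
        rows.append({
            "metric": name, "t": float(t), "p": float(p), "n": n,
            "mean_state1": arr[:, 0].mean(),
            "sem_state1": arr[:, 0].std(ddof=1) / np.sqrt(n),
            "mean_state2": arr[:, 1].mean(),
            "sem_state2": arr[:, 1].std(ddof=1) / np.sqrt(n),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def state_metric_heritability(metrics: pd.DataFrame, manifest: TwinManifest,
                              on_insufficient: str = "error") -> pd.DataFrame:
    """Twin analysis of state temporal metrics (occupancy, dwell, transitions).

    Per metric: intraclass correlations by zygosity, AE heritability, and the
    positive-genetic-pattern flag rMZ > rDZ.  Requires metrics for both twins
    of at least 4 pairs per zygosity; a metric with fewer complete pairs (a
    never-visited state leaves dwell missing) errors, or with
    ``on_insufficient="skip"`` is reported as a missing-value row.
    """
    if manifest.n_mz < 4 or manifest.n_dz < 4:
        raise StateError("need >= 4 pairs per zygosity")
    rows = []
    for metric in metrics.columns:
        recs = []
        for p in manifest.pairs:
            if p.subject1 not in metrics.index or p.subject2 not in metrics.index:
                raise StateError(f"metrics missing subject of pair {p.pair_id}")
            v1 = metrics.loc[p.subject1, metric]
            v2 = metrics.loc[p.subject2, metric]
            if not (np.isfinite(v1) and np.isfinite(v2)):
                continue
            recs.append((p.zygosity, float(v1), float(v2)))
        pairs = pd.DataFrame(recs, columns=["zygosity", "value1", "value2"])
        if (pairs["zygosity"] == "MZ").sum() < 4 or (pairs["zygosity"] == "DZ").sum() < 4:
            if on_insufficient == "skip":
                rows.append({
                    "metric": metric, "r_mz": np.nan, "r_dz": np.nan,
                    "heritability_percent": np.nan,
                    "positive_genetic_pattern": False,
                })
                continue
            raise StateError(f"insufficient complete pairs for metric {metric!r}")
        r_mz, r_dz = twin_iccs(pairs)
        fit = fit_variance_components(pairs, "AE")
        rows.append({
            "metric": metric, "r_mz": r_mz, "r_dz": r_dz,
            "heritability_percent": heritability_percent(fit),
            "positive_genetic_pattern": bool(r_mz > r_dz),
        })
    return pd.DataFrame(rows)
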