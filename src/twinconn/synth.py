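"""Synthetic twin cohorts with known ground truth.

Two levels of generation back the test suite and the acceptance checks:

* **Phenotype level** — direct ACE (or ADE) draws per twin pair, for exact
  parameter-recovery experiments.  Additive factors are bivariate standard
  normal, correlated 1.0 within MZ pairs and 0.5 within DZ pairs (dominance:
  1.0 / 0.25); one shared environment draw per pair; independent unique
  environment per twin.  The phenotype is sqrt(a2)*A + sqrt(c2)*C +
  sqrt(e2)*E, so its marginal variance is 1 in expectation.

* **Time-series level** — block-design two-condition BOLD with frame-level
  Markov switching between covariance regimes and, optionally, heritable
  condition-dependent correlation increments on named target edges.  This is
  an artifact construct for end-to-end testing, not a biophysical model:
  there is no hemodynamic convolution and the noise is white within a regime.

One global seed is split into per-purpose substreams (phenotypes, states,
noise) via :class:`numpy.random.SeedSequence`, so components are
independently reproducible and all outputs are byte-identical across runs
with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (Block, RoiTimeSeries, TaskDesign, TwinManifest, TwinPair)

DEFAULT_N_MZ = 134
DEFAULT_N_DZ = 78
DEFAULT_TR = 0.72


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class AceSpec:
    """Variance fractions of the ACE decomposition (must sum to 1)."""

    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        if min(self.a2, self.c2, self.e2) < 0:
            raise SynthError("variance fractions must be non-negative")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-9:
            raise SynthError("a2 + c2 + e2 must equal 1")

    #: correlation of the familial factor within (MZ, DZ) pairs
    familial_corr = (1.0, 0.5)


@dataclass(frozen=True)
class AdeSpec:
    """Variance fractions of the ADE decomposition (dominance instead of C)."""

    a2: float
    d2: float
    e2: float

    def __post_init__(self) -> None:
        if min(self.a2, self.d2, self.e2) < 0:
            raise SynthError("variance fractions must be non-negative")
        if abs(self.a2 + self.d2 + self.e2 - 1.0) > 1e-9:
            raise SynthError("a2 + d2 + e2 must equal 1")


@dataclass(frozen=True)
class CohortShape:
    n_mz: int = DEFAULT_N_MZ
    n_dz: int = DEFAULT_N_DZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0 or self.n_mz + self.n_dz < 1:
            raise SynthError("cohort needs at least one pair")


def _correlated_pair(rng: np.random.Generator, n: int, rho: float,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """n draws of a bivariate standard normal with correlation rho."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2


def simulate_ace_phenotypes(spec: AceSpec | AdeSpec,
                            cohort: CohortShape) -> pd.DataFrame:
    """Draw one phenotype per twin of a cohort under ACE (or ADE) truth.

    Returns a DataFrame with columns pair_id, zygosity, value1, value2.
    Deterministic given ``cohort.seed``.
    """
    if isinstance(spec, AdeSpec):
        fam2, fam_corr = spec.d2, (1.0, 0.25)
        a2, e2 = spec.a2, spec.e2
    elif isinstance(spec, AceSpec):
        fam2, fam_corr = spec.c2, None  # C is perfectly shared in both zygosities
        a2, e2 = spec.a2, spec.e2
    else:
        raise SynthError("spec must be AceSpec or AdeSpec")

    rng = np.random.Generator(np.random.Philox(
        np.random.SeedSequence(cohort.seed).spawn(1)[0]))
    rows = []
    for zyg, n, rho_a in (("MZ", cohort.n_mz, 1.0), ("DZ", cohort.n_dz, 0.5)):
        if n == 0:
            continue
        g1, g2 = _correlated_pair(rng, n, rho_a)
        if fam_corr is None:  # shared environment: identical within pair
            f = rng.standard_normal(n)
            f1 = f2 = f
        else:  # dominance factor
            rho_d = fam_corr[0] if zyg == "MZ" else fam_corr[1]
            f1, f2 = _correlated_pair(rng, n, rho_d)
        u1 = rng.standard_normal(n)
        u2 = rng.standard_normal(n)
        v1 = np.sqrt(a2) * g1 + np.sqrt(fam2) * f1 + np.sqrt(e2) * u1
        v2 = np.sqrt(a2) * g2 + np.sqrt(fam2) * f2 + np.sqrt(e2) * u2
        for i in range(n):
            rows.append((f"{zyg}{i:05d}", zyg, v1[i], v2[i]))
    return pd.DataFrame(rows, columns=["pair_id", "zygosity", "value1", "value2"])


# ---------------------------------------------------------------------------
# Covariance regimes and Markov state planting

def repair_correlation(mat: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Nearest-PD repair: clip eigenvalues at ``eig_floor``, rescale to unit
    diagonal."""
    mat = np.asarray(mat, dtype=float)
    mat = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(mat)
    if w.min() < eig_floor:
        w = np.clip(w, eig_floor, None)
        mat = (v * w) @ v.T
    d = np.sqrt(np.diag(mat))
    mat = mat / np.outer(d, d)
    np.fill_diagonal(mat, 1.0)
    return (mat + mat.T) / 2.0


def block_correlation(networks: Sequence[str], within_r: float = 0.3,
                      between_r: float = 0.05,
                      boosts: Mapping[str, float] | None = None) -> np.ndarray:
    """Network-block ROI correlation: within-network ``within_r`` (plus any
    per-network boost), between-network ``between_r``; PD-repaired, unit
    diagonal."""
    networks = list(networks)
    n = len(networks)
    boosts = dict(boosts or {})
    mat = np.full((n, n), between_r, dtype=float)
    for i in range(n):
        for j in range(n):
            if networks[i] == networks[j]:
                mat[i, j] = min(0.95, within_r + boosts.get(networks[i], 0.0))
    np.fill_diagonal(mat, 1.0)
    return repair_correlation(mat)


@dataclass
class StatePlan:
    """Markov regime plan: per-state stay probability and ROI correlation."""

    stay_prob: Sequence[float]
    state_cov: Sequence[np.ndarray]

    def __post_init__(self) -> None:
        self.stay_prob = [float(p) for p in self.stay_prob]
        if len(self.stay_prob) != len(self.state_cov):
            raise SynthError("one stay probability per state required")
        if len(self.stay_prob) < 1:
            raise SynthError("at least one state required")
        for p in self.stay_prob:
            if not (0.0 <= p < 1.0):
                raise SynthError("stay probabilities must lie in [0, 1)")
        covs = []
        for c in self.state_cov:
            c = np.asarray(c, dtype=float)
            if not np.allclose(np.diag(c), 1.0, atol=1e-8):
                raise SynthError("state covariances must have unit diagonal")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise SynthError("state covariances must be positive definite")
            covs.append(c)
        self.state_cov = covs

    @property
    def n_states(self) -> int:
        return len(self.stay_prob)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the two-state chain (analytic)."""
        if self.n_states == 1:
            return np.array([1.0])
        if self.n_states != 2:
            raise SynthError("stationary() implemented for <= 2 states")
        q0 = 1.0 - self.stay_prob[0]  # leave-state-0 rate
        q1 = 1.0 - self.stay_prob[1]
        return np.array([q1, q0]) / (q0 + q1)


def plant_markov_states(plan: StatePlan, n_frames: int,
                        seed: int | np.random.SeedSequence) -> np.ndarray:
    """Frame-level regime labels from the plan's Markov chain.

    The first state is drawn from the stationary distribution; each later
    frame stays with the current state's stay probability, else switches
    (two-state chain).  Deterministic given the seed.
    """
    if n_frames < 1:
        raise SynthError("n_frames must be >= 1")
    if plan.n_states > 2:
        raise SynthError("only 1- or 2-state chains are supported")
    rng = np.random.Generator(np.random.Philox(
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)))
    if plan.n_states == 1:
        return np.zeros(n_frames, dtype=int)
    labels = np.empty(n_frames, dtype=int)
    u = rng.random(n_frames)
    labels[0] = int(u[0] >= plan.stationary()[0])
    stay = np.asarray(plan.stay_prob)
    for t in range(1, n_frames):
        s = labels[t - 1]
        labels[t] = s if u[t] < stay[s] else 1 - s
    return labels


# ---------------------------------------------------------------------------
# Default task design and network map

def nback_design(block_seconds: float = 25.0, n_blocks_per_condition: int = 4,
                 cue_seconds: float = 2.5,
                 fixation_seconds: float = 15.0) -> TaskDesign:
    """A canonical two-condition n-back run: alternating 0-back and 2-back
    blocks, each preceded by a cue, with fixation breaks after every fourth
    block (eight task blocks per run)."""
    blocks: list[Block] = []
    t = 0.0
    order = ["0bk", "2bk"] * n_blocks_per_condition
    for i, cond in enumerate(order):
        blocks.append(Block(t, cue_seconds, "cue"))
        t += cue_seconds
        blocks.append(Block(t, block_seconds, cond))
        t += block_seconds
        if (i + 1) % 4 == 0 and (i + 1) < len(order):
            blocks.append(Block(t, fixation_seconds, "fixation"))
            t += fixation_seconds
    return TaskDesign(blocks)


DEFAULT_ROI_NETWORKS: dict[str, str] = {
    # 12 synthetic ROIs, two per network across six of the Yeo-7 systems.
    "V1s": "Visual", "V2s": "Visual",
    "M1s": "Somatomotor", "S1s": "Somatomotor",
    "FEFs": "DorsalAttention", "IPSs": "DorsalAttention",
    "INSs": "VentralAttention", "ACCs": "VentralAttention",
    "DLPFCs": "Frontoparietal", "PPCs": "Frontoparietal",
    "PCCs": "Default", "MPFCs": "Default",
}


def default_manifest(n_mz: int = DEFAULT_N_MZ, n_dz: int = DEFAULT_N_DZ,
                     ) -> TwinManifest:
    pairs = [TwinPair(f"MZP{i:04d}", f"MZ{i:04d}a", f"MZ{i:04d}b", "MZ")
             for i in range(n_mz)]
    pairs += [TwinPair(f"DZP{i:04d}", f"DZ{i:04d}a", f"DZ{i:04d}b", "DZ")
              for i in range(n_dz)]
    return TwinManifest(pairs)


# ---------------------------------------------------------------------------
# Time-series level generation

@dataclass(frozen=True)
class EdgeHeritabilitySpec:
    """Heritable 2-back correlation increments on named target edges.

    Each pair draws an ACE-structured standard deviate per edge (the same
    machinery as the phenotype generator); twin i's increment on a target
    edge is ``effect_mean + effect_sd * deviate`` and is added to that edge's
    correlation during 2-back frames only.
    """

    edges: tuple[tuple[str, str], ...]
    ace: AceSpec = AceSpec(0.6, 0.0, 0.4)
    effect_mean: float = 0.2
    effect_sd: float = 0.15


@dataclass
class GroundTruth:
    """Everything the generator drew, recorded exactly, keyed by subject."""

    seed: int
    edge_spec: EdgeHeritabilitySpec | None
    edge_increments: dict[str, dict[str, float]] = field(default_factory=dict)
    frame_states: dict[str, list[int]] = field(default_factory=dict)
    n_clipped: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "edge_spec": None if self.edge_spec is None else {
                "edges": [list(e) for e in self.edge_spec.edges],
                "ace": [self.edge_spec.ace.a2, self.edge_spec.ace.c2,
                        self.edge_spec.ace.e2],
                "effect_mean": self.edge_spec.effect_mean,
                "effect_sd": self.edge_spec.effect_sd,
            },
            "edge_increments": self.edge_increments,
            "frame_states": self.frame_states,
            "n_clipped": self.n_clipped,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _design_frames(design: TaskDesign, tr: float) -> tuple[int, np.ndarray]:
    """(n_frames, per-frame condition code) covering the design; 1 marks
    2-back frames."""
    import math
    n_frames = int(math.ceil(design.end_time / tr))
    is_2bk = np.zeros(n_frames, dtype=bool)
    for b in design.of_condition("2bk"):
        lo = max(0, math.ceil(b.onset / tr - 1e-9))
        hi = min(n_frames, math.ceil((b.onset + b.duration) / tr - 1e-9))
        is_2bk[lo:hi] = True
    return n_frames, is_2bk


def simulate_twin_timeseries(manifest: TwinManifest, design: TaskDesign,
                             plan: StatePlan,
                             roi_labels: Sequence[str],
                             edge_spec: EdgeHeritabilitySpec | None = None,
                             seed: int = 0, tr: float = DEFAULT_TR,
                             n_runs: int = 2, switch_every: int = 1,
                             ) -> tuple[dict[str, list[RoiTimeSeries]], GroundTruth]:
    """Per-subject block-design time series with planted regimes and effects.

    Each frame is drawn from its regime's ROI covariance; on 2-back frames a
    subject's heritable increments are added to the target edges and the
    matrix PD-repaired.  ``switch_every`` sets the chain cadence in frames
    (1 = per frame; a window length aligns regime switches with
    non-overlapping analysis windows).  Increments that push a correlation
    past |r| = 0.99 are clipped and counted in the ground truth.

    Returns ``({subject: [RoiTimeSeries per run]}, GroundTruth)``.
    """
    roi_labels = list(roi_labels)
    if not design.of_condition("0bk") or not design.of_condition("2bk"):
        raise SynthError("design must contain both 0-back and 2-back blocks")
    for c in plan.state_cov:
        if c.shape[0] != len(roi_labels):
            raise SynthError("state covariance size does not match ROI count")
    if edge_spec is not None:
        for e in edge_spec.edges:
            if e[0] not in roi_labels or e[1] not in roi_labels:
                raise SynthError(f"target edge {e} not in ROI labels")

    root = np.random.SeedSequence(seed)
    ss_pheno, ss_states, ss_noise = root.spawn(3)
    truth = GroundTruth(seed=seed, edge_spec=edge_spec)

    # Heritable per-subject increments per target edge (ACE-structured).
    increments: dict[str, dict[tuple[str, str], float]] = {
        s: {} for s in manifest.subjects}
    if edge_spec is not None:
        for e in edge_spec.edges:
            # reuse the phenotype machinery with a dedicated substream per edge
            sub = np.random.Generator(np.random.Philox(ss_pheno.spawn(1)[0]))
            draws = _ace_deviates(edge_spec.ace, manifest, sub)
            for subj, dev in draws.items():
                increments[subj][e] = (edge_spec.effect_mean
                                       + edge_spec.effect_sd * dev)
        truth.edge_increments = {
            s: {f"{a}--{b}": v for (a, b), v in d.items()}
            for s, d in increments.items()}

    n_frames, is_2bk = _design_frames(design, tr)
    n_chain = -(-n_frames // switch_every)  # ceil

    idx = {l: i for i, l in enumerate(roi_labels)}
    out: dict[str, list[RoiTimeSeries]] = {s: [] for s in manifest.subjects}
    state_seqs = ss_states.spawn(len(manifest.subjects) * n_runs)
    noise_seqs = ss_noise.spawn(len(manifest.subjects) * n_runs)
    k = 0
    for subj in manifest.subjects:
        # Per-subject regime covariances with 2-back increments applied.
        chols: dict[tuple[int, bool], np.ndarray] = {}
        for si, cov in enumerate(plan.state_cov):
            chols[(si, False)] = np.linalg.cholesky(cov)
            mod = cov.copy()
            for (a, b), delta in increments[subj].items():
                i, j = idx[a], idx[b]
                r = mod[i, j] + delta
                if abs(r) > 0.99:
                    truth.n_clipped += 1
                    r = float(np.clip(r, -0.99, 0.99))
                mod[i, j] = mod[j, i] = r
            chols[(si, True)] = np.linalg.cholesky(repair_correlation(mod))
        for run in range(n_runs):
            chain = plant_markov_states(plan, n_chain, state_seqs[k])
            frame_states = np.repeat(chain, switch_every)[:n_frames]
            rng = np.random.Generator(np.random.Philox(noise_seqs[k]))
            k += 1
            z = rng.standard_normal((n_frames, len(roi_labels)))
            data = np.empty_like(z)
            key = frame_states * 2 + is_2bk.astype(int)
            for si in range(plan.n_states):
                for active in (False, True):
                    mask = key == si * 2 + int(active)
                    if mask.any():
                        data[mask] = z[mask] @ chols[(si, active)].T
            out[subj].append(RoiTimeSeries(
                subject=subj, run=f"run{run + 1}", data=data, tr=tr,
                roi_labels=roi_labels))
            if run == 0:
                truth.frame_states[subj] = frame_states.tolist()
    return out, truth


def _ace_deviates(spec: AceSpec, manifest: TwinManifest,
                  rng: np.random.Generator) -> dict[str, float]:
    """One standard ACE-structured deviate per subject, keyed by subject id."""
    out: dict[str, float] = {}
    for p in manifest.pairs:
        rho = 1.0 if p.zygosity == "MZ" else 0.5
        g1, g2 = _correlated_pair(rng, 1, rho)
        c = rng.standard_normal(1)
        u1, u2 = rng.standard_normal(1), rng.standard_normal(1)
        out[p.subject1] = float(np.sqrt(spec.a2) * g1[0]
                                + np.sqrt(spec.c2) * c[0]
                                + np.sqrt(spec.e2) * u1[0])
        out[p.subject2] = float(np.sqrt(spec.a2) * g2[0]
                                + np.sqrt(spec.c2) * c[0]
                                + np.sqrt(spec.e2) * u2[0])
    return out
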