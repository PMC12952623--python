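"""Edge-level connectivity phenotypes from ROI time series.

Three phenotypes per edge and condition: static functional connectivity
(correlation over all retained frames of a condition), the mean of sliding-
window dynamic FC, and its variance across windows.  The working-memory
contrast is formed as the elementwise 2-back minus 0-back difference
("diff"), the differential phenotype used for all genetic modelling.

Windows are rectangular, computed per task block (never crossing block
boundaries) and pooled across all blocks and runs of a condition.  Each
window's time series is re-standardized within the window before the
correlation is taken.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

from .io import RoiTimeSeries, TaskDesign

logger = logging.getLogger("twinconn")

Measure = Literal["staticFC", "dfcMean", "dfcVar"]


class ConnectivityError(ValueError):
    pass


@dataclass
class ConnMatrix:
    """ROI x ROI correlation matrix with labels.

    Always symmetric with unit diagonal and entries in [-1, 1]; enforced on
    construction (tiny numerical excursions are clipped).
    """

    values: np.ndarray
    roi_labels: Sequence[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectivityError("connectivity matrix must be square")
        if len(self.roi_labels) != v.shape[0]:
            raise ConnectivityError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ConnectivityError("connectivity matrix must be symmetric")
        v = (v + v.T) / 2.0
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise ConnectivityError("correlation out of [-1, 1]")
        v = np.clip(v, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v
        self.roi_labels = list(self.roi_labels)

    def edge(self, roi_a: str, roi_b: str) -> float:
        i, j = self.roi_labels.index(roi_a), self.roi_labels.index(roi_b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class WindowInfo:
    block_index: int
    start: int  # absolute frame index, inclusive
    end: int    # absolute frame index, exclusive


@dataclass
class WindowedConnStack:
    """Ordered per-window connectivity matrices sharing one label set."""

    matrices: list[ConnMatrix]
    windows: list[WindowInfo]
    roi_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.matrices) != len(self.windows):
            raise ConnectivityError("matrix/window count mismatch")
        if self.matrices and not self.roi_labels:
            self.roi_labels = list(self.matrices[0].roi_labels)
        for m in self.matrices:
            if list(m.roi_labels) != list(self.roi_labels):
                raise ConnectivityError("window matrices have differing labels")
        lengths = {w.end - w.start for w in self.windows}
        if len(lengths) > 1:
            raise ConnectivityError("window length not uniform")

    def __len__(self) -> int:
        return len(self.matrices)

    def as_array(self) -> np.ndarray:
        """Stack as (n_windows, n_rois, n_rois)."""
        return np.stack([m.values for m in self.matrices], axis=0)


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window settings.

    ``window_seconds`` is converted to a whole frame count as
    round(window_seconds / tr); the default 18 s at TR 0.72 s gives 25 frames.
    ``step_frames`` is the slide in frames (default 3).
    """

    window_seconds: float = 18.0
    step_frames: int = 3
    tr: float = 0.72

    def __post_init__(self) -> None:
        if self.step_frames < 1:
            raise ConnectivityError("step must be >= 1 frame")
        w = self.window_frames
        if abs(self.window_seconds / self.tr - w) > 1e-6:
            logger.debug(
                "window length %.4g s is %.4g frames; rounded to %d",
                self.window_seconds, self.window_seconds / self.tr, w,
            )
        if w < 2:
            raise ConnectivityError("window must span at least 2 frames")

    @property
    def window_frames(self) -> int:
        return int(round(self.window_seconds / self.tr))


def standardize_timeseries(data: np.ndarray,
                           roi_labels: Sequence[str] | None = None) -> np.ndarray:
    """Z-score each ROI column to mean 0, sample SD 1 (ddof=1).

    Fails loudly on a zero-variance ROI, naming it; there is no silent drop at
    this level (window-level degeneracy is handled by the caller).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ConnectivityError("need at least 2 frames to standardize")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        name = roi_labels[zero[0]] if roi_labels is not None else f"column {zero[0]}"
        raise ConnectivityError(f"zero-variance ROI {name!r} on selected frames")
    return (data - mean) / sd


def select_condition_frames(ts: RoiTimeSeries, design: TaskDesign, condition: str,
                            lag: float = 0.0) -> list[list[int]]:
    """Frame indices of a condition's blocks, one list per block.

    A frame at time ``i * tr`` belongs to a block when it falls in the
    half-open interval [onset + lag, onset + duration + lag).  Cue and
    fixation frames are excluded by construction.
    """
    blocks = design.of_condition(condition)
    if not blocks:
        raise ConnectivityError(f"design has no blocks of condition {condition!r}")
    out: list[list[int]] = []
    for b in blocks:
        lo = b.onset + lag
        hi = b.onset + b.duration + lag
        first = max(0, math.ceil(lo / ts.tr - 1e-9))
        # last frame index with frame_time < hi
        last = min(ts.n_frames - 1, math.ceil(hi / ts.tr - 1e-9) - 1)
        out.append(list(range(first, last + 1)) if last >= first else [])
    return out


def static_fc(ts: RoiTimeSeries, frames: Iterable[int],
              method: Literal["pearson", "partial"] = "pearson") -> ConnMatrix:
    """Connectivity matrix over the given frames.

    ``pearson`` is the plain correlation of the standardized series.
    ``partial`` regularizes the covariance with Ledoit-Wolf shrinkage toward
    a scaled identity, inverts it, and returns the standardized negated
    off-diagonal of the precision matrix.
    """
    frames = list(frames)
    if len(frames) < 3:
        raise ConnectivityError("need at least 3 frames for a correlation")
    z = standardize_timeseries(ts.data[frames, :], ts.roi_labels)
    if method == "pearson":
        r = (z.T @ z) / (len(frames) - 1)
    elif method == "partial":
        lw = LedoitWolf(assume_centered=True).fit(z)
        prec = np.linalg.pinv(lw.covariance_)
        d = np.sqrt(np.diag(prec))
        r = -prec / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    else:
        raise ConnectivityError(f"unknown method {method!r}")
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnMatrix(r, ts.roi_labels)


def window_indices(n_frames: int, params: WindowParams) -> list[tuple[int, int]]:
    """Half-open [start, start+w) windows inside a block of ``n_frames``.

    Count is floor((n - w) / step) + 1 when n >= w, else zero (a legal,
    reported outcome).
    """
    w = params.window_frames
    if n_frames < w:
        return []
    n_windows = (n_frames - w) // params.step_frames + 1
    return [(i * params.step_frames, i * params.step_frames + w)
            for i in range(n_windows)]


def dynamic_fc(ts: RoiTimeSeries, design: TaskDesign, condition: str,
               params: WindowParams, lag: float = 0.0,
               method: Literal["pearson", "partial"] = "pearson",
               ) -> WindowedConnStack:
    """Sliding-window connectivity for one condition.

    Windows are laid out inside each of the condition's blocks (never crossing
    a boundary) and pooled in block order.  Each window is re-standardized
    before the correlation is taken, so a window matrix is exactly
    :func:`static_fc` restricted to the window's frames.  Windows containing a
    zero-variance ROI segment are dropped with a logged count rather than
    failing the subject.
    """
    block_frames = select_condition_frames(ts, design, condition, lag=lag)
    matrices: list[ConnMatrix] = []
    infos: list[WindowInfo] = []
    n_dropped = 0
    for bi, frames in enumerate(block_frames):
        for start, end in window_indices(len(frames), params):
            sel = frames[start:end]
            try:
                m = static_fc(ts, sel, method=method)
            except ConnectivityError:
                n_dropped += 1
                continue
            matrices.append(m)
            infos.append(WindowInfo(bi, sel[0], sel[-1] + 1))
    if n_dropped:
        logger.info("subject %s: dropped %d degenerate window(s)", ts.subject,
                    n_dropped)
    if not matrices:
        raise ConnectivityError(
            f"no usable windows for condition {condition!r} "
            f"(window {params.window_frames} frames)"
        )
    return WindowedConnStack(matrices, infos, ts.roi_labels)


def dfc_summary(stack: WindowedConnStack) -> tuple[pd.Series, pd.Series]:
    """Per-edge mean and unbiased variance of windowed correlations.

    Returns two Series indexed by ``(roi_i, roi_j)`` with i < j in ROI order.
    Variance requires at least 2 retained windows.
    """
    if len(stack) < 1:
        raise ConnectivityError("empty window stack")
    arr = stack.as_array()
    labels = list(stack.roi_labels)
    iu = np.triu_indices(len(labels), k=1)
    edges = [(labels[i], labels[j]) for i, j in zip(*iu)]
    vals = arr[:, iu[0], iu[1]]  # (n_windows, n_edges)
    mean = pd.Series(vals.mean(axis=0), index=pd.Index(edges, tupleize_cols=False))
    if len(stack) < 2:
        raise ConnectivityError("need >= 2 windows for a variance")
    var = pd.Series(vals.var(axis=0, ddof=1), index=mean.index)
    return mean, var


@dataclass
class EdgePhenotypeTable:
    """Per-subject scalar per edge for one measure and condition tag.

    ``values`` is a DataFrame indexed by subject id with one column per edge
    ``(roi_i, roi_j)``, i < j in ROI order.
    """

    measure: Measure
    condition: str  # "0bk" | "2bk" | "diff"
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ConnectivityError("phenotype table contains missing values")

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.values.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)


def edge_series(conn: ConnMatrix) -> pd.Series:
    """Upper-triangular edges of a matrix as a Series keyed by (roi_i, roi_j)."""
    labels = list(conn.roi_labels)
    iu = np.triu_indices(len(labels), k=1)
    edges = [(labels[i], labels[j]) for i, j in zip(*iu)]
    return pd.Series(conn.values[iu], index=pd.Index(edges, tupleize_cols=False))


def differential_phenotype(table_2bk: EdgePhenotypeTable,
                           table_0bk: EdgePhenotypeTable) -> EdgePhenotypeTable:
    """Elementwise 2-back minus 0-back phenotype ("diff")."""
    if table_2bk.measure != table_0bk.measure:
        raise ConnectivityError("measure mismatch between condition tables")
    if {table_2bk.condition, table_0bk.condition} != {"2bk", "0bk"}:
        raise ConnectivityError("inputs must be the 2bk and 0bk tables")
    if list(table_2bk.values.index) != list(table_0bk.values.index):
        raise ConnectivityError("subject sets differ between condition tables")
    if list(table_2bk.values.columns) != list(table_0bk.values.columns):
        raise ConnectivityError("edge sets differ between condition tables")
    return EdgePhenotypeTable(
        measure=table_2bk.measure,
        condition="diff",
        values=table_2bk.values - table_0bk.values,
    )


def subject_phenotypes(ts_by_run: Sequence[RoiTimeSeries],
                       design_by_run: Sequence[TaskDesign],
                       params: WindowParams,
                       method: Literal["pearson", "partial"] = "pearson",
                       lag: float = 0.0,
                       fisher_z: bool = False,
                       ) -> dict[str, dict[Measure, pd.Series]]:
    """All three edge phenotypes for one subject, per condition.

    Static FC pools every retained frame of a condition across runs; dynamic
    FC pools windows across blocks and runs.  With ``fisher_z`` the atanh
    transform is applied to staticFC and dfcMean (not dfcVar).

    Returns ``{condition: {measure: edge Series}}`` for conditions 0bk/2bk.
    """
    out: dict[str, dict[Measure, pd.Series]] = {}
    for condition in ("0bk", "2bk"):
        stacks: list[WindowedConnStack] = []
        pooled_ms: list[ConnMatrix] = []
        pooled_infos: list[WindowInfo] = []
        for ts, design in zip(ts_by_run, design_by_run):
            stacks.append(dynamic_fc(ts, design, condition, params,
                                     lag=lag, method=method))
        # Static FC per run (runs are standardized separately), then a
        # frame-weighted average of the run matrices.
        statics: list[tuple[int, ConnMatrix]] = []
        for ts, design in zip(ts_by_run, design_by_run):
            frames = [i for blk in
                      select_condition_frames(ts, design, condition, lag=lag)
                      for i in blk]
            statics.append((len(frames), static_fc(ts, frames, method=method)))
        total = sum(n for n, _ in statics)
        stat = sum((n / total) * m.values for n, m in statics)
        stat_series = edge_series(ConnMatrix(stat, ts_by_run[0].roi_labels))
        for st in stacks:
            pooled_ms.extend(st.matrices)
            pooled_infos.extend(st.windows)
        pooled = WindowedConnStack(pooled_ms, pooled_infos)
        mean, var = dfc_summary(pooled)
        if fisher_z:
            stat_series = np.arctanh(stat_series.clip(-0.999999, 0.999999))
            mean = np.arctanh(mean.clip(-0.999999, 0.999999))
        out[condition] = {"staticFC": stat_series, "dfcMean": mean, "dfcVar": var}
    return out


def phenotype_tables(per_subject: dict[str, dict[str, dict[Measure, pd.Series]]],
                     ) -> dict[Measure, EdgePhenotypeTable]:
    """Assemble per-subject condition phenotypes into differential tables.

    ``per_subject`` maps subject id -> output of :func:`subject_phenotypes`.
    Returns one "diff" table per measure.
    """
    tables: dict[Measure, EdgePhenotypeTable] = {}
    subjects = list(per_subject)
    for measure in ("staticFC", "dfcMean", "dfcVar"):
        per_cond = {}
        for condition in ("0bk", "2bk"):
            rows = {s: per_subject[s][condition][measure] for s in subjects}
            per_cond[condition] = EdgePhenotypeTable(
                measure=measure, condition=condition,
                values=pd.DataFrame(rows).T.loc[subjects],
            )
        tables[measure] = differential_phenotype(per_cond["2bk"], per_cond["0bk"])
    return tables
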