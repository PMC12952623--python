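"""Readers and writers for every file the pipeline touches.

All on-disk formats are plain text: ROI time series as TSV with a ``#`` header
comment carrying subject/run/TR metadata, task timing as FSL three-column event
files, twin manifests and ROI maps as CSV/TSV.  Every reader validates its
input and raises :class:`DataError` with a located message on malformed files;
every writer/reader pair round-trips.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("twinconn")

YEO7_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "Default",
)

CONDITIONS = ("0bk", "2bk", "fixation", "cue")

#: Float text precision used by all writers (round-trip policy).
FLOAT_FORMAT = "%.10g"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class RoiTimeSeries:
    """One subject/run's frames x ROI BOLD matrix.

    Parameters
    ----------
    subject, run : str
        Identifiers; the pair is the unit keyed throughout the pipeline.
    data : ndarray, shape (n_frames, n_rois)
        Parcellated signal, arbitrary units.
    tr : float
        Repetition time in seconds (frame spacing).
    roi_labels : sequence of str
        Column labels, unique, one per ROI (e.g. Glasser names, optionally
        hemisphere-prefixed "L-"/"R-").
    """

    subject: str
    run: str
    data: np.ndarray
    tr: float
    roi_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = list(self.roi_labels)
        if self.data.ndim != 2:
            raise DataError("time-series data must be 2-D (frames x ROIs)")
        if self.data.shape[0] < 2:
            raise DataError("time series needs at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise DataError(
                f"non-finite value at frame {bad[0]}, ROI "
                f"{self.roi_labels[bad[1]] if bad[1] < len(self.roi_labels) else bad[1]}"
            )
        if len(self.roi_labels) != self.data.shape[1]:
            raise DataError(
                f"{len(self.roi_labels)} labels for {self.data.shape[1]} columns"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            dupes = sorted({l for l in self.roi_labels if self.roi_labels.count(l) > 1})
            raise DataError(f"duplicate ROI labels: {dupes}")
        if not self.tr > 0:
            raise DataError("TR must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Block:
    onset: float
    duration: float
    condition: str


@dataclass
class TaskDesign:
    """Block timing of the two-condition n-back run (plus fixation/cue)."""

    blocks: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.blocks:
            if b.condition not in CONDITIONS:
                raise DataError(f"unknown condition {b.condition!r}")
            if b.onset < 0:
                raise DataError(f"negative onset {b.onset}")
            if b.duration <= 0:
                raise DataError(f"non-positive duration {b.duration}")
        self.blocks = sorted(self.blocks, key=lambda b: b.onset)
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.onset < prev.onset + prev.duration - 1e-9:
                raise DataError(
                    f"overlapping blocks at onsets {prev.onset} and {nxt.onset}"
                )

    def of_condition(self, condition: str) -> list[Block]:
        return [b for b in self.blocks if b.condition == condition]

    @property
    def end_time(self) -> float:
        return max((b.onset + b.duration for b in self.blocks), default=0.0)


@dataclass(frozen=True)
class TwinPair:
    pair_id: str
    subject1: str
    subject2: str
    zygosity: str  # "MZ" | "DZ"


@dataclass
class TwinManifest:
    """Pair structure and zygosity; the unit of the genetic analysis."""

    pairs: list[TwinPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            if p.zygosity not in ("MZ", "DZ"):
                raise DataError(f"pair {p.pair_id}: unknown zygosity {p.zygosity!r}")
            for s in (p.subject1, p.subject2):
                if s in seen:
                    raise DataError(f"subject {s} appears in more than one pair slot")
                seen.add(s)

    def of_zygosity(self, zygosity: str) -> list[TwinPair]:
        return [p for p in self.pairs if p.zygosity == zygosity]

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out.extend((p.subject1, p.subject2))
        return out

    @property
    def n_mz(self) -> int:
        return len(self.of_zygosity("MZ"))

    @property
    def n_dz(self) -> int:
        return len(self.of_zygosity("DZ"))


def _validated_map(mapping: Mapping[str, str], allowed: Sequence[str] | None,
                   kind: str) -> dict[str, str]:
    out = dict(mapping)
    for roi, name in out.items():
        if allowed is not None and name not in allowed:
            raise DataError(f"{kind} map: unknown name {name!r} for ROI {roi!r} "
                            f"(allowed: {', '.join(allowed)})")
    return out


class NetworkMap(dict):
    """ROI label -> Yeo-7 network name."""

    def __init__(self, mapping: Mapping[str, str]):
        super().__init__(_validated_map(mapping, YEO7_NETWORKS, "network"))


class RegionGroupMap(dict):
    """ROI label -> anatomical group used for the region-contribution summary."""

    def __init__(self, mapping: Mapping[str, str]):
        super().__init__(_validated_map(mapping, None, "region-group"))
        if any(not g for g in self.values()):
            raise DataError("region-group map contains an empty group name")


# ---------------------------------------------------------------------------
# ROI time series TSV

def write_roi_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a time series as TSV with a ``#`` metadata header line."""
    path = Path(path)
    meta = json.dumps({"subject": ts.subject, "run": ts.run, "tr": ts.tr})
    with path.open("w") as fh:
        fh.write(f"# twinconn-roi-timeseries {meta}\n")
        fh.write("\t".join(ts.roi_labels) + "\n")
        np.savetxt(fh, ts.data, fmt=FLOAT_FORMAT, delimiter="\t")


def read_roi_timeseries(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# twinconn-roi-timeseries "):
            raise DataError(f"{path}: missing metadata header line")
        meta = json.loads(first.split(" ", 2)[2])
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DataError(f"{path}: duplicate ROI labels {dupes}")
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(labels):
                raise DataError(
                    f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                    f"expected {len(labels)})"
                )
            vals = []
            for col, cell in enumerate(cells):
                if cell.strip() == "":
                    raise DataError(
                        f"{path}:{lineno}: missing cell in column {labels[col]!r}"
                    )
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise DataError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column "
                        f"{labels[col]!r}"
                    ) from None
            rows.append(vals)
    return RoiTimeSeries(
        subject=meta["subject"], run=meta["run"], data=np.array(rows),
        tr=float(meta["tr"]), roi_labels=labels,
    )


# ---------------------------------------------------------------------------
# FSL three-column event files

def write_task_design(design: TaskDesign, paths: Mapping[str, str | Path]) -> None:
    """Write one FSL three-column file per condition (weight fixed at 1)."""
    for condition, path in paths.items():
        blocks = design.of_condition(condition)
        with Path(path).open("w") as fh:
            for b in blocks:
                fh.write(f"{b.onset:g}\t{b.duration:g}\t1\n")


def read_task_design(paths: Mapping[str, str | Path]) -> TaskDesign:
    """Read FSL three-column (onset, duration, weight) files, one per condition.

    The weight column is ignored.  Blocks are merged across conditions, sorted
    by onset and validated for overlap.
    """
    blocks: list[Block] = []
    for condition, path in paths.items():
        if condition not in CONDITIONS:
            raise DataError(f"unknown condition {condition!r}")
        path = Path(path)
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split()
            if len(cells) < 2:
                raise DataError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
            try:
                onset, duration = float(cells[0]), float(cells[1])
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-numeric onset/duration") from None
            if onset < 0:
                raise DataError(f"{path}:{lineno}: negative onset {onset}")
            blocks.append(Block(onset, duration, condition))
    return TaskDesign(blocks)


# ---------------------------------------------------------------------------
# Manifest and ROI maps

def write_twin_manifest(manifest: TwinManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.pair_id, p.subject1, p.subject2, p.zygosity) for p in manifest.pairs],
        columns=["pair_id", "subject1", "subject2", "zygosity"],
    )
    df.to_csv(path, index=False)


def read_twin_manifest(path: str | Path) -> TwinManifest:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"pair_id", "subject1", "subject2", "zygosity"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if df.isna().any().any():
        raise DataError(f"{path}: missing cell in manifest")
    pairs = [
        TwinPair(r.pair_id, r.subject1, r.subject2, r.zygosity)
        for r in df.itertuples(index=False)
    ]
    return TwinManifest(pairs)


def _read_two_column_tsv(path: str | Path, value_name: str) -> dict[str, str]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two tab-separated columns")
    roi_col, val_col = df.columns[0], df.columns[1]
    if df[roi_col].duplicated().any():
        dupes = df.loc[df[roi_col].duplicated(), roi_col].tolist()
        raise DataError(f"{path}: duplicate ROI rows {dupes}")
    if df.isna().any().any():
        raise DataError(f"{path}: missing {value_name} cell")
    return dict(zip(df[roi_col], df[val_col]))


def read_network_map(path: str | Path) -> NetworkMap:
    """Read a TSV mapping ROI label -> Yeo-7 network name."""
    return NetworkMap(_read_two_column_tsv(path, "network"))


def write_network_map(nmap: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(nmap.items()), columns=["roi", "network"]).to_csv(
        path, sep="\t", index=False
    )


def read_region_groups(path: str | Path) -> RegionGroupMap:
    return RegionGroupMap(_read_two_column_tsv(path, "group"))


def write_region_groups(gmap: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(gmap.items()), columns=["roi", "group"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Edge-level results table

EDGE_RESULT_COLUMNS = ["ROI1", "ROI2", "A_effect", "p", "p_adjusted", "model"]


def write_edge_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write edge heritability results as TSV in deterministic order.

    Rows are sorted by descending ``A_effect``; ties break lexicographically on
    the (ROI1, ROI2) label pair.
    """
    df = results.copy()
    missing = [c for c in EDGE_RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"edge results missing columns {missing}")
    extra = [c for c in df.columns if c not in EDGE_RESULT_COLUMNS]
    df = df[EDGE_RESULT_COLUMNS + extra]
    df = df.sort_values(
        by=["A_effect", "ROI1", "ROI2"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_edge_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def setup_logging(verbose: bool = False) -> None:
    """Structured logging to stderr; DEBUG when verbose."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
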