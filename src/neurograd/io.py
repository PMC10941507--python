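"""Plain-text file formats and the run manifest.

Everything the pipeline reads or writes is TSV or JSON:

* time series — T rows × R columns, header row = ROI ids;
* connectivity — R×R with ROI ids as header row and first column;
* vertex areas — long format: roi_id, vertex_index, area_mm2;
* subject metadata — subject_id, group, age, sex, updrs3_pre, updrs3_post;
* partition — roi_id, network;
* gradients — roi_id, g1..gk TSV plus a JSON sidecar with eigenvalues,
  explained ratios and embedding parameters.

Readers validate shape line-by-line so malformed files fail with the
offending line number rather than a downstream numerics error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectomes import ConnectivityMatrix, ParcellatedTimeSeries, VertexAreaTable
from .gradients import GradientSet
from .stats import NetworkPartition, SubjectRecord

__all__ = [
    "read_timeseries_tsv", "write_timeseries_tsv",
    "read_connectivity_tsv", "write_connectivity_tsv",
    "read_vertex_areas_tsv", "write_vertex_areas_tsv",
    "read_metadata_tsv", "write_metadata_tsv",
    "read_partition_tsv", "write_partition_tsv",
    "read_gradients", "write_gradients",
    "write_cohort",
    "FileManifest", "ManifestEntry",
]


def _read_table(path: str | Path) -> list[list[str]]:
    """Read a TSV into rows of strings, enforcing rectangular shape."""
    path = Path(path)
    rows: list[list[str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if rows and len(cells) != len(rows[0]):
                raise ValueError(
                    f"{path.name}: line {lineno} has {len(cells)} fields, "
                    f"expected {len(rows[0])} (ragged row)"
                )
            rows.append(cells)
    if not rows:
        raise ValueError(f"{path.name}: empty file")
    return rows


def _to_float(cell: str, path: Path, lineno: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValueError(
            f"{path.name}: non-numeric cell {cell!r} at line {lineno}"
        ) from None


def _numeric_block(rows: list[list[str]], path: Path, start_line: int,
                   skip_first_col: bool = False) -> np.ndarray:
    out = []
    for i, row in enumerate(rows):
        cells = row[1:] if skip_first_col else row
        out.append([_to_float(c, path, start_line + i) for c in cells])
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def write_timeseries_tsv(ts: ParcellatedTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.roi_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries_tsv(path: str | Path, subject_id: str = "",
                        session: str = "") -> ParcellatedTimeSeries:
    path = Path(path)
    rows = _read_table(path)
    roi_ids = rows[0]
    if len(set(roi_ids)) != len(roi_ids):
        dupes = sorted({r for r in roi_ids if roi_ids.count(r) > 1})
        raise ValueError(f"{path.name}: duplicate ROI ids in header: {dupes[:5]}")
    data = _numeric_block(rows[1:], path, start_line=2)
    return ParcellatedTimeSeries(subject_id, session, data, roi_ids)


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------

def write_connectivity_tsv(cm: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.values, index=list(cm.roi_ids), columns=list(cm.roi_ids))
    df.index.name = "roi_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_connectivity_tsv(path: str | Path, kind: str = "functional",
                          subject_id: str = "", session: str = "") -> ConnectivityMatrix:
    path = Path(path)
    rows = _read_table(path)
    header = rows[0][1:]
    row_ids = [r[0] for r in rows[1:]]
    if header != row_ids:
        raise ValueError(f"{path.name}: header ROI order differs from first column")
    if len(set(header)) != len(header):
        raise ValueError(f"{path.name}: duplicate ROI ids")
    values = _numeric_block(rows[1:], path, start_line=2, skip_first_col=True)
    return ConnectivityMatrix(values, kind, header, subject_id, session)


# ---------------------------------------------------------------------------
# Vertex areas (long format)
# ---------------------------------------------------------------------------

def write_vertex_areas_tsv(vt: VertexAreaTable, path: str | Path) -> None:
    recs = [
        (roi, i, a)
        for roi, vals in vt.areas.items()
        for i, a in enumerate(vals)
    ]
    df = pd.DataFrame(recs, columns=["roi_id", "vertex_index", "area_mm2"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_vertex_areas_tsv(path: str | Path, subject_id: str = "",
                          session: str = "") -> VertexAreaTable:
    path = Path(path)
    rows = _read_table(path)
    if rows[0] != ["roi_id", "vertex_index", "area_mm2"]:
        raise ValueError(f"{path.name}: expected header roi_id/vertex_index/area_mm2")
    areas: dict[str, list[float]] = {}
    for i, row in enumerate(rows[1:], start=2):
        areas.setdefault(row[0], []).append(_to_float(row[2], path, i))
    return VertexAreaTable(subject_id, session, {k: np.asarray(v) for k, v in areas.items()})


# ---------------------------------------------------------------------------
# Metadata and partition
# ---------------------------------------------------------------------------

_META_COLS = ["subject_id", "group", "age", "sex", "updrs3_pre", "updrs3_post"]


def write_metadata_tsv(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (s.subject_id, s.group, s.age, s.sex,
             "" if s.updrs3_pre is None else s.updrs3_pre,
             "" if s.updrs3_post is None else s.updrs3_post)
            for s in subjects
        ],
        columns=_META_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    subjects = []
    for _, row in df.iterrows():
        pre = None if pd.isna(row["updrs3_pre"]) else float(row["updrs3_pre"])
        post = None if pd.isna(row["updrs3_post"]) else float(row["updrs3_post"])
        subjects.append(
            SubjectRecord(str(row["subject_id"]), str(row["group"]),
                          float(row["age"]), int(row["sex"]), pre, post)
        )
    return subjects


def write_partition_tsv(part: NetworkPartition, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(part.assignment.items()), columns=["roi_id", "network"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition_tsv(path: str | Path) -> NetworkPartition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["roi_id", "network"]:
        raise ValueError(f"{Path(path).name}: expected columns roi_id, network")
    labels = [l for l in df["network"].unique()]
    from .stats import CANONICAL_NETWORKS

    if set(labels) <= set(CANONICAL_NETWORKS):
        labels = [l for l in CANONICAL_NETWORKS if l in set(labels)]
    return NetworkPartition(dict(zip(df["roi_id"], df["network"])), tuple(labels))


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

def write_gradients(gs: GradientSet, tsv_path: str | Path,
                    json_path: str | Path | None = None) -> None:
    cols = {f"g{c + 1}": gs.scores[:, c] for c in range(gs.n_components)}
    df = pd.DataFrame({"roi_id": list(gs.roi_ids), **cols})
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    if json_path is not None:
        meta = {
            "eigenvalues": gs.eigenvalues.tolist(),
            "explained_ratio": gs.explained_ratio.tolist(),
            "alpha": gs.alpha,
            "diffusion_time": gs.diffusion_time,
            "aligned": gs.aligned,
            "subject_id": gs.subject_id,
            "session": gs.session,
            "kind": gs.kind,
        }
        Path(json_path).write_text(json.dumps(meta, indent=2))


def read_gradients(tsv_path: str | Path, json_path: str | Path) -> GradientSet:
    df = pd.read_csv(tsv_path, sep="\t")
    meta = json.loads(Path(json_path).read_text())
    comps = [c for c in df.columns if c != "roi_id"]
    return GradientSet(
        scores=df[comps].to_numpy(float),
        eigenvalues=np.asarray(meta["eigenvalues"]),
        explained_ratio=np.asarray(meta["explained_ratio"]),
        alpha=meta["alpha"],
        diffusion_time=meta["diffusion_time"],
        aligned=meta["aligned"],
        roi_ids=tuple(df["roi_id"].astype(str)),
        subject_id=meta.get("subject_id", ""),
        session=meta.get("session", ""),
        kind=meta.get("kind", ""),
    )


# ---------------------------------------------------------------------------
# Cohort export
# ---------------------------------------------------------------------------

def write_cohort(cohort, outdir: str | Path) -> list[Path]:
    """Write a synthetic cohort in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (sid, session), ts in cohort.timeseries.items():
        p = outdir / f"{sid}_{session}_timeseries.tsv"
        write_timeseries_tsv(ts, p)
        written.append(p)
    for (sid, session), vt in cohort.vertex_areas.items():
        p = outdir / f"{sid}_{session}_vertex_areas.tsv"
        write_vertex_areas_tsv(vt, p)
        written.append(p)
    p = outdir / "metadata.tsv"
    write_metadata_tsv(cohort.subjects, p)
    written.append(p)
    p = outdir / "partition.tsv"
    write_partition_tsv(cohort.partition, p)
    written.append(p)
    p = outdir / "truth.json"
    p.write_text(json.dumps(cohort.truth, indent=2))
    written.append(p)
    return written


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class ManifestEntry:
    path: str
    format: str
    checksum: str
    stage: str
    timestamp: str


@dataclasses.dataclass
class FileManifest:
    root: str
    entries: list[ManifestEntry] = dataclasses.field(default_factory=list)

    def add(self, path: str | Path, fmt: str, stage: str) -> None:
        path = Path(path)
        rel = str(path.relative_to(self.root))
        self.entries.append(
            ManifestEntry(
                path=rel,
                format=fmt,
                checksum=_sha256(path),
                stage=stage,
                timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            )
        )

    def write(self, path: str | Path) -> None:
        payload = {
            "root": self.root,
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def verify(self) -> list[str]:
        """Return the relative paths whose on-disk checksum no longer matches."""
        bad = []
        for e in self.entries:
            p = Path(self.root) / e.path
            if not p.exists() or _sha256(p) != e.checksum:
                bad.append(e.path)
        return bad
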