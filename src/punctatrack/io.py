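"""File interfaces: TIFF stacks, CSV tables, and the result workbook.

Stacks travel as multi-frame TIFF with the physical calibration (pixel
size in nm, frame interval in s) stored as JSON in the image description
tag, so a write/read round-trip is lossless for both raster and
calibration.  Tabular outputs are plain CSV with stable, versioned
headers.  Per-photoreceptor results can also be written to / read from a
two-tab spreadsheet ("Kinetics" and "Contacts") laid out like the study's
deposited per-photoreceptor tables: one column per metric x condition,
one row per photoreceptor.
"""

from __future__ import annotations

import datetime
import json
import re
import zipfile
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .kinematics import PRSummary, TrackMetrics
from .stats import ComparisonResult
from .synthetic import FrameStack, TruthTrack
from .tracking import Track

SCHEMA_VERSION = "1"

TRACKS_COLUMNS = ["track_id", "frame", "x_px", "y_px", "x_nm", "y_nm", "pixel_count"]
TRUTH_COLUMNS = ["particle_id", "frame", "x_nm", "y_nm"]
SHIFTS_COLUMNS = ["frame", "dx_px", "dy_px"]
METRICS_COLUMNS = [
    "cell_id", "track_id", "n_frames", "displacement_nm", "trajectory_um",
    "max_speed_nm_s", "directionality", "area_um2", "contacted_bb", "n_contact_frames",
]
SUMMARY_COLUMNS = [
    "cell_id", "condition", "n_tracks", "mean_displacement_nm", "mean_trajectory_um",
    "mean_max_speed_nm_s", "mean_directionality", "mean_area_um2",
    "n_contacting", "contact_proportion",
]
COMPARISONS_COLUMNS = ["metric", "groups", "test", "statistic", "p_value", "stars"]
STUDY_COLUMNS = ["animal_id", "cell_id", "condition", "metric", "value"]

#: canonical metric name -> header synonyms accepted when reading workbooks
_METRIC_SYNONYMS = {
    "displacement": ("displacement",),
    "trajectory": ("trajectory",),
    "size": ("size", "area"),
    "max_speed": ("maximum speed", "max speed", "max_speed", "speed"),
    "directionality": ("directionality",),
    "contact_proportion": ("proportion", "contact_proportion"),
    "n_contacting": ("number", "n_contacting", "absolute number", "contacts"),
}

KINETICS_METRICS = ["displacement", "trajectory", "size", "max_speed", "directionality"]
CONTACTS_METRICS = ["contact_proportion", "n_contacting"]


# ---------------------------------------------------------------------------
# TIFF stacks

def write_stack(stack: FrameStack, path: Union[str, Path]) -> None:
    """Write a FrameStack as multi-frame TIFF with JSON calibration tag."""
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_interval_s": stack.frame_interval_s,
        "axes": "CTYX",
        "schema_version": SCHEMA_VERSION,
    }
    tifffile.imwrite(
        Path(path), stack.data.astype(np.float32),
        photometric="minisblack", description=json.dumps(meta),
    )


def read_stack(path: Union[str, Path]) -> FrameStack:
    """Read a FrameStack written by :func:`write_stack` (lossless)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    if data.ndim == 2:  # single frame, single channel
        data = data[None, None]
    elif data.ndim == 3:  # T x H x W, single channel
        data = data[None]
    elif data.ndim != 4:
        raise ValueError(f"unsupported TIFF shape {data.shape}")
    return FrameStack(
        data=data,
        pixel_size_nm=float(meta.get("pixel_size_nm", 210.0)),
        frame_interval_s=float(meta.get("frame_interval_s", 1.0)),
    )


# ---------------------------------------------------------------------------
# CSV tables

def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = [
        {
            "track_id": tr.track_id,
            "frame": det.frame,
            "x_px": det.barycenter_px[0],
            "y_px": det.barycenter_px[1],
            "x_nm": det.barycenter_nm[0],
            "y_nm": det.barycenter_nm[1],
            "pixel_count": det.pixel_count,
        }
        for tr in tracks
        for det in tr.detections
    ]
    return pd.DataFrame(rows, columns=TRACKS_COLUMNS)


def truth_to_frame(truth: Sequence[TruthTrack]) -> pd.DataFrame:
    rows = [
        {"particle_id": tr.particle_id, "frame": tr.birth_frame + i,
         "x_nm": tr.positions_nm[i, 0], "y_nm": tr.positions_nm[i, 1]}
        for tr in truth
        for i in range(tr.n_frames)
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def shifts_to_frame(shifts: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"frame": np.arange(len(shifts)), "dx_px": shifts[:, 0], "dy_px": shifts[:, 1]},
        columns=SHIFTS_COLUMNS,
    )


def metrics_to_frame(metrics: Sequence[TrackMetrics], cell_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "cell_id": cell_id,
            "track_id": m.track_id,
            "n_frames": m.n_frames,
            "displacement_nm": m.displacement_nm,
            "trajectory_um": m.trajectory_um,
            "max_speed_nm_s": m.max_speed_nm_s,
            "directionality": m.directionality,
            "area_um2": m.area_um2,
            "contacted_bb": m.contacted_bb,
            "n_contact_frames": m.n_contact_frames,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def summaries_to_frame(summaries: Sequence[PRSummary]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": s.cell_id,
            "condition": s.condition,
            "n_tracks": s.n_tracks,
            "mean_displacement_nm": s.mean_displacement_nm,
            "mean_trajectory_um": s.mean_trajectory_um,
            "mean_max_speed_nm_s": s.mean_max_speed_nm_s,
            "mean_directionality": s.mean_directionality,
            "mean_area_um2": s.mean_area_um2,
            "n_contacting": s.n_contacting,
            "contact_proportion": s.contact_proportion,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def comparisons_to_frame(results: Sequence[tuple[str, ComparisonResult]]) -> pd.DataFrame:
    rows = [
        {
            "metric": metric,
            "groups": " vs ".join(r.group_labels),
            "test": r.test_name,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "stars": r.stars,
        }
        for metric, r in results
    ]
    return pd.DataFrame(rows, columns=COMPARISONS_COLUMNS)


# ---------------------------------------------------------------------------
# Study table (long format) and the two-tab workbook

def summaries_to_study_table(summaries: Sequence[PRSummary], animal_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Long-format per-photoreceptor records (one row per cell x metric)."""
    field_for_metric = {
        "displacement": "mean_displacement_nm",
        "trajectory": "mean_trajectory_um",
        "size": "mean_area_um2",
        "max_speed": "mean_max_speed_nm_s",
        "directionality": "mean_directionality",
        "contact_proportion": "contact_proportion",
        "n_contacting": "n_contacting",
    }
    rows = []
    for i, s in enumerate(summaries):
        animal = animal_ids[i] if animal_ids is not None else ""
        for metric, attr in field_for_metric.items():
            rows.append(
                {"animal_id": animal, "cell_id": s.cell_id, "condition": s.condition,
                 "metric": metric, "value": getattr(s, attr)}
            )
    df = pd.DataFrame(rows, columns=STUDY_COLUMNS)
    dup = df.duplicated(subset=["animal_id", "cell_id", "metric"])
    if dup.any():
        raise ValueError("duplicate (animal_id, cell_id, metric) records in study table")
    return df


def _match_metric(header: str) -> Optional[str]:
    h = header.strip().lower()
    for canonical, synonyms in _METRIC_SYNONYMS.items():
        for syn in synonyms:
            if h.startswith(syn):
                return canonical
    return None


def _split_header(header: str) -> tuple[Optional[str], str]:
    """Split a workbook column header into (canonical metric, condition)."""
    if "|" in header:
        metric_part, cond = header.split("|", 1)
        return _match_metric(metric_part), cond.strip()
    metric = _match_metric(header)
    if metric is None:
        return None, header.strip()
    h = header.strip()
    for syn in _METRIC_SYNONYMS[metric]:
        m = re.match(re.escape(syn), h, flags=re.IGNORECASE)
        if m:
            rest = h[m.end():].strip(" -:()")
            return metric, rest
    return metric, ""


def write_result_workbook(study: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a study table to a two-tab workbook (Kinetics / Contacts).

    Column headers follow the "Metric | condition" convention; each row is
    one photoreceptor of that condition.
    """
    path = Path(path)
    pretty = {
        "displacement": "Displacement", "trajectory": "Trajectory", "size": "Size",
        "max_speed": "Maximum Speed", "directionality": "Directionality",
        "contact_proportion": "Proportion", "n_contacting": "Number",
    }
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        # fixed timestamps keep reruns bit-identical
        writer.book.properties.created = datetime.datetime(2000, 1, 1)
        writer.book.properties.modified = datetime.datetime(2000, 1, 1)
        for sheet, metrics in (("Kinetics", KINETICS_METRICS), ("Contacts", CONTACTS_METRICS)):
            cols = {}
            for metric in metrics:
                sub = study[study["metric"] == metric]
                for cond in sub["condition"].unique():
                    vals = sub.loc[sub["condition"] == cond, "value"].to_numpy()
                    cols[f"{pretty[metric]} | {cond}"] = pd.Series(vals)
            pd.DataFrame(cols).to_excel(writer, sheet_name=sheet, index=False)
    _repack_zip_deterministic(path)


def _repack_zip_deterministic(path: Path) -> None:
    """Rewrite a zip archive with fixed entry timestamps (bit-stable reruns)."""
    entries = []
    with zipfile.ZipFile(path) as zf:
        for name in zf.namelist():
            entries.append((name, zf.read(name)))
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, payload in sorted(entries):
            if name == "docProps/core.xml":
                # openpyxl stamps save time into dcterms:modified
                payload = re.sub(
                    rb"(<dcterms:modified[^>]*>)[^<]*(</dcterms:modified>)",
                    rb"\g<1>2000-01-01T00:00:00Z\g<2>",
                    payload,
                )
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, payload)


def read_s1_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-photoreceptor result workbook into a long study table.

    Expects "Kinetics" and "Contacts" tabs in which every column heading
    names a metric and a condition ("Displacement | wt Rab8a cones", or
    the metric word followed by the condition).  Header synonyms such as
    "Maximum Speed"/"Max speed" and "Size"/"Area" are accepted; rows are
    photoreceptors, numbered per condition in file order.
    """
    path = Path(path)
    xls = pd.ExcelFile(path, engine="openpyxl")
    missing = [s for s in ("Kinetics", "Contacts") if s not in xls.sheet_names]
    if missing:
        raise ValueError(
            f"workbook {path.name} lacks required tab(s) {missing}; expected "
            "'Kinetics' (Displacement/Trajectory/Size/Maximum Speed columns per "
            "condition) and 'Contacts' (Proportion/Number columns per condition)"
        )
    rows = []
    for sheet in ("Kinetics", "Contacts"):
        df = xls.parse(sheet)
        parsed_any = False
        for col in df.columns:
            metric, cond = _split_header(str(col))
            if metric is None:
                continue
            parsed_any = True
            vals = pd.to_numeric(df[col], errors="coerce").dropna()
            for i, v in enumerate(vals):
                rows.append(
                    {"animal_id": "", "cell_id": f"{cond}/PR{i}", "condition": cond,
                     "metric": metric, "value": float(v)}
                )
        if not parsed_any:
            raise ValueError(
                f"no metric columns recognised in tab {sheet!r}; headers must "
                "name one of: " + ", ".join(sorted(_METRIC_SYNONYMS))
            )
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def grand_means(study: pd.DataFrame) -> dict[str, float]:
    """Mean of every metric over all per-photoreceptor rows, all conditions."""
    return {m: float(g["value"].mean()) for m, g in study.groupby("metric")}
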