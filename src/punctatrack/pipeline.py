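"""End-to-end orchestration: simulate -> register -> track -> quantify -> compare.

A :class:`PipelineConfig` aggregates every stage's parameters with explicit
unit suffixes (nm, s, px) and per-stage seeds; its canonical-YAML SHA-256
hash is stamped into every output file's sidecar metadata so a rerun with
the same configuration is bit-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .kinematics import (
    ContactConfig,
    PRSummary,
    TrackMetrics,
    compute_track_metrics,
    summarize_pr,
)
from .stats import compare_two
from .synthetic import (
    CellGeometry,
    FrameStack,
    MotionConfig,
    NoiseModel,
    RenderConfig,
    make_geometry,
    mutant_motion,
    mutant_render,
    render_video,
    simulate_tracks,
)
from .tracking import (
    AssignmentCosts,
    SegmentationConfig,
    Track,
    filter_tracks,
    link_tracks,
    register_stack,
    segment_stack,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition of the simulated study."""

    label: str
    n_cells: int = 13
    mutant: bool = False


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    costs: AssignmentCosts = field(default_factory=AssignmentCosts)
    contact: ContactConfig = field(default_factory=ContactConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    min_frames: int = 10
    n_frames: int = 600
    frame_interval_s: float = 1.0
    pixel_size_nm: float = 210.0
    seed: int = 0
    # drift correction is for acquisitions with stage drift; synthetic videos
    # without injected drift must skip it (with only moving puncta in channel 1,
    # registration would lock onto and cancel the particle motion itself)
    register: bool = False
    conditions: tuple[ConditionSpec, ...] = (
        ConditionSpec("wt Rab8a cones"),
        ConditionSpec("wt Rab8a rods"),
        ConditionSpec("wt Rab8ba rods"),
        ConditionSpec("mut Rab8a rods", mutant=True),
        ConditionSpec("mut Rab8ba rods", mutant=True),
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [asdict(c) for c in self.conditions]
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        # YAML 1.1 floats need a signed exponent ("1.0e+9"); tolerate the
        # common unsigned form by coercing numeric-looking strings
        def _coerce(obj):
            if isinstance(obj, dict):
                return {k: _coerce(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [_coerce(v) for v in obj]
            if isinstance(obj, str):
                try:
                    return float(obj)
                except ValueError:
                    return obj
            return obj

        kwargs = {
            k: (_coerce(v) if k != "conditions" else v) for k, v in dict(d).items()
        }
        for key, sub in (
            ("segmentation", SegmentationConfig),
            ("costs", AssignmentCosts),
            ("contact", ContactConfig),
            ("motion", MotionConfig),
            ("render", RenderConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = dict(kwargs[key])
                if key == "render" and isinstance(sub_kwargs.get("noise"), dict):
                    sub_kwargs["noise"] = NoiseModel(**sub_kwargs["noise"])
                if key == "render" and isinstance(sub_kwargs.get("drift_per_frame_px"), list):
                    sub_kwargs["drift_per_frame_px"] = tuple(sub_kwargs["drift_per_frame_px"])
                kwargs[key] = sub(**sub_kwargs)
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(
                ConditionSpec(**c) if isinstance(c, dict) else c for c in kwargs["conditions"]
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text_or_path: Union[str, Path]) -> "PipelineConfig":
        try:
            is_file = Path(text_or_path).is_file()
        except OSError:  # YAML text itself, too long for a path
            is_file = False
        text = Path(text_or_path).read_text() if is_file else str(text_or_path)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        return cls.from_dict(data)


def quantify_cell(
    stack: FrameStack,
    geometry: CellGeometry,
    config: PipelineConfig,
    condition: str = "",
) -> tuple[list[Track], list[TrackMetrics], PRSummary]:
    """Register, segment, link, filter and quantify one cell's stack."""
    if config.register and stack.n_frames >= 2:
        stack, _ = register_stack(stack)
    detections = segment_stack(stack, config.segmentation)
    result = link_tracks(detections, config.costs)
    eligible = filter_tracks(result.tracks, config.min_frames)
    if not eligible:
        logger.warning("cell %s: no tracks with >= %d frames", geometry.cell_id, config.min_frames)
    metrics = [
        compute_track_metrics(
            tr, geometry, config.contact,
            pixel_size_nm=stack.pixel_size_nm,
            frame_interval_s=stack.frame_interval_s,
        )
        for tr in eligible
    ]
    summary = summarize_pr(metrics, geometry.cell_id, condition)
    return eligible, metrics, summary


def simulate_cell(
    config: PipelineConfig,
    cell_seed: int,
    cell_id: str,
    mutant: bool = False,
    theta: Optional[float] = None,
):
    """Simulate one cell: geometry, truth tracks and rendered stack."""
    rng = np.random.default_rng(cell_seed)
    if theta is None:
        theta = float(rng.uniform(-np.pi / 6, np.pi / 6))
    geometry = make_geometry(theta, cell_id=cell_id, seed=cell_seed)
    motion = replace(config.motion, seed=int(rng.integers(2**31)))
    render = replace(config.render, seed=int(rng.integers(2**31)))
    if mutant:
        motion = mutant_motion(motion)
        render = mutant_render(render)
    truth = simulate_tracks(
        motion, geometry, config.n_frames,
        pixel_size_nm=config.pixel_size_nm,
        frame_interval_s=config.frame_interval_s,
    )
    stack = render_video(
        truth, geometry, render, n_frames=config.n_frames,
        pixel_size_nm=config.pixel_size_nm,
        frame_interval_s=config.frame_interval_s,
    )
    return geometry, truth, stack


#: (metric, study-table key, test) pairs compared between wt and mutant;
#: kinetic parameters use Student's t, contact parameters Mann-Whitney U.
WT_MUT_TESTS = [
    ("displacement", "student_t"),
    ("trajectory", "student_t"),
    ("size", "student_t"),
    ("max_speed", "student_t"),
    ("directionality", "student_t"),
    ("contact_proportion", "mann_whitney_u"),
    ("n_contacting", "mann_whitney_u"),
]


def compare_study(study) -> list[tuple[str, "object"]]:
    """Pairwise wt-vs-mutant comparisons per metric, matched by paralog.

    Pairs every condition labelled mutant ("mut ..."/"cc2d2a ...") with the
    wild-type condition sharing the remaining label words, mirroring the
    study's per-paralog comparisons.
    """
    results = []
    conditions = list(dict.fromkeys(study["condition"]))
    wt = [c for c in conditions if not _is_mutant_label(c)]
    mut = [c for c in conditions if _is_mutant_label(c)]
    for m in mut:
        tail = _label_tail(m)
        partners = [c for c in wt if _label_tail(c) == tail]
        if not partners:
            continue
        w = partners[0]
        for metric, test in WT_MUT_TESTS:
            a = study.query("condition == @w and metric == @metric")["value"].dropna().to_numpy()
            b = study.query("condition == @m and metric == @metric")["value"].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            results.append((metric, compare_two(a, b, test=test, labels=(w, m))))
    return results


def _is_mutant_label(label: str) -> bool:
    l = label.lower()
    return l.startswith("mut") or "cc2d2a" in l or "-/-" in l


def _label_tail(label: str) -> str:
    words = [w for w in label.lower().replace("-/-", " ").split() if w not in ("wt", "mut", "mutant", "cc2d2a")]
    return " ".join(words)


def _concat_nonempty(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    non_empty = [f for f in frames if not f.empty]
    if not non_empty:
        return frames[0]
    return pd.concat(non_empty, ignore_index=True)


def run_pipeline(config: PipelineConfig, out_dir: Union[str, Path]) -> dict:
    """Run the full simulated study and write the result bundle.

    Writes tracks, per-track metrics, per-photoreceptor summaries and
    wt-vs-mutant comparisons as CSV, the study table workbook, a run log
    and a metadata sidecar carrying the config hash and seeds.  Rerunning
    with an identical config produces byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    summaries: list[PRSummary] = []
    animal_ids: list[str] = []
    all_metrics = []
    all_tracks = []
    log_lines = [f"config_hash={config.config_hash}", f"seed={config.seed}"]
    for cond in config.conditions:
        for i in range(cond.n_cells):
            cell_seed = int(master.integers(2**31))
            cell_id = f"{cond.label}/PR{i}"
            geometry, truth, stack = simulate_cell(config, cell_seed, cell_id, mutant=cond.mutant)
            tracks, metrics, summary = quantify_cell(stack, geometry, config, cond.label)
            summaries.append(summary)
            # 3-4 cells are drawn per animal in the study design
            animal_ids.append(f"{cond.label}/animal{i // 4}")
            all_metrics.append((cell_id, metrics))
            all_tracks.append((cell_id, tracks))
            log_lines.append(
                f"{cell_id}: seed={cell_seed} n_truth={len(truth)} "
                f"n_eligible={len(tracks)} "
                f"n_undef_dir={summary.n_undefined_directionality}"
            )
            if summary.n_tracks == 0:
                log_lines.append(f"{cell_id}: WARNING no eligible tracks")

    track_frames = []
    for cell_id, tracks in all_tracks:
        df = pio.tracks_to_frame(tracks)
        df.insert(0, "cell_id", cell_id)
        track_frames.append(df)
    tracks_df = _concat_nonempty(track_frames)
    metrics_df = _concat_nonempty([pio.metrics_to_frame(m, cell_id) for cell_id, m in all_metrics])
    summary_df = pio.summaries_to_frame(summaries)
    study = pio.summaries_to_study_table(summaries, animal_ids)
    comparisons = compare_study(study)
    comp_df = pio.comparisons_to_frame(comparisons)

    tracks_df.to_csv(out / "tracks.csv", index=False)
    metrics_df.to_csv(out / "metrics.csv", index=False)
    summary_df.to_csv(out / "pr_summary.csv", index=False)
    comp_df.to_csv(out / "comparisons.csv", index=False)
    pio.write_result_workbook(study, out / "study_table.xlsx")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    meta = {"config_hash": config.config_hash, "seed": config.seed, "config": config.to_dict()}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return {
        "summaries": summaries,
        "study": study,
        "comparisons": comparisons,
        "metrics": metrics_df,
        "out_dir": out,
    }
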