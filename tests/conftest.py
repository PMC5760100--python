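"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from punctatrack.synthetic import TruthTrack
from punctatrack.tracking import Detection, Track


def make_track(positions_px, pixel_size_nm: float = 210.0, pixel_counts=None,
               start_frame: int = 0, track_id: int = 0) -> Track:
    """Build a Track directly from (x, y) pixel barycenters."""
    positions_px = np.atleast_2d(np.asarray(positions_px, dtype=float))
    if pixel_counts is None:
        pixel_counts = [2] * len(positions_px)
    dets = [
        Detection(
            frame=start_frame + i,
            barycenter_px=(float(x), float(y)),
            barycenter_nm=(float(x) * pixel_size_nm, float(y) * pixel_size_nm),
            pixel_count=int(pixel_counts[i]),
            pixel_set=np.zeros((int(pixel_counts[i]), 2), dtype=int),
        )
        for i, (x, y) in enumerate(positions_px)
    ]
    return Track(track_id=track_id, detections=dets)


def truth_to_track(truth: TruthTrack, pixel_size_nm: float = 210.0, track_id: int = 0) -> Track:
    """Turn a ground-truth trajectory into a Track (barycenter = true position)."""
    return make_track(
        truth.positions_nm / pixel_size_nm,
        pixel_size_nm=pixel_size_nm,
        start_frame=truth.birth_frame,
        track_id=track_id,
    )


def enumerate_pair_matchings(prev_xy, curr_xy, costs):
    """Exhaustively enumerate all partial matchings between two frames.

    Independent oracle for the per-frame-pair assignment: recursion over
    all injective partial matchings, each unmatched earlier detection
    paying the disappearance cost and each unmatched later detection the
    appearance cost.  Returns (minimal cost, argmin set of (i, j) pairs).
    """
    prev_xy = [tuple(p) for p in prev_xy]
    curr_xy = [tuple(p) for p in curr_xy]
    n_p, n_c = len(prev_xy), len(curr_xy)
    best = [float("inf"), None]

    def pair_cost(i: int, j: int) -> float:
        d2 = (prev_xy[i][0] - curr_xy[j][0]) ** 2 + (prev_xy[i][1] - curr_xy[j][1]) ** 2
        if d2 > costs.gating_radius_px**2:
            return float("inf")
        return costs.transition_weight * d2

    def recurse(i: int, used: frozenset, acc: float, pairs: tuple):
        if i == n_p:
            total = acc + costs.appearance_cost * (n_c - len(used))
            if total < best[0]:
                best[0], best[1] = total, set(pairs)
            return
        recurse(i + 1, used, acc + costs.disappearance_cost, pairs)
        for j in range(n_c):
            if j in used:
                continue
            c = pair_cost(i, j)
            if c < float("inf"):
                recurse(i + 1, used | {j}, acc + c, pairs + ((i, j),))

    recurse(0, frozenset(), 0.0, ())
    return best[0], best[1]


def links_from_tracks(tracks, detections_per_frame):
    """Extract the set of (frame, i, j) links realised by a track set."""
    index_of = {}
    for t, dets in enumerate(detections_per_frame):
        for i, d in enumerate(dets):
            index_of[id(d)] = (t, i)
    links = set()
    for tr in tracks:
        for a, b in zip(tr.detections, tr.detections[1:]):
            ta, ia = index_of[id(a)]
            tb, ib = index_of[id(b)]
            assert tb == ta + 1
            links.add((ta, ia, ib))
    return links


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
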