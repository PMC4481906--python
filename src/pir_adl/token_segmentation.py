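"""Token-based segmentation of the feature grid.

Every grid row is encoded as a *token*: a bitmask over the canonical room
order with bit r set iff room r's PIR fired at that row (0 = motionless).
A change point is set whenever a *different active* constellation appears;
transitions into the motionless state are neglected, and a return from
motionless to the unchanged constellation does not split.  The periods
between change points are compressed to single feature rows (mean, variance
and other key figures per feature) carrying their own token plus the tokens
of the neighbouring periods as context.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .home import GRID_STEP_S, NO_ACTIVITY
from .preprocess import TRUTH_COLUMNS, room_pir_matrix

MOTIONLESS = 0

#: Sentinel token for the context of the first/last segment.
BOUNDARY_TOKEN = -1

#: Statistics computed per feature column when compressing a period.
SEGMENT_STATS = ("mean", "var", "min", "max", "first", "last")


def compute_tokens(grid: pd.DataFrame) -> np.ndarray:
    """One token per grid row: bitmask of firing rooms in canonical order."""
    mat, rooms = room_pir_matrix(grid)
    weights = (1 << np.arange(len(rooms), dtype=np.int64))
    return mat.astype(np.int64) @ weights


def detect_token_changepoints(tokens: np.ndarray) -> np.ndarray:
    """Row indices at which a different active token appears.

    The first active token of the sequence opens the first period and is not
    itself a change point; motionless rows never split.
    """
    tokens = np.asarray(tokens)
    if tokens.size == 0:
        raise ValueError("empty token sequence")
    active_idx = np.flatnonzero(tokens != MOTIONLESS)
    if active_idx.size == 0:
        return np.array([], dtype=np.int64)
    vals = tokens[active_idx]
    changed = vals[1:] != vals[:-1]
    return active_idx[1:][changed].astype(np.int64)


def _modal_label(codes: np.ndarray, n_labels: int) -> int:
    """Modal code; ties broken in favour of the code seen latest."""
    counts = np.bincount(codes, minlength=n_labels)
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if len(candidates) == 1:
        return int(candidates[0])
    last_seen = {c: i for i, c in enumerate(codes)}
    return int(max(candidates, key=lambda c: last_seen[int(c)]))


def compress_segments(
    grid: pd.DataFrame,
    changepoints: np.ndarray,
    tokens: np.ndarray | None = None,
) -> pd.DataFrame:
    """Compress inter-change-point periods into single feature rows.

    Every feature column yields mean, population variance (0 for single-row
    periods), min, max and first/last values.  Each segment carries its token
    (first active token of the period, 0 if none), the neighbouring segments'
    tokens (−1 at the stream boundaries), the modal ground-truth label, the
    majority visitor flag and the activity degree (fraction of rows with any
    PIR firing).
    """
    n = len(grid)
    if n == 0:
        raise ValueError("cannot compress an empty grid")
    cps = np.asarray(changepoints, dtype=np.int64)
    if cps.size and (np.any(np.diff(cps) <= 0) or cps[0] <= 0 or cps[-1] >= n):
        raise ValueError("change points must be strictly ascending within (0, n)")
    bounds = np.concatenate([[0], cps, [n]])
    starts, ends = bounds[:-1], bounds[1:]
    counts = (ends - starts).astype(float)

    if tokens is None:
        tokens = compute_tokens(grid)
    feat_cols = [c for c in grid.columns if c not in TRUTH_COLUMNS and c != "weekday"]
    X = grid[feat_cols].to_numpy(dtype=float)

    sums = np.add.reduceat(X, starts, axis=0)
    sumsq = np.add.reduceat(X * X, starts, axis=0)
    mean = sums / counts[:, None]
    var = np.clip(sumsq / counts[:, None] - mean**2, 0.0, None)
    mins = np.minimum.reduceat(X, starts, axis=0)
    maxs = np.maximum.reduceat(X, starts, axis=0)
    firsts = X[starts]
    lasts = X[ends - 1]

    any_pir, _rooms = room_pir_matrix(grid)
    any_fire = any_pir.max(axis=1).astype(float)
    degree = np.add.reduceat(any_fire, starts) / counts

    seg_tokens = np.empty(len(starts), dtype=np.int64)
    for k, (s, e) in enumerate(zip(starts, ends)):
        seg = tokens[s:e]
        nz = seg[seg != MOTIONLESS]
        seg_tokens[k] = nz[0] if nz.size else MOTIONLESS
    prev_tok = np.concatenate([[BOUNDARY_TOKEN], seg_tokens[:-1]])
    next_tok = np.concatenate([seg_tokens[1:], [BOUNDARY_TOKEN]])

    if "truth_label" in grid.columns:
        cat = pd.Categorical(grid["truth_label"])
        codes = np.asarray(cat.codes)
        labels = [
            str(cat.categories[_modal_label(codes[s:e], len(cat.categories))])
            for s, e in zip(starts, ends)
        ]
        vis = grid["truth_visitor"].to_numpy(dtype=float)
        seg_vis = (np.add.reduceat(vis, starts) / counts >= 0.5).astype(np.int64)
    else:
        labels = [NO_ACTIVITY] * len(starts)
        seg_vis = np.zeros(len(starts), dtype=np.int64)

    times = grid.index.to_numpy()
    out = pd.DataFrame({
        "start_s": times[starts],
        "end_s": times[ends - 1] + GRID_STEP_S,
        "duration_s": counts * GRID_STEP_S,
        "token": seg_tokens,
        "prev_token": prev_tok,
        "next_token": next_tok,
        "activity_degree": degree,
        "weekday": grid["weekday"].to_numpy()[starts] if "weekday" in grid.columns
                   else np.zeros(len(starts), dtype=np.int64),
        "truth_label": labels,
        "truth_visitor": seg_vis,
    })
    stats = {"mean": mean, "var": var, "min": mins, "max": maxs, "first": firsts, "last": lasts}
    for stat in SEGMENT_STATS:
        block = pd.DataFrame(stats[stat], columns=[f"{c}_{stat}" for c in feat_cols])
        out = pd.concat([out, block], axis=1)
    out.index.name = "segment_id"
    return out


def segment_tokens(grid: pd.DataFrame) -> pd.DataFrame:
    """Full token pipeline: tokens, change points, compression."""
    tokens = compute_tokens(grid)
    cps = detect_token_changepoints(tokens)
    return compress_segments(grid, cps, tokens=tokens)
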