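"""Frame-to-frame trajectory linking with gap closing.

Localizations are assembled into tracks by optimal bipartite assignment between
consecutive frames: among all candidate pairs closer than ``max_disp`` the
assignment minimizing total squared displacement is kept (Hungarian algorithm,
deterministic, order-independent). Track ends that find no continuation stay
eligible for ``max_gap`` further frames, so short blinking gaps are closed with
the same search radius. Tracks with fewer than ``min_len`` detections are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["LinkParams", "link"]


@dataclass(frozen=True)
class LinkParams:
    """Linking thresholds (defaults match 5 px = 725 nm at 145 nm pixels)."""

    max_disp: float = 0.725   # um, largest allowed frame-to-frame displacement
    max_gap: int = 3          # frames a track end survives unmatched
    min_len: int = 2          # minimum detections per reported track
    pixel_size: float = 0.145  # um, for callers converting pixel units

    def __post_init__(self) -> None:
        if self.max_disp <= 0 or self.pixel_size <= 0:
            raise ValueError("max_disp and pixel_size must be positive")
        if self.max_gap < 0 or self.min_len < 1:
            raise ValueError("max_gap must be >= 0 and min_len >= 1")


def link(localizations: pd.DataFrame, params: LinkParams | None = None) -> pd.DataFrame:
    """Assemble a localization table into tracks.

    Parameters
    ----------
    localizations : DataFrame
        Columns ``frame, x_um, y_um``, sorted by frame (any further columns are
        carried through). Duplicate positions are permitted.
    params : LinkParams, optional

    Returns
    -------
    DataFrame with columns ``track_id, frame, x_um, y_um`` (plus carried
    columns), sorted by (track_id, frame). Track ids are assigned in order of
    first appearance, ties broken by (frame, x, y).
    """
    if params is None:
        params = LinkParams()
    cols = ["frame", "x_um", "y_um"]
    if localizations is None or len(localizations) == 0:
        return pd.DataFrame(columns=["track_id", *cols])
    loc = localizations.sort_values(["frame", "x_um", "y_um"], kind="stable").reset_index(drop=True)
    frames = loc["frame"].to_numpy()
    if np.any(np.diff(frames) < 0):  # defensive; sort above guarantees this
        raise ValueError("localizations must be sorted by frame")
    xy = loc[["x_um", "y_um"]].to_numpy(dtype=float)

    # active track ends: row index of last detection, per track
    track_of_row = np.full(len(loc), -1, dtype=np.int64)
    open_rows: list[int] = []      # row index of each open track end
    open_frame: list[int] = []     # frame of that end
    n_tracks = 0

    for f in np.unique(frames):
        rows = np.flatnonzero(frames == f)
        keep = [i for i, fr in enumerate(open_frame) if f - fr <= params.max_gap + 1]
        open_rows = [open_rows[i] for i in keep]
        open_frame = [open_frame[i] for i in keep]

        assigned_new = np.zeros(rows.size, dtype=bool)
        if open_rows and rows.size:
            prev_xy = xy[open_rows]
            d2 = ((prev_xy[:, None, :] - xy[rows][None, :, :]) ** 2).sum(axis=2)
            feasible = d2 <= params.max_disp**2
            # forbid infeasible pairs with a large finite cost so the Hungarian
            # solve stays well posed, then drop any forbidden matches after
            big = 1e12
            cost = np.where(feasible, d2, big)
            ri, ci = linear_sum_assignment(cost)
            used_ends = []
            for a, b in zip(ri, ci):
                if feasible[a, b]:
                    row = rows[b]
                    track_of_row[row] = track_of_row[open_rows[a]]
                    open_rows[a] = int(row)
                    open_frame[a] = int(f)
                    assigned_new[b] = True
                    used_ends.append(a)

        for i, b in enumerate(np.flatnonzero(~assigned_new)):
            row = rows[b]
            track_of_row[row] = n_tracks
            open_rows.append(int(row))
            open_frame.append(int(f))
            n_tracks += 1

    out = loc.copy()
    out.insert(0, "track_id", track_of_row)
    sizes = out.groupby("track_id")["frame"].transform("size")
    out = out[sizes >= params.min_len]
    # renumber surviving tracks consecutively, in order of first appearance
    first = out.groupby("track_id")["frame"].transform("min")
    order = out[["track_id"]].assign(first=first).drop_duplicates("track_id")
    remap = {t: i for i, t in enumerate(order.sort_values(["first", "track_id"])["track_id"])}
    out = out.assign(track_id=out["track_id"].map(remap))
    return out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
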