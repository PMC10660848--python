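"""Epoch-coded hypnograms: IO, cycle segmentation, per-cycle measures.

Stage codes are ``W, N1, N2, SWS, REM`` over consecutive (default 30 s)
epochs, optionally with an eye-movement count per epoch.  Segmentation
follows standard visual-scoring conventions: an NREM episode runs from the
first two consecutive stage-2 epochs to the first REM epoch of the cycle; a
REM episode is the interval between consecutive NREM episodes (or between
the last NREM episode and the final awakening); a cycle is completed by an
NREM episode of at least 10 min followed by a REM episode of at least
3 min, with no REM minimum for the last cycle of the night.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "Hypnogram",
    "CycleBounds",
    "CycleSegmentation",
    "read_hypnograms",
    "read_hypnogram",
    "write_hypnograms",
    "segment_cycles",
    "per_cycle_measures",
    "sleep_efficiency",
]

STAGES = ("W", "N1", "N2", "SWS", "REM")

#: night-filter thresholds (%): standard inclusion and high-quality sleep
EFFICIENCY_STANDARD = 85.0
EFFICIENCY_HIGH = 93.0


@dataclass
class Hypnogram:
    """One night of epoch-coded sleep stages.

    ``stages`` is a sequence of codes from :data:`STAGES`; ``em_counts``
    (optional) gives eye movements per epoch and must match in length.
    """

    stages: np.ndarray
    night_id: str = "night"
    epoch_len_s: float = 30.0
    em_counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="U3")
        bad = ~np.isin(self.stages, STAGES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"unknown stage code {self.stages[i]!r} at epoch {i} "
                f"(valid: {STAGES})"
            )
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be > 0")
        if self.em_counts is not None:
            self.em_counts = np.asarray(self.em_counts, dtype=int)
            if self.em_counts.shape != self.stages.shape:
                raise ValueError("em_counts must match stages in length")
            if np.any(self.em_counts < 0):
                raise ValueError("em_counts must be non-negative")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def epochs_per_min(self) -> float:
        return 60.0 / self.epoch_len_s

    def minutes(self, n_epochs: int) -> float:
        return n_epochs * self.epoch_len_s / 60.0


def read_hypnograms(path) -> list[Hypnogram]:
    """Read all nights from a delimited stage file.

    Expected columns (header required): ``night_id, epoch_index, stage``
    and optionally ``em_count``.  Epoch indices must be contiguous within
    each night.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"night_id", "epoch_index", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)} in {path}")
    bad = ~df["stage"].isin(STAGES)
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based, after header
        raise ValueError(
            f"unknown stage {df.loc[df.index[bad][0], 'stage']!r} "
            f"at row {row} of {path}"
        )
    if "em_count" in df.columns and (df["em_count"] < 0).any():
        raise ValueError(f"negative em_count in {path}")
    out = []
    for night_id, g in df.groupby("night_id", sort=False):
        idx = g["epoch_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
            raise ValueError(f"non-contiguous epoch indices for night {night_id}")
        out.append(
            Hypnogram(
                stages=g["stage"].to_numpy(),
                night_id=str(night_id),
                em_counts=g["em_count"].to_numpy() if "em_count" in g else None,
            )
        )
    return out


def read_hypnogram(path, night_id: Optional[str] = None) -> Hypnogram:
    """Read a single night (the only one, or the one named)."""
    nights = read_hypnograms(path)
    if night_id is not None:
        for h in nights:
            if h.night_id == night_id:
                return h
        raise ValueError(f"night {night_id!r} not found in {path}")
    if len(nights) != 1:
        raise ValueError(
            f"{path} holds {len(nights)} nights; pass night_id to pick one"
        )
    return nights[0]


def write_hypnograms(nights, path) -> None:
    """Write one or more nights as a comma-delimited stage file."""
    if isinstance(nights, Hypnogram):
        nights = [nights]
    frames = []
    for h in nights:
        d = {
            "night_id": h.night_id,
            "epoch_index": np.arange(h.n_epochs),
            "stage": h.stages,
        }
        if h.em_counts is not None:
            d["em_count"] = h.em_counts
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass(frozen=True)
class CycleBounds:
    """Half-open epoch intervals of one cycle's episodes (REM may be absent)."""

    nrem_start: int
    nrem_end: int
    rem_start: Optional[int] = None
    rem_end: Optional[int] = None

    @property
    def complete(self) -> bool:
        return self.rem_start is not None


@dataclass
class CycleSegmentation:
    """Ordered, non-overlapping cycles plus any segmentation warnings."""

    cycles: list[CycleBounds] = field(default_factory=list)
    epoch_len_s: float = 30.0
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)


def _final_awakening(stages: np.ndarray) -> int:
    """Start of the maximal trailing run of W epochs (== n if none)."""
    i = len(stages)
    while i > 0 and stages[i - 1] == "W":
        i -= 1
    return i


def _find_two_n2(stages: np.ndarray, start: int, stop: int) -> Optional[int]:
    for i in range(start, stop - 1):
        if stages[i] == "N2" and stages[i + 1] == "N2":
            return i
    return None


def _find_rem(stages: np.ndarray, start: int, stop: int) -> Optional[int]:
    for i in range(start, stop):
        if stages[i] == "REM":
            return i
    return None


def segment_cycles(h: Hypnogram, min_nrem_min: float = 10.0,
                   min_rem_min: float = 3.0) -> CycleSegmentation:
    """Segment a hypnogram into NREM/REM cycles.

    Episodes are time intervals between anchors, so intervening wake epochs
    count toward an episode's span (:func:`per_cycle_measures` also reports
    pure-stage minutes).  A non-terminal REM run shorter than ``min_rem_min``
    does not close the cycle: it is absorbed into the ongoing NREM episode.
    A terminal NREM episode with no following REM is emitted as an
    incomplete cycle.
    """
    stages = h.stages
    seg = CycleSegmentation(epoch_len_s=h.epoch_len_s)
    per_min = h.epochs_per_min
    min_nrem_ep = int(round(min_nrem_min * per_min))
    min_rem_ep = int(round(min_rem_min * per_min))
    end = _final_awakening(stages)

    pos = 0
    while True:
        ns = _find_two_n2(stages, pos, end)
        if ns is None:
            if not seg.cycles:
                seg.warnings.append("no qualifying stage-2 onset found")
            break
        search_from = ns
        while True:
            r = _find_rem(stages, search_from, end)
            if r is None:
                # terminal NREM with no REM: incomplete cycle
                if end > ns:
                    seg.cycles.append(CycleBounds(ns, end))
                pos = end
                break
            nxt = _find_two_n2(stages, r, end)
            if nxt is None:
                # terminal REM episode: runs to final awakening, no minimum
                if r - ns >= min_nrem_ep:
                    seg.cycles.append(CycleBounds(ns, r, r, end))
                else:
                    seg.warnings.append(
                        f"terminal cycle dropped: NREM {h.minutes(r - ns):.1f} "
                        f"min < {min_nrem_min} min"
                    )
                pos = end
                break
            if r - ns < min_nrem_ep or nxt - r < min_rem_ep:
                # short NREM, or sub-threshold mid-night REM: keep the cycle
                # open and absorb the run into the ongoing NREM episode
                if nxt - r < min_rem_ep and r - ns >= min_nrem_ep:
                    seg.warnings.append(
                        f"REM run of {h.minutes(nxt - r):.1f} min at epoch {r} "
                        f"< {min_rem_min} min: merged into NREM episode"
                    )
                search_from = nxt
                continue
            seg.cycles.append(CycleBounds(ns, r, r, nxt))
            pos = nxt
            break
        if pos >= end:
            break
    return seg


def per_cycle_measures(seg: CycleSegmentation, h: Hypnogram,
                       pure_stage: bool = False) -> pd.DataFrame:
    """Per-cycle sleep measures from a segmentation of the same hypnogram.

    Columns: cycle ``n``, episode boundaries, ``nrem_min``, ``rem_min``,
    ``sws_min`` (SWS epochs inside the NREM episode — the NREM intensity
    proxy) and ``rem_density`` (eye movements per REM minute; NaN when the
    hypnogram carries no counts).  ``pure_stage`` adds wake-free episode
    minutes.
    """
    rows = []
    for k, c in enumerate(seg.cycles, start=1):
        nrem_slice = h.stages[c.nrem_start:c.nrem_end]
        row = {
            "n": k,
            "nrem_start": c.nrem_start,
            "nrem_end": c.nrem_end,
            "rem_start": c.rem_start,
            "rem_end": c.rem_end,
            "nrem_min": h.minutes(c.nrem_end - c.nrem_start),
            "sws_min": h.minutes(int(np.sum(nrem_slice == "SWS"))),
        }
        if c.complete:
            rem_len = c.rem_end - c.rem_start
            row["rem_min"] = h.minutes(rem_len)
            if h.em_counts is not None and row["rem_min"] > 0:
                total = int(np.sum(h.em_counts[c.rem_start:c.rem_end]))
                row["rem_em_total"] = total
                row["rem_density"] = total / row["rem_min"]
            else:
                row["rem_em_total"] = np.nan
                row["rem_density"] = np.nan
        else:
            row["rem_min"] = np.nan
            row["rem_em_total"] = np.nan
            row["rem_density"] = np.nan
        if pure_stage:
            row["nrem_pure_min"] = h.minutes(int(np.sum(
                np.isin(nrem_slice, ("N1", "N2", "SWS")))))
            if c.complete:
                rem_slice = h.stages[c.rem_start:c.rem_end]
                row["rem_pure_min"] = h.minutes(int(np.sum(rem_slice == "REM")))
            else:
                row["rem_pure_min"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def sleep_efficiency(h: Hypnogram) -> float:
    """Percentage of epochs spent asleep (non-W) over the whole recording."""
    if h.n_epochs == 0:
        raise ValueError("empty hypnogram")
    return 100.0 * float(np.sum(h.stages != "W")) / h.n_epochs
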