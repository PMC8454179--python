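"""Windowed GC-content profiling and elevated-GC island detection.

Fungal centromeres are extended AT-rich tracts; mobile elements embedded
in them show up as local islands of elevated GC.  This module computes
per-window GC tracks (the profile a genome-browser style min/mean/max
display is binned from) and finds contiguous islands whose GC exceeds the
enclosing region's mean by a contrast margin.

GC values are percentages in [0, 100].  The N policy controls the
denominator: ``exclude-N`` (default) drops N residues from it,
``count-N-as-AT`` keeps them (counting them as AT-like).  An all-N
sequence or window has no defined GC and is reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_GC_SET = frozenset("GCgcSs")


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return boolean arrays (is_gc, is_n) for a DNA string."""
    a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (a == ord("G")) | (a == ord("C"))
    is_n = a == ord("N")
    return is_gc, is_n


def gc_content(seq: str, n_policy: str = "exclude-N") -> float:
    """GC percentage of ``seq``: 100·(G+C)/denominator.

    Returns NaN for an all-N sequence under ``exclude-N`` (no defined
    denominator).  Raises on an empty sequence.
    """
    if not seq:
        raise ValueError("gc_content requires a non-empty sequence")
    is_gc, is_n = _encode(seq)
    gc = int(is_gc.sum())
    if n_policy == "exclude-N":
        denom = len(seq) - int(is_n.sum())
        if denom == 0:
            return float("nan")
    elif n_policy == "count-N-as-AT":
        denom = len(seq)
    else:
        raise ValueError(f"unknown n_policy {n_policy!r}")
    return 100.0 * gc / denom


def at_content(seq: str, n_policy: str = "exclude-N") -> float:
    gc = gc_content(seq, n_policy=n_policy)
    return float("nan") if np.isnan(gc) else 100.0 - gc


@dataclass
class GCProfile:
    """Per-window GC percentages along one contig.

    ``starts[i]`` is the 0-based start of window ``i``; every window has
    length ``window``; windows are spaced ``step`` apart and the trailing
    partial window is dropped, so the number of windows is
    ``floor((L - window)/step) + 1``.
    """

    contig_id: str
    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig_id,
                "start": self.starts,
                "end": self.starts + self.window,
                "gc": self.values,
            }
        )


def windowed_gc(
    seq: str,
    window: int = 25,
    step: int | None = None,
    contig_id: str = "",
    n_policy: str = "exclude-N",
) -> GCProfile:
    """GC profile over fixed-size windows (default 25 bp, non-overlapping).

    Computed from cumulative sums so whole-chromosome profiles are cheap.
    All-N windows yield NaN under ``exclude-N``.
    """
    if window < 1 or (step is not None and step < 1):
        raise ValueError("window and step must be >= 1")
    step = window if step is None else step
    L = len(seq)
    if window > L:
        raise ValueError(f"window ({window}) exceeds sequence length ({L})")
    is_gc, is_n = _encode(seq)
    cgc = np.concatenate(([0], np.cumsum(is_gc)))
    cn = np.concatenate(([0], np.cumsum(is_n)))
    n_windows = (L - window) // step + 1
    starts = np.arange(n_windows) * step
    gc = cgc[starts + window] - cgc[starts]
    nn = cn[starts + window] - cn[starts]
    if n_policy == "exclude-N":
        denom = (window - nn).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, 100.0 * gc / denom, np.nan)
    elif n_policy == "count-N-as-AT":
        vals = 100.0 * gc / window
    else:
        raise ValueError(f"unknown n_policy {n_policy!r}")
    return GCProfile(contig_id=contig_id, window=window, step=step, starts=starts, values=vals)


def summarize_bins(profile: GCProfile, bin: int) -> pd.DataFrame:
    """Per-bin min/mean/max of the window values (display binning).

    ``bin`` is in bp and must be >= the profile's window size.  Windows are
    assigned to bins by their start coordinate; NaN windows are ignored
    within a bin.
    """
    if bin < profile.window:
        raise ValueError(f"bin ({bin}) must be >= window ({profile.window})")
    idx = profile.starts // bin
    df = pd.DataFrame({"bin": idx, "gc": profile.values})
    agg = df.groupby("bin")["gc"].agg(["min", "mean", "max"]).reset_index()
    agg["start"] = agg["bin"] * bin
    agg["end"] = np.minimum((agg["bin"] + 1) * bin, profile.starts[-1] + profile.window)
    return agg[["start", "end", "min", "mean", "max"]]


@dataclass(frozen=True)
class GCIsland:
    """A run of windows whose GC exceeds the enclosing region mean."""

    start: int
    end: int
    mean_gc: float
    contrast: float  # mean_gc minus enclosing-region mean


def find_gc_islands(
    seq: str,
    region: tuple[int, int] | None = None,
    min_len: int = 5000,
    min_contrast: float = 10.0,
    window: int = 200,
    merge_gap: int = 500,
) -> list[GCIsland]:
    """Find elevated-GC islands inside a (typically AT-rich) region.

    Windows whose GC exceeds the region mean by ``min_contrast`` points are
    flagged; flagged runs separated by <= ``merge_gap`` bp are merged; a
    merged run is emitted when it is >= ``min_len`` bp AND its overall GC
    still clears the contrast margin (this second check discards chains of
    borderline noise windows).  Coordinates are relative to the contig
    (absolute), 0-based half-open.
    """
    L = len(seq)
    if region is None:
        region = (0, L)
    r0, r1 = region
    if not (0 <= r0 < r1 <= L):
        raise ValueError(f"region [{r0}, {r1}) outside contig of length {L}")
    sub = seq[r0:r1]
    if r1 - r0 < window:
        return []
    region_mean = gc_content(sub)
    if np.isnan(region_mean):
        return []
    prof = windowed_gc(sub, window=window)
    flagged = np.nan_to_num(prof.values, nan=-1.0) >= region_mean + min_contrast
    runs: list[list[int]] = []  # [start, end) in bp within sub
    for s in np.flatnonzero(flagged):
        ws, we = int(prof.starts[s]), int(prof.starts[s]) + window
        if runs and ws - runs[-1][1] <= merge_gap:
            runs[-1][1] = we
        else:
            runs.append([ws, we])
    islands = []
    for s, e in runs:
        if e - s < min_len:
            continue
        mean = gc_content(sub[s:e])
        contrast = mean - region_mean
        if contrast < min_contrast:
            continue
        islands.append(GCIsland(start=r0 + s, end=r0 + e, mean_gc=mean, contrast=contrast))
    return islands
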