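"""Windowed coverage depth and normalized copy-number profiles.

Per-site depth tables (the 3-column output of ``samtools depth``: sequence
name, 1-based position, depth) are averaged over non-overlapping 1000-bp
windows.  Positions absent from the table are zero-coverage (the producing
tool omits them by default).  Window means divided by the median window
mean give a copy-number profile that is comparable across samples and
robust to the CNV segments themselves; windows overlapping annotated
repeats are flagged so repeat-associated depth structure is visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class DepthTable:
    seq_id: str
    positions: np.ndarray  # 1-based, strictly increasing
    depths: np.ndarray

    @property
    def max_position(self) -> int:
        return int(self.positions.max()) if self.positions.size else 0


@dataclass
class DepthProfile:
    """Non-overlapping window means over the genome (0-based half-open)."""

    starts: np.ndarray
    ends: np.ndarray
    mean_depth: np.ndarray
    norm_copy: np.ndarray | None = None
    is_repeat: np.ndarray | None = None
    genome_median_depth: float | None = None

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"start": self.starts, "end": self.ends,
                           "mean_depth": self.mean_depth})
        df["norm_copy"] = self.norm_copy if self.norm_copy is not None else np.nan
        df["is_repeat"] = (self.is_repeat if self.is_repeat is not None
                           else False)
        return df


def read_depth(path: str | Path, seq_id: str | None = None) -> DepthTable:
    """Read a samtools-depth style 3-column TSV."""
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["seq_id", "pos", "depth"],
                         dtype={"pos": np.int64, "depth": np.int64})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed depth table {path}: {exc}") from exc
    if seq_id is not None:
        df = df[df["seq_id"] == seq_id]
    if df.empty:
        raise ValueError(f"no depth records in {path}")
    if (df["depth"] < 0).any():
        line = int(df.index[df["depth"] < 0][0]) + 1
        raise ValueError(f"negative depth at line {line} of {path}")
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 1
        raise ValueError(f"non-positive position at line {line} of {path}")
    df = df.sort_values("pos")
    return DepthTable(seq_id=str(df["seq_id"].iloc[0]),
                      positions=df["pos"].to_numpy(),
                      depths=df["depth"].to_numpy())


def window_means(table: DepthTable, genome_length: int, window: int = 1000,
                 drop_partial: bool = False) -> DepthProfile:
    """Mean depth of non-overlapping windows tiling the genome from position 1.

    Positions missing from the table count as zero depth; the final partial
    window is averaged over its own length (or dropped with
    ``drop_partial=True``).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    if table.max_position > genome_length:
        raise ValueError(
            f"depth position {table.max_position} exceeds genome length "
            f"{genome_length}")
    full = np.zeros(genome_length, dtype=np.float64)
    full[table.positions - 1] = table.depths
    starts = np.arange(0, genome_length, window, dtype=np.int64)
    ends = np.minimum(starts + window, genome_length)
    sums = np.add.reduceat(full, starts)
    means = sums / (ends - starts)
    if drop_partial and ends[-1] - starts[-1] < window:
        starts, ends, means = starts[:-1], ends[:-1], means[:-1]
    return DepthProfile(starts=starts, ends=ends, mean_depth=means)


def normalize_profile(profile: DepthProfile) -> DepthProfile:
    """norm_copy = window mean / median of all window means."""
    median = float(np.median(profile.mean_depth))
    profile.genome_median_depth = median
    if median == 0:
        log.warning("median window depth is 0; norm_copy undefined")
        profile.norm_copy = np.full(profile.n_windows, np.nan)
    else:
        profile.norm_copy = profile.mean_depth / median
    return profile


def overlay_repeats(profile: DepthProfile,
                    repeats: Sequence[Interval]) -> DepthProfile:
    """Flag windows overlapping any repeat interval by at least 1 bp."""
    flags = np.zeros(profile.n_windows, dtype=bool)
    for s, e in repeats:
        flags |= (profile.starts < e) & (profile.ends > s)
    profile.is_repeat = flags
    return profile


def flag_cnv_windows(profile: DepthProfile,
                     bounds: tuple[float, float] = (0.5, 2.0)) -> np.ndarray:
    """Simple fold-change flag: norm_copy outside [lo, hi]."""
    if profile.norm_copy is None:
        raise ValueError("profile not normalized")
    return (profile.norm_copy < bounds[0]) | (profile.norm_copy > bounds[1])


def write_profile(profile: DepthProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def plot_profile(profile: DepthProfile, path: str | Path,
                 title: str | None = None) -> None:
    """Depth-vs-window plot with repeat windows highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    mid = (profile.starts + profile.ends) / 2
    ax.plot(mid, profile.mean_depth, lw=0.8, color="black")
    if profile.is_repeat is not None and profile.is_repeat.any():
        rep = profile.is_repeat
        ax.scatter(mid[rep], profile.mean_depth[rep], s=6, color="crimson",
                   label="repeat", zorder=3)
        ax.legend(frameon=False)
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel("mean depth")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
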