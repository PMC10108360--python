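"""Time-block averaging: the error estimate used for per-molecule H-bond
counts and group SASA (grand mean over contiguous blocks, SD of the block
means as the error bar)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError

__all__ = ["BlockAverage", "block_average"]


@dataclass
class BlockAverage:
    """Grand mean ± SD over contiguous, equal-duration time blocks."""

    n_blocks: int
    block_means: np.ndarray
    grand_mean: float
    sd: float  # sample SD (ddof=1) over block means; NaN when n_blocks < 2
    block_duration: float  # same unit as the frame times (ps)
    n_frames_used: int
    n_frames_dropped: int

    def __str__(self) -> str:  # "0.80 ± 0.04"-style, mirroring the report tables
        return f"{self.grand_mean:.3g} ± {self.sd:.2g}"


def block_average(values, times, n_blocks: int) -> BlockAverage:
    """Split a per-frame series into ``n_blocks`` contiguous blocks.

    Frames are assiged by position: each block holds ``len(values) //
    n_blocks`` consecutive frames and remainder frames are dropped from the
    end. With uniform frame spacing dt the block duration is m·dt (e.g. a
    1500 ns span in 5 blocks gives 300 ns blocks).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if n_blocks < 1:
        raise AnalysisError("need at least one block")
    n = len(values)
    if n < n_blocks:
        raise AnalysisError(f"fewer frames ({n}) than blocks ({n_blocks})")
    m = n // n_blocks
    used = m * n_blocks
    trimmed = values[:used].reshape(n_blocks, m)
    block_means = trimmed.mean(axis=1)
    dt = float((times[-1] - times[0]) / (n - 1)) if n > 1 else 0.0
    return BlockAverage(
        n_blocks=n_blocks,
        block_means=block_means,
        grand_mean=float(block_means.mean()),
        sd=float(block_means.std(ddof=1)) if n_blocks >= 2 else float("nan"),
        block_duration=m * dt,
        n_frames_used=used,
        n_frames_dropped=n - used,
    )
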