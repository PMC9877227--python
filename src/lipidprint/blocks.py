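"""Block-averaged standard errors for correlated time series."""

from __future__ import annotations

import numpy as np

__all__ = ["block_standard_error", "DEFAULT_BLOCKS"]

DEFAULT_BLOCKS = 5


def block_standard_error(values, n_blocks: int = DEFAULT_BLOCKS) -> float:
    """SE of the mean from contiguous block means: SD(block means)/sqrt(n).

    The series is split into ``n_blocks`` contiguous, near-equal blocks
    (np.array_split); blocks shorter than one sample are dropped. A constant
    series yields 0 exactly.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    blocks = [b for b in np.array_split(x, n_blocks) if b.size > 0]
    if len(blocks) < 2:
        return 0.0
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(len(blocks)))
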