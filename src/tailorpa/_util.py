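"""Small shared helpers."""
from __future__ import annotations

import numpy as np


def rle(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode a 1-D array.

    Returns (values, starts, lengths) for maximal runs of equal values.
    """
    x = np.asarray(mask)
    if x.size == 0:
        return x[:0], np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [x.size])))
    return x[starts], starts, lengths
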