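"""The six regression targets and their fixed order."""

from __future__ import annotations

import numpy as np

#: Fixed label order: body weight (kg), shoulder width, shoulder height,
#: hip width, hip height, body length (all cm).
LABEL_NAMES: tuple[str, ...] = ("BW", "SW", "SH", "HW", "HH", "BL")

N_TARGETS = len(LABEL_NAMES)


def validate_label_vector(values) -> np.ndarray:
    """Return a validated (6,) float vector: finite and strictly positive."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size != N_TARGETS:
        raise ValueError(f"label vector must have {N_TARGETS} entries, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("label vector contains non-finite entries")
    if np.any(arr <= 0):
        raise ValueError("label vector entries must be strictly positive")
    return arr
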