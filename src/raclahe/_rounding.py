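"""Integer rounding helpers shared by the histogram enhancers.

All intensity look-up tables in this package are built by rounding
``(L - 1) * CDF`` style expressions.  The rounding convention changes the
result at exact .5 boundaries (e.g. a two-level patch whose CDF hits 0.5),
so it is configurable everywhere it matters.
"""

from __future__ import annotations

import numpy as np

ROUNDING_MODES = ("half-up", "half-even")


def round_levels(x: np.ndarray | float, mode: str = "half-up") -> np.ndarray:
    """Round ``x`` to integers under the given tie-breaking mode.

    ``half-up`` rounds .5 away from zero toward +inf (floor(x + 0.5)),
    the convention used by the worked examples in this package;
    ``half-even`` is IEEE banker's rounding (numpy's default).
    """
    if mode == "half-up":
        return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)
    if mode == "half-even":
        return np.rint(np.asarray(x, dtype=float)).astype(np.int64)
    raise ValueError(f"unknown rounding mode {mode!r}; expected one of {ROUNDING_MODES}")
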