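"""Small numeric helpers shared across modules."""
from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Any

import numpy as np


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest integer with ties going away from zero.

    This is the quantization convention used everywhere intensities are
    written to 8-bit, matching how MATLAB-style ``round`` behaves (as opposed
    to numpy's banker's rounding).
    """
    x = np.asarray(x, dtype=np.float64)
    out = np.copysign(np.floor(np.abs(x) + 0.5), x)
    if out.ndim == 0:
        return float(out)
    return out


def render_2dp(x: float) -> float:
    """Render a statistic at two decimals, ties away from zero.

    Goes through the shortest ``repr`` of the value snapped to 1e-9 so that
    binary-float artifacts (0.71499999...) do not flip a genuine .5 tie.
    """
    snapped = round(float(x), 9)
    return float(Decimal(repr(snapped)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def config_digest(obj: Any) -> str:
    """Stable short digest of a JSON-serializable configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def child_seed(base_seed: int, *salt: Any) -> int:
    """Derive a reproducible sub-seed below 2**31 from a base seed and salt."""
    blob = json.dumps([int(base_seed), *map(str, salt)]).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31 - 1)
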