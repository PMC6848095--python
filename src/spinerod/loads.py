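"""Per-vertebral-level gravitational load tables.

Gravity acts as concentrated downward forces at the vertebral centers.  The
default "anthropometric" scheme distributes the total load according to the
superincumbent trunk-weight fraction carried at each level — the share of
body weight supported by the spine at that level, which grows monotonically
from roughly 9% at T1 (head, neck and shoulder girdle) to roughly 47% at L5
(whole trunk plus upper limbs), as used throughout the spine-loading
literature.  The applied per-level forces are these fractions renormalized
so they sum to ``total_load``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidParameterError

__all__ = ["LoadTable", "make_load_table", "SUPERINCUMBENT_FRACTIONS_17"]

#: Fraction of body weight supported at each level T1..L5.  Piecewise-linear
#: anthropometric profile: ~9% at T1 rising by ~2.2%/level through the
#: thoracic spine (rib cage and soft tissue accrue steadily) and ~2.7%/level
#: through the lumbar spine, reaching ~47% at L5.
SUPERINCUMBENT_FRACTIONS_17 = np.array([
    0.090, 0.112, 0.134, 0.156, 0.178, 0.200, 0.222, 0.244, 0.266,
    0.288, 0.310, 0.333,              # T1..T12
    0.360, 0.387, 0.414, 0.442, 0.470,  # L1..L5
])


@dataclass(frozen=True)
class LoadTable:
    """Downward force magnitude per vertebral level (T1 first)."""

    forces: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "forces", np.asarray(self.forces, dtype=float))

    @property
    def total_load(self) -> float:
        return float(self.forces.sum())

    @property
    def n_levels(self) -> int:
        return self.forces.size


def make_load_table(n_levels: int, total_load: float,
                    scheme: str = "anthropometric") -> LoadTable:
    """Build a per-level gravity table summing exactly to ``total_load``.

    Schemes: ``uniform`` (equal shares), ``linear-ramp`` (F_i proportional
    to the level index, 1-based) and ``anthropometric`` (superincumbent
    trunk-weight fractions; requires interpolation for n_levels != 17).
    """
    if total_load <= 0:
        raise InvalidParameterError("total_load must be positive")
    if n_levels < 1:
        raise InvalidParameterError("n_levels must be positive")
    if scheme == "uniform":
        w = np.ones(n_levels)
    elif scheme == "linear-ramp":
        w = np.arange(1, n_levels + 1, dtype=float)
    elif scheme == "anthropometric":
        if n_levels == SUPERINCUMBENT_FRACTIONS_17.size:
            w = SUPERINCUMBENT_FRACTIONS_17.copy()
        else:
            x = np.linspace(0.0, 1.0, SUPERINCUMBENT_FRACTIONS_17.size)
            w = np.interp(np.linspace(0.0, 1.0, n_levels), x,
                          SUPERINCUMBENT_FRACTIONS_17)
    else:
        raise ConfigurationError(f"unknown load scheme {scheme!r}")
    forces = w * (total_load / w.sum())
    # Guard the sum against accumulated rounding: pin it to machine precision.
    forces[-1] += total_load - forces.sum()
    return LoadTable(forces=forces, scheme=scheme)
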