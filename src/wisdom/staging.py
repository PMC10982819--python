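"""Nodal (N) staging by metastatic lymph-node count.

Staging follows the standard rectal-cancer convention: N0 when no node is
metastatic, N1 for one to three metastatic nodes, N2 for four or more. The
map is total on the non-negative integers and monotone non-decreasing.
"""

from __future__ import annotations

import enum

from .errors import ConfigurationError

__all__ = ["Stage", "count_to_stage", "STAGE_ORDER"]


class Stage(str, enum.Enum):
    """Ordinal N stage. Comparison helpers use :data:`STAGE_ORDER`."""

    N0 = "N0"
    N1 = "N1"
    N2 = "N2"

    @property
    def index(self) -> int:
        return STAGE_ORDER[self]

    def __str__(self) -> str:  # CSV-friendly
        return self.value


STAGE_ORDER = {Stage.N0: 0, Stage.N1: 1, Stage.N2: 2}


def count_to_stage(k) -> Stage:
    """Map a metastatic-node count to the ternary N stage.

    Parameters
    ----------
    k : int
        Number of metastatic lymph nodes; must be a non-negative integer
        (integer-valued floats are accepted).

    Returns
    -------
    Stage
        ``N0`` for ``k == 0``, ``N1`` for ``1 <= k <= 3``, ``N2`` for
        ``k >= 4``.
    """
    if isinstance(k, bool):
        raise ConfigurationError("count_to_stage: k must be an integer, got bool")
    kf = float(k)
    if kf != int(kf):
        raise ConfigurationError(f"count_to_stage: k must be an integer, got {k!r}")
    ki = int(kf)
    if ki < 0:
        raise ConfigurationError(f"count_to_stage: k must be >= 0, got {ki}")
    if ki == 0:
        return Stage.N0
    if ki <= 3:
        return Stage.N1
    return Stage.N2
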