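"""Shared Monte Carlo search settings.

Both combinatorial searches in this package (Voronoi seed placement and
substitution-rule optimization) are stochastic hill climbs: propose a small
random change, accept only strict improvements, stop a restart after
``patience`` consecutive non-improving proposals, and keep the best of
``restarts`` independent restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class MCParams:
    """Hill-climb settings.

    patience
        consecutive non-improving proposals before a restart stops.
    restarts
        independent random initializations; the best result is kept.
    max_move
        largest number of elements (seeds or letters) altered per proposal;
        the move size is drawn uniformly from ``1..max_move``.
    """

    patience: int = 10_000
    restarts: int = 20
    max_move: int = 3

    def __post_init__(self) -> None:
        if self.patience < 1 or self.restarts < 1 or self.max_move < 1:
            raise ConfigurationError("MC parameters must be positive")
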