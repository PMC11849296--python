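"""Poisson statistics of digital single-molecule counting.

In a digital immunoassay, analyte molecules captured on antibody-coated
beads are enzyme-labelled and the beads are read out one per femtolitre
well as on/off signals.  When molecules are scarcer than beads, per-bead
molecule numbers are Poisson, so the fraction of "on" beads ``f_on``
determines the average number of enzyme labels per bead (AEB) through the
Poisson-corrected estimator ``-ln(1 - f_on)``.

The module also covers the arithmetic that motivates large-volume sample
loading (a 100 uL sample at 1 aM holds ~60 molecules; 1 uL holds fewer
than one) and the bead-number trade-off: fewer beads concentrate the
label per bead but capture fewer molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SaturationError

#: Avogadro's number, 1/mol
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class AssaySample:
    """An analyte sample: molar concentration (mol/L) and volume (L)."""

    concentration: float
    volume: float

    def __post_init__(self):
        if self.concentration < 0:
            raise InvalidInputError("concentration must be >= 0")
        if not self.volume > 0:
            raise InvalidInputError("volume must be > 0")


@dataclass(frozen=True)
class BeadAssayState:
    """Per-bead captured-molecule counts."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.ndim != 1 or c.size == 0:
            raise InvalidInputError("counts must be a non-empty 1-D array")
        if np.any(c < 0):
            raise InvalidInputError("counts must be >= 0")

    @property
    def n_beads(self) -> int:
        return int(self.counts.size)

    @property
    def f_on(self) -> float:
        """Fraction of beads carrying at least one molecule."""
        return float(np.mean(self.counts >= 1))


def expected_molecules(sample: AssaySample) -> float:
    """Expected number of analyte molecules, ``c * V * N_A`` (real-valued)."""
    return sample.concentration * sample.volume * AVOGADRO


def distribute_molecules(
    n_molecules: int, n_beads: int, seed: int = 0
) -> BeadAssayState:
    """Assign each molecule to a uniformly random bead (multinomial).

    The per-bead counts sum to ``n_molecules`` exactly; for molecules much
    scarcer than beads the per-bead distribution approaches
    Poisson(n_molecules / n_beads).
    """
    if n_beads < 1:
        raise InvalidInputError("n_beads must be >= 1")
    if n_molecules < 0:
        raise InvalidInputError("n_molecules must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_molecules, np.full(n_beads, 1.0 / n_beads))
    return BeadAssayState(counts)


def aeb_estimate(state: BeadAssayState) -> float:
    """Average enzymes per bead, the Poisson-corrected digital readout.

    ``AEB = -ln(1 - f_on)`` inverts ``f_on = 1 - exp(-lambda)`` for the
    Poisson mean; at low ``f_on`` it reduces to ``AEB ~ f_on``.  Undefined
    (saturated) when every bead is on.
    """
    f_on = state.f_on
    if f_on >= 1.0:
        raise SaturationError(
            "all beads are signal-positive; -ln(1 - f_on) is undefined"
        )
    return -math.log1p(-f_on)


def retention_percentage(count: int, expected: float, mode: str) -> float:
    """Bead retention percentage from waste or recovered counts.

    ``from_waste``: ``100 * (1 - count / expected)`` with ``count`` the
    beads found in the waste droplet.  ``from_recovered``:
    ``100 * count / expected`` with ``count`` the beads in the densified
    droplet.
    """
    if not expected > 0:
        raise InvalidInputError("expected bead count must be > 0")
    if count < 0:
        raise InvalidInputError("bead count must be >= 0")
    if mode == "from_waste":
        return 100.0 * (1.0 - count / expected)
    if mode == "from_recovered":
        return 100.0 * count / expected
    raise InvalidInputError(f"mode must be 'from_waste' or 'from_recovered', got {mode!r}")


def bead_number_tradeoff(
    sample: AssaySample,
    bead_grid,
    capture_scale: float,
) -> pd.DataFrame:
    """The sensitivity trade-off against bead number.

    Capture efficiency saturates with bead number,
    ``eff(n) = 1 - exp(-n / capture_scale)``, while the captured molecules
    per bead, ``E[N] * eff(n) / n``, falls; raising bead numbers therefore
    trades label density for capture completeness.  Returns a table with
    columns ``n_beads``, ``capture_efficiency``, ``molecules_per_bead``.
    """
    if not capture_scale > 0:
        raise InvalidInputError("capture_scale must be > 0")
    grid = np.asarray(list(bead_grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise InvalidInputError("bead_grid must be non-empty and positive")
    eff = 1.0 - np.exp(-grid / capture_scale)
    per_bead = expected_molecules(sample) * eff / grid
    return pd.DataFrame(
        {
            "n_beads": grid,
            "capture_efficiency": eff,
            "molecules_per_bead": per_bead,
        }
    )
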