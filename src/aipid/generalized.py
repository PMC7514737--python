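"""Variables in generalised coordinates of motion.

A generalised variable bundles a quantity with its higher temporal
derivatives (value, velocity, acceleration, ...). Representing signals
this way is what lets a linear state-space model describe smooth
(non-Markovian, Stratonovich-style) noise: each embedding order carries
its own observation and its own precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionMismatchError, InvalidInputError, InvalidParameterError

__all__ = ["GeneralizedVector", "shift", "precision_ladder", "log_precision_ladder"]


@dataclass
class GeneralizedVector:
    """A scalar variable and its orders of motion.

    Parameters
    ----------
    values:
        One entry per order: ``values[0]`` is the value, ``values[1]`` its
        first derivative, and so on. Stored as a float ndarray.
    units:
        Optional per-order unit labels (e.g. ``["km/h", "km/h^2"]``),
        purely descriptive.
    """

    values: np.ndarray
    units: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)  # defensive copy
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidInputError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("generalised coordinates must be finite")
        if self.units is not None and len(self.units) != self.values.size:
            raise DimensionMismatchError(
                f"{len(self.units)} unit labels for {self.values.size} orders"
            )

    @property
    def n_orders(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n_orders

    def __getitem__(self, k: int) -> float:
        return float(self.values[k])

    def copy(self) -> "GeneralizedVector":
        return GeneralizedVector(self.values.copy(), self.units)


def shift(gv: GeneralizedVector) -> GeneralizedVector:
    """Apply the derivative (block-shift) operator ``D``.

    Each order takes the value of the order above it and the highest order
    is zero-filled, so ``D mu = mu'`` within the retained embedding and
    ``D`` is nilpotent: applying it ``n_orders`` times annihilates any
    vector.
    """
    out = np.empty_like(gv.values)
    out[:-1] = gv.values[1:]
    out[-1] = 0.0
    return GeneralizedVector(out, gv.units)


def precision_ladder(
    base_log_precision: float, smoothness: float, n_orders: int
) -> np.ndarray:
    """Precisions across embedding orders from a base log-precision.

    A geometric ladder ``pi_k = exp(base) * smoothness**k``. The
    smoothness (decay) factor, 1/2 by convention here, encodes how quickly
    confidence falls off for higher derivatives; ``smoothness = 1`` treats
    all orders alike. Full temporal-autocorrelation precision matrices are
    deliberately out of scope.

    Returns a strictly positive, non-increasing array of length
    ``n_orders``.
    """
    if n_orders < 1:
        raise InvalidParameterError("n_orders must be >= 1")
    if not (0.0 < smoothness <= 1.0):
        raise InvalidParameterError(
            f"smoothness must lie in (0, 1], got {smoothness!r}"
        )
    k = np.arange(n_orders)
    return np.exp(float(base_log_precision)) * smoothness**k


def log_precision_ladder(
    base_log_precision: float, smoothness: float, n_orders: int
) -> np.ndarray:
    """Log of :func:`precision_ladder`: ``base + k*log(smoothness)``."""
    return np.log(precision_ladder(base_log_precision, smoothness, n_orders))
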