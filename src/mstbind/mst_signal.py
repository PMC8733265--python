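"""Mapping between binding occupancy and the normalized MST observable.

MST reads out binding as a change in thermophoretic mobility of the
fluorescently labeled species.  For a two-state system the observable is a
linear mix of a free-state and a bound-state signal; the mixing weight is
the occupancy of the labeled species.  The response amplitude can have
either sign.

Two normalization conventions are provided:

``normalize_series``
    Per-series min–max rescaling to [0, 1], the convention behind
    "normalized" binding-curve axes.  It is biased toward steeper apparent
    curves whenever the top of the ladder does not reach saturation, so it
    is the *plotting* convention here.
``amplitude_normalize``
    Baseline-anchored: subtract a (typically fitted) free-state plateau
    and divide by the fitted amplitude, yielding an occupancy estimate
    that does not assume the ladder reached saturation.  This is the
    analysis convention; the fitting module estimates both plateaus as
    free parameters so the raw signal never needs pre-normalizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import BindingDomainError

__all__ = [
    "SignalModel",
    "NormalizedSeries",
    "signal_from_occupancy",
    "normalize_series",
    "amplitude_normalize",
]

#: Occupancies may stray this far outside [0, 1] before being rejected
#: (floating-point slop from the equilibrium solvers).
_THETA_SLOP = 1.0e-9


@dataclass(frozen=True)
class SignalModel:
    """Two-state signal endpoints (arbitrary units)."""

    signal_free: float = 0.0
    signal_bound: float = 1.0

    @property
    def amplitude(self) -> float:
        return self.signal_bound - self.signal_free


@dataclass(frozen=True)
class NormalizedSeries:
    """Result of :func:`normalize_series`: values in [0, 1] plus a flat flag."""

    values: np.ndarray
    flat: bool


def signal_from_occupancy(theta, model: SignalModel):
    """Linear two-state signal: ``signal_free + theta * amplitude``.

    ``theta`` may be a scalar or array of occupancies in [0, 1] (tolerance
    1e−9 for solver round-off, which is clipped away).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -_THETA_SLOP) or np.any(theta > 1.0 + _THETA_SLOP):
        raise BindingDomainError(f"occupancy outside [0, 1]: {theta!r}")
    theta = np.clip(theta, 0.0, 1.0)
    out = model.signal_free + theta * model.amplitude
    return float(out) if out.ndim == 0 else out


def normalize_series(signals) -> NormalizedSeries:
    """Min–max normalize one titration series to [0, 1].

    A series whose range is below a machine-scaled epsilon of its
    magnitude is *flat* (the shape of a no-binding control): all zeros are
    returned with ``flat=True``.

    Raises
    ------
    BindingDomainError
        For fewer than 4 points or non-finite signals.
    """
    y = np.asarray(signals, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise BindingDomainError(f"need >= 4 points in one series, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise BindingDomainError("signals must be finite")
    scale = max(float(np.max(np.abs(y))), 1.0)
    span = float(np.ptp(y))
    if span < 64.0 * np.finfo(float).eps * scale:
        return NormalizedSeries(values=np.zeros_like(y), flat=True)
    return NormalizedSeries(values=(y - np.min(y)) / span, flat=False)


def amplitude_normalize(signals, model: SignalModel) -> np.ndarray:
    """Occupancy estimate from raw signals given fitted plateaus.

    ``(y - signal_free) / amplitude``; not clipped, so values outside
    [0, 1] diagnose plateau misfit or noise.
    """
    y = np.asarray(signals, dtype=float)
    if model.amplitude == 0.0:
        raise BindingDomainError("zero amplitude: plateaus coincide")
    return (y - model.signal_free) / model.amplitude
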