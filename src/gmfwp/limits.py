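"""Frequency-dependent magnetic-flux-density exposure limit curves.

Encodes the EU regulatory limit tables for time-varying magnetic fields as
evaluable piecewise functions of frequency:

* ``LOW_AL_B``, ``HIGH_AL_B``, ``LIMB_AL_B`` — occupational action levels
  (ALs) of Directive 2013/35/EU, defined from 1 Hz to 10 MHz.  The low AL
  relates to sensory-effect exposure limit values, the high AL to
  health-effect ones; the two columns coincide at and above 300 Hz.
* ``RL_B`` — reference levels (RLs) of Recommendation 1999/519/EC for the
  general public, defined from 0 Hz to 300 GHz (B-field column only).

All limits are RMS values in microtesla.  Each curve is stored row-for-row
as printed in its source table (see ``data/limit_curves.yaml``): a row keeps
its printed coefficient together with the frequency unit in which ``f``
enters that row's formula, so the shipped numbers remain auditable against
the official tables.

Segment bands are lower-inclusive / upper-exclusive; a curve's terminal
segment is closed at its upper edge.  Evaluation outside the curve domain
raises :class:`FrequencyDomainError` — limits are never extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "CURVE_IDS",
    "FrequencyDomainError",
    "LimitSegment",
    "LimitCurve",
    "get_curve",
    "load_curves",
    "limit_value",
    "breakpoints",
    "continuity_report",
]

CURVE_IDS = ("RL_B", "LOW_AL_B", "HIGH_AL_B", "LIMB_AL_B")

#: multiplicative factor from a row's frequency unit to Hz
_UNIT_HZ = {"Hz": 1.0, "kHz": 1e3, "MHz": 1e6, "GHz": 1e9}

#: log-log slope of 1/limit(f) implied by each formula form
_FORM_SLOPE = {"constant": 0.0, "c_over_f": 1.0, "c_over_f2": 2.0, "c_sqrt_f": -0.5}


class FrequencyDomainError(ValueError):
    """Raised when a limit curve is evaluated outside its frequency domain."""


@dataclass(frozen=True)
class LimitSegment:
    """One printed row of a limit table.

    Parameters
    ----------
    f_lo, f_hi
        Band edges in Hz (lower-inclusive, upper-exclusive).
    form
        Formula shape: ``constant``, ``c_over_f``, ``c_over_f2`` or
        ``c_sqrt_f``.
    coefficient
        The printed coefficient, in uT when evaluated with ``f`` expressed
        in ``freq_unit``.
    freq_unit
        Unit in which ``f`` enters the formula on this row (``Hz``,
        ``kHz``, ``MHz`` or ``GHz``), exactly as in the source table.
    """

    f_lo: float
    f_hi: float
    form: str
    coefficient: float
    freq_unit: str = "Hz"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.form not in _FORM_SLOPE:
            raise ValueError(f"unknown segment form {self.form!r}")
        if self.freq_unit not in _UNIT_HZ:
            raise ValueError(f"unknown frequency unit {self.freq_unit!r}")
        if not self.f_lo < self.f_hi:
            raise ValueError(f"segment requires f_lo < f_hi, got [{self.f_lo}, {self.f_hi})")

    @property
    def inverse_slope(self) -> float:
        """Log-log slope of 1/limit(f) on this segment (0, +1, +2 or -1/2)."""
        return _FORM_SLOPE[self.form]

    def value(self, f_hz: float) -> float:
        """Evaluate the row formula at a frequency given in Hz."""
        fu = f_hz / _UNIT_HZ[self.freq_unit]
        if self.form == "constant":
            return self.coefficient
        if self.form == "c_over_f":
            return self.coefficient / fu
        if self.form == "c_over_f2":
            return self.coefficient / fu**2
        return self.coefficient * math.sqrt(fu)  # c_sqrt_f

    def coefficient_hz(self) -> float:
        """Coefficient rescaled so the formula reads in Hz: limit = C * f^(-slope)."""
        u = _UNIT_HZ[self.freq_unit]
        return self.coefficient * u ** self.inverse_slope


@dataclass(frozen=True)
class LimitCurve:
    """A complete piecewise limit curve (RMS uT as a function of Hz)."""

    curve_id: str
    segments: tuple[LimitSegment, ...]
    source: str = ""
    value_convention: str = "RMS"

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("curve needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if a.f_hi != b.f_lo:
                raise ValueError(
                    f"{self.curve_id}: segments not contiguous at {a.f_hi} Hz vs {b.f_lo} Hz"
                )

    @property
    def f_min(self) -> float:
        return self.segments[0].f_lo

    @property
    def f_max(self) -> float:
        return self.segments[-1].f_hi

    @property
    def domain(self) -> tuple[float, float]:
        return (self.f_min, self.f_max)

    @property
    def leading_slope(self) -> float:
        """Log-log slope of 1/limit on the lowest-frequency segment."""
        return self.segments[0].inverse_slope

    def __iter__(self) -> Iterator[LimitSegment]:
        return iter(self.segments)

    def segment_at(self, f: float) -> LimitSegment:
        """Segment containing ``f`` (Hz), lower-inclusive; terminal edge closed."""
        if not (self.f_min <= f <= self.f_max):
            raise FrequencyDomainError(
                f"{f} Hz outside domain [{self.f_min}, {self.f_max}] Hz of {self.curve_id}"
            )
        if f == self.f_max:
            return self.segments[-1]
        for seg in self.segments:
            if seg.f_lo <= f < seg.f_hi:
                return seg
        raise AssertionError("unreachable: contiguous segments cover the domain")

    def limit_value(self, f: float) -> float:
        """RMS flux-density limit (uT) at frequency ``f`` in Hz."""
        if f < 0:
            raise FrequencyDomainError("frequency must be non-negative")
        return self.segment_at(f).value(f)

    def breakpoints(self) -> list[tuple[float, float]]:
        """Interior breakpoints where the log-log slope of 1/limit changes.

        Returns ``(frequency_hz, slope_change)`` pairs, slope change being
        the jump in the slope of ``log(1/limit)`` vs ``log f``.  Boundaries
        between rows that print the same formula shape (e.g. two adjacent
        ``c/f`` rows) carry no slope change and are omitted.
        """
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            delta = b.inverse_slope - a.inverse_slope
            if delta != 0.0:
                out.append((b.f_lo, delta))
        return out

    def contains(self, f: float) -> bool:
        return self.f_min <= f <= self.f_max


def continuity_report(curve: LimitCurve) -> list[tuple[float, float]]:
    """Relative jump of the curve at every interior segment boundary.

    Returns ``(frequency_hz, relative_jump)`` where the jump is
    ``|left - right| / min(left, right)`` of the two one-sided evaluations.
    The AL curves are analytically continuous (jump 0); the printed RL
    table has small rounding steps at its uppermost transitions.
    """
    out = []
    for a, b in zip(curve.segments, curve.segments[1:]):
        f = b.f_lo
        left, right = a.value(f), b.value(f)
        out.append((f, abs(left - right) / min(left, right)))
    return out


def _load_yaml() -> dict:
    text = resources.files("gmfwp.data").joinpath("limit_curves.yaml").read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=1)
def load_curves() -> dict[str, LimitCurve]:
    """Load all shipped limit curves from the packaged table file."""
    raw = _load_yaml()
    curves = {}
    for cid, spec in raw["curves"].items():
        segs = tuple(
            LimitSegment(
                f_lo=float(row["f_lo_hz"]),
                f_hi=float(row["f_hi_hz"]),
                form=row["form"],
                coefficient=float(row["coefficient"]),
                freq_unit=row.get("freq_unit", "Hz"),
                metadata=row.get("metadata", {}),
            )
            for row in spec["segments"]
        )
        curves[cid] = LimitCurve(
            curve_id=cid,
            segments=segs,
            source=spec.get("source", ""),
            value_convention=spec.get("value_convention", "RMS"),
        )
    return curves


def get_curve(curve_id: str) -> LimitCurve:
    """Fetch a shipped curve by id (``RL_B``, ``LOW_AL_B``, ``HIGH_AL_B``, ``LIMB_AL_B``)."""
    curves = load_curves()
    try:
        return curves[curve_id]
    except KeyError:
        raise KeyError(f"unknown curve id {curve_id!r}; known: {sorted(curves)}") from None


def limit_value(curve: LimitCurve | str, f: float) -> float:
    """Module-level convenience: RMS limit (uT) of ``curve`` at ``f`` Hz."""
    if isinstance(curve, str):
        curve = get_curve(curve)
    return curve.limit_value(f)


def breakpoints(curve: LimitCurve | str) -> list[tuple[float, float]]:
    """Module-level convenience wrapper for :meth:`LimitCurve.breakpoints`."""
    if isinstance(curve, str):
        curve = get_curve(curve)
    return curve.breakpoints()


def limit_values(curve: LimitCurve, f: np.ndarray) -> np.ndarray:
    """Vectorised limit evaluation; frequencies outside the domain yield NaN."""
    f = np.asarray(f, dtype=float)
    out = np.full(f.shape, np.nan)
    for seg in curve.segments:
        mask = (f >= seg.f_lo) & (f < seg.f_hi)
        if seg is curve.segments[-1]:
            mask |= f == seg.f_hi
        if not mask.any():
            continue
        fu = f[mask] / _UNIT_HZ[seg.freq_unit]
        if seg.form == "constant":
            out[mask] = seg.coefficient
        elif seg.form == "c_over_f":
            out[mask] = seg.coefficient / fu
        elif seg.form == "c_over_f2":
            out[mask] = seg.coefficient / fu**2
        else:
            out[mask] = seg.coefficient * np.sqrt(fu)
    return out
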