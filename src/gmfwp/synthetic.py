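"""Synthetic MRI-gradient-like signals and distance profiles.

MRI gradient coils emit trains of trapezoidal field lobes whose repetition
rates sit in the hundreds of hertz to few-kilohertz range, so nearly all
their spectral energy lies above 300 Hz — the frequency from which the
occupational low- and high-AL limit curves coincide.  This module generates
such waveforms with known ground truth (no published raw waveform exists
for the surveyed scanners), plus spatial index-vs-distance profiles drawn
from an offset power-law decay, so that the weighting and clearance
machinery can be exercised end-to-end without instruments.

It also exposes the published measurement tables of the three surveyed
tomographs (Philips Panorama 1 T, Philips Ingenia 1.5 T, Siemens Magnetom
Aera 1.5 T) as packaged fixtures: these absolute indices encode real
instrument waveforms and cannot be regenerated, so they serve purely as
inputs to the clearance and zoning stages.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .clearance import DistanceProfile
from .weighting import TimeSeriesRecord

__all__ = [
    "SequenceSpec",
    "DecayGroundTruth",
    "MeasurementFixture",
    "gen_waveform",
    "gen_distance_profile",
    "gen_measurement_fixture",
]

_TABLES_BY_TOMOGRAPH = {"A": ("table4", "table5"), "B": ("table6", "table7"), "C": ("table8",)}


@dataclass(frozen=True)
class SequenceSpec:
    """Geometry of a synthetic gradient waveform.

    ``kind`` is one of ``tone`` (reference cosine), ``trapezoid_train``
    (one trapezoidal lobe per period: linear rise, flat plateau, linear
    fall) or ``bipolar_epi_train`` (EPI-readout-like train with a lobe of
    alternating polarity in each half-period).  ``amplitude_at_reference``
    is the peak flux density (uT) at the probe position.
    """

    kind: str = "trapezoid_train"
    fundamental: float = 500.0
    rise_time: float = 2e-4
    plateau: float = 8e-4
    amplitude_at_reference: float = 100.0
    repetitions: int = 10
    sample_rate: float = 100_000.0

    def __post_init__(self) -> None:
        if self.kind not in ("tone", "trapezoid_train", "bipolar_epi_train"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.fundamental <= 0:
            raise ValueError("fundamental must be positive")
        if self.rise_time < 0:
            raise ValueError("violated: rise_time >= 0")
        period = 1.0 / self.fundamental
        lobe_window = period / 2.0 if self.kind == "bipolar_epi_train" else period
        if self.kind != "tone" and 2 * self.rise_time + self.plateau > lobe_window + 1e-15:
            raise ValueError(
                "violated: 2*rise_time + plateau <= "
                + ("period/2 (bipolar lobes)" if self.kind == "bipolar_epi_train" else "period")
            )
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.sample_rate < 20 * self.fundamental:
            raise ValueError("violated: sample_rate >= 20 * fundamental")

    @property
    def period(self) -> float:
        return 1.0 / self.fundamental


def _lobe(t: np.ndarray, rise: float, plateau: float) -> np.ndarray:
    """Unit trapezoidal lobe on [0, 2*rise + plateau], zero elsewhere."""
    if rise == 0:
        return ((t >= 0) & (t < plateau)).astype(float)
    up = np.clip(t / rise, 0.0, 1.0)
    down = np.clip((2 * rise + plateau - t) / rise, 0.0, 1.0)
    return np.where((t >= 0) & (t <= 2 * rise + plateau), np.minimum(up, down), 0.0)


def gen_waveform(spec: SequenceSpec) -> TimeSeriesRecord:
    """Generate an integer number of periods of the configured waveform.

    The sample grid is snapped to an integer number of samples per period
    (the effective sample rate is recorded on the returned record), so the
    output is exactly periodic — peak-holding metrics then need no window.
    The peak sample equals ``amplitude_at_reference`` up to one sample
    quantisation step.
    """
    n_per = int(round(spec.sample_rate / spec.fundamental))
    fs = spec.fundamental * n_per
    t = np.arange(n_per) / fs
    A = spec.amplitude_at_reference
    if spec.kind == "tone":
        one = A * np.cos(2 * np.pi * spec.fundamental * t)
    elif spec.kind == "trapezoid_train":
        one = A * _lobe(t, spec.rise_time, spec.plateau)
    else:  # bipolar_epi_train; built from one half-period lobe so the two
        # half-periods are exactly antisymmetric on the sample grid
        n_a = (n_per + 1) // 2
        t_half = np.arange(n_a) / fs
        lobe = A * _lobe(t_half, spec.rise_time, spec.plateau)
        one = np.concatenate([lobe, -lobe[: n_per - n_a]])
    samples = np.tile(one, spec.repetitions)[None, :]
    return TimeSeriesRecord(sample_rate=fs, samples=samples)


@dataclass(frozen=True)
class DecayGroundTruth:
    """Ground-truth offset power law for index-vs-distance profiles.

    index(d) = A * (d + d0)^(-n), d in cm, index in percent.  ``noise_sd``
    is the relative standard deviation of multiplicative measurement noise
    emulating probe-positioning reproducibility error.
    """

    A: float
    d0: float = 50.0
    n: float = 3.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.d0 <= 0 or self.n <= 0:
            raise ValueError("A, d0 and n must all be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_crossing(
        cls, crossing_cm: float, d0: float = 50.0, n: float = 3.0,
        threshold: float = 100.0, noise_sd: float = 0.0,
    ) -> "DecayGroundTruth":
        """Construct a truth whose index crosses ``threshold`` at ``crossing_cm``."""
        return cls(A=threshold * (crossing_cm + d0) ** n, d0=d0, n=n, noise_sd=noise_sd)

    def index_at(self, d: float | np.ndarray) -> float | np.ndarray:
        return self.A * (np.asarray(d, dtype=float) + self.d0) ** (-self.n)

    def crossing(self, threshold: float = 100.0) -> float:
        return (self.A / threshold) ** (1.0 / self.n) - self.d0


def gen_distance_profile(
    truth: DecayGroundTruth,
    distances,
    seed: int,
    *,
    height: float | None = None,
    sequence_label: str = "synthetic",
    curve_id: str = "RL_B",
) -> DistanceProfile:
    """Sample the ground-truth decay at the given distances (cm).

    Each index is ``truth.index_at(d) * (1 + eps)`` with ``eps`` zero-mean
    normal of sd ``noise_sd``, reproducible from ``seed``; with zero noise
    the model values are returned exactly.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 distances (three-parameter decay model)")
    if np.any(d < 0) or np.any(np.diff(d) <= 0):
        raise ValueError("distances must be non-negative and strictly increasing")
    vals = np.asarray(truth.index_at(d), dtype=float)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals * (1.0 + rng.normal(0.0, truth.noise_sd, size=len(d)))
        vals = np.maximum(vals, 1e-6)  # indices stay positive under extreme draws
    return DistanceProfile(
        tuple(zip(d.tolist(), vals.tolist())),
        height=height,
        sequence_label=sequence_label,
        curve_id=curve_id,
    )


@dataclass(frozen=True)
class MeasurementFixture:
    """Published weighted-peak indices of one surveyed tomograph."""

    tomograph_id: str
    table: pd.DataFrame  # sequence, distance_cm, height_cm, position_label, curve_id, index_percent, instrument

    def profile(
        self,
        sequence: str,
        height: float = 100.0,
        curve_id: str = "RL_B",
        instrument: str | None = None,
    ) -> DistanceProfile:
        """Distance profile (labelled points excluded) for one sequence/height/curve."""
        t = self.table
        sel = (
            (t["sequence"] == sequence)
            & (t["height_cm"] == height)
            & (t["curve_id"] == curve_id)
            & t["distance_cm"].notna()
        )
        if instrument is not None:
            sel &= t["instrument"] == instrument
        rows = t[sel].sort_values("distance_cm")
        if rows.empty:
            raise KeyError(f"no profile for {sequence} h={height} {curve_id} {instrument or ''}")
        return DistanceProfile(
            tuple(zip(rows["distance_cm"].tolist(), rows["index_percent"].tolist())),
            height=height,
            sequence_label=sequence,
            curve_id=curve_id,
        )

    def point_index(
        self, sequence: str, position_label: str, curve_id: str = "RL_B",
        height: float = 100.0,
    ) -> float:
        """Index at a labelled point (``OP`` opposite the bed, ``REAR`` behind the magnet)."""
        t = self.table
        sel = (
            (t["sequence"] == sequence)
            & (t["position_label"] == position_label)
            & (t["curve_id"] == curve_id)
            & (t["height_cm"] == height)
        )
        rows = t[sel]
        if rows.empty:
            raise KeyError(f"no point {position_label} for {sequence} {curve_id}")
        return float(rows["index_percent"].iloc[0])


def _read_table(name: str) -> pd.DataFrame:
    text = resources.files("gmfwp.data").joinpath(f"{name}.tsv").read_text()
    df = pd.read_csv(
        _io.StringIO(text),
        sep="\t",
        comment="#",
        dtype={"sequence": str, "position_label": str, "curve_id": str, "instrument": str},
    )
    df["position_label"] = df["position_label"].fillna("")
    df["source_table"] = name
    return df


def gen_measurement_fixture(tomograph_id: str) -> MeasurementFixture:
    """Published result tables for tomograph ``A``, ``B`` or ``C``.

    A: Philips Panorama 1 T (open magnet) — compliant everywhere, whole
    room Zone 0.  B: Philips Ingenia 1.5 T.  C: Siemens Magnetom Aera
    1.5 T.  Indices are percent against the named limit curve; points with
    a ``position_label`` (OP/REAR) carry no departure-line distance.
    """
    if tomograph_id not in _TABLES_BY_TOMOGRAPH:
        raise KeyError(f"unknown tomograph id {tomograph_id!r}; known: A, B, C")
    frames = [_read_table(t) for t in _TABLES_BY_TOMOGRAPH[tomograph_id]]
    return MeasurementFixture(tomograph_id, pd.concat(frames, ignore_index=True))
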