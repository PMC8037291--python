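"""Plain-text I/O for waveforms, distance profiles and result tables.

Waveform dialect: CSV or TSV with ``# key=value`` header lines
(``sample_rate_hz``, ``units``) followed by columns ``t,Bx[,By,Bz]``; a
headerless two-column ``t,B`` dialect is accepted when the sample rate is
supplied by the caller.  All tabular outputs are TSV so they can be
consumed by external plotters and spreadsheets.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clearance import ClearanceResult, DistanceProfile
from .weighting import TimeSeriesRecord, WPResult

__all__ = [
    "read_waveform",
    "write_waveform",
    "read_profiles",
    "write_profiles",
    "write_wp_results",
    "write_clearance_report",
]


class WaveformFormatError(ValueError):
    """Malformed waveform file; message carries the offending line number."""


def _parse_headers(lines: list[str]) -> dict[str, str]:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_waveform(path: str | Path, sample_rate: float | None = None) -> TimeSeriesRecord:
    """Read a waveform file in the package dialect.

    The sample rate comes from a ``# sample_rate_hz=...`` header or, for
    the headerless dialect, from the ``sample_rate`` argument; when both
    are absent it is inferred from the time column spacing.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    header_lines = [ln for ln in raw if ln.startswith("#")]
    meta = _parse_headers(header_lines)
    if "sample_rate_hz" in meta:
        sample_rate = float(meta["sample_rate_hz"])

    body = "\n".join(ln for ln in raw if not ln.startswith("#") and ln.strip())
    if not body:
        raise WaveformFormatError(f"{path}: no data rows")
    sep = "\t" if "\t" in body.splitlines()[0] else ","
    first = body.splitlines()[0].split(sep)
    has_names = not all(_is_number(tok) for tok in first)
    try:
        df = pd.read_csv(_io.StringIO(body), sep=sep, header=0 if has_names else None)
    except (ValueError, TypeError) as exc:
        raise WaveformFormatError(f"{path}: {exc}") from exc
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] not in (2, 4):
        raise WaveformFormatError(
            f"{path}: expected columns t,Bx[,By,Bz]; got {values.shape[1]} columns (line 1)"
        )
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        row = int(bad[0][0]) + len(header_lines) + (2 if has_names else 1)
        raise WaveformFormatError(f"{path}: non-numeric or missing value at line {row}")
    t = values[:, 0]
    if sample_rate is None:
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise WaveformFormatError(f"{path}: cannot infer sample rate from time column")
        sample_rate = 1.0 / dt[0]
    return TimeSeriesRecord(sample_rate=sample_rate, samples=values[:, 1:].T)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_waveform(ts: TimeSeriesRecord, path: str | Path, header_extra: dict | None = None) -> None:
    path = Path(path)
    cols = ["t"] + list(ts.axes)
    with path.open("w") as fh:
        fh.write(f"# sample_rate_hz={ts.sample_rate!r}\n# units=uT\n")
        for k, v in (header_extra or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(cols) + "\n")
        t = ts.times
        for i in range(ts.n_samples):
            row = [f"{t[i]:.9g}"] + [f"{ts.samples[c, i]:.9g}" for c in range(ts.n_channels)]
            fh.write("\t".join(row) + "\n")


PROFILE_COLUMNS = ["sequence", "distance_cm", "height_cm", "curve_id", "index_percent"]


def read_profiles(path: str | Path) -> list[DistanceProfile]:
    """Read a profile TSV and group rows into one profile per
    (sequence, height, curve)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (seq, h, cid), grp in df.groupby(
        ["sequence", "height_cm", "curve_id"], sort=True, dropna=False
    ):
        grp = grp.sort_values("distance_cm")
        out.append(
            DistanceProfile(
                tuple(zip(grp["distance_cm"].tolist(), grp["index_percent"].tolist())),
                height=None if pd.isna(h) else float(h),
                sequence_label=str(seq),
                curve_id=str(cid),
            )
        )
    return out


def write_profiles(profiles: Iterable[DistanceProfile], path: str | Path,
                   header_extra: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (header_extra or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for p in profiles:
            for d, i in p.points:
                fh.write(
                    f"{p.sequence_label}\t{d:.6g}\t{p.height if p.height is not None else ''}"
                    f"\t{p.curve_id}\t{i:.6g}\n"
                )


def write_wp_results(results: Sequence[WPResult], path: str | Path,
                     header_extra: dict | None = None) -> None:
    path = Path(path)
    n_axes = max(len(r.per_axis_index) for r in results)
    axis_cols = [f"index_{ax}" for ax in ("Bx", "By", "Bz")[:n_axes]]
    with path.open("w") as fh:
        for k, v in (header_extra or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(["curve_id", "index_percent", *axis_cols,
                            "t_max_s", "phase_model", "low_cut_hz"]) + "\n")
        for r in results:
            ax = [f"{v:.6g}" for v in r.per_axis_index]
            ax += [""] * (n_axes - len(ax))
            fh.write(
                "\t".join(
                    [r.curve_id, f"{r.index_percent:.6g}", *ax, f"{r.t_max:.9g}",
                     r.phase_model, "" if r.low_cut is None else f"{r.low_cut:g}"]
                )
                + "\n"
            )


def write_clearance_report(
    rows: Sequence[tuple[DistanceProfile, object, ClearanceResult | None, str]],
    path: str | Path,
    header_extra: dict | None = None,
) -> None:
    """Write one row per (profile, fit, clearance, status).

    ``status`` is ``ok``, ``compliant_everywhere`` or an error message for
    groups that could not be fitted (other groups are still reported).
    """
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (header_extra or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write(
            "sequence\theight_cm\tcurve_id\tn_points\tA\td0_cm\tn_exp\trms_log_residual"
            "\tclearance_cm\tuncertainty_cm\tthreshold_pct\tboundary\tstatus\n"
        )
        for prof, fit, res, status in rows:
            base = f"{prof.sequence_label}\t{prof.height if prof.height is not None else ''}\t{prof.curve_id}\t{len(prof.points)}"
            if fit is None:
                fh.write(base + "\t\t\t\t\t\t\t\t\t" + status + "\n")
                continue
            mid = f"{fit.A:.6g}\t{fit.d0:.4f}\t{fit.n:.4f}\t{fit.rms_log_residual:.3e}"
            if res is None:
                fh.write(f"{base}\t{mid}\t\t\t\t\t{status}\n")
            else:
                fh.write(
                    f"{base}\t{mid}\t{res.distance:.2f}\t{res.uncertainty:.2f}"
                    f"\t{res.threshold:g}\t{res.boundary_label or ''}\t{status}\n"
                )
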