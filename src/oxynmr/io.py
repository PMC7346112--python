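"""Readers and writers: JCAMP-DX and two-column CSV spectra, concentration
tables, kinetics summaries.

The JCAMP-DX support is a deliberately small, self-consistent subset of the
format (AFFN ``##XYDATA=(X++(Y..Y))`` on an even grid) sufficient for 1D 1H
spectra; pipeline metadata travels in ``##$``-prefixed private labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import KineticsSummary
from .synth import ConcentrationTable, Spectrum

__all__ = [
    "write_jcampdx",
    "read_jcampdx",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "read_spectrum",
    "write_concentration_csv",
    "read_concentration_csv",
    "summary_to_frame",
    "write_summary",
]

_META_KEYS = ("day", "fwhm", "area_scale", "noise_sd", "seed", "replicate")


def write_jcampdx(s: Spectrum, path: str | Path, title: str = "oxynmr synthetic spectrum") -> None:
    p = Path(path)
    n = len(s.ppm)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=5.01",
        "##DATA TYPE=NMR SPECTRUM",
        "##DATA CLASS=XYDATA",
        f"##.OBSERVE FREQUENCY={s.field_mhz:g}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##FIRSTX={s.ppm[0]:.10g}",
        f"##LASTX={s.ppm[-1]:.10g}",
        f"##NPOINTS={n}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
    ]
    for k in _META_KEYS:
        if k in s.meta and s.meta[k] is not None:
            lines.append(f"##${k.upper()}={s.meta[k]}")
    lines.append("##XYDATA=(X++(Y..Y))")
    per_line = 6
    for i in range(0, n, per_line):
        ys = " ".join(f"{v:.8e}" for v in s.intensity[i : i + per_line])
        lines.append(f"{s.ppm[i]:.6f} {ys}")
    lines.append("##END=")
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_jcampdx(path: str | Path) -> Spectrum:
    """Parse a JCAMP-DX file written by :func:`write_jcampdx` (or compatible
    AFFN XYDATA files on an even grid).  Raises ``ValueError`` on malformed
    input."""
    text = Path(path).read_text(encoding="utf-8")
    headers: dict[str, str] = {}
    data: list[float] = []
    in_data = False
    for rawline in text.splitlines():
        line = rawline.strip()
        if not line:
            continue
        if line.startswith("##"):
            if line.upper().startswith("##END"):
                in_data = False
                continue
            key, _, val = line[2:].partition("=")
            headers[key.strip().upper()] = val.strip()
            if key.strip().upper() == "XYDATA":
                in_data = True
            continue
        if in_data:
            toks = line.split()
            try:
                vals = [float(t) for t in toks]
            except ValueError as exc:
                raise ValueError(f"{path}: malformed XYDATA line {line!r}") from exc
            data.extend(vals[1:])  # first token is the line's abscissa
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in headers:
            raise ValueError(f"{path}: missing ##{req}")
    n = int(headers["NPOINTS"])
    if len(data) != n:
        raise ValueError(f"{path}: expected {n} points, found {len(data)}")
    yfactor = float(headers.get("YFACTOR", 1.0))
    ppm = np.linspace(float(headers["FIRSTX"]), float(headers["LASTX"]), n)
    meta: dict = {}
    for k in _META_KEYS:
        v = headers.get(f"${k.upper()}")
        if v is not None:
            meta[k] = float(v) if "." in v or "e" in v.lower() else int(v)
    field = float(headers.get(".OBSERVE FREQUENCY", 400.0))
    return Spectrum(ppm=ppm, intensity=np.array(data) * yfactor, field_mhz=field, meta=meta)


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity}).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, field_mhz: float = 400.0, meta: dict | None = None) -> Spectrum:
    df = pd.read_csv(path)
    if not {"ppm", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: need 'ppm' and 'intensity' columns")
    return Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(), field_mhz, dict(meta or {}))


def read_spectrum(path: str | Path) -> Spectrum:
    """Dispatch on extension: .jdx/.dx -> JCAMP-DX, .csv -> two-column CSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".jdx", ".dx", ".jcamp"):
        return read_jcampdx(path)
    if suffix == ".csv":
        return read_spectrum_csv(path)
    raise ValueError(f"{path}: unknown spectrum format {suffix!r}")


def write_concentration_csv(table: ConcentrationTable, path: str | Path) -> None:
    table.data.to_csv(path, index=True)


def read_concentration_csv(path: str | Path, replicate_id: str | None = None) -> ConcentrationTable:
    df = pd.read_csv(path)
    if "day" not in df.columns:
        raise ValueError(f"{path}: need a 'day' column")
    df = df.set_index("day")
    df.index = df.index.astype(float)
    return ConcentrationTable(data=df, replicate_id=replicate_id)


def summary_to_frame(summary: KineticsSummary) -> pd.DataFrame:
    """Flatten a kinetics summary to one row per compound."""
    rows = []
    n_stages = len(summary.scheme.stages)
    for cid in sorted(summary.events):
        ev = summary.events[cid]
        rates = summary.stage_rates.get(cid, [])
        row = {
            "compound_id": cid,
            "appearance_day": ev.appearance_day,
            "max_day": ev.max_day,
            "max_value": ev.max_value,
            "disappeared_day": ev.disappeared_day,
        }
        for i, r in enumerate(rates):
            row[f"rate_stage{i + 1}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary(summary: KineticsSummary, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    df = summary_to_frame(summary)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "scheme": list(summary.scheme.breakpoints),
            "lod": summary.lod,
            "compounds": {
                cid: {
                    **asdict(summary.events[cid]),
                    "stage_rates": summary.stage_rates.get(cid),
                }
                for cid in sorted(summary.events)
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
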