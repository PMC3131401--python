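"""Readers and writers for spectra, cohort tables and calibration tables.

Since no raw data were ever deposited for this method, the native
spectrum formats are transparent and self-describing:

* ``native_json`` — one JSON object with a ``metadata`` block and two
  parallel ``real`` / ``imag`` arrays;
* ``native_csv`` — ``# key = value`` comment header followed by a
  two-column ``real,imag`` table;
* ``jcamp_dx`` — a minimal JCAMP-DX NMR-FID subset (NTUPLES, AFFN
  encoding, two pages for the real and imaginary channels).  Vendor
  compression schemes (SQZ/DIF/DUP) are out of scope.

Cohort tables are plain CSV with the documented column set; calibration
tables pair % type-II area with carnosine.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .quantify import bilateral_mean
from .types import Spectrum, SubjectRecord

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_cohort_table",
    "write_cohort_table",
    "read_calibration_table",
    "DIALECTS",
    "COHORT_COLUMNS",
]

DIALECTS = ("native_json", "native_csv", "jcamp_dx")

#: Documented cohort CSV columns, in order.
COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "group",
    "category",
    "discipline",
    "best_distance_m",
    "carnosine_left_mM",
    "carnosine_right_mM",
]

_META_FIELDS = [
    ("domain", str),
    ("role", str),
    ("bandwidth_hz", float),
    ("transmitter_mhz", float),
    ("reference_ppm", float),
    ("echo_time_ms", float),
    ("repetition_time_ms", float),
    ("n_averages", int),
]


def _spectrum_from_parts(meta: dict, real: Sequence[float], imag: Sequence[float]) -> Spectrum:
    missing = [name for name, _ in _META_FIELDS if name not in meta]
    if missing:
        raise ValueError(f"missing mandatory metadata field(s): {', '.join(missing)}")
    if len(real) != len(imag):
        raise ValueError("real and imaginary channels differ in length")
    if len(real) == 0:
        raise ValueError("empty spectrum")
    kwargs = {name: cast(meta[name]) for name, cast in _META_FIELDS}
    return Spectrum(samples=np.asarray(real, dtype=float) + 1j * np.asarray(imag, dtype=float), **kwargs)


# ---------------------------------------------------------------- native JSON


def _read_json(path: Path) -> Spectrum:
    with open(path) as fh:
        doc = json.load(fh)
    if "metadata" not in doc or "real" not in doc or "imag" not in doc:
        raise ValueError(f"{path}: not a carnotype spectrum file (metadata/real/imag required)")
    return _spectrum_from_parts(doc["metadata"], doc["real"], doc["imag"])


def _write_json(spectrum: Spectrum, path: Path) -> None:
    doc = {
        "format": "carnotype-spectrum",
        "version": 1,
        "metadata": {name: getattr(spectrum, name) for name, _ in _META_FIELDS},
        "real": spectrum.samples.real.tolist(),
        "imag": spectrum.samples.imag.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ----------------------------------------------------------------- native CSV


def _read_csv(path: Path) -> Spectrum:
    meta: dict = {}
    real: List[float] = []
    imag: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if line.lower().startswith("real"):
                continue  # column header
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'real,imag', got {line!r}")
            try:
                real.append(float(parts[0]))
                imag.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric sample {line!r}") from exc
    return _spectrum_from_parts(meta, real, imag)


def _write_csv(spectrum: Spectrum, path: Path) -> None:
    with open(path, "w") as fh:
        for name, _ in _META_FIELDS:
            fh.write(f"# {name} = {getattr(spectrum, name)}\n")
        fh.write("real,imag\n")
        for s in spectrum.samples:
            fh.write(f"{float(s.real)!r},{float(s.imag)!r}\n")


# ------------------------------------------------------------------- JCAMP-DX

_JCAMP_META = {
    "##$BANDWIDTHHZ": "bandwidth_hz",
    "##$REFERENCEPPM": "reference_ppm",
    "##$ECHOTIMEMS": "echo_time_ms",
    "##$REPETITIONTIMEMS": "repetition_time_ms",
    "##$NAVERAGES": "n_averages",
    "##$ROLE": "role",
}


def _read_jcamp(path: Path) -> Spectrum:
    """Minimal JCAMP-DX NMR-FID reader (NTUPLES pages, AFFN numbers only)."""
    meta: dict = {"domain": "time"}
    pages: dict = {}
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                label, _, value = line.partition("=")
                label = label.strip().upper().replace(" ", "")
                value = value.strip()
                if label == "##.OBSERVEFREQUENCY":
                    meta["transmitter_mhz"] = float(value)
                elif label in _JCAMP_META:
                    key = _JCAMP_META[label]
                    meta[key] = value if key == "role" else float(value)
                elif label == "##PAGE":
                    current = value  # e.g. N=1
                    pages[current] = []
                elif label in ("##ENDNTUPLES", "##END"):
                    current = None
                continue
            if current is not None and line.strip():
                try:
                    values = [float(v) for v in line.replace(",", " ").split()]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric JCAMP data line") from exc
                pages[current].extend(values[1:])  # first value is the X index
    if len(pages) < 2:
        raise ValueError(f"{path}: JCAMP file lacks the two FID pages (real, imaginary)")
    keys = sorted(pages)
    meta.setdefault("n_averages", 1)
    return _spectrum_from_parts(meta, pages[keys[0]], pages[keys[1]])


def _write_jcamp(spectrum: Spectrum, path: Path) -> None:
    if spectrum.domain != "time":
        raise ValueError("JCAMP-DX writer supports time-domain FIDs only")
    n = spectrum.n_points
    with open(path, "w") as fh:
        fh.write("##TITLE=carnotype FID\n##JCAMP-DX=6.00\n##DATA TYPE=NMR FID\n")
        fh.write(f"##.OBSERVE FREQUENCY={spectrum.transmitter_mhz!r}\n")
        fh.write(f"##$BANDWIDTHHZ={spectrum.bandwidth_hz!r}\n")
        fh.write(f"##$REFERENCEPPM={spectrum.reference_ppm!r}\n")
        fh.write(f"##$ECHOTIMEMS={spectrum.echo_time_ms!r}\n")
        fh.write(f"##$REPETITIONTIMEMS={spectrum.repetition_time_ms!r}\n")
        fh.write(f"##$NAVERAGES={spectrum.n_averages}\n")
        fh.write(f"##$ROLE={spectrum.role}\n")
        fh.write("##NTUPLES=NMR FID\n##VAR_NAME=TIME, FID/REAL, FID/IMAG\n##SYMBOL=X, R, I\n")
        fh.write(f"##VAR_DIM={n}, {n}, {n}\n")
        for page, channel in (("N=1", spectrum.samples.real), ("N=2", spectrum.samples.imag)):
            fh.write(f"##PAGE={page}\n##DATA TABLE=(X++(Y..Y)), XYDATA\n")
            for i in range(0, n, 4):
                chunk = " ".join(repr(float(v)) for v in channel[i : i + 4])
                fh.write(f"{i} {chunk}\n")
        fh.write("##END NTUPLES=NMR FID\n##END=\n")


# ------------------------------------------------------------------ front end


def read_spectrum(path, dialect: str = "native_json") -> Spectrum:
    """Read one spectrum file in the named dialect."""
    path = Path(path)
    if dialect == "native_json":
        return _read_json(path)
    if dialect == "native_csv":
        return _read_csv(path)
    if dialect == "jcamp_dx":
        return _read_jcamp(path)
    raise ValueError(f"unknown dialect {dialect!r}; valid: {DIALECTS}")


def write_spectrum(spectrum: Spectrum, path, dialect: str = "native_json") -> str:
    """Write a spectrum; the file round-trips through :func:`read_spectrum`."""
    path = Path(path)
    if dialect == "native_json":
        _write_json(spectrum, path)
    elif dialect == "native_csv":
        _write_csv(spectrum, path)
    elif dialect == "jcamp_dx":
        _write_jcamp(spectrum, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; valid: {DIALECTS}")
    return str(path)


def read_cohort_table(path) -> List[SubjectRecord]:
    """Read a cohort CSV into records, order-preserving.

    ``carnosine_mean`` is filled by the bilateral mean of whichever leg
    values are present.  Unknown sex/group/category tokens and duplicate
    subject ids are hard errors.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in COHORT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject_id(s): {sorted(set(dup))}")
    records = []
    for row in df.itertuples(index=False):
        def opt(name):
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        left, right = opt("carnosine_left_mM"), opt("carnosine_right_mM")
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                sex=row.sex,
                group=row.group,
                category=row.category,
                discipline="" if pd.isna(row.discipline) else str(row.discipline),
                best_distance_m=opt("best_distance_m"),
                carnosine_left_mm=left,
                carnosine_right_mm=right,
                carnosine_mean_mm=bilateral_mean(left, right),
            )
        )
    return records


def write_cohort_table(records: Sequence[SubjectRecord], path) -> str:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "sex": r.sex,
                "group": r.group,
                "category": r.category,
                "discipline": r.discipline,
                "best_distance_m": r.best_distance_m,
                "carnosine_left_mM": r.carnosine_left_mm,
                "carnosine_right_mM": r.carnosine_right_mm,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
    return str(path)


def read_calibration_table(path):
    """Calibration CSV: subject_id,ft_area_pct,carnosine_mM."""
    df = pd.read_csv(path)
    for col in ("ft_area_pct", "carnosine_mM"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df["ft_area_pct"].to_numpy(float), df["carnosine_mM"].to_numpy(float)
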