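"""Image and signal I/O.

CSV is the primary record format (`lead,t_seconds,v_mV`, one row per
sample, units fixed). A minimal WFDB-compatible writer (format-16 .dat
plus a text header) is provided for waveform tooling; its per-lead gain is
derived from the calibration ratio theta so the int16 samples are exact
pixel quanta.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from PIL import Image

from .digitize import EcgRecord, LeadSignal

__all__ = [
    "read_image",
    "write_image",
    "read_signal_csv",
    "write_record_csv",
    "read_record_csv",
    "write_record_wfdb",
]


def read_image(path) -> np.ndarray:
    """Load a PNG/JPEG photograph as an HxWx3 uint8 RGB array."""
    from .rectify import InputError

    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read image {os.fspath(path)!r}: {exc}") from exc


def write_image(path, img: np.ndarray) -> None:
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def read_signal_csv(path) -> tuple[np.ndarray, float]:
    """Read a 1-D signal CSV with columns ``t_seconds,v_mV`` (or a single
    value column sampled uniformly at 500 Hz). Returns (values, fs)."""
    df = pd.read_csv(path)
    if "t_seconds" in df.columns and "v_mV" in df.columns:
        t = df["t_seconds"].to_numpy(float)
        v = df["v_mV"].to_numpy(float)
        if t.size < 2:
            raise ValueError("signal CSV needs at least two samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        return v, fs
    return df.iloc[:, 0].to_numpy(float), 500.0


def write_record_csv(record: EcgRecord, path) -> None:
    """One row per sample: ``lead,t_seconds,v_mV``."""
    if not record.leads:
        raise ValueError("refusing to write an empty record")
    frames = [
        pd.DataFrame({"lead": name, "t_seconds": sig.t, "v_mV": sig.v})
        for name, sig in record.leads.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_record_csv(path) -> EcgRecord:
    df = pd.read_csv(path)
    leads = {
        str(name): LeadSignal(
            t=g["t_seconds"].to_numpy(float), v=g["v_mV"].to_numpy(float)
        )
        for name, g in df.groupby("lead", sort=False)
    }
    return EcgRecord(leads=leads, calibrations=[], meta={"source": os.fspath(path)})


def write_record_wfdb(record: EcgRecord, directory, name: str = "record") -> str:
    """Write a WFDB-compatible record: ``name.hea`` + format-16 ``name.dat``.

    Requires uniformly sampled leads (digitize with resampling first).
    Digital units are pixel quanta: gain = 1/theta ADU per mV, taken from
    the record's first calibration (or 200 ADU/mV when absent).
    Returns the header path.
    """
    if not record.leads:
        raise ValueError("refusing to write an empty record")
    names = list(record.leads)
    sigs = [record.leads[n] for n in names]
    dts = [np.diff(s.t) for s in sigs]
    for d in dts:
        if d.size == 0 or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("WFDB output needs uniformly resampled leads")
    fs = 1.0 / float(dts[0][0])
    n = min(s.v.size for s in sigs)
    gain = 1.0 / record.calibrations[0].theta if record.calibrations else 200.0
    digital = np.stack(
        [np.clip(np.rint(s.v[:n] * gain), -32768, 32767).astype(np.int16) for s in sigs],
        axis=1,
    )
    os.makedirs(directory, exist_ok=True)
    dat = os.path.join(directory, f"{name}.dat")
    digital.astype("<i2").tofile(dat)
    lines = [f"{name} {len(names)} {fs:g} {n}"]
    for j, lead in enumerate(names):
        first = int(digital[0, j])
        checksum = int(np.sum(digital[:, j], dtype=np.int64) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        lines.append(
            f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} {checksum} 0 {lead}"
        )
    hea = os.path.join(directory, f"{name}.hea")
    with open(hea, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return hea
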