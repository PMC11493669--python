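"""File I/O: CSV signals with JSON sidecars, sensing operators and
observations, and a minimal local-only WFDB record reader/writer.

CSV signals are one value per line with an optional single header line;
the sampling rate travels in a ``<path>.json`` sidecar.  Operators are
stored as an ``.npy`` array plus a JSON sidecar recording (N, M, seed,
ensemble).

The WFDB support covers the subset needed to load a local PhysioNet-style
two-file record (``.hea`` header + ``.dat`` signal): formats 16 (16-bit
little-endian) and 212 (packed 12-bit pairs), single segment, no skew or
byte offsets.  No network access is ever attempted.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .sensing import MeasurementOperator, Observation, Signal1D

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "save_operator",
    "load_operator",
    "save_observation",
    "load_observation",
    "read_signal_wfdb",
    "write_signal_wfdb",
]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_signal_csv(signal: Signal1D, path: str | Path, header: bool = True) -> None:
    path = Path(path)
    pd.Series(signal.samples, name="value").to_csv(path, index=False, header=header)
    _sidecar(path).write_text(
        json.dumps({"sampling_rate_hz": signal.sampling_rate_hz}) + "\n"
    )


def read_signal_csv(path: str | Path) -> Signal1D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    df = pd.read_csv(path, header=None)
    values = df.iloc[:, 0]
    # tolerate a single non-numeric header line
    if values.dtype == object:
        values = pd.to_numeric(values.iloc[1:], errors="raise")
    fs = 1.0
    if _sidecar(path).exists():
        fs = float(json.loads(_sidecar(path).read_text()).get("sampling_rate_hz", 1.0))
    return Signal1D(samples=values.to_numpy(dtype=float), sampling_rate_hz=fs)


def save_operator(phi: MeasurementOperator, path: str | Path) -> None:
    """Binary array file (.npy) plus a JSON sidecar with provenance."""
    path = Path(path)
    np.save(path, phi.matrix)
    real = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    _sidecar(real).write_text(
        json.dumps(
            {
                "n_samples": phi.n_samples,
                "n_measurements": phi.n_measurements,
                "seed": phi.seed,
                "ensemble": phi.ensemble,
            }
        )
        + "\n"
    )


def load_operator(path: str | Path) -> MeasurementOperator:
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(path.suffix + ".npy")
    mat = np.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return MeasurementOperator(matrix=mat, seed=meta["seed"], ensemble=meta["ensemble"])


def save_observation(obs: Observation, path: str | Path) -> None:
    path = Path(path)
    pd.Series(obs.y, name="value").to_csv(path, index=False, header=False)
    _sidecar(path).write_text(
        json.dumps({"noise_sigma": obs.noise_sigma, "operator_ref": obs.operator_ref})
        + "\n"
    )


def load_observation(path: str | Path) -> Observation:
    path = Path(path)
    y = pd.read_csv(path, header=None).iloc[:, 0].to_numpy(dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    return Observation(
        y=y, noise_sigma=meta["noise_sigma"], operator_ref=meta["operator_ref"]
    )


# -- WFDB subset ------------------------------------------------------------

_SIGSPEC = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)\s+"
    r"(?P<gain>[\d.]+)?(?:\((?P<baseline>-?\d+)\))?(?:/\S+)?"
)


def read_signal_wfdb(record_path: str | Path, channel_name: str) -> Signal1D:
    """Read one named channel of a local WFDB record (formats 16 and 212).

    ``record_path`` is the record name with or without the ``.hea``
    extension.  Sample values are converted to physical units via
    (adc - baseline) / gain.
    """
    record_path = Path(record_path)
    hea = record_path if record_path.suffix == ".hea" else record_path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0

    channels = []
    for ln in lines[1 : 1 + n_sig]:
        m = _SIGSPEC.match(ln)
        if not m:
            raise ValueError(f"unparseable WFDB signal line: {ln!r}")
        desc = ln.split()[-1]
        channels.append(
            {
                "file": m.group("file"),
                "fmt": int(m.group("fmt")),
                "gain": float(m.group("gain") or 200.0) or 200.0,
                "baseline": int(m.group("baseline") or 0),
                "desc": desc,
            }
        )
    names = [c["desc"] for c in channels]
    if channel_name not in names:
        raise KeyError(f"channel {channel_name!r} not in record (has {names})")
    idx = names.index(channel_name)

    fmts = {c["fmt"] for c in channels}
    files = {c["file"] for c in channels}
    if len(fmts) > 1 or len(files) > 1:
        raise ValueError("multi-file or mixed-format WFDB records are not supported")
    fmt = fmts.pop()
    dat = hea.parent / files.pop()
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = dat.read_bytes()

    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2").astype(np.int64)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8).astype(np.int64)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] >> 4) << 8)
        adc = np.empty(2 * len(b), dtype=np.int64)
        adc[0::2] = first
        adc[1::2] = second
        adc[adc > 2047] -= 4096
    else:
        raise ValueError(f"unsupported WFDB format {fmt} (supported: 16, 212)")

    total = n_samp * n_sig if n_samp else (adc.size // n_sig) * n_sig
    frames = adc[:total].reshape(-1, n_sig)
    ch = channels[idx]
    phys = (frames[:, idx] - ch["baseline"]) / ch["gain"]
    return Signal1D(samples=phys.astype(float), sampling_rate_hz=fs)


def write_signal_wfdb(
    record_path: str | Path,
    signals: np.ndarray,
    fs_hz: float,
    channel_names: list[str],
    gain: float = 200.0,
    baseline: int = 0,
) -> None:
    """Write a format-16 WFDB record (used for fixtures and round trips)."""
    record_path = Path(record_path)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] == len(channel_names) and signals.shape[0] != signals.shape[1]:
        signals = signals.T  # accept channel-major input
    n_samp, n_sig = signals.shape
    if n_sig != len(channel_names):
        raise ValueError("channel_names length must match signal count")
    name = record_path.stem
    hea = record_path.with_suffix(".hea")
    dat = record_path.with_suffix(".dat")
    adc = np.rint(signals * gain + baseline)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal exceeds 16-bit ADC range at this gain")
    interleaved = adc.astype("<i2").reshape(-1)
    dat.write_bytes(interleaved.tobytes())
    lines = [f"{name} {n_sig} {fs_hz:g} {n_samp}"]
    for ch in channel_names:
        lines.append(f"{dat.name} 16 {gain:g}({baseline})/mV 16 0 0 0 0 {ch}")
    hea.write_text("\n".join(lines) + "\n")
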