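"""Recording and montage I/O.

EEG enters the pipeline either as EDF files or as plain delimited numeric
matrices (rows = channels).  Electrode geometry is carried as a
:class:`Montage` of unit-sphere positions in a single declared head frame:
+x through the right preauricular direction, +y through the nasion
(anterior), +z through the vertex.  All projection code downstream depends
only on this convention.

EDF reading is delegated to :mod:`mne`; writing uses a minimal 16-bit EDF
encoder (physical range ±1000 µV) so that the simulator's output can be
round-tripped without extra dependencies.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("topogru")

#: physical range (µV) used when encoding EDF; covers blink artifacts
#: without clipping ordinary EEG.
EDF_PHYS_RANGE_UV = 1000.0

STANDARD_1020_16_NAMES = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T3", "T4", "T5", "T6", "P3", "P4", "O1", "O2",
]


class MontageError(ValueError):
    """Raised for unknown montages or unplaceable channels."""


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per row of ``data``; drives channel order everywhere
        downstream.
    subject_id : str
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        """New recording sharing metadata but holding ``data``."""
        return RawRecording(data, self.fs, list(self.channel_names), self.subject_id)


@dataclass
class Montage:
    """Named electrode set on the unit sphere (head-centred).

    ``coords[i]`` is the (x, y, z) unit vector of ``channel_names[i]``:
    +x right, +y nasion (anterior), +z vertex.
    """

    name: str
    channel_names: list[str]
    coords: np.ndarray  # (n, 3), unit norm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.channel_names), 3):
            raise ValueError("coords shape must be (n_channels, 3)")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise MontageError("duplicate electrode names in montage")
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise MontageError("montage coordinates are not unit-norm")

    def __len__(self) -> int:
        return len(self.channel_names)

    def get_positions(self, channel_names: list[str]) -> np.ndarray:
        """Coordinates in the order of ``channel_names``.

        Channels absent from the montage are a hard error: spatial
        features are meaningless with unplaced channels.
        """
        index = {n: i for i, n in enumerate(self.channel_names)}
        missing = [n for n in channel_names if n not in index]
        if missing:
            raise MontageError(f"channels not in montage {self.name!r}: {missing}")
        return self.coords[[index[n] for n in channel_names]]


def _fit_sphere(points: np.ndarray) -> np.ndarray:
    """Least-squares sphere centre of a point cloud (n ≥ 4)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def _standard_1020_16() -> Montage:
    import mne

    mne.set_log_level("error")
    std = mne.channels.make_standard_montage("standard_1020")
    pos = std.get_positions()["ch_pos"]
    pts = np.array([pos[n] for n in STANDARD_1020_16_NAMES])
    # template positions sit on an approximate sphere; recentre and
    # project onto the unit sphere of the declared head frame
    centre = _fit_sphere(np.array(list(pos.values())))
    pts = pts - centre
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return Montage("standard-1020-16", list(STANDARD_1020_16_NAMES), pts)


def _dense_sim_128() -> Montage:
    """Synthetic 128-electrode cap: deterministic Fibonacci lattice over the
    upper sphere (z ≥ −0.25) with an exact vertex electrode E1.

    A geometric stand-in with the density of a 128-channel sensor net; it
    does not reproduce any vendor's electrode positions.
    """
    n = 128
    coords = [np.array([0.0, 0.0, 1.0])]
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z_hi, z_lo = 0.995, -0.25
    for i in range(n - 1):
        z = z_hi - (z_hi - z_lo) * (i + 0.5) / (n - 1)
        r = math.sqrt(max(0.0, 1.0 - z * z))
        a = golden * i
        # azimuth measured from +y (nasion) toward +x (right)
        coords.append(np.array([r * math.sin(a), r * math.cos(a), z]))
    names = [f"E{i + 1}" for i in range(n)]
    return Montage("dense-sim-128", names, np.vstack(coords))


def load_montage(name_or_path: str | Path) -> Montage:
    """Resolve a packaged montage by name or read an sfp-style file.

    Packaged names: ``"standard-1020-16"`` (the 16 cup electrodes of the
    10-20 layout) and ``"dense-sim-128"``.  A file must hold one electrode
    per line, ``name x y z`` whitespace-delimited; coordinates off the unit
    sphere are renormalised with a logged warning.
    """
    name = str(name_or_path)
    if name == "standard-1020-16":
        return _standard_1020_16()
    if name == "dense-sim-128":
        return _dense_sim_128()
    path = Path(name_or_path)
    if not path.exists():
        raise MontageError(
            f"unknown montage {name!r}: not a packaged name and no such file"
        )
    names, vecs = [], []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise MontageError(f"{path}:{ln}: expected 'name x y z'")
        names.append(parts[0])
        vecs.append([float(v) for v in parts[1:]])
    pts = np.asarray(vecs, dtype=np.float64)
    norms = np.linalg.norm(pts, axis=1)
    if np.any(norms == 0):
        raise MontageError("electrode at the origin cannot be normalised")
    if not np.allclose(norms, 1.0, atol=1e-6):
        logger.warning(
            "montage %s: %d electrode(s) off the unit sphere; renormalising",
            path.name, int(np.sum(np.abs(norms - 1.0) > 1e-6)),
        )
    pts = pts / norms[:, None]
    return Montage(path.stem, names, pts)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as a plain EDF file (16-bit, ±1000 µV physical).

    One data record per second when the sample count divides evenly by the
    (integer) rate; otherwise a single record holding the whole signal.
    Values outside the physical range are clipped.
    """
    path = Path(path)
    fs = rec.fs
    ns_total = rec.n_samples
    if abs(fs - round(fs)) < 1e-9 and ns_total % int(round(fs)) == 0:
        spr = int(round(fs))  # samples per record (1 s records)
        n_records = ns_total // spr
        rec_dur = 1.0
    else:
        spr = ns_total
        n_records = 1
        rec_dur = ns_total / fs
    nch = rec.n_channels
    phys_min, phys_max = -EDF_PHYS_RANGE_UV, EDF_PHYS_RANGE_UV
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(f"X X X {rec.subject_id}", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (nch + 1)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field(f"{rec_dur:g}", 8),
        _edf_field(str(nch), 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(n, 16) for n in rec.channel_names),
        b"".join(_edf_field("EEG", 80) for _ in range(nch)),
        b"".join(_edf_field("uV", 8) for _ in range(nch)),
        b"".join(_edf_field(f"{phys_min:g}", 8) for _ in range(nch)),
        b"".join(_edf_field(f"{phys_max:g}", 8) for _ in range(nch)),
        b"".join(_edf_field(str(dig_min), 8) for _ in range(nch)),
        b"".join(_edf_field(str(dig_max), 8) for _ in range(nch)),
        b"".join(_edf_field("", 80) for _ in range(nch)),
        b"".join(_edf_field(str(spr), 8) for _ in range(nch)),
        _edf_field("", 32 * nch),
    ])

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.clip(rec.data, phys_min, phys_max)
    digital = np.round((digital - phys_min) / scale + dig_min).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # channel-major within the record


def _edf_channel_rates(path: Path) -> tuple[list[str], list[float], float]:
    """Parse channel names and per-channel rates from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            nch = int(head[252:256].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed EDF header") from exc
        if nch <= 0:
            raise ValueError(f"{path}: EDF file declares zero channels")
        sig = fh.read(256 * nch)
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii", "replace").strip()
              for i in range(nch)]
    off = nch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [int(sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
           for i in range(nch)]
    if rec_dur <= 0:
        raise ValueError(f"{path}: non-positive record duration")
    rates = [s / rec_dur for s in spr]
    return labels, rates, rec_dur


def read_edf(path: str | Path) -> RawRecording:
    """Load an EDF file into a :class:`RawRecording` (µV).

    Mixed per-channel sampling rates are rejected rather than resampled;
    annotation channels are ignored.
    """
    import mne

    mne.set_log_level("error")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, rates, _ = _edf_channel_rates(path)
    signal_rates = {r for lab, r in zip(labels, rates)
                    if "annotation" not in lab.lower()}
    if len(signal_rates) > 1:
        raise ValueError(f"{path}: mixed sampling rates {sorted(signal_rates)}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    if np.isnan(data).any():
        raise ValueError(f"{path}: NaNs in loaded data")
    return RawRecording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                        subject_id=path.stem)


# ---------------------------------------------------------------------------
# Delimited matrices and labels
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, fs: float, channel_names: list[str],
                subject_id: str | None = None) -> RawRecording:
    """Read a whitespace/comma-delimited numeric matrix, rows = channels."""
    path = Path(path)
    text = path.read_text()
    delimiter = "," if ("," in text.splitlines()[0]) else None
    data = np.atleast_2d(np.loadtxt(path, delimiter=delimiter))
    if data.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: {data.shape[0]} rows but {len(channel_names)} channel names"
        )
    return RawRecording(data, fs, list(channel_names),
                        subject_id or path.stem)


def write_matrix(rec: RawRecording, path: str | Path) -> None:
    np.savetxt(path, rec.data, fmt="%.6f", delimiter="\t")


def save_labels(labels: dict[str, int], path: str | Path) -> None:
    """Write ``subject_id,label`` CSV (label 1 = depressed)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "label"])
        for sid, lab in labels.items():
            w.writerow([sid, int(lab)])


def load_labels(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["subject_id"]] = int(row["label"])
    return out
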