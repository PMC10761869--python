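"""Photon timestamp containers and I/O for µs-ALEX measurements.

A diffusion-based smFRET measurement with alternating laser excitation
produces a single time-ordered list of detected photons.  Each photon
carries two labels: which detector fired (donor or acceptor channel) and
which excitation window it arrived in (donor or acceptor laser on).  The
three photon streams used throughout burst analysis are

* ``DD`` — donor detector, donor excitation (n_D^D)
* ``DA`` — acceptor detector, donor excitation (n_D^A, the FRET stream)
* ``AA`` — acceptor detector, acceptor excitation (n_A^A)

Donor-detector photons arriving during acceptor excitation are physically
possible (background, afterglow) and are retained in the container but
excluded from every analysis count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

# Detector codes
DONOR_DET = 0
ACCEPTOR_DET = 1

# Excitation codes
DONOR_EXC = 0
ACCEPTOR_EXC = 1
GUARD = -1

# Stream codes (fixed order; used for same-tick tie-breaking)
DD, DA, AA = 0, 1, 2
EXCLUDED = 3  # donor detector during acceptor excitation

STREAM_NAMES = {DD: "DD", DA: "DA", AA: "AA", EXCLUDED: "excluded"}


class PhotonDataError(ValueError):
    """Raised for malformed photon containers or files."""


@dataclass(frozen=True)
class AlternationScheme:
    """Excitation alternation: which part of each period each laser is on.

    Windows are half-open intervals ``[start, stop)`` in seconds within one
    period.  Photons outside both windows fall into guard intervals and are
    dropped from analysis (tallied in metadata).
    """

    period: float
    donor_window: tuple[float, float]
    acceptor_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise PhotonDataError("alternation period must be positive")
        for name, (a, b) in (
            ("donor_window", self.donor_window),
            ("acceptor_window", self.acceptor_window),
        ):
            if not (0 <= a < b <= self.period):
                raise PhotonDataError(f"{name} must satisfy 0 <= start < stop <= period")
        d0, d1 = self.donor_window
        a0, a1 = self.acceptor_window
        if max(d0, a0) < min(d1, a1):
            raise PhotonDataError("donor and acceptor windows overlap")

    @classmethod
    def square(cls, period: float, donor_fraction: float = 0.5) -> "AlternationScheme":
        """50/50-style alternation: donor first, acceptor second, no guards."""
        split = period * donor_fraction
        return cls(period, (0.0, split), (split, period))


@dataclass
class PhotonStream:
    """Time-ordered photon arrivals with detector and excitation labels.

    ``timestamps`` are integer clock ticks (0-based); multiply by
    ``clock_period`` for seconds.  ``detector`` and ``excitation`` are
    per-photon code arrays (see module constants).
    """

    timestamps: np.ndarray
    detector: np.ndarray
    excitation: np.ndarray
    clock_period: float
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.detector = np.asarray(self.detector, dtype=np.int8)
        self.excitation = np.asarray(self.excitation, dtype=np.int8)
        n = self.timestamps.size
        if self.detector.size != n or self.excitation.size != n:
            raise PhotonDataError("detector/excitation length mismatch with timestamps")
        if n > 1:
            bad = np.nonzero(np.diff(self.timestamps) < 0)[0]
            if bad.size:
                raise PhotonDataError(
                    f"timestamps not sorted: first offending index {bad[0] + 1}"
                )
        unknown = ~np.isin(self.detector, (DONOR_DET, ACCEPTOR_DET))
        if unknown.any():
            raise PhotonDataError(
                f"unknown detector code at index {int(np.nonzero(unknown)[0][0])}"
            )

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def times(self) -> np.ndarray:
        """Arrival times in seconds."""
        return self.timestamps * self.clock_period

    def stream_labels(self) -> np.ndarray:
        """Per-photon stream code: DD, DA, AA or EXCLUDED (cached)."""
        cached = self.__dict__.get("_labels_cache")
        if cached is not None and cached.size == len(self):
            return cached
        out = np.full(len(self), EXCLUDED, dtype=np.int8)
        don = self.excitation == DONOR_EXC
        acc = self.excitation == ACCEPTOR_EXC
        out[don & (self.detector == DONOR_DET)] = DD
        out[don & (self.detector == ACCEPTOR_DET)] = DA
        out[acc & (self.detector == ACCEPTOR_DET)] = AA
        self.__dict__["_labels_cache"] = out
        return out

    def stream_counts(self) -> dict[str, int]:
        lab = self.stream_labels()
        return {STREAM_NAMES[s]: int(np.sum(lab == s)) for s in (DD, DA, AA, EXCLUDED)}


def assign_excitation(stream: PhotonStream, scheme: AlternationScheme) -> PhotonStream:
    """Label photons by excitation window from their arrival time.

    Each photon's position within the alternation period (``time mod
    period``) decides its label; windows are half-open so a photon exactly
    at a window end belongs to the next window.  Photons in guard intervals
    (outside both windows) are removed and tallied in
    ``metadata['guard_dropped']``.
    """
    d0, d1 = scheme.donor_window
    a0, a1 = scheme.acceptor_window
    clk = stream.clock_period
    period_ticks = round(scheme.period / clk)
    edges = (d0, d1, a0, a1)
    commensurate = abs(period_ticks * clk - scheme.period) <= 1e-9 * scheme.period and all(
        abs(round(x / clk) * clk - x) <= 1e-9 * scheme.period for x in edges
    )
    if commensurate:
        # exact integer-tick arithmetic avoids float round-off at window edges
        phase = np.mod(stream.timestamps, period_ticks)
        d0t, d1t, a0t, a1t = (round(x / clk) for x in edges)
        don = (phase >= d0t) & (phase < d1t)
        acc = (phase >= a0t) & (phase < a1t)
    else:
        phase = np.mod(stream.times, scheme.period)
        don = (phase >= d0) & (phase < d1)
        acc = (phase >= a0) & (phase < a1)
    exc = np.full(len(stream), GUARD, dtype=np.int8)
    exc[don] = DONOR_EXC
    exc[acc] = ACCEPTOR_EXC
    keep = exc != GUARD
    meta = dict(stream.metadata)
    meta["guard_dropped"] = int(np.sum(~keep))
    meta["alternation"] = {
        "period": scheme.period,
        "donor_window": list(scheme.donor_window),
        "acceptor_window": list(scheme.acceptor_window),
    }
    return PhotonStream(
        timestamps=stream.timestamps[keep],
        detector=stream.detector[keep],
        excitation=exc[keep],
        clock_period=stream.clock_period,
        duration=stream.duration,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# I/O: columnar text and a Photon-HDF5-style container
# ---------------------------------------------------------------------------

_TEXT_HEADER = "# getfret photon stream v1"


def write_photons(stream: PhotonStream, path, format: str = "auto") -> None:
    path = str(path)
    if format == "auto":
        format = "photon-hdf5" if path.endswith((".h5", ".hdf5")) else "columnar-text"
    if format == "columnar-text":
        _write_text(stream, path)
    elif format == "photon-hdf5":
        _write_hdf5(stream, path)
    else:
        raise PhotonDataError(f"unknown format {format!r}")


def read_photons(path, format: str = "auto") -> PhotonStream:
    """Read a photon stream from disk (text or Photon-HDF5-style layout)."""
    path = str(path)
    if format == "auto":
        format = "photon-hdf5" if path.endswith((".h5", ".hdf5")) else "columnar-text"
    if format == "columnar-text":
        return _read_text(path)
    if format == "photon-hdf5":
        return _read_hdf5(path)
    raise PhotonDataError(f"unknown format {format!r}")


def _write_text(stream: PhotonStream, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_TEXT_HEADER + "\n")
        fh.write(f"# clock_period_s = {stream.clock_period!r}\n")
        fh.write(f"# duration_s = {stream.duration!r}\n")
        fh.write("tick\tdetector\texcitation\n")
        for t, d, e in zip(stream.timestamps, stream.detector, stream.excitation):
            fh.write(f"{t}\t{d}\t{e}\n")


def _read_text(path: str) -> PhotonStream:
    clock, duration = None, None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "clock_period_s" in line:
                    clock = float(line.split("=")[1])
                elif "duration_s" in line:
                    duration = float(line.split("=")[1])
                continue
            if line[0].isalpha():  # column header
                continue
            rows.append(tuple(int(x) for x in line.split()))
    if clock is None:
        raise PhotonDataError(f"{path}: missing clock_period_s header")
    arr = np.array(rows, dtype=np.int64).reshape(-1, 3)
    if duration is None:
        duration = float(arr[-1, 0] * clock) if len(arr) else 0.0
    return PhotonStream(arr[:, 0], arr[:, 1], arr[:, 2], clock, duration)


def _write_hdf5(stream: PhotonStream, path: str) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.timestamps)
        g.create_dataset("detectors", data=stream.detector)
        g.create_dataset("excitation", data=stream.excitation)
        g.attrs["timestamps_unit"] = stream.clock_period
        f.attrs["acquisition_duration"] = stream.duration
        meta = stream.metadata or {}
        alt = meta.get("alternation")
        setup = f.create_group("setup")
        if alt is not None:
            setup.attrs["alex_period"] = alt["period"]
            setup.attrs["alex_donor_window"] = alt["donor_window"]
            setup.attrs["alex_acceptor_window"] = alt["acceptor_window"]
        if "seed" in meta:
            setup.attrs["seed"] = meta["seed"]


def _read_hdf5(path: str) -> PhotonStream:
    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        ts = g["timestamps"][()]
        det = g["detectors"][()]
        clock = float(g.attrs["timestamps_unit"])
        duration = float(f.attrs["acquisition_duration"])
        meta: dict = {}
        setup = f.get("setup")
        if setup is not None and "alex_period" in setup.attrs:
            meta["alternation"] = {
                "period": float(setup.attrs["alex_period"]),
                "donor_window": list(setup.attrs["alex_donor_window"]),
                "acceptor_window": list(setup.attrs["alex_acceptor_window"]),
            }
        if setup is not None and "seed" in setup.attrs:
            meta["seed"] = int(setup.attrs["seed"])
        if "excitation" in g:
            exc = g["excitation"][()]
            return PhotonStream(ts, det, exc, clock, duration, meta)
    # Derive excitation labels from the stored alternation scheme.
    if "alternation" not in meta:
        raise PhotonDataError(f"{path}: no excitation labels and no alternation metadata")
    alt = meta["alternation"]
    raw = PhotonStream(ts, det, np.zeros(len(ts), np.int8), clock, duration, meta)
    scheme = AlternationScheme(alt["period"], tuple(alt["donor_window"]), tuple(alt["acceptor_window"]))
    return assign_excitation(raw, scheme)


def slice_stream(stream: PhotonStream, start: int, stop: int) -> PhotonStream:
    """Photon-index slice [start, stop) preserving metadata."""
    return replace(
        stream,
        timestamps=stream.timestamps[start:stop],
        detector=stream.detector[start:stop],
        excitation=stream.excitation[start:stop],
    )
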