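"""Recording container and file I/O.

A recording on disk is a pair of files: a raw little-endian float32
payload (``<stem>.f32``, channel-interleaved frames) and a JSON sidecar
(``<stem>.json``) declaring the sampling rate, dtype, layout and channel
metadata.  Metric tables are plain RFC-4180 CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelMeta",
    "Recording",
    "MetricTable",
    "METRIC_REGISTRY",
    "read_recording",
    "write_recording",
    "write_metrics",
    "read_metrics",
    "FormatError",
    "IntegrityError",
]

VALID_AREAS = ("PrL", "M1", "S1", "V1", "synthetic")

#: Metric names that may appear in a MetricTable.
METRIC_REGISTRY = frozenset(
    {
        "so_frequency_hz",
        "mean_up_s",
        "mean_down_s",
        "cv_freq",
        "fr_up",
        "fr_down",
        "rel_fr",
        "sampen_up",
        "sampen_down",
        "peak_hz_up",
        "peak_hz_down",
        "peak_excess_up",
        "peak_excess_down",
        "alpha_1f_up",
        "alpha_1f_down",
        "wave_speed_mm_s",
        "n_cycles",
    }
)


class FormatError(ValueError):
    """Missing or malformed sidecar / payload."""


class IntegrityError(ValueError):
    """Sidecar metadata inconsistent with the payload."""


@dataclass
class ChannelMeta:
    """Metadata for one electrode.

    ``position_mm`` is the coordinate along the array axis, used by the
    wave-propagation analysis; it may be None for single-electrode
    recordings.
    """

    label: str
    area: str = "synthetic"
    hemisphere: str = "n/a"
    position_mm: float | None = None

    def __post_init__(self) -> None:
        if self.area not in VALID_AREAS:
            raise ValueError(f"unknown area {self.area!r}; expected one of {VALID_AREAS}")
        if self.hemisphere not in ("left", "right", "n/a"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "area": self.area,
            "hemisphere": self.hemisphere,
            "position_mm": self.position_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMeta":
        return cls(
            label=d["label"],
            area=d.get("area", "synthetic"),
            hemisphere=d.get("hemisphere", "n/a"),
            position_mm=d.get("position_mm"),
        )


@dataclass
class Recording:
    """A multichannel extracellular recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts (arbitrary scale for synthetic data).
    rate : float
        Sampling frequency in Hz.
    channels : list of ChannelMeta
    arbitrary_units : bool
        True for synthetic signals whose amplitude scale is not calibrated.
    """

    samples: np.ndarray
    rate: float
    channels: list[ChannelMeta] = field(default_factory=list)
    arbitrary_units: bool = False

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float32))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[1] == 0:
            raise ValueError("zero-length channels are forbidden")
        if not self.channels:
            self.channels = [ChannelMeta(label=f"ch{i}") for i in range(self.samples.shape[0])]
        if len(self.channels) != self.samples.shape[0]:
            raise IntegrityError(
                f"{len(self.channels)} channel metadata entries for "
                f"{self.samples.shape[0]} payload channels"
            )
        positions = [c.position_mm for c in self.channels]
        if any(p is not None for p in positions):
            if any(p is None for p in positions):
                raise IntegrityError("position_mm must be present for all channels or none")
            if not np.all(np.diff(positions) > 0):
                raise IntegrityError("channel positions must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    @property
    def positions_mm(self) -> np.ndarray:
        if self.channels[0].position_mm is None:
            raise ValueError("recording has no electrode geometry")
        return np.array([c.position_mm for c in self.channels], dtype=float)

    def channel(self, index: int) -> np.ndarray:
        return self.samples[index]


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` as a float32 payload plus JSON sidecar.

    ``path`` may carry any suffix; the payload is written to
    ``<stem>.f32`` and the sidecar to ``<stem>.json``.  Returns the
    payload path.  ``read_recording`` inverts this bit-exactly.
    """
    path = Path(path)
    stem = path.with_suffix("")
    payload_path = stem.with_suffix(".f32")
    sidecar_path = stem.with_suffix(".json")
    data = np.ascontiguousarray(rec.samples.T, dtype="<f4")  # frame-interleaved
    payload_path.write_bytes(data.tobytes())
    sidecar = {
        "format": "slowosc-recording",
        "version": 1,
        "rate_hz": rec.rate,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "layout": "interleaved",
        "amplitude_unit": "uV",
        "arbitrary_units": bool(rec.arbitrary_units),
        "channels": [c.to_dict() for c in rec.channels],
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return payload_path


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``path`` may point at the payload, the sidecar, or the common stem.
    """
    stem = Path(path).with_suffix("")
    payload_path = stem.with_suffix(".f32")
    sidecar_path = stem.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    if not payload_path.exists():
        raise FormatError(f"missing payload {payload_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("rate_hz", "n_channels", "dtype"):
        if key not in meta:
            raise FormatError(f"sidecar lacks required key {key!r}")
    raw = np.frombuffer(payload_path.read_bytes(), dtype=meta["dtype"])
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch != 0:
        raise IntegrityError(
            f"payload holds {raw.size} values, not divisible by {n_ch} channels"
        )
    samples = raw.reshape(-1, n_ch).T.copy()
    if "n_samples" in meta and samples.shape[1] != int(meta["n_samples"]):
        raise IntegrityError(
            f"sidecar declares {meta['n_samples']} samples/channel, payload holds "
            f"{samples.shape[1]}"
        )
    channels = [ChannelMeta.from_dict(d) for d in meta.get("channels", [])]
    return Recording(
        samples=samples,
        rate=float(meta["rate_hz"]),
        channels=channels,
        arbitrary_units=bool(meta.get("arbitrary_units", False)),
    )


@dataclass
class MetricTable:
    """Long-format table of per-recording metric values."""

    rows: list[dict] = field(default_factory=list)

    COLUMNS = ("recording_id", "group", "age", "area", "metric_name", "value", "se")

    def add(
        self,
        recording_id: str,
        group: str,
        age: str,
        area: str,
        metric_name: str,
        value: float,
        se: float = float("nan"),
    ) -> None:
        if metric_name not in METRIC_REGISTRY:
            raise KeyError(f"metric {metric_name!r} not in registry")
        if not np.isfinite(value):
            raise ValueError(f"metric value must be finite, got {value!r} for {metric_name}")
        self.rows.append(
            {
                "recording_id": recording_id,
                "group": group,
                "age": age,
                "area": area,
                "metric_name": metric_name,
                "value": float(value),
                "se": float(se),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.COLUMNS))

    def __len__(self) -> int:
        return len(self.rows)


def write_metrics(table: MetricTable, path: str | Path) -> Path:
    """Write a MetricTable as CSV with full float precision."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty metric table")
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_metrics(path: str | Path) -> MetricTable:
    df = pd.read_csv(path)
    table = MetricTable()
    for row in df.itertuples(index=False):
        table.add(
            str(row.recording_id),
            str(row.group),
            str(row.age),
            str(row.area),
            str(row.metric_name),
            float(row.value),
            float(row.se),
        )
    return table
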