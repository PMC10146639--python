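"""In-memory containers for e-nose data.

A Cyranose-style electronic nose exposes 32 polymer-composite sensors to an
exhaled-breath sample; each sensor's resistance is recorded over time.  Two
representations matter downstream:

* :class:`RawSensorTrace` — the time-resolved resistances for one sample,
  with a baseline window (clean carrier gas) and an exposure window
  (sample gas at full concentration).
* :class:`BreathPrint` — the 32-element relative-response vector
  ``dR/R = (R_max - R_0) / R_0`` extracted from a trace, plus subject and
  group metadata and a per-sensor active mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

N_SENSORS = 32

#: sensors the manufacturer flags as most humidity-sensitive (1-based)
HUMIDITY_SENSORS = (5, 6, 23, 31)

GROUPS = ("asthma", "control", "unknown")

SENSOR_COLUMNS = [f"s{i:02d}" for i in range(1, N_SENSORS + 1)]


def _full_mask() -> np.ndarray:
    return np.ones(N_SENSORS, dtype=bool)


def mask_from_disabled(disabled: Iterable[int] | None) -> np.ndarray:
    """Build a 32-element active mask from 1-based sensor indices to disable."""
    mask = _full_mask()
    if disabled:
        for s in disabled:
            if not 1 <= int(s) <= N_SENSORS:
                raise ValueError(f"sensor index {s} outside 1..{N_SENSORS}")
            mask[int(s) - 1] = False
    return mask


@dataclass
class RawSensorTrace:
    """Time-resolved resistance of the 32 sensors for one breath sample.

    ``sensor_values`` is a (32, T) array of strictly positive resistances in
    arbitrary resistance units.  ``baseline_window`` and ``exposure_window``
    are half-open index intervals ``(start, stop)`` into ``time_axis``; the
    baseline precedes the exposure plateau.
    """

    sample_id: str
    sensor_values: np.ndarray
    time_axis: np.ndarray
    baseline_window: tuple[int, int]
    exposure_window: tuple[int, int]
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.sensor_values = np.asarray(self.sensor_values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.sensor_values.ndim != 2 or self.sensor_values.shape[0] != N_SENSORS:
            raise ValueError(
                f"sensor_values must be ({N_SENSORS}, T); got {self.sensor_values.shape}"
            )
        if self.sensor_values.shape[1] != self.time_axis.size:
            raise ValueError("time_axis length does not match sensor_values")
        if np.any(np.diff(self.time_axis) <= 0):
            raise ValueError("time_axis must be strictly increasing")
        if not np.all(self.sensor_values > 0):
            raise ValueError("resistance values must be strictly positive")
        b0, b1 = self.baseline_window
        e0, e1 = self.exposure_window
        T = self.time_axis.size
        if not (0 <= b0 < b1 <= T) or not (0 <= e0 < e1 <= T):
            raise ValueError("windows must be non-empty index intervals within the trace")
        if b1 > e0:
            raise ValueError("baseline window must precede the exposure window")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}; got {self.group!r}")

    @property
    def n_timepoints(self) -> int:
        return int(self.time_axis.size)


@dataclass
class BreathPrint:
    """One breath print: 32 relative sensor responses with metadata.

    ``response`` holds dR/R for every sensor, including masked-out ones;
    ``mask`` marks which sensors are active for analysis (True = active).
    """

    sample_id: str
    subject_id: str
    group: str
    response: np.ndarray
    mask: np.ndarray = field(default_factory=_full_mask)
    replicate: int = 1

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.response.shape != (N_SENSORS,):
            raise ValueError(f"response must have {N_SENSORS} entries")
        if self.mask.shape != (N_SENSORS,):
            raise ValueError(f"mask must have {N_SENSORS} entries")
        if not np.all(np.isfinite(self.response)):
            raise ValueError(f"non-finite response in sample {self.sample_id!r}")
        if int(self.mask.sum()) < 2:
            raise ValueError("at least 2 sensors must be active")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}; got {self.group!r}")

    @property
    def active_response(self) -> np.ndarray:
        return self.response[self.mask]


class BreathPrintSet:
    """An ordered collection of breath prints with array/DataFrame views."""

    def __init__(self, prints: Sequence[BreathPrint]):
        prints = list(prints)
        seen: set[str] = set()
        for bp in prints:
            if bp.sample_id in seen:
                raise ValueError(f"duplicate sample_id {bp.sample_id!r}")
            seen.add(bp.sample_id)
        self._prints = prints

    def __len__(self) -> int:
        return len(self._prints)

    def __iter__(self) -> Iterator[BreathPrint]:
        return iter(self._prints)

    def __getitem__(self, i: int) -> BreathPrint:
        return self._prints[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BreathPrintSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self, other):
            if (
                a.sample_id != b.sample_id
                or a.subject_id != b.subject_id
                or a.group != b.group
                or a.replicate != b.replicate
                or not np.array_equal(a.mask, b.mask)
                or not np.allclose(a.response, b.response, rtol=0, atol=0)
            ):
                return False
        return True

    # -- array views -------------------------------------------------------

    @property
    def X(self) -> np.ndarray:
        """(n_samples, 32) response matrix (all sensors)."""
        return np.array([bp.response for bp in self._prints], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([bp.group for bp in self._prints])

    @property
    def sample_ids(self) -> list[str]:
        return [bp.sample_id for bp in self._prints]

    @property
    def common_mask(self) -> np.ndarray:
        """Sensors active in every print of the set."""
        if not self._prints:
            return _full_mask()
        mask = _full_mask()
        for bp in self._prints:
            mask &= bp.mask
        return mask

    @property
    def X_active(self) -> np.ndarray:
        return self.X[:, self.common_mask]

    def subset(self, indices: Sequence[int]) -> "BreathPrintSet":
        return BreathPrintSet([self._prints[i] for i in indices])

    def with_mask(self, mask: np.ndarray) -> "BreathPrintSet":
        mask = np.asarray(mask, dtype=bool)
        return BreathPrintSet([replace(bp, mask=mask.copy()) for bp in self._prints])

    # -- conversions -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: Sequence[str],
        subject_ids: Sequence[str] | None = None,
        mask: np.ndarray | None = None,
    ) -> "BreathPrintSet":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_SENSORS:
            raise ValueError(f"X must be (n, {N_SENSORS})")
        if mask is None:
            mask = _full_mask()
        prints = []
        for i in range(X.shape[0]):
            sid = subject_ids[i] if subject_ids is not None else f"S{i:04d}"
            prints.append(
                BreathPrint(
                    sample_id=f"sample{i:04d}",
                    subject_id=sid,
                    group=str(y[i]),
                    response=X[i],
                    mask=np.asarray(mask, dtype=bool).copy(),
                )
            )
        return cls(prints)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bp in self._prints:
            row: dict = {
                "sample_id": bp.sample_id,
                "subject_id": bp.subject_id,
                "group": bp.group,
                "replicate": bp.replicate,
            }
            row.update({c: bp.response[i] for i, c in enumerate(SENSOR_COLUMNS)})
            rows.append(row)
        return pd.DataFrame(rows, columns=["sample_id", "subject_id", "group", "replicate", *SENSOR_COLUMNS])
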