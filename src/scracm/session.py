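"""Recording-session container and its HDF5 on-disk layout.

One :class:`RecordingSession` holds everything recorded from a single cell:
per-trial current sweeps (pA, voltage clamp at -70 mV, 20 kHz), the stimulus
schedule (each grid spot once per trial plus one full-field event), and the
cell geometry / QC metadata needed downstream.

HDF5 layout (all datasets uncompressed):

* ``/sweeps/trial{n}`` — float32 current trace (pA) for trial ``n``
* ``/schedule`` — table with columns ``trial`` (int32), ``spot_index``
  (int32, -1 for full-field), ``t_ms`` (float64), ``is_full_field`` (int8)
* ``/meta`` — attributes: ``sample_rate_hz``, ``soma_row``, ``soma_col``
  (quadrant indices), ``soma_depth_um``, ``medial_sign``,
  ``series_resistance_mohm``, ``holding_mv``, ``pia_row``, ``n_rows``,
  ``n_cols``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import geometry

SCHEDULE_COLUMNS = ["trial", "spot_index", "t_ms", "is_full_field"]


@dataclass
class RecordingSession:
    """Raw sweeps, stimulus schedule and metadata for one recorded cell."""

    sweeps: list[np.ndarray]
    schedule: pd.DataFrame
    sample_rate_hz: float = 20_000.0
    soma_row: int = 0          # quadrant-resolution row of the soma
    soma_col: int = 0          # quadrant-resolution column of the soma
    soma_depth_um: float = np.nan
    medial_sign: int = 1       # +1 if increasing column index points medially
    series_resistance_mohm: float = np.nan
    holding_mv: float = -70.0
    pia_row: int = 0           # quadrant-resolution row of the pia
    n_rows: int = geometry.N_ROWS
    n_cols: int = geometry.N_COLS

    def __post_init__(self) -> None:
        missing = [c for c in SCHEDULE_COLUMNS if c not in self.schedule.columns]
        if missing:
            raise ValueError(f"schedule is missing columns {missing}")
        n_spots = self.n_rows * self.n_cols
        spots = self.schedule[~self.schedule["is_full_field"].astype(bool)]
        for trial, grp in spots.groupby("trial"):
            counts = grp["spot_index"].value_counts()
            if len(counts) != n_spots or (counts != 1).any():
                bad = (set(range(n_spots)) - set(counts.index)) or \
                      set(counts.index[counts > 1])
                raise ValueError(
                    f"trial {trial}: every spot must appear exactly once "
                    f"(offending spots: {sorted(bad)[:5]}...)")
            t = grp.sort_index()["t_ms"].to_numpy()
            if not np.all(np.diff(np.sort(t)) > 0):
                raise ValueError(f"trial {trial}: stimulus times must be strictly increasing")
        if not (0 <= self.soma_row < 2 * self.n_rows and 0 <= self.soma_col < 2 * self.n_cols):
            raise ValueError("soma position outside the stimulation grid")

    @property
    def n_trials(self) -> int:
        return len(self.sweeps)

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("sweeps")
            for i, sw in enumerate(self.sweeps):
                g.create_dataset(f"trial{i}", data=np.asarray(sw, dtype=np.float32))
            sched = np.zeros(len(self.schedule), dtype=[
                ("trial", "i4"), ("spot_index", "i4"),
                ("t_ms", "f8"), ("is_full_field", "i1")])
            sched["trial"] = self.schedule["trial"]
            sched["spot_index"] = self.schedule["spot_index"]
            sched["t_ms"] = self.schedule["t_ms"]
            sched["is_full_field"] = self.schedule["is_full_field"].astype(np.int8)
            f.create_dataset("schedule", data=sched)
            m = f.create_group("meta")
            for key in ("sample_rate_hz", "soma_row", "soma_col", "soma_depth_um",
                        "medial_sign", "series_resistance_mohm", "holding_mv",
                        "pia_row", "n_rows", "n_cols"):
                m.attrs[key] = getattr(self, key)

    @classmethod
    def load(cls, path) -> "RecordingSession":
        with h5py.File(path, "r") as f:
            n = len(f["sweeps"])
            sweeps = [np.asarray(f["sweeps"][f"trial{i}"], dtype=np.float64)
                      for i in range(n)]
            raw = f["schedule"][()]
            schedule = pd.DataFrame({
                "trial": raw["trial"], "spot_index": raw["spot_index"],
                "t_ms": raw["t_ms"], "is_full_field": raw["is_full_field"].astype(bool)})
            m = f["meta"].attrs
            return cls(sweeps, schedule,
                       sample_rate_hz=float(m["sample_rate_hz"]),
                       soma_row=int(m["soma_row"]), soma_col=int(m["soma_col"]),
                       soma_depth_um=float(m["soma_depth_um"]),
                       medial_sign=int(m["medial_sign"]),
                       series_resistance_mohm=float(m["series_resistance_mohm"]),
                       holding_mv=float(m["holding_mv"]),
                       pia_row=int(m["pia_row"]),
                       n_rows=int(m["n_rows"]), n_cols=int(m["n_cols"]))
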