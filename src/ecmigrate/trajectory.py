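"""Time-stamped cell-position records produced by the simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Uniformly sampled positions of every cell over a run.

    ``positions`` has shape (n_frames, n_cells, 3) in mm; ``times`` in
    hours; ``mobile`` flags are immutable over a run.  ``meta`` carries the
    resolved configuration (geometry, seed, config hash) so every analysis
    artifact can be regenerated from the file alone.
    """

    times: np.ndarray
    positions: np.ndarray
    mobile: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        if self.positions.ndim != 3 or self.positions.shape[0] != len(self.times):
            raise ValueError("positions must be (n_frames, n_cells, 3)")
        if np.any(np.diff(self.times) <= 0) and len(self.times) > 1:
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    @property
    def interval(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def window(self, t0: float, t1: float) -> "Trajectory":
        """Sub-trajectory with t0 <= t <= t1 (inclusive, small tolerance)."""
        eps = 1e-9
        sel = (self.times >= t0 - eps) & (self.times <= t1 + eps)
        if not sel.any():
            raise ValueError(f"window [{t0}, {t1}] outside trajectory span")
        return Trajectory(self.times[sel], self.positions[sel], self.mobile,
                          dict(self.meta))

    def to_csv(self, path) -> None:
        """Long-format CSV with a '# key=value' metadata header block."""
        with open(path, "w") as fh:
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k}={v}\n")
            fh.write("time_h,cell_id,x_mm,y_mm,z_mm,mobile\n")
            for fi, t in enumerate(self.times):
                P = self.positions[fi]
                for ci in range(self.n_cells):
                    fh.write(f"{float(t)!r},{ci},{float(P[ci, 0])!r},"
                             f"{float(P[ci, 1])!r},{float(P[ci, 2])!r},"
                             f"{int(self.mobile[ci])}\n")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        meta = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    k, _, v = line.lstrip("# ").rstrip("\n").partition("=")
                    meta[k] = v
                    skip += 1
                else:
                    break
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
        times = np.unique(df["time_h"].to_numpy())
        n_cells = int(df["cell_id"].max()) + 1
        pos = np.full((len(times), n_cells, 3), np.nan)
        t_idx = {t: i for i, t in enumerate(times)}
        fi = df["time_h"].map(t_idx).to_numpy()
        ci = df["cell_id"].to_numpy()
        pos[fi, ci, 0] = df["x_mm"].to_numpy()
        pos[fi, ci, 1] = df["y_mm"].to_numpy()
        pos[fi, ci, 2] = df["z_mm"].to_numpy()
        mobile = np.zeros(n_cells, dtype=bool)
        mobile[df["cell_id"].to_numpy()] = df["mobile"].to_numpy().astype(bool)
        return cls(times, pos, mobile, meta)
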