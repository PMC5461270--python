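"""Trajectory container and serialization (CSV and HDF5).

A trajectory is a uniformly decimated log of the simulation: time, the six
position and six velocity coordinates, per-foot grounded flags and,
optionally, controller diagnostics (switching coefficients, mobility
indices, axial actuator forces, and the worst per-step error of the
local+residual = command identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "SCHEMA_VERSION", "STATE_COLUMNS", "DIAG_COLUMNS"]

SCHEMA_VERSION = 1

STATE_COLUMNS = [
    "t",
    "x_trunk", "z_trunk", "x_rfoot", "z_rfoot", "x_lfoot", "z_lfoot",
    "vx_trunk", "vz_trunk", "vx_rfoot", "vz_rfoot", "vx_lfoot", "vz_lfoot",
    "grounded_r", "grounded_l",
]

DIAG_COLUMNS = [
    "a_1", "a_2", "a_3",
    "k_1", "k_2", "k_3",
    "f_1", "f_2", "f_3",
    "eq_split_err",
]


@dataclass
class Trajectory:
    """Columnar simulation log.

    ``pos`` and ``vel`` have shape (n, 3, 2) with mass order (trunk, right
    foot, left foot) and coordinate order (lateral x, vertical z);
    ``grounded`` is (n, 2) int8 for (right, left); ``diag`` is an optional
    (n, 10) block, see :data:`DIAG_COLUMNS`.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    grounded: np.ndarray
    diag: np.ndarray | None = None

    def __len__(self) -> int:
        return self.t.shape[0]

    # -- views -------------------------------------------------------------

    def foot_height(self, foot: int) -> np.ndarray:
        """Vertical position of a foot (1 = right, 2 = left)."""
        if foot not in (1, 2):
            raise ValueError("foot must be 1 (right) or 2 (left)")
        return self.pos[:, foot, 1]

    @property
    def trunk_x(self) -> np.ndarray:
        return self.pos[:, 0, 0]

    @property
    def trunk_z(self) -> np.ndarray:
        return self.pos[:, 0, 1]

    # -- combination --------------------------------------------------------

    @staticmethod
    def concatenate(parts: list["Trajectory"]) -> "Trajectory":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("no trajectory parts to concatenate")
        has_diag = all(p.diag is not None for p in parts)
        return Trajectory(
            t=np.concatenate([p.t for p in parts]),
            pos=np.concatenate([p.pos for p in parts]),
            vel=np.concatenate([p.vel for p in parts]),
            grounded=np.concatenate([p.grounded for p in parts]),
            diag=np.concatenate([p.diag for p in parts]) if has_diag else None,
        )

    def slice_time(self, t0: float, t1: float) -> "Trajectory":
        """Rows with t in the half-open window [t0, t1)."""
        mask = (self.t >= t0) & (self.t < t1)
        return Trajectory(
            t=self.t[mask],
            pos=self.pos[mask],
            vel=self.vel[mask],
            grounded=self.grounded[mask],
            diag=self.diag[mask] if self.diag is not None else None,
        )

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        data = {
            "t": self.t,
            "x_trunk": self.pos[:, 0, 0], "z_trunk": self.pos[:, 0, 1],
            "x_rfoot": self.pos[:, 1, 0], "z_rfoot": self.pos[:, 1, 1],
            "x_lfoot": self.pos[:, 2, 0], "z_lfoot": self.pos[:, 2, 1],
            "vx_trunk": self.vel[:, 0, 0], "vz_trunk": self.vel[:, 0, 1],
            "vx_rfoot": self.vel[:, 1, 0], "vz_rfoot": self.vel[:, 1, 1],
            "vx_lfoot": self.vel[:, 2, 0], "vz_lfoot": self.vel[:, 2, 1],
            "grounded_r": self.grounded[:, 0].astype(np.int8),
            "grounded_l": self.grounded[:, 1].astype(np.int8),
        }
        if self.diag is not None:
            for j, name in enumerate(DIAG_COLUMNS):
                data[name] = self.diag[:, j]
        frame = pd.DataFrame(data)
        frame.attrs["schema_version"] = SCHEMA_VERSION
        assert len(frame) == n
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Trajectory":
        n = len(frame)
        pos = np.empty((n, 3, 2))
        vel = np.empty((n, 3, 2))
        for m, tag in enumerate(("trunk", "rfoot", "lfoot")):
            pos[:, m, 0] = frame[f"x_{tag}"].to_numpy()
            pos[:, m, 1] = frame[f"z_{tag}"].to_numpy()
            vel[:, m, 0] = frame[f"vx_{tag}"].to_numpy()
            vel[:, m, 1] = frame[f"vz_{tag}"].to_numpy()
        diag = None
        if all(c in frame.columns for c in DIAG_COLUMNS):
            diag = frame[DIAG_COLUMNS].to_numpy(dtype=np.float64)
        grounded = np.stack(
            [frame["grounded_r"].to_numpy(), frame["grounded_l"].to_numpy()], axis=1
        ).astype(np.int8)
        return cls(frame["t"].to_numpy(dtype=np.float64), pos, vel, grounded, diag)

    def save_csv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# sidestep trajectory schema v{SCHEMA_VERSION}\n")
            frame.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")

    @classmethod
    def load_csv(cls, path) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["schema_version"] = SCHEMA_VERSION
            fh.create_dataset("t", data=self.t)
            fh.create_dataset("pos", data=self.pos)
            fh.create_dataset("vel", data=self.vel)
            fh.create_dataset("grounded", data=self.grounded)
            if self.diag is not None:
                fh.create_dataset("diag", data=self.diag)

    @classmethod
    def load_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            diag = fh["diag"][...] if "diag" in fh else None
            return cls(
                fh["t"][...], fh["pos"][...], fh["vel"][...],
                fh["grounded"][...], diag,
            )
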