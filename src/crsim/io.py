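"""Long-format dataset container and CSV readers/writers.

The on-disk format is a plain CSV with header ``id,time,status,group``:
one row per subject, ``time`` the observed time in days (event or censoring,
whichever came first), ``status`` an integer in 0..k with 0 meaning
censored, and ``group`` in {1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GroupData", "Dataset", "read_dataset", "write_dataset"]

_COLUMNS = ["id", "time", "status", "group"]


@dataclass
class GroupData:
    """Observed (time, status) pairs for one group."""

    times: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.times.shape != self.status.shape:
            raise ValueError("times and status must have equal length")

    @property
    def n(self) -> int:
        return self.times.size

    def n_events(self, k: int) -> np.ndarray:
        return np.array([int(np.sum(self.status == j)) for j in range(1, k + 1)])

    @property
    def n_censored(self) -> int:
        return int(np.sum(self.status == 0))


@dataclass
class Dataset:
    """Two-group competing-risks sample in long format."""

    df: pd.DataFrame
    k: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        self.df = self.df[_COLUMNS].reset_index(drop=True)
        self.df["time"] = self.df["time"].astype(float)
        for c in ("status", "group"):
            self.df[c] = self.df[c].astype(int)
        _validate_rows(self.df, self.k)

    @classmethod
    def from_groups(cls, g1: GroupData, g2: GroupData, k: int, meta: dict | None = None) -> "Dataset":
        df = pd.DataFrame(
            {
                "id": np.arange(g1.n + g2.n),
                "time": np.concatenate([g1.times, g2.times]),
                "status": np.concatenate([g1.status, g2.status]),
                "group": np.concatenate([np.ones(g1.n, int), np.full(g2.n, 2)]),
            }
        )
        return cls(df=df, k=k, meta=meta or {})

    def group(self, ell: int) -> GroupData:
        sub = self.df[self.df["group"] == ell]
        return GroupData(sub["time"].to_numpy(), sub["status"].to_numpy())

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def censored_fraction(self) -> float:
        return float(np.mean(self.df["status"].to_numpy() == 0))

    def summary(self) -> str:
        parts = []
        for ell in (1, 2):
            g = self.group(ell)
            counts = ", ".join(
                f"state {j}: {c}" for j, c in enumerate(g.n_events(self.k), 1)
            )
            parts.append(f"group {ell}: n={g.n}, censored={g.n_censored}, {counts}")
        return "; ".join(parts)


def _validate_rows(df: pd.DataFrame, k: int) -> None:
    bad = df.index[~df["group"].isin([1, 2])]
    if len(bad):
        raise ValueError(f"row {bad[0]}: group must be 1 or 2, got {df.loc[bad[0], 'group']}")
    status = df["status"]
    bad = df.index[(status < 0) | (status > k)]
    if len(bad):
        raise ValueError(
            f"row {bad[0]}: status {df.loc[bad[0], 'status']} out of range 0..{k}"
        )
    bad = df.index[~(df["time"] > 0) | ~np.isfinite(df["time"])]
    if len(bad):
        raise ValueError(f"row {bad[0]}: time must be positive, got {df.loc[bad[0], 'time']}")


def read_dataset(path, k: int) -> Dataset:
    """Read and validate a long-format CSV (columns id,time,status,group)."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["time"] = df["time"].astype(float)
    for c in ("status", "group"):
        df[c] = df[c].astype(int)
    return Dataset(df=df, k=k, meta={"source": str(path)})


def write_dataset(ds: Dataset, path) -> None:
    """Write the canonical CSV dialect (comma separated, header, fixed column
    order); round-trips bit-identically through :func:`read_dataset`."""
    ds.df.to_csv(path, index=False, columns=_COLUMNS)
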