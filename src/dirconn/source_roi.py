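"""Source projection and ROI reduction.

Sensor-space analytic signals are projected through a precomputed linear
inverse operator (3 dipole components per point source; computing the
operator itself — head model, regularization — is outside this package's
scope).  Power at a source is the squared norm of the 3-component complex
vector.  Power is z-scored across time per source to remove per-source
activation biases before averaging.

For connectivity, the source cloud inside each atlas ROI is reduced to a
single representative time course: the first component of the singular
value decomposition of the stacked member time series (all three dipole
orientations of every member source stacked as separate rows).  The SVD
sign indeterminacy is resolved by the majority-of-vectors rule: the
component is flipped so that most member rows load on it with positive
weight (ties favour no flip).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class InverseOperator:
    """Linear map from n_channels sensor signals to 3-component dipole
    time courses at n_sources grid points.

    ``weights`` is (n_sources, 3, n_channels); ``coords`` holds the MNI
    coordinates (mm) of each source.
    """

    weights: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.weights.ndim != 3 or self.weights.shape[1] != 3:
            raise ValueError("inverse weights must be (n_sources, 3, n_channels)")
        if self.coords.shape != (self.weights.shape[0], 3):
            raise ValueError("one 3-D coordinate is required per source")

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]

    @classmethod
    def from_files(cls, matrix_path, coords_path) -> "InverseOperator":
        """Load from a delimited (3*n_sources, n_channels) matrix and a
        whitespace-delimited x/y/z coordinate table."""
        flat = np.loadtxt(matrix_path)
        coords = np.loadtxt(coords_path, ndmin=2)
        if flat.shape[0] % 3:
            raise ValueError("inverse matrix must have 3 rows per source")
        weights = flat.reshape(-1, 3, flat.shape[1])
        return cls(weights=weights, coords=coords)


@dataclass
class SourceActivity:
    """Per-source dipole time courses and the derived power map.

    ``components`` is (n_sources, 3, n_samples) complex; ``power`` is the
    per-sample squared norm, (n_sources, n_samples), always >= 0.
    """

    components: np.ndarray
    power: np.ndarray
    coords: np.ndarray | None = None


def apply_inverse(sensor: np.ndarray, inv: InverseOperator) -> SourceActivity:
    """Project sensor analytic signals into source space.

    ``sensor`` is (n_samples, n_channels), real or complex; the map is
    applied independently to real and imaginary parts (it is linear, so
    this is one complex matrix product).  Per-source power is
    |s1|^2 + |s2|^2 + |s3|^2 over the three dipole components.
    """
    sensor = np.atleast_2d(np.asarray(sensor))
    if sensor.shape[1] != inv.n_channels:
        raise ValueError(
            f"sensor has {sensor.shape[1]} channels, operator expects "
            f"{inv.n_channels}"
        )
    # (n_samples, n_ch) x (n_src, 3, n_ch) -> (n_src, 3, n_samples)
    comps = np.tensordot(inv.weights, sensor, axes=([2], [1]))
    power = np.sum(np.abs(comps) ** 2, axis=1)
    return SourceActivity(components=comps, power=power, coords=inv.coords)


def standardize_power(
    power: np.ndarray, ddof: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score power across time independently for each source.

    Returns ``(z, valid)`` where ``valid`` flags sources with nonzero
    temporal variance; zero-variance sources get NaN rows and are meant
    to be excluded from statistics downstream.
    """
    power = np.asarray(power, dtype=float)
    mean = power.mean(axis=-1, keepdims=True)
    sd = power.std(axis=-1, ddof=ddof, keepdims=True)
    valid = (sd > 0).ravel()
    z = np.full_like(power, np.nan)
    z[valid] = (power[valid] - mean[valid]) / sd[valid]
    return z, valid


def condition_average_power(
    power_by_condition: dict[str, list[np.ndarray]], ddof: int = 0
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Average standardized power per source and condition.

    Power is z-scored once per source across the pooled time axis of all
    conditions' trials (standardizing within a condition and then
    averaging over the same window would be identically zero), then
    averaged across time and trials within each condition.  Returns the
    per-condition (n_sources,) averages and the valid-source mask.
    """
    conds = list(power_by_condition)
    lengths = {
        c: [np.asarray(p).shape[-1] for p in power_by_condition[c]] for c in conds
    }
    pooled = np.concatenate(
        [np.asarray(p, dtype=float) for c in conds for p in power_by_condition[c]],
        axis=-1,
    )
    z, valid = standardize_power(pooled, ddof=ddof)
    out = {}
    offset = 0
    for c in conds:
        n_c = sum(lengths[c])
        out[c] = z[..., offset : offset + n_c].mean(axis=-1)
        offset += n_c
    return out, valid


class RoiTable:
    """Atlas table: ROI id, abbreviation, MNI centroid and member sources.

    Backed by a DataFrame with columns ``roi``, ``abbrev``, ``x``, ``y``,
    ``z`` and a ``sources`` column holding comma-separated member source
    indices (may be empty when the table is used at ROI level only).
    """

    COLUMNS = ["roi", "abbrev", "x", "y", "z", "sources"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"RoiTable missing columns {missing}")
        if not np.all(np.isfinite(df[["x", "y", "z"]].to_numpy(dtype=float))):
            raise ValueError("ROI centroids must be finite")
        members = [self._parse_sources(s) for s in df["sources"]]
        flat = [i for m in members for i in m]
        if len(flat) != len(set(flat)):
            raise ValueError("a source may belong to at most one ROI")
        self.df = df.reset_index(drop=True)
        self._members = members

    @staticmethod
    def _parse_sources(s) -> list[int]:
        if isinstance(s, (list, tuple, np.ndarray)):
            return [int(i) for i in s]
        s = "" if s is None or (isinstance(s, float) and np.isnan(s)) else str(s)
        return [int(tok) for tok in s.split(",") if tok.strip() != ""]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def abbrevs(self) -> list[str]:
        return list(self.df["abbrev"])

    @property
    def centroids(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    def members(self, i: int) -> list[int]:
        return self._members[i]

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["sources"] = [",".join(str(i) for i in m) for m in self._members]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RoiTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sources": str}))


def leading_component(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First SVD component of a (n_rows, n_samples) stack, sign-corrected.

    Returns ``(time_course, weights)`` where ``time_course`` is the first
    right singular vector scaled by the first singular value and
    ``weights`` the corresponding loadings of the rows.  The sign is
    chosen so that the majority of rows load positively; an exact tie
    leaves the SVD's sign untouched.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    w = u[:, 0]
    tc = s[0] * vt[0]
    if np.sum(w > 0) < np.sum(w < 0):  # majority-of-vectors rule
        w, tc = -w, -tc
    return tc, w


def roi_reduce(
    source_signals: np.ndarray,
    roi_table: RoiTable,
    rows_per_source: int | None = None,
) -> np.ndarray:
    """One representative time course per ROI.

    ``source_signals`` is (n_rows, n_samples) of real band-filtered
    signals where consecutive triplets of rows are the three dipole
    orientations of one source (a single row per source is also accepted
    for orientation-free inputs; pass ``rows_per_source`` explicitly when
    the row count is ambiguous).  For each ROI, all rows of its member
    sources are stacked and reduced to the first sign-corrected SVD
    component.  Empty ROIs are rejected by id.
    """
    X = np.atleast_2d(np.asarray(source_signals, dtype=float))
    n_rows = X.shape[0]
    max_src = max(
        (max(roi_table.members(i), default=-1) for i in range(len(roi_table))),
        default=-1,
    )
    if rows_per_source is None:
        if n_rows == 3 * (max_src + 1):
            rows_per_source = 3
        elif n_rows >= max_src + 1:
            rows_per_source = 1
        else:
            raise ValueError(
                "source_signals rows must cover every source referenced by the ROI table"
            )
    if n_rows < rows_per_source * (max_src + 1):
        raise ValueError(
            "source_signals rows must cover every source referenced by the ROI table"
        )
    out = np.empty((len(roi_table), X.shape[1]))
    for i in range(len(roi_table)):
        members = roi_table.members(i)
        if not members:
            raise ValueError(f"ROI {roi_table.df['roi'].iloc[i]!r} has no member sources")
        rows = [
            r
            for src in members
            for r in range(rows_per_source * src, rows_per_source * (src + 1))
        ]
        out[i], _ = leading_component(X[rows])
    return out


def roi_series_to_tsv(path, series: np.ndarray, roi_table: RoiTable) -> None:
    """Write an (n_roi, n_samples) ROI series as a delimited matrix with a
    header row of ROI abbreviations (rows = samples)."""
    pd.DataFrame(series.T, columns=roi_table.abbrevs).to_csv(
        path, sep="\t", index=False
    )
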