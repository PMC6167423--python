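"""Spectral preprocessing: binning, total-area normalization, scaling.

Binned 1H-NMR spectra are held in a :class:`SpectraMatrix` (samples x ppm
bins).  The scaling state machine is one-way:

    raw -> normalized -> (centered | pareto | centered_pareto)

so a matrix can never be normalized or scaled twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraMatrix",
    "bin_spectra",
    "normalize_total_area",
    "scale",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_EXCLUSIONS",
]

#: Community-standard bucket width (ppm).
DEFAULT_BIN_WIDTH = 0.01
#: Residual-water and chemical-shift-reference regions dropped by default.
DEFAULT_EXCLUSIONS = ((4.5, 5.0), (-0.05, 0.05))

_SCALED_STATES = {"centered", "pareto", "centered_pareto"}
_STATES = {"raw", "normalized"} | _SCALED_STATES


@dataclass(frozen=True)
class SpectraMatrix:
    """Binned spectral intensities for a set of samples.

    ``ppm_centers`` is strictly monotone (stored descending by NMR
    convention, but every operation is order-agnostic).
    """

    intensities: np.ndarray  # (n_samples, n_bins)
    ppm_centers: np.ndarray  # (n_bins,)
    bin_width: float
    sample_ids: tuple[str, ...]
    scaling_state: str = "raw"
    constant_bins: tuple[int, ...] = ()  # zero-SD columns flagged by scale()

    def __post_init__(self) -> None:
        X = np.asarray(self.intensities, dtype=float)
        ppm = np.asarray(self.ppm_centers, dtype=float)
        object.__setattr__(self, "intensities", X)
        object.__setattr__(self, "ppm_centers", ppm)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if X.ndim != 2:
            raise ValueError("intensities must be 2-D (samples x bins)")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite intensities")
        if ppm.shape != (X.shape[1],):
            raise ValueError("ppm_centers length must equal the column count")
        d = np.diff(ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm_centers must be strictly monotone")
        if len(self.sample_ids) != X.shape[0]:
            raise ValueError("sample_ids length must equal the row count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if self.scaling_state not in _STATES:
            raise ValueError(f"unknown scaling_state {self.scaling_state!r}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_bins(self) -> int:
        return self.intensities.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=list(self.sample_ids), columns=self.ppm_centers
        )

    # ------------------------------------------------------------------
    def write_tsv(self, path) -> None:
        """First column ``sample_id``, header row of bin ppm centers."""
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path, bin_width: float = DEFAULT_BIN_WIDTH,
                 scaling_state: str = "raw") -> "SpectraMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            df.to_numpy(dtype=float),
            np.array([float(c) for c in df.columns]),
            bin_width,
            tuple(str(i) for i in df.index),
            scaling_state,
        )


# ----------------------------------------------------------------------
def bin_spectra(
    traces: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    bin_width: float = DEFAULT_BIN_WIDTH,
    exclusions: Iterable[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> SpectraMatrix:
    """Sum per-sample (ppm, intensity) points into fixed-width buckets.

    Bins are half-open ``[left, right)`` on an axis covering the ppm range
    shared by all traces; a point exactly on a bin's right edge falls in
    the next bin.  Any bin intersecting an exclusion interval is dropped
    entirely.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not traces:
        raise ValueError("no traces given")
    lows, highs = [], []
    for sid, (ppm, inten) in traces.items():
        ppm = np.asarray(ppm, float)
        inten = np.asarray(inten, float)
        if not np.all(np.isfinite(inten)) or not np.all(np.isfinite(ppm)):
            raise ValueError(f"non-finite values in trace {sid!r}")
        if ppm.size == 0:
            raise ValueError(f"empty trace {sid!r}")
        lows.append(ppm.min())
        highs.append(ppm.max())
    lo, hi = max(lows), min(highs)
    if hi <= lo:
        raise ValueError("traces share no overlapping ppm range")

    left = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - left) / bin_width)) + 1
    edges = left + bin_width * np.arange(n_bins + 1)
    centers = edges[:-1] + bin_width / 2.0

    sample_ids = list(traces)
    X = np.zeros((len(sample_ids), n_bins))
    for i, sid in enumerate(sample_ids):
        ppm, inten = traces[sid]
        ppm = np.asarray(ppm, float)
        inten = np.asarray(inten, float)
        inside = (ppm >= edges[0]) & (ppm < edges[-1])
        idx = np.floor((ppm[inside] - edges[0]) / bin_width).astype(int)
        np.add.at(X[i], idx, inten[inside])

    keep = np.ones(n_bins, bool)
    for a, b in exclusions:
        a, b = min(a, b), max(a, b)
        keep &= (edges[1:] <= a) | (edges[:-1] >= b)
    if not keep.any():
        raise ValueError("all bins excluded")
    # descending ppm axis by NMR convention
    order = np.argsort(centers[keep])[::-1]
    return SpectraMatrix(
        X[:, keep][:, order], centers[keep][order], bin_width, tuple(sample_ids)
    )


def normalize_total_area(m: SpectraMatrix) -> SpectraMatrix:
    """Divide each spectrum by its total intensity so rows sum to 1."""
    if m.scaling_state != "raw":
        raise ValueError(f"cannot normalize a {m.scaling_state!r} matrix")
    sums = m.intensities.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = [m.sample_ids[i] for i in bad]
        raise ValueError(f"non-positive total area for sample(s) {names}")
    return replace(
        m, intensities=m.intensities / sums[:, None], scaling_state="normalized"
    )


def scale(m: SpectraMatrix, method: str) -> SpectraMatrix:
    """Mean-center and/or Pareto-scale the columns.

    Pareto scaling divides each column by the square root of its sample
    standard deviation (ddof=1), damping but not flattening the intensity
    differences between spectral regions.  Columns with zero SD are left
    unscaled and recorded in ``constant_bins``.
    """
    if method not in {"center", "pareto", "center_pareto"}:
        raise ValueError(f"unknown scaling method {method!r}")
    if m.scaling_state in _SCALED_STATES:
        raise ValueError(f"matrix already scaled ({m.scaling_state!r})")
    if m.n_samples < 2:
        raise ValueError("scaling needs at least 2 samples")
    X = m.intensities
    sd = X.std(axis=0, ddof=1)
    constant = tuple(int(i) for i in np.flatnonzero(sd == 0))
    if "center" in method:
        X = X - X.mean(axis=0, keepdims=True)
    if "pareto" in method:
        divisor = np.where(sd > 0, np.sqrt(sd), 1.0)
        X = X / divisor
    state = {"center": "centered", "pareto": "pareto", "center_pareto": "centered_pareto"}
    return replace(m, intensities=X, scaling_state=state[method], constant_bins=constant)
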