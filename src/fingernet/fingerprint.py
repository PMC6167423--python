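"""Metabolic fingerprints: discriminant-bin selection and annotation.

A *metabolic fingerprint* is the set of metabolites whose spectral bins
are both influential in the discriminant model (VIP above a threshold)
and significantly different between groups (Kruskal-Wallis below alpha)
for one comparison.  Selected bins are annotated to metabolites by
nearest tabulated 1H chemical shift; fingerprints from several
comparisons aggregate into a metabolite x comparison flag table.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .chemometrics import VIPResult, kruskal_wallis
from .design import StudyDesign
from .preprocess import SpectraMatrix

__all__ = [
    "ShiftRow",
    "ShiftTable",
    "FingerprintEntry",
    "Fingerprint",
    "FingerprintTable",
    "select_discriminant_bins",
    "annotate_bins",
    "aggregate_fingerprints",
    "table_fingerprints",
    "load_shift_table",
    "PACKAGED_SHIFT_TABLES",
]

UNASSIGNED = "unassigned"

#: Packaged transcriptions of the study's discriminance tables:
#: per-metabolite 1H chemical shifts plus per-exposure-group flags.
PACKAGED_SHIFT_TABLES = {
    "bpa": "shifts_bpa.tsv",
    "e2": "shifts_e2.tsv",
    "combined": "shifts_combined.tsv",
}

_SHIFT_RE = re.compile(r"([0-9]+(?:\.[0-9]+)?)\s*(?:\(([^)]*)\))?")


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ShiftRow:
    metabolite: str
    shifts: tuple[tuple[float, str], ...]  # (ppm, multiplicity)
    flags: dict  # comparison/group label -> bool


@dataclass(frozen=True)
class ShiftTable:
    """Chemical-shift assignments, one row per metabolite."""

    rows: tuple[ShiftRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        names = [r.metabolite for r in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate metabolite names in shift table")
        for r in self.rows:
            for ppm, _ in r.shifts:
                if not -0.5 <= ppm <= 10:
                    raise ValueError(
                        f"{r.metabolite}: shift {ppm} ppm outside [-0.5, 10]"
                    )

    @property
    def metabolites(self) -> list[str]:
        return [r.metabolite for r in self.rows]

    @property
    def flag_columns(self) -> list[str]:
        cols: list[str] = []
        for r in self.rows:
            for c in r.flags:
                if c not in cols:
                    cols.append(c)
        return cols

    @classmethod
    def from_tsv(cls, path) -> "ShiftTable":
        tab = pd.read_csv(path, sep="\t", comment="#")
        flag_cols = [c for c in tab.columns if c not in ("metabolite", "shifts")]
        rows = []
        for _, rec in tab.iterrows():
            shifts = tuple(
                (float(m.group(1)), m.group(2) or "")
                for part in str(rec["shifts"]).split(";")
                if (m := _SHIFT_RE.search(part))
            )
            flags = {c: str(rec[c]).strip().lower() == "x" for c in flag_cols}
            rows.append(ShiftRow(str(rec["metabolite"]), shifts, flags))
        return cls(tuple(rows))


def load_shift_table(which: str) -> ShiftTable:
    """Load a packaged shift/flag table: ``"bpa"``, ``"e2"`` or ``"combined"``."""
    try:
        fname = PACKAGED_SHIFT_TABLES[which]
    except KeyError:
        raise ValueError(
            f"unknown table {which!r}; choose from {sorted(PACKAGED_SHIFT_TABLES)}"
        ) from None
    return ShiftTable.from_tsv(resources.files("fingernet.data") / fname)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FingerprintEntry:
    bin_ppm: float
    metabolite: str  # UNASSIGNED when no tabulated shift is close enough
    vip: float
    p_kw: float


@dataclass(frozen=True)
class Fingerprint:
    """Discriminant bins of one comparison, annotated to metabolites."""

    comparison_id: str
    entries: tuple[FingerprintEntry, ...]
    vip_threshold: float
    alpha: float

    @property
    def metabolites(self) -> list[str]:
        """Unique assigned metabolite names (unassigned bins excluded)."""
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.metabolite != UNASSIGNED:
                seen.setdefault(e.metabolite, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.bin_ppm, e.metabolite, e.vip, e.p_kw) for e in self.entries],
            columns=["bin_ppm", "metabolite", "vip", "p_kw"],
        )


@dataclass(frozen=True)
class FingerprintTable:
    """Metabolite x comparison discriminance flags."""

    table: pd.DataFrame  # bool, metabolites as index, comparisons as columns

    @property
    def n_unique_metabolites(self) -> int:
        return int(len(self.table.index))

    def write_tsv(self, path) -> None:
        out = self.table.replace({True: "x", False: ""})
        out.index.name = "metabolite"
        out.to_csv(path, sep="\t")


# ----------------------------------------------------------------------
def select_discriminant_bins(
    vip: VIPResult | np.ndarray,
    m: SpectraMatrix,
    design: StudyDesign,
    vip_threshold: float = 1.5,
    alpha: float = 0.05,
    fdr_correction: bool = False,
) -> pd.DataFrame:
    """Bins with VIP above threshold AND Kruskal-Wallis p below alpha.

    The Kruskal-Wallis test runs per bin across the groups of ``design``
    (use a 2-group subset design for a dose-vs-control comparison).  Both
    statistics are reported for every selected bin.  ``fdr_correction``
    applies Benjamini-Hochberg to the per-bin p-values before the alpha
    cut (off by default, matching the raw-threshold convention).
    """
    vip_arr = np.asarray(vip.vip if isinstance(vip, VIPResult) else vip, float)
    if vip_arr.shape != (m.n_bins,):
        raise ValueError(
            f"VIP length {vip_arr.shape} does not match the {m.n_bins} bins"
        )
    if vip_threshold <= 0 or not 0 < alpha < 1:
        raise ValueError("vip_threshold must be > 0 and alpha in (0, 1)")
    pvals = np.empty(m.n_bins)
    hstats = np.empty(m.n_bins)
    for j in range(m.n_bins):
        hstats[j], pvals[j] = kruskal_wallis(m.intensities[:, j], design)
    p_eff = _benjamini_hochberg(pvals) if fdr_correction else pvals
    selected = (vip_arr > vip_threshold) & (p_eff < alpha)
    return pd.DataFrame(
        {
            "bin_index": np.flatnonzero(selected),
            "ppm": m.ppm_centers[selected],
            "vip": vip_arr[selected],
            "kw_h": hstats[selected],
            "p_kw": p_eff[selected],
        }
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def annotate_bins(
    bins: pd.DataFrame,
    table: ShiftTable,
    tol_ppm: float = 0.02,
    comparison_id: str = "comparison",
    vip_threshold: float = 1.5,
    alpha: float = 0.05,
) -> Fingerprint:
    """Assign each selected bin to the metabolite owning the nearest
    tabulated shift within ``tol_ppm``.

    Ties are broken by smallest |delta ppm|, then alphabetically; bins
    with no shift within tolerance are kept with metabolite
    ``"unassigned"``.  Pure function of (bins, table, tol).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if not table.rows:
        raise ValueError("empty shift table")
    catalog = sorted(
        (ppm, row.metabolite)
        for row in table.rows
        for ppm, _ in row.shifts
    )
    entries = []
    for _, rec in bins.iterrows():
        ppm = float(rec["ppm"])
        diffs = [(abs(t - ppm), name) for t, name in catalog]
        dmin = min(d for d, _ in diffs) if diffs else math.inf
        if dmin <= tol_ppm + 1e-9:  # tolerance edge is inclusive despite float jitter
            # distances equal within float jitter tie-break alphabetically
            name = min(n for d, n in diffs if d <= dmin + 1e-9)
        else:
            name = UNASSIGNED
        entries.append(
            FingerprintEntry(
                ppm, name, float(rec.get("vip", math.nan)),
                float(rec.get("p_kw", math.nan)),
            )
        )
    return Fingerprint(comparison_id, tuple(entries), vip_threshold, alpha)


def aggregate_fingerprints(fps: list[Fingerprint]) -> FingerprintTable:
    """Union of assigned metabolites as rows, comparisons as columns."""
    if not fps:
        raise ValueError("need at least one fingerprint")
    mets: dict[str, None] = {}
    for fp in fps:
        for name in fp.metabolites:
            mets.setdefault(name, None)
    tab = pd.DataFrame(
        False, index=list(mets), columns=[fp.comparison_id for fp in fps]
    )
    for fp in fps:
        for name in fp.metabolites:
            tab.loc[name, fp.comparison_id] = True
    return FingerprintTable(tab)


def table_fingerprints(table: ShiftTable) -> list[Fingerprint]:
    """One fingerprint per flag column of a packaged shift table.

    Each flagged metabolite contributes one entry per tabulated shift;
    VIP and p are not part of the printed tables and are NaN.
    """
    fps = []
    for col in table.flag_columns:
        entries = tuple(
            FingerprintEntry(ppm, row.metabolite, math.nan, math.nan)
            for row in table.rows
            if row.flags.get(col)
            for ppm, _ in row.shifts
        )
        fps.append(Fingerprint(col, entries, math.nan, math.nan))
    return fps
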