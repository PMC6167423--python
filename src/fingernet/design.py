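"""Sample design: assignment of spectra to treatment groups.

A study design assigns every sample to exactly one treatment group
(compound x dose), with exactly one group flagged as the vehicle control.
The design drives the dummy response matrix of the discriminant models and
the group splits of the univariate tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StudyDesign", "default_design"]


@dataclass(frozen=True)
class StudyDesign:
    """Per-sample group assignment for a multi-group exposure study.

    Parameters
    ----------
    table
        One row per sample with columns ``sample_id``, ``compound``,
        ``dose_label``, ``group`` and ``group_index``.  ``group`` is the
        label used everywhere downstream (e.g. ``"BPA_1e-6M"`` or the
        control label).
    control_group
        The group label flagged as control; must occur in ``table``.
    """

    table: pd.DataFrame
    control_group: str

    def __post_init__(self) -> None:
        required = {"sample_id", "compound", "dose_label", "group", "group_index"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table misses columns {sorted(missing)}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        if self.control_group not in set(self.table["group"]):
            raise ValueError(f"control group {self.control_group!r} not in design")
        sizes = self.table.groupby("group").size()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(f"groups with fewer than 2 samples: {list(small.index)}")
        # one group label per group_index and vice versa
        pairs = self.table[["group", "group_index"]].drop_duplicates()
        if pairs["group"].duplicated().any() or pairs["group_index"].duplicated().any():
            raise ValueError("group labels and group_index must map one-to-one")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        """Group labels ordered by ``group_index``."""
        pairs = self.table[["group", "group_index"]].drop_duplicates()
        return list(pairs.sort_values("group_index")["group"])

    @property
    def labels(self) -> np.ndarray:
        """Per-sample group label, aligned with the table rows."""
        return self.table["group"].to_numpy()

    def group_sizes(self) -> dict[str, int]:
        sizes = self.table.groupby("group").size().to_dict()
        return {g: int(sizes[g]) for g in self.groups}

    # ------------------------------------------------------------------
    def indicator_matrix(self, center: bool = True) -> tuple[np.ndarray, list[str]]:
        """Dummy response matrix: one column per group, optionally column-centered.

        Returns ``(Y, group_order)`` with ``Y`` of shape (n_samples, n_groups).
        """
        groups = self.groups
        idx = {g: j for j, g in enumerate(groups)}
        Y = np.zeros((self.n_samples, len(groups)))
        for i, g in enumerate(self.labels):
            Y[i, idx[g]] = 1.0
        if center:
            Y = Y - Y.mean(axis=0, keepdims=True)
        return Y, groups

    def subset(self, groups: list[str]) -> tuple["StudyDesign", np.ndarray]:
        """Restrict the design to ``groups``; returns the design and row indices."""
        unknown = [g for g in groups if g not in self.groups]
        if unknown:
            raise ValueError(f"unknown group(s) in subset: {unknown}")
        mask = self.table["group"].isin(groups).to_numpy()
        sub = self.table.loc[mask].reset_index(drop=True)
        control = self.control_group if self.control_group in groups else groups[0]
        return StudyDesign(sub, control), np.flatnonzero(mask)

    def permuted(self, rng: np.random.Generator) -> "StudyDesign":
        """Design with group labels randomly reassigned to samples."""
        perm = rng.permutation(self.n_samples)
        tab = self.table.copy()
        for col in ("compound", "dose_label", "group", "group_index"):
            tab[col] = tab[col].to_numpy()[perm]
        return StudyDesign(tab, self.control_group)

    # ------------------------------------------------------------------
    @classmethod
    def from_group_sizes(
        cls,
        sizes: dict[str, int],
        control_group: str,
        compound_of: dict[str, str] | None = None,
    ) -> "StudyDesign":
        """Build a design from ``{group: n_samples}``.

        ``compound_of`` optionally maps group labels to compound names;
        by default the compound is the part of the label before ``"_"``.
        """
        rows = []
        for j, (group, n) in enumerate(sizes.items()):
            if compound_of and group in compound_of:
                compound = compound_of[group]
            else:
                compound = group.split("_")[0]
            dose = group.split("_", 1)[1] if "_" in group else group
            for k in range(n):
                rows.append(
                    {
                        "sample_id": f"{group}_s{k:02d}",
                        "compound": compound,
                        "dose_label": dose,
                        "group": group,
                        "group_index": j,
                    }
                )
        return cls(pd.DataFrame(rows), control_group)

    @classmethod
    def read_tsv(cls, path, control_group: str | None = None) -> "StudyDesign":
        """Read a 3-column TSV (sample_id, compound, dose_label).

        The group label is ``"{compound}_{dose_label}"`` except for rows with
        ``dose_label == "control"``, whose group is the compound (vehicle)
        name itself.  If ``control_group`` is None the single group with
        dose_label ``"control"`` is used.
        """
        tab = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "compound", "dose_label"}
        if not required <= set(tab.columns):
            raise ValueError(f"design TSV needs columns {sorted(required)}")
        tab["group"] = np.where(
            tab["dose_label"] == "control",
            tab["compound"],
            tab["compound"] + "_" + tab["dose_label"],
        )
        order = {g: j for j, g in enumerate(pd.unique(tab["group"]))}
        tab["group_index"] = tab["group"].map(order)
        if control_group is None:
            controls = sorted(tab.loc[tab["dose_label"] == "control", "group"].unique())
            if len(controls) != 1:
                raise ValueError(f"expected exactly one control group, found {controls}")
            control_group = controls[0]
        return cls(tab, control_group)

    def write_tsv(self, path) -> None:
        self.table[["sample_id", "compound", "dose_label"]].to_csv(
            path, sep="\t", index=False
        )


def default_design(compounds: tuple[str, ...] = ("BPA",)) -> StudyDesign:
    """The hepatic-cell exposure design used throughout the examples.

    One DMSO vehicle-control group of 17 samples plus three dose groups of
    12 samples per compound.  Doses follow the study layout: BPA at 1e-6,
    1e-9 and 1e-12 M; E2 (17beta-estradiol) at 1e-9, 1e-12 and 1e-15 M.
    """
    doses = {
        "BPA": ["1e-6M", "1e-9M", "1e-12M"],
        "E2": ["1e-9M", "1e-12M", "1e-15M"],
    }
    sizes: dict[str, int] = {"DMSO": 17}
    compound_of = {"DMSO": "DMSO"}
    for c in compounds:
        labels = doses.get(c, ["1e-6M", "1e-9M", "1e-12M"])
        for d in labels:
            sizes[f"{c}_{d}"] = 12
            compound_of[f"{c}_{d}"] = c
    return StudyDesign.from_group_sizes(sizes, "DMSO", compound_of)
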