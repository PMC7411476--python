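"""Cytokine panel data model and I/O.

A *panel table* is the animal x cytokine concentration matrix (pg/mL)
produced by a multiplex immunoassay, annotated with an experimental
``group`` and ``timepoint`` per animal.  Every downstream analysis track
(group statistics, correlation networks, cell-cell communication
networks) consumes this one structure.

Two delimited-text layouts are supported:

* **wide** — columns ``animal_id, group, timepoint`` followed by one
  column per cytokine;
* **long** — columns ``animal_id, group, timepoint, cytokine, value``.

The default 24-cytokine roster is the Bio-Plex rat 24-plex analyte list
(23 multiplex analytes plus CRP), grouped into chemokines, innate
cytokines, adaptive cytokines and growth factors.  Cytokine names are
normalised on read through a fixed alias table so that ASCII spellings
(``IL-1b``, ``TNF-alpha``) and Greek spellings (``IL-1β``, ``TNF-α``)
refer to the same analyte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CYTOKINE_CLASSES",
    "CYTOKINE_ROSTER",
    "DEFAULT_FLOOR",
    "CellCytokineMap",
    "PanelFormatError",
    "PanelTable",
    "PanelValidationError",
    "StratumNotFoundError",
    "default_cell_map",
    "normalize_cytokine",
    "read_cell_map",
    "read_panel",
    "stratify",
    "write_panel",
]

#: Kit floor for below-detection concentrations, pg/mL.  Values read in
#: below this floor (including zeros) are stored at the floor, never as
#: missing, so that correlations and fold changes stay total.
DEFAULT_FLOOR = 0.01

#: Cytokine -> functional class for the default 24-analyte roster.
CYTOKINE_CLASSES: dict[str, str] = {
    # chemokines
    "MCP-1": "chemokine",
    "CXCL1": "chemokine",
    "MIP-1α": "chemokine",
    "MIP-3α": "chemokine",
    "RANTES": "chemokine",
    # innate immunity
    "IL-1α": "innate",
    "IL-1β": "innate",
    "IL-6": "innate",
    "TNF-α": "innate",
    "IL-7": "innate",
    "IL-18": "innate",
    "CRP": "innate",
    # adaptive immunity
    "IL-2": "adaptive",
    "IL-4": "adaptive",
    "IL-5": "adaptive",
    "IL-10": "adaptive",
    "IL-12": "adaptive",
    "IL-13": "adaptive",
    "IL-17": "adaptive",
    "IFN-γ": "adaptive",
    # growth factors
    "GM-CSF": "growth_factor",
    "G-CSF": "growth_factor",
    "M-CSF": "growth_factor",
    "VEGF": "growth_factor",
}

#: Canonical 24-cytokine roster, in class order.
CYTOKINE_ROSTER: tuple[str, ...] = tuple(CYTOKINE_CLASSES)


class PanelFormatError(ValueError):
    """A panel or mapping file does not match the documented layout."""


class PanelValidationError(ValueError):
    """File parsed, but the content violates a data-model invariant."""


class StratumNotFoundError(KeyError):
    """A requested (group, timepoint) stratum has no animals."""


# ---------------------------------------------------------------------------
# name normalisation

def _fold(name: str) -> str:
    return "".join(str(name).split()).lower()


def _build_alias_table() -> dict[str, str]:
    table: dict[str, str] = {}
    for canon in CYTOKINE_ROSTER:
        table[_fold(canon)] = canon
    greek = {"α": ("a", "alpha"), "β": ("b", "beta"), "γ": ("g", "gamma", "y")}
    for canon in CYTOKINE_ROSTER:
        for letter, subs in greek.items():
            if letter in canon:
                for sub in subs:
                    table[_fold(canon.replace(letter, sub))] = canon
    # spellings seen in vendor sheets and papers
    extras = {
        "cxcl-1": "CXCL1",
        "gro/kc": "CXCL1",
        "mip-3": "MIP-3α",  # bare form used interchangeably with MIP-3α
        "ccl2": "MCP-1",
        "ccl3": "MIP-1α",
        "ccl20": "MIP-3α",
        "ccl5": "RANTES",
        "ifng": "IFN-γ",
        "tnf": "TNF-α",
    }
    table.update(extras)
    return table


_ALIASES = _build_alias_table()


def normalize_cytokine(name: str) -> str:
    """Map a cytokine spelling to its canonical roster name.

    Unknown names are returned stripped but otherwise unchanged, so
    panels with analytes outside the default roster still load.
    """
    return _ALIASES.get(_fold(name), str(name).strip())


# ---------------------------------------------------------------------------
# PanelTable

@dataclass
class PanelTable:
    """Animal x cytokine concentration matrix with design annotations.

    Parameters
    ----------
    values
        DataFrame indexed by animal id, one float column per cytokine.
    groups, timepoints
        Per-animal labels, aligned with ``values.index``.
    """

    values: pd.DataFrame
    groups: pd.Series
    timepoints: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups, index=self.values.index).astype(str)
        self.timepoints = pd.Series(self.timepoints, index=self.values.index).astype(str)
        self._validate()

    def _validate(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise PanelValidationError(f"duplicate animal ids: {dupes}")
        if pd.Index(self.values.columns).has_duplicates:
            raise PanelValidationError("duplicate cytokine names in panel")
        bad = ~np.isfinite(self.values.to_numpy())
        bad |= self.values.to_numpy() < 0
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                f"(animal={self.values.index[r]}, cytokine={self.values.columns[c]}, "
                f"value={self.values.iat[r, c]!r})"
                for r, c in zip(rows, cols)
            ]
            raise PanelValidationError(
                "concentrations must be finite and >= 0; offending cells: "
                + "; ".join(cells[:20])
            )

    # -- accessors ---------------------------------------------------------

    @property
    def cytokine_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_animals(self) -> int:
        return len(self.values)

    def group_labels(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def timepoint_labels(self) -> list[str]:
        return list(dict.fromkeys(self.timepoints))

    # -- operations --------------------------------------------------------

    def stratify(self, group: str, timepoint: str) -> "PanelTable":
        """Sub-table of exactly the animals in one (group, timepoint) cell."""
        mask = (self.groups == str(group)) & (self.timepoints == str(timepoint))
        if not mask.any():
            raise StratumNotFoundError(
                f"no animals in stratum (group={group!r}, timepoint={timepoint!r})"
            )
        return PanelTable(
            values=self.values.loc[mask].copy(),
            groups=self.groups.loc[mask].copy(),
            timepoints=self.timepoints.loc[mask].copy(),
        )

    def strata(self) -> Iterator[tuple[tuple[str, str], "PanelTable"]]:
        for g in self.group_labels():
            for t in self.timepoint_labels():
                mask = (self.groups == g) & (self.timepoints == t)
                if mask.any():
                    yield (g, t), self.stratify(g, t)

    def to_wide(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"animal_id": self.values.index, "group": self.groups.values,
             "timepoint": self.timepoints.values}
        )
        for c in self.values.columns:
            out[c] = self.values[c].values
        return out

    def to_long(self) -> pd.DataFrame:
        wide = self.to_wide()
        return wide.melt(
            id_vars=["animal_id", "group", "timepoint"],
            var_name="cytokine",
            value_name="value",
        )

    def equals(self, other: "PanelTable") -> bool:
        return (
            self.values.equals(other.values)
            and self.groups.equals(other.groups)
            and self.timepoints.equals(other.timepoints)
        )


def stratify(panel: PanelTable, group: str, timepoint: str) -> PanelTable:
    """Functional alias for :meth:`PanelTable.stratify`."""
    return panel.stratify(group, timepoint)


# ---------------------------------------------------------------------------
# panel I/O

_META_COLS = ("animal_id", "group", "timepoint")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_panel(
    path: str | Path,
    layout: str = "wide",
    floor: float = DEFAULT_FLOOR,
) -> PanelTable:
    """Read a panel table from delimited text (comma or tab separated).

    Values below ``floor`` (the kit's detection floor, pg/mL) are stored
    at the floor; negative or non-numeric values raise
    :class:`PanelValidationError` naming the offending cells.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    df = _read_delimited(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing required columns {missing}")
    if layout == "long":
        for c in ("cytokine", "value"):
            if c not in df.columns:
                raise PanelFormatError(f"{path}: long layout requires column {c!r}")
        df = df.copy()
        df["cytokine"] = df["cytokine"].map(normalize_cytokine)
        wide = df.pivot_table(
            index=["animal_id", "group", "timepoint"],
            columns="cytokine",
            values="value",
            aggfunc="first",
            sort=False,
        ).reset_index()
        wide.columns.name = None
        # preserve first-appearance cytokine order from the long file
        order = list(dict.fromkeys(df["cytokine"]))
        df = wide[list(_META_COLS) + order]
    else:
        df = df.rename(columns={c: normalize_cytokine(c) for c in df.columns
                                if c not in _META_COLS})
    cyto_cols = [c for c in df.columns if c not in _META_COLS]
    if not cyto_cols:
        raise PanelFormatError(f"{path}: no cytokine columns found")
    vals = df[cyto_cols].apply(pd.to_numeric, errors="coerce")
    nonnum = vals.isna() & df[cyto_cols].notna()
    if nonnum.to_numpy().any():
        rows, cols = np.nonzero(nonnum.to_numpy())
        cells = [
            f"(animal={df['animal_id'].iat[r]}, cytokine={cyto_cols[c]}, "
            f"value={df[cyto_cols[c]].iat[r]!r})"
            for r, c in zip(rows, cols)
        ]
        raise PanelValidationError(
            "non-numeric concentrations: " + "; ".join(cells[:20])
        )
    neg = vals.to_numpy() < 0
    if neg.any():
        rows, cols = np.nonzero(neg)
        cells = [
            f"(animal={df['animal_id'].iat[r]}, cytokine={cyto_cols[c]}, "
            f"value={vals.iat[r, c]})"
            for r, c in zip(rows, cols)
        ]
        raise PanelValidationError(
            "negative concentrations: " + "; ".join(cells[:20])
        )
    vals = vals.clip(lower=floor)
    vals.index = pd.Index(df["animal_id"].astype(str), name="animal_id")
    return PanelTable(
        values=vals,
        groups=pd.Series(df["group"].astype(str).values, index=vals.index),
        timepoints=pd.Series(df["timepoint"].astype(str).values, index=vals.index),
    )


def write_panel(panel: PanelTable, path: str | Path, layout: str = "wide") -> None:
    """Write a panel table as comma-separated text in either layout."""
    if layout == "wide":
        panel.to_wide().to_csv(path, index=False)
    elif layout == "long":
        panel.to_long().to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


# ---------------------------------------------------------------------------
# cell-cytokine mapping

@dataclass
class CellCytokineMap:
    """Per-cytokine secretory-cell and target-cell memberships.

    ``secretors[c]`` is the set of roster cells that produce cytokine
    ``c``; ``targets[c]`` the set of cells it acts on.  Pairs absent from
    the map score zero in communication calculations.
    """

    cell_roster: tuple[str, ...]
    secretors: dict[str, frozenset[str]]
    targets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_roster = tuple(str(c) for c in self.cell_roster)
        roster = set(self.cell_roster)
        if len(roster) != len(self.cell_roster):
            raise PanelValidationError("duplicate cells in roster")
        self.secretors = {normalize_cytokine(k): frozenset(v)
                          for k, v in self.secretors.items()}
        self.targets = {normalize_cytokine(k): frozenset(v)
                        for k, v in self.targets.items()}
        for role, mapping in (("secretors", self.secretors),
                              ("targets", self.targets)):
            for cyto, cells in mapping.items():
                unknown = cells - roster
                if unknown:
                    raise PanelValidationError(
                        f"{role}[{cyto}]: unknown cells {sorted(unknown)}"
                    )
        for cyto in set(self.secretors) | set(self.targets):
            if not self.secretors.get(cyto) and not self.targets.get(cyto):
                warnings.warn(
                    f"cytokine {cyto!r} has no secretory and no target cells "
                    "(isolated; it contributes nothing to communication scores)",
                    stacklevel=2,
                )

    @property
    def cytokines(self) -> list[str]:
        return sorted(set(self.secretors) | set(self.targets))

    def validate_against(self, cytokines: Iterable[str]) -> None:
        """Require every panel cytokine to appear in both mappings."""
        missing = [c for c in cytokines
                   if c not in self.secretors or c not in self.targets]
        if missing:
            raise PanelValidationError(
                f"cell map missing cytokines: {missing}"
            )

    def secretes(self, cell: str, cytokine: str) -> bool:
        return cell in self.secretors.get(cytokine, frozenset())

    def targeted_by(self, cell: str, cytokine: str) -> bool:
        return cell in self.targets.get(cytokine, frozenset())


def _map_from_mapping(doc: Mapping) -> CellCytokineMap:
    for key in ("cells", "secretors", "targets"):
        if key not in doc:
            raise PanelFormatError(f"cell map missing top-level key {key!r}")
    return CellCytokineMap(
        cell_roster=tuple(doc["cells"]),
        secretors={k: frozenset(v or ()) for k, v in doc["secretors"].items()},
        targets={k: frozenset(v or ()) for k, v in doc["targets"].items()},
    )


def _map_from_edge_list(df: pd.DataFrame,
                        cell_roster: Iterable[str] | None) -> CellCytokineMap:
    need = {"cytokine", "cell", "role"}
    if not need.issubset(df.columns):
        raise PanelFormatError(
            f"edge-list cell map requires columns {sorted(need)}"
        )
    bad_roles = set(df["role"]) - {"secretor", "target"}
    if bad_roles:
        raise PanelFormatError(f"unknown roles in cell map: {sorted(bad_roles)}")
    roster = tuple(cell_roster) if cell_roster is not None else tuple(
        dict.fromkeys(df["cell"])
    )
    secretors: dict[str, set[str]] = {}
    targets: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        cyto = normalize_cytokine(row["cytokine"])
        dest = secretors if row["role"] == "secretor" else targets
        dest.setdefault(cyto, set()).add(str(row["cell"]))
    all_cytos = set(secretors) | set(targets)
    return CellCytokineMap(
        cell_roster=roster,
        secretors={c: frozenset(secretors.get(c, ())) for c in all_cytos},
        targets={c: frozenset(targets.get(c, ())) for c in all_cytos},
    )


def read_cell_map(path: str | Path,
                  cell_roster: Iterable[str] | None = None) -> CellCytokineMap:
    """Read a cell-cytokine map.

    Accepts either structured text (YAML with top-level keys ``cells``,
    ``secretors``, ``targets``) or a three-column delimited edge list
    ``cytokine, cell, role`` with role in {secretor, target}.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        return _map_from_mapping(yaml.safe_load(text))
    head = text.lstrip().splitlines()[0] if text.strip() else ""
    if "cytokine" in head and "role" in head:
        return _map_from_edge_list(_read_delimited(path), cell_roster)
    doc = yaml.safe_load(text)
    if isinstance(doc, Mapping):
        return _map_from_mapping(doc)
    raise PanelFormatError(f"{path}: unrecognised cell-map format")


def default_cell_map() -> CellCytokineMap:
    """The packaged default mapping over the 28-cell roster.

    The mapping is an editorial reconstruction from standard immunology
    references; see the file header of ``data/cell_map.yaml``.
    """
    from importlib.resources import files

    resource = files("cytonet.data").joinpath("cell_map.yaml")
    cmap = _map_from_mapping(yaml.safe_load(resource.read_text(encoding="utf-8")))
    cmap.validate_against(CYTOKINE_ROSTER)
    return cmap
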