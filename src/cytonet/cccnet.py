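"""Directed weighted cell-cell communication (CCC) networks.

The communication effect from a secretory cell to a target cell under a
condition contrast is

    Ecc(s, t) = sum_i  S_i(s) * F_i(t) * p'_i

over the panel cytokines i, where S_i(s) = 1 iff cell s secretes
cytokine i, F_i(t) = 1 iff cytokine i targets cell t (both from the
cell-cytokine map), and p'_i is the signed relative change of the
cytokine's mean concentration between the condition stratum and the
reference stratum:

    p'_i = (mean_cond(i) - mean_ref(i)) / max(mean_ref(i), floor).

The cell x cell matrix E of Ecc values (rows = secretory cells,
columns = target cells; the diagonal, autocrine communication, is
included) is aggregated into:

* ``secretory_density`` — row sums (a cell's total outgoing signal);
* ``target_density`` — column sums (total incoming signal);
* ``network_sd`` — grand total of E, the whole-network communication
  density of the contrast;
* ``cell_sd`` — |secretory density| + |target density| per cell.

Key cells are the argmaxes of target density, secretory density and
cell_sd; ties are logged and broken by roster order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .panel import CellCytokineMap, PanelTable

__all__ = [
    "CCCNetwork",
    "ConditionContrast",
    "KeyCellScreen",
    "build_ccc",
    "condition_delta",
    "ecc",
    "screen_key_cells",
]

DEFAULT_FLOOR = 0.01


@dataclass
class ConditionContrast:
    """Per-cytokine signed relative changes between two strata."""

    condition: tuple[str, str]
    reference: tuple[str, str]
    delta: pd.Series  # cytokine -> p'

    def __post_init__(self) -> None:
        self.delta = pd.Series(self.delta, dtype=float)
        if not np.isfinite(self.delta.to_numpy()).all():
            bad = self.delta.index[~np.isfinite(self.delta)].tolist()
            raise ValueError(f"non-finite relative changes for {bad}")


def condition_delta(
    panel: PanelTable,
    condition: tuple[str, str],
    reference: tuple[str, str],
    floor: float = DEFAULT_FLOOR,
    mode: str = "relative",
) -> ConditionContrast:
    """Compute p' for every cytokine between two (group, timepoint) strata.

    ``mode="relative"`` is the default signed relative change; the
    alternative ``mode="difference"`` uses the raw mean difference
    (pg/mL) for sensitivity analysis.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    if mode not in ("relative", "difference"):
        raise ValueError(f"unknown delta mode {mode!r}")
    cond = panel.stratify(*condition)
    ref = panel.stratify(*reference)
    m_cond = cond.values.mean(axis=0)
    m_ref = ref.values.mean(axis=0)
    if mode == "relative":
        delta = (m_cond - m_ref) / np.maximum(m_ref, floor)
    else:
        delta = m_cond - m_ref
    return ConditionContrast(condition=tuple(condition),
                             reference=tuple(reference), delta=delta)


def _roster_check(cmap: CellCytokineMap, *cells: str) -> None:
    roster = set(cmap.cell_roster)
    for c in cells:
        if c not in roster:
            raise KeyError(f"cell {c!r} not in roster")


def ecc(
    contrast: ConditionContrast,
    cmap: CellCytokineMap,
    secretory_cell: str,
    target_cell: str,
) -> float:
    """Communication effect of one ordered cell pair (diagonal allowed)."""
    _roster_check(cmap, secretory_cell, target_cell)
    total = 0.0
    for cyto, dp in contrast.delta.items():
        if cmap.secretes(secretory_cell, cyto) and cmap.targeted_by(target_cell, cyto):
            total += dp
    return float(total)


@dataclass
class CCCNetwork:
    """Directed weighted cell graph with its density aggregates."""

    cells: tuple[str, ...]
    E: pd.DataFrame  # rows = secretory cells, columns = target cells
    secretory_density: pd.Series = field(init=False)
    target_density: pd.Series = field(init=False)
    network_sd: float = field(init=False)
    cell_sd: pd.Series = field(init=False)
    contrast: ConditionContrast | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.E.to_numpy()).all():
            raise ValueError("E contains non-finite entries")
        self.secretory_density = self.E.sum(axis=1)
        self.target_density = self.E.sum(axis=0)
        self.network_sd = float(self.E.to_numpy().sum())
        self.cell_sd = self.secretory_density.abs() + self.target_density.abs()

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.cells)
        for s in self.cells:
            for t in self.cells:
                w = self.E.at[s, t]
                if w != 0:
                    g.add_edge(s, t, ecc=float(w), weight=abs(float(w)))
        return g


def build_ccc(
    contrast: ConditionContrast,
    cmap: CellCytokineMap,
    include_diagonal: bool = True,
) -> CCCNetwork:
    """Fill E over all ordered roster pairs and aggregate densities.

    Vectorised as E = S diag(p') F^T with S, F the 0/1 secretor and
    target membership matrices (cells x cytokines).  Autocrine
    (diagonal) terms are included by default; ``include_diagonal=False``
    zeroes them for sensitivity analysis.
    """
    cells = list(cmap.cell_roster)
    cytos = list(contrast.delta.index)
    s_mat = np.array([[cmap.secretes(c, k) for k in cytos] for c in cells],
                     dtype=float)
    f_mat = np.array([[cmap.targeted_by(c, k) for k in cytos] for c in cells],
                     dtype=float)
    e = (s_mat * contrast.delta.to_numpy()) @ f_mat.T
    if not include_diagonal:
        np.fill_diagonal(e, 0.0)
    frame = pd.DataFrame(e, index=pd.Index(cells, name="secretory_cell"),
                         columns=pd.Index(cells, name="target_cell"))
    return CCCNetwork(cells=tuple(cells), E=frame, contrast=contrast)


@dataclass
class KeyCellScreen:
    """Argmax key cells of a CCC network, with tie provenance."""

    key_target: str
    key_secretory: str
    key_total: str
    tie_log: list[str] = field(default_factory=list)


def _argmax_roster(series: pd.Series, label: str,
                   tie_log: list[str]) -> str:
    top = series.max()
    winners = list(series.index[series == top])
    if len(winners) > 1:
        tie_log.append(
            f"{label}: {len(winners)}-way tie at {top:g} between "
            f"{winners}; first by roster order reported"
        )
    return winners[0]


def screen_key_cells(net: CCCNetwork) -> KeyCellScreen:
    """Maxima of target density, secretory density (signed) and cell_sd."""
    if not net.cells:
        raise ValueError("empty cell roster")
    tie_log: list[str] = []
    return KeyCellScreen(
        key_target=_argmax_roster(net.target_density, "target_density", tie_log),
        key_secretory=_argmax_roster(net.secretory_density, "secretory_density",
                                     tie_log),
        key_total=_argmax_roster(net.cell_sd, "cell_sd", tie_log),
        tie_log=tie_log,
    )


# ---------------------------------------------------------------------------
# export

def density_table(net: CCCNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "secretory_density": net.secretory_density,
            "target_density": net.target_density,
            "cell_sd": net.cell_sd,
        }
    )


def write_edge_list(net: CCCNetwork, path) -> None:
    rows = [
        (s, t, net.E.at[s, t])
        for s in net.cells
        for t in net.cells
        if net.E.at[s, t] != 0
    ]
    pd.DataFrame(rows, columns=["source_cell", "target_cell", "ecc"]).to_csv(
        path, index=False
    )


def write_graphml(net: CCCNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)
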