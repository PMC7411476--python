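"""Three-track orchestration and the cross-track consensus summary.

``run_pipeline`` loads (or simulates) a panel, runs the statistics
track, the correlation-network track per requested stratum and the CCC
track per condition contrast, writes all tables / networks / figures
into an output directory, and returns a :class:`ConsensusSummary`
flagging items selected by two or more tracks at each timepoint.

The consensus rule (>= 2 tracks) is an explicit artifact convention —
the cross-track synthesis it automates is otherwise narrative — and
every listed item keeps per-track provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cccnet import build_ccc, condition_delta, density_table, screen_key_cells
from .cccnet import write_edge_list as write_ccc_edge_list
from .corrnet import (
    build_network,
    correlation_matrix,
    network_str,
    node_metrics,
    screen_key_cytokines,
    write_edge_list,
    write_graphml,
)
from .panel import CellCytokineMap, PanelTable, default_cell_map, read_cell_map, read_panel, write_panel
from .simulate import SimConfig, simulate_panel
from .stats import key_cytokines, results_table, screen_all

__all__ = ["ConsensusSummary", "RunConfig", "consensus", "run_pipeline"]

log = logging.getLogger("cytonet")

DEFAULT_CONTRAST_PAIRS = (("CFA", "control"), ("CFA+MA", "CFA"))


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one serialisable record."""

    panel_path: str | None = None
    layout: str = "wide"
    cell_map_path: str | None = None
    sim: SimConfig | None = None
    threshold: float = 0.8
    alpha: float = 0.05
    #: group-level contrast pairs (condition group, reference group),
    #: applied at every timepoint
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRAST_PAIRS
    #: groups whose per-timepoint correlation networks are built
    network_groups: tuple[str, ...] = ("CFA", "CFA+MA")
    #: group whose network-track key set feeds the consensus
    consensus_group: str = "CFA+MA"
    key_contrast: tuple[str, str] = ("CFA+MA", "CFA")
    log_scale_corr: bool = False
    bh_correct: bool = False
    zero_diagonal_ccc: bool = False
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.panel_path is None and self.sim is None:
            raise ValueError("provide either panel_path or a simulation config")


@dataclass
class ConsensusSummary:
    """Per-timepoint key items with track provenance.

    ``entries`` maps timepoint -> list of records with keys ``item``,
    ``kind`` (cytokine/cell), ``tracks`` and ``consensus``.
    """

    entries: dict[str, list[dict]] = field(default_factory=dict)

    def consensus_items(self, timepoint: str) -> list[str]:
        return [e["item"] for e in self.entries.get(timepoint, [])
                if e["consensus"]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tp, items in self.entries.items():
            for e in items:
                rows.append({"timepoint": tp, **e,
                             "tracks": "+".join(e["tracks"])})
        return pd.DataFrame(rows,
                            columns=["timepoint", "item", "kind", "tracks",
                                     "consensus"])


def consensus(
    stat_keys: dict[str, list[str]],
    network_keys: dict[str, list[str]],
    cell_keys: dict[str, list[str]],
) -> ConsensusSummary:
    """Merge per-track key lists; flag items selected by >= 2 tracks."""
    summary = ConsensusSummary()
    timepoints = list(dict.fromkeys(
        [*stat_keys, *network_keys, *cell_keys]
    ))
    for tp in timepoints:
        tracks_of: dict[str, list[str]] = {}
        kind_of: dict[str, str] = {}
        for track, keys, kind in (
            ("stats", stat_keys.get(tp, []), "cytokine"),
            ("corr_network", network_keys.get(tp, []), "cytokine"),
            ("ccc", cell_keys.get(tp, []), "cell"),
        ):
            for item in keys:
                tracks_of.setdefault(item, []).append(track)
                kind_of[item] = kind
        entries = [
            {"item": item, "kind": kind_of[item], "tracks": tracks,
             "consensus": len(tracks) >= 2}
            for item, tracks in tracks_of.items()
        ]
        if entries:
            summary.entries[tp] = entries
    return summary


def _load_inputs(config: RunConfig) -> tuple[PanelTable, CellCytokineMap]:
    try:
        if config.panel_path is not None:
            panel = read_panel(config.panel_path, layout=config.layout)
        else:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            panel = simulate_panel(sim)
    except Exception as err:
        raise PipelineError(f"[stage: panel-load] {err}") from err
    try:
        if config.cell_map_path is not None:
            cmap = read_cell_map(config.cell_map_path)
        else:
            cmap = default_cell_map()
        cmap.validate_against(panel.cytokine_names)
    except Exception as err:
        raise PipelineError(f"[stage: cell-map] {err}") from err
    return panel, cmap


def run_pipeline(config: RunConfig, outdir: str | Path) -> ConsensusSummary:
    """Execute all three tracks and write artifacts into ``outdir``."""
    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        panel, cmap = _load_inputs(config)
        write_panel(panel, outdir / "panel.csv", layout="wide")
        log.info("panel loaded: %d animals x %d cytokines",
                 panel.n_animals, len(panel.cytokine_names))

        # --- statistics track ------------------------------------------
        try:
            results = screen_all(panel, alpha=config.alpha,
                                 key_contrast=config.key_contrast,
                                 bh_correct=config.bh_correct)
        except Exception as err:
            raise PipelineError(f"[stage: group-stats] {err}") from err
        results_table(results).to_csv(outdir / "stats_results.csv", index=False)
        stat_keys = key_cytokines(results)
        with open(outdir / "key_cytokines_stats.json", "w") as fh:
            json.dump(stat_keys, fh, indent=2, ensure_ascii=False)
        for r in results:
            log.info("stats %s @ %s: branch=%s key=%s", r.cytokine,
                     r.timepoint, r.method_trail.get("branch"), r.is_key)

        # --- correlation-network track ---------------------------------
        network_keys: dict[str, list[str]] = {}
        net_summary_rows = []
        try:
            for group in config.network_groups:
                for tp in panel.timepoint_labels():
                    stratum = panel.stratify(group, tp)
                    vals = stratum
                    if config.log_scale_corr:
                        vals = PanelTable(
                            values=np.log(stratum.values.clip(lower=1e-12)),
                            groups=stratum.groups,
                            timepoints=stratum.timepoints,
                        )
                    matrix = correlation_matrix(vals)
                    net = build_network(matrix, threshold=config.threshold,
                                        stratum=(group, tp))
                    metrics = node_metrics(net)
                    screen = screen_key_cytokines(metrics)
                    tag = f"{group}_{tp}".replace("+", "plus").replace(" ", "_")
                    matrix.to_csv(outdir / f"corr_matrix_{tag}.csv")
                    metrics.to_csv(outdir / f"node_metrics_{tag}.csv")
                    write_edge_list(net, outdir / f"corr_edges_{tag}.csv")
                    write_graphml(net, outdir / f"corr_network_{tag}.graphml")
                    if config.make_figures:
                        from .plotting import plot_correlation_network

                        plot_correlation_network(
                            net, outdir / f"corr_network_{tag}.png"
                        )
                    net_summary_rows.append({
                        "group": group, "timepoint": tp,
                        "n_edges": len(net.edges),
                        "network_str": network_str(net),
                        "key_cytokines": ";".join(sorted(screen.key_set)),
                    })
                    for line in screen.tie_log:
                        log.info("corrnet %s @ %s: %s", group, tp, line)
                    if group == config.consensus_group:
                        network_keys[tp] = sorted(screen.key_set)
        except Exception as err:
            if isinstance(err, PipelineError):
                raise
            raise PipelineError(f"[stage: corr-network] {err}") from err
        pd.DataFrame(net_summary_rows).to_csv(
            outdir / "network_summary.csv", index=False
        )

        # --- CCC track --------------------------------------------------
        cell_keys: dict[str, list[str]] = {}
        ccc_rows = []
        try:
            for cond_group, ref_group in config.contrasts:
                for tp in panel.timepoint_labels():
                    contrast = condition_delta(
                        panel, (cond_group, tp), (ref_group, tp)
                    )
                    net = build_ccc(
                        contrast, cmap,
                        include_diagonal=not config.zero_diagonal_ccc,
                    )
                    screen = screen_key_cells(net)
                    tag = (f"{cond_group}_vs_{ref_group}_{tp}"
                           .replace("+", "plus").replace(" ", "_"))
                    net.E.to_csv(outdir / f"ccc_E_{tag}.csv")
                    density_table(net).to_csv(outdir / f"ccc_density_{tag}.csv")
                    write_ccc_edge_list(net, outdir / f"ccc_edges_{tag}.csv")
                    if config.make_figures:
                        from .plotting import plot_ccc_diagram, plot_ccc_heatmaps

                        plot_ccc_heatmaps(net, outdir / f"ccc_heatmap_{tag}.png")
                        plot_ccc_diagram(net, outdir / f"ccc_diagram_{tag}.png")
                    ccc_rows.append({
                        "condition": cond_group, "reference": ref_group,
                        "timepoint": tp, "network_sd": net.network_sd,
                        "key_target": screen.key_target,
                        "key_secretory": screen.key_secretory,
                        "key_total": screen.key_total,
                    })
                    for line in screen.tie_log:
                        log.info("ccc %s vs %s @ %s: %s", cond_group,
                                 ref_group, tp, line)
                    if (cond_group, ref_group) == tuple(config.key_contrast):
                        cell_keys[tp] = sorted(
                            {screen.key_target, screen.key_secretory,
                             screen.key_total}
                        )
        except Exception as err:
            if isinstance(err, PipelineError):
                raise
            raise PipelineError(f"[stage: ccc-network] {err}") from err
        pd.DataFrame(ccc_rows).to_csv(outdir / "ccc_summary.csv", index=False)

        # --- consensus --------------------------------------------------
        summary = consensus(stat_keys, network_keys, cell_keys)
        summary.to_frame().to_csv(outdir / "consensus.csv", index=False)

        manifest = {
            "cytonet_version": __version__,
            "seed": config.seed,
            "threshold": config.threshold,
            "alpha": config.alpha,
            "key_contrast": list(config.key_contrast),
            "contrasts": [list(c) for c in config.contrasts],
            "flags": {
                "log_scale_corr": config.log_scale_corr,
                "bh_correct": config.bh_correct,
                "zero_diagonal_ccc": config.zero_diagonal_ccc,
            },
            "panel_source": config.panel_path or "simulated",
            "cell_map_source": config.cell_map_path or "packaged default",
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, ensure_ascii=False)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig (and optional nested sim config) from YAML."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    sim_doc = doc.pop("sim", None)
    sim = None
    if sim_doc is not None:
        if "corr_blocks" in sim_doc:
            sim_doc["corr_blocks"] = tuple(
                (tuple(members), float(r)) for members, r in sim_doc["corr_blocks"]
            )
        if "group_effects" in sim_doc:
            sim_doc["group_effects"] = {
                tuple(k.split("|")): float(v)
                for k, v in sim_doc["group_effects"].items()
            }
        sim = SimConfig(**sim_doc)
    for key in ("contrasts", "network_groups", "key_contrast"):
        if key in doc and doc[key] is not None:
            doc[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                             for x in doc[key])
    return RunConfig(sim=sim, **doc)
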