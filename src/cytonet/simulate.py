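"""Synthetic multiplex-panel generator.

Emulates the statistical structure the analysis tracks assume: a
3-group x 3-timepoint design with 6-7 animals per cell, 24 strictly
positive right-skewed concentrations, configurable between-cytokine
correlation blocks, and multiplicative group effects on selected
cytokines.

Concentrations are drawn from a multivariate log-normal: correlation
targets are imposed on the log scale (block-diagonal, zero elsewhere),
and the per-cytokine *median* equals ``baseline_mean x fold``, so a
fold factor of 3 triples the typical concentration.  Marginals are
log-normal rather than Gaussian because immunoassay concentrations are
strictly positive and right-skewed.

Seeding contract: one master seed; each (group, timepoint) stratum
draws from a substream derived from ``(seed, group index, timepoint
index)``, so adding or reordering strata does not perturb the draws of
the others, and identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import CYTOKINE_ROSTER, PanelTable

__all__ = [
    "SimConfig",
    "default_baseline_means",
    "default_paperlike_config",
    "null_config",
    "simulate_panel",
]

DEFAULT_GROUPS = ("control", "CFA", "CFA+MA")
DEFAULT_TIMEPOINTS = ("day1", "day7", "day15")

#: PSD-repair tolerance for user-assembled correlation blocks.
PSD_TOL = 1e-8


class SimConfigError(ValueError):
    """The simulation configuration violates an invariant."""


def default_baseline_means() -> dict[str, float]:
    """Plausible resting-tissue concentrations (pg/mL) for the roster.

    Magnitudes are order-of-magnitude realistic for rat tissue
    homogenates (chemokines hundreds of pg/mL, interleukins tens,
    CRP much higher); only directions and correlation structure are
    meant to carry information, not these absolute levels.
    """
    return {
        "MCP-1": 250.0, "CXCL1": 180.0, "MIP-1α": 90.0, "MIP-3α": 60.0,
        "RANTES": 120.0,
        "IL-1α": 45.0, "IL-1β": 80.0, "IL-6": 70.0, "TNF-α": 35.0,
        "IL-7": 20.0, "IL-18": 150.0, "CRP": 5000.0,
        "IL-2": 30.0, "IL-4": 12.0, "IL-5": 25.0, "IL-10": 40.0,
        "IL-12": 50.0, "IL-13": 15.0, "IL-17": 18.0, "IFN-γ": 55.0,
        "GM-CSF": 22.0, "G-CSF": 28.0, "M-CSF": 65.0, "VEGF": 110.0,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic panel draw.

    ``corr_blocks`` is a list of ``(cytokine tuple, target r)`` pairs,
    applied on the log scale; blocks must be disjoint.  ``group_effects``
    maps ``(group, timepoint, cytokine)`` to a multiplicative fold
    factor on the stratum median.
    """

    n_per_stratum: int = 7
    baseline_means: Mapping[str, float] = field(default_factory=default_baseline_means)
    cv: float = 0.3
    corr_blocks: tuple[tuple[tuple[str, ...], float], ...] = ()
    group_effects: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    groups: tuple[str, ...] = DEFAULT_GROUPS
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_stratum < 1:
            raise SimConfigError("n_per_stratum must be >= 1")
        if self.cv <= 0:
            raise SimConfigError("cv must be positive")
        for cyto, mean in self.baseline_means.items():
            if not mean > 0:
                raise SimConfigError(f"baseline mean for {cyto} must be > 0")
        seen: set[str] = set()
        for members, r in self.corr_blocks:
            if abs(r) > 0.99:
                raise SimConfigError(f"|block correlation| must be <= 0.99, got {r}")
            overlap = seen & set(members)
            if overlap:
                raise SimConfigError(f"correlation blocks overlap on {sorted(overlap)}")
            unknown = set(members) - set(self.baseline_means)
            if unknown:
                raise SimConfigError(f"block cytokines not in panel: {sorted(unknown)}")
            seen |= set(members)
        for (g, t, c), fold in self.group_effects.items():
            if not fold > 0:
                raise SimConfigError(f"fold factor for {(g, t, c)} must be > 0")
            if c not in self.baseline_means:
                raise SimConfigError(f"group effect on unknown cytokine {c!r}")

    @property
    def cytokines(self) -> tuple[str, ...]:
        return tuple(self.baseline_means)


def _log_correlation(config: SimConfig) -> np.ndarray:
    """Assemble the block-diagonal log-scale correlation matrix.

    If the assembled matrix is not positive semi-definite (possible for
    adversarial block targets), eigenvalues are clipped at ``PSD_TOL``
    and the matrix rescaled to unit diagonal (nearest-PSD repair).
    """
    cytos = config.cytokines
    idx = {c: i for i, c in enumerate(cytos)}
    corr = np.eye(len(cytos))
    for members, r in config.corr_blocks:
        ii = [idx[m] for m in members]
        for a in ii:
            for b in ii:
                if a != b:
                    corr[a, b] = r
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -PSD_TOL:
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, PSD_TOL, None)
        corr = (v * w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() < -PSD_TOL:
            raise SimConfigError("correlation blocks are jointly infeasible")
    return corr


def simulate_panel(config: SimConfig) -> PanelTable:
    """Draw a full panel table under ``config``.

    Per stratum, ``n_per_stratum`` animals are drawn from a multivariate
    log-normal whose log-scale covariance is ``sigma^2 x R`` with
    ``sigma^2 = ln(1 + cv^2)`` and ``R`` the configured block
    correlation, and whose per-cytokine median is
    ``baseline_mean x fold``.
    """
    cytos = list(config.cytokines)
    corr = _log_correlation(config)
    sigma2 = np.log1p(config.cv ** 2)
    cov = sigma2 * corr
    chol = np.linalg.cholesky(cov + PSD_TOL * np.eye(len(cytos)))
    base_mu = np.log(np.array([config.baseline_means[c] for c in cytos]))

    frames = []
    for gi, group in enumerate(config.groups):
        for ti, tp in enumerate(config.timepoints):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed), gi, ti])
            )
            folds = np.array([
                config.group_effects.get((group, tp, c), 1.0) for c in cytos
            ])
            mu = base_mu + np.log(folds)
            z = rng.standard_normal((config.n_per_stratum, len(cytos)))
            vals = np.exp(mu + z @ chol.T)
            ids = [f"{group}_{tp}_a{k + 1:02d}" for k in range(config.n_per_stratum)]
            df = pd.DataFrame(vals, columns=cytos,
                              index=pd.Index(ids, name="animal_id"))
            df.insert(0, "_group", group)
            df.insert(1, "_timepoint", tp)
            frames.append(df)
    full = pd.concat(frames)
    return PanelTable(
        values=full[cytos],
        groups=full["_group"],
        timepoints=full["_timepoint"],
    )


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """No planted effects, no correlation blocks: the calibration null."""
    return SimConfig(seed=seed, **overrides)


def default_paperlike_config(seed: int = 0, n_per_stratum: int = 7) -> SimConfig:
    """Config mirroring the qualitative treatment effects of the study design.

    Under the treated condition (CFA+MA), the chemokines MCP-1 and CXCL1
    and the innate cytokines IL-1β and IL-6 are elevated 2.5-3x at day 1
    and day 15 (MIP-3α additionally at day 15) while GM-CSF is halved at
    day 1; day 7 carries no planted effects.  Two modest co-regulation
    blocks (chemokine and innate) are planted at r = 0.85 on the log
    scale.  Magnitudes are the generator's own choices; only the
    directions mirror the reported pattern.
    """
    effects: dict[tuple[str, str, str], float] = {
        ("CFA+MA", "day1", "MCP-1"): 3.0,
        ("CFA+MA", "day1", "CXCL1"): 2.5,
        ("CFA+MA", "day1", "IL-1β"): 2.5,
        ("CFA+MA", "day1", "IL-6"): 3.0,
        ("CFA+MA", "day1", "GM-CSF"): 0.5,
        ("CFA+MA", "day15", "MCP-1"): 2.5,
        ("CFA+MA", "day15", "CXCL1"): 2.0,
        ("CFA+MA", "day15", "MIP-3α"): 2.0,
        ("CFA+MA", "day15", "IL-1β"): 2.0,
        ("CFA+MA", "day15", "IL-6"): 2.5,
    }
    blocks = (
        (("MCP-1", "CXCL1", "MIP-3α"), 0.85),
        (("IL-1β", "IL-6", "TNF-α"), 0.85),
    )
    return SimConfig(
        n_per_stratum=n_per_stratum,
        corr_blocks=blocks,
        group_effects=effects,
        seed=seed,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Same configuration, different master seed."""
    return replace(config, seed=seed)
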