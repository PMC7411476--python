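"""Per-cytokine three-group screening.

For each cytokine at each timepoint the three treatment groups are
compared with a branch that mirrors common multiplex-panel practice:

1. *Normality*: Shapiro-Wilk per group (alpha 0.05).  If any group
   rejects, the data are natural-log transformed and re-checked; if a
   group still rejects, the nonparametric branch is taken
   (Kruskal-Wallis omnibus + pairwise Mann-Whitney).
2. *Homogeneity* (parametric branch): median-centred Levene test
   (alpha 0.05).  Homogeneous variances lead to one-way ANOVA with
   Fisher's LSD pairwise comparisons (pooled mean-square error);
   heterogeneous variances lead to a Welch omnibus ANOVA with
   Dunnett's T3 pairwise comparisons.

A cytokine is flagged *key* when the pairwise p-value of the primary
contrast (treated vs model group, default CFA+MA vs CFA) is below
alpha.  Pairwise tests are reported unconditionally (not gated on the
omnibus), matching the conventional SPSS post-hoc output this
procedure emulates.  No multiple-testing correction is applied across
cytokines by default; Benjamini-Hochberg is available behind a flag.

Every verdict taken along the branch is recorded in ``method_trail``
so a run is fully auditable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import PanelTable

__all__ = [
    "DEFAULT_KEY_CONTRAST",
    "DegenerateDataError",
    "InsufficientDataError",
    "StatResult",
    "key_cytokines",
    "screen_all",
    "screen_cytokine",
]

DEFAULT_KEY_CONTRAST = ("CFA+MA", "CFA")

_LOG_CLIP = 1e-12


class InsufficientDataError(ValueError):
    """A stratum needed by the screen has fewer than 3 animals."""


class DegenerateDataError(ValueError):
    """All groups have zero within-group variance; no test is defined."""


@dataclass
class StatResult:
    """Outcome of one cytokine x timepoint three-group comparison."""

    cytokine: str
    timepoint: str
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]
    method_trail: dict = field(default_factory=dict)
    is_key: bool = False
    key_contrast: tuple[str, str] = DEFAULT_KEY_CONTRAST


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b)


def _lookup_pair(pairwise: dict[tuple[str, str], float],
                 a: str, b: str) -> float:
    if (a, b) in pairwise:
        return pairwise[(a, b)]
    return pairwise[(b, a)]


def _shapiro_ok(x: np.ndarray, alpha: float) -> bool:
    """True when normality is *not* rejected.  Constant samples cannot
    be tested and are treated as passing."""
    if np.ptp(x) == 0:
        return True
    return sps.shapiro(x).pvalue >= alpha


def _lsd_pairwise(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Fisher's LSD: pairwise t with the pooled ANOVA mean-square error."""
    groups = list(samples)
    ns = {g: len(samples[g]) for g in groups}
    big_n = sum(ns.values())
    k = len(groups)
    sse = sum(((samples[g] - samples[g].mean()) ** 2).sum() for g in groups)
    df = big_n - k
    mse = sse / df
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        if se == 0:
            p = 1.0 if samples[a].mean() == samples[b].mean() else 0.0
        else:
            t = (samples[a].mean() - samples[b].mean()) / se
            p = 2 * sps.t.sf(abs(t), df)
        out[_pair_key(a, b)] = float(p)
    return out


def _dunnett_t3_pairwise(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunnett's T3: Welch t statistics referenced to the studentized
    maximum modulus, via the independence approximation
    ``p = 1 - (2 F_t(|t|; nu) - 1)^m`` with m pairwise comparisons."""
    groups = list(samples)
    m = len(groups) * (len(groups) - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(groups, 2):
        xa, xb = samples[a], samples[b]
        va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
        if va + vb == 0:
            p = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            t = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
            nu = (va + vb) ** 2 / (
                va ** 2 / (len(xa) - 1) + vb ** 2 / (len(xb) - 1)
            )
            central = 2 * sps.t.cdf(abs(t), nu) - 1
            p = 1 - central ** m
        out[_pair_key(a, b)] = float(min(max(p, 0.0), 1.0))
    return out


def _welch_omnibus(samples: dict[str, np.ndarray]) -> float:
    import pingouin as pg

    df = pd.DataFrame(
        {"y": np.concatenate(list(samples.values())),
         "g": np.repeat(list(samples), [len(v) for v in samples.values()])}
    )
    return float(pg.welch_anova(data=df, dv="y", between="g")["p_unc"].iloc[0])


def _mw_pairwise(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(list(samples), 2):
        p = sps.mannwhitneyu(samples[a], samples[b],
                             alternative="two-sided").pvalue
        out[_pair_key(a, b)] = float(p)
    return out


def screen_cytokine(
    panel: PanelTable,
    cytokine: str,
    timepoint: str,
    alpha: float = 0.05,
    key_contrast: tuple[str, str] = DEFAULT_KEY_CONTRAST,
    normality_alpha: float = 0.05,
    homogeneity_alpha: float = 0.05,
) -> StatResult:
    """Run the three-group branch for one cytokine at one timepoint."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    groups = panel.group_labels()
    samples: dict[str, np.ndarray] = {}
    for g in groups:
        sub = panel.stratify(g, timepoint)
        x = sub.values[cytokine].to_numpy(dtype=float)
        if len(x) < 3:
            raise InsufficientDataError(
                f"stratum ({g}, {timepoint}) has {len(x)} < 3 animals"
            )
        samples[g] = x
    if all(np.ptp(x) == 0 for x in samples.values()):
        raise DegenerateDataError(
            f"{cytokine} at {timepoint}: zero variance in every group"
        )

    trail: dict = {"groups": groups, "n": {g: len(x) for g, x in samples.items()}}
    normal_raw = all(_shapiro_ok(x, normality_alpha) for x in samples.values())
    trail["normality_raw"] = normal_raw
    transform = None
    work = samples
    if not normal_raw:
        logged = {g: np.log(np.clip(x, _LOG_CLIP, None))
                  for g, x in samples.items()}
        normal_log = all(_shapiro_ok(x, normality_alpha) for x in logged.values())
        trail["normality_log"] = normal_log
        if normal_log:
            transform = "log"
            work = logged
    trail["transform"] = transform

    if normal_raw or trail.get("normality_log", False):
        lev_p = float(sps.levene(*work.values(), center="median").pvalue)
        homogeneous = lev_p >= homogeneity_alpha
        trail["homogeneity_p"] = lev_p
        trail["homogeneous"] = homogeneous
        if homogeneous:
            omnibus_p = float(sps.f_oneway(*work.values()).pvalue)
            pairwise = _lsd_pairwise(work)
            trail["omnibus"] = "one-way ANOVA"
            trail["posthoc"] = "Fisher LSD"
            trail["branch"] = "anova_lsd"
        else:
            omnibus_p = _welch_omnibus(work)
            pairwise = _dunnett_t3_pairwise(work)
            trail["omnibus"] = "Welch ANOVA"
            trail["posthoc"] = "Dunnett T3"
            trail["branch"] = "welch_t3"
    else:
        omnibus_p = float(sps.kruskal(*samples.values()).pvalue)
        pairwise = _mw_pairwise(samples)
        trail["omnibus"] = "Kruskal-Wallis"
        trail["posthoc"] = "Mann-Whitney U"
        trail["branch"] = "kruskal_mw"

    omnibus_p = float(min(max(omnibus_p, 0.0), 1.0))
    if not np.isfinite(omnibus_p):
        # identical groups make F = 0/0; no evidence against the null
        omnibus_p = 1.0
    cond, ref = key_contrast
    try:
        key_p = _lookup_pair(pairwise, cond, ref)
    except KeyError:
        key_p = np.nan
    is_key = bool(np.isfinite(key_p) and key_p < alpha)
    return StatResult(
        cytokine=cytokine,
        timepoint=timepoint,
        omnibus_p=omnibus_p,
        pairwise_p=pairwise,
        method_trail=trail,
        is_key=is_key,
        key_contrast=key_contrast,
    )


def screen_all(
    panel: PanelTable,
    alpha: float = 0.05,
    key_contrast: tuple[str, str] = DEFAULT_KEY_CONTRAST,
    bh_correct: bool = False,
    **kwargs,
) -> list[StatResult]:
    """Screen every cytokine at every timepoint.

    With ``bh_correct`` the key rule is applied to Benjamini-Hochberg
    adjusted key-contrast p-values within each timepoint (off by
    default; the conventional report is per-cytokine alpha).
    """
    results: list[StatResult] = []
    for tp in panel.timepoint_labels():
        tp_results = []
        for cyto in panel.cytokine_names:
            try:
                res = screen_cytokine(panel, cyto, tp, alpha=alpha,
                                      key_contrast=key_contrast, **kwargs)
            except (InsufficientDataError, DegenerateDataError) as err:
                raise type(err)(f"[cytokine={cyto}, timepoint={tp}] {err}") from err
            tp_results.append(res)
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            ps = np.array([
                _lookup_pair(r.pairwise_p, *key_contrast) for r in tp_results
            ])
            rej, p_adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
            for r, rj, pa in zip(tp_results, rej, p_adj):
                r.method_trail["key_p_bh"] = float(pa)
                r.is_key = bool(rj)
        results.extend(tp_results)
    return results


def key_cytokines(results: list[StatResult]) -> dict[str, list[str]]:
    """Per-timepoint key lists, ordered by key-contrast p ascending."""
    out: dict[str, list[str]] = {}
    for tp in dict.fromkeys(r.timepoint for r in results):
        hits = [r for r in results if r.timepoint == tp and r.is_key]
        hits.sort(key=lambda r: _lookup_pair(r.pairwise_p, *r.key_contrast))
        out[tp] = [r.cytokine for r in hits]
    return out


def results_table(results: list[StatResult]) -> pd.DataFrame:
    """Flat one-row-per-(cytokine, timepoint) result table."""
    rows = []
    for r in results:
        row = {
            "cytokine": r.cytokine,
            "timepoint": r.timepoint,
            "omnibus_p": r.omnibus_p,
            "branch": r.method_trail.get("branch"),
            "transform": r.method_trail.get("transform"),
            "is_key": r.is_key,
        }
        for (a, b), p in r.pairwise_p.items():
            row[f"p[{a} vs {b}]"] = p
        rows.append(row)
    return pd.DataFrame(rows)
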