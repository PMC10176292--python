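"""Channel-wise planned contrasts with FDR and additivity labelling.

For each channel, chromophore and activation window the planned simple
contrast compares the baseline-to-window change between the two conditions:
per participant

    d = (mean_window - mean_baseline)_bimodal
        - (mean_window - mean_baseline)_alternating

and tests d = 0 as a 1-df contrast (F = squared paired t, df2 = n - 1 within
an age group).  Post-hoc paired comparisons give the direction of the
condition difference inside the window, which together with the chromophore
determines the additivity interpretation: a larger HbO (or more negative
HbR) response to the synchronous bimodal condition than to the combined
unimodal presentation is consistent with super-additive integration, the
reverse with sub-additive integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .montage import Montage, default_montage
from .preprocess import CHROMOPHORES

ACTIVATION_WINDOWS = ("W1", "W2")
ALPHA = 0.05
_EPS_VAR = 1e-24  # guard for exactly-zero variance constructions


@dataclass
class ChannelStat:
    chromophore: str
    hemisphere: str
    region: str
    channel: int
    window: str
    age_group: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    posthoc_p: float
    direction: str  # "bimodal>alternating" | "alternating>bimodal" | "none"
    additivity: str  # "super" | "sub" | "none"
    fdr_significant: bool = False
    p_fdr: float = float("nan")
    n: int = 0
    interaction_F: float = float("nan")
    interaction_p: float = float("nan")


def _contrast_values(
    table: pd.DataFrame, channel: int, chromophore: str, window: str
) -> pd.Series:
    """Per-participant contrast d (complete cases for this channel only)."""
    sub = table[(table.channel == channel) & (table.chromophore == chromophore)
                & (table.window.isin([window, "baseline"]))]
    wide = sub.pivot_table(index="participant", columns=["condition", "window"],
                           values="mean")
    need = [("bimodal", window), ("bimodal", "baseline"),
            ("alternating", window), ("alternating", "baseline")]
    if not all(c in wide.columns for c in need):
        return pd.Series(dtype=float)
    wide = wide.dropna(subset=need)
    return ((wide[("bimodal", window)] - wide[("bimodal", "baseline")])
            - (wide[("alternating", window)] - wide[("alternating", "baseline")]))


def planned_contrast(
    table: pd.DataFrame,
    channel: int,
    chromophore: str,
    window: str,
    age_group: str | None = None,
    montage: Montage | None = None,
) -> Optional[ChannelStat]:
    """1-df planned contrast for one channel/chromophore/window.

    With ``age_group`` set, the contrast is tested within that group
    (F = t^2 of the one-sample t on d; df2 = n - 1).  With ``age_group=None``
    both groups enter: age is a between factor, the contrast main effect is
    the test of the grand mean of the two group means and the age x contrast
    interaction is reported alongside.
    Returns None (channel skipped) with fewer than 2 complete participants.
    """
    montage = montage or default_montage()
    sub = table if age_group is None else table[table.age_group == age_group]
    d = _contrast_values(sub, channel, chromophore, window)
    n = len(d)
    if n < 2:
        return None

    inter_F = inter_p = float("nan")
    if age_group is None and sub.age_group.nunique() > 1:
        groups = sub.drop_duplicates("participant").set_index("participant")[
            "age_group"]
        g = groups.reindex(d.index)
        d1, d2 = d[g == "younger"], d[g == "older"]
        if len(d1) >= 2 and len(d2) >= 2:
            F, df1, df2 = _unweighted_means_F(d1.values, d2.values)
            inter_F, inter_df = _interaction_F(d1.values, d2.values)
            inter_p = float(stats.f.sf(inter_F, 1, inter_df))
        else:
            return None
    else:
        var = max(float(d.var(ddof=1)), _EPS_VAR)
        F = n * float(d.mean()) ** 2 / var
        df1, df2 = 1, n - 1

    p = float(stats.f.sf(F, df1, df2))
    eta = F * df1 / (F * df1 + df2)

    direction, posthoc_p = posthoc_condition(sub, channel, chromophore, window)
    ch = montage.channel(channel)
    return ChannelStat(
        chromophore=chromophore, hemisphere=ch.hemisphere, region=ch.region,
        channel=channel, window=window,
        age_group=age_group or "both",
        F=float(F), df1=df1, df2=int(df2), p=p,
        partial_eta_sq=float(eta), posthoc_p=posthoc_p, direction=direction,
        additivity=label_additivity(chromophore, direction, p < ALPHA),
        n=n, interaction_F=inter_F, interaction_p=inter_p,
    )


def _unweighted_means_F(d1: np.ndarray, d2: np.ndarray) -> tuple[float, int, int]:
    """Contrast main effect across two groups: grand mean of group means
    against the pooled within-group error."""
    n1, n2 = len(d1), len(d2)
    ss_err = ((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()
    df2 = n1 + n2 - 2
    mse = max(ss_err / df2, _EPS_VAR)
    grand = (d1.mean() + d2.mean()) / 2.0
    nh = 2.0 / (1.0 / n1 + 1.0 / n2)  # harmonic cell size
    F = nh * 2 * grand**2 / mse
    return float(F), 1, df2


def _interaction_F(d1: np.ndarray, d2: np.ndarray) -> tuple[float, int]:
    n1, n2 = len(d1), len(d2)
    ss_err = ((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()
    df2 = n1 + n2 - 2
    mse = max(ss_err / df2, _EPS_VAR)
    diff = d1.mean() - d2.mean()
    F = diff**2 / (mse * (1.0 / n1 + 1.0 / n2))
    return float(F), df2


def posthoc_condition(
    table: pd.DataFrame, channel: int, chromophore: str, window: str
) -> tuple[str, float]:
    """Paired comparison of condition means inside the activation window.

    Returns (direction, two-sided p).  The direction is reported regardless
    of significance; labelling suppresses non-significant directions
    downstream.
    """
    sub = table[(table.channel == channel) & (table.chromophore == chromophore)
                & (table.window == window)]
    wide = sub.pivot_table(index="participant", columns="condition", values="mean")
    if not {"bimodal", "alternating"} <= set(wide.columns):
        return "none", float("nan")
    wide = wide.dropna(subset=["bimodal", "alternating"])
    if len(wide) < 2:
        return "none", float("nan")
    diff = (wide["bimodal"] - wide["alternating"]).values
    mean = diff.mean()
    var = max(diff.var(ddof=1), _EPS_VAR)
    t = mean / np.sqrt(var / len(diff))
    p = float(2 * stats.t.sf(abs(t), len(diff) - 1))
    if mean > 0:
        return "bimodal>alternating", p
    if mean < 0:
        return "alternating>bimodal", p
    return "none", p


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def label_additivity(chromophore: str, direction: str, significant: bool) -> str:
    """Additivity interpretation of a significant condition difference.

    HbO larger to bimodal -> super-additive; HbO larger to alternating ->
    sub-additive; for HbR the mapping flips (a larger HbR increase to the
    bimodal condition is sub-additive, to the alternating condition
    super-additive).
    """
    if not significant or direction == "none":
        return "none"
    if chromophore not in CHROMOPHORES:
        raise ValueError(f"bad chromophore {chromophore!r}")
    bimodal_up = direction == "bimodal>alternating"
    if chromophore == "HbO":
        return "super" if bimodal_up else "sub"
    return "sub" if bimodal_up else "super"


def analyze_channels(
    table: pd.DataFrame,
    age_group: str | None = None,
    montage: Montage | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """All channels x chromophores x activation windows for one analysis.

    FDR families are all channels within a chromophore x window (x age
    group) analysis.  Returns a tidy frame of ChannelStat fields.
    """
    montage = montage or default_montage()
    stats_rows: list[ChannelStat] = []
    for chrom in CHROMOPHORES:
        for win in ACTIVATION_WINDOWS:
            family: list[ChannelStat] = []
            for cid in montage.ids:
                cs = planned_contrast(table, cid, chrom, win, age_group, montage)
                if cs is not None:
                    family.append(cs)
            if family:
                adj = fdr_adjust([cs.p for cs in family])
                for cs, pa in zip(family, adj):
                    cs.p_fdr = float(pa)
                    cs.fdr_significant = bool(pa < alpha)
            stats_rows.extend(family)
    return pd.DataFrame([vars(cs) for cs in stats_rows])
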