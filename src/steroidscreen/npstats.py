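"""Pooled nonparametric testing of normalized activities.

Technical replicates across the biological replicates are pooled into one
group per (chemical, endpoint, concentration), nominally n = 9.  An omnibus
Kruskal-Wallis test gates a series of two-sided Mann-Whitney U comparisons
of each concentration against the appropriate control, whose p-values are
binned into the conventional significance stars (hashes for sham / direct
comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .normalize import DIRECT_REFERENCE_LEVEL, Endpoint

__all__ = [
    "Direction",
    "StatCall",
    "StatsConfig",
    "pool_replicates",
    "kruskal_wallis",
    "mann_whitney",
    "star_bin",
    "normality_screen",
    "compute_stat_calls",
]

STAR_CUTPOINTS = (0.05, 0.01, 0.001, 0.0001)


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"
    NONE = "none"


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    omnibus_gate: bool = True
    #: largest combined sample size for which an exact (enumeration)
    #: Mann-Whitney p-value is used when the data are tie-free
    exact_threshold_n: int = 12


@dataclass
class StatCall:
    chemical_id: str
    endpoint: Endpoint
    conc: float
    n_treated: int
    n_control: int
    u_statistic: float
    p_value: float
    star_bin: str
    significant: bool
    direction: Direction
    underpowered: bool = False


def pool_replicates(df: pd.DataFrame, value_col: str,
                    ) -> dict[tuple[str, str, float], np.ndarray]:
    """Group normalized records by (chemical, endpoint, concentration).

    All technical replicates across biological replicates fall into one
    group (nominal n = 9; smaller groups are kept and their size recorded
    downstream).  Duplicate wells (same plate / bio / tech coordinates for
    one key) are an input error.
    """
    groups: dict[tuple[str, str, float], np.ndarray] = {}
    key_cols = ["chemical_id", "endpoint", "conc_h295r"]
    for key, sub in df.groupby(key_cols, dropna=False):
        coords = list(zip(sub["plate_id"], sub["bio_rep"], sub["tech_rep"]))
        if len(coords) != len(set(coords)):
            raise ValueError(f"duplicate replicate records in group {key}")
        values = sub[value_col].to_numpy(dtype=float)
        if len(values) == 0:
            raise ValueError(f"empty group {key}")
        groups[key] = values
    return groups


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical data across all groups gives (0, 1) by convention.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(treated: Sequence[float], control: Sequence[float],
                 exact_threshold_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of treated vs control.

    Exact enumeration when the combined sample is small (n <= threshold)
    and tie-free; otherwise the normal approximation with tie and
    continuity correction.  Returns (U of the treated side, p).
    """
    x = np.asarray(treated, dtype=float)
    y = np.asarray(control, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= exact_threshold_n and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return float(res.statistic), min(float(res.pvalue), 1.0)


def star_bin(p: float, family: str = "steroidogenic") -> str:
    """Bin a p-value into significance glyphs.

    Steroidogenic comparisons use stars, direct (sham) comparisons hashes:
    1 glyph for .01 < p <= .05 up to 4 glyphs for p <= .0001; "ns" above.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    glyph = "*" if family == "steroidogenic" else "#"
    n = sum(p <= cut for cut in STAR_CUTPOINTS)
    return glyph * n if n else "ns"


def normality_screen(groups: dict, min_n: int = 3) -> pd.DataFrame:
    """Shapiro-Wilk p per group; diagnostic only, never changes the
    nonparametric testing pathway."""
    rows = []
    for key, values in groups.items():
        values = np.asarray(values, dtype=float)
        p = None
        flag = None
        if len(values) < min_n:
            flag = "too_small"
        elif np.ptp(values) == 0:
            flag = "constant"
        else:
            p = float(sps.shapiro(values).pvalue)
        rows.append({"group": key, "n": len(values), "shapiro_p": p, "flag": flag})
    return pd.DataFrame(rows)


def _direction(values: np.ndarray, reference_level: float) -> Direction:
    med = median(values)
    if med > reference_level:
        return Direction.UP
    if med < reference_level:
        return Direction.DOWN
    return Direction.NONE


def compute_stat_calls(df: pd.DataFrame, endpoint: Endpoint,
                       cfg: StatsConfig = StatsConfig()) -> list[StatCall]:
    """Per-concentration calls for one chemical's endpoint.

    ``df`` holds the normalized records of a single chemical plus its
    control wells: hormone-activity endpoints compare % of basal against
    the vehicle-treated cells (reference level 100), direct endpoints
    compare sham %RI against the sham vehicle (level 0 agonist / 100
    antagonist).  Pairwise significance is gated by the omnibus test when
    ``cfg.omnibus_gate`` is set.
    """
    direct = endpoint in DIRECT_REFERENCE_LEVEL
    value_col = "pct_ri" if direct else "pct_of_basal"
    ref_level = DIRECT_REFERENCE_LEVEL.get(endpoint, 100.0)
    sub = df[df["endpoint"] == endpoint.value]
    control = sub[sub["role"] == "vehicle_control"]
    treated_df = sub[sub["role"].isin(["h295r_treated", "sham"])]
    if control.empty or treated_df.empty:
        return []
    control_values = control[value_col].to_numpy(dtype=float)
    chemical = treated_df["chemical_id"].dropna().unique()
    if len(chemical) != 1:
        raise ValueError(f"expected one chemical per call set, got {list(chemical)}")
    chemical = chemical[0]

    groups = pool_replicates(treated_df, value_col)
    concs = sorted(k[2] for k in groups)
    all_groups = [control_values] + [groups[(chemical, endpoint.value, c)] for c in concs]
    try:
        _, omnibus_p = kruskal_wallis(all_groups)
    except ValueError:
        omnibus_p = 1.0
    gate_open = (not cfg.omnibus_gate) or omnibus_p <= cfg.alpha

    calls = []
    for conc in concs:
        values = groups[(chemical, endpoint.value, conc)]
        u, p = mann_whitney(values, control_values, cfg.exact_threshold_n)
        direction = _direction(values, ref_level)
        # The omnibus gate suppresses both the call and its glyphs, keeping
        # ``significant <=> star_bin != ns``; a direction tie (median exactly
        # at the reference) is resolved at classification time.
        significant = p <= cfg.alpha and gate_open
        stars = star_bin(p, "direct" if direct else "steroidogenic") if gate_open else "ns"
        calls.append(StatCall(
            chemical_id=chemical, endpoint=endpoint, conc=float(conc),
            n_treated=len(values), n_control=len(control_values),
            u_statistic=u, p_value=p,
            star_bin=stars,
            significant=significant, direction=direction,
            underpowered=len(values) < 3 or len(control_values) < 3))
    return calls


def calls_frame(calls: Iterable[StatCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "chemical_id": c.chemical_id, "endpoint": c.endpoint.value,
            "conc_h295r": c.conc, "n_treated": c.n_treated,
            "n_control": c.n_control, "u": c.u_statistic, "p": c.p_value,
            "stars": c.star_bin, "significant": c.significant,
            "direction": c.direction.value, "underpowered": c.underpowered,
        })
    return pd.DataFrame(rows)
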