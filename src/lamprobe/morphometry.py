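"""Hippocampal layer-width morphometry and species comparison.

Works from summary statistics (mean, SEM, n per layer) of the kind printed in
histology figures: percent differences between species, Welch's unequal-variance
t-test recomputed from the summaries, and per-layer comparison reports.

The canonical pig (Yucatan, n = 8) and rat (Long-Evans, n = 6) dorsal
hippocampus layer-width tables are shipped as module constants; layer order is
dorsal to ventral: alveus, oriens, pyramidale, radiatum, lacunosum-moleculare,
moleculare, granulosum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recording import InvalidParameterError

LAYER_ORDER = (
    "alveus",
    "oriens",
    "pyramidale",
    "radiatum",
    "lacunosum-moleculare",
    "moleculare",
    "granulosum",
)


@dataclass(frozen=True)
class LayerSummaryTable:
    """Per-layer width summaries (mean ± SEM, n subjects) for one group."""

    group: str
    table: pd.DataFrame  # index: layer name; columns: mean_um, sem_um, n

    def __post_init__(self) -> None:
        required = {"mean_um", "sem_um", "n"}
        if not required.issubset(self.table.columns):
            raise InvalidParameterError(f"summary table needs columns {sorted(required)}")
        if (self.table["sem_um"] <= 0).any():
            raise InvalidParameterError("SEM must be positive for every layer")
        if (self.table["n"] < 2).any():
            raise InvalidParameterError("summaries require n >= 2 subjects")

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(self.table.index)


def _summary(group: str, rows: dict[str, tuple[float, float, int]]) -> LayerSummaryTable:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["mean_um", "sem_um", "n"])
    df.index.name = "layer"
    return LayerSummaryTable(group=group, table=df)


#: Yucatan pig dorsal hippocampus layer widths, µm (mean, SEM, n).
PIG_LAYER_WIDTHS = _summary(
    "pig",
    {
        "alveus": (173.8, 11.55, 8),
        "oriens": (178.3, 15.01, 8),
        "pyramidale": (213.2, 15.9, 8),
        "radiatum": (394.1, 22.36, 8),
        "lacunosum-moleculare": (223.1, 11.7, 8),
        "moleculare": (335.1, 17.85, 8),
        "granulosum": (81.3, 4.5, 8),
    },
)

#: Long-Evans rat dorsal hippocampus layer widths, µm (mean, SEM, n).
RAT_LAYER_WIDTHS = _summary(
    "rat",
    {
        "alveus": (69.1, 9.05, 6),
        "oriens": (144.4, 7.52, 6),
        "pyramidale": (53.12, 1.9, 6),
        "radiatum": (343.9, 12.33, 6),
        "lacunosum-moleculare": (112.2, 8.21, 6),
        "moleculare": (232.8, 11.35, 6),
        "granulosum": (90.6, 3.52, 6),
    },
)


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_difference(a: float, b: float) -> int:
    """Percent by which ``a`` exceeds reference ``b``, rounded to an integer.

    Rounding is half-away-from-zero, matching how such percentages are
    conventionally printed.
    """
    if b <= 0:
        raise InvalidParameterError("reference mean must be positive")
    return _round_half_away(100.0 * (a - b) / b)


def discrepancy_percent(nominal: float, measured: float) -> int:
    """Percent shortfall of a measured value relative to its nominal target."""
    if nominal <= 0:
        raise InvalidParameterError("nominal value must be positive")
    return _round_half_away(100.0 * (nominal - measured) / nominal)


def welch_t_from_summary(
    m1: float, sem1: float, n1: int, m2: float, sem2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from group means, SEMs and sizes.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom and
    a two-sided p-value.  SEM already carries the 1/sqrt(n) factor, so
    t = (m1 - m2) / sqrt(sem1^2 + sem2^2).
    """
    if sem1 <= 0 or sem2 <= 0:
        raise InvalidParameterError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("Welch test requires n >= 2 per group")
    v1, v2 = sem1**2, sem2**2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def summarize_mean_sem(values) -> tuple[float, float | None, int]:
    """Mean, SEM (sample SD / sqrt(n); ``None`` when n = 1) and n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("cannot summarize an empty sample")
    n = arr.size
    mean = float(arr.mean())
    if n == 1:
        return mean, None, 1
    sem = float(arr.std(ddof=1) / math.sqrt(n))
    return mean, sem, n


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_layer_tables(
    group_a: LayerSummaryTable,
    group_b: LayerSummaryTable,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-layer comparison of two layer-width summary tables.

    For each layer the report carries the integer percent difference of group A
    relative to group B, Welch's t, its degrees of freedom, the two-sided
    p-value, a significance flag at ``alpha`` and conventional stars.  With
    ``holm=True`` p-values are Holm–Bonferroni adjusted across layers before
    flagging (off by default: layers are conventionally tested individually).
    """
    missing = set(group_a.layers) ^ set(group_b.layers)
    if missing:
        raise InvalidParameterError(f"layer sets differ: {sorted(missing)}")
    rows = []
    for layer in group_a.layers:
        ra = group_a.table.loc[layer]
        rb = group_b.table.loc[layer]
        t, df, p = welch_t_from_summary(
            ra["mean_um"], ra["sem_um"], int(ra["n"]),
            rb["mean_um"], rb["sem_um"], int(rb["n"]),
        )
        rows.append(
            {
                "layer": layer,
                "percent_diff": percent_difference(ra["mean_um"], rb["mean_um"]),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    report = pd.DataFrame(rows).set_index("layer")
    pvals = report["p"].to_numpy()
    if holm:
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        m = len(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        pvals = adj
        report["p_adjusted"] = adj
    report["significant"] = pvals < alpha
    report["stars"] = [_stars(p) for p in pvals]
    return report
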