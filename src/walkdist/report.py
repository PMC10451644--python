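"""Human-readable summary table and per-day plot data."""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)


def summary_table_text(summary: pd.DataFrame) -> str:
    """Render the placement summary as a fixed-width text table.

    Layout mirrors the conventional report: algorithm, state, placement,
    LS mean +/- SE with grouping letter, and the p-values.
    """
    if summary.empty:
        logger.warning("summary table is empty")
        return "(no data)\n"
    lines = [
        f"{'Distance':<18}{'State':<12}{'Placement':<10}"
        f"{'LSmean±SE (m)':>22}  {'ltr':<4}{'p(static=nonstatic)':>20}{'p(mu=0)':>10}"
    ]
    for algo, g in summary.groupby("algorithm", sort=False):
        first = True
        for _, r in g.iterrows():
            contrast = f"{r['p_static_vs_nonstatic']:.3g}" if first else ""
            lines.append(
                f"{(algo if first else ''):<18}{r['state']:<12}{r['placement']:<10}"
                f"{r['ls_mean_m']:>12.0f} ± {r['se_m']:<7.0f}  {r['letter']:<4}"
                f"{contrast:>20}{r['p_vs_zero']:>10.3g}"
            )
            first = False
    return "\n".join(lines) + "\n"


def per_day_means(daily: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-placement-per-date mean and SE table for plotting.

    One row per (algorithm, placement, date) with mean daily distance, its
    standard error across trackers, and the tracker count.
    """
    if daily.empty:
        logger.warning("per_day_means: empty daily-distance input")
        return pd.DataFrame(
            columns=["algorithm", "placement", "date", "mean_m", "se_m", "n"]
        )
    g = daily.groupby(["algorithm", "placement", "date"])["distance_m"]
    out = g.agg(mean_m="mean", se_m="sem", n="size").reset_index()
    out["se_m"] = out["se_m"].fillna(0.0)
    return out
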