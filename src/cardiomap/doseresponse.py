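"""Sequential-dose drug-response analysis.

Each well is recorded at a predrug baseline (dose 0) and again after each of
several increasing doses of the same drug.  Effects are expressed per well
as the percent change of a metric from that well's own baseline
(``100·(post − pre)/pre``, prolongation positive); group summaries are
mean ± SEM across wells.  Between-group comparisons (atrial vs ventricular)
at each dose use an unpaired t test (Welch by default); within-group dose
trends use one-way ANOVA with Dunnett's post-hoc comparisons of every dose
against baseline.  Sequential dosing is treated as independent per-dose
contrasts against baseline, not as a repeated-measures model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import StatResult, anova_dunnett, stars, student_ttest, welch_ttest

__all__ = [
    "percent_change",
    "build_dose_table",
    "add_percent_change",
    "summarize_groups",
    "compare_groups",
    "dose_trend",
    "assemble_screen_report",
]

_REQUIRED_COLUMNS = ("well", "group", "dose", "metric", "value")


def percent_change(pre: float, post: float) -> float:
    """Signed percent change from a predrug baseline: ``100·(post − pre)/pre``.

    Prolongation is positive, shortening negative (a reporting layer may
    print the magnitude with a direction word).
    """
    if np.ndim(pre) == 0 and pre <= 0:
        raise ValueError(f"baseline value must be positive, got {pre}")
    pre_arr = np.asarray(pre, dtype=float)
    if np.any(pre_arr <= 0):
        raise ValueError("baseline values must be positive")
    return 100.0 * (np.asarray(post, dtype=float) - pre_arr) / pre_arr


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"dose table missing columns: {missing}")
    return table


def build_dose_table(rows: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Assemble and validate a tidy per-(well, dose, metric) value table.

    Requires exactly one baseline (dose 0) record per (well, metric).
    """
    table = pd.DataFrame(rows)
    _validate(table)
    base = table[table["dose"] == 0]
    counts = base.groupby(["well", "metric"]).size()
    bad = counts[counts != 1]
    if not bad.empty:
        raise ValueError(f"wells with != 1 baseline record: {bad.index.tolist()}")
    pairs = set(map(tuple, table[["well", "metric"]].drop_duplicates().values))
    have = set(map(tuple, base[["well", "metric"]].values))
    if pairs - have:
        raise ValueError(f"wells missing a baseline record: {sorted(pairs - have)}")
    return table.reset_index(drop=True)


def add_percent_change(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``pct_change`` from each well's own dose-0 baseline.

    Baseline rows get exactly 0 by construction.  Validates the
    one-baseline-per-(well, metric) invariant first.
    """
    table = build_dose_table(table)
    base = (
        table[table["dose"] == 0]
        .set_index(["well", "metric"])["value"]
        .rename("baseline_value")
    )
    table = table.join(base, on=["well", "metric"])
    table["pct_change"] = percent_change(
        table["baseline_value"].to_numpy(), table["value"].to_numpy()
    )
    table.loc[table["dose"] == 0, "pct_change"] = 0.0
    return table


def summarize_groups(table: pd.DataFrame, value_col: str = "pct_change") -> pd.DataFrame:
    """Mean, SEM (sd/√n, ddof=1) and n per (group, dose, metric).

    Percent changes are computed per well first and then averaged across
    wells, so the printed "mean% ± SEM%" summarizes well-level changes.
    ``n = 1`` cells report the mean with an undefined SEM.
    """
    def _sem(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) >= 2 else np.nan

    grouped = table.groupby(["group", "dose", "metric"])[value_col]
    out = grouped.agg(mean="mean", sem=_sem, n="count").reset_index()
    return out


def compare_groups(
    table: pd.DataFrame,
    dose: float,
    metric: str,
    value_col: str = "pct_change",
    variant: str = "welch",
) -> StatResult:
    """Unpaired two-sided t test between the two groups at one dose."""
    sub = table[(table["dose"] == dose) & (table["metric"] == metric)]
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        return StatResult(
            f"{metric}@{dose}", np.nan, np.nan, np.nan,
            note=f"need exactly 2 groups, have {groups}",
        )
    x = sub.loc[sub["group"] == groups[0], value_col].dropna().to_numpy()
    y = sub.loc[sub["group"] == groups[1], value_col].dropna().to_numpy()
    test = welch_ttest if variant == "welch" else student_ttest
    return test(x, y, label=f"{metric}@{dose}: {groups[0]} vs {groups[1]}")


def dose_trend(
    table: pd.DataFrame,
    group: str,
    metric: str,
    on: str = "pct_change",
    alpha: float = 0.05,
) -> tuple[StatResult, list[StatResult]]:
    """Within-group dose dependence: one-way ANOVA + Dunnett vs baseline.

    ``on`` selects the response column — per-well percent changes by
    default, raw values via ``on="value"``.  Doses with fewer than 2 wells
    are skipped with a diagnostic note in their result.
    """
    sub = table[(table["group"] == group) & (table["metric"] == metric)]
    doses = sorted(sub["dose"].unique())
    if 0 not in doses or len(doses) < 2:
        raise ValueError(f"{group}/{metric}: needs baseline plus >= 1 dose")
    arrays = [
        sub.loc[sub["dose"] == d, on].dropna().to_numpy() for d in doses
    ]
    labels = [f"{metric}@{d} vs baseline" for d in doses[1:]]
    return anova_dunnett(arrays[0], *arrays[1:], labels=labels, alpha=alpha)


def assemble_screen_report(
    tables: dict[str, pd.DataFrame],
    variant: str = "welch",
) -> tuple[pd.DataFrame, str]:
    """Per-drug screen summary across groups and doses.

    For every drug table (tidy, with ``pct_change``): group mean ± SEM per
    dose and metric, the between-group t-test stars at each dose, and the
    within-group Dunnett stars against baseline.  Returns a machine-readable
    table and a human-readable text rendering.  Drugs whose table lacks a
    baseline are excluded with a diagnostic line.
    """
    if not tables:
        raise ValueError("no drug tables supplied")
    rows = []
    notes = []
    for drug, table in tables.items():
        try:
            table = _validate(table)
            if "pct_change" not in table.columns:
                table = add_percent_change(table)
        except ValueError as exc:
            notes.append(f"{drug}: excluded ({exc})")
            continue
        summary = summarize_groups(table)
        dunnett_cache: dict[tuple[str, str], dict[float, StatResult]] = {}
        for group in sorted(table["group"].unique()):
            for metric in sorted(table["metric"].unique()):
                try:
                    _, comps = dose_trend(table, group, metric)
                    per_dose = {}
                    doses = sorted(
                        d for d in table.loc[table["group"] == group, "dose"].unique()
                        if d != 0
                    )
                    for d, comp in zip(doses, comps):
                        per_dose[d] = comp
                    dunnett_cache[(group, metric)] = per_dose
                except ValueError as exc:
                    notes.append(f"{drug}/{group}/{metric}: {exc}")
        for _, row in summary.iterrows():
            group, dose, metric = row["group"], row["dose"], row["metric"]
            raw = table[
                (table["group"] == group)
                & (table["dose"] == dose)
                & (table["metric"] == metric)
            ]["value"]
            between = (
                compare_groups(table, dose, metric, variant=variant)
                if dose != 0
                else None
            )
            dunnett = dunnett_cache.get((group, metric), {}).get(dose)
            rows.append(
                {
                    "drug": drug,
                    "group": group,
                    "dose": dose,
                    "metric": metric,
                    "raw_mean": raw.mean(),
                    "raw_sem": raw.std(ddof=1) / np.sqrt(len(raw))
                    if len(raw) >= 2
                    else np.nan,
                    "pct_mean": row["mean"],
                    "pct_sem": row["sem"],
                    "n": row["n"],
                    "between_group_p": between.pvalue if between else np.nan,
                    "between_group_stars": between.stars if between else "",
                    "dunnett_adj_p": dunnett.adj_pvalue if dunnett else np.nan,
                    "dunnett_stars": dunnett.stars if dunnett else "",
                }
            )
    report = pd.DataFrame(rows).sort_values(["drug", "metric", "dose", "group"])
    report = report.reset_index(drop=True)

    lines = ["Drug screen summary (mean % change from predrug baseline ± SEM)"]
    for drug in report["drug"].unique():
        lines.append(f"\n== {drug} ==")
        sub = report[report["drug"] == drug]
        for metric in sub["metric"].unique():
            lines.append(f"  {metric}:")
            for _, r in sub[sub["metric"] == metric].iterrows():
                sem = f"{r.pct_sem:.1f}" if np.isfinite(r.pct_sem) else "nd"
                lines.append(
                    f"    {r.group:<12} dose {r.dose:<8g} "
                    f"{r.pct_mean:+7.1f}% ± {sem:>5}%  (n={int(r.n)})"
                    f"  vs-other-group {r.between_group_stars or '-':<3}"
                    f"  vs-baseline {r.dunnett_stars or '-'}"
                )
    lines += [f"note: {n}" for n in notes]
    return report, "\n".join(lines)
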