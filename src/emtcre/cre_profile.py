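"""Per-stage CRE frequency statistic, top-K ranking and time-course charts.

The statistic is the *percentile of frequency*: for an element within a gene
group at one stage,

    freq_percent = 100 x (total occurrences across the group's promoters)
                       / (number of genes in the group)

Counting is uncapped per promoter, so the value exceeds 100% whenever an
element occurs repeatedly ("clusters") — that is a feature of the statistic,
not an error.  Elements are ranked by descending frequency within each
(stage, group); ties break lexicographically by element name.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from emtcre.errors import ConfigurationError, DataError

__all__ = [
    "tabulate_frequencies",
    "top_k_elements",
    "frequency_timecourse",
    "plot_frequency_chart",
]

DEFAULT_TOP_K = 6

_COLUMNS = ["element", "stage", "group", "total_hits", "n_genes",
            "freq_percent", "rank"]


def tabulate_frequencies(hits: pd.DataFrame, genes: Iterable[str],
                         stage: str, group: str,
                         elements: Sequence[str] | None = None
                         ) -> pd.DataFrame:
    """CRE frequency rows for one gene group at one stage.

    ``hits`` is a scan table (columns gene_id / element / ...); only rows for
    the given genes are counted.  ``elements`` fixes the element universe
    (zero-hit elements are reported with 0%); by default it is the set of
    elements present in the hit table.
    """
    genes = sorted(set(genes))
    if not genes:
        raise DataError(f"empty gene group ({group} @ {stage})")
    sub = hits[hits["gene_id"].isin(genes)]
    if elements is None:
        elements = sorted(hits["element"].unique())
    counts = sub.groupby("element").size().reindex(elements, fill_value=0)
    n = len(genes)
    df = pd.DataFrame({
        "element": list(elements),
        "stage": stage,
        "group": group,
        "total_hits": counts.to_numpy(),
        "n_genes": n,
    })
    df["freq_percent"] = 100.0 * df["total_hits"] / n
    order = df.sort_values(["freq_percent", "element"],
                           ascending=[False, True]).index
    df.loc[order, "rank"] = range(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    return df[_COLUMNS]


def top_k_elements(profile: pd.DataFrame, k: int = DEFAULT_TOP_K,
                   common: bool = False) -> dict[tuple[str, str], list[str]]:
    """Highest-frequency elements per (stage, group).

    With ``common=True`` the per-stage lists are restricted to elements that
    make the top k of *every* stage within the group.  If k exceeds the
    number of elements, all are returned with a warning.  A tie at rank k is
    resolved lexicographically (both candidates noted in a warning).
    """
    if profile.empty:
        raise DataError("empty frequency profile")
    out: dict[tuple[str, str], list[str]] = {}
    for (stage, group), sub in profile.groupby(["stage", "group"], sort=True):
        sub = sub.sort_values("rank")
        if k > len(sub):
            warnings.warn(f"top-{k} requested but only {len(sub)} elements "
                          f"available for {group} @ {stage}; returning all")
        if k < len(sub):
            border = sub["freq_percent"].iloc[k - 1]
            tied = sub[sub["freq_percent"] == border]["element"].tolist()
            if len(tied) > 1:
                warnings.warn(
                    f"tie at rank {k} for {group} @ {stage}: {tied}; "
                    "lexicographic winner kept")
        out[(stage, group)] = sub["element"].head(k).tolist()
    if common:
        for group in {g for _, g in out}:
            stage_sets = [set(v) for (s, g), v in out.items() if g == group]
            shared = set.intersection(*stage_sets)
            for key in [key for key in out if key[1] == group]:
                out[key] = [e for e in out[key] if e in shared]
    return out


def frequency_timecourse(profile: pd.DataFrame,
                         stage_order: Sequence[str] | None = None
                         ) -> pd.DataFrame:
    """Long-format chart table across stages with a per-element trend.

    Requires >= 2 stages; every (element, group) must be present at every
    stage (tabulate with a fixed element universe to guarantee this).  The
    trend is the frequency difference between the last and the first stage.
    """
    stages = list(stage_order) if stage_order is not None \
        else sorted(profile["stage"].unique())
    if len(stages) < 2:
        raise ConfigurationError("need at least two stages for a time course")
    missing = set(stages) - set(profile["stage"].unique())
    if missing:
        raise DataError(f"stages absent from the profile: {sorted(missing)}")
    rows = []
    for (element, group), sub in profile.groupby(["element", "group"]):
        present = set(sub["stage"])
        if not set(stages) <= present:
            raise DataError(
                f"element {element!r} ({group}) missing stages "
                f"{sorted(set(stages) - present)}; stage labels misaligned")
        freq = sub.set_index("stage")["freq_percent"]
        trend = freq[stages[-1]] - freq[stages[0]]
        for s in stages:
            rows.append({"element": element, "group": group, "stage": s,
                         "freq_percent": freq[s], "trend": trend})
    return pd.DataFrame(rows,
                        columns=["element", "group", "stage", "freq_percent",
                                 "trend"])


def plot_frequency_chart(timecourse: pd.DataFrame, path: str | Path,
                         group: str | None = None) -> None:
    """Grouped bar chart of element frequency per stage (one file)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = timecourse if group is None else \
        timecourse[timecourse["group"] == group]
    stages = list(dict.fromkeys(df["stage"]))
    elements = list(dict.fromkeys(df["element"]))
    fig, ax = plt.subplots(figsize=(max(6, len(elements)), 4))
    width = 0.8 / len(stages)
    for si, s in enumerate(stages):
        vals = [float(df[(df["element"] == e) & (df["stage"] == s)]
                      ["freq_percent"].iloc[0]) for e in elements]
        ax.bar([i + si * width for i in range(len(elements))], vals,
               width=width, label=s)
    ax.set_xticks([i + 0.4 for i in range(len(elements))])
    ax.set_xticklabels(elements, rotation=45, ha="right")
    ax.set_ylabel("frequency (% of genes)")
    ax.legend(title="stage")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
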