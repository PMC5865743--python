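"""Resampling-based robustness ranking of survival subpathways.

The feature screen + hypergeometric call is repeated over 100 stratified
half-subsets of the training set; each subpathway's robustness count is the
number of subsets in which it was called significant.  Subpathways are
ranked by count (dense ranks, ties broken by mean p-value then id), and the
top-ranked ones form the candidate prognostic signature.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .graphs import SubpathwayGraph
from .screening import screen_features
from .significance import SubpathwayCall, identify_survival_subpathways


def run_resampled_screens(
    subsets: Sequence[Sequence[str]],
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    clin: pd.DataFrame,
    subpathways: Sequence[SubpathwayGraph],
    alpha_feature: float = 0.05,
    alpha_subpathway: float = 0.05,
    cache_dir: str | Path | None = None,
) -> list[list[SubpathwayCall]]:
    """Screen features and call subpathways on every training subset.

    Fully deterministic given the subset list.  With ``cache_dir`` set, each
    subset's calls are written to ``subset_<j>.tsv`` and reloaded on re-run,
    so interrupted sweeps resume where they stopped.
    """
    clin = clin.set_index(clin["sample_id"].astype(str), drop=False)
    measured_genes = set(gene_expr.index)
    measured_mirnas = set(mirna_expr.index)
    universe = (len(gene_expr.index), len(mirna_expr.index))

    out: list[list[SubpathwayCall]] = []
    for j, ids in enumerate(subsets):
        cache_file = Path(cache_dir) / f"subset_{j:03d}.tsv" if cache_dir else None
        if cache_file is not None and cache_file.exists():
            cached = pd.read_csv(cache_file, sep="\t", dtype={"subpathway_id": str})
            out.append(
                [
                    SubpathwayCall(row.subpathway_id, float(row.p_value), None, bool(row.significant))
                    for row in cached.itertuples()
                ]
            )
            continue
        sub_clin = clin.loc[list(ids)].reset_index(drop=True)
        screen = screen_features(mirna_expr, gene_expr, sub_clin, alpha=alpha_feature)
        calls = identify_survival_subpathways(
            subpathways,
            screen.survival_genes,
            screen.survival_mirnas,
            universe,
            measured_genes,
            measured_mirnas,
            alpha=alpha_subpathway,
        )
        if cache_file is not None:
            cache_file.parent.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                {
                    "subpathway_id": [c.subpathway_id for c in calls],
                    "p_value": [c.p_value for c in calls],
                    "significant": [c.significant for c in calls],
                }
            ).to_csv(cache_file, sep="\t", index=False)
        out.append(calls)
    return out


def count_subpathway_hits(call_lists: Sequence[Sequence[SubpathwayCall]]) -> pd.DataFrame:
    """Aggregate per-subset calls into the robustness table.

    Columns: subpathway_id, count (subsets where significant), mean_p (over
    all subsets where the subpathway was evaluated), rank (dense, 1 = highest
    count; ties broken by mean_p ascending then id).
    """
    counts: dict[str, int] = {}
    psums: dict[str, list[float]] = {}
    for calls in call_lists:
        for c in calls:
            counts.setdefault(c.subpathway_id, 0)
            psums.setdefault(c.subpathway_id, []).append(c.p_value)
            if c.significant:
                counts[c.subpathway_id] += 1
    tab = pd.DataFrame(
        {
            "subpathway_id": sorted(counts),
            "count": [counts[s] for s in sorted(counts)],
            "mean_p": [sum(psums[s]) / len(psums[s]) for s in sorted(counts)],
        }
    )
    tab = tab.sort_values(
        ["count", "mean_p", "subpathway_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    tab["rank"] = tab["count"].rank(method="dense", ascending=False).astype(int)
    return tab


def select_robust(
    table: pd.DataFrame,
    mode: Literal["top_n", "min_count"] = "top_n",
    value: int = 3,
) -> list[str]:
    """Pick the robust subpathways: dense rank <= value, or count >= value."""
    if value < 1:
        raise ValueError("selection value must be >= 1")
    if mode == "top_n":
        sel = table.loc[table["rank"] <= value]
    elif mode == "min_count":
        sel = table.loc[table["count"] >= value]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return list(sel["subpathway_id"])
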