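"""Nonparametric comparisons between scenario populations, and reporting.

Simulated biomarker distributions are compared with the Mann-Whitney U test
(two groups) or Kruskal-Wallis followed by Dunn's post-hoc pairwise z-tests
with a Bonferroni family adjustment (multiple groups), at the conventional
P < 0.05 cut-off.  Dunn's test is implemented directly from pooled ranks
with the standard tie correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["mann_whitney", "kruskal_dunn", "KruskalDunnResult", "scenario_report"]


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Uses the exact null distribution when the combined sample size is at
    most 12 and there are no ties, and the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class KruskalDunnResult:
    H: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, z, p_raw, p_adj

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.pairwise[self.pairwise["p_adj"] < alpha]


def kruskal_dunn(groups, labels=None, p_adjust: str = "bonferroni") -> KruskalDunnResult:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc comparisons.

    ``groups`` is a sequence of samples.  Pairwise Dunn z statistics use the
    pooled-rank variance with tie correction; raw two-sided p values are
    adjusted across all k(k-1)/2 pairs (Bonferroni by default, or "none").
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # degenerate all-identical data: no evidence of any difference
        pairs = [{"group_a": labels[i], "group_b": labels[j],
                  "z": 0.0, "p_raw": 1.0, "p_adj": 1.0}
                 for i, j in itertools.combinations(range(len(groups)), 2)]
        return KruskalDunnResult(H=0.0, p=1.0, pairwise=pd.DataFrame(pairs))

    H, p = sps.kruskal(*groups)

    ranks = sps.rankdata(pooled)
    N = pooled.size
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))]
    # tie correction for the pooled-rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        if p_adjust == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif p_adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown p_adjust {p_adjust!r}")
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": float(z), "p_raw": float(p_raw), "p_adj": float(p_adj)})
    return KruskalDunnResult(H=float(H), p=float(p), pairwise=pd.DataFrame(rows))


def scenario_report(
    biomarker_tables: dict[str, pd.DataFrame],
    biomarkers=None,
    compare: list[tuple[str, str]] | None = None,
    multi_compare: list[str] | None = None,
) -> pd.DataFrame:
    """Summary table across scenarios with optional statistical comparisons.

    ``biomarker_tables`` maps scenario name -> biomarker DataFrame (models x
    biomarkers, as produced by the population pipeline).  For each scenario
    and biomarker the report carries mean, SD, median and IQR.  ``compare``
    adds a Mann-Whitney p value per biomarker for each (a, b) scenario pair;
    ``multi_compare`` adds Kruskal-Wallis + Dunn-adjusted p values of every
    listed scenario against the first one.
    """
    if not biomarker_tables:
        raise ValueError("no scenarios supplied")
    names = list(biomarker_tables)
    cols = set(biomarker_tables[names[0]].columns)
    for n in names[1:]:
        if set(biomarker_tables[n].columns) != cols:
            raise ValueError(f"scenario {n!r} has mismatched biomarker columns")
    if biomarkers is None:
        biomarkers = list(biomarker_tables[names[0]].columns)

    rows = []
    for scen in names:
        tab = biomarker_tables[scen]
        for biom in biomarkers:
            v = tab[biom].dropna()
            row = {
                "scenario": scen, "biomarker": biom, "n": int(v.size),
                "mean": v.mean(), "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                "median": v.median(),
                "q25": v.quantile(0.25), "q75": v.quantile(0.75),
            }
            rows.append(row)
    report = pd.DataFrame(rows)

    if compare:
        for a, b in compare:
            col = f"mw_p__{a}__vs__{b}"
            pvals = {}
            for biom in biomarkers:
                va = biomarker_tables[a][biom].dropna()
                vb = biomarker_tables[b][biom].dropna()
                pvals[biom] = mann_whitney(va, vb)[1]
            report[col] = [
                pvals[r.biomarker] if r.scenario in (a, b) else np.nan
                for r in report.itertuples()
            ]
    if multi_compare:
        ref = multi_compare[0]
        for biom in biomarkers:
            samples = [biomarker_tables[s][biom].dropna() for s in multi_compare]
            res = kruskal_dunn(samples, labels=multi_compare)
            pw = res.pairwise.set_index(["group_a", "group_b"])["p_adj"]
            for scen in multi_compare[1:]:
                key = (ref, scen) if (ref, scen) in pw.index else (scen, ref)
                mask = (report["scenario"] == scen) & (report["biomarker"] == biom)
                report.loc[mask, f"dunn_p_vs_{ref}"] = pw[key]
    return report


def plot_scenario_bars(report: pd.DataFrame, biomarker: str, path=None, ax=None):
    """Mean ± SD bar plot of one biomarker across scenarios (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = report[report["biomarker"] == biomarker]
    if sub.empty:
        raise ValueError(f"biomarker {biomarker!r} not in report")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(sub) + 1, 3))
    ax.bar(sub["scenario"], sub["mean"], yerr=sub["sd"], capsize=3)
    ax.set_ylabel(biomarker)
    ax.tick_params(axis="x", rotation=45)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
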