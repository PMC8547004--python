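"""Fisher-exact enrichment of DEGs and clustering of log-ratio profiles.

Stratum- and replicon-level enrichment calls use the raw two-sided Fisher
p-value at a per-unit alpha (no multiplicity correction), matching the
per-subset convention of the figures this mirrors; pathway enrichment
instead controls the FDR with Benjamini-Hochberg across pathways within
one comparison.  An enrichment call ("+") additionally requires an odds
ratio above 1, a depletion call ("-") one below 1; an odds ratio of
exactly 1 is never significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .expression import PSEUDOCOUNT, bh_adjust
from .expression import SampleSheet

__all__ = [
    "fisher_exact_2x2",
    "subset_deg_enrichment",
    "replicon_stratified_enrichment",
    "pathway_enrichment",
    "log2_ratio_matrix",
    "hierarchical_cluster_average",
    "ClusterReport",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``; the odds ratio is the sample odds ratio
    ``(a*d)/(b*c)``, with ``+inf`` when ``b*c == 0`` and ``a*d > 0`` and
    ``nan`` for the fully degenerate ``0/0`` case.  The p-value sums the
    hypergeometric probabilities of all tables with the same margins that
    are no more probable than the observed one.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in 2x2 table {cells}")
    if any(x != int(x) for x in cells):
        raise ValueError(f"non-integer cell in 2x2 table {cells}")
    if sum(cells) < 1:
        raise ValueError("empty 2x2 table")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return odds, min(p, 1.0)


def _call(odds: float, p_or_q: float, threshold: float) -> str:
    if not np.isfinite(p_or_q) or p_or_q >= threshold:
        return "ns"
    if np.isnan(odds) or odds == 1.0:
        return "ns"
    return "+" if odds > 1.0 else "-"


def subset_deg_enrichment(
    deg_flags: pd.Series,
    strata: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-stratum DEG enrichment/depletion against the rest of the background.

    ``deg_flags`` (bool) and ``strata`` (labels) are indexed by gene and
    must cover the same background.  Also reports each stratum's share of
    all DEGs.  Strata with zero genes yield an ``ns`` row with empty table.
    """
    background = strata.index
    missing = background.difference(deg_flags.index)
    if len(missing):
        raise ValueError(f"DEG flags missing for genes: {list(missing)[:5]}")
    deg = deg_flags.loc[background].astype(bool)
    total_deg = int(deg.sum())
    rows = []
    for stratum in dict.fromkeys(strata):
        in_unit = strata == stratum
        a = int((deg & in_unit).sum())
        b = total_deg - a
        c = int((~deg & in_unit).sum())
        d = int(len(background) - a - b - c)
        if a + c == 0:
            warnings.warn(f"stratum {stratum!r} has no genes in background")
            rows.append((stratum, 0, b, 0, d, np.nan, np.nan, "ns", np.nan))
            continue
        odds, p = fisher_exact_2x2(a, b, c, d)
        prop = a / total_deg if total_deg else 0.0
        rows.append((stratum, a, b, c, d, odds, p, _call(odds, p, alpha), prop))
    return pd.DataFrame(
        rows,
        columns=["unit", "a", "b", "c", "d", "odds_ratio", "p", "call",
                 "deg_proportion"],
    ).set_index("unit")


def replicon_stratified_enrichment(
    deg_flags: pd.Series,
    strata: pd.Series,
    replicon_classes: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stratum enrichment repeated within each replicon class.

    The background of each test is restricted to the genes of that class,
    so a replicon whose genes all share one stratum yields only ``ns`` rows
    (there is no contrast).
    """
    missing = strata.index.difference(replicon_classes.index)
    if len(missing):
        raise ValueError(f"genes without replicon class: {list(missing)[:5]}")
    frames = []
    for cls in dict.fromkeys(replicon_classes.loc[strata.index]):
        genes = strata.index[replicon_classes.loc[strata.index] == cls]
        sub = subset_deg_enrichment(deg_flags.loc[genes], strata.loc[genes], alpha)
        sub = sub.reset_index()
        sub.insert(0, "replicon_class", cls)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True).set_index(["replicon_class", "unit"])


def pathway_enrichment(
    deg_genes: set[str],
    pathway_map: pd.DataFrame,
    background: set[str],
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment per pathway with BH control across pathways.

    ``pathway_map`` needs columns ``gene`` and ``pathway`` (optionally
    ``pathway_name``).  The background is the full annotated gene set of
    the organism; pathways without background genes are dropped with a
    warning.  Run separately for up- and down-regulated DEG sets.
    """
    need = {"gene", "pathway"}
    if not need.issubset(pathway_map.columns):
        raise ValueError(f"pathway map needs columns {sorted(need)}")
    deg_in_bg = deg_genes & background
    rows = []
    for pathway, sub in pathway_map.groupby("pathway", sort=True):
        members = set(sub["gene"]) & background
        if not members:
            warnings.warn(f"pathway {pathway!r} has no background genes; excluded")
            continue
        a = len(deg_in_bg & members)
        b = len(deg_in_bg) - a
        c = len(members) - a
        d = len(background) - a - b - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        name = sub["pathway_name"].iloc[0] if "pathway_name" in sub.columns else pathway
        rows.append((pathway, name, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows,
        columns=["unit", "pathway_name", "a", "b", "c", "d", "odds_ratio", "p"],
    ).set_index("unit")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["call"] = [
            _call(o, q, q_cutoff) for o, q in zip(out["odds_ratio"], out["q"])
        ]
    else:
        out["q"] = pd.Series(dtype=float)
        out["call"] = pd.Series(dtype=str)
    return out


def log2_ratio_matrix(
    tpm: pd.DataFrame, sheet: SampleSheet, reference: str | None = None
) -> pd.DataFrame:
    """Gene x comparison matrix of log2(TPM_treatment / TPM_reference).

    Replicates are averaged per treatment first; the 0.5 pseudocount is
    applied only when either mean falls below it, so zero/zero maps to 0.
    """
    reference = sheet.reference if reference is None else reference
    ref_mean = tpm[sheet.samples_of(reference)].mean(axis=1).to_numpy()
    out = {}
    for trt in sheet.treatments:
        if trt == reference:
            continue
        trt_mean = tpm[sheet.samples_of(trt)].mean(axis=1).to_numpy()
        need_pc = (ref_mean < PSEUDOCOUNT) | (trt_mean < PSEUDOCOUNT)
        r = np.where(need_pc, ref_mean + PSEUDOCOUNT, ref_mean)
        t = np.where(need_pc, trt_mean + PSEUDOCOUNT, trt_mean)
        out[trt] = np.log2(t / r)
    return pd.DataFrame(out, index=tpm.index)


@dataclass
class ClusterReport:
    """Average-linkage merge tree over log-ratio profiles."""

    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        """Dendrogram as Newick; branch lengths are half-height differences."""
        root = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.10g}"
            h = node.dist
            left = rec(node.get_left(), h)
            right = rec(node.get_right(), h)
            return f"({left},{right}):{parent_height - h:.10g}"

        h = root.dist
        return f"({rec(root.get_left(), h)},{rec(root.get_right(), h)});"


def hierarchical_cluster_average(matrix: pd.DataFrame) -> ClusterReport:
    """Agglomerative clustering of rows, average linkage, Euclidean distance.

    Rows with missing values are dropped with a warning; fewer than two
    usable rows is an error.  The cluster whose pair attains the minimum
    average distance merges first; scipy's nearest-neighbor chain algorithm
    resolves exact ties by original index order.
    """
    keep = matrix.dropna(axis=0)
    if len(keep) < len(matrix):
        dropped = matrix.index.difference(keep.index)
        warnings.warn(f"dropping rows with missing values: {list(dropped)[:5]}")
    if len(keep) < 2:
        raise ValueError("need at least 2 complete rows to cluster")
    z = hierarchy.linkage(keep.to_numpy(dtype=float), method="average",
                          metric="euclidean")
    order = hierarchy.leaves_list(z)
    labels = [str(i) for i in keep.index]
    return ClusterReport(z, labels, [labels[i] for i in order])
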