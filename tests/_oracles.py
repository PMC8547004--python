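"""Independent reference implementations used only to check the package.

These are deliberately written in the most literal way possible (exact
integer arithmetic, exhaustive scans, O(n^3) loops) and share no code with
the implementations they verify.
"""

from __future__ import annotations

from math import comb, sqrt

import numpy as np

TIE_RTOL = 1e-7


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration, exact fractions.

    Sums P(table) over all tables with the observed margins whose
    probability is at most that of the observed table (with a small
    relative tolerance for floating-point ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # unnormalized weights are exact integers
    w_obs = comb(r1, a) * comb(r2, c)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    keep = [w for w in weights if w <= w_obs * (1 + TIE_RTOL)]
    return sum(keep) / total


def average_linkage_brute(x: np.ndarray):
    """O(n^3) agglomerative average-linkage clustering, Euclidean distance.

    Returns a list of merges ``(members_of_new_cluster, height)`` with the
    smallest-pair average distance merged first; ties broken by the
    smallest involved original row index.
    """
    n = x.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {
        (i, j): sqrt(((x[i] - x[j]) ** 2).sum())
        for i in range(n)
        for j in range(i + 1, n)
    }

    def avg(ca: list[int], cb: list[int]) -> float:
        return sum(
            dist[(min(i, j), max(i, j))] for i in ca for j in cb
        ) / (len(ca) * len(cb))

    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ii, ka in enumerate(keys):
            for kb in keys[ii + 1 :]:
                h = avg(clusters[ka], clusters[kb])
                cand = (h, min(clusters[ka] + clusters[kb]), ka, kb)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        h, _tie, ka, kb = best
        merged = sorted(clusters.pop(ka) + clusters.pop(kb))
        clusters[min(merged)] = merged
        merges.append((frozenset(merged), h))
    return merges


def scheme_scan_oracle(pattern: dict[str, int], scheme, chron) -> str:
    """Brute-force stratum assignment by scanning scheme nodes root-to-tip.

    MRCA strata: walk anchors from oldest to youngest and take the first
    whose clade leaf set is contained in the clade of the pattern's MRCA,
    where the MRCA is found by exhaustive leaf-set containment over all
    nodes.  Predicates are re-evaluated literally from their parameters.
    """
    present = {g for g, v in pattern.items() if v >= 1}
    if scheme.mrca_rules and scheme.focal_genomes <= present:
        # pattern MRCA = smallest clade containing all present genomes
        containing = [
            nid for nid in chron.node_ids if present <= chron.clade_leaves(nid)
        ]
        m = min(containing, key=lambda nid: len(chron.clade_leaves(nid)))
        for rule in scheme.mrca_rules:
            anchor = scheme.anchors[rule.label]
            if chron.clade_leaves(anchor) <= chron.clade_leaves(m):
                return rule.label
    for rule in scheme.predicate_rules:
        if rule.kind == "all_of" and set(rule.genomes) <= present:
            return rule.label
        if rule.kind == "any_group_all" and any(
            set(g) <= present for g in rule.groups
        ):
            return rule.label
        if rule.kind == "count_range" and (
            rule.lo <= len(present & set(rule.genomes)) <= rule.hi
        ):
            return rule.label
        if rule.kind == "remainder":
            return rule.label
    raise AssertionError("oracle fell through a non-total scheme")
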