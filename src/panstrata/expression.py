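"""Count normalization and two-group negative-binomial differential expression.

The differential-expression caller is deliberately self-contained and
transparent:

* per-sample size factors by the median-of-ratios rule against a
  geometric-mean pseudo-reference (factors are *not* renormalized);
* per-gene dispersion by the method of moments on normalized counts,
  pooled within groups: ``alpha = max(floor, (s2 - ybar) / ybar**2)``;
* a Wald test on ``ln(mu_t) - ln(mu_r)`` with a delta-method standard
  error ``SE^2 = sum_g (1/n_g) * (1/mu_g + alpha)``;
* Benjamini-Hochberg step-up adjustment per organism and comparison.

A gene is a DEG when ``|log2FC| > 1`` (strict) and adjusted ``p < 0.05``
(strict).  No dispersion shrinkage, independent filtering or outlier
replacement is applied; calibration is asserted by simulation in the test
suite instead of by matching an external tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_tpm",
    "compute_rpkm",
    "size_factors_median_ratio",
    "estimate_dispersion_mom",
    "nb_wald_test",
    "bh_adjust",
    "call_degs",
    "de_test",
    "stratum_expression_summary",
]

ALPHA_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
LOG2FC_CUTOFF = 1.0
Q_CUTOFF = 0.05


class NormalizationError(ValueError):
    pass


def _check_counts(counts: pd.DataFrame) -> None:
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids in counts matrix")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: per-kb read rate scaled to 1e6 per sample.

    All-zero samples yield an all-zero column (with a warning) rather than
    an error.
    """
    _check_counts(counts)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes without length entries: {list(missing)[:5]}")
    if (lengths.loc[counts.index] <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths.loc[counts.index] / 1e3, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"all-zero samples in TPM: {list(counts.columns[zero])}")
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    _check_counts(counts)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes without length entries: {list(missing)[:5]}")
    libsize = counts.sum(axis=0)
    zero = libsize == 0
    if zero.any():
        warnings.warn(f"all-zero samples in RPKM: {list(counts.columns[zero])}")
        libsize = libsize.replace(0, np.nan)
    rpkm = counts.div(lengths.loc[counts.index], axis=0).div(libsize, axis=1) * 1e9
    return rpkm.fillna(0.0)


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    Only genes with strictly positive counts in every sample enter the
    reference; factors are not renormalized afterwards.
    """
    _check_counts(counts)
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; "
            "median-of-ratios undefined (a pseudo-reference fallback flag "
            "would be required for such sparse data)"
        )
    ref = np.exp(np.log(x[allpos]).mean(axis=1))
    factors = np.median(x[allpos] / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_arrays(
    counts: pd.DataFrame, factors: pd.Series, groups: dict[str, list[str]]
) -> dict[str, np.ndarray]:
    out = {}
    for name, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {name!r} needs >= 2 samples")
        y = counts[samples].to_numpy(dtype=float) / factors[samples].to_numpy()
        out[name] = y
    return out


def estimate_dispersion_mom(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: dict[str, list[str]],
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.Series:
    """Method-of-moments NB dispersion per gene, floored at ``alpha_floor``.

    On normalized counts, the pooled within-group variance ``s2`` and the
    mean ``ybar`` give ``alpha = (s2 - ybar) / ybar**2``; genes at or below
    the Poisson boundary get the floor.
    """
    ys = _group_arrays(counts, factors, groups)
    n_total = sum(y.shape[1] for y in ys.values())
    ybar = sum(y.sum(axis=1) for y in ys.values()) / n_total
    ss = sum(
        ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for y in ys.values()
    )
    s2 = ss / (n_total - len(ys))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - ybar) / ybar**2
    alpha = np.where(np.isfinite(alpha), alpha, alpha_floor)
    return pd.Series(
        np.maximum(alpha, alpha_floor), index=counts.index, name="dispersion"
    )


def nb_wald_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersion: pd.Series,
    groups: dict[str, list[str]],
    reference: str,
    treatment: str,
) -> pd.DataFrame:
    """Two-group Wald test on normalized count means under an NB model.

    The fold change is ``log2((mu_t + c) / (mu_r + c))`` with the
    pseudocount ``c = 0.5`` applied only when either group mean falls below
    it, so exact integer ratios stay exact in the common case.  Genes that
    are all-zero in both groups get ``p = 1``.
    """
    ys = _group_arrays(counts, factors, {g: groups[g] for g in (reference, treatment)})
    yr, yt = ys[reference], ys[treatment]
    nr, nt = yr.shape[1], yt.shape[1]
    mur = yr.mean(axis=1)
    mut = yt.mean(axis=1)
    alpha = dispersion.loc[counts.index].to_numpy(dtype=float)

    need_pc = (mur < PSEUDOCOUNT) | (mut < PSEUDOCOUNT)
    amur = np.where(need_pc, mur + PSEUDOCOUNT, mur)
    amut = np.where(need_pc, mut + PSEUDOCOUNT, mut)
    log2fc = np.log2(amut / amur)
    se = np.sqrt((1.0 / nr) * (1.0 / amur + alpha) + (1.0 / nt) * (1.0 / amut + alpha))
    z = (np.log(amut) - np.log(amur)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (mur == 0) & (mut == 0)
    p = np.where(both_zero, 1.0, p)
    return pd.DataFrame(
        {
            "mean_ref": mur,
            "mean_trt": mut,
            "log2fc": log2fc,
            "se": se,
            "p": np.clip(p, 0.0, 1.0),
        },
        index=counts.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(
    de: pd.DataFrame,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    q_cutoff: float = Q_CUTOFF,
) -> pd.DataFrame:
    """Apply the DEG rule: |log2FC| strictly above 1 and q strictly below 0.05."""
    out = de.copy()
    if "q" not in out.columns:
        out["q"] = bh_adjust(out["p"].to_numpy())
    deg = (out["log2fc"].abs() > log2fc_cutoff) & (out["q"] < q_cutoff)
    direction = np.where(
        ~deg, "ns", np.where(out["log2fc"] > 0, "up", "down")
    )
    out["deg"] = deg
    out["direction"] = direction
    return out


def de_test(
    counts: pd.DataFrame,
    samples_ref: list[str],
    samples_trt: list[str],
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    q_cutoff: float = Q_CUTOFF,
) -> pd.DataFrame:
    """Full pipeline for one comparison: normalize, estimate, test, adjust, call."""
    sub = counts[samples_ref + samples_trt]
    factors = size_factors_median_ratio(sub)
    groups = {"ref": samples_ref, "trt": samples_trt}
    disp = estimate_dispersion_mom(sub, factors, groups)
    de = nb_wald_test(sub, factors, disp, groups, "ref", "trt")
    de["q"] = bh_adjust(de["p"].to_numpy())
    return call_degs(de, log2fc_cutoff, q_cutoff)


@dataclass
class SampleSheet:
    """Sample annotations: organism context, treatment and replicate index."""

    frame: pd.DataFrame  # index: sample id; columns: organism, treatment, replicate
    reference: str

    def __post_init__(self) -> None:
        need = {"organism", "treatment", "replicate"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"sample sheet needs columns {sorted(need)}")
        if self.reference not in set(self.frame["treatment"]):
            raise ValueError(f"reference treatment {self.reference!r} absent")
        sizes = self.frame.groupby("treatment").size()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(f"treatments with < 2 replicates: {list(small.index)}")

    def samples_of(self, treatment: str) -> list[str]:
        return list(self.frame.index[self.frame["treatment"] == treatment])

    @property
    def treatments(self) -> list[str]:
        seen = dict.fromkeys(self.frame["treatment"])
        return list(seen)

    @property
    def comparisons(self) -> list[str]:
        return [t for t in self.treatments if t != self.reference]


def stratum_expression_summary(
    tpm: pd.DataFrame,
    gene_strata: pd.DataFrame,
    sheet: SampleSheet,
    deg_flags: pd.Series | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean TPM with bootstrap CIs per (stratum, copy class, treatment).

    Replicates are averaged per treatment first; the 95% CI is a percentile
    bootstrap over genes (``n_boot`` resamples, seeded).  Strata without
    genes are reported with ``n = 0`` and missing means rather than raising.
    Per-stratum DEG counts/proportions are attached when flags are given.
    """
    rng = np.random.default_rng(seed)
    common = tpm.index.intersection(gene_strata.index)
    missing = tpm.index.difference(gene_strata.index)
    if len(missing):
        raise ValueError(f"genes without stratum labels: {list(missing)[:5]}")
    rows = []
    strata_levels = list(dict.fromkeys(gene_strata["stratum"]))
    for stratum in strata_levels:
        for copy_class in ("single", "multi"):
            sel = common[
                (gene_strata.loc[common, "stratum"] == stratum)
                & (gene_strata.loc[common, "copy_class"] == copy_class)
            ]
            for treatment in sheet.treatments:
                cols = sheet.samples_of(treatment)
                if len(sel) == 0:
                    rows.append((stratum, copy_class, treatment, 0,
                                 np.nan, np.nan, np.nan, np.nan, np.nan))
                    continue
                vals = tpm.loc[sel, cols].mean(axis=1).to_numpy()
                mean = float(vals.mean())
                if len(vals) == 1:
                    lo = hi = mean
                else:
                    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
                    boot = vals[idx].mean(axis=1)
                    lo, hi = np.percentile(boot, [2.5, 97.5])
                if deg_flags is not None:
                    nd = int(deg_flags.reindex(sel).fillna(False).sum())
                    prop = nd / len(sel)
                else:
                    nd, prop = np.nan, np.nan
                rows.append(
                    (stratum, copy_class, treatment, len(sel),
                     mean, float(lo), float(hi), nd, prop)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum", "copy_class", "treatment", "n_genes",
            "mean_tpm", "ci_lower", "ci_upper", "n_deg", "deg_proportion",
        ],
    )
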