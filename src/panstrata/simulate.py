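"""Synthetic chronograms, pangenomes and nodule count matrices with ground truth.

The generator emulates the data shape of a dual pantranscriptomics study:

* orthogroups gained once at a tree node (Dollo, single origin) with
  optional per-branch losses below the gain node and occasional copy-number
  expansion;
* multipartite replicon assignment (chromosome / chromid / symbiosis
  plasmid / accessory plasmid) with a tunable per-orthogroup consistency
  probability;
* negative-binomial counts with sample-specific size factors and planted
  log2 fold changes concentrated in a chosen conservation stratum.

One integer seed feeds a single generator stream consumed in a fixed,
documented order (tree -> orthogroups -> replicons -> lengths -> counts),
so identical configurations give bit-identical bundles.  Reproducibility
across *partial* reruns is explicitly not promised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import SampleSheet
from .pangenome import REPLICON_CLASSES, OrthogroupTable, write_genecount_table
from .trees import Chronogram, chronogram_from_newick, simulate_chronogram

__all__ = ["SimConfig", "SimTruth", "SimBundle", "simulate_bundle",
           "simulate_orthogroups", "simulate_replicon_map", "simulate_counts",
           "write_fixture_bundle", "read_fixture_bundle"]

_POISSON_LIMIT = 1e-12
_MAX_RESAMPLE = 100


class SimConfigError(ValueError):
    pass


_DEFAULT_REPLICON_PROBS = {
    # rough replicon size shares of a multipartite Sinorhizobium genome
    "chromosome": 0.50,
    "chromid": 0.30,
    "symbiosis_plasmid": 0.15,
    "accessory_plasmid": 0.05,
}


@dataclass
class SimConfig:
    """All knobs of the generator; every probability is validated on creation.

    ``tree_newick`` takes precedence over ``(n_leaves, root_age)``.
    ``gain_node_weights`` maps node ids to sampling weights for the gain
    node of each orthogroup (default: uniform over all nodes, leaves
    included).  ``de_target_stratum`` names the stratum (or, when no
    stratum map is attached to the truth, the gain node) whose genes
    receive the planted effects.
    """

    tree_newick: str | None = None
    n_leaves: int = 8
    root_age: float = 106.0          # MYA, Glycine- vs Medicago-associated split
    n_orthogroups: int = 200
    gain_node_weights: dict[str, float] | None = None
    loss_prob: float = 0.1
    multi_copy_prob: float = 0.2
    replicon_classes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REPLICON_PROBS)
    )
    replicon_consistency: float = 0.834
    n_samples_per_group: int = 2     # two independent nodule sample sets
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    dispersion: float = 0.1
    mu_range: tuple[float, float] = (50.0, 2000.0)
    length_range: tuple[int, int] = (300, 3000)
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    de_target_stratum: str | None = None
    count_genome: str | None = None  # genome whose genes get a count matrix
    organism: str = "symbiont"
    reference_label: str = "wildtype"
    treatment_label: str = "mutant"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_prob", "multi_copy_prob", "replicon_consistency",
                     "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if self.n_samples_per_group < 2:
            raise SimConfigError("need >= 2 samples per group")
        if self.n_orthogroups < 0:
            raise SimConfigError("n_orthogroups must be >= 0")
        if not (0 < self.size_factor_range[0] <= self.size_factor_range[1]):
            raise SimConfigError("size_factor_range must be a positive interval")
        probs = np.array(list(self.replicon_classes.values()), dtype=float)
        if len(probs) == 0 or (probs < 0).any() or probs.sum() <= 0:
            raise SimConfigError("replicon_classes needs non-negative weights")
        if self.gain_node_weights is not None:
            w = np.array(list(self.gain_node_weights.values()), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise SimConfigError("gain_node_weights must be non-negative, not all 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated bundle."""

    gain_node: dict[str, str] = field(default_factory=dict)
    loss_edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    replicon_class: dict[str, str] = field(default_factory=dict)
    stratum_of: dict[str, str] | None = None       # orthogroup -> stratum label
    log2fc: pd.Series | None = None                # per gene
    baseline_mu: pd.Series | None = None           # per gene
    size_factors: pd.Series | None = None          # per sample


@dataclass
class SimBundle:
    config: SimConfig
    chronogram: Chronogram
    table: OrthogroupTable
    replicon_map: pd.DataFrame
    lengths: pd.Series
    counts: pd.DataFrame
    sheet: SampleSheet
    truth: SimTruth


def _simulate_tree(config: SimConfig, rng: np.random.Generator) -> Chronogram:
    if config.tree_newick is not None:
        return chronogram_from_newick(config.tree_newick)
    return simulate_chronogram(config.n_leaves, config.root_age, rng)


def simulate_orthogroups(
    config: SimConfig, chron: Chronogram, rng: np.random.Generator
) -> tuple[OrthogroupTable, SimTruth]:
    """Dollo gain/loss presence patterns with copy-number expansion.

    Each orthogroup picks a gain node from ``gain_node_weights``; every
    branch strictly below it is lost independently with ``loss_prob``
    (losing a branch prunes its whole clade).  Orthogroups losing all
    leaves are resampled up to 100 times, then dropped with a warning.
    """
    if config.gain_node_weights is None:
        nodes = list(chron.ages)
        weights = np.full(len(nodes), 1.0 / len(nodes))
    else:
        nodes = list(config.gain_node_weights)
        unknown = set(nodes) - set(chron.ages)
        if unknown:
            raise SimConfigError(f"gain_node_weights name unknown nodes: {sorted(unknown)}")
        weights = np.array([config.gain_node_weights[n] for n in nodes], dtype=float)
        weights = weights / weights.sum()

    genomes = sorted(chron.leaves)
    truth = SimTruth()
    rows: dict[str, dict[str, int]] = {}
    genes: dict[tuple[str, str], list[str]] = {}
    width = max(4, len(str(config.n_orthogroups)))
    dropped = 0
    for i in range(config.n_orthogroups):
        og = f"OG{i:0{width}d}"
        for _attempt in range(_MAX_RESAMPLE):
            gain = nodes[int(rng.choice(len(nodes), p=weights))]
            lost_edges: list[tuple[str, str]] = []
            present = set(chron.clade_leaves(gain))
            if config.loss_prob > 0:
                for parent, child in chron.edges_below(gain):
                    if rng.random() < config.loss_prob:
                        lost_edges.append((parent, child))
                for _, child in lost_edges:
                    present -= chron.clade_leaves(child)
            if present:
                break
        else:
            dropped += 1
            continue
        counts = {}
        for gn in genomes:
            if gn not in present:
                counts[gn] = 0
                continue
            n_copies = 2 if rng.random() < config.multi_copy_prob else 1
            counts[gn] = n_copies
            genes[(og, gn)] = [f"{og}_{gn}_{k + 1}" for k in range(n_copies)]
        rows[og] = counts
        truth.gain_node[og] = gain
        truth.loss_edges[og] = lost_edges
    if dropped:
        warnings.warn(
            f"{dropped} orthogroups went extinct in all {_MAX_RESAMPLE} resampling "
            "attempts and were dropped"
        )
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    if frame.empty:
        frame = pd.DataFrame(columns=genomes, dtype=np.int64)
    frame = frame.reindex(columns=genomes)
    frame.index.name = "orthogroup"
    if len(frame) == 0:
        return OrthogroupTable(frame, {}), truth
    return OrthogroupTable(frame, genes), truth


def simulate_replicon_map(
    table: OrthogroupTable, truth: SimTruth, config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign every simulated gene a replicon class.

    Each orthogroup draws one true class; with probability
    ``replicon_consistency`` all member genes keep it, otherwise one
    randomly chosen gene (when the orthogroup has >= 2) moves to a
    different class.
    """
    classes = list(config.replicon_classes)
    probs = np.array(list(config.replicon_classes.values()), dtype=float)
    probs = probs / probs.sum()
    rows = []
    for og in table.orthogroups:
        true_cls = classes[int(rng.choice(len(classes), p=probs))]
        truth.replicon_class[og] = true_cls
        members = [
            (gn, g)
            for gn in table.genomes
            for g in (table.genes or {}).get((og, gn), [])
        ]
        assigned = {g: true_cls for _, g in members}
        consistent = rng.random() < config.replicon_consistency
        if not consistent and len(members) >= 2 and len(classes) >= 2:
            victim = members[int(rng.integers(len(members)))][1]
            others = [c for c in classes if c != true_cls]
            assigned[victim] = others[int(rng.integers(len(others)))]
        for gn, g in members:
            rows.append((g, gn, assigned[g]))
    out = pd.DataFrame(rows, columns=["gene", "genome", "replicon_class"])
    return out.set_index("gene")


def _target_orthogroups(truth: SimTruth, config: SimConfig) -> set[str] | None:
    if config.de_target_stratum is None:
        return None
    if truth.stratum_of is not None:
        return {og for og, s in truth.stratum_of.items()
                if s == config.de_target_stratum}
    return {og for og, n in truth.gain_node.items()
            if n == config.de_target_stratum}


def simulate_counts(
    table: OrthogroupTable, truth: SimTruth, config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SampleSheet, pd.Series, SimTruth]:
    """Negative-binomial counts for the genes of one genome, two groups.

    ``counts[g, s] ~ NB(mean = sf_s * mu_g * 2**(x_s * beta_g),
    dispersion alpha)`` with ``x_s = 1`` in the treatment group.  Planted
    effects go only to genes of orthogroups in the target stratum, signs
    alternating (+, -, +, ...) in deterministic gene order.  Returns
    ``(counts, sample sheet, gene lengths, truth)``.
    """
    if config.dispersion < 0:
        raise SimConfigError("dispersion must be >= 0")
    genome = config.count_genome or (table.genomes[0] if table.genomes else None)
    if genome is None or genome not in table.genomes:
        raise SimConfigError(f"count_genome {genome!r} not in table")
    gene_og = [
        (g, og)
        for og in table.orthogroups
        for g in (table.genes or {}).get((og, genome), [])
    ]
    gene_ids = [g for g, _ in gene_og]
    n_genes = len(gene_ids)
    n = config.n_samples_per_group
    samples = [f"{config.reference_label}_{i + 1}" for i in range(n)] + [
        f"{config.treatment_label}_{i + 1}" for i in range(n)
    ]
    x = np.array([0] * n + [1] * n)

    lengths = pd.Series(
        rng.integers(config.length_range[0], config.length_range[1] + 1,
                     size=n_genes),
        index=gene_ids, name="length", dtype=np.int64,
    )
    lo, hi = config.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=2 * n))
    sf = sf / np.exp(np.log(sf).mean())  # geometric mean 1
    mu = np.exp(
        rng.uniform(np.log(config.mu_range[0]), np.log(config.mu_range[1]),
                    size=n_genes)
    )

    beta = np.zeros(n_genes)
    targets = _target_orthogroups(truth, config)
    if config.de_fraction > 0 and n_genes:
        eligible = [
            i for i, (_, og) in enumerate(gene_og)
            if targets is None or og in targets
        ]
        n_de = min(len(eligible), int(round(config.de_fraction * n_genes)))
        chosen = (
            sorted(rng.choice(eligible, size=n_de, replace=False).tolist())
            if n_de else []
        )
        for k, i in enumerate(chosen):
            beta[i] = config.de_log2fc if k % 2 == 0 else -config.de_log2fc

    mean = sf[None, :] * mu[:, None] * np.exp2(x[None, :] * beta[:, None])
    if config.dispersion < _POISSON_LIMIT:
        counts = rng.poisson(mean)
    else:
        a = config.dispersion
        counts = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * mean))
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"),
                         columns=samples, dtype=np.int64)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "organism": config.organism,
                "treatment": [config.reference_label] * n
                + [config.treatment_label] * n,
                "replicate": list(range(1, n + 1)) * 2,
            },
            index=pd.Index(samples, name="sample"),
        ),
        reference=config.reference_label,
    )
    truth = replace(
        truth,
        log2fc=pd.Series(beta, index=gene_ids, name="log2fc"),
        baseline_mu=pd.Series(mu, index=gene_ids, name="mu"),
        size_factors=pd.Series(sf, index=samples, name="size_factor"),
    )
    return frame, sheet, lengths, truth


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Full bundle from one seed: tree, orthogroups, replicons, counts."""
    rng = np.random.default_rng(config.seed)
    chron = _simulate_tree(config, rng)
    table, truth = simulate_orthogroups(config, chron, rng)
    rmap = simulate_replicon_map(table, truth, config, rng)
    counts, sheet, lengths, truth = simulate_counts(table, truth, config, rng)
    return SimBundle(config, chron, table, rmap, lengths, counts, sheet, truth)


# ---------------------------------------------------------------------------
# fixture bundle I/O (UTF-8 TSV with header row; Newick + metadata sidecar)


def write_fixture_bundle(bundle: SimBundle, directory) -> dict[str, Path]:
    """Write every simulated object as the plain-text format the pipeline reads."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": d / "tree.nwk",
        "tree_meta": d / "tree_meta.tsv",
        "genecounts": d / "orthogroup_gene_count.tsv",
        "members": d / "orthogroup_members.tsv",
        "replicons": d / "replicons.tsv",
        "counts": d / "counts.tsv",
        "samples": d / "samples.tsv",
        "lengths": d / "lengths.tsv",
        "truth_genes": d / "truth_genes.tsv",
        "truth_orthogroups": d / "truth_orthogroups.tsv",
    }
    paths["tree"].write_text(bundle.chronogram.as_newick() + "\n")
    pd.DataFrame(
        {"key": ["root_age_mya"], "value": [bundle.chronogram.root_age]}
    ).to_csv(paths["tree_meta"], sep="\t", index=False)
    write_genecount_table(bundle.table, paths["genecounts"])
    rows = [
        (og, gn, ",".join(genes))
        for (og, gn), genes in (bundle.table.genes or {}).items()
    ]
    pd.DataFrame(rows, columns=["orthogroup", "genome", "genes"]).to_csv(
        paths["members"], sep="\t", index=False
    )
    bundle.replicon_map.to_csv(paths["replicons"], sep="\t")
    bundle.counts.to_csv(paths["counts"], sep="\t")
    bundle.sheet.frame.assign(reference=bundle.sheet.reference).to_csv(
        paths["samples"], sep="\t"
    )
    bundle.lengths.rename_axis("gene").to_csv(paths["lengths"], sep="\t")
    t = bundle.truth
    pd.DataFrame(
        {
            "log2fc": t.log2fc,
            "baseline_mu": t.baseline_mu,
        }
    ).rename_axis("gene").to_csv(paths["truth_genes"], sep="\t")
    ogs = list(bundle.table.orthogroups)
    pd.DataFrame(
        {
            "orthogroup": ogs,
            "gain_node": [t.gain_node[o] for o in ogs],
            "n_losses": [len(t.loss_edges.get(o, [])) for o in ogs],
            "replicon_class": [t.replicon_class.get(o, "") for o in ogs],
        }
    ).to_csv(paths["truth_orthogroups"], sep="\t", index=False)
    return paths


def read_fixture_bundle(directory):
    """Round-trip reader for :func:`write_fixture_bundle` outputs.

    Returns ``(chronogram, table, replicon_map, counts, sheet, lengths)``.
    """
    from .pangenome import read_genecount_table, read_replicon_map
    from .trees import read_chronogram

    d = Path(directory)
    chron = read_chronogram(d / "tree.nwk")
    table = read_genecount_table(d / "orthogroup_gene_count.tsv")
    members = pd.read_csv(d / "orthogroup_members.tsv", sep="\t", dtype=str)
    genes = {
        (r.orthogroup, r.genome): r.genes.split(",")
        for r in members.itertuples()
    }
    table = OrthogroupTable(table.counts, genes or ({} if table.counts.empty else None))
    rmap = read_replicon_map(d / "replicons.tsv")
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col="gene")
    sframe = pd.read_csv(d / "samples.tsv", sep="\t", index_col="sample")
    reference = sframe.pop("reference").iloc[0]
    sheet = SampleSheet(sframe, reference=reference)
    lengths = pd.read_csv(d / "lengths.tsv", sep="\t", index_col="gene")["length"]
    return chron, table, rmap, counts, sheet, lengths
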