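"""Pangenome conservation strata along a chronogram.

Orthogroups (gene families shared across genomes) are partitioned into
ordered conservation strata.  Two stratum styles are supported through one
configurable scheme format:

* **MRCA-anchored strata** (the plant-style sequential subsets 1..7): a
  family present in both focal genomes is assigned to the scheme node
  anchoring the oldest clade compatible, under Dollo parsimony, with the
  family's observed presence pattern — i.e. the ancestral-most scheme node
  at or below the MRCA of all genomes carrying the family.
* **Predicate strata** (accessory subsets 8/9 and the bacterial-style
  subsets I..IV): set-membership rules over the presence pattern, applied
  first-match-wins.

Copy-number class is orthogonal to stratum: a family is *single*-copy when
no focal genome carries more than one member, *multi* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .trees import Chronogram, mrca

__all__ = [
    "OrthogroupTable",
    "StratumRule",
    "StratumScheme",
    "SchemeError",
    "TableError",
    "read_genecount_table",
    "write_genecount_table",
    "read_replicon_map",
    "assign_stratum",
    "assign_table",
    "classify_copy_number",
    "replicon_consistency_fraction",
]

REPLICON_CLASSES = ("chromosome", "chromid", "symbiosis_plasmid", "accessory_plasmid")


class TableError(ValueError):
    """Malformed orthogroup count table."""


class SchemeError(ValueError):
    """Invalid or non-total stratum scheme."""


@dataclass
class OrthogroupTable:
    """Orthogroup x genome copy-count matrix, plus optional member genes.

    ``genes`` maps ``(orthogroup, genome)`` to the member gene ids; when
    present, list lengths must equal the copy counts.
    """

    counts: pd.DataFrame  # index: orthogroup id, columns: genome id, int >= 0
    genes: dict[tuple[str, str], list[str]] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableError(f"duplicate orthogroup id {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise TableError("negative copy counts")
        zero = self.counts.sum(axis=1) == 0
        if zero.any():
            raise TableError(
                f"orthogroups with no members anywhere: {list(self.counts.index[zero])}"
            )
        if self.genes is not None:
            for (og, gn), members in self.genes.items():
                want = int(self.counts.at[og, gn])
                if len(members) != want:
                    raise TableError(
                        f"member list for ({og}, {gn}) has {len(members)} genes, "
                        f"count says {want}"
                    )

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.counts.index)

    def members(self, og: str) -> list[str]:
        if self.genes is None:
            raise TableError("table carries no member gene lists")
        return [g for gn in self.genomes for g in self.genes.get((og, gn), [])]


def read_genecount_table(path) -> OrthogroupTable:
    """Parse a gene-count TSV (orthogroup rows, one column per genome).

    A trailing ``Total`` column, if present, is ignored.  Cells must be
    non-negative integers; duplicate orthogroup ids and all-zero rows are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableError(f"{path}: expected an id column plus genome columns")
    id_col = df.columns[0]
    if df.columns[-1] == "Total":
        df = df.drop(columns="Total")
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise TableError(f"{path}: duplicate orthogroup id {dup!r}")
    df = df.set_index(id_col)
    df.index.name = "orthogroup"
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.round())
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise TableError(
                f"{path}: non-integer count at row {row!r}, column {col!r}"
            )
        out[col] = parsed.astype(np.int64)
    return OrthogroupTable(out)


def write_genecount_table(table: OrthogroupTable, path) -> None:
    """Write the gene-count TSV dialect, including the trailing Total column."""
    df = table.counts.copy()
    df["Total"] = df.sum(axis=1)
    df.to_csv(path, sep="\t", index_label="Orthogroup")


def read_replicon_map(path) -> pd.DataFrame:
    """Read a gene -> (genome, replicon_class) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene", "genome", "replicon_class"}
    if not need.issubset(df.columns):
        raise TableError(f"{path}: replicon map needs columns {sorted(need)}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise TableError(f"{path}: gene {dup!r} mapped to more than one replicon")
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# stratum schemes


@dataclass
class StratumRule:
    """One stratum label and the rule that admits presence patterns to it.

    kinds:
      ``mrca``          - anchored at the MRCA of ``genomes`` on the tree
      ``all_of``        - present in every genome in ``genomes``
      ``any_group_all`` - present in every genome of at least one of ``groups``
      ``count_range``   - number of ``genomes`` present within [lo, hi]
      ``remainder``     - always true (catch-all)
    """

    label: str
    kind: str
    genomes: tuple[str, ...] = ()
    groups: tuple[tuple[str, ...], ...] = ()
    lo: int = 0
    hi: int = 0

    def matches(self, present: frozenset[str]) -> bool:
        if self.kind == "all_of":
            return set(self.genomes) <= present
        if self.kind == "any_group_all":
            return any(set(g) <= present for g in self.groups)
        if self.kind == "count_range":
            k = len(present & set(self.genomes))
            return self.lo <= k <= self.hi
        if self.kind == "remainder":
            return True
        raise SchemeError(f"rule {self.label!r} of kind {self.kind!r} is not a predicate")


@dataclass
class StratumScheme:
    """Ordered stratum rules plus the focal genome set.

    MRCA rules are only consulted when every focal genome is present;
    predicate rules are applied in order, first match wins, and the scheme
    must end in a ``remainder`` rule so that every pattern gets a label.
    """

    rules: list[StratumRule]
    focal_genomes: frozenset[str]
    anchors: dict[str, str] = field(default_factory=dict)  # label -> node id

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rules]

    @property
    def mrca_rules(self) -> list[StratumRule]:
        return [r for r in self.rules if r.kind == "mrca"]

    @property
    def predicate_rules(self) -> list[StratumRule]:
        return [r for r in self.rules if r.kind != "mrca"]

    def validate(self, chron: Chronogram) -> None:
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise SchemeError("stratum labels are not unique")
        if not self.focal_genomes <= chron.leaves:
            raise SchemeError("focal genomes not all present in the tree")
        preds = self.predicate_rules
        if not preds or preds[-1].kind != "remainder":
            raise SchemeError(
                "scheme is not total: last predicate rule must be a remainder"
            )
        m_rules = self.mrca_rules
        if m_rules:
            focal_node = mrca(chron, self.focal_genomes)
            self.anchors = {}
            for r in m_rules:
                if not r.genomes:
                    raise SchemeError(f"mrca rule {r.label!r} lacks anchor genomes")
                node = mrca(chron, r.genomes)
                # anchor must sit on the root-to-focal path
                if not chron.is_ancestor_or_equal(node, focal_node):
                    raise SchemeError(
                        f"anchor of {r.label!r} ({node}) is off the root-to-focal path"
                    )
                self.anchors[r.label] = node
            nodes = list(self.anchors.values())
            ages = [chron.ages[n] for n in nodes]
            if sorted(ages, reverse=True) != ages:
                raise SchemeError("mrca strata must be listed oldest to youngest")
            if len(set(nodes)) != len(nodes):
                raise SchemeError("two mrca strata share one anchor node")
            if nodes[-1] != focal_node:
                raise SchemeError(
                    "youngest mrca anchor must be the MRCA of the focal genomes "
                    f"({focal_node}), got {nodes[-1]}"
                )


def scheme_from_dict(spec: Mapping, chron: Chronogram) -> StratumScheme:
    """Build and validate a scheme from a plain mapping (YAML-compatible)."""
    rules = []
    for r in spec["strata"]:
        rules.append(
            StratumRule(
                label=str(r["label"]),
                kind=r["type"],
                genomes=tuple(r.get("genomes", ())),
                groups=tuple(tuple(g) for g in r.get("groups", ())),
                lo=int(r.get("lo", 0)),
                hi=int(r.get("hi", 0)),
            )
        )
    scheme = StratumScheme(rules, frozenset(spec["focal_genomes"]))
    scheme.validate(chron)
    return scheme


def read_scheme(path, chron: Chronogram) -> StratumScheme:
    with open(path) as fh:
        return scheme_from_dict(yaml.safe_load(fh), chron)


def assign_stratum(
    pattern: Mapping[str, int] | pd.Series,
    scheme: StratumScheme,
    chron: Chronogram,
) -> str:
    """Assign one presence/copy-count pattern to exactly one stratum label.

    Presence means copy count >= 1; copy numbers beyond 1 never influence
    the stratum.  When every focal genome is present, the pattern is placed
    at the ancestral-most scheme anchor at or below its MRCA (Dollo
    reading); otherwise the predicate rules decide.
    """
    present = frozenset(g for g, c in dict(pattern).items() if c >= 1)
    if not present:
        raise SchemeError("pattern has no positive entries")
    unknown = present - chron.leaves
    if unknown:
        raise SchemeError(f"pattern names unknown genomes: {sorted(unknown)}")
    if scheme.mrca_rules and scheme.focal_genomes <= present:
        node = mrca(chron, present)
        # anchors at or below the pattern MRCA, oldest (= first listed) wins
        for rule in scheme.mrca_rules:
            anchor = scheme.anchors[rule.label]
            if chron.is_ancestor_or_equal(node, anchor):
                return rule.label
    for rule in scheme.predicate_rules:
        if rule.matches(present):
            return rule.label
    raise SchemeError("non-total scheme slipped through validation")


def classify_copy_number(
    pattern: Mapping[str, int] | pd.Series, focal_genomes: Iterable[str]
) -> str:
    """``single`` when no focal genome holds >= 2 copies, else ``multi``."""
    p = dict(pattern)
    return "multi" if max((p.get(g, 0) for g in focal_genomes), default=0) > 1 else "single"


def assign_table(
    table: OrthogroupTable, scheme: StratumScheme, chron: Chronogram
) -> pd.DataFrame:
    """Stratum + copy class for every orthogroup in the table.

    Returns a frame indexed by orthogroup with columns ``stratum`` and
    ``copy_class``; the labels partition the table by construction.
    """
    strata = []
    classes = []
    for og in table.orthogroups:
        row = table.counts.loc[og]
        strata.append(assign_stratum(row, scheme, chron))
        classes.append(classify_copy_number(row, scheme.focal_genomes))
    return pd.DataFrame(
        {"stratum": strata, "copy_class": classes},
        index=pd.Index(table.orthogroups, name="orthogroup"),
    )


def gene_strata(table: OrthogroupTable, assignment: pd.DataFrame) -> pd.DataFrame:
    """Propagate orthogroup strata to member genes (requires gene lists)."""
    if table.genes is None:
        raise TableError("table carries no member gene lists")
    rows = []
    for (og, gn), members in table.genes.items():
        st = assignment.at[og, "stratum"]
        cc = assignment.at[og, "copy_class"]
        for g in members:
            rows.append((g, og, gn, st, cc))
    return pd.DataFrame(
        rows, columns=["gene", "orthogroup", "genome", "stratum", "copy_class"]
    ).set_index("gene")


def replicon_consistency_fraction(
    core_orthogroups: Iterable[str],
    table: OrthogroupTable,
    replicon_map: pd.DataFrame,
) -> tuple[float, dict[str, bool]]:
    """Fraction of core orthogroups whose members share one replicon class.

    An orthogroup is consistent when all its member genes, across all
    genomes, sit on the same replicon class (chromosome, chromid, symbiosis
    plasmid, ...).  Raises on genes missing from the map.
    """
    flags: dict[str, bool] = {}
    for og in core_orthogroups:
        classes = set()
        for gene in table.members(og):
            if gene not in replicon_map.index:
                raise TableError(f"gene {gene!r} of {og!r} missing from replicon map")
            classes.add(replicon_map.at[gene, "replicon_class"])
        flags[og] = len(classes) == 1
    if not flags:
        warnings.warn("no core orthogroups supplied; consistency undefined, using 0/0=nan")
        return float("nan"), flags
    return sum(flags.values()) / len(flags), flags
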