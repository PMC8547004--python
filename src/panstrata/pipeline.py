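"""End-to-end orchestration: simulate -> stratify -> express -> enrich -> report.

A pipeline run is driven by one YAML configuration and one seed.  Inputs
come either from the built-in generator (``simulate:`` section) or from
files on disk (``inputs:`` section).  Comparisons are generated
automatically as each non-reference treatment versus the reference, per
organism.  Identical configuration + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import enrichment as en
from . import expression as ex
from . import pangenome as pg
from . import simulate as sim
from .trees import read_chronogram

log = logging.getLogger("panstrata")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    alpha: float = 0.05
    log2fc_cutoff: float = 1.0
    q_cutoff: float = 0.05
    n_boot: int = 1000
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    scheme: dict[str, Any] | None = None
    pathway_map: str | None = None
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise PipelineError("config needs exactly one of 'simulate:' or 'inputs:'")
        if self.scheme is None:
            raise PipelineError("config needs a 'scheme:' section")
        for name in ("alpha", "log2fc_cutoff", "q_cutoff"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")


def load_config(path, seed: int | None = None, outdir=None) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = PipelineConfig(
        outdir=Path(outdir if outdir is not None else raw.get("outdir", "panstrata_out")),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        alpha=float(raw.get("alpha", 0.05)),
        log2fc_cutoff=float(raw.get("log2fc_cutoff", 1.0)),
        q_cutoff=float(raw.get("q_cutoff", 0.05)),
        n_boot=int(raw.get("n_boot", 1000)),
        simulate=raw.get("simulate"),
        inputs=raw.get("inputs"),
        scheme=raw.get("scheme"),
        pathway_map=raw.get("pathway_map"),
        raw=raw,
    )
    return cfg


@dataclass
class RunReport:
    seed: int
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    warnings: list[str] = field(default_factory=list)
    config_echo: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "stages": self.stages,
                "outputs": self.outputs,
                "warnings": self.warnings,
                "config": self.config_echo,
            },
            indent=2,
            default=str,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, report: RunReport, index=True) -> None:
    df.to_csv(path, sep="\t", index=index)
    report.outputs[str(path)] = _sha256(path)


def _acquire_inputs(cfg: PipelineConfig, report: RunReport):
    """Either simulate a bundle or read the configured input files."""
    if cfg.simulate is not None:
        sc_kwargs = dict(cfg.simulate)
        sc_kwargs.setdefault("seed", cfg.seed)
        sc = sim.SimConfig(**sc_kwargs)
        rng = np.random.default_rng(sc.seed)
        chron = sim._simulate_tree(sc, rng)
        table, truth = sim.simulate_orthogroups(sc, chron, rng)
        rmap = sim.simulate_replicon_map(table, truth, sc, rng)
        scheme = pg.scheme_from_dict(cfg.scheme, chron)
        assignment = pg.assign_table(table, scheme, chron)
        truth.stratum_of = assignment["stratum"].to_dict()
        counts, sheet, lengths, truth = sim.simulate_counts(table, truth, sc, rng)
        return chron, table, rmap, counts, sheet, lengths, scheme, assignment, truth
    paths = {k: Path(v) for k, v in cfg.inputs.items()}
    for k, p in paths.items():
        if not p.exists():
            raise PipelineError(f"input file for {k!r} not found: {p}")
    if "bundle_dir" in paths:
        chron, table, rmap, counts, sheet, lengths = sim.read_fixture_bundle(
            paths["bundle_dir"]
        )
    else:
        chron = read_chronogram(paths["tree"])
        table = pg.read_genecount_table(paths["genecounts"])
        if "members" in paths:
            members = pd.read_csv(paths["members"], sep="\t", dtype=str)
            genes = {
                (r.orthogroup, r.genome): r.genes.split(",")
                for r in members.itertuples()
            }
            table = pg.OrthogroupTable(table.counts, genes)
        rmap = pg.read_replicon_map(paths["replicons"]) if "replicons" in paths else None
        counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
        sframe = pd.read_csv(paths["samples"], sep="\t", index_col=0)
        reference = sframe.pop("reference").iloc[0]
        sheet = ex.SampleSheet(sframe, reference=reference)
        lengths = pd.read_csv(paths["lengths"], sep="\t", index_col=0).iloc[:, 0]
    scheme = pg.scheme_from_dict(cfg.scheme, chron)
    assignment = pg.assign_table(table, scheme, chron)
    return chron, table, rmap, counts, sheet, lengths, scheme, assignment, None


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    report = RunReport(seed=cfg.seed, config_echo=dict(cfg.raw))
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        t0 = time.perf_counter()
        (chron, table, rmap, counts, sheet, lengths, scheme, assignment,
         truth) = _acquire_inputs(cfg, report)
        gene_map = pg.gene_strata(table, assignment)
        _write(assignment, outdir / "strata.tsv", report)
        _write(gene_map, outdir / "gene_strata.tsv", report)
        report.stages["stratify"] = {
            "orthogroups": len(table.orthogroups),
            "genes": len(gene_map),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stratify: %d orthogroups", len(table.orthogroups))

        # core-gene replicon consistency (oldest stratum = core), when mapped
        if rmap is not None and len(table.orthogroups):
            core_label = scheme.labels[0]
            core = assignment.index[assignment["stratum"] == core_label]
            if len(core):
                frac, _flags = pg.replicon_consistency_fraction(core, table, rmap)
                report.stages["replicon_consistency"] = {
                    "core_stratum": core_label,
                    "n_core": int(len(core)),
                    "consistent_fraction": float(frac),
                }

        t0 = time.perf_counter()
        tpm = ex.compute_tpm(counts, lengths)
        _write(tpm.round(4), outdir / "tpm.tsv", report)
        strata_for_counts = gene_map.loc[
            gene_map.index.intersection(counts.index),
            ["stratum", "copy_class"],
        ]
        missing = counts.index.difference(strata_for_counts.index)
        if len(missing):
            raise PipelineError(f"counted genes without strata: {list(missing)[:5]}")

        de_frames = {}
        for trt in sheet.comparisons:
            de = ex.de_test(
                counts,
                sheet.samples_of(sheet.reference),
                sheet.samples_of(trt),
                cfg.log2fc_cutoff,
                cfg.q_cutoff,
            )
            de_frames[trt] = de
            _write(de.round(6), outdir / f"de_{trt}_vs_{sheet.reference}.tsv", report)
        report.stages["de"] = {
            "comparisons": len(de_frames),
            "degs": {t: int(d["deg"].sum()) for t, d in de_frames.items()},
            "seconds": round(time.perf_counter() - t0, 3),
        }

        t0 = time.perf_counter()
        any_deg = (
            pd.concat([d["deg"] for d in de_frames.values()], axis=1).any(axis=1)
            if de_frames
            else pd.Series(False, index=counts.index)
        )
        summary = ex.stratum_expression_summary(
            tpm, strata_for_counts, sheet, any_deg, n_boot=cfg.n_boot, seed=cfg.seed
        )
        _write(summary.round(4), outdir / "stratum_summary.tsv", report, index=False)

        enr_frames = []
        planted_calls = {}
        for trt, de in de_frames.items():
            enr = en.subset_deg_enrichment(
                de["deg"], strata_for_counts["stratum"], cfg.alpha
            )
            enr = enr.reset_index()
            enr.insert(0, "comparison", trt)
            enr_frames.append(enr)
            planted_calls[trt] = dict(zip(enr["unit"], enr["call"]))
            if rmap is not None:
                classes = rmap.loc[
                    rmap.index.intersection(counts.index), "replicon_class"
                ]
                have = strata_for_counts.index.intersection(classes.index)
                if len(have):
                    renr = en.replicon_stratified_enrichment(
                        de.loc[have, "deg"],
                        strata_for_counts.loc[have, "stratum"],
                        classes.loc[have],
                        cfg.alpha,
                    )
                    _write(
                        renr.reset_index(),
                        outdir / f"replicon_enrichment_{trt}.tsv",
                        report,
                        index=False,
                    )
        if enr_frames:
            _write(
                pd.concat(enr_frames, ignore_index=True),
                outdir / "stratum_enrichment.tsv",
                report,
                index=False,
            )

        if cfg.pathway_map is not None:
            pmap = pd.read_csv(cfg.pathway_map, sep="\t", dtype=str)
            background = set(counts.index)
            for trt, de in de_frames.items():
                for direction in ("up", "down"):
                    genes = set(de.index[de["direction"] == direction])
                    pe = en.pathway_enrichment(genes, pmap, background, cfg.q_cutoff)
                    _write(
                        pe.reset_index(),
                        outdir / f"pathway_{direction}_{trt}.tsv",
                        report,
                        index=False,
                    )

        if de_frames:
            lfc = en.log2_ratio_matrix(tpm, sheet)
            _write(lfc.round(6), outdir / "log2_ratio_matrix.tsv", report)
            var_rows = lfc.index[(lfc.abs().sum(axis=1) > 0)]
            if len(var_rows) >= 2:
                cl = en.hierarchical_cluster_average(lfc.loc[var_rows])
                (outdir / "dendrogram.nwk").write_text(cl.to_newick() + "\n")
                report.outputs[str(outdir / "dendrogram.nwk")] = _sha256(
                    outdir / "dendrogram.nwk"
                )
        report.stages["enrich"] = {
            "strata_tested": len(scheme.labels),
            "calls": planted_calls,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        report.warnings = [str(w.message) for w in caught]

    (outdir / "run_report.json").write_text(report.to_json() + "\n")
    return report
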