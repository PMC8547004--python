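"""Small synthetic demo fixtures: trees, stratum schemes, pipeline configs.

Two 8-leaf chronograms mirror the two stratification styles the package
supports.  The *plant-style* tree carries two focal soybean-like accessions
plus one wild relative, a sister legume, two deeper legumes and two
nonlegume outgroups; its scheme is an MRCA ladder (subset_1..subset_3)
followed by accessory predicates.  The *bacterial-style* tree carries five
focal strains plus three congeneric outgroup strains; its scheme is purely
predicate-based (genus core, focal core, shared-accessory, strain-specific),
applied first-match-wins.

All fixtures are synthetic: topologies and the 106-MYA root age only
emulate the shape of real host/symbiont chronograms.
"""

from __future__ import annotations

from .pangenome import StratumScheme, scheme_from_dict
from .trees import Chronogram, chronogram_from_newick

PLANT_FIXTURE_NEWICK = (
    "((((GmA:5,GmB:5):8,Gs:13):41,Vg:54):52,"
    "((Md:40,Lt:40):26,(Ng1:30,Ng2:30):36):40);"
)

PLANT_SCHEME = {
    "focal_genomes": ["GmA", "GmB", "Gs"],
    "strata": [
        {"label": "subset_1", "type": "mrca", "genomes": ["GmA", "Ng1"]},
        {"label": "subset_2", "type": "mrca", "genomes": ["GmA", "Vg"]},
        {"label": "subset_3", "type": "mrca", "genomes": ["GmA", "Gs"]},
        # all accessions of at least one focal species (subset-8 style)
        {"label": "subset_4", "type": "any_group_all",
         "groups": [["GmA", "GmB"], ["Gs"]]},
        {"label": "subset_5", "type": "remainder"},
    ],
}

BACTERIAL_FIXTURE_NEWICK = (
    "(((F1:20,F2:20):20,(F3:30,(F4:15,F5:15):15):10):66,"
    "((M1:30,M2:30):30,M3:60):46);"
)

BACTERIAL_SCHEME = {
    "focal_genomes": ["F1", "F2", "F3", "F4", "F5"],
    "strata": [
        {"label": "subset_I", "type": "all_of",
         "genomes": ["F1", "F2", "F3", "F4", "F5", "M1", "M2", "M3"]},
        {"label": "subset_II", "type": "all_of",
         "genomes": ["F1", "F2", "F3", "F4", "F5"]},
        {"label": "subset_III", "type": "count_range",
         "genomes": ["F1", "F2", "F3", "F4", "F5"], "lo": 2, "hi": 4},
        {"label": "subset_IV", "type": "remainder"},
    ],
}


def plant_fixture() -> tuple[Chronogram, StratumScheme]:
    chron = chronogram_from_newick(PLANT_FIXTURE_NEWICK)
    return chron, scheme_from_dict(PLANT_SCHEME, chron)


def bacterial_fixture() -> tuple[Chronogram, StratumScheme]:
    chron = chronogram_from_newick(BACTERIAL_FIXTURE_NEWICK)
    return chron, scheme_from_dict(BACTERIAL_SCHEME, chron)


def demo_pipeline_config(outdir, seed: int = 0, n_orthogroups: int = 150,
                         n_samples_per_group: int = 4) -> dict:
    """A complete pipeline config on the bacterial-style fixture.

    Simulates a symbiont pangenome on the fixture tree, plants effects in
    the genus-core stratum of strain F1, and runs every downstream stage.
    """
    return {
        "seed": seed,
        "outdir": str(outdir),
        "alpha": 0.05,
        "log2fc_cutoff": 1.0,
        "q_cutoff": 0.05,
        "n_boot": 200,
        "simulate": {
            "tree_newick": BACTERIAL_FIXTURE_NEWICK,
            "n_orthogroups": n_orthogroups,
            "loss_prob": 0.05,
            "multi_copy_prob": 0.15,
            "n_samples_per_group": n_samples_per_group,
            "de_fraction": 0.15,
            "de_log2fc": 2.0,
            "de_target_stratum": "subset_I",
            "count_genome": "F1",
            "organism": "symbiont",
        },
        "scheme": BACTERIAL_SCHEME,
    }
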