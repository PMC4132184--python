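"""Bundled example data.

``dtc_rnai_screen.tsv`` is the distal-tip-cell migration RNAi screen
distributed with the package: per-treatment gonad-arm outcome
percentages for knockdowns of the TAP-MS candidate interactors of the
spliceosome-associated protein CACN-1 in C. elegans, plus the bait
itself, one network-expansion node, and the empty-vector control.
Five interactor treatments arrested as larvae and are unscored.
"""

from __future__ import annotations

from importlib import resources

from ..interactome import read_phenotype_table

#: bait treatment (the cacn-1 locus, sequence name W03H9.4)
BAIT_ID = "W03H9.4"
#: node contributed by parsimony network expansion (cdc-25.1)
EXTENDED_IDS = frozenset({"K06A5.7"})
#: candidate-interactor treatments with scorable adults
SCORED_INTERACTOR_IDS = frozenset(
    {
        "C07A9.2",
        "EEED8.5",
        "F49D11.1",
        "F53B7.3",
        "M03F8.3",
        "T11G6.8",
        "Y49E10.15",
        "Y57A10A.19",
        "Y66D12A.8",
    }
)
#: candidate-interactor treatments that arrested as early larvae (unscored)
ARRESTED_INTERACTOR_IDS = frozenset({"ubl-1", "Y37E3.8", "eftu-2", "prp-8", "skp-1"})

INTERACTOR_IDS = SCORED_INTERACTOR_IDS | ARRESTED_INTERACTOR_IDS


def load_dtc_screen():
    """Load the bundled DTC-migration screen.

    Returns ``(records, roles)``: the phenotype records (counts
    reconstructed from the printed percentages) and a mapping from
    treatment id to role (``control``/``bait``/``interactor``/
    ``extended``).
    """
    path = resources.files(__package__) / "dtc_rnai_screen.tsv"
    with resources.as_file(path) as p:
        records = read_phenotype_table(p)
    roles = {"control": "control", BAIT_ID: "bait"}
    roles.update({t: "interactor" for t in INTERACTOR_IDS})
    roles.update({t: "extended" for t in EXTENDED_IDS})
    return records, roles
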