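"""TAP-MS candidate filtering.

Raw affinity-purification hit lists mix true bait interactors with
stochastic background (abundant cytoplasmic proteins, chaperones,
organellar contaminants). The filter retains a protein only if it

1. appears in at least ``min_replicates`` distinct bait replicates,
2. never appears in a negative-control purification, and
3. belongs to no user-supplied contaminant blocklist (e.g. heat-shock
   proteins, mitochondrial/organellar proteins).

Rules are audited in that fixed order: the audit records the first rule
that removed each protein. Peptide counts are carried through for
reporting but are not a filter criterion. Blocklists are explicit input
sets rather than built-in annotation lookups — contaminant category
membership is curation-dependent, so reproducing a given published
candidate list requires the corresponding lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .interactome import HitRecord, ValidationError

RULE_RETAINED = "retained"
RULE_REPLICATE = "replicate"
RULE_CONTROL = "control"
RULE_BLOCKLIST = "blocklist"


@dataclass(frozen=True)
class FilterConfig:
    """Filtering thresholds and contaminant blocklists.

    ``blocklists`` maps a name (e.g. ``"heat_shock"``) to a set of gene
    ids. ``min_replicates`` defaults to 2: a protein must be seen in
    two independent purifications.
    """

    min_replicates: int = 2
    blocklists: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        if self.min_replicates < 1:
            raise ValidationError("min_replicates must be >= 1")


@dataclass
class CandidateSet:
    """Filter outcome: retained proteins plus a per-protein audit trail.

    ``audit`` maps every input protein to ``"retained"`` or the name of
    the first rule that removed it (``replicate``, ``control``, or
    ``blocklist:<name>``). ``peptide_support`` maps retained proteins to
    their maximum unique-peptide count across bait replicates.
    """

    proteins: set
    audit: dict
    peptide_support: dict

    def removed_by(self, rule_prefix: str) -> set:
        return {p for p, r in self.audit.items() if r.startswith(rule_prefix)}


def _by_replicate(records: Sequence[HitRecord], condition: str) -> dict:
    reps: dict[str, set] = {}
    for r in records:
        if r.condition != condition:
            raise ValidationError(
                f"record for {r.protein} has condition {r.condition!r}, expected {condition!r}"
            )
        reps.setdefault(r.replicate, set()).add(r.protein)
    return reps


def filter_candidates(
    bait_runs: Sequence[Sequence[HitRecord]],
    control_runs: Sequence[Sequence[HitRecord]] = (),
    config: FilterConfig | None = None,
) -> CandidateSet:
    """Reduce TAP-MS identifications to high-confidence candidate interactors.

    ``bait_runs`` and ``control_runs`` are collections of hit tables,
    one per purification run; replicate labels inside each table
    further partition records (a single flat table covering several
    replicates is equally valid input).

    A protein is retained iff present in >= ``config.min_replicates``
    distinct bait replicates, absent from every control run, and in no
    blocklist. The audit records the first failing rule in the order
    replicate -> control -> blocklist.
    """
    config = config or FilterConfig()
    if not bait_runs:
        raise ValidationError("at least one bait run is required")

    bait_reps: dict[str, set] = {}
    n_empty_runs = 0
    for run in bait_runs:
        if not run:
            n_empty_runs += 1  # a purification that identified nothing
            continue
        for label, prots in _by_replicate(run, "bait").items():
            bait_reps.setdefault(label, set()).update(prots)
    if len(bait_reps) + n_empty_runs < config.min_replicates:
        raise ValidationError(
            f"{len(bait_reps)} bait replicates present but min_replicates={config.min_replicates}"
        )

    control_proteins: set = set()
    for run in control_runs:
        for prots in _by_replicate(run, "control").values():
            control_proteins.update(prots)

    all_bait_proteins = set().union(*bait_reps.values()) if bait_reps else set()
    peptides: dict[str, int] = {}
    for run in bait_runs:
        for r in run:
            peptides[r.protein] = max(peptides.get(r.protein, 0), r.unique_peptides)

    audit: dict[str, str] = {}
    retained: set = set()
    for p in sorted(all_bait_proteins):
        n_reps = sum(1 for prots in bait_reps.values() if p in prots)
        if n_reps < config.min_replicates:
            audit[p] = RULE_REPLICATE
            continue
        if p in control_proteins:
            audit[p] = RULE_CONTROL
            continue
        blocked = next(
            (name for name, members in config.blocklists.items() if p in members), None
        )
        if blocked is not None:
            audit[p] = f"{RULE_BLOCKLIST}:{blocked}"
            continue
        audit[p] = RULE_RETAINED
        retained.add(p)

    return CandidateSet(
        proteins=retained,
        audit=audit,
        peptide_support={p: peptides[p] for p in retained},
    )
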