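"""Statistics for a categorical RNAi phenotype screen.

Each treatment (gene knockdown) is scored over five mutually exclusive
gonad-arm outcome categories (normal, extra turn, wandering, overshoot,
other). Published tables often print integer percentages plus the
number of animals ``n``; :func:`counts_from_percent` reconstructs the
underlying integer counts deterministically.

Testing collapses the five categories to normal-vs-defective and
compares each treatment against the control with Fisher's exact test
(two-sided, the sum-of-less-probable-tables convention). Significance
tiers follow the two conventional thresholds p < 0.05 (``star``) and
p < 0.0005 (``four_star``). No multiple-testing correction is applied
by default, matching per-comparison reporting; a Benjamini-Hochberg
q-value column is emitted alongside for modern use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interactome import PHENOTYPE_CATEGORIES, PhenotypeCounts, ValidationError

TIER_NS = "ns"
TIER_STAR = "star"          # p < 0.05
TIER_FOUR_STAR = "four_star"  # p < 0.0005

DEFAULT_ALPHA_TIERS = (0.0005, 0.05)


def counts_from_percent(percents: Sequence[float], n: int, treatment: str = "sample") -> PhenotypeCounts:
    """Reconstruct integer category counts from printed percentages.

    Provisional counts are round-half-up(p_i/100 * n), computed in
    exact rational arithmetic. Any residual between their sum and ``n``
    (printed percentages are rounded, so a few units of drift are
    expected) is repaired one unit at a time, largest-remainder style:
    a missing unit goes to the category that was rounded down with the
    largest fractional part; a surplus unit comes off the category that
    was rounded up with the smallest fractional part. Ties break in
    column order normal -> other; the walk cycles until the counts sum
    to ``n``. A residual larger than the number of categories means the
    percentages are inconsistent with ``n`` and raises.
    """
    if len(percents) != len(PHENOTYPE_CATEGORIES):
        raise ValidationError(f"expected {len(PHENOTYPE_CATEGORIES)} percentages")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if any(p < 0 for p in percents):
        raise ValidationError("percentages must be non-negative")

    exact = [Fraction(str(p)) * n / 100 for p in percents]
    counts = [int(math.floor(x + Fraction(1, 2))) for x in exact]
    fracs = [x - math.floor(x) for x in exact]

    residual = n - sum(counts)
    if abs(residual) > len(counts):
        raise ValidationError(
            f"{treatment}: percentages inconsistent with n={n} (residual {residual})"
        )
    half = Fraction(1, 2)
    if residual > 0:
        # prefer categories rounded down, largest fractional part first
        order = sorted(range(len(counts)), key=lambda i: (fracs[i] >= half, -fracs[i], i))
    else:
        # prefer categories rounded up, smallest fractional part first
        order = sorted(
            range(len(counts)),
            key=lambda i: (fracs[i] < half, fracs[i] if fracs[i] >= half else -fracs[i], i),
        )
    step = 1 if residual > 0 else -1
    k = 0
    while residual != 0:
        i = order[k % len(order)]
        k += 1
        if step < 0 and counts[i] == 0:
            continue
        counts[i] += step
        residual -= step

    return PhenotypeCounts(treatment, *counts, n)


def percent_table(counts: PhenotypeCounts) -> list:
    """Category percentages (0-100) of a scored phenotype record."""
    if not counts.scored:
        raise ValidationError(f"{counts.treatment}: unscored treatment has no percentages")
    return [100.0 * c / counts.n for c in counts.categories]


@dataclass(frozen=True)
class FisherResult:
    """One treatment-vs-control exact test on normal-vs-defective counts.

    ``table`` is ((treatment normal, treatment defective),
    (control normal, control defective)).
    """

    treatment: str
    table: tuple
    odds_ratio: float
    p_two_sided: float
    tier: str

    @property
    def significant(self) -> bool:
        return self.tier != TIER_NS


def _tier(p: float, alpha_tiers: Sequence[float]) -> str:
    strong, weak = sorted(alpha_tiers)
    if p < strong:
        return TIER_FOUR_STAR
    if p < weak:
        return TIER_STAR
    return TIER_NS


def fisher_normal_vs_control(
    treatment: PhenotypeCounts,
    control: PhenotypeCounts,
    alpha_tiers: Sequence[float] = DEFAULT_ALPHA_TIERS,
) -> FisherResult:
    """Fisher's exact test of %-normal, treatment vs control.

    Two-sided p sums the hypergeometric probabilities of all tables
    with the same margins that are no more probable than the observed
    one. Unscored records and empty groups are errors.
    """
    for rec in (treatment, control):
        if not rec.scored:
            raise ValidationError(f"{rec.treatment}: cannot test an unscored treatment")
        if rec.n < 1:
            raise ValidationError(f"{rec.treatment}: empty group")
    table = ((treatment.normal, treatment.defective), (control.normal, control.defective))
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherResult(
        treatment=treatment.treatment,
        table=table,
        odds_ratio=float(odds),
        p_two_sided=float(p),
        tier=_tier(float(p), alpha_tiers),
    )


@dataclass
class ScreenResults:
    """Per-treatment exact tests plus screen-level tallies.

    ``n_significant`` counts significant treatments among
    ``interactor_ids`` when that set was given (treatments outside it,
    e.g. nodes added by network expansion, are tallied separately in
    ``n_significant_other``). Unscored treatments are excluded from
    testing and never counted as hits.
    """

    results: dict
    unscored: list
    interactor_ids: set | None
    alpha_tiers: tuple
    control: PhenotypeCounts

    def _in_scope(self, treatment: str) -> bool:
        return self.interactor_ids is None or treatment in self.interactor_ids

    @property
    def n_significant(self) -> int:
        return sum(1 for r in self.results.values() if r.significant and self._in_scope(r.treatment))

    @property
    def n_significant_other(self) -> int:
        return sum(
            1 for r in self.results.values() if r.significant and not self._in_scope(r.treatment)
        )

    @property
    def total_screened(self) -> int:
        scoped = [t for t in list(self.results) + self.unscored if self._in_scope(t)]
        return len(scoped)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ps = [self.results[t].p_two_sided for t in self.results]
        qs = stats.false_discovery_control(ps, method="bh") if ps else []
        for (t, r), q in zip(self.results.items(), qs):
            rows.append(
                {
                    "treatment": t,
                    "normal": r.table[0][0],
                    "defective": r.table[0][1],
                    "n": sum(r.table[0]),
                    "pct_normal": 100.0 * r.table[0][0] / sum(r.table[0]),
                    "odds_ratio": r.odds_ratio,
                    "p_two_sided": r.p_two_sided,
                    "tier": r.tier,
                    "q_bh": float(q),
                }
            )
        for t in self.unscored:
            rows.append({"treatment": t, "tier": "unscored"})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "RNAi phenotype screen: Fisher exact tests vs control",
            "=" * 60,
            f"control: {self.control.normal}/{self.control.n} normal",
            f"treatments tested: {len(self.results)}  unscored: {len(self.unscored)}",
            f"significant (tiers {self.alpha_tiers}): {self.n_significant}"
            + (
                f" of {self.total_screened} screened interactors"
                if self.interactor_ids is not None
                else ""
            ),
        ]
        if self.interactor_ids is not None and self.n_significant_other:
            lines.append(f"significant outside interactor set: {self.n_significant_other}")
        lines.append("")
        with pd.option_context("display.width", 120):
            lines.append(df.to_string(index=False))
        return "\n".join(lines)


class PhenotypeScreen:
    """Model a phenotype screen against a shared control treatment.

    Parameters
    ----------
    treatments
        Scored and unscored :class:`PhenotypeCounts`, optionally
        including a record named ``"control"`` which is used as the
        control when the ``control`` argument is omitted.
    control
        The control record (overrides any ``"control"`` row).
    interactor_ids
        When given, screen-level tallies (``n_significant``,
        ``total_screened``) are restricted to these treatments;
        other treatments are still tested and reported separately.
    """

    def __init__(
        self,
        treatments: Iterable[PhenotypeCounts],
        control: PhenotypeCounts | None = None,
        interactor_ids: Iterable[str] | None = None,
    ):
        records = list(treatments)
        labels = [r.treatment for r in records]
        dup = {t for t in labels if labels.count(t) > 1}
        if dup:
            raise ValidationError(f"treatment id collision: {sorted(dup)}")
        if control is None:
            ctrl = [r for r in records if r.treatment == "control"]
            if not ctrl:
                raise ValidationError("no control record present and none supplied")
            control = ctrl[0]
        self.control = control
        self.treatments = [r for r in records if r.treatment != control.treatment]
        if not self.treatments:
            raise ValidationError("no treatments to test")
        if not control.scored:
            raise ValidationError("control must be scored")
        self.interactor_ids = set(interactor_ids) if interactor_ids is not None else None

    def fit(self, alpha_tiers: Sequence[float] = DEFAULT_ALPHA_TIERS) -> ScreenResults:
        results = {}
        unscored = []
        for rec in self.treatments:
            if not rec.scored:
                unscored.append(rec.treatment)
                continue
            results[rec.treatment] = fisher_normal_vs_control(
                rec, self.control, alpha_tiers=alpha_tiers
            )
        return ScreenResults(
            results=results,
            unscored=unscored,
            interactor_ids=self.interactor_ids,
            alpha_tiers=tuple(sorted(alpha_tiers)),
            control=self.control,
        )


def screen_summary(
    treatments: Iterable[PhenotypeCounts],
    control: PhenotypeCounts | None = None,
    interactor_ids: Iterable[str] | None = None,
    alpha_tiers: Sequence[float] = DEFAULT_ALPHA_TIERS,
) -> ScreenResults:
    """Functional one-call form of :class:`PhenotypeScreen` + ``fit``."""
    return PhenotypeScreen(treatments, control=control, interactor_ids=interactor_ids).fit(
        alpha_tiers=alpha_tiers
    )
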