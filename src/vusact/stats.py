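"""Validation statistics: 2x2 contingency, exact test, proximity binning.

The central question the validation layer answers: are variants classified
*Potentially* actionable more likely to be oncogenic in the viability assay
than variants classified *Unknown*? The 2x2 table crosses classification
(rows: Potentially, Unknown) with assay outcome (columns: oncogenic, not
oncogenic); conflicting and non-informative assay calls are excluded
before tabulation. Significance is a two-sided Fisher exact test, and the
reported odds ratio is the **conditional maximum-likelihood estimate** —
the odds parameter maximizing the noncentral hypergeometric likelihood of
the table with all margins fixed — not the sample cross-product ratio
(``a*d/(b*c)``). The two differ in finite samples (e.g. 3.945 vs 3.958 on
the [[76,128],[30,200]] table), and the conditional MLE is the convention
of R's ``fisher.test``; a flag exposes the sample OR for comparison.

The proximity distribution bins each oncogenic VUS by the distance to its
nearest actionable alteration, default categories {0, 1-2, 3-5, >5}.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .assay import AssayCall, AssayVerdict
from .classifier import ClassificationResult
from .errors import DegenerateTableError, JoinError
from .knowledgebase import ActionabilityValue, Knowledgebase
from .proximity import DistanceFallback, nearest_actionable
from .variant import ProteinVariant

DEFAULT_BINS: tuple[tuple[str, int, int | None], ...] = (
    ("0", 0, 0),
    ("1-2", 1, 2),
    ("3-5", 3, 5),
    (">5", 6, None),
)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows (Potentially, Unknown) x columns
    (oncogenic, not oncogenic)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_lists(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class FisherResult:
    """Two-sided exact p and conditional-MLE odds ratio.

    ``odds_ratio`` is 0 or +inf for boundary tables (a zero cell on the
    diagonal); ``sample_odds_ratio`` is the cross-product estimate.
    """

    p_two_sided: float
    odds_ratio: float
    sample_odds_ratio: float
    table: ContingencyTable2x2


@dataclass(frozen=True)
class ProximityDistribution:
    """Counts and fractions of variants per nearest-neighbor distance bin.

    ``unreached`` counts variants with no eligible actionable neighbor at
    all; they are excluded from the fractions' denominator."""

    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    unreached: int = 0

    @property
    def n(self) -> int:
        return sum(self.counts.values())


def build_contingency(
    classifications: Sequence[ClassificationResult],
    assay_calls: Sequence[AssayCall],
    *,
    strict: bool = False,
) -> ContingencyTable2x2:
    """Cross-tabulate classification against assay outcome.

    Joined on (gene, normalized change). Only Potentially/Unknown
    classifications enter; conflicting and non-informative assay calls are
    dropped. In strict mode a classified variant with no assay call raises
    :class:`~vusact.errors.JoinError`; otherwise it is skipped.
    """
    calls = {c.variant.key: c for c in assay_calls}
    a = b = c_ = d = 0
    for cls in classifications:
        if cls.value not in (
            ActionabilityValue.POTENTIALLY,
            ActionabilityValue.UNKNOWN,
        ):
            continue
        call = calls.get(cls.variant.key)
        if call is None:
            if strict:
                raise JoinError(f"no assay call for {cls.variant.key}")
            continue
        if call.call in (AssayVerdict.CONFLICTING, AssayVerdict.NON_INFORMATIVE):
            continue
        oncogenic = call.call is AssayVerdict.ONCOGENIC
        if cls.value is ActionabilityValue.POTENTIALLY:
            if oncogenic:
                a += 1
            else:
                b += 1
        else:
            if oncogenic:
                c_ += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c_, d)


def fisher_exact_2x2(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio.

    The p-value sums hypergeometric point probabilities (margins fixed) of
    all tables no more probable than the observed one; the odds ratio
    maximizes the noncentral hypergeometric likelihood. Degenerate tables
    (a zero margin) are rejected.
    """
    t = table.as_lists()
    row1, row2 = table.a + table.b, table.c + table.d
    col1, col2 = table.a + table.c, table.b + table.d
    if 0 in (row1, row2, col1, col2):
        raise DegenerateTableError(f"zero margin in table {t}")
    _, p = _scipy_fisher(t, alternative="two-sided")
    cmle = _scipy_odds_ratio(t, kind="conditional").statistic
    if table.b * table.c == 0:
        sample = math.inf if table.a * table.d > 0 else math.nan
    else:
        sample = (table.a * table.d) / (table.b * table.c)
    return FisherResult(
        p_two_sided=float(p),
        odds_ratio=float(cmle),
        sample_odds_ratio=sample,
        table=table,
    )


def proximity_distribution(
    oncogenic_vus: Iterable[ProteinVariant],
    kb: Knowledgebase,
    bins: Sequence[tuple[str, int, int | None]] = DEFAULT_BINS,
    *,
    fallback: DistanceFallback = "start",
) -> ProximityDistribution:
    """Bin oncogenic VUS by distance to their nearest actionable alteration.

    Truncating variants must be excluded by the caller beforehand (they are
    not scored by proximity). Variants on genes with no eligible actionable
    record are tallied as ``unreached`` and excluded from fractions.
    """
    counts = {label: 0 for label, _, _ in bins}
    unreached = 0
    for v in oncogenic_vus:
        if v.is_truncating():
            raise ValueError(
                f"truncating variant {v.key} must be excluded before binning"
            )
        near = nearest_actionable(v, kb, fallback=fallback)
        if not near:
            unreached += 1
            continue
        for label, lo, hi in bins:
            if near.distance >= lo and (hi is None or near.distance <= hi):
                counts[label] += 1
                break
        else:
            raise ValueError(f"distance {near.distance} fits no bin")
    n = sum(counts.values())
    fractions = {
        label: (count / n if n else math.nan) for label, count in counts.items()
    }
    return ProximityDistribution(counts=counts, fractions=fractions, unreached=unreached)
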