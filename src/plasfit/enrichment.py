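"""COG functional-category enrichment of a DE gene set.

For each single-letter COG category, the number of DE ORFs in the
category (k, out of a DE set of n) is compared with the genome background
(K category members out of N ORFs) via the upper tail of the
hypergeometric distribution, P(X >= k) — the one-sided Fisher exact test
for overrepresentation.  The tail is evaluated by direct summation of the
hypergeometric mass with log-factorial (gammaln) stabilization.

ORFs without a COG assignment are carried under the "–" marker: they
count toward the set sizes n and N but are never tested as a category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "COG_CODES",
    "UNASSIGNED",
    "CogAnnotation",
    "EnrichmentResult",
    "CogTally",
    "tally_by_cog",
    "hypergeom_enrichment_p",
    "enrich_table",
]

UNASSIGNED = "–"
#: The 23 single-letter COG functional categories, in the conventional
#: information-storage / cellular-processes / metabolism / poorly-known order.
COG_CODES = (
    "J", "A", "K", "L", "B",
    "D", "V", "T", "M", "N", "U", "O",
    "C", "G", "E", "F", "H", "I", "P", "Q",
    "R", "S",
)
_VALID = set(COG_CODES) | {UNASSIGNED, "-"}


@dataclass(frozen=True)
class CogAnnotation:
    orf_id: str
    cog_code: str

    def __post_init__(self) -> None:
        if self.cog_code not in _VALID:
            raise ValueError(f"unknown COG code {self.cog_code!r}")
        if self.cog_code == "-":  # accept ASCII hyphen as the unassigned marker
            object.__setattr__(self, "cog_code", UNASSIGNED)


@dataclass(frozen=True)
class CogTally:
    """Per-category (k, K) counts with DE-set size n and genome size N."""

    per_code: Mapping[str, tuple[int, int]]  # code -> (k, K)
    n: int
    N: int


@dataclass(frozen=True)
class EnrichmentResult:
    cog_code: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    significant: bool


def tally_by_cog(
    annotations: Sequence[CogAnnotation], de_set: Iterable[str]
) -> CogTally:
    """Count DE-set (k) and genome (K) membership per COG category.

    Every annotated ORF contributes to the genome background N; DE ORFs
    absent from the annotation are counted under the unassigned marker.
    Sum of k over all codes (including "–") equals n, and of K equals N.
    """
    de = set(de_set)
    codes = list(COG_CODES) + [UNASSIGNED]
    k = dict.fromkeys(codes, 0)
    K = dict.fromkeys(codes, 0)
    annotated = set()
    for ann in annotations:
        K[ann.cog_code] += 1
        annotated.add(ann.orf_id)
        if ann.orf_id in de:
            k[ann.cog_code] += 1
    missing = de - annotated
    for _ in missing:  # flagged by the caller's input validation if it cares
        k[UNASSIGNED] += 1
        K[UNASSIGNED] += 1
    per_code = {c: (k[c], K[c]) for c in codes}
    return CogTally(per_code, n=len(de), N=len(annotations) + len(missing))


def hypergeom_enrichment_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category members in a size-n sample drawn without
    replacement from N ORFs of which K are in the category.  The mass is
    summed directly over x = k .. min(n, K) in log space (gammaln) for
    numerical stability; P(X >= 0) = 1 exactly.
    """
    if min(k, n, K, N) < 0:
        raise ValueError("counts must be non-negative")
    if n > N or K > N:
        raise ValueError(f"inconsistent 2x2 counts: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    if k > min(n, K):  # past the support: empty tail
        return 0.0
    xs = np.arange(k, min(n, K) + 1)
    log_mass = (
        _lchoose(K, xs)
        + _lchoose(N - K, n - xs)
        - _lchoose(N, n)
    )
    return float(min(1.0, np.exp(log_mass).sum()))


def _lchoose(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def enrich_table(
    tally: CogTally,
    alpha: float = 0.05,
    two_sided: bool = False,
    bonferroni: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment p-value per tested COG category.

    One-sided (overrepresentation) by default; ``two_sided`` doubles the
    smaller tail (capped at 1).  No multiple-testing correction by
    default; ``bonferroni`` scales alpha by the number of tested
    categories.  The unassigned marker is never tested.
    """
    codes = [c for c in tally.per_code if c != UNASSIGNED]
    level = alpha / len(codes) if bonferroni else alpha
    out = []
    for code in codes:
        k, K = tally.per_code[code]
        p = hypergeom_enrichment_p(k, tally.n, K, tally.N)
        if two_sided:
            lower = 1.0 - hypergeom_enrichment_p(k + 1, tally.n, K, tally.N)
            p = min(1.0, 2.0 * min(p, lower))
        out.append(
            EnrichmentResult(code, k, tally.n, K, tally.N, p, significant=p < level)
        )
    return out
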