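"""Overlap statistics between alternative-splicing event lists.

Two experiments' significant-intron sets are compared against a shared
universe of testable introns: the representation factor is the observed
overlap divided by the overlap expected for two independent draws, and the
enrichment p-value is the exact upper-tail hypergeometric probability
P(X >= observed).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps

__all__ = ["OverlapResult", "overlap"]


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    expected_overlap: float
    representation_factor: float
    hypergeometric_p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def overlap(set_a: set, set_b: set, n_universe: int) -> OverlapResult:
    """Representation factor and hypergeometric enrichment of two event sets.

    Elements are intron identifiers such as ``(gene_id, intron_index)``
    under the same annotation.  ``n_universe`` is the total number of
    introns both experiments could have called (must cover the union).
    """
    a, b = set(set_a), set(set_b)
    if n_universe < len(a | b):
        raise ValueError(
            f"universe size {n_universe} smaller than the union ({len(a | b)})"
        )
    k = len(a & b)
    expected = len(a) * len(b) / n_universe if n_universe else 0.0
    rf = k / expected if expected > 0 else float("nan")
    # P(X >= k) for X ~ Hypergeom(M=n_universe, n=|a|, N=|b|)
    p = float(sps.hypergeom.sf(k - 1, n_universe, len(a), len(b)))
    return OverlapResult(
        n_universe=n_universe,
        n_a=len(a),
        n_b=len(b),
        n_overlap=k,
        expected_overlap=expected,
        representation_factor=rf,
        hypergeometric_p=p,
    )


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Exclusive region counts for 2–3 named sets (text Venn table)."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    names = list(sets)
    out: dict[str, int] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            out["&".join(combo)] = len(inside - outside)
    return out
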