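"""Best-hyper enrichment of gene sets over nested extremes of a ranked list.

For a deregulation list sorted decreasingly, the "best hyper test" scans
nested extremes of k = 10 .. 500 genes from the top (healthy-activated) and
from the bottom (damage-activated) of the list.  At each k an upper-tail
hypergeometric test measures the overlap of the gene set with the k-extreme;
the minimum p-value over all admissible (extreme, k) pairs signifies the
set's enrichment.  Sets with fewer than 15 members are excluded outright,
and (set, k) pairs whose overlap with the k-extreme is below 10 are skipped.
The minimum over a scan is anticonservative by construction — the default
significance cut-off is therefore a stringent 1e-5, and no multiplicity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "best_hyper_test",
    "results_table",
]

MIN_SET_SIZE = 15
MIN_OVERLAP = 10
SIGNIFICANCE_CUTOFF = 1e-5


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (complexes, pathways); duplicate members removed."""

    sets: dict[str, tuple[str, ...]]
    source: str = ""

    def __post_init__(self) -> None:
        deduped = {
            name: tuple(dict.fromkeys(genes))
            for name, genes in self.sets.items()
        }
        object.__setattr__(self, "sets", deduped)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    set_name: str
    extreme: str | None = None  # "top" or "bottom"
    best_k: int | None = None
    overlap: int | None = None
    p_min: float | None = None
    significant: bool = False
    excluded: bool = False
    reason: str = ""


def hypergeom_upper_tail(
    overlap: int, set_size: int, k: int, universe: int
) -> float:
    """Exact upper-tail hypergeometric probability P[X >= overlap].

    X counts members of a ``set_size``-gene set among ``k`` genes drawn
    without replacement from a universe of ``universe`` genes; the tail
    includes the observed overlap.
    """
    if not (0 <= overlap <= min(set_size, k)):
        raise ValueError(
            f"overlap {overlap} inconsistent with set size {set_size} and "
            f"draw {k}"
        )
    if set_size > universe or k > universe:
        raise ValueError(
            f"set size {set_size} and draw {k} must not exceed the "
            f"universe {universe}"
        )
    return float(hypergeom.sf(overlap - 1, universe, set_size, k))


def best_hyper_test(
    ranked: pd.Series | list[str],
    sets: GeneSetCollection,
    k_range: range = range(10, 501),
    universe: int | None = None,
    min_set_size: int = MIN_SET_SIZE,
    min_overlap: int = MIN_OVERLAP,
    cutoff: float = SIGNIFICANCE_CUTOFF,
) -> list[EnrichmentResult]:
    """Scan nested extremes of a ranked gene list for gene-set enrichment.

    Parameters
    ----------
    ranked:
        Gene ids sorted decreasingly by deregulation score (a sorted
        Series' index is used).  The top extreme holds healthy-activated
        genes, the bottom damage-activated ones.
    sets:
        Gene sets to test.
    k_range:
        Extreme sizes to scan (default every integer 10..500; pass a
        strided range for speed).
    universe:
        Size of the gene universe for the hypergeometric model; defaults
        to the number of genes in the ranked list (for the full analyzed
        matrix this is the number of genes on the array).
    min_set_size, min_overlap:
        Exclusion filters: sets smaller than ``min_set_size`` are skipped
        entirely; (set, k) pairs with overlap below ``min_overlap`` are
        skipped.
    cutoff:
        Minimum-p threshold flagging a set significant (default 1e-5).

    Returns
    -------
    list of EnrichmentResult
        One per set, with the minimum p over admissible (extreme, k) pairs
        and its location, or an exclusion flag with the reason.
    """
    genes = list(ranked.index) if isinstance(ranked, pd.Series) else list(ranked)
    n = len(genes)
    if universe is None:
        universe = n
    if universe < n:
        raise ValueError(
            f"universe size {universe} smaller than the ranked list ({n})"
        )
    ks = np.array([k for k in k_range if k <= n], dtype=int)
    results: list[EnrichmentResult] = []
    pos = {g: i for i, g in enumerate(genes)}
    for name, members in sets.sets.items():
        if len(members) < min_set_size:
            results.append(EnrichmentResult(
                set_name=name, excluded=True,
                reason=f"set has {len(members)} genes (< {min_set_size})",
            ))
            continue
        member_flags = np.zeros(n, dtype=int)
        for g in members:
            if g in pos:
                member_flags[pos[g]] = 1
        cum_top = np.cumsum(member_flags)
        cum_bottom = np.cumsum(member_flags[::-1])
        best: EnrichmentResult | None = None
        for extreme, cum in (("top", cum_top), ("bottom", cum_bottom)):
            if ks.size == 0:
                continue
            overlaps = cum[ks - 1]
            admissible = overlaps >= min_overlap
            if not admissible.any():
                continue
            ka = ks[admissible]
            oa = overlaps[admissible]
            pvals = hypergeom.sf(oa - 1, universe, len(members), ka)
            i = int(np.argmin(pvals))
            cand = EnrichmentResult(
                set_name=name, extreme=extreme, best_k=int(ka[i]),
                overlap=int(oa[i]), p_min=float(pvals[i]),
                significant=bool(pvals[i] <= cutoff),
            )
            if best is None or cand.p_min < best.p_min:
                best = cand
        if best is None:
            results.append(EnrichmentResult(
                set_name=name, excluded=True,
                reason=f"overlap with every scanned extreme < {min_overlap}",
            ))
        else:
            results.append(best)
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per set)."""
    return pd.DataFrame([
        {
            "set": r.set_name,
            "extreme": r.extreme if r.extreme is not None else "NA",
            "best_k": r.best_k if r.best_k is not None else "NA",
            "overlap": r.overlap if r.overlap is not None else "NA",
            "p_min": r.p_min if r.p_min is not None else "NA",
            "significant": r.significant,
            "excluded": r.excluded,
            "reason": r.reason,
        }
        for r in results
    ])
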