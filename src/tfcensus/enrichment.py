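"""One-tailed Fisher DBD-CD association tests with BH correction.

The counting unit is the protein: for a (family, CD) pair,

    a = family TFs carrying the CD        b = family TFs lacking it
    c = other-family TFs carrying the CD  d = other-family TFs lacking it

with the universe defaulting to all TF proteins in the dataset.  The raw
p-value is the upper hypergeometric tail P(X >= a); adjusted p-values come
from the Benjamini-Hochberg step-up over all tests jointly, and a pair is
flagged enriched at adjusted p <= 1e-10 by default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .io_model import FamilyCatalog, ProteinArchitecture

DEFAULT_ALPHA = 1e-10


@dataclass(frozen=True)
class EnrichmentResult:
    family: str
    cd_model: str
    a: int
    b: int
    c: int
    d: int
    p_raw: float
    p_adj: float
    enriched: bool
    unique: bool


def fisher_one_tail(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher p-value, P(X >= a) under fixed margins."""
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"count {name} must be >= 0, got {v}")
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be >= 1")
    # X ~ Hypergeom(N=n, K=a+b, n=a+c); sf(a-1) = P(X >= a)
    return float(min(1.0, hypergeom.sf(a - 1, n, a + b, a + c)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def enrich_all(
    architectures: Iterable[ProteinArchitecture],
    catalog: FamilyCatalog,
    alpha: float = DEFAULT_ALPHA,
    threshold_on: str = "adjusted",
) -> list[EnrichmentResult]:
    """Test every (family, CD) pair with >= 1 co-occurrence.

    The universe is the set of TF proteins (dbd_family set); a protein with
    DBDs of several families is attributed to its primary family so the 2x2
    margins stay consistent.  CDs are counted once per protein.
    ``threshold_on`` selects whether ``enriched`` compares ``alpha`` against
    the adjusted (default) or raw p-value.
    """
    if threshold_on not in ("adjusted", "raw"):
        raise ValueError(f"threshold_on must be 'adjusted' or 'raw'")
    tfs = [a for a in architectures if a.dbd_family is not None]
    n_total = len(tfs)
    fam_sizes: dict[str, int] = defaultdict(int)
    pair_counts: dict[tuple[str, str], int] = defaultdict(int)
    cd_families: dict[str, set[str]] = defaultdict(set)
    cd_totals: dict[str, int] = defaultdict(int)
    for arch in tfs:
        fam = arch.dbd_family
        fam_sizes[fam] += 1
        for cd in arch.cd_models:
            pair_counts[(fam, cd)] += 1
            cd_families[cd].add(fam)
            cd_totals[cd] += 1

    keys = sorted(pair_counts)
    p_raw = []
    tables = []
    for fam, cd in keys:
        a = pair_counts[(fam, cd)]
        b = fam_sizes[fam] - a
        c = cd_totals[cd] - a
        d = n_total - a - b - c
        tables.append((a, b, c, d))
        p_raw.append(fisher_one_tail(a, b, c, d))
    p_adj = bh_adjust(p_raw)

    results = []
    for (fam, cd), (a, b, c, d), pr, pa in zip(keys, tables, p_raw, p_adj):
        p_for_flag = pa if threshold_on == "adjusted" else pr
        results.append(
            EnrichmentResult(
                family=fam,
                cd_model=cd,
                a=a, b=b, c=c, d=d,
                p_raw=pr,
                p_adj=float(pa),
                enriched=bool(p_for_flag <= alpha),
                unique=len(cd_families[cd]) == 1,
            )
        )
    return results


def enriched_cd_sets(
    results: Iterable[EnrichmentResult], families: Sequence[str] | None = None
) -> dict[str, frozenset[str]]:
    """Per-family sets of enriched CD models (empty set when none)."""
    out: dict[str, set[str]] = {}
    if families is not None:
        out = {f: set() for f in families}
    for r in results:
        out.setdefault(r.family, set())
        if r.enriched:
            out[r.family].add(r.cd_model)
    return {f: frozenset(s) for f, s in out.items()}


__all__ = [
    "EnrichmentResult", "fisher_one_tail", "bh_adjust", "enrich_all",
    "enriched_cd_sets", "DEFAULT_ALPHA",
]
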