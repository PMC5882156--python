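"""Companion-domain repertoires and the weighted architecture score.

For a family DBD ``d`` in a genome with ``P_t`` total proteins, of which
``P_d`` carry the DBD, and with ``f_d`` distinct partner domain models
adjacent to the DBD across those proteins:

    IAF(d) = log2(P_t / P_d)        (inverse abundance frequency, bits)
    IV(d)  = 1 / f_d                (inverse variability; 1 when f_d = 0)
    WS     = IAF * IV

WS near 0 marks a promiscuous (architecture-diverse) family; large WS a
monolithic one.  Families are classified by the coefficient of variation
of WS across genomes, and genome sizes are binned with Sturges' rule.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    ARCH_MONODOMAIN,
    ARCH_MULTIDOMAIN,
    ARCH_TWO_DOMAIN,
    FamilyCatalog,
    GenomeRecord,
    ProteinArchitecture,
)

logger = logging.getLogger(__name__)

ADJACENCY_ADJACENT = "adjacent"   # partners = segments flanking the DBD
ADJACENCY_ALL = "all"             # partners = every non-DBD segment

CLASS_HIGHLY_PROMISCUOUS = "highly_promiscuous"
CLASS_INTERMEDIATE = "intermediate"
CLASS_MONOLITHIC = "monolithic"
CLASS_UNDEFINED = "undefined"
CLASS_UNCLASSIFIED = "unclassified"

#: Default CV class boundaries (midpoints of the published interval gaps).
CV_HIGH_MAX = 1.55
CV_INTERMEDIATE_MAX = 3.0

#: Published CV intervals, used by strict mode.
STRICT_INTERVALS = {
    CLASS_HIGHLY_PROMISCUOUS: (0.0, 1.36),
    CLASS_INTERMEDIATE: (1.74, 2.5),
    CLASS_MONOLITHIC: (3.5, 4.5),
}


def iaf(p_t: int, p_d: int) -> float:
    """Inverse abundance frequency, log2(P_t / P_d), in bits."""
    if p_d < 1:
        raise ValueError("P_d must be >= 1 (family absent -> no score row)")
    if p_t < p_d:
        raise ValueError(f"P_t ({p_t}) must be >= P_d ({p_d})")
    return math.log2(p_t / p_d)


def iv(f_d: int) -> float:
    """Inverse variability, 1/f_d; a partner-less DBD (f_d = 0) scores 1."""
    if f_d < 0:
        raise ValueError("f_d must be >= 0")
    if f_d == 0:
        return 1.0
    return 1.0 / f_d


def ws(iaf_value: float, iv_value: float) -> float:
    """Weighted architecture score; values near 0 indicate promiscuity."""
    return iaf_value * iv_value


@dataclass(frozen=True)
class CdExtraction:
    """Companion-domain repertoire of one family.

    ``partners_by_genome`` holds, per genome, the distinct partner models
    (adjacent or all non-DBD, per mode); ``global_cds`` every non-DBD model
    on the family's proteins anywhere; ``adjacency_counts`` occurrence
    counts of each partner model (one per protein).  Multi-family proteins
    are excluded throughout.
    """

    family: str
    mode: str
    partners_by_genome: dict[str, frozenset[str]]
    global_cds: frozenset[str]
    adjacency_counts: Counter

    def f_d(self, genome_id: str) -> int:
        return len(self.partners_by_genome.get(genome_id, frozenset()))


def _dbd_indices(arch: ProteinArchitecture, family: str) -> list[int]:
    return [
        i for i, seg in enumerate(arch.segments) if seg.family_id == family
    ]


def extract_cds(
    architectures: Iterable[ProteinArchitecture],
    family: str,
    mode: str = ADJACENCY_ADJACENT,
) -> CdExtraction:
    """Collect the family's companion domains per genome and globally.

    In ``adjacent`` mode a protein contributes the segments immediately
    before and after each of its DBD segments; in ``all`` mode every
    non-DBD segment counts as a partner.  ``f_d`` for a genome is the size
    of the union over that genome's family members.
    """
    if mode not in (ADJACENCY_ADJACENT, ADJACENCY_ALL):
        raise ValueError(f"unknown adjacency mode {mode!r}")
    partners: dict[str, set[str]] = {}
    global_cds: set[str] = set()
    adjacency_counts: Counter = Counter()
    for arch in architectures:
        if family not in arch.all_families or arch.is_multi_family:
            continue
        idxs = _dbd_indices(arch, family)
        if not idxs:
            continue
        if mode == ADJACENCY_ALL:
            protein_partners = {
                seg.model_id
                for i, seg in enumerate(arch.segments)
                if i not in idxs and seg.family_id is None
            }
        else:
            protein_partners = set()
            for i in idxs:
                for j in (i - 1, i + 1):
                    if 0 <= j < len(arch.segments) and j not in idxs:
                        seg = arch.segments[j]
                        if seg.family_id is None:
                            protein_partners.add(seg.model_id)
        partners.setdefault(arch.genome_id, set()).update(protein_partners)
        adjacency_counts.update(protein_partners)
        global_cds.update(
            seg.model_id
            for i, seg in enumerate(arch.segments)
            if i not in idxs and seg.family_id is None
        )
    return CdExtraction(
        family=family,
        mode=mode,
        partners_by_genome={g: frozenset(s) for g, s in partners.items()},
        global_cds=frozenset(global_cds),
        adjacency_counts=adjacency_counts,
    )


def compute_scores(
    architectures: Sequence[ProteinArchitecture],
    genomes: Sequence[GenomeRecord],
    catalog: FamilyCatalog,
    mode: str = ADJACENCY_ADJACENT,
) -> pd.DataFrame:
    """Per-family, per-genome score table (P_t, P_d, f_d, IAF, IV, WS).

    P_t is the genome's ORF count from metadata; P_d the number of proteins
    carrying the family DBD (multi-family proteins included, matching the
    census); f_d comes from :func:`extract_cds`.  Genomes where the family
    is absent emit no row.
    """
    orfs = {g.genome_id: g.n_orfs for g in genomes}
    p_d: dict[tuple[str, str], int] = Counter()
    for arch in architectures:
        for fam in arch.all_families:
            p_d[(fam, arch.genome_id)] += 1

    rows = []
    for fam in catalog.families:
        extraction = extract_cds(architectures, fam, mode=mode)
        for g in genomes:
            pd_count = p_d.get((fam, g.genome_id), 0)
            if pd_count == 0:
                continue
            p_t = orfs[g.genome_id]
            if pd_count > p_t:
                logger.warning(
                    "family %s in %s: P_d %d > P_t %d; clamping",
                    fam, g.genome_id, pd_count, p_t,
                )
                pd_count = p_t
            f_d = extraction.f_d(g.genome_id)
            iaf_v = iaf(p_t, pd_count)
            iv_v = iv(f_d)
            rows.append(
                {
                    "family": fam,
                    "genome_id": g.genome_id,
                    "P_t": p_t,
                    "P_d": pd_count,
                    "f_d": f_d,
                    "IAF": iaf_v,
                    "IV": iv_v,
                    "WS": ws(iaf_v, iv_v),
                }
            )
    return pd.DataFrame(
        rows, columns=["family", "genome_id", "P_t", "P_d", "f_d", "IAF", "IV", "WS"]
    )


def ws_vector(
    scores: pd.DataFrame,
    family: str,
    genomes: Sequence[GenomeRecord],
    include_absent: bool = True,
) -> np.ndarray:
    """WS values of one family over all genomes.

    With ``include_absent`` (default) genomes lacking the family contribute
    WS = 0, mirroring a per-genome score table with one column per family;
    otherwise only genomes with a score row are returned.
    """
    sub = scores[scores["family"] == family]
    by_genome = dict(zip(sub["genome_id"], sub["WS"]))
    if include_absent:
        return np.array([by_genome.get(g.genome_id, 0.0) for g in genomes])
    return np.array([by_genome[g.genome_id] for g in genomes if g.genome_id in by_genome])


# ---------------------------------------------------------------------------
# Genome-size binning (Sturges)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinningScheme:
    """Equal-width genome-size windows from Sturges' rule.

    k = round(1 + log2(N)) classes of width c = (max - min)/k; bins are
    left-closed right-open, the last bin closed.
    """

    k: int
    n: int
    c: float
    r: float
    edges: tuple[float, ...]

    def assign(self, value: float) -> int:
        """0-based bin index for a value inside the range."""
        lo, hi = self.edges[0], self.edges[-1]
        if not lo <= value <= hi:
            raise ValueError(f"{value} outside binned range [{lo}, {hi}]")
        if value == hi:
            return self.k - 1
        return min(int((value - lo) // self.c), self.k - 1)


def sturges_k(n: int) -> int:
    """Number of classes, 1 + log2(N), rounded to the nearest integer."""
    if n < 2:
        raise ValueError("need >= 2 data points")
    return int(round(1 + math.log2(n)))


def bin_genomes(n_orfs: Sequence[float]) -> BinningScheme:
    """Bin genome sizes into Sturges windows; zero range is an error."""
    a = np.asarray(n_orfs, dtype=float)
    k = sturges_k(a.size)
    lo, hi = float(a.min()), float(a.max())
    r = hi - lo
    if r == 0:
        raise ValueError("all genome sizes equal: zero range")
    c = r / k
    edges = tuple(lo + i * c for i in range(k)) + (hi,)
    return BinningScheme(k=k, n=int(a.size), c=c, r=r, edges=edges)


# ---------------------------------------------------------------------------
# CV classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromiscuityClass:
    family: str
    cv: float
    label: str
    n_distinct_cds: int = 0


def classify_cv(cv: float, strict: bool = False) -> str:
    if math.isnan(cv):
        return CLASS_UNDEFINED
    if strict:
        for label, (lo, hi) in STRICT_INTERVALS.items():
            if lo <= cv <= hi:
                return label
        return CLASS_UNCLASSIFIED
    if cv < CV_HIGH_MAX:
        return CLASS_HIGHLY_PROMISCUOUS
    if cv < CV_INTERMEDIATE_MAX:
        return CLASS_INTERMEDIATE
    return CLASS_MONOLITHIC


def classify_promiscuity(
    ws_values: Sequence[float],
    family: str = "",
    strict: bool = False,
    n_distinct_cds: int = 0,
) -> PromiscuityClass:
    """CV = sample sd / mean of the family's WS values, then class label.

    A zero mean leaves CV undefined (label ``undefined``).
    """
    a = np.asarray(ws_values, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 WS values")
    mean = float(a.mean())
    if mean == 0.0:
        return PromiscuityClass(family, float("nan"), CLASS_UNDEFINED, n_distinct_cds)
    cv = float(a.std(ddof=1)) / mean
    return PromiscuityClass(family, cv, classify_cv(cv, strict=strict), n_distinct_cds)


# ---------------------------------------------------------------------------
# Census and sharing
# ---------------------------------------------------------------------------

def architecture_census(
    architectures: Iterable[ProteinArchitecture],
) -> tuple[float, float, float]:
    """Fractions of monodomain / two-domain / multidomain TFs (sum = 1)."""
    counts = Counter(
        a.arch_class for a in architectures if a.dbd_family is not None
    )
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no TF architectures to census")
    return (
        counts[ARCH_MONODOMAIN] / total,
        counts[ARCH_TWO_DOMAIN] / total,
        counts[ARCH_MULTIDOMAIN] / total,
    )


def cd_sharing(enriched_cds: Mapping[str, frozenset[str] | set[str]]) -> pd.DataFrame:
    """Directed sharing matrix S[a, b] = |E_a & E_b| / |E_a|.

    Families with no enriched CDs get a NaN (null) row; the diagonal is 1
    wherever E_a is non-empty.
    """
    fams = list(enriched_cds)
    s = pd.DataFrame(np.nan, index=fams, columns=fams, dtype=float)
    for fa in fams:
        ea = set(enriched_cds[fa])
        if not ea:
            continue
        for fb in fams:
            s.loc[fa, fb] = len(ea & set(enriched_cds[fb])) / len(ea)
    return s


__all__ = [
    "iaf", "iv", "ws",
    "CdExtraction", "extract_cds", "compute_scores", "ws_vector",
    "BinningScheme", "sturges_k", "bin_genomes",
    "PromiscuityClass", "classify_cv", "classify_promiscuity",
    "architecture_census", "cd_sharing",
    "ADJACENCY_ADJACENT", "ADJACENCY_ALL",
    "CLASS_HIGHLY_PROMISCUOUS", "CLASS_INTERMEDIATE", "CLASS_MONOLITHIC",
    "CLASS_UNDEFINED", "CLASS_UNCLASSIFIED",
    "CV_HIGH_MAX", "CV_INTERMEDIATE_MAX", "STRICT_INTERVALS",
]
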