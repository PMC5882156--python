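"""Family census, normalized abundance profiles and genome-size correlation.

Abundance of a family in a genome is the number of proteins with at least
one DBD hit of that family.  Profiles are z-normalized per family across
genomes (A_n = (A_i - A_avg) / A_sdv, sample sd), and the Pearson
correlation of abundance with genome size (in ORFs) is classified as
strong (R >= 0.70), intermediate, or low (R < 0.20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import FamilyCatalog, GenomeRecord, ProteinArchitecture

logger = logging.getLogger(__name__)

R_STRONG = 0.70
R_LOW = 0.20

CLASS_STRONG = "strong"
CLASS_INTERMEDIATE = "intermediate"
CLASS_LOW = "low"
CLASS_UNDEFINED = "undefined"


@dataclass(frozen=True)
class AbundanceProfile:
    """Normalized abundance of one family across genomes."""

    family: str
    values: np.ndarray          # A_n per genome
    a_avg: float
    a_sdv: float
    degenerate: bool = False    # zero-variance input; values are all zeros


@dataclass(frozen=True)
class CorrelationClass:
    family: str
    r: float
    label: str


def count_families(
    architectures: Iterable[ProteinArchitecture],
    catalog: FamilyCatalog,
    genomes: Sequence[GenomeRecord],
) -> pd.DataFrame:
    """Build the family x genome abundance matrix A.

    A[f, g] counts proteins of genome g carrying >= 1 DBD segment of family
    f; a protein with repeated DBD segments of one family counts once, a
    protein with DBDs of several families counts once per family.  Genomes
    without architecture rows get a zero column.
    """
    families = catalog.families
    genome_ids = [g.genome_id for g in genomes]
    counts = pd.DataFrame(0, index=families, columns=genome_ids, dtype=int)
    for arch in architectures:
        if not arch.all_families:
            continue
        if arch.genome_id not in counts.columns:
            logger.warning(
                "protein %s in genome %s absent from metadata; skipped",
                arch.protein_id, arch.genome_id,
            )
            continue
        for fam in arch.all_families:
            counts.loc[fam, arch.genome_id] += 1
    return counts


def normalize_profile(counts_row: Sequence[float], family: str = "") -> AbundanceProfile:
    """z-normalize one family's counts across genomes (sample sd, n-1).

    A zero-variance row yields all zeros with ``degenerate=True`` so
    downstream clustering never sees NaNs.
    """
    a = np.asarray(counts_row, dtype=float)
    if a.size < 2:
        raise ValueError("profile needs >= 2 genomes")
    a_avg = float(a.mean())
    a_sdv = float(a.std(ddof=1))
    if a_sdv == 0.0:
        return AbundanceProfile(family, np.zeros_like(a), a_avg, 0.0, degenerate=True)
    return AbundanceProfile(family, (a - a_avg) / a_sdv, a_avg, a_sdv)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def classify_r(r: float) -> str:
    if np.isnan(r):
        return CLASS_UNDEFINED
    if r >= R_STRONG:
        return CLASS_STRONG
    if r < R_LOW:
        return CLASS_LOW
    return CLASS_INTERMEDIATE


def correlate_size(
    counts: Sequence[float], n_orfs: Sequence[float], family: str = ""
) -> CorrelationClass:
    """Pearson correlation of family abundance with genome size.

    Works identically on raw counts or the normalized profile (the linear
    transform leaves R unchanged when A_sdv > 0).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need >= 3 genomes for a correlation")
    r = pearson_r(counts, n_orfs)
    return CorrelationClass(family, r, classify_r(r))


def family_share(count: int, grand_total: int) -> float:
    """Percentage of the full TF dataset in one family (or family group)."""
    if grand_total <= 0:
        raise ValueError("grand_total must be > 0")
    return 100.0 * count / grand_total


def per_genome_mean(count_total: int, n_genomes: int) -> float:
    """Mean family members per genome."""
    if n_genomes <= 0:
        raise ValueError("n_genomes must be > 0")
    return count_total / n_genomes


def abundance_groups(
    per_genome_means: Mapping[str, float], mode: str = "fixed"
) -> dict[str, int]:
    """Partition families into the four published abundance groups.

    ``mode="fixed"`` returns the published memberships (requires the 19
    canonical family names).  ``mode="rank"`` sorts families by mean and
    cuts at the three largest gaps, which suits synthetic data; with all
    means equal a single group is returned.
    """
    from . import refdata

    if mode == "fixed":
        missing = [f for f in per_genome_means if all(
            f not in members for members in refdata.ABUNDANCE_GROUPS.values()
        )]
        if missing:
            raise ValueError(f"families not in the fixed grouping: {missing}")
        out: dict[str, int] = {}
        for fam in per_genome_means:
            for gid, members in refdata.ABUNDANCE_GROUPS.items():
                if fam in members:
                    out[fam] = gid
        return out

    if mode != "rank":
        raise ValueError(f"unknown mode {mode!r}")
    fams = sorted(per_genome_means, key=lambda f: (-per_genome_means[f], f))
    means = [per_genome_means[f] for f in fams]
    if len(set(means)) == 1:
        logger.warning("all per-genome means equal; single group (tie)")
        return {f: 1 for f in fams}
    gaps = [(means[i] - means[i + 1], i) for i in range(len(means) - 1)]
    n_cuts = min(3, sum(1 for g, _ in gaps if g > 0))
    cut_idx = sorted(i for _, i in sorted(gaps, key=lambda t: (-t[0], t[1]))[:n_cuts])
    out = {}
    group = 1
    for i, fam in enumerate(fams):
        out[fam] = group
        if i in cut_idx:
            group += 1
    return out


def family_summary(
    counts: pd.DataFrame, genomes: Sequence[GenomeRecord]
) -> pd.DataFrame:
    """Per-family summary: total, share %, per-genome mean, Pearson R, class."""
    n_orfs = np.array([g.n_orfs for g in genomes], dtype=float)
    grand_total = int(counts.to_numpy().sum())
    rows = []
    for fam in counts.index:
        row = counts.loc[fam].to_numpy(dtype=float)
        total = int(row.sum())
        r = pearson_r(row, n_orfs) if row.size >= 3 else float("nan")
        rows.append(
            {
                "family": fam,
                "total": total,
                "share_pct": family_share(total, grand_total) if grand_total else 0.0,
                "per_genome_mean": per_genome_mean(total, len(genomes)),
                "pearson_r": r,
                "r_class": classify_r(r),
            }
        )
    return pd.DataFrame(rows).set_index("family")


__all__ = [
    "AbundanceProfile", "CorrelationClass",
    "count_families", "normalize_profile", "pearson_r", "classify_r",
    "correlate_size", "family_share", "per_genome_mean",
    "abundance_groups", "family_summary",
    "R_STRONG", "R_LOW",
    "CLASS_STRONG", "CLASS_INTERMEDIATE", "CLASS_LOW", "CLASS_UNDEFINED",
]
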