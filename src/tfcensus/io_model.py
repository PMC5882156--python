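"""Domain types, assignment-table I/O and hit filtering.

The on-disk dialect is a tab-separated table, one row per structural-domain
hit, one file per genome, with columns::

    genome_id  protein_id  model_id  position  e_value  model_description
    family_e_value  family_id  coverage  pdb_ref

``position`` encodes 1-based inclusive amino-acid coordinates as
``"start-end"``; optional fields use ``NA``.  Two thresholds from the source
protocol apply: family (DBD) hits are kept at family E-value <= 1e-4 with
>= 60% model coverage, superfamily (companion-domain candidate) hits at
E-value <= 1e-3.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Closed lifestyle vocabulary.
LIFESTYLES: tuple[str, ...] = (
    "free-living", "pathogen", "extremophile", "intracellular",
)

ARCH_MONODOMAIN = "monodomain"
ARCH_TWO_DOMAIN = "two-domain"
ARCH_MULTIDOMAIN = "multidomain"

#: Default thresholds.
DBD_E_MAX = 1e-4
DBD_MIN_COVERAGE = 0.60
SUPERFAM_E_MAX = 1e-3

_COLUMNS = (
    "genome_id", "protein_id", "model_id", "position", "e_value",
    "model_description", "family_e_value", "family_id", "coverage", "pdb_ref",
)

_NA = "NA"


@dataclass(frozen=True)
class DomainHit:
    """One structural-domain model assignment on a protein.

    Coordinates are 1-based inclusive amino-acid positions.  ``family_id``
    is set only when the hit is a DNA-binding domain matched by a
    family-specific profile; such hits also carry ``family_e_value`` and,
    when available, the fraction of the model length covered.
    """

    genome_id: str
    protein_id: str
    model_id: str
    start: int
    end: int
    e_value: float
    model_description: str = ""
    family_id: str | None = None
    family_e_value: float | None = None
    coverage: float | None = None
    pdb_ref: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"hit {self.protein_id}/{self.model_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if self.family_e_value is not None and self.family_e_value < 0:
            raise ValueError("family_e_value must be >= 0")
        if self.coverage is not None and not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"coverage must be in [0, 1], got {self.coverage}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_family_hit(self) -> bool:
        return self.family_id is not None


@dataclass(frozen=True)
class GenomeRecord:
    """Genome metadata: size in ORFs and lifestyle class."""

    genome_id: str
    organism_name: str
    n_orfs: int
    lifestyle: str

    def __post_init__(self) -> None:
        if self.n_orfs < 1:
            raise ValueError(f"n_orfs must be >= 1, got {self.n_orfs}")
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(
                f"genome {self.genome_id}: unknown lifestyle {self.lifestyle!r}; "
                f"expected one of {LIFESTYLES}"
            )


class FamilyCatalog:
    """Mapping of TF family names to their DBD model identifiers.

    Every DBD model id belongs to exactly one family.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, frozenset[str]] = {
            fam: frozenset(models) for fam, models in entries.items()
        }
        self._model_to_family: dict[str, str] = {}
        for fam, models in self.entries.items():
            for m in models:
                if m in self._model_to_family:
                    raise ValueError(
                        f"DBD model {m!r} mapped to both "
                        f"{self._model_to_family[m]!r} and {fam!r}"
                    )
                self._model_to_family[m] = fam

    @property
    def families(self) -> list[str]:
        return list(self.entries)

    @property
    def dbd_models(self) -> frozenset[str]:
        return frozenset(self._model_to_family)

    def family_of(self, model_id: str) -> str | None:
        return self._model_to_family.get(model_id)

    def __contains__(self, family: str) -> bool:
        return family in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyCatalog":
        """Read a two-column (family, model_id) TSV, optional header."""
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"family catalog not found: {path}")
        entries: dict[str, set[str]] = defaultdict(set)
        with path.open(encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if row[0] == "family" and row[1] == "model_id":
                    continue
                entries[row[0]].add(row[1])
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            fh.write("family\tmodel_id\n")
            for fam in sorted(self.entries):
                for model in sorted(self.entries[fam]):
                    fh.write(f"{fam}\t{model}\n")


@dataclass(frozen=True)
class ProteinArchitecture:
    """Ordered, overlap-resolved domain string of one protein.

    ``dbd_family`` is the primary family (lowest family E-value) when the
    protein carries family DBD hits; ``all_families`` lists every distinct
    family present (rarely more than one).  ``cd_models`` are the model ids
    of the non-DBD segments.
    """

    protein_id: str
    genome_id: str
    segments: tuple[DomainHit, ...]
    dbd_family: str | None
    all_families: frozenset[str]
    cd_models: frozenset[str]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"protein {self.protein_id}: no segments")

    @property
    def n_domains(self) -> int:
        return len(self.segments)

    @property
    def arch_class(self) -> str:
        n = self.n_domains
        if n == 1:
            return ARCH_MONODOMAIN
        if n == 2:
            return ARCH_TWO_DOMAIN
        return ARCH_MULTIDOMAIN

    @property
    def is_multi_family(self) -> bool:
        return len(self.all_families) > 1

    @property
    def arch_string(self) -> str:
        return "+".join(seg.model_id for seg in self.segments)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _fmt_opt(value) -> str:
    if value is None:
        return _NA
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_opt_float(text: str) -> float | None:
    if text == _NA or text == "":
        return None
    return float(text)


def read_assignment_file(path: str | Path, genome_id: str | None = None) -> list[DomainHit]:
    """Read one per-genome domain-assignment table.

    Rows with unparseable coordinates or E-values are rejected; their count
    is logged.  A missing file raises :class:`FileNotFoundError` naming the
    path; a file with zero parseable rows returns an empty list with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"assignment file not found: {path}")
    hits: list[DomainHit] = []
    n_rejected = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "genome_id":  # header
                continue
            try:
                rec = dict(zip(_COLUMNS, row))
                start_s, _, end_s = rec["position"].partition("-")
                hit = DomainHit(
                    genome_id=genome_id or rec["genome_id"],
                    protein_id=rec["protein_id"],
                    model_id=rec["model_id"],
                    start=int(start_s),
                    end=int(end_s),
                    e_value=float(rec["e_value"]),
                    model_description=rec.get("model_description", ""),
                    family_e_value=_parse_opt_float(rec.get("family_e_value", _NA)),
                    family_id=None if rec.get("family_id", _NA) in (_NA, "") else rec["family_id"],
                    coverage=_parse_opt_float(rec.get("coverage", _NA)),
                    pdb_ref=None if rec.get("pdb_ref", _NA) in (_NA, "") else rec["pdb_ref"],
                )
            except (KeyError, ValueError) as exc:
                n_rejected += 1
                logger.debug("rejected row %d of %s: %s", lineno, path, exc)
                continue
            hits.append(hit)
    if n_rejected:
        logger.warning("%s: rejected %d unparseable row(s)", path, n_rejected)
    if not hits:
        logger.warning("%s: zero parseable rows", path)
    return hits


def write_assignment_file(path: str | Path, hits: Sequence[DomainHit]) -> None:
    """Write hits in the canonical tab-separated dialect (round-trip safe)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.genome_id,
                        h.protein_id,
                        h.model_id,
                        f"{h.start}-{h.end}",
                        repr(h.e_value),
                        h.model_description,
                        _fmt_opt(h.family_e_value),
                        _fmt_opt(h.family_id),
                        _fmt_opt(h.coverage),
                        _fmt_opt(h.pdb_ref),
                    )
                )
                + "\n"
            )


def read_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read the genome metadata TSV (genome_id, organism, n_orfs, lifestyle)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    records: list[GenomeRecord] = []
    with path.open(encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "genome_id":
                continue
            records.append(
                GenomeRecord(
                    genome_id=row[0],
                    organism_name=row[1],
                    n_orfs=int(row[2]),
                    lifestyle=row[3],
                )
            )
    return records


def write_metadata(path: str | Path, records: Sequence[GenomeRecord]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("genome_id\torganism\tn_orfs\tlifestyle\n")
        for r in records:
            fh.write(f"{r.genome_id}\t{r.organism_name}\t{r.n_orfs}\t{r.lifestyle}\n")


def write_architectures_tsv(path: str | Path, archs: Sequence[ProteinArchitecture]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("protein_id\tgenome_id\tarchitecture\tdbd_family\tarch_class\n")
        for a in archs:
            fh.write(
                f"{a.protein_id}\t{a.genome_id}\t{a.arch_string}\t"
                f"{_fmt_opt(a.dbd_family)}\t{a.arch_class}\n"
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_dbd_hits(
    hits: Iterable[DomainHit],
    e_max: float = DBD_E_MAX,
    min_coverage: float = DBD_MIN_COVERAGE,
) -> list[DomainHit]:
    """Apply the family-profile thresholds to DBD hits.

    Keeps family hits with ``family_e_value <= e_max`` and
    ``coverage >= min_coverage``.  Hits without a ``family_id`` pass through
    unchanged (candidate companion domains, filtered separately).  When a hit
    lacks a coverage value the coverage criterion is skipped with a warning.
    """
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    if not 0.0 <= min_coverage <= 1.0:
        raise ValueError("min_coverage must be in [0, 1]")
    kept: list[DomainHit] = []
    warned_no_cov = False
    for h in hits:
        if not h.is_family_hit:
            kept.append(h)
            continue
        fe = h.family_e_value if h.family_e_value is not None else h.e_value
        if fe > e_max:
            continue
        if h.coverage is None:
            if not warned_no_cov:
                logger.warning(
                    "hits lack a coverage value; coverage filter skipped"
                )
                warned_no_cov = True
        elif h.coverage < min_coverage:
            continue
        kept.append(h)
    return kept


def filter_superfam_hits(
    hits: Iterable[DomainHit], e_max: float = SUPERFAM_E_MAX
) -> list[DomainHit]:
    """Keep non-family hits with ``e_value <= e_max``; family hits pass through."""
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    return [h for h in hits if h.is_family_hit or h.e_value <= e_max]


def filter_hits(
    hits: Iterable[DomainHit],
    dbd_e_max: float = DBD_E_MAX,
    dbd_min_coverage: float = DBD_MIN_COVERAGE,
    sf_e_max: float = SUPERFAM_E_MAX,
) -> list[DomainHit]:
    """Compose both threshold filters (order-independent, idempotent)."""
    return filter_superfam_hits(
        filter_dbd_hits(hits, dbd_e_max, dbd_min_coverage), sf_e_max
    )


# ---------------------------------------------------------------------------
# Architecture assembly
# ---------------------------------------------------------------------------

def _overlap_frac_of_shorter(a: DomainHit, b: DomainHit) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return ov / min(a.length, b.length)


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Best-hit-wins overlap resolution on one protein.

    When two hits overlap by more than 50% of the shorter one, the hit with
    the smaller E-value wins; ties break on smaller start, then lexicographic
    model_id.  Returns survivors sorted by start.
    """
    ranked = sorted(hits, key=lambda h: (h.e_value, h.start, h.model_id))
    accepted: list[DomainHit] = []
    for h in ranked:
        if all(_overlap_frac_of_shorter(h, kept) <= 0.5 for kept in accepted):
            accepted.append(h)
    return sorted(accepted, key=lambda h: (h.start, h.end, h.model_id))


def assemble_architectures(
    hits: Iterable[DomainHit], catalog: FamilyCatalog
) -> list[ProteinArchitecture]:
    """Group filtered hits into per-protein ordered domain architectures.

    Hits are grouped by (genome_id, protein_id), overlap-resolved and sorted
    by start.  ``dbd_family`` is taken from the family hit with the smallest
    family E-value; every distinct family present is recorded in
    ``all_families``.  Family ids absent from the catalog raise.
    """
    by_protein: dict[tuple[str, str], list[DomainHit]] = defaultdict(list)
    for h in hits:
        if h.family_id is not None and h.family_id not in catalog:
            raise ValueError(
                f"hit {h.protein_id}/{h.model_id}: family {h.family_id!r} "
                "not in catalog"
            )
        by_protein[(h.genome_id, h.protein_id)].append(h)

    archs: list[ProteinArchitecture] = []
    for (genome_id, protein_id), protein_hits in by_protein.items():
        segments = resolve_overlaps(protein_hits)
        if not segments:
            logger.warning(
                "protein %s/%s: zero segments after overlap resolution; excluded",
                genome_id, protein_id,
            )
            continue
        family_segs = [s for s in segments if s.family_id is not None]
        all_families = frozenset(s.family_id for s in family_segs)
        dbd_family = None
        if family_segs:
            best = min(
                family_segs,
                key=lambda s: (
                    s.family_e_value if s.family_e_value is not None else s.e_value,
                    s.start,
                ),
            )
            dbd_family = best.family_id
        if len(all_families) > 1:
            logger.info(
                "protein %s/%s carries DBDs of %d families: %s",
                genome_id, protein_id, len(all_families), sorted(all_families),
            )
        dbd_model_ids = {s.model_id for s in family_segs}
        cd_models = frozenset(
            s.model_id for s in segments
            if s.family_id is None and s.model_id not in dbd_model_ids
        )
        archs.append(
            ProteinArchitecture(
                protein_id=protein_id,
                genome_id=genome_id,
                segments=tuple(segments),
                dbd_family=dbd_family,
                all_families=all_families,
                cd_models=cd_models,
            )
        )
    return archs


__all__ = [
    "DomainHit", "GenomeRecord", "FamilyCatalog", "ProteinArchitecture",
    "LIFESTYLES", "ARCH_MONODOMAIN", "ARCH_TWO_DOMAIN", "ARCH_MULTIDOMAIN",
    "DBD_E_MAX", "DBD_MIN_COVERAGE", "SUPERFAM_E_MAX",
    "read_assignment_file", "write_assignment_file",
    "read_metadata", "write_metadata", "write_architectures_tsv",
    "filter_dbd_hits", "filter_superfam_hits", "filter_hits",
    "resolve_overlaps", "assemble_architectures",
]
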