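"""Family-centric data model for whole-genome-duplication retention analysis.

A *gene family* is the set of genes descending, by duplication and
speciation, from a single pre-1R/2R ancestral deuterostome gene.  Families
pass through up to four nested rounds of whole-genome duplication (WGD):
the two basal vertebrate rounds (here ``VGD1``/``VGD2``, jointly the 1R/2R
era), the teleost-specific third round (``TSGD``, a.k.a. Ts3R) and the
salmonid-specific fourth round (``SSGD``, a.k.a. Ss4R).  At each WGD every
surviving gene lineage either keeps its duplicate (retained) or loses one
copy (lost); those outcomes are the :class:`RetentionEvent` rows consumed
by the :mod:`ohnoretain.retention` statistics.

Families are *pigmentation gene-containing families* (PGCFs): they hold at
least one pigmentation gene (PG), i.e. a gene involved in the
differentiation of a neural-crest derived pigment cell, possibly alongside
paralogs with no documented pigmentary function.  A family retaining
exactly one gene after the 1R/2R era is *monogenic*, otherwise
*multigenic*.

Input tables are plain TSV; see :func:`ingest_gene_table` and
:func:`ingest_event_table` for the dialects.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

MONOGENIC = "monogenic"
MULTIGENIC = "multigenic"

#: Allowed functional-category labels for pigmentation genes.  The
#: classification follows the standard functional grouping of the
#: vertebrate pigmentation repertoire by pigment-cell type and molecular
#: role; a gene may additionally belong to several subcategories.
FUNCTIONAL_CATEGORIES = frozenset(
    {
        "pigment-cell-differentiation",
        "melanocyte-differentiation",
        "melanosome-biogenesis",
        "melanin-synthesis",
        "melanosome-transport",
        "xanthophore-differentiation",
        "pteridine-synthesis",
        "iridophore-differentiation",
        "leucophore-differentiation",
        "patterning",
        "other",
    }
)

GENE_COLUMNS = (
    "gene_id",
    "family_id",
    "is_pg",
    "functional_category",
    "subcategories",
    "interaction_count",
    "salmonid_present",
)
REQUIRED_GENE_COLUMNS = ("gene_id", "family_id", "is_pg")
EVENT_COLUMNS = ("family_id", "lineage_id", "event", "retained", "prior_retained")


class IngestError(ValueError):
    """An input table (or programmatically built record) violates the model."""


class WGDEvent(str, enum.Enum):
    """The four WGD events, ordered by era.

    ``VGD1``/``VGD2`` are the two basal vertebrate rounds (1R/2R); their
    effects cannot be separated in practice, so analyses pool them into one
    compound era while the model keeps them mechanistically distinct.
    ``TSGD`` is the teleost-specific round (Ts3R) and ``SSGD`` the
    salmonid-specific round (Ss4R), which only applies to lineages with
    salmonid representation.
    """

    VGD1 = "VGD1"
    VGD2 = "VGD2"
    TSGD = "TSGD"
    SSGD = "SSGD"

    @property
    def era_order(self) -> int:
        return _ERA_ORDER[self]

    @property
    def lineage_scope(self) -> str:
        return _LINEAGE_SCOPE[self]

    @classmethod
    def from_label(cls, label: str) -> "WGDEvent":
        try:
            return cls(str(label).strip())
        except ValueError:
            raise IngestError(
                f"unknown WGD event label {label!r}; expected one of "
                f"{sorted(e.value for e in cls)}"
            ) from None


_ERA_ORDER = {WGDEvent.VGD1: 1, WGDEvent.VGD2: 2, WGDEvent.TSGD: 3, WGDEvent.SSGD: 4}
_LINEAGE_SCOPE = {
    WGDEvent.VGD1: "vertebrates",
    WGDEvent.VGD2: "vertebrates",
    WGDEvent.TSGD: "teleosts",
    WGDEvent.SSGD: "salmonids",
}

#: The compound 1R/2R era.
VGD_ERA = (WGDEvent.VGD1, WGDEvent.VGD2)


@dataclass(frozen=True)
class GeneRecord:
    """One gene retained after the 1R/2R era.

    ``functional_category`` is the primary functional label and is only
    meaningful for pigmentation genes; ``subcategories`` records
    multi-membership.  ``salmonid_present`` flags whether the gene lineage
    has salmonid representation and is therefore in scope for SSGD.
    """

    gene_id: str
    family_id: str
    is_pg: bool
    functional_category: str | None = None
    subcategories: frozenset = frozenset()
    interaction_count: int | None = None
    salmonid_present: bool = True

    def __post_init__(self) -> None:
        if self.functional_category is not None:
            if not self.is_pg:
                raise IngestError(
                    f"gene {self.gene_id!r}: functional_category is only valid "
                    "for pigmentation genes"
                )
            _check_category(self.functional_category, self.gene_id)
        for sub in self.subcategories:
            _check_category(sub, self.gene_id)
        if self.interaction_count is not None and self.interaction_count < 0:
            raise IngestError(
                f"gene {self.gene_id!r}: interaction_count must be >= 0"
            )


def _check_category(label: str, gene_id: str) -> None:
    if label not in FUNCTIONAL_CATEGORIES:
        raise IngestError(
            f"gene {gene_id!r}: unknown functional_category {label!r}; "
            f"allowed labels: {sorted(FUNCTIONAL_CATEGORIES)}"
        )


@dataclass(frozen=True)
class RetentionEvent:
    """One duplication opportunity: a gene lineage at one WGD event.

    ``retained`` is True when both post-WGD copies were kept.
    ``carries_pg`` says whether the lineage contains or leads to a
    pigmentation gene; ``post_1r2r_class`` is the family's
    monogenic/multigenic status; ``prior_retained`` is the outcome of the
    same lineage at the immediately preceding WGD (None when unknown).
    """

    family_id: str
    lineage_id: str
    event: WGDEvent
    retained: bool
    carries_pg: bool = True
    post_1r2r_class: str | None = None
    prior_retained: bool | None = None

    def __post_init__(self) -> None:
        if self.post_1r2r_class not in (None, MONOGENIC, MULTIGENIC):
            raise IngestError(
                f"event {self.family_id}/{self.lineage_id}/{self.event.value}: "
                f"invalid post_1r2r_class {self.post_1r2r_class!r}"
            )


@dataclass(frozen=True)
class FamilySummary:
    """Per-family copy counts after 1R/2R and the compound-era retention rate.

    ``vgd_rr`` is the node-averaged 1R/2R retention rate (see
    :func:`ohnoretain.retention.compound_vgd_rate`), or None when the
    family's VGD-era events are unavailable.
    """

    family_id: str
    n_post_1r2r: int
    copy_class: str
    n_pg: int
    n_nonpg: int
    vgd_rr: object | None = None  # fractions.Fraction when available

    def __post_init__(self) -> None:
        if self.n_post_1r2r < 1:
            raise IngestError(f"family {self.family_id!r}: must retain >= 1 gene")
        expected = MULTIGENIC if self.n_post_1r2r >= 2 else MONOGENIC
        if self.copy_class != expected:
            raise IngestError(
                f"family {self.family_id!r}: copy_class {self.copy_class!r} "
                f"inconsistent with n_post_1r2r={self.n_post_1r2r}"
            )
        if self.n_pg + self.n_nonpg != self.n_post_1r2r:
            raise IngestError(
                f"family {self.family_id!r}: n_pg + n_nonpg != n_post_1r2r"
            )
        if self.n_pg < 1:
            raise IngestError(
                f"family {self.family_id!r}: a pigmentation gene-containing "
                "family needs at least one PG"
            )


# ---------------------------------------------------------------------------
# parsing helpers

_TRUE = {"1", "true"}
_FALSE = {"0", "false"}


def _parse_bool(raw: str, *, context: str) -> bool:
    token = str(raw).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise IngestError(f"{context}: cannot parse boolean from {raw!r} (use 0/1/true/false)")


def _parse_opt_bool(raw: str, *, context: str) -> bool | None:
    if str(raw).strip() == "":
        return None
    return _parse_bool(raw, context=context)


# ---------------------------------------------------------------------------
# gene table IO


def ingest_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene table into validated :class:`GeneRecord` rows.

    Required columns: ``gene_id``, ``family_id``, ``is_pg``.  Optional:
    ``functional_category``, ``subcategories`` (semicolon-delimited),
    ``interaction_count``, ``salmonid_present`` (default true).  Empty
    strings denote absent optional values.  Duplicate gene ids and unknown
    category labels are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"gene table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REQUIRED_GENE_COLUMNS) - set(df.columns)
    if missing:
        raise IngestError(f"gene table {path}: missing columns {sorted(missing)}")
    dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
    if dups:
        raise IngestError(f"gene table {path}: duplicate gene_id(s) {sorted(set(dups))}")
    genes: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        gid = d["gene_id"].strip()
        ctx = f"gene table {path}, gene {gid!r}"
        cat = d.get("functional_category", "").strip() or None
        subs = frozenset(
            s.strip() for s in d.get("subcategories", "").split(";") if s.strip()
        )
        icount_raw = d.get("interaction_count", "").strip()
        try:
            icount = int(icount_raw) if icount_raw else None
        except ValueError:
            raise IngestError(f"{ctx}: bad interaction_count {icount_raw!r}") from None
        sal_raw = d.get("salmonid_present", "")
        sal = _parse_opt_bool(sal_raw, context=ctx)
        genes.append(
            GeneRecord(
                gene_id=gid,
                family_id=d["family_id"].strip(),
                is_pg=_parse_bool(d["is_pg"], context=ctx),
                functional_category=cat,
                subcategories=subs,
                interaction_count=icount,
                salmonid_present=True if sal is None else sal,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> Path:
    """Write genes as TSV in the canonical column order (lossless round-trip)."""
    path = Path(path)
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "family_id": g.family_id,
                "is_pg": int(g.is_pg),
                "functional_category": g.functional_category or "",
                "subcategories": ";".join(sorted(g.subcategories)),
                "interaction_count": "" if g.interaction_count is None else g.interaction_count,
                "salmonid_present": int(g.salmonid_present),
            }
        )
    pd.DataFrame(rows, columns=list(GENE_COLUMNS)).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# event table IO and annotation


def match_gene(lineage_id: str, family_genes: Sequence[GeneRecord]) -> GeneRecord | None:
    """Resolve the gene a lineage belongs to by longest gene-id prefix match.

    Lineage ids are opaque to the analysis, but descendants of a post-1R/2R
    gene are conventionally named by extending the gene id, which makes the
    gene recoverable without tree reconstruction.
    """
    best: GeneRecord | None = None
    for g in family_genes:
        if lineage_id.startswith(g.gene_id):
            if best is None or len(g.gene_id) > len(best.gene_id):
                best = g
    return best


def annotate_events(
    events: Iterable[RetentionEvent], genes: Sequence[GeneRecord]
) -> list[RetentionEvent]:
    """Validate raw events against the gene table and fill annotations.

    Fills ``carries_pg`` (VGD-era lineages of a PGCF always lead to a PG;
    later eras resolve the lineage's gene by prefix match),
    ``post_1r2r_class`` (from family gene counts) and, when absent,
    ``prior_retained`` (from the unique previous-era event whose lineage id
    prefixes this one).  Hard errors: orphan family ids, duplicated
    (family, lineage, event) keys, SSGD events on non-salmonid lineages,
    post-TSGD lineages that resolve to no gene.
    """
    by_family: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_family[g.family_id].append(g)
    class_of = {
        fam: (MULTIGENIC if len(gs) >= 2 else MONOGENIC) for fam, gs in by_family.items()
    }
    has_pg = {fam: any(g.is_pg for g in gs) for fam, gs in by_family.items()}

    raw = list(events)
    seen: set[tuple[str, str, str]] = set()
    for e in raw:
        key = (e.family_id, e.lineage_id, e.event.value)
        if key in seen:
            raise IngestError(f"duplicate event row {key}")
        seen.add(key)
        if e.family_id not in by_family:
            raise IngestError(
                f"event {e.lineage_id!r}/{e.event.value}: unknown family_id "
                f"{e.family_id!r} (not in gene table)"
            )

    # index per family and era for prior-outcome derivation
    per_fam_era: dict[tuple[str, int], list[RetentionEvent]] = defaultdict(list)
    for e in raw:
        per_fam_era[(e.family_id, e.event.era_order)].append(e)

    out: list[RetentionEvent] = []
    for e in raw:
        fam_genes = by_family[e.family_id]
        if e.event in VGD_ERA:
            carries = has_pg[e.family_id]
            gene = None
        else:
            gene = match_gene(e.lineage_id, fam_genes)
            if gene is None:
                raise IngestError(
                    f"event {e.lineage_id!r}/{e.event.value}: lineage does not "
                    f"resolve to any gene of family {e.family_id!r}"
                )
            carries = gene.is_pg
            if e.event is WGDEvent.SSGD and not gene.salmonid_present:
                raise IngestError(
                    f"SSGD event on lineage {e.lineage_id!r}: gene "
                    f"{gene.gene_id!r} is not flagged salmonid-present"
                )
        prior = e.prior_retained
        if prior is None and e.event.era_order >= 2:
            prior = _derive_prior(e, per_fam_era)
        out.append(
            replace(
                e,
                carries_pg=carries,
                post_1r2r_class=class_of[e.family_id],
                prior_retained=prior,
            )
        )
    return out


def _derive_prior(
    e: RetentionEvent, per_fam_era: Mapping[tuple[str, int], list[RetentionEvent]]
) -> bool | None:
    candidates = [
        c
        for c in per_fam_era.get((e.family_id, e.event.era_order - 1), [])
        if e.lineage_id.startswith(c.lineage_id)
    ]
    if not candidates:
        return None
    best = max(candidates, key=lambda c: len(c.lineage_id))
    return best.retained


def ingest_event_table(
    path: str | Path, genes: Sequence[GeneRecord]
) -> list[RetentionEvent]:
    """Read a TSV retention-event table and annotate it against the genes.

    Columns: ``family_id``, ``lineage_id``, ``event`` (VGD1/VGD2/TSGD/SSGD),
    ``retained`` (0/1) and optionally ``prior_retained`` (0/1/empty; empty
    values are derived from lineage-id prefix linkage where possible).
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"event table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"family_id", "lineage_id", "event", "retained"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"event table {path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        log.warning("event table %s is empty; no retention events ingested", path)
        return []
    raw = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ctx = f"event table {path}, lineage {d['lineage_id']!r}"
        raw.append(
            RetentionEvent(
                family_id=d["family_id"].strip(),
                lineage_id=d["lineage_id"].strip(),
                event=WGDEvent.from_label(d["event"]),
                retained=_parse_bool(d["retained"], context=ctx),
                prior_retained=_parse_opt_bool(d.get("prior_retained", ""), context=ctx),
            )
        )
    return annotate_events(raw, genes)


def write_event_table(events: Iterable[RetentionEvent], path: str | Path) -> Path:
    """Write events as TSV; ``prior_retained`` is emitted explicitly so the
    table round-trips even when linkage is not encoded in lineage ids."""
    path = Path(path)
    rows = []
    for e in events:
        rows.append(
            {
                "family_id": e.family_id,
                "lineage_id": e.lineage_id,
                "event": e.event.value,
                "retained": int(e.retained),
                "prior_retained": "" if e.prior_retained is None else int(e.prior_retained),
            }
        )
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# family classification


def classify_families(
    genes: Sequence[GeneRecord], events: Sequence[RetentionEvent] = ()
) -> list[FamilySummary]:
    """Summarise each family: copy counts, monogenic/multigenic status and,
    when VGD-era events are supplied, the compound 1R/2R retention rate."""
    by_family: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_family[g.family_id].append(g)
    vgd_by_family: dict[str, list[RetentionEvent]] = defaultdict(list)
    for e in events:
        if e.event in VGD_ERA:
            vgd_by_family[e.family_id].append(e)

    summaries = []
    for fam in sorted(by_family):
        gs = by_family[fam]
        n = len(gs)
        n_pg = sum(g.is_pg for g in gs)
        vgd_rr = None
        if vgd_by_family.get(fam):
            from .retention import compound_vgd_rate  # local import avoids a cycle

            vgd_rr = compound_vgd_rate(fam, vgd_by_family[fam])
        summaries.append(
            FamilySummary(
                family_id=fam,
                n_post_1r2r=n,
                copy_class=MULTIGENIC if n >= 2 else MONOGENIC,
                n_pg=n_pg,
                n_nonpg=n - n_pg,
                vgd_rr=vgd_rr,
            )
        )
    return summaries
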