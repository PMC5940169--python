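"""Reference dataset built from the curated pigmentation-family counts.

The curated vertebrate pigmentation dataset comprises 169 pigmentation
gene-containing families with 184 pigmentation genes and 144 non-PG
paralogs (328 genes); 77 families are monogenic and 92 multigenic after
the 1R/2R era.  This module reconstructs gene and retention-event tables
whose stratum counts match the published summary of that dataset exactly
(Ts3R: 63/184 overall PGs, 13/77 monogenic, 50/107 multigenic, 52/140
non-PG; Ss4R: 65/90, 112/153 and 133/186 with the conditional split on
the Ts3R outcome), so the full analysis pipeline can be exercised and
checked without the underlying sequence data.

Only the stratum-level counts are constrained; the assignment of events
to individual synthetic gene ids is an arbitrary but deterministic
convention.  The salmonid-round conditional counts are taken as printed
and are *not* derivable from a single consistent gene tree (see
``SS4R_OVERALL_REPORTED`` and the methods note), which is exactly why the
event table carries an explicit ``prior_retained`` column.
"""

from __future__ import annotations

import json
from itertools import cycle
from pathlib import Path

from .family_model import (
    GeneRecord,
    RetentionEvent,
    WGDEvent,
    annotate_events,
    write_event_table,
    write_gene_table,
)
from .stat_tests import BaselineRange

#: Genome-wide retention ranges from published estimates (fractions).
BASELINES: dict[str, BaselineRange] = {
    "TSGD": BaselineRange("TSGD", 0.04, 0.18, "genome-wide Ts3R retention estimates"),
    "SSGD": BaselineRange("SSGD", 0.48, 0.55, "genome-wide Ss4R retention estimates"),
    "VGD": BaselineRange("VGD", 0.17, 0.345, "genome-wide 1R/2R retention estimates"),
}

#: Externally reported overall Ss4R count.  Inconsistent with the sum of
#: its category cells (65/90 + 112/153 = 177/243); kept as input data so
#: the report can flag the discrepancy instead of adopting either side
#: silently.
SS4R_OVERALL_REPORTED: tuple[int, int] = (182, 242)


def _mono_family(fam: str) -> tuple[list[GeneRecord], list[RetentionEvent]]:
    """One surviving gene: both 1R/2R rounds lost (compound rate 0/2)."""
    genes = [GeneRecord(fam, fam, is_pg=True)]
    events = [
        RetentionEvent(fam, fam, WGDEvent.VGD1, False),
        RetentionEvent(fam, fam, WGDEvent.VGD2, False),
    ]
    return genes, events


def _two_gene_family(fam: str, second_is_pg: bool) -> tuple[list, list]:
    """Two survivors via a kept 1R duplicate and two lost 2R duplicates
    (compound rate 1/3)."""
    genes = [
        GeneRecord(fam + "a", fam, is_pg=True),
        GeneRecord(fam + "b", fam, is_pg=second_is_pg),
    ]
    events = [
        RetentionEvent(fam, fam, WGDEvent.VGD1, True),
        RetentionEvent(fam, fam + "a", WGDEvent.VGD2, False),
        RetentionEvent(fam, fam + "b", WGDEvent.VGD2, False),
    ]
    return genes, events


def _three_gene_family(fam: str) -> tuple[list, list]:
    """Three survivors: 1R kept, one 2R duplicate kept (compound rate 2/3)."""
    genes = [
        GeneRecord(fam + "aa", fam, is_pg=True),
        GeneRecord(fam + "ab", fam, is_pg=False),
        GeneRecord(fam + "b", fam, is_pg=False),
    ]
    events = [
        RetentionEvent(fam, fam, WGDEvent.VGD1, True),
        RetentionEvent(fam, fam + "a", WGDEvent.VGD2, True),
        RetentionEvent(fam, fam + "b", WGDEvent.VGD2, False),
    ]
    return genes, events


def _block(genes, event, n_events, n_retained, prior=None, tag=""):
    """Emit ``n_events`` rows for ``event`` cycling over ``genes``; the
    first ``n_retained`` are retained.  ``tag`` keeps lineage ids unique
    across blocks attached to the same genes."""
    out = []
    gene_cycle = cycle(genes)
    for k in range(n_events):
        g = next(gene_cycle)
        lid = g.gene_id if prior is None and tag == "" else f"{g.gene_id}{tag}{k}"
        out.append(
            RetentionEvent(
                g.family_id,
                lid,
                event,
                retained=k < n_retained,
                prior_retained=prior,
            )
        )
    return out


def curated_dataset() -> tuple[list[GeneRecord], list[RetentionEvent]]:
    """Gene and event tables matching the curated-dataset stratum counts.

    Returns annotated records ready for :func:`ohnoretain.retention.
    build_summary_report`; writing then re-ingesting them is lossless.
    """
    genes: list[GeneRecord] = []
    events: list[RetentionEvent] = []

    # 77 monogenic families, one PG each
    mono_pgs: list[GeneRecord] = []
    for i in range(1, 78):
        gs, evs = _mono_family(f"M{i:03d}")
        genes += gs
        events += evs
        mono_pgs += gs

    # 15 multigenic families carrying two PGs (size 2)
    multi_pgs: list[GeneRecord] = []
    nonpg: list[GeneRecord] = []
    for i in range(1, 16):
        gs, evs = _two_gene_family(f"D{i:03d}", second_is_pg=True)
        genes += gs
        events += evs
        multi_pgs += gs

    # 77 multigenic families with one PG; the first 67 have two non-PG
    # paralogs (size 3), the remainder one (size 2) -> 144 non-PGs total
    for i in range(1, 78):
        fam = f"U{i:03d}"
        if i <= 67:
            gs, evs = _three_gene_family(fam)
        else:
            gs, evs = _two_gene_family(fam, second_is_pg=False)
        genes += gs
        events += evs
        multi_pgs += [g for g in gs if g.is_pg]
        nonpg += [g for g in gs if not g.is_pg]

    assert len(mono_pgs) == 77 and len(multi_pgs) == 107 and len(nonpg) == 144

    # Teleost round (Ts3R): one event per gene with data
    events += _block(mono_pgs, WGDEvent.TSGD, 77, 13)
    events += _block(multi_pgs, WGDEvent.TSGD, 107, 50)
    events += _block(nonpg[:140], WGDEvent.TSGD, 140, 52)

    # Salmonid round (Ss4R): per-salmonid-lineage counting with the
    # conditional split on the Ts3R outcome supplied explicitly
    events += _block(mono_pgs, WGDEvent.SSGD, 64, 46, prior=True, tag="sr")
    events += _block(mono_pgs, WGDEvent.SSGD, 26, 19, prior=False, tag="sl")
    events += _block(multi_pgs, WGDEvent.SSGD, 55, 40, prior=True, tag="sr")
    events += _block(multi_pgs, WGDEvent.SSGD, 98, 72, prior=False, tag="sl")
    events += _block(nonpg, WGDEvent.SSGD, 82, 62, prior=True, tag="sr")
    events += _block(nonpg, WGDEvent.SSGD, 104, 71, prior=False, tag="sl")

    return genes, annotate_events(events, genes)


def write_curated_dataset(outdir: str | Path) -> dict[str, Path]:
    """Write the curated-count tables and baseline ranges as TSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, events = curated_dataset()
    paths = {
        "genes": write_gene_table(genes, outdir / "gene_table.tsv"),
        "events": write_event_table(events, outdir / "event_table.tsv"),
        "baselines": outdir / "baselines.json",
    }
    paths["baselines"].write_text(
        json.dumps(
            {
                key: {"low": b.low, "high": b.high, "source_note": b.source_note}
                for key, b in BASELINES.items()
            },
            indent=2,
        )
        + "\n"
    )
    return paths
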