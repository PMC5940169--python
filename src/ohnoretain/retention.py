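"""Retention-rate statistics over WGD duplication opportunities.

The retention rate (RR) of a set of duplication opportunities is the
fraction of lineages that kept both copies after a WGD: each event scores
1 if retained, 0 if lost, and the RR is the average.  Counts are kept as
exact integer pairs throughout; percentages with one decimal appear only
at the reporting boundary.

Three views are provided:

* :func:`retention_rate` — RR of an arbitrary stratum (event x copy-class
  x PG status x prior-WGD outcome).
* :func:`compound_vgd_rate` — node-averaged RR of one family across the
  compound 1R/2R era: a retained first-round duplicate contributes two
  second-round duplication nodes, a lost one contributes a single node on
  the surviving lineage, and the family rate averages all node outcomes.
* :func:`conditional_rate_table` — RR at a later WGD conditioned on the
  lineage's outcome at an earlier WGD (e.g. Ss4R retention given Ts3R
  retention), stratified by family class and PG status.

:func:`build_summary_report` assembles these into an
:class:`AnalysisReport` with the standard four-column layout (overall PGs,
PGs in monogenic families, PGs in multigenic families, non-PG paralogs in
multigenic families) per WGD, a conditional block, baseline-range
comparisons and group-effect tests.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from . import stat_tests
from .family_model import (
    MONOGENIC,
    MULTIGENIC,
    FamilySummary,
    GeneRecord,
    RetentionEvent,
    VGD_ERA,
    WGDEvent,
    classify_families,
    match_gene,
)


class EmptyStratumError(ValueError):
    """Raised when a requested stratum contains no retention events."""


class LinkageError(ValueError):
    """Raised when conditional analysis lacks ancestor-outcome linkage."""


@dataclass(frozen=True)
class RetentionRate:
    """Exact retained/total count pair for one stratum."""

    n_retained: int
    n_events: int
    stratum: tuple = ()

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise EmptyStratumError("a RetentionRate needs at least one event")
        if not 0 <= self.n_retained <= self.n_events:
            raise ValueError("n_retained must lie in [0, n_events]")

    @property
    def rate(self) -> float:
        return self.n_retained / self.n_events

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.n_retained, self.n_events)

    @property
    def percent(self) -> float:
        """Percentage rounded to one decimal (reporting precision)."""
        return round(100.0 * self.n_retained / self.n_events, 1)

    @property
    def display(self) -> str:
        return f"{100.0 * self.n_retained / self.n_events:.1f}% ({self.n_retained}/{self.n_events})"

    def labels(self) -> dict:
        return dict(self.stratum)

    @classmethod
    def pooled(cls, parts: Iterable["RetentionRate"], stratum: tuple = ()) -> "RetentionRate":
        """Combine disjoint strata; exact on counts, so the pooled rate is
        the count-weighted combination of the parts."""
        parts = list(parts)
        if not parts:
            raise EmptyStratumError("cannot pool zero strata")
        return cls(
            n_retained=sum(p.n_retained for p in parts),
            n_events=sum(p.n_events for p in parts),
            stratum=stratum,
        )


def retention_rate(
    events: Iterable[RetentionEvent],
    *,
    event: WGDEvent | None = None,
    carries_pg: bool | None = None,
    post_1r2r_class: str | None = None,
    prior_retained: bool | None = None,
    predicate: Callable[[RetentionEvent], bool] | None = None,
) -> RetentionRate:
    """Retention rate of the stratum selected by the keyword filters.

    Raises :class:`EmptyStratumError` when no event matches (never returns
    a 0/0 rate).
    """
    labels = []
    if event is not None:
        labels.append(("event", event.value))
    if carries_pg is not None:
        labels.append(("carries_pg", carries_pg))
    if post_1r2r_class is not None:
        labels.append(("post_1r2r_class", post_1r2r_class))
    if prior_retained is not None:
        labels.append(("prior_retained", prior_retained))

    n = k = 0
    for e in events:
        if event is not None and e.event is not event:
            continue
        if carries_pg is not None and e.carries_pg != carries_pg:
            continue
        if post_1r2r_class is not None and e.post_1r2r_class != post_1r2r_class:
            continue
        if prior_retained is not None and e.prior_retained != prior_retained:
            continue
        if predicate is not None and not predicate(e):
            continue
        n += 1
        k += e.retained
    if n == 0:
        raise EmptyStratumError(f"no events in stratum {dict(labels)!r}")
    return RetentionRate(n_retained=k, n_events=n, stratum=tuple(labels))


def compound_vgd_rate(
    family_id: str, events: Iterable[RetentionEvent]
) -> Fraction:
    """Node-averaged retention rate of one family over the 1R/2R era.

    Every duplication node of the era counts once: the single first-round
    node, plus one second-round node per lineage surviving the first round
    (two nodes if the first-round duplicate was retained, one otherwise).
    The rate is the mean of node outcomes, returned exactly.  Invariant to
    how lineages are labelled or ordered.
    """
    vgd1 = [e for e in events if e.family_id == family_id and e.event is WGDEvent.VGD1]
    vgd2 = [e for e in events if e.family_id == family_id and e.event is WGDEvent.VGD2]
    if not vgd1 or not vgd2:
        raise LinkageError(
            f"family {family_id!r}: both VGD1 and VGD2 events are required for "
            "the compound 1R/2R rate"
        )
    expected_vgd2 = len(vgd1) + sum(e.retained for e in vgd1)
    if len(vgd2) != expected_vgd2:
        raise LinkageError(
            f"family {family_id!r}: inconsistent VGD node structure "
            f"({len(vgd2)} VGD2 nodes, expected {expected_vgd2})"
        )
    retained = sum(e.retained for e in vgd1) + sum(e.retained for e in vgd2)
    return Fraction(retained, len(vgd1) + len(vgd2))


@dataclass(frozen=True)
class ConditionalRateTable:
    """Per-cell and marginal retention rates of an outcome WGD conditioned
    on the lineage's ancestor outcome at an earlier WGD."""

    condition_event: WGDEvent
    outcome_event: WGDEvent
    extra_strata: tuple
    cells: Mapping[tuple, RetentionRate]
    by_prior: Mapping[bool, RetentionRate]
    by_stratum: Mapping[tuple, RetentionRate]

    def cell(self, prior_retained: bool, *values) -> RetentionRate:
        return self.cells[(prior_retained, *values)]


def conditional_rate_table(
    events: Iterable[RetentionEvent],
    condition_event: WGDEvent,
    outcome_event: WGDEvent,
    extra_strata: Sequence[str] = ("post_1r2r_class", "carries_pg"),
) -> ConditionalRateTable:
    """Cross-tabulate retention at ``outcome_event`` by the ancestor outcome
    at ``condition_event``, plus any extra stratum attributes.

    Requires ``era_order(condition) < era_order(outcome)`` and that every
    outcome-event row carries a ``prior_retained`` annotation (supplied in
    the event table or derived from lineage-id linkage at ingest); missing
    linkage raises :class:`LinkageError` naming the offending lineages.
    """
    if condition_event.era_order >= outcome_event.era_order:
        raise ValueError(
            f"condition event {condition_event.value} must precede outcome "
            f"event {outcome_event.value}"
        )
    outcome = [e for e in events if e.event is outcome_event]
    if not outcome:
        raise EmptyStratumError(f"no {outcome_event.value} events")
    unlinked = sorted(e.lineage_id for e in outcome if e.prior_retained is None)
    if unlinked:
        raise LinkageError(
            f"{len(unlinked)} {outcome_event.value} lineages lack "
            f"{condition_event.value}-outcome linkage: {unlinked[:10]}"
        )
    groups: dict[tuple, list[RetentionEvent]] = defaultdict(list)
    for e in outcome:
        key = (e.prior_retained, *(getattr(e, a) for a in extra_strata))
        groups[key].append(e)

    def _rr(evts: list[RetentionEvent], stratum: tuple) -> RetentionRate:
        return RetentionRate(sum(e.retained for e in evts), len(evts), stratum)

    cells = {
        key: _rr(evts, (("prior_retained", key[0]),) + tuple(zip(extra_strata, key[1:])))
        for key, evts in groups.items()
    }
    by_prior = {
        prior: RetentionRate.pooled(
            [rr for key, rr in cells.items() if key[0] == prior],
            stratum=(("prior_retained", prior),),
        )
        for prior in {key[0] for key in cells}
    }
    by_stratum = {
        rest: RetentionRate.pooled(
            [rr for key, rr in cells.items() if key[1:] == rest],
            stratum=tuple(zip(extra_strata, rest)),
        )
        for rest in {key[1:] for key in cells}
    }
    return ConditionalRateTable(
        condition_event=condition_event,
        outcome_event=outcome_event,
        extra_strata=tuple(extra_strata),
        cells=cells,
        by_prior=by_prior,
        by_stratum=by_stratum,
    )


# ---------------------------------------------------------------------------
# summary report

#: Table layout: (cell name, filters)
_TABLE_CELLS = (
    ("overall_pg", dict(carries_pg=True)),
    ("pg_monogenic", dict(carries_pg=True, post_1r2r_class=MONOGENIC)),
    ("pg_multigenic", dict(carries_pg=True, post_1r2r_class=MULTIGENIC)),
    ("nonpg_multigenic", dict(carries_pg=False, post_1r2r_class=MULTIGENIC)),
)


@dataclass
class AnalysisReport:
    """Counts, rates and test results per stratum, serialisable to JSON and
    to an aligned-text / long-TSV rendering.

    Every rate in the report stores its exact (retained, total) counts, so
    each number is traceable to a concrete subset of retention events.
    """

    dimensions: dict
    table: dict
    conditional: dict
    vgd: dict
    tests: list
    gaps: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dimensions": self.dimensions,
            "table": self.table,
            "conditional": self.conditional,
            "vgd": self.vgd,
            "tests": self.tests,
            "gaps": self.gaps,
            "flags": self.flags,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        return render_text(self.to_dict())

    def to_long_rows(self) -> list[dict]:
        rows = []
        for ev, cells in self.table.items():
            for name, cell in cells.items():
                if cell is not None:
                    rows.append({"section": "table", "event": ev, "cell": name, **cell})
        for name, cell in self.conditional.items():
            if isinstance(cell, dict) and "n_events" in cell:
                rows.append({"section": "conditional", "event": "SSGD|TSGD", "cell": name, **cell})
        return rows

    def write(self, outdir: str | Path, stem: str = "report") -> dict[str, Path]:
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "json": outdir / f"{stem}.json",
            "tsv": outdir / f"{stem}.tsv",
            "txt": outdir / f"{stem}.txt",
        }
        paths["json"].write_text(self.to_json() + "\n")
        pd.DataFrame(self.to_long_rows()).to_csv(paths["tsv"], sep="\t", index=False)
        paths["txt"].write_text(self.to_text())
        return paths


def _cell_dict(rr: RetentionRate) -> dict:
    return {
        "n_retained": rr.n_retained,
        "n_events": rr.n_events,
        "percent": rr.percent,
        "display": rr.display,
    }


def _test_dict(comparison: str, result: stat_tests.TestResult) -> dict:
    return {
        "comparison": comparison,
        "method": result.method,
        "statistic": result.statistic,
        "df": result.df,
        "p_value": result.p_value,
        "inputs": dict(result.inputs),
    }


def build_summary_report(
    genes: Sequence[GeneRecord],
    events: Sequence[RetentionEvent],
    baselines: Mapping[str, stat_tests.BaselineRange] | None = None,
    *,
    continuity_correction: bool = True,
    expand_subcategories: bool = False,
    reported_totals: Mapping[str, tuple[int, int]] | None = None,
) -> AnalysisReport:
    """Assemble the full per-stratum summary.

    Empty strata become annotated gaps rather than errors.  ``baselines``
    maps event labels (``TSGD``, ``SSGD``, ``VGD``) to genome-wide
    retention ranges for one-sample comparisons.  ``reported_totals`` maps
    ``"<event>.<cell>"`` to externally reported (retained, total) counts;
    any mismatch with the computed pooled counts is flagged, not silently
    adopted.  ``expand_subcategories`` switches the functional-category
    group test from primary labels to multi-membership expansion.
    """
    summaries = classify_families(genes, events)
    gaps: list[dict] = []
    flags: list[dict] = []
    tests: list[dict] = []

    n_mono = sum(s.copy_class == MONOGENIC for s in summaries)
    n_multi = len(summaries) - n_mono
    dimensions = {
        "n_families": len(summaries),
        "n_monogenic": n_mono,
        "n_multigenic": n_multi,
        "percent_multigenic": round(100.0 * n_multi / len(summaries), 1) if summaries else None,
        "n_genes": len(genes),
        "n_pg": sum(g.is_pg for g in genes),
        "n_nonpg": sum(not g.is_pg for g in genes),
    }

    # Table block: four columns per teleost-era WGD
    table: dict[str, dict] = {}
    rates: dict[tuple[str, str], RetentionRate] = {}
    for ev in (WGDEvent.TSGD, WGDEvent.SSGD):
        row: dict[str, dict | None] = {}
        for name, filt in _TABLE_CELLS:
            try:
                rr = retention_rate(events, event=ev, **filt)
            except EmptyStratumError as err:
                row[name] = None
                gaps.append({"cell": f"{ev.value}.{name}", "reason": str(err)})
                continue
            rates[(ev.value, name)] = rr
            row[name] = _cell_dict(rr)
        table[ev.value] = row

    # Conditional block: outcome WGD given the previous WGD's outcome
    conditional: dict[str, object] = {}
    try:
        ct = conditional_rate_table(events, WGDEvent.TSGD, WGDEvent.SSGD)
    except (EmptyStratumError, LinkageError) as err:
        gaps.append({"cell": "conditional.SSGD|TSGD", "reason": str(err)})
        ct = None
    if ct is not None:
        named = {
            "pg_monogenic_prior_retained": (True, MONOGENIC, True),
            "pg_monogenic_prior_lost": (False, MONOGENIC, True),
            "pg_multigenic_prior_retained": (True, MULTIGENIC, True),
            "pg_multigenic_prior_lost": (False, MULTIGENIC, True),
            "nonpg_prior_retained": (True, MULTIGENIC, False),
            "nonpg_prior_lost": (False, MULTIGENIC, False),
        }
        for name, key in named.items():
            if key in ct.cells:
                conditional[name] = _cell_dict(ct.cells[key])
            else:
                gaps.append({"cell": f"conditional.{name}", "reason": "no events in cell"})
        for prior, name in ((True, "pg_pooled_prior_retained"), (False, "pg_pooled_prior_lost")):
            try:
                rr = retention_rate(
                    events, event=WGDEvent.SSGD, carries_pg=True, prior_retained=prior
                )
            except EmptyStratumError as err:
                gaps.append({"cell": f"conditional.{name}", "reason": str(err)})
                continue
            rates[("SSGD", name)] = rr
            conditional[name] = _cell_dict(rr)

    # Compound 1R/2R era: family-averaged node rate
    vgd: dict[str, object] = {}
    with_vgd = [s for s in summaries if s.vgd_rr is not None]
    if with_vgd:
        mean_rr = sum(float(s.vgd_rr) for s in with_vgd) / len(with_vgd)
        vgd = {
            "n_families_with_vgd_events": len(with_vgd),
            "family_mean_rr_percent": round(100.0 * mean_rr, 1),
        }
        if baselines and "VGD" in baselines:
            b = baselines["VGD"]
            vgd["baseline_range_percent"] = [100 * b.low, 100 * b.high]
            vgd["within_baseline_range"] = bool(b.low <= mean_rr <= b.high)
    else:
        gaps.append({"cell": "vgd.family_mean_rr", "reason": "no 1R/2R-era events"})

    # Two-sample comparisons between strata
    comparisons = [
        ("TSGD", "pg_monogenic", "pg_multigenic"),
        ("TSGD", "overall_pg", "nonpg_multigenic"),
        ("TSGD", "pg_multigenic", "nonpg_multigenic"),
        ("SSGD", "pg_monogenic", "pg_multigenic"),
        ("SSGD", "pg_multigenic", "nonpg_multigenic"),
        ("SSGD", "pg_pooled_prior_retained", "pg_pooled_prior_lost"),
    ]
    for ev, a, b in comparisons:
        ra, rb = rates.get((ev, a)), rates.get((ev, b))
        if ra is None or rb is None:
            continue
        try:
            res = stat_tests.two_sample_prop_test(
                ra, rb, continuity_correction=continuity_correction
            )
        except stat_tests.DegenerateTableError as err:
            gaps.append({"cell": f"test.{ev}.{a}_vs_{b}", "reason": str(err)})
            continue
        tests.append(_test_dict(f"{a}_vs_{b}@{ev}", res))

    # One-sample comparisons against genome-wide baseline ranges
    if baselines:
        for (ev, name), rr in sorted(rates.items()):
            if name.startswith("pg_pooled"):
                continue
            b = baselines.get(ev)
            if b is None:
                continue
            res = stat_tests.one_sample_prop_vs_baseline(rr, b)
            tests.append(_test_dict(f"{name}@{ev}_vs_baseline", res))

    # Functional-category group effect on retention (PG events only)
    by_family: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_family[g.family_id].append(g)
    for ev in (WGDEvent.TSGD, WGDEvent.SSGD):
        outcomes: list[int] = []
        groups: list[str] = []
        for e in events:
            if e.event is not ev or not e.carries_pg:
                continue
            g = match_gene(e.lineage_id, by_family[e.family_id])
            if g is None or not g.is_pg:
                continue
            labels = (
                sorted(g.subcategories) if expand_subcategories and g.subcategories
                else ([g.functional_category] if g.functional_category else [])
            )
            for lab in labels:
                outcomes.append(int(e.retained))
                groups.append(lab)
        distinct = set(groups)
        if len(distinct) < 2:
            gaps.append(
                {
                    "cell": f"test.{ev.value}.category_group_effect",
                    "reason": "fewer than two functional categories with events",
                }
            )
            continue
        try:
            res = stat_tests.wald_group_effect(outcomes, groups)
        except stat_tests.SeparationError as err:
            gaps.append(
                {"cell": f"test.{ev.value}.category_group_effect", "reason": str(err)}
            )
            continue
        tests.append(_test_dict(f"category_group_effect@{ev.value}", res))

    # Externally reported totals are cross-checked, never substituted
    if reported_totals:
        for key, (rk, rn) in reported_totals.items():
            ev, _, name = key.partition(".")
            rr = rates.get((ev, name))
            if rr is None:
                flags.append({"cell": key, "note": "reported total has no computed counterpart"})
            elif (rr.n_retained, rr.n_events) != (rk, rn):
                flags.append(
                    {
                        "cell": key,
                        "computed": [rr.n_retained, rr.n_events],
                        "reported": [rk, rn],
                        "note": (
                            "externally reported counts disagree with the pooled "
                            "category counts; the computed value is used"
                        ),
                    }
                )

    return AnalysisReport(
        dimensions=dimensions,
        table=table,
        conditional=conditional,
        vgd=vgd,
        tests=tests,
        gaps=gaps,
        flags=flags,
    )


def render_text(report: Mapping) -> str:
    """Aligned human-readable rendering of a report dictionary."""
    lines: list[str] = []
    dims = report.get("dimensions", {})
    lines.append("Retention-rate summary")
    lines.append(
        "families: {n_families} ({n_monogenic} monogenic / {n_multigenic} multigenic, "
        "{percent_multigenic}% multigenic); genes: {n_genes} "
        "({n_pg} PG + {n_nonpg} non-PG)".format(**dims)
        if dims
        else "(no dimensions)"
    )
    lines.append("")
    cols = [name for name, _ in _TABLE_CELLS]
    widths = {c: max(len(c), 18) for c in cols}
    header = "event  " + "  ".join(c.ljust(widths[c]) for c in cols)
    lines.append(header)
    for ev, row in report.get("table", {}).items():
        cells = []
        for c in cols:
            cell = row.get(c)
            cells.append((cell["display"] if cell else "absent").ljust(widths[c]))
        lines.append(f"{ev:<5}  " + "  ".join(cells))
    cond = report.get("conditional", {})
    if cond:
        lines.append("")
        lines.append("SSGD retention conditioned on TSGD outcome")
        for name, cell in cond.items():
            if isinstance(cell, dict) and "display" in cell:
                lines.append(f"  {name:<32} {cell['display']}")
    vgd = report.get("vgd", {})
    if vgd:
        lines.append("")
        lines.append(
            "compound 1R/2R era: family-mean RR "
            f"{vgd.get('family_mean_rr_percent')}% over "
            f"{vgd.get('n_families_with_vgd_events')} families"
            + (
                f" (baseline {vgd['baseline_range_percent'][0]:.1f}-"
                f"{vgd['baseline_range_percent'][1]:.1f}%, within range: "
                f"{vgd['within_baseline_range']})"
                if "baseline_range_percent" in vgd
                else ""
            )
        )
    if report.get("tests"):
        lines.append("")
        lines.append("statistical tests")
        for t in report["tests"]:
            lines.append(
                f"  {t['comparison']:<44} {t['method']:<16} "
                f"stat={t['statistic']:.4g} df={t['df']:g} p={t['p_value']:.3g}"
            )
    for section in ("gaps", "flags"):
        if report.get(section):
            lines.append("")
            lines.append(section)
            for item in report[section]:
                lines.append(f"  {item}")
    return "\n".join(lines) + "\n"
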