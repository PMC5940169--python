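"""Retention-rate statistics: strata, compound era, conditional tables, report."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ohnoretain import (
    EmptyStratumError,
    GeneRecord,
    LinkageError,
    RetentionEvent,
    RetentionRate,
    SimulationConfig,
    WGDEvent,
    build_summary_report,
    compound_vgd_rate,
    conditional_rate_table,
    retention_rate,
    simulate_families,
)
from ohnoretain.family_model import MONOGENIC, MULTIGENIC


def _ev(fam, lid, event, retained, **kw):
    return RetentionEvent(fam, lid, event, retained, **kw)


class TestRetentionRate:
    def test_all_retained_is_one(self):
        events = [_ev("f", f"l{i}", WGDEvent.TSGD, True) for i in range(5)]
        assert retention_rate(events).rate == 1.0

    def test_curated_overall_pg_rate(self, curated):
        genes, events = curated
        rr = retention_rate(events, event=WGDEvent.TSGD, carries_pg=True)
        assert (rr.n_retained, rr.n_events) == (63, 184)
        assert rr.percent == 34.2

    def test_empty_stratum_is_an_error_not_zero_over_zero(self):
        events = [_ev("f", "l", WGDEvent.TSGD, True)]
        with pytest.raises(EmptyStratumError, match="no events in stratum"):
            retention_rate(events, event=WGDEvent.SSGD)

    def test_matches_bruteforce_row_loop(self):
        rng = np.random.default_rng(42)
        evs = list(WGDEvent)
        for _ in range(100):
            events = [
                _ev(
                    "f",
                    f"l{i}",
                    evs[int(rng.integers(4))],
                    bool(rng.random() < 0.5),
                    carries_pg=bool(rng.random() < 0.6),
                    post_1r2r_class=MONOGENIC if rng.random() < 0.5 else MULTIGENIC,
                )
                for i in range(int(rng.integers(1, 40)))
            ]
            ev = evs[int(rng.integers(4))]
            pg = bool(rng.random() < 0.5)
            subset = [e for e in events if e.event is ev and e.carries_pg == pg]
            if not subset:
                with pytest.raises(EmptyStratumError):
                    retention_rate(events, event=ev, carries_pg=pg)
                continue
            expected_k = sum(1 for e in subset if e.retained)
            rr = retention_rate(events, event=ev, carries_pg=pg)
            assert (rr.n_retained, rr.n_events) == (expected_k, len(subset))

    @settings(max_examples=100, deadline=None)
    @given(
        outcomes=st.lists(st.booleans(), min_size=1, max_size=60),
        data=st.data(),
    )
    def test_pooled_rate_is_countweighted_combination(self, outcomes, data):
        cuts = sorted(
            data.draw(
                st.lists(
                    st.integers(min_value=1, max_value=max(1, len(outcomes) - 1)),
                    max_size=4,
                )
            )
        )
        bounds = [0] + [c for c in cuts if c < len(outcomes)] + [len(outcomes)]
        parts = []
        for lo, hi in zip(bounds, bounds[1:]):
            if hi > lo:
                parts.append(
                    RetentionRate(sum(outcomes[lo:hi]), hi - lo)
                )
        pooled = RetentionRate.pooled(parts)
        assert pooled.fraction == Fraction(sum(outcomes), len(outcomes))
        total = sum(p.n_events for p in parts)
        assert pooled.fraction == sum(
            p.fraction * Fraction(p.n_events, total) for p in parts
        )


class TestCompoundVgdRate:
    def _family(self, vgd1_retained, vgd2_outcomes):
        events = [_ev("f", "r", WGDEvent.VGD1, vgd1_retained)]
        lids = ["ra", "rb"] if vgd1_retained else ["r"]
        for lid, out in zip(lids, vgd2_outcomes):
            events.append(_ev("f", lid, WGDEvent.VGD2, out))
        return events

    @pytest.mark.parametrize(
        "vgd1,vgd2,expected",
        [
            (True, (True, True), Fraction(1)),      # all four copies kept
            (False, (False,), Fraction(0)),          # both rounds lost
            (False, (True,), Fraction(1, 2)),        # 1R lost, 2R kept
            (True, (False, False), Fraction(1, 3)),  # 1R kept, both 2R lost
            (True, (True, False), Fraction(2, 3)),
        ],
    )
    def test_node_averaging_convention(self, vgd1, vgd2, expected):
        assert compound_vgd_rate("f", self._family(vgd1, vgd2)) == expected

    def test_invariant_to_lineage_relabelling(self):
        events = self._family(True, (True, False))
        relabelled = [
            RetentionEvent(e.family_id, f"x{hash(e.lineage_id) % 997}", e.event, e.retained)
            for e in reversed(events)
        ]
        assert compound_vgd_rate("f", relabelled) == compound_vgd_rate("f", events)

    def test_missing_era_is_an_error(self):
        with pytest.raises(LinkageError, match="VGD1 and VGD2"):
            compound_vgd_rate("f", [_ev("f", "r", WGDEvent.VGD1, False)])

    def test_inconsistent_node_structure_is_an_error(self):
        events = [
            _ev("f", "r", WGDEvent.VGD1, True),
            _ev("f", "ra", WGDEvent.VGD2, False),
        ]
        with pytest.raises(LinkageError, match="node structure"):
            compound_vgd_rate("f", events)


class TestConditionalRateTable:
    def test_curated_margins_match_published_pooling(self, curated):
        genes, events = curated
        table = conditional_rate_table(events, WGDEvent.TSGD, WGDEvent.SSGD)
        mono = RetentionRate.pooled(
            [table.cell(True, MONOGENIC, True), table.cell(False, MONOGENIC, True)]
        )
        assert (mono.n_retained, mono.n_events) == (65, 90) and mono.percent == 72.2
        ret = retention_rate(
            events, event=WGDEvent.SSGD, carries_pg=True, prior_retained=True
        )
        lost = retention_rate(
            events, event=WGDEvent.SSGD, carries_pg=True, prior_retained=False
        )
        assert (ret.n_retained, ret.n_events) == (86, 119) and ret.percent == 72.3
        assert (lost.n_retained, lost.n_events) == (91, 124) and lost.percent == 73.4

    def test_all_cells_retained_gives_unit_rates(self):
        events = [
            _ev("f", f"l{i}", WGDEvent.SSGD, True, prior_retained=bool(i % 2))
            for i in range(8)
        ]
        table = conditional_rate_table(events, WGDEvent.TSGD, WGDEvent.SSGD)
        assert all(rr.rate == 1.0 for rr in table.cells.values())
        assert all(rr.rate == 1.0 for rr in table.by_prior.values())

    def test_wrong_era_order_rejected(self, curated):
        genes, events = curated
        with pytest.raises(ValueError, match="must precede"):
            conditional_rate_table(events, WGDEvent.SSGD, WGDEvent.TSGD)

    def test_unlinked_lineages_are_named(self):
        events = [
            _ev("f", "orphan1", WGDEvent.SSGD, True, prior_retained=None),
            _ev("f", "linked", WGDEvent.SSGD, True, prior_retained=True),
        ]
        with pytest.raises(LinkageError, match="orphan1"):
            conditional_rate_table(events, WGDEvent.TSGD, WGDEvent.SSGD)


class TestSummaryReport:
    def test_curated_table_row(self, curated_report):
        row = curated_report.table["TSGD"]
        assert [row[c]["percent"] for c in
                ("overall_pg", "pg_monogenic", "pg_multigenic", "nonpg_multigenic")] == [
            34.2, 16.9, 46.7, 37.1
        ]

    def test_every_rate_traceable_to_counts(self, curated_report):
        for row in curated_report.table.values():
            for cell in row.values():
                if cell is not None:
                    assert cell["percent"] == round(
                        100 * cell["n_retained"] / cell["n_events"], 1
                    )

    def test_all_retained_simulation_reports_100_everywhere(self):
        cfg = SimulationConfig.from_probs(
            {"VGD1": 1.0, "VGD2": 1.0, "TSGD": 1.0, "SSGD": 1.0},
            n_families=10,
            seed=3,
        )
        ds = simulate_families(cfg)
        report = build_summary_report(ds.genes, ds.events)
        # certain retention makes every family multigenic, so the monogenic
        # strata are reported as gaps; every populated cell is at 100%
        for row in report.table.values():
            for name, cell in row.items():
                if name == "pg_monogenic":
                    assert cell is None
                else:
                    assert cell is not None and cell["percent"] == 100.0

    def test_missing_ssgd_row_becomes_gap_not_crash(self):
        genes = [GeneRecord("f1", "f1", True)]
        events = [
            _ev("f1", "f1", WGDEvent.VGD1, False),
            _ev("f1", "f1", WGDEvent.VGD2, False),
            _ev("f1", "f1", WGDEvent.TSGD, True),
        ]
        report = build_summary_report(genes, events)
        assert all(cell is None for cell in report.table["SSGD"].values())
        assert any(g["cell"].startswith("SSGD") for g in report.gaps)

    def test_text_rendering_contains_table_cells(self, curated_report):
        text = curated_report.to_text()
        assert "34.2% (63/184)" in text and "73.2% (112/153)" in text
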