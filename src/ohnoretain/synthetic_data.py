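"""Generative model for gene families evolving through nested WGDs.

Each family starts as a single pre-1R/2R lineage and passes through the
four WGD events in era order (VGD1, VGD2, TSGD, SSGD).  At every event
each surviving in-scope lineage keeps its duplicate with probability

    p = logistic(base_logit[event] + beta_pg * PG + beta_category[cat]
                 + gamma_carryover * [ancestor retained at previous WGD])

A retained duplicate splits the lineage into two daughters; a lost one
leaves a single continuing lineage.  The SSGD round only applies to
lineages of genes flagged salmonid-present.  Post-1R/2R survivors become
the family's genes; one is designated the pigmentation gene (two, with a
configurable probability, when the family is multigenic), mirroring the
composition of curated pigmentation gene-containing families.

Carryover acts on the immediately preceding WGD only, the simplest
mechanism for the "predestination" pattern in which lineages retained at
one WGD are preferentially retained at the next.  Interaction-partner
counts are drawn from a gamma-Poisson (negative binomial) mixture with
class-specific means, emulating the observation that genes of multigenic
families sit more centrally in protein-protein interaction networks.

The default configuration targets the dimensions of the curated
169-family pigmentation dataset; every draw is reproducible from the seed
and the true per-event probability of every outcome is recorded in a
ground-truth sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy.special import expit

from .family_model import (
    MONOGENIC,
    MULTIGENIC,
    GeneRecord,
    RetentionEvent,
    WGDEvent,
    annotate_events,
    classify_families,
    write_event_table,
    write_gene_table,
)
from .retention import EmptyStratumError, retention_rate

#: Categories sampled for simulated PGs when no category effects are given.
DEFAULT_CATEGORY_POOL = (
    "melanocyte-differentiation",
    "melanosome-biogenesis",
    "melanin-synthesis",
    "xanthophore-differentiation",
)


def _logit(p: float) -> float:
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p / (1.0 - p))


class InteractionModel(BaseModel):
    """Gamma-Poisson interaction-count model.

    ``dispersion`` is the gamma shape; the count variance is
    ``mean + mean^2 / dispersion``, so large dispersion approaches the
    Poisson limit.
    """

    mean_multigenic: float = Field(5.5, ge=0.0)
    mean_monogenic: float = Field(2.2, ge=0.0)
    dispersion: float = Field(2.0, gt=0.0)


class SimulationConfig(BaseModel):
    """Parameters of the family-evolution simulator.

    Defaults emulate the curated dataset: 169 families, per-event retention
    probabilities 0.30/0.30 (the two 1R/2R rounds), 0.34 (TSGD) and 0.73
    (SSGD), a 15/92 chance that a multigenic family carries a second PG,
    no covariate or carryover effects, and all lineages salmonid-present.
    """

    n_families: int = Field(169, ge=1)
    frac_pg_families_two_pg: float = Field(15 / 92, ge=0.0, le=1.0)
    base_logit: dict[str, float] = Field(
        default_factory=lambda: {
            "VGD1": _logit(0.30),
            "VGD2": _logit(0.30),
            "TSGD": _logit(0.34),
            "SSGD": _logit(0.73),
        }
    )
    beta_pg: float = 0.0
    beta_category: dict[str, float] = Field(default_factory=dict)
    gamma_carryover: float = 0.0
    salmonid_fraction: float = Field(1.0, ge=0.0, le=1.0)
    interaction_model: InteractionModel = Field(default_factory=InteractionModel)
    seed: int = 20180329

    @field_validator("base_logit")
    @classmethod
    def _known_events(cls, v: dict[str, float]) -> dict[str, float]:
        valid = {e.value for e in WGDEvent}
        unknown = set(v) - valid
        if unknown:
            raise ValueError(f"unknown WGD labels in base_logit: {sorted(unknown)}")
        missing = valid - set(v)
        if missing:
            raise ValueError(f"base_logit must cover all events; missing {sorted(missing)}")
        return v

    @classmethod
    def from_probs(cls, probs: Mapping[str, float], **kwargs) -> "SimulationConfig":
        """Build a config from per-event retention probabilities."""
        return cls(base_logit={k: _logit(float(p)) for k, p in probs.items()}, **kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        return cls.model_validate_json(Path(path).read_text())

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.model_dump_json(indent=2) + "\n")
        return path


@dataclass
class SimulatedDataset:
    """A simulated gene/event table pair with its generative ground truth.

    ``truth`` holds one row per emitted event with the exact Bernoulli
    probability the outcome was drawn from.
    """

    genes: list[GeneRecord]
    events: list[RetentionEvent]
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": write_gene_table(self.genes, outdir / "gene_table.tsv"),
            "events": write_event_table(self.events, outdir / "event_table.tsv"),
            "truth": outdir / "ground_truth.tsv",
        }
        self.truth[["lineage_id", "event", "p_true"]].to_csv(
            paths["truth"], sep="\t", index=False
        )
        return paths


def simulate_families(config: SimulationConfig, seed=None) -> SimulatedDataset:
    """Run the branching retention process for every family.

    ``seed`` overrides ``config.seed``; identical config and seed give a
    byte-identical dataset.  With ``gamma_carryover = 0`` the outcomes of
    successive eras are independent given covariates.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base = {WGDEvent(k): float(v) for k, v in config.base_logit.items()}
    cats = sorted(config.beta_category) or list(DEFAULT_CATEGORY_POOL)
    gamma = config.gamma_carryover

    genes: list[GeneRecord] = []
    events: list[RetentionEvent] = []
    truth_rows: list[tuple] = []

    def draw(eta: float) -> tuple[bool, float]:
        p = float(expit(eta))
        return bool(rng.random() < p), p

    for i in range(config.n_families):
        fam = f"F{i + 1:05d}"
        # --- compound 1R/2R era ---------------------------------------
        lineages: list[tuple[str, bool | None]] = [(fam, None)]
        for ev in (WGDEvent.VGD1, WGDEvent.VGD2):
            nxt: list[tuple[str, bool | None]] = []
            for lid, prev in lineages:
                eta = base[ev] + (gamma if prev else 0.0)
                retained, p = draw(eta)
                events.append(
                    RetentionEvent(fam, lid, ev, retained, carries_pg=True,
                                   prior_retained=prev)
                )
                truth_rows.append((fam, lid, ev.value, p))
                if retained:
                    nxt.extend([(lid + "a", True), (lid + "b", True)])
                else:
                    nxt.append((lid, False))
            lineages = nxt

        # --- post-1R/2R genes and PG designation ----------------------
        n_genes = len(lineages)
        pg_idx = {int(rng.integers(n_genes))}
        if n_genes >= 2 and rng.random() < config.frac_pg_families_two_pg:
            others = [j for j in range(n_genes) if j not in pg_idx]
            pg_idx.add(int(rng.choice(others)))
        copy_class = MULTIGENIC if n_genes >= 2 else MONOGENIC
        fam_genes: list[tuple[GeneRecord, bool]] = []
        for j, (lid, prev) in enumerate(lineages):
            is_pg = j in pg_idx
            cat = str(rng.choice(cats)) if is_pg else None
            g = GeneRecord(
                gene_id=lid,
                family_id=fam,
                is_pg=is_pg,
                functional_category=cat,
                subcategories=frozenset([cat]) if cat else frozenset(),
                salmonid_present=bool(rng.random() < config.salmonid_fraction),
            )
            genes.append(g)
            fam_genes.append((g, bool(prev)))

        def covariate_eta(g: GeneRecord) -> float:
            eta = config.beta_pg if g.is_pg else 0.0
            if g.functional_category is not None:
                eta += config.beta_category.get(g.functional_category, 0.0)
            return eta

        # --- teleost round (TSGD) -------------------------------------
        teleost: list[tuple[str, bool, GeneRecord]] = []
        for g, prev in fam_genes:
            eta = base[WGDEvent.TSGD] + covariate_eta(g) + (gamma if prev else 0.0)
            retained, p = draw(eta)
            events.append(
                RetentionEvent(fam, g.gene_id, WGDEvent.TSGD, retained,
                               carries_pg=g.is_pg, post_1r2r_class=copy_class,
                               prior_retained=prev)
            )
            truth_rows.append((fam, g.gene_id, WGDEvent.TSGD.value, p))
            if retained:
                teleost.extend([(g.gene_id + "a", True, g), (g.gene_id + "b", True, g)])
            else:
                teleost.append((g.gene_id, False, g))

        # --- salmonid round (SSGD), salmonid-present lineages only ----
        for lid, prev, g in teleost:
            if not g.salmonid_present:
                continue
            eta = base[WGDEvent.SSGD] + covariate_eta(g) + (gamma if prev else 0.0)
            retained, p = draw(eta)
            events.append(
                RetentionEvent(fam, lid, WGDEvent.SSGD, retained,
                               carries_pg=g.is_pg, post_1r2r_class=copy_class,
                               prior_retained=prev)
            )
            truth_rows.append((fam, lid, WGDEvent.SSGD.value, p))

    truth = pd.DataFrame(
        truth_rows, columns=["family_id", "lineage_id", "event", "p_true"]
    )
    # run the ingest-side annotation so emitted events are exactly what a
    # write/ingest round-trip would produce
    events = annotate_events(events, genes)
    return SimulatedDataset(genes=genes, events=events, truth=truth, config=config)


def gamma_poisson(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    """Draw overdispersed counts: Poisson rates gamma-distributed around ``mean``."""
    if mean == 0.0:
        return np.zeros(size, dtype=int)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam)


def simulate_interaction_counts(
    dataset: SimulatedDataset, config: SimulationConfig | None = None, seed=None
) -> SimulatedDataset:
    """Annotate every gene with an interaction-partner count.

    Counts are gamma-Poisson with the class-specific mean of the gene's
    family (multigenic vs monogenic).  Reproducible from the seed; by
    default a stream distinct from the family simulation is derived from
    ``config.seed``.
    """
    cfg = config or dataset.config
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 104729])
    class_of = {
        s.family_id: s.copy_class for s in classify_families(dataset.genes)
    }
    im = cfg.interaction_model
    annotated = []
    for g in dataset.genes:
        mean = im.mean_multigenic if class_of[g.family_id] == MULTIGENIC else im.mean_monogenic
        count = int(gamma_poisson(rng, mean, im.dispersion, 1)[0])
        annotated.append(replace(g, interaction_count=count))
    return SimulatedDataset(
        genes=annotated, events=dataset.events, truth=dataset.truth, config=dataset.config
    )


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass
class RecoveryReport:
    """Replicate-level estimates and their summary against ground truth."""

    replicates: pd.DataFrame
    summary: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "replicates": outdir / "recovery_replicates.tsv",
            "summary": outdir / "recovery_summary.tsv",
        }
        self.replicates.to_csv(paths["replicates"], sep="\t", index=False)
        self.summary.to_csv(paths["summary"], sep="\t", index=False)
        return paths


def recovery_experiment(config: SimulationConfig, n_replicates: int) -> RecoveryReport:
    """Simulate-then-analyze calibration of the retention estimators.

    Per replicate: estimate the per-event retention rate and the carryover
    contrast (RR given prior retention minus RR given prior loss) and
    record the generating means alongside.  The summary reports, per
    stratum, the mean and spread of the estimates, the mean generating
    probability, the bias and its Monte-Carlo standard error, plus the
    rejection rate at alpha = 0.05 of the monogenic-vs-multigenic
    two-sample comparison at TSGD (type-I error under a null config, power
    under a planted effect).
    """
    if n_replicates < 2:
        raise ValueError("recovery_experiment needs n_replicates >= 2")
    rows: list[dict] = []
    from .stat_tests import DegenerateTableError, two_sample_prop_test

    for r in range(n_replicates):
        ds = simulate_families(config, seed=[config.seed, r])
        truth_mean = ds.truth.groupby("event")["p_true"].mean()
        for ev in WGDEvent:
            try:
                rr = retention_rate(ds.events, event=ev)
            except EmptyStratumError:
                continue
            rows.append(
                {
                    "replicate": r,
                    "stratum": ev.value,
                    "estimate": rr.rate,
                    "generating_mean": float(truth_mean.get(ev.value, np.nan)),
                    "n_events": rr.n_events,
                }
            )
        for ev in (WGDEvent.TSGD, WGDEvent.SSGD):
            try:
                hi = retention_rate(ds.events, event=ev, prior_retained=True)
                lo = retention_rate(ds.events, event=ev, prior_retained=False)
            except EmptyStratumError:
                continue
            keyed = ds.truth[ds.truth["event"] == ev.value].set_index(
                ["family_id", "lineage_id"]
            )["p_true"]
            p_hi = [
                keyed[(e.family_id, e.lineage_id)]
                for e in ds.events
                if e.event is ev and e.prior_retained is True
            ]
            p_lo = [
                keyed[(e.family_id, e.lineage_id)]
                for e in ds.events
                if e.event is ev and e.prior_retained is False
            ]
            rows.append(
                {
                    "replicate": r,
                    "stratum": f"{ev.value}_carryover_contrast",
                    "estimate": hi.rate - lo.rate,
                    "generating_mean": float(np.mean(p_hi) - np.mean(p_lo)),
                    "n_events": hi.n_events + lo.n_events,
                }
            )
        try:
            mono = retention_rate(
                ds.events, event=WGDEvent.TSGD, carries_pg=True, post_1r2r_class=MONOGENIC
            )
            multi = retention_rate(
                ds.events, event=WGDEvent.TSGD, carries_pg=True, post_1r2r_class=MULTIGENIC
            )
            p = two_sample_prop_test(mono, multi, continuity_correction=False).p_value
            rows.append(
                {
                    "replicate": r,
                    "stratum": "TSGD_mono_vs_multi_reject_at_05",
                    "estimate": float(p < 0.05),
                    "generating_mean": np.nan,
                    "n_events": mono.n_events + multi.n_events,
                }
            )
        except (EmptyStratumError, DegenerateTableError):
            pass

    replicates = pd.DataFrame(rows)
    grouped = replicates.groupby("stratum")
    summary = grouped.agg(
        mean_estimate=("estimate", "mean"),
        sd_estimate=("estimate", "std"),
        mean_generating=("generating_mean", "mean"),
        n_replicates=("estimate", "size"),
    ).reset_index()
    summary["bias"] = summary["mean_estimate"] - summary["mean_generating"]
    summary["mc_se"] = summary["sd_estimate"] / np.sqrt(summary["n_replicates"])
    return RecoveryReport(replicates=replicates, summary=summary, config=config)
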