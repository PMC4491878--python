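"""Synthetic pan-cancer cohorts with planted network-module structure.

The generator emulates the statistical structure the stratification
pipeline assumes: a gene interaction network with planted modules
(stochastic block wiring), subgroups of patients whose sparse binary
alterations concentrate on their subgroup's module plus uniform passenger
noise, subgroup-dependent exponential survival and stage/grade
multinomials, and expression mean-shifts on module genes.  Crucially,
distinct samples of the same subgroup mostly alter *different* genes of the
same module — the heterogeneity that network smoothing is designed to
resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import EventMatrix, write_matrix, write_network

#: Major-stage labels used for the synthetic clinical table.
STAGES = ("Stage I", "Stage II", "Stage III", "Stage IV")
GRADES = ("G1", "G2", "G3")


def _default_hazards() -> tuple[float, ...]:
    # per-day exponential rates spanning median survival ~2400 -> ~320 days
    return tuple(0.0003 * 1.5 ** g for g in range(6))


def _default_stage_probs() -> tuple[tuple[float, ...], ...]:
    # skew from early-stage-dominated to late-stage-dominated subgroups
    base = np.array(
        [
            [0.55, 0.25, 0.15, 0.05],
            [0.45, 0.30, 0.15, 0.10],
            [0.35, 0.30, 0.20, 0.15],
            [0.25, 0.30, 0.25, 0.20],
            [0.15, 0.25, 0.30, 0.30],
            [0.10, 0.20, 0.30, 0.40],
        ]
    )
    return tuple(tuple(row) for row in base)


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults are the strong-signal planted-module configuration used
    throughout the test-bench: 6 modules of 25 genes (plus 100 background
    genes), within/between wiring 0.25/0.01, 6 subgroups of 40 samples,
    a mean of 8 alterations per sample of which 80 % hit the subgroup's
    own module.
    """

    n_modules: int = 6
    module_size: int = 25
    n_background_genes: int = 100
    p_in: float = 0.25
    p_out: float = 0.01
    k_true: int = 6
    samples_per_subgroup: int = 40
    alts_per_sample: float = 8.0
    module_fraction: float = 0.8
    hazard_per_subgroup: tuple[float, ...] = field(default_factory=_default_hazards)
    censor_rate: float = 0.3
    stage_probs_per_subgroup: tuple[tuple[float, ...], ...] = field(
        default_factory=_default_stage_probs
    )
    grade_probs_per_subgroup: tuple[tuple[float, ...], ...] | None = None
    expr_shift: float = 1.0
    expr_sd: float = 1.0
    type_confusion: float = 0.1
    n_region_events: int = 0
    region_size: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 1 or self.module_size < 1:
            raise ValueError("need at least one module with at least one gene")
        if not 0.0 <= self.module_fraction <= 1.0:
            raise ValueError("module_fraction must lie in [0, 1]")
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        if not (0.0 <= self.p_out and self.p_in <= 1.0):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if self.k_true > self.n_modules:
            raise ValueError("k_true cannot exceed the number of planted modules")
        hazards = self._hazards()
        if any(h <= 0 for h in hazards):
            raise ValueError("hazards must be positive")
        for probs in self._stage_probs():
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError("stage probabilities must be non-negative and sum to 1")
        for probs in self._grade_probs():
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError("grade probabilities must be non-negative and sum to 1")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")

    def _cycle(self, rows, n) -> list[tuple[float, ...]]:
        return [tuple(rows[g % len(rows)]) for g in range(n)]

    def _hazards(self) -> list[float]:
        rates = list(self.hazard_per_subgroup)
        return [rates[g % len(rates)] for g in range(self.k_true)]

    def _stage_probs(self) -> list[tuple[float, ...]]:
        return self._cycle(self.stage_probs_per_subgroup, self.k_true)

    def _grade_probs(self) -> list[tuple[float, ...]]:
        if self.grade_probs_per_subgroup is not None:
            return self._cycle(self.grade_probs_per_subgroup, self.k_true)
        # default: collapse the stage skew onto three grades
        out = []
        for probs in self._stage_probs():
            p = np.asarray(probs, dtype=float)
            g = np.array([p[0], p[1] + p[2] / 2, p[3] + p[2] / 2])
            out.append(tuple(g / g.sum()))
        return out


@dataclass
class SyntheticCohort:
    """A complete simulated input set plus the planted ground truth."""

    events: EventMatrix
    network: nx.Graph
    clinical: pd.DataFrame
    expression: pd.DataFrame          # genes x samples
    truth: pd.Series                  # sample -> true subgroup (1-based)
    module_genes: list[list[str]]     # per planted module
    background_genes: list[str]
    config: SimConfig

    @property
    def gene_matrix(self) -> pd.DataFrame:
        """Samples x genes binary matrix implied by the (single-gene) events."""
        from .preprocess import expand_events

        return expand_events(self.events)


def _gene_names(cfg: SimConfig) -> tuple[list[list[str]], list[str]]:
    modules = [
        [f"G{m:02d}_{j:03d}" for j in range(cfg.module_size)]
        for m in range(cfg.n_modules)
    ]
    background = [f"BG_{j:03d}" for j in range(cfg.n_background_genes)]
    return modules, background


def generate_network(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[nx.Graph, list[list[str]]]:
    """Planted-partition network over module plus background genes.

    Each module block is wired internally with ``p_in``; all remaining pairs
    (cross-module, background-background, module-background) with ``p_out``.
    Connectedness is enforced deterministically by a spanning path: a chain
    within each block and one bridging edge between consecutive blocks, so
    the ``p_in=1, p_out=0`` extreme yields cliques joined by a path.  Unit
    edge weights.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    modules, background = _gene_names(cfg)
    blocks = [list(m) for m in modules]
    if background:
        blocks.append(list(background))

    graph = nx.Graph()
    for block in blocks:
        graph.add_nodes_from(block)

    for bi, block in enumerate(blocks):
        is_module = bi < cfg.n_modules
        p = cfg.p_in if is_module else cfg.p_out
        n = len(block)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    graph.add_edge(block[i], block[j], weight=1.0)
    # cross-block wiring
    for bi in range(len(blocks)):
        for bj in range(bi + 1, len(blocks)):
            for u in blocks[bi]:
                for v in blocks[bj]:
                    if rng.random() < cfg.p_out:
                        graph.add_edge(u, v, weight=1.0)
    # spanning path: chain within blocks, bridge consecutive blocks
    for block in blocks:
        for u, v in zip(block, block[1:]):
            graph.add_edge(u, v, weight=1.0)
    for prev, nxt in zip(blocks, blocks[1:]):
        graph.add_edge(prev[-1], nxt[0], weight=1.0)
    return graph, modules


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort under ``cfg`` (byte-reproducible by seed).

    Per sample of subgroup ``g``: Poisson(``alts_per_sample``) alteration
    draws, each hitting a uniform gene of module ``g`` with probability
    ``module_fraction`` and a uniform background gene otherwise (duplicate
    hits collapse, so profiles are sparse and heterogeneous within a
    subgroup); survival ~ Exponential(hazard_g) with independent uniform
    censoring at rate ``censor_rate``; stage and grade from the subgroup's
    multinomials; expression N(0, expr_sd) plus ``expr_shift`` on module-g
    genes.  Pseudo cancer-type labels are a noisy surjection of the true
    subgroups (confusion rate ``type_confusion``) so enrichment tests have a
    planted truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    network, modules = generate_network(cfg, rng)
    _, background = _gene_names(cfg)
    all_genes = [g for m in modules for g in m] + background

    n = cfg.k_true * cfg.samples_per_subgroup
    sample_ids = [f"S{idx:04d}" for idx in range(n)]
    truth = pd.Series(
        [g + 1 for g in range(cfg.k_true) for _ in range(cfg.samples_per_subgroup)],
        index=sample_ids, name="subgroup",
    )

    # --- binary alterations -------------------------------------------------
    alt = pd.DataFrame(0, index=sample_ids, columns=all_genes, dtype="int8")
    for sample, g in truth.items():
        module = modules[g - 1]
        n_alts = rng.poisson(cfg.alts_per_sample)
        for _ in range(n_alts):
            if background and rng.random() >= cfg.module_fraction:
                gene = background[rng.integers(len(background))]
            else:
                gene = module[rng.integers(len(module))]
            alt.loc[sample, gene] = 1

    # one degenerate single-gene event per gene, plus optional region events
    values = alt.T.copy()
    values.index = [f"ev_{g}" for g in values.index]
    classes = {e: "mutation" for e in values.index}
    member = {f"ev_{g}": (g,) for g in all_genes}
    for r in range(cfg.n_region_events):
        module = modules[r % cfg.n_modules]
        start = (r * cfg.region_size) % max(1, len(module) - cfg.region_size)
        region = tuple(module[start:start + cfg.region_size])
        event_id = f"region_{r:02d}"
        hit = alt[list(region)].max(axis=1).astype("int8")
        values.loc[event_id] = hit.values
        classes[event_id] = "cn_gain"
        member[event_id] = region
    events = EventMatrix(
        values=values.astype("int8"),
        event_class=pd.Series(classes).reindex(values.index),
        member_genes=member,
    )

    # --- clinical -----------------------------------------------------------
    hazards = cfg._hazards()
    stage_probs = cfg._stage_probs()
    grade_probs = cfg._grade_probs()
    rows = {}
    for sample, g in truth.items():
        t_event = rng.exponential(1.0 / hazards[g - 1])
        censored = rng.random() < cfg.censor_rate
        time = t_event * rng.random() if censored else t_event
        if cfg.type_confusion > 0 and rng.random() < cfg.type_confusion:
            label = int(rng.integers(cfg.k_true)) + 1
        else:
            label = g
        stage = STAGES[rng.choice(len(STAGES), p=np.asarray(stage_probs[g - 1]))]
        grade = GRADES[rng.choice(len(GRADES), p=np.asarray(grade_probs[g - 1]))]
        rows[sample] = {
            "cancer_type": f"T{label}",
            "subtype": pd.NA,
            "survival_time": float(time),
            "event_indicator": 0 if censored else 1,
            "stage": stage,
            "grade": grade,
        }
    clinical = pd.DataFrame.from_dict(rows, orient="index")
    clinical.index.name = "sample_id"

    # --- expression ---------------------------------------------------------
    expr = rng.normal(0.0, cfg.expr_sd, size=(len(all_genes), n))
    expression = pd.DataFrame(expr, index=all_genes, columns=sample_ids)
    for g in range(cfg.k_true):
        cols = truth.index[truth == g + 1]
        expression.loc[modules[g], cols] += cfg.expr_shift

    return SyntheticCohort(
        events=events,
        network=network,
        clinical=clinical,
        expression=expression,
        truth=truth,
        module_genes=modules,
        background_genes=background,
        config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Persist the cohort in the same TSV formats the readers consume."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": outdir / "events.tsv",
        "event_annotation": outdir / "event_annotation.tsv",
        "network": outdir / "network.tsv",
        "clinical": outdir / "clinical.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_matrix(cohort.events.values, paths["events"], index_name="event_id")
    ann = pd.DataFrame(
        {
            "event_class": cohort.events.event_class,
            "member_genes": [
                ",".join(cohort.events.member_genes[e]) for e in cohort.events.event_ids
            ],
        },
        index=pd.Index(cohort.events.event_ids, name="event_id"),
    )
    ann.to_csv(paths["event_annotation"], sep="\t")
    write_network(cohort.network, paths["network"])
    cohort.clinical.to_csv(paths["clinical"], sep="\t")
    write_matrix(cohort.expression, paths["expression"], index_name="gene")
    cohort.truth.to_frame().to_csv(paths["truth"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
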