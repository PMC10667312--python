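"""End-to-end orchestration: simulate, observe, reconstruct, analyze, report.

A run is a pure function of (config, code version): a single integer seed
drives every stage through spawned child generators, and the report JSON is
byte-identical across repeated runs of the same config.  Timestamps are
confined to the log.  Ploidy-flagged strains (whole-genome-duplication
escapees detected from the wt:syn read ratio) are excluded from the
association scan and ESR scoring but retained in the report with their
flag.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .segment_model import (
    SegmentMap,
    load_segment_map,
    write_segment_map,
    synthetic_map,
    causal_region_ids,
    reference_structure,
    retained_fraction,
    canonical_form,
)
from .scramble_sim import (
    SimParams,
    simulate_population,
    reference_colony_sizes,
)
from .evidence_gen import DepthParams, generate_evidence, estimate_copy_numbers, flag_ploidy_anomaly
from .reconstruct import (
    build_graph,
    infer_structures,
    min_event_distance,
    classify_population,
)
from .fitness_stats import growth_recovery_rate, retention_recovery_regression, association_scan
from .expression_esr import (
    ExprParams,
    default_esr_sets,
    simulate_expression,
    esr_score,
    esr_reversal_report,
)

logger = logging.getLogger("synscramble")

__all__ = [
    "MapConfig",
    "SimConfig",
    "EvidenceConfig",
    "AnalysisConfig",
    "ExpressionConfig",
    "RunConfig",
    "RunReport",
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
    "summarize_population",
    "mean_events_per_strain",
    "topology_percent",
    "validate_report",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


class MapConfig(BaseModel):
    path: Optional[str] = None  # load a BED-like TSV instead of generating
    n_segments: int = 40
    total_bp: int = 1_028_952
    map_seed: int = 7


class SimConfig(BaseModel):
    event_type_probs: tuple[float, float, float] = (0.622, 0.292, 0.086)
    mean_events: float = 4.42
    event_count_dispersion: float = 2.0
    circularization_prob: float = 0.89
    causal_region: tuple[str, ...] = ()  # default: the 20-kb right-arm segment
    beta0: float = 5.0
    beta_mass: float = 45.0
    beta_region: float = 25.0
    noise_sd: float = 8.0
    ref_colony_mm: float = 1.2
    colony_cv: float = 0.12
    n_colonies: int = 200
    trisomy_fraction: float = 3 / 219
    rejection_cap: int = 1000


class EvidenceConfig(BaseModel):
    baseline: float = 100.0
    circular_recovery_factor: float = 1.0 / 3.0
    junction_rate: float = 20.0
    pcrtag_reads: float = 300.0
    noise: bool = False  # default run analyses noise-free evidence


class AnalysisConfig(BaseModel):
    alpha: float = 0.05
    n_perm: int = 0
    ploidy_alpha: float = 0.05
    ploidy_fold: float = 1.5
    k_max: int = 4
    traversal_cap: int = 50


class ExpressionConfig(BaseModel):
    enabled: bool = True
    baseline_mean: float = 200.0
    nb_shape: float = 100.0
    buffered_fraction: float = 0.10
    iesr_log2: float = 1.2
    resr_log2: float = 1.6
    n_background: int = 600
    n_iesr: int = 300
    n_resr: int = 600
    noise: bool = True
    de_threshold: float = 0.001
    reversal_ratio: float = 0.5


class RunConfig(BaseModel):
    seed: int = 0
    n_strains: int = 219
    map: MapConfig = Field(default_factory=MapConfig)
    sim: SimConfig = Field(default_factory=SimConfig)
    evidence: EvidenceConfig = Field(default_factory=EvidenceConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    expression: ExpressionConfig = Field(default_factory=ExpressionConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------


class PopulationSummary(BaseModel):
    n_strains: int
    mean_events: float
    circular_pct: int
    linear_pct: int
    event_fractions: dict[str, float]
    size_range_bp: dict[str, list[int]]


class RegressionReport(BaseModel):
    r: float
    r_pvalue: float
    slope: float
    intercept: float


class AssociationRow(BaseModel):
    segment: str
    n_deleted: int
    n_retained: int
    effect: Optional[float] = None
    stat: Optional[float] = None
    p: Optional[float] = None
    significant: bool = False
    tested: bool = True
    reason: str = ""


class ESRRow(BaseModel):
    strain: str
    frac_iesr_up: float
    frac_resr_down: float
    esr_reversed: bool


class Provenance(BaseModel):
    seed: int
    config_hash: str
    package_version: str


class RunReport(BaseModel):
    provenance: Provenance
    population: PopulationSummary
    n_excluded_ploidy: int
    excluded_strains: list[str]
    retention_recovery: RegressionReport
    association: list[AssociationRow]
    top_association_segment: Optional[str] = None
    esr: list[ESRRow]


def validate_report(data: dict) -> RunReport:
    """Validate a report dict against the shipped schema (pydantic model)."""
    return RunReport.model_validate(data)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# population summary helpers
# ---------------------------------------------------------------------------


def mean_events_per_strain(counts) -> float:
    """Mean recombination events per strain, reported at 2 decimals."""
    counts = list(counts)
    if not counts:
        raise ValueError("empty event-count list")
    return round(float(np.sum(counts)) / len(counts), 2)


def topology_percent(n_topology: int, n_total: int) -> int:
    """Share of strains with a given topology, nearest integer percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(round(100.0 * n_topology / n_total))


def summarize_population(records, decompositions, smap: SegmentMap | None = None) -> dict:
    """Population summary: mean events, topology percentages, size ranges."""
    if not records or not decompositions:
        raise ValueError("records and decompositions must be nonempty")
    per_strain = [
        sum(1 for e in d.events if e.kind != "circularization") for d in decompositions
    ]
    circ = [d for d in decompositions if any(e.kind == "circularization" for e in d.events)]
    sizes: dict[str, list[int]] = {}
    if smap is not None:
        for rec in records:
            bp = sum(smap.get(i).length_bp for i, _ in rec.structure.word)
            sizes.setdefault(rec.structure.topology, []).append(bp)
    return {
        "n_strains": len(records),
        "mean_events": mean_events_per_strain(per_strain),
        "circular_pct": topology_percent(len(circ), len(decompositions)),
        "linear_pct": topology_percent(len(decompositions) - len(circ), len(decompositions)),
        "size_range_bp": {k: [min(v), max(v)] for k, v in sizes.items()},
    }


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


class PipelineResult:
    """In-memory artifacts of one run (the report plus stage outputs)."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def _build_map(cfg: MapConfig) -> SegmentMap:
    if cfg.path:
        return load_segment_map(cfg.path)
    return synthetic_map(n_segments=cfg.n_segments, total_bp=cfg.total_bp, seed=cfg.map_seed)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run simulate -> evidence -> reconstruct -> fitness -> expression -> report.

    Returns a :class:`PipelineResult`; when ``outdir`` is given, intermediate
    TSV/JSON artifacts and the report are persisted there.
    """
    rng_sim, rng_ev, rng_expr, rng_perm = [
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
    ]

    smap = _stage("map")(_build_map)(config.map)
    causal = config.sim.causal_region or causal_region_ids(smap)
    sim_params = SimParams(
        event_type_probs=tuple(config.sim.event_type_probs),
        mean_events=config.sim.mean_events,
        event_count_dispersion=config.sim.event_count_dispersion,
        circularization_prob=config.sim.circularization_prob,
        causal_region=tuple(causal),
        beta0=config.sim.beta0,
        beta_mass=config.sim.beta_mass,
        beta_region=config.sim.beta_region,
        noise_sd=config.sim.noise_sd,
        ref_colony_mm=config.sim.ref_colony_mm,
        colony_cv=config.sim.colony_cv,
        n_colonies=config.sim.n_colonies,
        trisomy_fraction=config.sim.trisomy_fraction,
        rejection_cap=config.sim.rejection_cap,
    )

    @_stage("simulate")
    def _simulate():
        pop = simulate_population(smap, sim_params, config.n_strains, rng_sim)
        ref_sizes = reference_colony_sizes(sim_params, rng_sim)
        return pop, ref_sizes

    population, ref_sizes = _simulate()
    logger.info("simulated %d strains (seed=%d)", len(population), config.seed)

    depth_params = DepthParams(
        baseline=config.evidence.baseline,
        circular_recovery_factor=config.evidence.circular_recovery_factor,
        junction_rate=config.evidence.junction_rate,
        pcrtag_reads=config.evidence.pcrtag_reads,
        noise=config.evidence.noise,
    )

    @_stage("evidence")
    def _evidence():
        evs, ploidy = [], []
        for rec in population:
            ev = generate_evidence(rec, smap, depth_params, rng_ev)
            flag, _ = flag_ploidy_anomaly(
                ev, alpha=config.analysis.ploidy_alpha, fold=config.analysis.ploidy_fold
            )
            evs.append(ev)
            ploidy.append(flag)
        return evs, ploidy

    evidences, ploidy_flags = _evidence()

    ref = reference_structure(smap)

    @_stage("reconstruct")
    def _reconstruct():
        structures, decomps, copies_list = [], [], []
        for rec, ev in zip(population, evidences):
            copies = estimate_copy_numbers(ev, smap)
            graph = build_graph(ev, smap, copies=copies)
            cands = infer_structures(
                graph, smap, topology_hint=ev.topology_hint, cap=config.analysis.traversal_cap
            )
            best = cands[0]
            decomp = min_event_distance(ref, best, smap, k_max=config.analysis.k_max)
            structures.append(best)
            decomps.append(decomp)
            copies_list.append(copies)
        return structures, decomps, copies_list

    structures, decompositions, copies_list = _reconstruct()
    classification = classify_population(decompositions)

    @_stage("fitness")
    def _fitness():
        recov = {}
        for rec in population:
            rr = growth_recovery_rate(rec.colony_sizes_mm, ref_sizes, min_n=0)
            recov[rec.strain_id] = rr.value_pct
        recovery = pd.Series(recov, name="recovery_pct")

        included = [r.strain_id for r, fl in zip(population, ploidy_flags) if not fl]
        delmat = pd.DataFrame(
            {
                seg.id: [int(copies_list[k][seg.id]) == 0 for k in range(len(population))]
                for seg in smap
            },
            index=[r.strain_id for r in population],
        ).loc[included]
        scan = association_scan(
            delmat,
            recovery.loc[included],
            n_perm=config.analysis.n_perm,
            alpha=config.analysis.alpha,
            rng=rng_perm,
        )
        est_retained = {
            r.strain_id: sum(
                smap.get(seg.id).length_bp for seg in smap if int(copies_list[k][seg.id]) > 0
            )
            / smap.total_length_bp
            for k, r in enumerate(population)
        }
        reg = retention_recovery_regression(
            (
                np.array([est_retained[s] for s in included]),
                recovery.loc[included].to_numpy(),
            )
        )
        return recovery, delmat, scan, reg

    recovery, deletion_matrix, scan, regression = _fitness()

    esr_table = pd.DataFrame()
    if config.expression.enabled:

        @_stage("expression")
        def _expression():
            gene_sets = default_esr_sets(config.expression.n_iesr, config.expression.n_resr)
            expr_params = ExprParams(
                baseline_mean=config.expression.baseline_mean,
                nb_shape=config.expression.nb_shape,
                buffered_fraction=config.expression.buffered_fraction,
                iesr_log2=config.expression.iesr_log2,
                resr_log2=config.expression.resr_log2,
                n_background=config.expression.n_background,
                noise=config.expression.noise,
            )
            included_pop = [
                r for r, fl in zip(population, ploidy_flags) if not fl
            ]
            matrix = simulate_expression(included_pop, smap, gene_sets, expr_params, rng_expr)
            scores = esr_score(
                matrix,
                gene_sets,
                reference="WT",
                de_threshold=config.expression.de_threshold,
                dispersion=config.expression.nb_shape,
            )
            return esr_reversal_report(
                scores, disome_strain="disome", ratio_cutoff=config.expression.reversal_ratio
            )

        esr_table = _expression()

    # ---- report ----------------------------------------------------------
    summary = summarize_population(population, decompositions, smap)
    excluded = [r.strain_id for r, fl in zip(population, ploidy_flags) if fl]
    tested = scan[scan["tested"]]
    top_seg = tested["p"].idxmin() if len(tested) else None

    def _opt(x):
        return None if (x is None or (isinstance(x, float) and np.isnan(x))) else float(x)

    report = RunReport(
        provenance=Provenance(
            seed=config.seed, config_hash=config.config_hash(), package_version=__version__
        ),
        population=PopulationSummary(
            n_strains=summary["n_strains"],
            mean_events=summary["mean_events"],
            circular_pct=summary["circular_pct"],
            linear_pct=summary["linear_pct"],
            event_fractions={k: round(v, 4) for k, v in classification.fractions.items()},
            size_range_bp=summary["size_range_bp"],
        ),
        n_excluded_ploidy=len(excluded),
        excluded_strains=excluded,
        retention_recovery=RegressionReport(
            r=regression.r,
            r_pvalue=regression.r_pvalue,
            slope=regression.slope,
            intercept=regression.intercept,
        ),
        association=[
            AssociationRow(
                segment=str(seg),
                n_deleted=int(row["n_deleted"]),
                n_retained=int(row["n_retained"]),
                effect=_opt(row["effect"]),
                stat=_opt(row["stat"]),
                p=_opt(row["p"]),
                significant=bool(row["significant"]),
                tested=bool(row["tested"]),
                reason=str(row["reason"]),
            )
            for seg, row in scan.iterrows()
        ],
        top_association_segment=str(top_seg) if top_seg is not None else None,
        esr=[
            ESRRow(
                strain=str(s),
                frac_iesr_up=float(row["frac_iesr_up"]),
                frac_resr_down=float(row["frac_resr_down"]),
                esr_reversed=bool(row["esr_reversed"]),
            )
            for s, row in esr_table.iterrows()
        ],
    )

    result = PipelineResult(
        config=config,
        smap=smap,
        population=population,
        evidences=evidences,
        ploidy_flags=ploidy_flags,
        structures=structures,
        decompositions=decompositions,
        classification=classification,
        recovery=recovery,
        deletion_matrix=deletion_matrix,
        scan=scan,
        regression=regression,
        esr_table=esr_table,
        report=report,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


# ---------------------------------------------------------------------------
# artifact persistence
# ---------------------------------------------------------------------------


def report_json(report: RunReport) -> str:
    """Deterministic JSON rendering of a report."""
    return json.dumps(report.model_dump(mode="json"), sort_keys=True, indent=2) + "\n"


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = result.config.config_hash()

    write_segment_map(result.smap, outdir / "map.tsv")

    rows = []
    for rec, flag, struct, decomp in zip(
        result.population, result.ploidy_flags, result.structures, result.decompositions
    ):
        rows.append(
            {
                "strain": rec.strain_id,
                "topology": rec.structure.topology,
                "retained_fraction": round(rec.retained_fraction, 6),
                "recovery_pct": round(float(result.recovery[rec.strain_id]), 4),
                "trisomy_simulated": rec.trisomy_flag,
                "ploidy_flagged": flag,
                "n_events_applied": sum(1 for e in rec.events if e.kind != "circularization"),
                "n_events_called": sum(1 for e in decomp.events if e.kind != "circularization"),
                "call_is_minimal": decomp.is_minimal,
                "structure": struct.to_line().replace("\t", ":"),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "population.tsv", sep="\t", index=False)

    with (outdir / "structures.txt").open("w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        for rec, struct in zip(result.population, result.structures):
            fh.write(f"{rec.strain_id}\t{struct.to_line()}\n")

    result.scan.reset_index().to_csv(outdir / "association_scan.tsv", sep="\t", index=False)
    if len(result.esr_table):
        result.esr_table.reset_index().to_csv(outdir / "esr.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(report_json(result.report))
    (outdir / "config.json").write_text(
        json.dumps(result.config.model_dump(mode="json"), sort_keys=True, indent=2) + "\n"
    )
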