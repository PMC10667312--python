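"""Cre/loxPsym rearrangement simulator for disomic strains.

Stage 1 of the synthetic-data generator.  A SCRaMbLE reaction is modelled as
a sequence of events acting on the synthetic homolog's structure word:

* ``deletion``      — remove the spanned sub-word,
* ``inversion``     — reverse the spanned sub-word and flip signs,
* ``duplication``   — insert a tandem copy immediately after the span,
* ``circularization`` — keep the interior sub-word as a circular molecule and
  discard both telomeric fragments (linear molecules only; circles are locked
  in and never revert).

Event types are drawn from a phenomenological multinomial whose defaults are
the observed population mix (deletion 62.2%, inversion 29.2%, duplication
8.6%); per-strain event counts follow a zero-truncated negative binomial with
mean 4.42 and a long right tail.  Survivors must pass the dual-selection
filter (centromere + centromere-adjacent marker retained); strains failing it
are rejection-sampled.  Fitness is a mass-action dosage term plus a planted
causal-region bonus, realized as colony-size samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .segment_model import (
    ChromosomeStructure,
    SegmentMap,
    reference_structure,
    retained_fraction,
)

EVENT_KINDS = ("deletion", "inversion", "duplication", "circularization")

__all__ = [
    "ScrambleEvent",
    "SimParams",
    "StrainRecord",
    "GrowthParams",
    "GrowthCurve",
    "apply_event",
    "selection_filter",
    "simulate_strain",
    "assign_fitness",
    "reference_colony_sizes",
    "simulate_growth_curve",
    "simulate_population",
]


@dataclass(frozen=True)
class ScrambleEvent:
    """One recombination event.

    ``junctions`` are 1-based inter-segment positions in the word the event
    is applied to.  For linear words of length L they run 1..L+1 (position p
    sits before element p); for circular words they run 1..L and the span
    from i to j is read cyclically.  ``payload`` records the affected
    sub-word at application time (informational).
    """

    kind: str
    junctions: tuple[int, int]
    payload: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults encode the study conditions."""

    event_type_probs: tuple[float, float, float] = (0.622, 0.292, 0.086)
    mean_events: float = 4.42
    event_count_dispersion: float = 2.0
    circularization_prob: float = 0.89
    span_geometric_mean: float | None = 1.2  # segments; None = uniform junction pairs
    telomere_proximal_circ: float | None = 3.0  # segments from each telomere; None = uniform
    site_weights: dict | None = None
    causal_region: tuple[str, ...] = ()
    beta0: float = 5.0
    beta_mass: float = 45.0
    beta_region: float = 25.0
    noise_sd: float = 8.0
    recovery_floor: float = 0.0
    ref_colony_mm: float = 1.2
    colony_cv: float = 0.12
    n_colonies: int = 200
    trisomy_fraction: float = 0.0
    rejection_cap: int = 1000

    def __post_init__(self) -> None:
        p = self.event_type_probs
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("event_type_probs must be 3 nonnegative values summing to 1")
        if self.mean_events < 0:
            raise ValueError("mean_events must be >= 0")
        if 0 < self.mean_events <= 1:
            raise ValueError(
                "mean_events in (0, 1] is not representable by a zero-truncated "
                "negative binomial; use 0 for the no-event degenerate case"
            )
        if not (0 <= self.circularization_prob <= 1):
            raise ValueError("circularization_prob must be in [0,1]")
        if self.event_count_dispersion <= 0:
            raise ValueError("event_count_dispersion must be positive")


@dataclass
class StrainRecord:
    """One simulated SCRaMbLEd strain."""

    strain_id: str
    structure: ChromosomeStructure
    events: tuple[ScrambleEvent, ...]
    retained_fraction: float
    recovery_rate_pct: float | None = None
    colony_sizes_mm: np.ndarray | None = None
    trisomy_flag: bool = False


# ---------------------------------------------------------------------------
# event application
# ---------------------------------------------------------------------------


def _flip(block: Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    return [(i, -s) for i, s in reversed(block)]


def _span_slice(word, i: int, j: int, circular: bool):
    """Return (span, remainder-prefix, remainder-suffix) for junctions i, j.

    Linear: requires 1 <= i < j <= L+1; the span is word[i-1:j-1].
    Circular: positions 1..L, i != j; the span runs cyclically from i to j
    (wrapping through the stored origin when j < i).  Non-wrapping circular
    events keep the stored rotation, so recorded junction coordinates replay
    exactly.
    """
    L = len(word)
    if circular:
        if L < 2:
            raise ValueError("no valid junction pairs on a word of length < 2")
        if not (1 <= i <= L and 1 <= j <= L) or i == j:
            raise ValueError(f"junctions {(i, j)} out of range for circular word of length {L}")
        if i < j:
            return list(word[i - 1 : j - 1]), list(word[: i - 1]), list(word[j - 1 :])
        if j == 1:  # suffix span: runs to the stored origin, no true wrap
            return list(word[i - 1 :]), list(word[: i - 1]), []
        return list(word[i - 1 :]) + list(word[: j - 1]), [], list(word[j - 1 : i - 1])
    if not (1 <= i < j <= L + 1):
        raise ValueError(f"junctions {(i, j)} out of range for linear word of length {L}")
    return list(word[i - 1 : j - 1]), list(word[: i - 1]), list(word[j - 1 :])


def apply_event(structure: ChromosomeStructure, event: ScrambleEvent) -> ChromosomeStructure:
    """Apply one SCRaMbLE event, returning the new structure.

    Circularization is only defined on linear structures; circular
    structures never return to the linear state.
    """
    circular = structure.is_circular
    i, j = event.junctions
    if event.kind == "circularization":
        if circular:
            raise ValueError("cannot circularize an already circular structure")
        span, _, _ = _span_slice(structure.word, i, j, False)
        if not span:
            raise ValueError("circularization must retain a nonempty interior")
        return ChromosomeStructure("circular", tuple(span))

    span, pre, post = _span_slice(structure.word, i, j, circular)
    if not span:
        raise ValueError(f"{event.kind} span must cover >= 1 segment")
    if event.kind == "deletion":
        new = pre + post
    elif event.kind == "inversion":
        new = pre + _flip(span) + post
    elif event.kind == "duplication":
        new = pre + list(span) + list(span) + post
    else:  # pragma: no cover - guarded by ScrambleEvent
        raise ValueError(event.kind)
    return ChromosomeStructure(structure.topology, tuple(new))


def replay_events(
    reference: ChromosomeStructure, events: Sequence[ScrambleEvent]
) -> ChromosomeStructure:
    """Apply a recorded event list to the reference; the identity check used
    by the event-log replay invariant."""
    s = reference
    for ev in events:
        s = apply_event(s, ev)
    return s


def selection_filter(structure: ChromosomeStructure, smap: SegmentMap) -> bool:
    """True iff the word retains the centromere and the marker segment.

    Mirrors dual auxotrophic selection: survivors keep centromere function
    and the centromere-adjacent prototrophy marker on the synthetic homolog.
    """
    present = {i for i, _ in structure.word}
    return all(r in present for r in smap.required_ids)


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _ztnb_untruncated_mean(mean: float, r: float) -> float:
    """Solve for the untruncated NB mean giving a zero-truncated mean of `mean`."""

    def f(mu: float) -> float:
        p0 = (r / (r + mu)) ** r
        return mu / (1.0 - p0) - mean

    return brentq(f, 1e-12, mean)


def _draw_event_count(params: SimParams, rng: np.random.Generator) -> int:
    if params.mean_events == 0:
        return 0
    r = params.event_count_dispersion
    mu = _ztnb_untruncated_mean(params.mean_events, r)
    p = r / (r + mu)
    while True:
        n = int(rng.negative_binomial(r, p))
        if n > 0:
            return n


def _boundary_weights(word, n_boundaries: int, smap: SegmentMap, site_weights) -> np.ndarray:
    w = np.ones(n_boundaries)
    if site_weights:
        for b in range(n_boundaries):
            seg = word[min(b, len(word) - 1)][0]
            w[b] = float(site_weights.get(seg, 1.0))
    return w / w.sum()


def _sample_junctions(
    kind: str,
    structure: ChromosomeStructure,
    smap: SegmentMap,
    rng: np.random.Generator,
    site_weights=None,
    span_geometric_mean: float | None = None,
    telomere_proximal: float | None = None,
) -> tuple[int, int]:
    """Draw a junction pair for one event.

    Circularization junctions sit geometrically close to the two telomeres
    (circles form by a single intramolecular event between sites near the
    chromosome ends), giving large interiors; ``telomere_proximal`` is the
    mean distance in segments (``None`` = uniform pairs).  For
    deletion/inversion/duplication a geometric span length (mean
    ``span_geometric_mean`` segments) models the distance decay of
    intramolecular recombination between loxPsym sites; ``None`` falls back
    to uniform pairs.
    """
    L = len(structure.word)
    local = span_geometric_mean is not None and kind != "circularization"
    if kind == "circularization" and telomere_proximal is not None:
        while True:
            i = min(int(rng.geometric(1.0 / telomere_proximal)), L)
            j = L + 2 - min(int(rng.geometric(1.0 / telomere_proximal)), L)
            if i < j:
                return (i, j)
    if structure.is_circular:
        if L < 2:
            raise ValueError("no valid junction pairs on a circular word of length < 2")
        w = _boundary_weights(structure.word, L, smap, site_weights)
        i = 1 + int(rng.choice(L, p=w))
        if local:
            while True:
                s = int(rng.geometric(1.0 / span_geometric_mean))
                if s % L != 0:
                    return (i, 1 + (i - 1 + s) % L)
        while True:
            j = 1 + int(rng.choice(L, p=w))
            if j != i:
                return (i, j)
    n_bound = L + 1
    w = _boundary_weights(structure.word, n_bound, smap, site_weights)
    if local:
        while True:
            i = 1 + int(rng.choice(n_bound, p=w))
            s = int(rng.geometric(1.0 / span_geometric_mean))
            lo, hi = (i, i + s) if rng.random() < 0.5 else (i - s, i)
            if 1 <= lo < hi <= n_bound:
                return (lo, hi)
    while True:
        i = 1 + int(rng.choice(n_bound, p=w))
        j = 1 + int(rng.choice(n_bound, p=w))
        if i != j:
            return (min(i, j), max(i, j))


# ---------------------------------------------------------------------------
# strain-level simulation
# ---------------------------------------------------------------------------


def _sample_viable_event(
    kind: str,
    structure: ChromosomeStructure,
    smap: SegmentMap,
    rng: np.random.Generator,
    site_weights=None,
    span_geometric_mean: float | None = None,
    telomere_proximal: float | None = None,
    max_draws: int = 300,
) -> ScrambleEvent:
    """Draw junctions for one event, conditioned on a viable product.

    Deletion and circularization products that lose the centromere or the
    marker segment are never recovered under selection, so their junction
    pairs are redrawn until the product passes the selection filter; the
    observed events of a selected strain are thereby conditioned on
    viability.  Inversions and duplications never destroy content.
    """
    for _ in range(max_draws):
        junc = _sample_junctions(
            kind, structure, smap, rng, site_weights, span_geometric_mean, telomere_proximal
        )
        span, pre, post = _span_slice(structure.word, *junc, structure.is_circular)
        if kind == "deletion":
            if len(span) == len(structure.word):
                continue  # excising everything leaves no molecule
            kept = {i for i, _ in pre} | {i for i, _ in post}
            if not all(r in kept for r in smap.required_ids):
                continue
        elif kind == "circularization":
            interior = {i for i, _ in span}
            if not all(r in interior for r in smap.required_ids):
                continue
        return ScrambleEvent(kind, junc, tuple(span))
    raise RuntimeError(f"no viable {kind} junctions found within {max_draws} draws")


def simulate_strain(
    smap: SegmentMap,
    params: SimParams,
    rng: np.random.Generator,
    strain_id: str = "strain",
) -> StrainRecord:
    """Simulate one SCRaMbLEd strain passing selection.

    A strain optionally circularizes first (per-strain Bernoulli), then
    receives a zero-truncated-NB number of events with types drawn from the
    configured multinomial and uniformly chosen viability-valid junction
    pairs.  Whole attempts are rejection-sampled (cap
    ``params.rejection_cap``) as a safety net; with viability-conditioned
    junctions the selection filter passes by construction.
    """
    ref = reference_structure(smap)
    kinds = ("deletion", "inversion", "duplication")
    probs = np.asarray(params.event_type_probs, dtype=float)

    for _ in range(params.rejection_cap):
        structure = ref
        events: list[ScrambleEvent] = []
        ok = True
        try:
            if rng.random() < params.circularization_prob:
                ev = _sample_viable_event(
                    "circularization", structure, smap, rng, params.site_weights,
                    telomere_proximal=params.telomere_proximal_circ,
                )
                structure = apply_event(structure, ev)
                events.append(ev)
            n_events = _draw_event_count(params, rng)
            for _ in range(n_events):
                if len(structure.word) < (2 if structure.is_circular else 1):
                    ok = False
                    break
                kind = kinds[int(rng.choice(3, p=probs))]
                ev = _sample_viable_event(
                    kind, structure, smap, rng, params.site_weights, params.span_geometric_mean
                )
                structure = apply_event(structure, ev)
                events.append(ev)
        except RuntimeError:
            ok = False
        if not ok or not structure.word:
            continue
        if selection_filter(structure, smap):
            return StrainRecord(
                strain_id=strain_id,
                structure=structure,
                events=tuple(events),
                retained_fraction=retained_fraction(structure, smap),
            )
    raise RuntimeError(
        f"rejection cap exceeded: no viable strain within {params.rejection_cap} attempts"
    )


def assign_fitness(
    strain: StrainRecord, params: SimParams, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Assign a latent growth-recovery rate and colony-size sample.

    R = beta0 + beta_mass * (1 - retained_fraction)
        + beta_region * 1[causal region fully deleted] + Normal(0, noise_sd),
    clamped at ``recovery_floor``.  Colony diameters are drawn around the
    implied mean (reference size scaled by 1 + R/100) with the configured CV.
    """
    present = {i for i, _ in strain.structure.word}
    region_deleted = bool(params.causal_region) and all(
        c not in present for c in params.causal_region
    )
    r_latent = (
        params.beta0
        + params.beta_mass * (1.0 - strain.retained_fraction)
        + (params.beta_region if region_deleted else 0.0)
        + rng.normal(0.0, params.noise_sd)
    )
    r_latent = max(r_latent, params.recovery_floor)
    mean_mm = params.ref_colony_mm * (1.0 + r_latent / 100.0)
    sizes = rng.normal(mean_mm, params.colony_cv * mean_mm, size=params.n_colonies)
    sizes = np.clip(sizes, 0.05, None)
    strain.recovery_rate_pct = float(r_latent)
    strain.colony_sizes_mm = sizes
    return float(r_latent), sizes


def reference_colony_sizes(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Colony-size sample for the unSCRaMbLEd disome parent (the Sr sample)."""
    sizes = rng.normal(
        params.ref_colony_mm, params.colony_cv * params.ref_colony_mm, size=params.n_colonies
    )
    return np.clip(sizes, 0.05, None)


def simulate_population(
    smap: SegmentMap,
    params: SimParams,
    n_strains: int = 219,
    rng: np.random.Generator | None = None,
) -> list[StrainRecord]:
    """Simulate a selected population of SCRaMbLEd disomic strains.

    Each strain is drawn independently via :func:`simulate_strain` and
    :func:`assign_fitness`.  ``round(trisomy_fraction * n_strains)`` strains
    are flagged as whole-genome-duplication escapees (structure unaffected;
    the flag drives the 2:1 read-ratio anomaly downstream).
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    width = len(str(n_strains))
    records = []
    for k in range(n_strains):
        rec = simulate_strain(smap, params, rng, strain_id=f"scr{k + 1:0{width}d}")
        assign_fitness(rec, params, rng)
        records.append(rec)
    n_tri = int(round(params.trisomy_fraction * n_strains))
    if n_tri > 0:
        for idx in rng.choice(n_strains, size=n_tri, replace=False):
            records[int(idx)].trisomy_flag = True
    return records


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth-curve generator settings (Bioscreen-style readout)."""

    od0: float = 0.01
    capacity: float = 2.0
    noise_sd: float = 0.0  # multiplicative log-normal noise, sd on log-OD
    t_end_min: float = 2880.0
    grid_min: float = 20.0


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 readings on a uniform time grid (minutes)."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("time grid must be uniform")
        if np.any(od <= 0):
            raise ValueError("OD readings must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)


def simulate_growth_curve(
    doubling_time_min: float,
    params: GrowthParams = GrowthParams(),
    rng: np.random.Generator | None = None,
) -> GrowthCurve:
    """Logistic OD600 trajectory with the requested exponential-phase doubling time.

    OD(t) = K * OD0 * e^{rt} / (K + OD0 (e^{rt} - 1)) with r = ln2 / DT,
    sampled every 20 min for 48 h from ~0.01 OD, optionally with
    multiplicative noise.
    """
    if doubling_time_min <= 0:
        raise ValueError("doubling time must be positive")
    p = params
    t = np.arange(0.0, p.t_end_min + 0.5 * p.grid_min, p.grid_min)
    r = math.log(2.0) / doubling_time_min
    e = np.exp(np.minimum(r * t, 700.0))
    od = p.capacity * p.od0 * e / (p.capacity + p.od0 * (e - 1.0))
    if p.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        od = od * np.exp(rng.normal(0.0, p.noise_sd, size=od.shape))
    return GrowthCurve(times=t, od=od)
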