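"""Adjacency graphs, traversal enumeration, and event decomposition."""

import numpy as np
import pytest

from synscramble import (
    DepthParams,
    ScrambleEvent,
    SimParams,
    apply_event,
    build_graph,
    canonical_form,
    classify_population,
    estimate_copy_numbers,
    generate_evidence,
    infer_structures,
    min_event_distance,
    reference_structure,
    replay_events,
    simulate_population,
)
from synscramble.reconstruct import EventDecomposition, ReconstructionError
from synscramble.scramble_sim import StrainRecord
from conftest import linear, circular


def _evidence(structure, smap, rng):
    return generate_evidence(StrainRecord("s", structure, (), 1.0), smap,
                             DepthParams(noise=False), rng)


# ---------------------------------------------------------------------------
# build_graph / infer_structures
# ---------------------------------------------------------------------------

def test_deletion_case_unique_traversal(smap6, rng):
    ev = _evidence(linear("A", "B", "D", "E", "F"), smap6, rng)
    g = build_graph(ev, smap6)
    out = infer_structures(g, smap6, topology_hint="linear")
    assert out == [linear("A", "B", "D", "E", "F")]


def test_reference_evidence_reference_traversal(smap6, rng):
    ev = _evidence(reference_structure(smap6), smap6, rng)
    out = infer_structures(build_graph(ev, smap6), smap6, topology_hint="linear")
    assert out == [canonical_form(reference_structure(smap6), smap6)]


def test_inversion_case_admitted(smap6, rng):
    target = linear("A", "-C", "-B", "D", "E", "F")
    ev = _evidence(target, smap6, rng)
    out = infer_structures(build_graph(ev, smap6), smap6, topology_hint="linear")
    assert canonical_form(target, smap6) in out


def test_duplication_case_ranked_first(smap6, rng):
    target = linear("A", "B", "B", "C", "D", "E", "F")
    ev = _evidence(target, smap6, rng)
    out = infer_structures(build_graph(ev, smap6), smap6, topology_hint="linear")
    assert out[0] == canonical_form(target, smap6)


def test_conflicting_junction_recorded(smap6, rng):
    ev = _evidence(linear("A", "B", "D", "E", "F"), smap6, rng)
    # splice in a junction touching the deleted segment C
    bogus = ((("B", "R"), ("C", "L"), 5),)
    ev2 = type(ev)(
        segment_ids=ev.segment_ids,
        depths=ev.depths,
        baseline_depth=ev.baseline_depth,
        junctions=ev.junctions + bogus,
        wt_reads=ev.wt_reads,
        syn_reads=ev.syn_reads,
        topology_hint=ev.topology_hint,
    )
    g = build_graph(ev2, smap6)
    assert len(g.graph["conflicts"]) == 1
    assert g.graph["conflicts"][0][3] == "junction references zero-copy segment"


def test_unresolvable_evidence_raises(smap6, rng):
    ev = _evidence(linear("A", "B", "C", "D", "E", "F"), smap6, rng)
    # drop every junction: no traversal can explain a 6-segment chromosome
    ev2 = type(ev)(
        segment_ids=ev.segment_ids,
        depths=ev.depths,
        baseline_depth=ev.baseline_depth,
        junctions=(),
        wt_reads=ev.wt_reads,
        syn_reads=ev.syn_reads,
        topology_hint="linear",
    )
    with pytest.raises(ReconstructionError, match="unresolvable"):
        infer_structures(build_graph(ev2, smap6), smap6, topology_hint="linear")


def test_noise_free_recovery_random_small_scrambles(smap6):
    """True structure is always among the candidates for <= 3-event strains
    on a six-segment map (200/200 noise-free cases)."""
    rng = np.random.default_rng(77)
    params = SimParams(mean_events=2.0, circularization_prob=0.5)
    found = 0
    cases = 0
    while cases < 200:
        pop = simulate_population(smap6, params, 25, rng)
        for rec in pop:
            if cases >= 200:
                break
            if len(rec.events) > 3:
                continue
            cases += 1
            ev = generate_evidence(rec, smap6, DepthParams(noise=False), rng)
            out = infer_structures(build_graph(ev, smap6), smap6,
                                   topology_hint=ev.topology_hint)
            if canonical_form(rec.structure, smap6) in out:
                found += 1
    assert found == 200


# ---------------------------------------------------------------------------
# min_event_distance
# ---------------------------------------------------------------------------

def test_identity_distance_zero(smap6):
    ref = reference_structure(smap6)
    d = min_event_distance(ref, ref, smap6)
    assert d.k == 0 and d.is_minimal and d.events == ()


def test_single_deletion_distance(smap6):
    ref = reference_structure(smap6)
    d = min_event_distance(ref, linear("A", "B", "D", "E", "F"), smap6)
    assert d.k == 1 and d.is_minimal
    assert d.events[0].kind == "deletion"


def test_single_inversion_distance(smap6):
    ref = reference_structure(smap6)
    d = min_event_distance(ref, linear("A", "-C", "-B", "D", "E", "F"), smap6)
    assert d.k == 1 and d.is_minimal
    assert d.events[0].kind == "inversion"


def test_decomposition_replay_identity(smap6, default_map):
    """Replaying any returned decomposition reproduces the target canonically."""
    for smap, n_strains in ((smap6, 60), (default_map, 40)):
        rng = np.random.default_rng(13)
        pop = simulate_population(smap, SimParams(), n_strains, rng)
        ref = reference_structure(smap)
        for rec in pop:
            d = min_event_distance(ref, rec.structure, smap)
            replayed = replay_events(ref, d.events)
            assert canonical_form(replayed, smap) == canonical_form(rec.structure, smap)
            # parsimony never exceeds the applied history length
            assert d.k <= len(rec.events) or not d.is_minimal


def test_single_event_round_trip_kinds(smap6, rng):
    """One applied event decomposes to exactly one event of the same kind."""
    ref = reference_structure(smap6)
    cases = [
        ScrambleEvent("deletion", (2, 3)),
        ScrambleEvent("inversion", (2, 5)),
        ScrambleEvent("duplication", (3, 5)),
        ScrambleEvent("circularization", (2, 6)),
    ]
    for ev in cases:
        target = apply_event(ref, ev)
        d = min_event_distance(ref, target, smap6)
        assert d.k == 1
        assert d.events[0].kind == ev.kind


# ---------------------------------------------------------------------------
# classify_population
# ---------------------------------------------------------------------------

def _decomp(*kinds):
    events = tuple(ScrambleEvent(k, (1, 2)) for k in kinds)
    return EventDecomposition(events, len(events), True, "greedy")


def test_classify_fraction_counting():
    out = classify_population([_decomp("deletion", "deletion"), _decomp("inversion")])
    assert out.fractions["deletion"] == pytest.approx(2 / 3)
    assert out.per_strain_counts == (2, 1)
    assert out.circular_fraction == 0.0


def test_classify_identity_population():
    out = classify_population([_decomp(), _decomp()])
    assert out.mean_events == 0.0
    assert all(v == 0.0 for v in out.fractions.values())


def test_classify_circular_fraction_and_topology_split():
    out = classify_population(
        [_decomp("circularization", "deletion"), _decomp("inversion")]
    )
    assert out.circular_fraction == pytest.approx(0.5)
    assert out.by_topology["circular"]["deletion"] == 1.0
    assert out.by_topology["linear"]["inversion"] == 1.0
    with pytest.raises(ValueError):
        classify_population([])
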