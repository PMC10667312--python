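"""Event application, selection, strain/population simulation, growth curves."""

from collections import Counter

import numpy as np
import pytest

from synscramble import (
    GrowthParams,
    ScrambleEvent,
    SimParams,
    apply_event,
    doubling_time,
    reference_structure,
    replay_events,
    selection_filter,
    simulate_growth_curve,
    simulate_population,
    simulate_strain,
    canonical_form,
)
from synscramble.scramble_sim import _draw_event_count, StrainRecord, assign_fitness
from conftest import linear, circular


REF5 = linear("A", "B", "C", "D", "E")


# ---------------------------------------------------------------------------
# apply_event
# ---------------------------------------------------------------------------


def test_deletion_removes_span():
    assert apply_event(REF5, ScrambleEvent("deletion", (3, 4))) == linear("A", "B", "D", "E")


def test_inversion_reverses_and_flips():
    out = apply_event(REF5, ScrambleEvent("inversion", (2, 4)))
    assert out == linear("A", "-C", "-B", "D", "E")


def test_duplication_inserts_tandem_copy():
    out = apply_event(REF5, ScrambleEvent("duplication", (4, 5)))
    assert out == linear("A", "B", "C", "D", "D", "E")


def test_inversion_is_involution():
    ev = ScrambleEvent("inversion", (2, 5))
    assert apply_event(apply_event(REF5, ev), ev) == REF5


def test_circularization_keeps_interior_and_locks():
    out = apply_event(REF5, ScrambleEvent("circularization", (2, 5)))
    assert out == circular("B", "C", "D")
    with pytest.raises(ValueError, match="circular"):
        apply_event(out, ScrambleEvent("circularization", (1, 2)))


@pytest.mark.parametrize("junctions", [(0, 2), (2, 2), (3, 7), (6, 8)])
def test_junctions_out_of_range(junctions):
    with pytest.raises(ValueError):
        apply_event(REF5, ScrambleEvent("deletion", junctions))


def test_multiset_conservation(rng):
    """Inversion preserves the segment multiset; deletion only removes;
    duplication adds one copy of a contiguous run."""
    s = REF5
    for _ in range(80):
        L = len(s.word)
        if L < 2:
            s = REF5
            continue
        kind = rng.choice(["deletion", "inversion", "duplication"])
        if s.is_circular:
            i, j = (int(x) for x in rng.choice(np.arange(1, L + 1), 2, replace=False))
        else:
            i, j = sorted(int(x) for x in rng.choice(np.arange(1, L + 2), 2, replace=False))
        before = Counter(i_ for i_, _ in s.word)
        out = apply_event(s, ScrambleEvent(kind, (i, j)))
        after = Counter(i_ for i_, _ in out.word)
        if kind == "inversion":
            assert after == before
        elif kind == "deletion":
            assert all(after[k] <= before[k] for k in before)
        else:
            added = after - before
            assert sum(added.values()) >= 1
        if out.word:
            s = out


# ---------------------------------------------------------------------------
# selection filter
# ---------------------------------------------------------------------------


def test_selection_filter(smap6):
    assert selection_filter(reference_structure(smap6), smap6)
    assert not selection_filter(linear("A", "B", "D", "E", "F"), smap6)  # no CEN
    assert not selection_filter(linear("A", "B", "C", "E", "F"), smap6)  # no marker
    # minimal circular survivor: centromere-adjacent content only
    assert selection_filter(circular("C", "D"), smap6)


# ---------------------------------------------------------------------------
# strain simulation
# ---------------------------------------------------------------------------


def test_zero_mean_events_returns_reference(smap6):
    params = SimParams(mean_events=0.0, circularization_prob=0.0)
    rec = simulate_strain(smap6, params, np.random.default_rng(3))
    assert rec.structure == reference_structure(smap6)
    assert rec.events == ()
    assert rec.retained_fraction == 1.0


def test_mean_events_between_zero_and_one_rejected():
    with pytest.raises(ValueError, match="zero-truncated"):
        SimParams(mean_events=0.5)


def test_fixed_seed_reproducibility(smap6):
    params = SimParams()
    a = simulate_strain(smap6, params, np.random.default_rng(42))
    b = simulate_strain(smap6, params, np.random.default_rng(42))
    assert a.structure == b.structure
    assert a.events == b.events


def test_event_replay_identity_and_viability(default_map):
    params = SimParams()
    pop = simulate_population(default_map, params, 60, np.random.default_rng(5))
    ref = reference_structure(default_map)
    for rec in pop:
        assert selection_filter(rec.structure, default_map)
        replayed = replay_events(ref, rec.events)
        assert canonical_form(replayed, default_map) == canonical_form(
            rec.structure, default_map
        )
        # circular structures never revert to linear
        if any(e.kind == "circularization" for e in rec.events):
            assert rec.structure.is_circular


def test_zero_truncated_event_counts():
    params = SimParams()
    rng = np.random.default_rng(7)
    draws = [_draw_event_count(params, rng) for _ in range(4000)]
    assert min(draws) >= 1
    assert np.mean(draws) == pytest.approx(4.42, abs=0.15)


def test_retention_decreases_with_event_budget(default_map):
    """Deletion-only simulation: more events, less retained content."""
    means = []
    for budget in (2.0, 4.42, 9.0):
        params = SimParams(
            event_type_probs=(1.0, 0.0, 0.0),
            mean_events=budget,
            circularization_prob=0.0,
        )
        pop = simulate_population(default_map, params, 300, np.random.default_rng(17))
        means.append(np.mean([r.retained_fraction for r in pop]))
    assert means[0] > means[1] > means[2]


# ---------------------------------------------------------------------------
# fitness model
# ---------------------------------------------------------------------------


def test_fitness_formula_noise_free(smap6):
    params = SimParams(noise_sd=0.0, causal_region=("E",))
    full = StrainRecord("s", reference_structure(smap6), (), 1.0)
    r, sizes = assign_fitness(full, params, np.random.default_rng(0))
    assert r == pytest.approx(params.beta0)
    assert len(sizes) == params.n_colonies

    lost = StrainRecord("t", linear("A", "B", "C", "D", "F"), (), 0.75)
    r2, _ = assign_fitness(lost, params, np.random.default_rng(0))
    assert r2 == pytest.approx(params.beta0 + params.beta_mass * 0.25 + params.beta_region)


def test_retention_recovery_negatively_correlated(default_map):
    """Mass-action dosage term drives a negative retention-recovery trend."""
    from scipy.stats import pearsonr
    from synscramble.segment_model import causal_region_ids

    params = SimParams(causal_region=causal_region_ids(default_map))
    neg = 0
    n_rep = 40
    for k in range(n_rep):
        pop = simulate_population(default_map, params, 219, np.random.default_rng(100 + k))
        r, _ = pearsonr(
            [p.retained_fraction for p in pop], [p.recovery_rate_pct for p in pop]
        )
        neg += r < 0
    assert neg >= 0.95 * n_rep


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


def test_population_contracts(default_map):
    params = SimParams(trisomy_fraction=3 / 219)
    pop = simulate_population(default_map, params, 219, np.random.default_rng(9))
    assert len(pop) == 219
    assert sum(r.trisomy_flag for r in pop) == 3
    circ_frac = np.mean([r.structure.is_circular for r in pop])
    assert abs(circ_frac - params.circularization_prob) <= 0.05


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def test_growth_curve_contract():
    curve = simulate_growth_curve(120.0)
    assert curve.od[0] == pytest.approx(0.01)
    assert curve.times[0] == 0.0 and curve.times[-1] == 2880.0
    assert np.all(np.diff(curve.times) == 20.0)
    est = doubling_time(curve)
    assert est.dt_min == pytest.approx(120.0, abs=1.0)


def test_growth_curve_saturates_within_48h():
    p = GrowthParams()
    curve = simulate_growth_curve(180.0, p)
    assert curve.od[-1] >= 0.95 * p.capacity


def test_growth_curve_rejects_nonpositive_dt():
    with pytest.raises(ValueError):
        simulate_growth_curve(0.0)
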