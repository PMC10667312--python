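"""Segment maps, structure words, canonical forms and retention statistics."""

import itertools

import numpy as np
import pytest

from synscramble import (
    ChromosomeStructure,
    Segment,
    SegmentMap,
    SimParams,
    canonical_form,
    load_segment_map,
    preservation_profile,
    retained_fraction,
    simulate_population,
    synthetic_map,
    write_segment_map,
)
from synscramble.scramble_sim import StrainRecord
from conftest import linear, circular


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def test_load_three_row_map(tmp_path):
    p = tmp_path / "map.tsv"
    p.write_text(
        "#chrom\tstart\tend\tid\tflags\tgenes\n"
        "chr\t0\t100\tA\t.\t.\n"
        "chr\t100\t250\tB\tcentromere\t.\n"
        "chr\t250\t400\tC\t.\tg1;g2\n"
    )
    smap = load_segment_map(p)
    assert len(smap) == 3
    assert smap.total_length_bp == 400
    assert smap.centromere.id == "B"
    assert smap.get("C").genes == ("g1", "g2")
    assert [s.arm for s in smap] == ["left", "centromeric", "right"]


def test_roundtrip_write_load(tmp_path, smap6):
    p = tmp_path / "map.tsv"
    write_segment_map(smap6, p)
    assert load_segment_map(p) == smap6


def test_synthetic_map_full_scale(default_map):
    assert len(default_map) == 40
    assert default_map.total_length_bp == 1_028_952
    assert sum(len(s.genes) for s in default_map) == 563
    assert default_map.marker_segment.id == "S21"
    assert default_map.index(default_map.centromere.id) + 1 == default_map.index("S21")
    # deterministic
    assert synthetic_map() == default_map


@pytest.mark.parametrize(
    "rows, message",
    [
        (["chr\t0\t100\tA\t.\t.", "chr\t90\t200\tB\tcentromere\t."], "overlap"),
        (["chr\t0\t100\tA\t.\t.", "chr\t120\t200\tB\tcentromere\t."], "gap"),
        (["chr\t0\t100\tA\tcentromere\t.", "chr\t100\t200\tA\t.\t."], "duplicate"),
        (["chr\t0\t100\tA\t.\t.", "chr\t100\t200\tB\t.\t."], "centromere"),
    ],
)
def test_load_invalid_maps(tmp_path, rows, message):
    p = tmp_path / "bad.tsv"
    p.write_text("\n".join(rows) + "\n")
    with pytest.raises(ValueError, match=message):
        load_segment_map(p)


def test_structure_line_and_json_roundtrip():
    s = circular("A", "-C", "-B", "D")
    assert ChromosomeStructure.from_line(s.to_line()) == s
    assert ChromosomeStructure.from_json(s.to_json()) == s


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------


def test_canonical_rotation_and_mirror_equivalence():
    base = circular("A", "B", "C")
    rotated = circular("B", "C", "A")
    mirrored = circular("-C", "-B", "-A")
    assert canonical_form(base) == canonical_form(rotated) == canonical_form(mirrored)


def test_canonical_examples():
    assert canonical_form(linear("A", "B")) == linear("A", "B")
    assert canonical_form(circular("B", "-A")) == circular("A", "-B")


def test_canonical_exhaustive_small_words():
    """Idempotence and full rotation/mirror invariance for words of length <= 4."""
    ids = ["A", "B", "C", "D"]
    for n in (1, 2, 3, 4):
        for subset in itertools.combinations(ids, n):
            for signs in itertools.product((1, -1), repeat=n):
                word = tuple(zip(subset, signs))
                for topology in ("linear", "circular"):
                    s = ChromosomeStructure(topology, word)
                    c = canonical_form(s)
                    assert canonical_form(c) == c  # idempotent
                    variants = [word, tuple((i, -g) for i, g in reversed(word))]
                    if topology == "circular":
                        variants = [
                            v[r:] + v[:r] for v in variants for r in range(n)
                        ]
                    for v in variants:
                        assert canonical_form(ChromosomeStructure(topology, v)) == c


def test_canonical_empty_word_errors():
    with pytest.raises(ValueError):
        canonical_form(ChromosomeStructure("linear", ()))


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------


def test_retained_fraction_cases():
    smap = SegmentMap(
        [
            Segment("A", 10_000),
            Segment("CEN", 5_000, is_centromere=True, arm="centromeric"),
            Segment("B", 85_000, arm="right"),
        ]
    )
    full = linear("A", "CEN", "B")
    assert retained_fraction(full, smap) == 1.0
    assert retained_fraction(linear("CEN"), smap) == pytest.approx(0.05)
    # duplicates never push above 1
    assert retained_fraction(linear("A", "A", "CEN", "B"), smap) == 1.0
    assert retained_fraction(linear("CEN"), smap, weighting="segments") == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        retained_fraction(linear("Z"), smap)


def test_retained_fraction_event_invariances(smap6, rng):
    """Deletion is monotone non-increasing; inversion/duplication leave it fixed."""
    from synscramble import apply_event, reference_structure
    from synscramble.scramble_sim import ScrambleEvent

    s = reference_structure(smap6)
    for _ in range(50):
        L = len(s.word)
        if L < 2:
            break
        i, j = sorted(rng.choice(np.arange(1, L + 2), size=2, replace=False).tolist())
        before = retained_fraction(s, smap6)
        kind = rng.choice(["deletion", "inversion", "duplication"])
        nxt = apply_event(s, ScrambleEvent(kind, (int(i), int(j))))
        after = retained_fraction(nxt, smap6) if nxt.word else 0.0
        if kind == "deletion":
            assert after <= before + 1e-12
        else:
            assert after == pytest.approx(before)
        if nxt.word:
            s = nxt


# ---------------------------------------------------------------------------
# preservation profiles
# ---------------------------------------------------------------------------


def test_preservation_profile_counting(smap6):
    strains = [
        linear("A", "B", "C", "D", "E", "F"),
        linear("A", "C", "D", "E", "F"),
        linear("C", "D", "F"),
    ]
    prof = preservation_profile(strains, smap6)
    assert prof["A"] == pytest.approx(2 / 3)
    assert prof["B"] == pytest.approx(1 / 3)
    assert prof["C"] == 1.0
    with pytest.raises(ValueError):
        preservation_profile([], smap6)


def test_preservation_all_unscrambled(smap6):
    from synscramble import reference_structure

    recs = [
        StrainRecord(f"s{i}", reference_structure(smap6), (), 1.0) for i in range(5)
    ]
    assert (preservation_profile(recs, smap6) == 1.0).all()


def test_preservation_hotspot_from_weighted_deletions(default_map):
    """Elevated right-arm site weights carve a visible deletion hotspot."""
    right = {s.id: 12.0 for s in default_map if s.arm == "right" and s.marker is None}
    params = SimParams(
        event_type_probs=(1.0, 0.0, 0.0),
        mean_events=3.0,
        circularization_prob=0.0,
        site_weights=right,
    )
    pop = simulate_population(default_map, params, 150, np.random.default_rng(11))
    prof = preservation_profile(pop, default_map)
    left = np.mean([prof[s.id] for s in default_map if s.arm == "left"])
    right_mean = np.mean(
        [prof[s.id] for s in default_map if s.arm == "right" and s.marker is None]
    )
    assert right_mean < left - 0.05
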