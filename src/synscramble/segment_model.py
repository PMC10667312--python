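"""Reference chromosome model: loxPsym-delimited segments and rearranged structures.

An Sc2.0-style synthetic chromosome is partitioned by loxPsym sites into an
ordered run of segments.  A SCRaMbLEd derivative is described by a *structure
word*: an ordered list of signed segment occurrences (sign encodes strand
orientation) together with a topology, linear or circular.  This module holds
the reference map, structure words and their canonical forms, retention
statistics, and the plain-text I/O for both.

Coordinates follow BED convention (0-based, half-open) in segment-map files;
word and junction positions used elsewhere in the package are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ARMS = ("left", "right", "centromeric")

__all__ = [
    "Segment",
    "SegmentMap",
    "ChromosomeStructure",
    "reference_structure",
    "canonical_form",
    "retained_fraction",
    "preservation_profile",
    "load_segment_map",
    "write_segment_map",
    "synthetic_map",
]


@dataclass(frozen=True)
class Segment:
    """One inter-loxPsym interval of the reference chromosome."""

    id: str
    length_bp: int
    genes: tuple[str, ...] = ()
    is_centromere: bool = False
    marker: str | None = None
    arm: str = "left"

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"segment {self.id!r}: length_bp must be >= 1")
        if self.arm not in ARMS:
            raise ValueError(f"segment {self.id!r}: arm must be one of {ARMS}")


class SegmentMap:
    """Ordered segments of the reference chromosome, left telomere to right.

    Exactly one segment must be flagged as the centromere.  At most one
    segment carries the selection marker kept under dual auxotrophic
    selection (e.g. *LEU2* adjacent to *CEN7*).
    """

    def __init__(self, segments: Iterable[Segment]):
        self.segments: tuple[Segment, ...] = tuple(segments)
        if not self.segments:
            raise ValueError("segment map must contain at least one segment")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate segment ids: {dupes}")
        cens = [s for s in self.segments if s.is_centromere]
        if len(cens) != 1:
            raise ValueError(
                f"segment map must contain exactly one centromere segment, found {len(cens)}"
            )
        self._index = {s.id: i + 1 for i, s in enumerate(self.segments)}  # 1-based

    # -- basic container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, SegmentMap) and self.segments == other.segments

    def get(self, seg_id: str) -> Segment:
        try:
            return self.segments[self._index[seg_id] - 1]
        except KeyError:
            raise ValueError(f"unknown segment id: {seg_id!r}") from None

    def index(self, seg_id: str) -> int:
        """1-based position of a segment in the reference order."""
        try:
            return self._index[seg_id]
        except KeyError:
            raise ValueError(f"unknown segment id: {seg_id!r}") from None

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.segments)

    @property
    def total_length_bp(self) -> int:
        return sum(s.length_bp for s in self.segments)

    @property
    def centromere(self) -> Segment:
        return next(s for s in self.segments if s.is_centromere)

    @property
    def marker_segment(self) -> Segment | None:
        for s in self.segments:
            if s.marker is not None:
                return s
        return None

    @property
    def required_ids(self) -> tuple[str, ...]:
        """Segments a viable structure must retain (centromere, then marker)."""
        req = [self.centromere.id]
        m = self.marker_segment
        if m is not None and m.id != self.centromere.id:
            req.append(m.id)
        return tuple(req)


@dataclass(frozen=True)
class ChromosomeStructure:
    """A topology plus an ordered word of signed segment occurrences.

    ``word`` entries are ``(segment_id, sign)`` with sign ``+1`` or ``-1``.
    Circular structures are rotation- and mirror-equivalent; use
    :func:`canonical_form` before comparing them.
    """

    topology: str
    word: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be 'linear' or 'circular', got {self.topology!r}")
        object.__setattr__(self, "word", tuple((str(i), int(s)) for i, s in self.word))
        for _, s in self.word:
            if s not in (1, -1):
                raise ValueError("signs must be +1 or -1")

    def __len__(self) -> int:
        return len(self.word)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def segment_ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.word)

    # -- serialization -------------------------------------------------------------
    def to_line(self) -> str:
        body = ",".join(("" if s > 0 else "-") + i for i, s in self.word)
        return f"{self.topology}\t{body}"

    @classmethod
    def from_line(cls, line: str) -> "ChromosomeStructure":
        topology, _, body = line.strip().partition("\t")
        word = []
        if body:
            for tok in body.split(","):
                tok = tok.strip()
                if tok.startswith("-"):
                    word.append((tok[1:], -1))
                else:
                    word.append((tok, 1))
        return cls(topology, tuple(word))

    def to_json(self) -> str:
        return json.dumps({"topology": self.topology, "word": [[i, s] for i, s in self.word]})

    @classmethod
    def from_json(cls, text: str) -> "ChromosomeStructure":
        d = json.loads(text)
        return cls(d["topology"], tuple((i, s) for i, s in d["word"]))


def reference_structure(smap: SegmentMap) -> ChromosomeStructure:
    """The unrearranged linear chromosome: every segment once, forward."""
    return ChromosomeStructure("linear", tuple((s.id, 1) for s in smap))


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------


def _mirror(word: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    return tuple((i, -s) for i, s in reversed(word))


def canonical_form(structure: ChromosomeStructure, smap: SegmentMap | None = None) -> ChromosomeStructure:
    """Canonical representative of a structure word.

    Linear words are equivalent to their reversed-and-sign-flipped mirror
    (reading the molecule from the other end); circular words additionally to
    every rotation.  The canonical form is the lexicographically smallest
    equivalent word under the ordering (segment index, then ``+`` before
    ``-``); without a map, segment ids are compared lexicographically.
    """
    if not structure.word:
        raise ValueError("cannot canonicalize an empty word")

    if smap is not None:
        def key(elem: tuple[str, int]):
            return (smap.index(elem[0]), 0 if elem[1] > 0 else 1)
    else:
        def key(elem: tuple[str, int]):
            return (elem[0], 0 if elem[1] > 0 else 1)

    def word_key(word):
        return tuple(key(e) for e in word)

    w = structure.word
    if structure.topology == "linear":
        best = min(w, _mirror(w), key=word_key)
        return ChromosomeStructure("linear", best)

    candidates = []
    for variant in (w, _mirror(w)):
        for r in range(len(variant)):
            candidates.append(variant[r:] + variant[:r])
    best = min(candidates, key=word_key)
    return ChromosomeStructure("circular", best)


# ---------------------------------------------------------------------------
# retention statistics
# ---------------------------------------------------------------------------


def retained_fraction(
    structure: ChromosomeStructure, smap: SegmentMap, weighting: str = "bp"
) -> float:
    """Fraction of distinct reference segments present at >= 1 copy.

    ``bp`` weighting (default) reports the retained share of chromosome
    content in bases; ``segments`` counts segments.  Duplicate copies never
    raise the value above 1.
    """
    if weighting not in ("bp", "segments"):
        raise ValueError("weighting must be 'bp' or 'segments'")
    present = set()
    for seg_id, _ in structure.word:
        smap.get(seg_id)  # raises on unknown id
        present.add(seg_id)
    if weighting == "bp":
        kept = sum(smap.get(i).length_bp for i in present)
        return kept / smap.total_length_bp
    return len(present) / len(smap)


def _structure_of(item) -> ChromosomeStructure:
    if isinstance(item, ChromosomeStructure):
        return item
    return item.structure


def preservation_profile(population: Sequence, smap: SegmentMap) -> pd.Series:
    """Per-segment preservation frequency across a population of strains.

    For each reference segment, the fraction of strains whose structure word
    contains it at one or more copies.  Output is ordered as the map.
    """
    if len(population) == 0:
        raise ValueError("population must be nonempty")
    counts = np.zeros(len(smap), dtype=float)
    for item in population:
        present = {i for i, _ in _structure_of(item).word}
        for k, seg in enumerate(smap):
            if seg.id in present:
                counts[k] += 1.0
    return pd.Series(counts / len(population), index=list(smap.ids), name="preservation")


# ---------------------------------------------------------------------------
# segment-map file I/O (BED-like TSV)
# ---------------------------------------------------------------------------

_COLUMNS = ["chrom", "start", "end", "id", "flags", "genes"]


def _format_flags(seg: Segment) -> str:
    toks = []
    if seg.is_centromere:
        toks.append("centromere")
    if seg.marker is not None:
        toks.append(f"marker={seg.marker}")
    toks.append(f"arm={seg.arm}")
    return ";".join(toks) if toks else "."


def write_segment_map(smap: SegmentMap, path: str | Path, chrom: str = "synVII") -> None:
    """Write a segment map as BED-like TSV (0-based half-open coordinates)."""
    path = Path(path)
    rows = []
    pos = 0
    for seg in smap:
        rows.append(
            {
                "chrom": chrom,
                "start": pos,
                "end": pos + seg.length_bp,
                "id": seg.id,
                "flags": _format_flags(seg),
                "genes": ";".join(seg.genes) if seg.genes else ".",
            }
        )
        pos += seg.length_bp
    with path.open("w") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in _COLUMNS) + "\n")


def load_segment_map(path: str | Path) -> SegmentMap:
    """Load a segment map from BED-like TSV.

    Columns: chrom, start, end, id, flags, genes.  Flags are semicolon
    separated tokens: ``centromere``, ``marker=NAME``, ``arm=left|right|centromeric``.
    Records must tile the chromosome without gaps or overlaps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_COLUMNS, dtype={"chrom": str, "id": str}
    )
    if df.empty:
        raise ValueError(f"{path}: no records")
    if df["chrom"].nunique() > 1:
        raise ValueError(f"{path}: more than one chromosome in map")
    df = df.sort_values("start", kind="stable").reset_index(drop=True)

    segments = []
    expected = int(df.loc[0, "start"])
    if expected != 0:
        raise ValueError(f"{path}: map must start at coordinate 0, got {expected}")
    for _, row in df.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if end <= start:
            raise ValueError(f"{path}: segment {row['id']!r} has nonpositive length")
        if start < expected:
            raise ValueError(f"{path}: overlapping intervals at segment {row['id']!r}")
        if start > expected:
            raise ValueError(f"{path}: gap before segment {row['id']!r}")
        expected = end

        flags = str(row["flags"]) if not pd.isna(row["flags"]) else "."
        is_cen, marker, arm = False, None, None
        for tok in flags.split(";"):
            tok = tok.strip()
            if tok in (".", ""):
                continue
            if tok == "centromere":
                is_cen = True
            elif tok.startswith("marker="):
                marker = tok.split("=", 1)[1]
            elif tok.startswith("arm="):
                arm = tok.split("=", 1)[1]
            else:
                raise ValueError(f"{path}: unknown flag {tok!r} on segment {row['id']!r}")
        genes_raw = row["genes"]
        genes: tuple[str, ...] = ()
        if not (pd.isna(genes_raw) or str(genes_raw) in (".", "")):
            genes = tuple(g for g in str(genes_raw).split(";") if g)
        segments.append(
            Segment(
                id=str(row["id"]),
                length_bp=end - start,
                genes=genes,
                is_centromere=is_cen,
                marker=marker,
                arm=arm if arm is not None else "left",
            )
        )

    # infer arms from centromere position when the file does not carry them
    cen_idx = [i for i, s in enumerate(segments) if s.is_centromere]
    if len(cen_idx) != 1:
        raise ValueError(f"{path}: map must contain exactly one centromere segment")
    ci = cen_idx[0]
    fixed = []
    for i, s in enumerate(segments):
        arm = s.arm
        if "arm=" not in str(df.loc[i, "flags"]):
            arm = "centromeric" if i == ci else ("left" if i < ci else "right")
        fixed.append(Segment(s.id, s.length_bp, s.genes, s.is_centromere, s.marker, arm))
    return SegmentMap(fixed)


# ---------------------------------------------------------------------------
# synthetic reference map
# ---------------------------------------------------------------------------


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of `total` by `weights` (largest remainder)."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def synthetic_map(
    n_segments: int = 40,
    total_bp: int = 1_028_952,
    seed: int = 7,
    cen_position: int | None = None,
    marker: str = "LEU2",
    causal_position: int | None = None,
    causal_length_bp: int = 20_000,
    cen_length_bp: int = 5_000,
    n_genes: int = 563,
) -> SegmentMap:
    """Build the default synthetic reference chromosome.

    Emulates a ~1 Mb loxPsym-partitioned chromosome: `n_segments` segments
    whose lengths are lognormal-distributed and scaled to exactly
    ``total_bp``; a small centromeric segment near the middle; the selection
    marker on the segment immediately right of the centromere; and one
    mid-right-arm segment of exactly ``causal_length_bp`` that downstream
    defaults treat as the planted causal region (a del20K analogue).
    ``n_genes`` gene labels are apportioned to segments by length.

    The full-scale defaults (40 segments, 1,028,952 bp, 563 genes) are fixed
    by ``seed`` and fully deterministic.
    """
    if n_segments < 3:
        raise ValueError("n_segments must be >= 3")
    cen = (n_segments // 2) if cen_position is None else cen_position  # 1-based
    causal = (int(round(0.75 * n_segments))) if causal_position is None else causal_position
    if not (1 <= cen <= n_segments) or not (1 <= causal <= n_segments):
        raise ValueError("cen/causal positions out of range")
    if causal in (cen, cen + 1):
        raise ValueError("causal segment must not be the centromere or marker segment")

    rng = np.random.default_rng(seed)
    lengths = np.zeros(n_segments, dtype=int)
    lengths[cen - 1] = cen_length_bp
    lengths[causal - 1] = causal_length_bp
    free = [i for i in range(n_segments) if lengths[i] == 0]
    weights = rng.lognormal(mean=0.0, sigma=0.55, size=len(free))
    remaining = total_bp - int(lengths.sum())
    lengths_free = _apportion(remaining, weights)
    # keep every segment a plausible inter-loxPsym distance (>= 2 kb)
    lengths_free = np.maximum(lengths_free, 2_000)
    # re-balance the excess on the largest segment so the total is exact
    excess = int(lengths_free.sum()) - remaining
    lengths_free[int(np.argmax(lengths_free))] -= excess
    for i, L in zip(free, lengths_free):
        lengths[i] = int(L)

    gene_counts = _apportion(n_genes, lengths.astype(float))
    width = len(str(n_segments))
    segs = []
    g = 0
    for i in range(n_segments):
        pos = i + 1
        genes = tuple(f"g{j + 1:04d}" for j in range(g, g + int(gene_counts[i])))
        g += int(gene_counts[i])
        segs.append(
            Segment(
                id=f"S{pos:0{width}d}",
                length_bp=int(lengths[i]),
                genes=genes,
                is_centromere=(pos == cen),
                marker=marker if pos == cen + 1 else None,
                arm="centromeric" if pos == cen else ("left" if pos < cen else "right"),
            )
        )
    return SegmentMap(segs)


def causal_region_ids(smap: SegmentMap, length_bp: int = 20_000) -> tuple[str, ...]:
    """Segments used as the planted causal region: the right-arm segment whose
    length matches ``length_bp`` exactly (as laid down by :func:`synthetic_map`),
    falling back to the right-arm segment closest in length."""
    right = [s for s in smap if s.arm == "right" and s.marker is None]
    if not right:
        raise ValueError("map has no right-arm segments")
    exact = [s for s in right if s.length_bp == length_bp]
    if exact:
        return (exact[0].id,)
    best = min(right, key=lambda s: abs(s.length_bp - length_bp))
    return (best.id,)
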