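"""Sequencing-style observables for simulated strains.

Stage 2 of the synthetic-data generator: turns a strain's true structure
into segment-level evidence the way short-read sequencing of a SCRaMbLEd
disome would see it —

* per-segment read depth of the synthetic homolog, proportional to copy
  number, with optional Poisson noise and a constant circular-recovery
  deficit (circular molecules are recovered ~3x less efficiently during
  library preparation, so all their segments appear at ~1/3 depth);
* the list of oriented segment-end junctions present in the word, each with
  a support count;
* PCRTag-style read counts for the wild-type vs synthetic alleles, whose
  ratio sits at 1:1 for a disome and ~2:1 for a whole-genome-duplication
  (trisomic) escapee.

Evidence is deliberately segment-level; no read-level FASTQ/BAM emulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .segment_model import ChromosomeStructure, SegmentMap
from .scramble_sim import StrainRecord

End = tuple[str, str]  # (segment id, "L"|"R")
Junction = tuple[End, End]

__all__ = [
    "DepthParams",
    "EvidenceSet",
    "word_junctions",
    "generate_evidence",
    "estimate_copy_numbers",
    "flag_ploidy_anomaly",
    "write_evidence",
    "read_evidence",
]


@dataclass(frozen=True)
class DepthParams:
    """Evidence generator settings."""

    baseline: float = 100.0
    circular_recovery_factor: float = 1.0 / 3.0
    junction_rate: float = 20.0
    pcrtag_reads: float = 300.0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline depth must be positive")
        if self.circular_recovery_factor <= 0:
            raise ValueError("circular_recovery_factor must be positive")


@dataclass(frozen=True)
class EvidenceSet:
    """Per-strain sequencing-style observables."""

    segment_ids: tuple[str, ...]
    depths: np.ndarray  # synthetic-homolog depth per segment, map order
    baseline_depth: float
    junctions: tuple[tuple[End, End, int], ...]  # (end_a, end_b, support)
    wt_reads: int
    syn_reads: int
    topology_hint: str = "unknown"  # linear | circular | unknown

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("depths must be finite")
        object.__setattr__(self, "depths", d)
        for _, _, support in self.junctions:
            if support < 1:
                raise ValueError("junction support counts must be >= 1")

    @property
    def wt_syn_ratio(self) -> float:
        if self.syn_reads == 0:
            return float("inf")
        return self.wt_reads / self.syn_reads

    def depth_of(self, seg_id: str) -> float:
        return float(self.depths[self.segment_ids.index(seg_id)])


# ---------------------------------------------------------------------------
# junction bookkeeping
# ---------------------------------------------------------------------------


def _elem_ends(elem: tuple[str, int]) -> tuple[End, End]:
    """(leading end, trailing end) of a signed occurrence."""
    seg, sign = elem
    return ((seg, "L"), (seg, "R")) if sign > 0 else ((seg, "R"), (seg, "L"))


def junction_between(a: tuple[str, int], b: tuple[str, int]) -> Junction:
    """Unordered junction between consecutive occurrences a, b."""
    ta = _elem_ends(a)[1]
    lb = _elem_ends(b)[0]
    return tuple(sorted((ta, lb)))  # type: ignore[return-value]


def word_junctions(structure: ChromosomeStructure) -> dict[Junction, int]:
    """Multiset of adjacency types in a word (wrap pair included for circles)."""
    w = structure.word
    out: dict[Junction, int] = {}
    pairs = list(zip(w, w[1:]))
    if structure.is_circular and len(w) >= 1:
        pairs.append((w[-1], w[0]))
    for a, b in pairs:
        j = junction_between(a, b)
        out[j] = out.get(j, 0) + 1
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_evidence(
    strain: StrainRecord,
    smap: SegmentMap,
    depth_params: DepthParams = DepthParams(),
    rng: np.random.Generator | None = None,
) -> EvidenceSet:
    """Simulate depth/junction/read-ratio evidence for one strain.

    Expected depth per segment is ``baseline x copies x recovery_factor``
    where the recovery factor is ``circular_recovery_factor`` for circular
    molecules and 1 otherwise; Poisson noise applies when ``noise`` is on.
    Junction support is Poisson around ``junction_rate`` per adjacency copy;
    zero-support junctions are unobserved and dropped.
    """
    p = depth_params
    if rng is None:
        rng = np.random.default_rng()
    structure = strain.structure
    rf = p.circular_recovery_factor if structure.is_circular else 1.0

    copies = {s.id: 0 for s in smap}
    for seg, _ in structure.word:
        copies[seg] += 1
    expected = np.array([p.baseline * copies[s.id] * rf for s in smap], dtype=float)
    depths = rng.poisson(expected).astype(float) if p.noise else expected

    junctions = []
    for junc, mult in word_junctions(structure).items():
        if p.noise:
            support = int(rng.poisson(p.junction_rate * mult))
            if support < 1:
                continue
        else:
            support = max(1, int(round(p.junction_rate * mult)))
        junctions.append((junc[0], junc[1], support))
    junctions.sort()

    wt_copies = 2 if strain.trisomy_flag else 1
    syn_copies = 1
    if p.noise:
        wt = int(rng.poisson(p.pcrtag_reads * wt_copies))
        syn = int(rng.poisson(p.pcrtag_reads * syn_copies))
    else:
        wt = int(round(p.pcrtag_reads * wt_copies))
        syn = int(round(p.pcrtag_reads * syn_copies))

    return EvidenceSet(
        segment_ids=smap.ids,
        depths=depths,
        baseline_depth=p.baseline,
        junctions=tuple(junctions),
        wt_reads=wt,
        syn_reads=syn,
        topology_hint=structure.topology,
    )


# ---------------------------------------------------------------------------
# inference on evidence
# ---------------------------------------------------------------------------


def estimate_copy_numbers(evidence: EvidenceSet, smap: SegmentMap) -> pd.Series:
    """Round depths to per-segment integer copy numbers.

    The single-copy depth unit is anchored on the centromere-adjacent
    segments (always retained under selection, so the constant circular
    depth deficit self-normalizes) and then refined by Poisson maximum
    likelihood over all retained segments; because an anchor may itself be
    duplicated, the unit hypotheses anchor-mean / {1, 1.5, 2} and the
    robust median are scored by chi-square and the largest acceptable unit
    (fewest total copies) wins.  ``copies = round(depth / unit)``.
    """
    if evidence.baseline_depth <= 0:
        raise ValueError("baseline depth must be positive")
    depths = pd.Series(evidence.depths, index=list(evidence.segment_ids))
    if float(depths.sum()) == 0.0:
        raise ValueError("all segment depths are zero: no chromosome present")
    anchors = [i for i in smap.required_ids if i in depths.index]
    anchor_depths = depths.loc[anchors]
    anchor_depths = anchor_depths[anchor_depths > 0]
    pos = depths[depths > 0].to_numpy()
    if len(anchor_depths):
        base = float(anchor_depths.mean())
    else:  # selection anchors absent from the depth signal
        base = float(np.median(pos))

    # The anchor mean is 1x, 1.5x or 2x the single-copy unit depending on
    # whether the anchors themselves are duplicated.  Try those hypotheses
    # (plus the robust median), refine each by Poisson ML over all retained
    # segments, score by chi-square, and prefer the largest unit that fits
    # (fewest total copies).
    def refine(u: float) -> tuple[float, float]:
        # residual near-zero depths (zero-copy segments) are excluded from
        # the fit; a candidate explaining fewer than 70% of the retained
        # segments is an aliasing artefact and is rejected outright
        for _ in range(2):
            prov = np.rint(pos / u)
            mask = prov >= 1
            if mask.mean() < 0.7:
                return u, float("inf")
            u = float(pos[mask].sum() / prov[mask].sum())
        prov = np.rint(pos / u)
        mask = prov >= 1
        lam = prov[mask] * u
        chi2 = float(np.mean((pos[mask] - lam) ** 2 / np.maximum(lam, 1.0)))
        return u, chi2

    fits = [refine(u0) for u0 in (base, base / 1.5, base / 2.0, float(np.median(pos)))]
    accepted = [f for f in fits if f[1] < 4.0]
    unit = max(accepted)[0] if accepted else min(fits, key=lambda f: f[1])[0]
    copies = np.rint(depths.values / unit).astype(int)
    return pd.Series(np.clip(copies, 0, None), index=depths.index, name="copies")


def flag_ploidy_anomaly(
    evidence: EvidenceSet, alpha: float = 0.05, fold: float = 1.5
) -> tuple[bool, float]:
    """Exact binomial test of the synthetic-read fraction against 1/2.

    Flags a whole-genome-duplication escapee (wt:syn around 2:1) when the
    two-sided p-value falls below ``alpha`` and the observed major:minor
    ratio is at least ``fold``.  Returns ``(flag, p)``.
    """
    total = evidence.wt_reads + evidence.syn_reads
    if total == 0:
        raise ValueError("no PCRTag reads: cannot test allele ratio")
    p = binomtest(evidence.syn_reads, total, 0.5, alternative="two-sided").pvalue
    lo, hi = sorted((evidence.wt_reads, evidence.syn_reads))
    ratio = float("inf") if lo == 0 else hi / lo
    return (p < alpha and ratio >= fold), float(p)


# ---------------------------------------------------------------------------
# serialization (two TSVs + JSON header)
# ---------------------------------------------------------------------------


def write_evidence(evidence: EvidenceSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"id": evidence.segment_ids, "depth": evidence.depths}).to_csv(
        outdir / "segments.tsv", sep="\t", index=False
    )
    rows = [
        {
            "end_a": f"{a[0]}.{a[1]}",
            "end_b": f"{b[0]}.{b[1]}",
            "support": s,
        }
        for a, b, s in evidence.junctions
    ]
    pd.DataFrame(rows, columns=["end_a", "end_b", "support"]).to_csv(
        outdir / "junctions.tsv", sep="\t", index=False
    )
    header = {
        "baseline_depth": evidence.baseline_depth,
        "wt_reads": evidence.wt_reads,
        "syn_reads": evidence.syn_reads,
        "topology_hint": evidence.topology_hint,
    }
    (outdir / "header.json").write_text(json.dumps(header, indent=2) + "\n")


def _parse_end(tok: str) -> End:
    seg, _, side = tok.rpartition(".")
    if side not in ("L", "R"):
        raise ValueError(f"malformed junction end {tok!r}")
    return (seg, side)


def read_evidence(indir: str | Path) -> EvidenceSet:
    indir = Path(indir)
    seg = pd.read_csv(indir / "segments.tsv", sep="\t", dtype={"id": str})
    jdf = pd.read_csv(indir / "junctions.tsv", sep="\t")
    header = json.loads((indir / "header.json").read_text())
    junctions = tuple(
        (_parse_end(str(r.end_a)), _parse_end(str(r.end_b)), int(r.support))
        for r in jdf.itertuples()
    )
    return EvidenceSet(
        segment_ids=tuple(seg["id"]),
        depths=seg["depth"].to_numpy(dtype=float),
        baseline_depth=float(header["baseline_depth"]),
        junctions=junctions,
        wt_reads=int(header["wt_reads"]),
        syn_reads=int(header["syn_reads"]),
        topology_hint=str(header["topology_hint"]),
    )
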