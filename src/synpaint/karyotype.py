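"""Karyotype curation: chromosome assignment, size classes, scaffold splitting.

Scaffolds are assigned to chromosomes by majority vote over chromosome-linked
marker hits, classified macro/micro by length (macro ≥ 50 Mb, the squamate
convention; micro candidacy requires > 8 Mb), and a scaffold suspected of
fusing two chromosomes is split at a candidate junction showing an abrupt
composition shift — elevated GC and depressed repeat density flanks — picking
the signature-passing junction with the lowest local gene density.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .composition import WindowTrack
from .io import Assembly, HitRecord, SequenceRecord

MACRO_THRESHOLD = 50_000_000  # inclusive lower bound for macro
MICRO_MIN = 8_000_000  # exclusive lower bound for micro candidacy


class AssignmentError(ValueError):
    """No or conflicting chromosome-assignment evidence."""


class SplitError(ValueError):
    """No supported breakpoint for a requested scaffold split."""


@dataclass
class ScaffoldAssignment:
    scaffold: str
    chrom_label: str | None  # final size-ordered label, None when ambiguous
    source_label: str | None  # winning marker chromosome label
    chrom_class: str  # macro / micro / unplaced
    evidence: dict[str, int]
    ambiguous: bool


@dataclass
class ChromosomeAssignment:
    by_scaffold: dict[str, ScaffoldAssignment]
    n_unknown_markers: int = 0

    def label_of(self, scaffold: str) -> str | None:
        return self.by_scaffold[scaffold].chrom_label


@dataclass
class BreakpointCandidate:
    scaffold: str
    position: int
    source: str  # chicago_junction / gap_run / supplied
    delta_gc: float  # signed: mean GC(right flank) - mean GC(left flank)
    delta_repeat: float  # signed, likewise for repeat fraction
    local_gd: float
    shift_score: float = float("nan")  # z(|delta_gc|) + z(|delta_repeat|)
    flagged: bool = False  # scored with fewer than flank_windows on a side
    chosen: bool = False

    @property
    def opposed(self) -> bool:
        """GC and repeat shift in opposite directions across the junction —
        the macro/micro compositional syndrome (elevated GC goes with
        reduced repeat density), required of a real fusion junction."""
        return self.delta_gc * self.delta_repeat < 0


# ---------------------------------------------------------------------------
# assignment and classification


def classify_macro_micro(
    lengths: dict[str, int],
    macro_threshold: int = MACRO_THRESHOLD,
    micro_min: int = MICRO_MIN,
) -> dict[str, str]:
    """Length-based class: ≥ macro_threshold → macro; (micro_min, threshold) →
    micro; ≤ micro_min → unplaced. The macro bound is inclusive, the micro
    candidacy bound exclusive."""
    out = {}
    for scaf, length in lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {scaf}")
        if length >= macro_threshold:
            out[scaf] = "macro"
        elif length > micro_min:
            out[scaf] = "micro"
        else:
            out[scaf] = "unplaced"
    return out


def assign_chromosomes(
    marker_hits: list[HitRecord],
    marker_to_chrom: dict[str, str],
    assembly: Assembly,
    min_votes: int = 2,
    macro_threshold: int = MACRO_THRESHOLD,
    micro_min: int = MICRO_MIN,
) -> ChromosomeAssignment:
    """Assign scaffolds to chromosomes by majority vote of linked-marker hits.

    Each hit votes its marker's source chromosome label onto the scaffold it
    landed on. A scaffold is ambiguous when its top two tallies are equal or
    the top tally is below ``min_votes``. Winning scaffolds are then
    renumbered within each size class by descending length (macro1..n,
    micro1..m). Two source labels whose strongest scaffold coincides raise a
    conflict.
    """
    tallies: dict[str, Counter] = defaultdict(Counter)
    label_scaffold_votes: dict[str, Counter] = defaultdict(Counter)
    unknown = 0
    for h in marker_hits:
        label = marker_to_chrom.get(h.qseqid)
        if label is None:
            unknown += 1
            continue
        tallies[h.sseqid][label] += 1
        label_scaffold_votes[label][h.sseqid] += 1
    if not tallies:
        raise AssignmentError("no assignable evidence: no hits matched known markers")

    lengths = assembly.lengths()
    classes = classify_macro_micro(lengths, macro_threshold, micro_min)
    winners: dict[str, tuple[str | None, bool]] = {}
    for scaf, votes in tallies.items():
        ranked = votes.most_common()
        top_label, top_n = ranked[0]
        tie = len(ranked) > 1 and ranked[1][1] == top_n
        ambiguous = tie or top_n < min_votes
        winners[scaf] = (None if ambiguous else top_label, ambiguous)

    # conflict: a label whose strongest scaffold was unambiguously won by a
    # DIFFERENT label has nowhere to go — the evidence is inconsistent
    # (an evenly split scaffold is merely ambiguous, not a conflict)
    for label, votes in sorted(label_scaffold_votes.items()):
        scaf = votes.most_common(1)[0][0]
        winner, _amb = winners[scaf]
        if winner is not None and winner != label:
            raise AssignmentError(
                f"labels {winner!r} and {label!r} both place their majority "
                f"evidence on scaffold {scaf!r}"
            )

    by_scaffold: dict[str, ScaffoldAssignment] = {}
    for klass in ("macro", "micro"):
        scafs = [
            s
            for s, (label, amb) in winners.items()
            if label is not None and classes.get(s) == klass
        ]
        scafs.sort(key=lambda s: -lengths.get(s, 0))
        for i, scaf in enumerate(scafs, 1):
            label, amb = winners[scaf]
            by_scaffold[scaf] = ScaffoldAssignment(
                scaffold=scaf,
                chrom_label=f"{klass}{i}",
                source_label=label,
                chrom_class=klass,
                evidence=dict(tallies[scaf]),
                ambiguous=amb,
            )
    for scaf, (label, amb) in winners.items():
        if scaf in by_scaffold:
            continue
        by_scaffold[scaf] = ScaffoldAssignment(
            scaffold=scaf,
            chrom_label=None,
            source_label=label,
            chrom_class=classes.get(scaf, "unplaced"),
            evidence=dict(tallies[scaf]),
            ambiguous=amb,
        )
    return ChromosomeAssignment(by_scaffold=by_scaffold, n_unknown_markers=unknown)


# ---------------------------------------------------------------------------
# breakpoint detection and splitting


def find_gap_junctions(record: SequenceRecord, min_gap: int = 50) -> list[int]:
    """Candidate junctions at the midpoints of N runs of at least ``min_gap`` bases."""
    return [
        (m.start() + m.end()) // 2
        for m in re.finditer(rf"N{{{min_gap},}}", record.seq)
    ]


def score_breakpoints(
    scaffold: str,
    candidates: list[int],
    track: WindowTrack,
    flank_windows: int = 3,
) -> list[BreakpointCandidate]:
    """Score candidate junctions on a scaffold by local composition shifts.

    For each candidate, using up to ``flank_windows`` whole windows on each
    side: delta_gc and delta_repeat are the signed differences mean(right
    flank) − mean(left flank); local_gd is the mean genic fraction of the
    two windows straddling the junction. The composite shift score
    standardises the magnitude of each
    delta across the candidate set and sums them, so a genuine shift stands
    out against the background of the other candidates regardless of units.
    Standardisation is leave-one-out (each candidate is scored against the
    mean and SD of the *other* candidates, as in Grubbs-style outlier
    statistics): a real junction neither inflates its own reference spread
    nor shelters noisy candidates behind it.

    Candidates with truncated flanks (near scaffold ends) estimate their
    flank means from fewer windows, so their raw deltas are noisier; before
    z-scoring, each delta is rescaled by the variance-stabilising factor
    sqrt((2/flank_windows) / (1/n_left + 1/n_right)) — 1 for full flanks —
    so short-flank candidates are not mistaken for shifts.
    """
    wins = track.for_chrom(scaffold).reset_index(drop=True)
    if wins.empty:
        raise ValueError(f"track has no windows for scaffold {scaffold!r}")
    starts = wins["start"].to_numpy()
    ends = wins["end"].to_numpy()
    scaffold_end = int(ends.max())

    out: list[BreakpointCandidate] = []
    stab_weights: list[float] = []
    for pos in candidates:
        if not (0 < pos < scaffold_end):
            raise ValueError(f"candidate {pos} outside scaffold (0, {scaffold_end})")
        left = wins[ends <= pos].tail(flank_windows)
        right = wins[starts >= pos].head(flank_windows)
        flagged = len(left) < 1 or len(right) < 1
        if len(left) < 1:
            left = wins.head(1)
        if len(right) < 1:
            right = wins.tail(1)
        # straddling pair: last window ending at/before pos and first starting after
        straddle = wins[(starts < pos + 1) & (ends > pos - 1)]
        if straddle.empty:
            straddle = wins.iloc[
                [max(0, len(left) - 1), min(len(wins) - 1, len(left))]
            ]
        local = np.concatenate(
            [left.tail(1)["gene_frac"].to_numpy(), right.head(1)["gene_frac"].to_numpy()]
        )
        stab_weights.append(
            np.sqrt((2 / flank_windows) / (1 / len(left) + 1 / len(right)))
        )
        out.append(
            BreakpointCandidate(
                scaffold=scaffold,
                position=int(pos),
                source="supplied",
                delta_gc=float(
                    np.nanmean(right["gc_pct"]) - np.nanmean(left["gc_pct"])
                ),
                delta_repeat=float(
                    right["repeat_frac"].mean() - left["repeat_frac"].mean()
                ),
                local_gd=float(local.mean()),
                flagged=flagged,
            )
        )

    def zscores(x: np.ndarray) -> np.ndarray:
        n = x.size
        if n < 3:  # no reference spread to standardise against
            return np.zeros_like(x)
        z = np.zeros_like(x)
        for i in range(n):
            rest = np.delete(x, i)
            sd = rest.std(ddof=1)
            diff = x[i] - rest.mean()
            if sd > 0:
                z[i] = diff / sd
            else:  # zero-variance background: any nonzero shift is decisive
                z[i] = 0.0 if diff == 0 else np.copysign(np.inf, diff)
        return z

    w = np.asarray(stab_weights)
    z_gc = zscores(w * np.abs([c.delta_gc for c in out]))
    z_rep = zscores(w * np.abs([c.delta_repeat for c in out]))
    for c, zg, zr in zip(out, z_gc, z_rep):
        c.shift_score = float(zg + zr)
    return out


def split_scaffold(
    assembly: Assembly,
    scaffold: str,
    scored: list[BreakpointCandidate],
    shift_z_min: float = 2.0,
) -> tuple[Assembly, dict]:
    """Split a scaffold at the best-supported composition-shift junction.

    A candidate passes the abrupt-shift signature when its composite shift
    score reaches ``shift_z_min`` AND its GC and repeat shifts point in
    opposite directions (elevated GC with reduced repeat density is the
    compositional syndrome distinguishing chromosome classes; noise shifts
    have independent signs). Among passers the one with minimal local gene
    density is chosen (matching the curation rule of splitting at reduced
    gene density). The scaffold is replaced in place by ``<scaffold>_L`` and
    ``<scaffold>_R``; no candidate passing raises :class:`SplitError`.
    """
    passers = [
        c
        for c in scored
        if not np.isnan(c.shift_score) and c.shift_score >= shift_z_min and c.opposed
    ]
    if not passers:
        raise SplitError(
            f"no supported breakpoint on {scaffold!r}: "
            f"no candidate shift score reached {shift_z_min}"
        )
    chosen = min(passers, key=lambda c: (c.local_gd, c.position))
    chosen.chosen = True

    records: list[SequenceRecord] = []
    found = False
    for rec in assembly.records:
        if rec.id == scaffold:
            found = True
            records.append(SequenceRecord(id=f"{scaffold}_L", seq=rec.seq[: chosen.position]))
            records.append(SequenceRecord(id=f"{scaffold}_R", seq=rec.seq[chosen.position :]))
        else:
            records.append(rec)
    if not found:
        raise KeyError(f"scaffold {scaffold!r} not in assembly")
    curated = Assembly(records=records, name=assembly.name + "_curated")
    report = {
        "scaffold": scaffold,
        "chosen_position": chosen.position,
        "n_candidates": len(scored),
        "n_passing": len(passers),
        "candidates": [
            {
                "position": c.position,
                "delta_gc": c.delta_gc,
                "delta_repeat": c.delta_repeat,
                "local_gd": c.local_gd,
                "shift_score": c.shift_score,
                "chosen": c.chosen,
                "flagged": c.flagged,
            }
            for c in scored
        ],
    }
    return curated, report
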