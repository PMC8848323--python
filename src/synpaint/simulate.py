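"""Synthetic genomes with macro/micro structure and known rearrangement truth.

The generator emulates the three properties the pipeline measures:

* a karyotype of macro- and microchromosomes whose 1-Mb windows differ in GC
  percentage, genic fraction and repeat fraction between classes, with
  class-level window means and SDs matching the real-genome values the
  defaults encode (macro GC 35.9 ± 1.2, micro 38.5 ± 2.8; genic fraction
  0.19 ± 0.14 vs 0.27 ± 0.16; repeat 44.6 ± 5.6 % vs 39.4 ± 10 %);
* target genomes derived from the query by fusion / fission / translocation /
  inversion, with a base-exact truth map of query↔target homology;
* noisy marker hit tables in the 5-column tabular dialect.

GC and repeat window draws are hierarchical: each chromosome gets a mean
drawn around its class mean (between-chromosome SD = 0.8·class SD), and
windows scatter around the chromosome mean (within SD = 0.6·class SD), so
between² + within² equals the class variance and class-wide window moments
match the stated values while individual chromosomes remain compositionally
distinguishable — the property karyotype curation relies on. Gene density
carries no chromosome-level component (it is not part of the junction
signature) and is drawn flat per window at the full class SD. All truncated
normals are mean-calibrated: the location parameter is solved so the
truncated distribution's MEAN equals the stated class value, since the
values being emulated are empirical window means.

All randomness flows from one integer seed through named substreams:
changing the hit-noise stream never changes the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize as _opt, stats as _st

from ._rng import substream
from .io import Assembly, FeatureInterval, HitRecord, SequenceRecord
from .painting import Marker

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class ClassParams:
    """Per-window composition distribution for one chromosome class.

    GC and repeat values are percentages, genic fraction is in [0, 1]; SDs
    are class-wide window SDs (GC and repeat split 0.8/0.6 between/within
    chromosomes; gene density is flat per window).
    """

    gc_mean: float
    gc_sd: float
    gene_frac_mean: float
    gene_frac_sd: float
    repeat_pct_mean: float
    repeat_pct_sd: float


@dataclass(frozen=True)
class CompositionParams:
    macro: ClassParams = ClassParams(35.9, 1.2, 0.19, 0.14, 44.6, 5.6)
    micro: ClassParams = ClassParams(38.5, 2.8, 0.27, 0.16, 39.4, 10.0)
    between_sd_frac: float = 0.8  # share of class SD at the chromosome level

    @property
    def within_sd_frac(self) -> float:
        return float(np.sqrt(1.0 - self.between_sd_frac**2))

    def for_class(self, chrom_class: str) -> ClassParams:
        if chrom_class == "macro":
            return self.macro
        if chrom_class == "micro":
            return self.micro
        raise ValueError(f"unknown class {chrom_class!r}")


@dataclass(frozen=True)
class KaryotypeSpec:
    """Chromosome counts and lengths of the simulated query karyotype.

    Defaults give the desk-scale scenario: 6 macrochromosomes of 20 Mb and
    11 microchromosomes of 8 Mb (208 Mb, ≥ 200 analysis windows).
    """

    macro_lengths: tuple[int, ...] = (20_000_000,) * 6
    micro_lengths: tuple[int, ...] = (8_000_000,) * 11

    @property
    def n_macro(self) -> int:
        return len(self.macro_lengths)

    @property
    def n_micro(self) -> int:
        return len(self.micro_lengths)

    def chrom_names(self) -> list[str]:
        return [f"macro{i + 1}" for i in range(self.n_macro)] + [
            f"micro{i + 1}" for i in range(self.n_micro)
        ]

    def class_map(self) -> dict[str, str]:
        return {
            name: ("macro" if name.startswith("macro") else "micro")
            for name in self.chrom_names()
        }

    def lengths(self) -> dict[str, int]:
        return dict(
            zip(self.chrom_names(), list(self.macro_lengths) + list(self.micro_lengths))
        )


@dataclass(frozen=True)
class HitNoise:
    """Marker-level noise for emitted hit tables."""

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    aln_len_range: tuple[int, int] = (50, 100)
    pident_range: tuple[float, float] = (90.0, 100.0)

    def __post_init__(self) -> None:
        for r in (self.drop_rate, self.spurious_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"noise rate {r} outside [0, 1]")


# ---------------------------------------------------------------------------
# query simulation


def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter of a truncated normal whose MEAN is ``mean``.

    E[TN(loc, sd; lo, hi)] is strictly increasing in loc and spans (lo, hi),
    so the root exists and is unique; for targets many SDs inside the bounds
    the correction is negligible and loc == mean to machine precision.
    """

    def tn_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(_st.truncnorm.mean(a, b, loc=loc, scale=sd))

    if abs(tn_mean(mean) - mean) < 1e-9:
        return mean
    span = 0.0
    while span < 60 * sd:  # bracket the root
        span += 6 * sd
        if tn_mean(mean - span) < mean < tn_mean(mean + span):
            break
    return float(_opt.brentq(lambda L: tn_mean(L) - mean, mean - span, mean + span))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size=None):
    """Mean-calibrated truncated normal draw on [lo, hi]."""
    if sd <= 0:
        return np.full(size, mean) if size else mean
    mean = min(max(mean, lo + 1e-9), hi - 1e-9)
    loc = _calibrated_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return _st.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _window_bounds(length: int, window_size: int) -> list[tuple[int, int]]:
    # generation windows tile the whole chromosome; the remainder chunk is kept
    bounds = [(s, min(s + window_size, length)) for s in range(0, length, window_size)]
    return bounds


def _place_intervals(
    rng: np.random.Generator,
    chrom: str,
    win_start: int,
    win_len: int,
    target_frac: float,
    len_range: tuple[int, int],
    kind: str,
) -> list[FeatureInterval]:
    """Non-overlapping intervals covering ``target_frac`` of the window exactly
    (to the base), with lengths uniform in ``len_range`` and uniform-random
    placement via a random partition of the uncovered space into gaps."""
    total_target = int(round(target_frac * win_len))
    if total_target <= 0:
        return []
    if total_target > win_len:
        raise ValueError(
            f"{kind} coverage {target_frac:.3f} infeasible in window of {win_len} bp"
        )
    lengths: list[int] = []
    covered = 0
    lo, hi = len_range
    while covered < total_target:
        L = int(rng.integers(lo, hi + 1))
        if covered + L > total_target:
            L = total_target - covered
            if L < 1:
                break
        lengths.append(L)
        covered += L
    free = win_len - covered
    cuts = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    gaps = np.diff(np.concatenate([[0], cuts]))
    out: list[FeatureInterval] = []
    pos = win_start
    for gap, L in zip(gaps, lengths):
        pos += int(gap)
        out.append(FeatureInterval(chrom, pos, pos + L, strand="+", kind=kind))
        pos += L
    return out


def simulate_query(
    spec: KaryotypeSpec = KaryotypeSpec(),
    params: CompositionParams = CompositionParams(),
    seed: int = 0,
    window_size: int = 1_000_000,
    overrides: dict[str, dict[str, float]] | None = None,
) -> tuple[Assembly, list[FeatureInterval], list[FeatureInterval]]:
    """Simulate a query genome with class-structured composition.

    Per 1-Mb window, target GC / genic fraction / repeat fraction are drawn
    from the hierarchical truncated normals in ``params``; bases are i.i.d.
    with the window's GC probability; gene (1–50 kb) and repeat (0.1–5 kb)
    intervals are placed non-overlapping until each window's target fraction
    is met exactly. ``overrides`` forces chromosome-level means, e.g.
    ``{"micro3": {"gc_mean": 40.0}}`` — used to build compositionally
    distinct chromosomes for curation scenarios.
    """
    overrides = overrides or {}
    classes = spec.class_map()
    records: list[SequenceRecord] = []
    genes: list[FeatureInterval] = []
    repeats: list[FeatureInterval] = []
    bsf, wsf = params.between_sd_frac, params.within_sd_frac

    for chrom, length in spec.lengths().items():
        cp = params.for_class(classes[chrom])
        rng = substream(seed, "genome", chrom)
        ov = overrides.get(chrom, {})
        chrom_gc = ov.get(
            "gc_mean", _truncnorm(rng, cp.gc_mean, bsf * cp.gc_sd, 0.0, 100.0)
        )
        # gene density has no chromosome-level component: class mean directly
        chrom_gene = ov.get("gene_frac_mean", cp.gene_frac_mean)
        chrom_rep = ov.get(
            "repeat_pct_mean",
            _truncnorm(rng, cp.repeat_pct_mean, bsf * cp.repeat_pct_sd, 0.0, 100.0),
        )
        bounds = _window_bounds(length, window_size)
        n_win = len(bounds)
        win_gc = _truncnorm(rng, chrom_gc, wsf * cp.gc_sd, 0.0, 100.0, size=n_win)
        win_gene = _truncnorm(rng, chrom_gene, cp.gene_frac_sd, 0.0, 1.0, size=n_win)
        win_rep = _truncnorm(rng, chrom_rep, wsf * cp.repeat_pct_sd, 0.0, 100.0, size=n_win)

        chunks: list[np.ndarray] = []
        grng = substream(seed, "genes", chrom)
        rrng = substream(seed, "repeats", chrom)
        for (ws, we), gc, gfrac, rpct in zip(bounds, win_gc, win_gene, win_rep):
            wlen = we - ws
            g = gc / 100.0
            probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
            idx = np.searchsorted(np.cumsum(probs), rng.random(wlen), side="right")
            chunks.append(_BASES[idx])
            genes.extend(
                _place_intervals(grng, chrom, ws, wlen, gfrac, (1_000, 50_000), "gene")
            )
            repeats.extend(
                _place_intervals(rrng, chrom, ws, wlen, rpct / 100.0, (100, 5_000), "repeat")
            )
        seq = np.concatenate(chunks).tobytes().decode("ascii")
        records.append(SequenceRecord(id=chrom, seq=seq))
    return Assembly(records=records, name="simulated_query"), genes, repeats


# ---------------------------------------------------------------------------
# rearrangements and truth maps


@dataclass(frozen=True)
class Fusion:
    a: str
    b: str
    orientation: str = "head_tail"  # head_head reverse-complements b


@dataclass(frozen=True)
class Fission:
    chrom: str
    position: int


@dataclass(frozen=True)
class Translocation:
    src: str
    start: int
    end: int
    dest: str
    insert_position: int


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int
    end: int


RearrangementOp = Fusion | Fission | Translocation | Inversion


@dataclass(frozen=True)
class TruthSegment:
    q_chrom: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    strand: str  # + or -


@dataclass
class TruthMap:
    """Base-exact query↔target homology emitted by the simulator."""

    segments: list[TruthSegment]
    query_lengths: dict[str, int] = field(default_factory=dict)

    def target_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.segments:
            out[s.t_chrom] = max(out.get(s.t_chrom, 0), s.t_end)
        return out

    def validate_tiling(self) -> None:
        """Every query base must appear exactly once across segments."""
        by_q: dict[str, list[TruthSegment]] = {}
        for s in self.segments:
            by_q.setdefault(s.q_chrom, []).append(s)
        for q, segs in by_q.items():
            segs = sorted(segs, key=lambda s: s.q_start)
            pos = 0
            for s in segs:
                if s.q_start != pos:
                    raise ValueError(f"truth map gap/overlap on {q} at {pos}")
                pos = s.q_end
            if q in self.query_lengths and pos != self.query_lengths[q]:
                raise ValueError(f"truth map does not cover {q} to its end")

    def lookup(self, q_chrom: str, pos: int) -> tuple[str, int, str]:
        """Target (chrom, position, strand) of one query base."""
        for s in self.segments:
            if s.q_chrom == q_chrom and s.q_start <= pos < s.q_end:
                if s.strand == "+":
                    return s.t_chrom, s.t_start + (pos - s.q_start), "+"
                return s.t_chrom, s.t_start + (s.q_end - 1 - pos), "-"
        raise KeyError(f"{q_chrom}:{pos} not covered by truth map")

    def map_intervals(self, intervals: list[FeatureInterval]) -> list[FeatureInterval]:
        """Project query intervals onto target coordinates, splitting at
        segment boundaries and reversing orientation across '-' segments."""
        out: list[FeatureInterval] = []
        for iv in intervals:
            for s in self.segments:
                if s.q_chrom != iv.seq_id:
                    continue
                lo, hi = max(iv.start, s.q_start), min(iv.end, s.q_end)
                if lo >= hi:
                    continue
                if s.strand == "+":
                    t_lo = s.t_start + (lo - s.q_start)
                    t_hi = s.t_start + (hi - s.q_start)
                else:
                    t_lo = s.t_start + (s.q_end - hi)
                    t_hi = s.t_start + (s.q_end - lo)
                out.append(
                    FeatureInterval(
                        s.t_chrom, t_lo, t_hi,
                        strand=iv.strand, kind=iv.kind, attrs=dict(iv.attrs),
                    )
                )
        return out


@dataclass(frozen=True)
class _Seg:
    q_chrom: str
    q_start: int
    q_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    def reversed(self) -> "_Seg":
        return replace(self, strand="-" if self.strand == "+" else "+")


def _split_at(segs: list[_Seg], pos: int) -> tuple[list[_Seg], list[_Seg]]:
    if pos < 0 or pos > sum(s.length for s in segs):
        raise ValueError(f"position {pos} outside chromosome")
    left: list[_Seg] = []
    right: list[_Seg] = []
    off = 0
    for s in segs:
        if off + s.length <= pos:
            left.append(s)
        elif off >= pos:
            right.append(s)
        else:
            cut = pos - off
            if s.strand == "+":
                left.append(replace(s, q_end=s.q_start + cut))
                right.append(replace(s, q_start=s.q_start + cut))
            else:
                left.append(replace(s, q_start=s.q_end - cut))
                right.append(replace(s, q_end=s.q_end - cut))
        off += s.length
    return left, right


def apply_rearrangements(
    assembly: Assembly, ops: list[RearrangementOp]
) -> tuple[Assembly, TruthMap]:
    """Derive a target genome by applying ops sequentially to a working copy.

    Base content is conserved exactly; the returned truth map tiles every
    query base once. Chromosome names track their history (``a+b`` for a
    fusion, ``a.1``/``a.2`` for a fission).
    """
    work: dict[str, list[_Seg]] = {
        r.id: [_Seg(r.id, 0, r.length, "+")] for r in assembly.records
    }

    def need(name: str, op) -> list[_Seg]:
        if name not in work:
            raise ValueError(f"{op}: unknown chromosome {name!r}")
        return work[name]

    for op in ops:
        if isinstance(op, Fusion):
            a, b = need(op.a, op), need(op.b, op)
            if op.orientation not in ("head_tail", "head_head"):
                raise ValueError(f"{op}: unknown orientation")
            tail = b if op.orientation == "head_tail" else [s.reversed() for s in reversed(b)]
            fused = a + tail
            del work[op.a], work[op.b]
            work[f"{op.a}+{op.b}"] = fused
        elif isinstance(op, Fission):
            segs = need(op.chrom, op)
            total = sum(s.length for s in segs)
            if not 0 < op.position < total:
                raise ValueError(f"{op}: position outside (0, {total})")
            left, right = _split_at(segs, op.position)
            del work[op.chrom]
            work[f"{op.chrom}.1"] = left
            work[f"{op.chrom}.2"] = right
        elif isinstance(op, Translocation):
            src = need(op.src, op)
            total = sum(s.length for s in src)
            if not 0 <= op.start < op.end <= total:
                raise ValueError(f"{op}: segment outside [0, {total}]")
            left, rest = _split_at(src, op.start)
            mid, right = _split_at(rest, op.end - op.start)
            work[op.src] = left + right
            dest = need(op.dest, op)
            dtot = sum(s.length for s in dest)
            if not 0 <= op.insert_position <= dtot:
                raise ValueError(f"{op}: insert position outside [0, {dtot}]")
            dl, dr = _split_at(dest, op.insert_position)
            work[op.dest] = dl + mid + dr
        elif isinstance(op, Inversion):
            segs = need(op.chrom, op)
            total = sum(s.length for s in segs)
            if not 0 <= op.start < op.end <= total:
                raise ValueError(f"{op}: segment outside [0, {total}]")
            left, rest = _split_at(segs, op.start)
            mid, right = _split_at(rest, op.end - op.start)
            work[op.chrom] = left + [s.reversed() for s in reversed(mid)] + right
        else:
            raise TypeError(f"unknown rearrangement op {op!r}")

    seqs = {r.id: r.seq for r in assembly.records}
    records: list[SequenceRecord] = []
    truth_segments: list[TruthSegment] = []
    for t_chrom, segs in work.items():
        parts: list[str] = []
        off = 0
        for s in segs:
            piece = seqs[s.q_chrom][s.q_start : s.q_end]
            if s.strand == "-":
                piece = piece.translate(_COMPLEMENT)[::-1]
            parts.append(piece)
            truth_segments.append(
                TruthSegment(
                    q_chrom=s.q_chrom, q_start=s.q_start, q_end=s.q_end,
                    t_chrom=t_chrom, t_start=off, t_end=off + s.length,
                    strand=s.strand,
                )
            )
            off += s.length
        records.append(SequenceRecord(id=t_chrom, seq="".join(parts)))
    truth = TruthMap(
        segments=truth_segments, query_lengths=assembly.lengths()
    )
    truth.validate_tiling()
    target = Assembly(records=records, name=assembly.name + "_target")
    assert target.total_length == assembly.total_length
    return target, truth


# ---------------------------------------------------------------------------
# hit emission


def emit_hits(
    query_markers: list[Marker],
    truth: TruthMap,
    noise: HitNoise = HitNoise(),
    seed: int = 0,
) -> list[HitRecord]:
    """Emit a marker hit table through the truth map with optional noise.

    Each marker maps to its true target location; markers are dropped with
    ``drop_rate``; with ``spurious_rate`` the hit is instead placed uniformly
    at random on a wrong target chromosome. Alignment lengths and percent
    identities come from the uniform samplers in ``noise``; the row order of
    the output is shuffled (as an aligner's would effectively be).
    """
    rng = substream(seed, "hits")
    t_lengths = truth.target_lengths()
    t_names = sorted(t_lengths)
    by_chrom: dict[str, list[TruthSegment]] = {}
    for s in truth.segments:
        by_chrom.setdefault(s.q_chrom, []).append(s)
    for q in by_chrom:
        by_chrom[q].sort(key=lambda s: s.q_start)

    lo, hi = noise.aln_len_range
    plo, phi = noise.pident_range
    out: list[HitRecord] = []
    for m in query_markers:
        if noise.drop_rate and rng.random() < noise.drop_rate:
            continue
        aln = int(rng.integers(lo, hi + 1))
        pid = float(rng.uniform(plo, phi))
        segs = by_chrom.get(m.query_chrom)
        if not segs:
            continue
        t_chrom = t_pos = None
        for s in segs:
            if s.q_start <= m.start < s.q_end:
                if s.strand == "+":
                    t_pos = s.t_start + (m.start - s.q_start)
                else:
                    t_pos = s.t_start + (s.q_end - m.end)
                    if t_pos < s.t_start:
                        t_pos = s.t_start
                t_chrom = s.t_chrom
                break
        if t_chrom is None:
            continue
        if noise.spurious_rate and rng.random() < noise.spurious_rate:
            wrong = [t for t in t_names if t != t_chrom] or t_names
            t_chrom = wrong[int(rng.integers(0, len(wrong)))]
            t_pos = int(rng.integers(0, max(1, t_lengths[t_chrom] - aln)))
        out.append(
            HitRecord(
                qseqid=m.id, sseqid=t_chrom, sstart=int(t_pos) + 1,
                length=aln, pident=round(pid, 2),
            )
        )
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


# ---------------------------------------------------------------------------
# scenario builders (shared by tests, examples and the acceptance script)


def composition_scenario(seed: int):
    """The desk-scale composition study: 6×20-Mb macros + 11×8-Mb micros with
    default class parameters. Returns (assembly, genes, repeats, class_map)."""
    spec = KaryotypeSpec()
    assembly, genes, repeats = simulate_query(spec, CompositionParams(), seed=seed)
    return assembly, genes, repeats, spec.class_map()


#: chromosome-level composition means forced onto the two fused micros in the
#: hidden-fusion scenario; the gaps (GC Δ 3.5, repeat Δ 16) sit inside the
#: between-chromosome spread the class SDs imply (0.8·2.8 ≈ 2.2 GC points,
#: 0.8·10 = 8 repeat points).
FUSED_MICRO_OVERRIDES = (
    {"gc_mean": 36.75, "repeat_pct_mean": 47.0},
    {"gc_mean": 40.25, "repeat_pct_mean": 31.0},
)


_FUSION_MICRO_LENGTHS = (
    9_500_000, 9_000_000, 8_700_000, 8_600_000, 8_500_000, 8_400_000,
    8_300_000, 8_200_000, 8_100_000, 10_000_000, 9_200_000,
)


def hidden_fusion_scenario(seed: int, n_decoys: int = 10, with_macros: bool = True):
    """A curation fixture: one scaffold hides a fusion of two composition-
    distinct microchromosomes among otherwise ordinary scaffolds.

    Builds 11 micros (> 8 Mb each, so both fusion halves stay micro-class)
    and, by default, 6 macro-class scaffolds of 50 Mb; fuses the last two
    micros into one scaffold, projects annotations through the truth map,
    and returns a dict with the target assembly, projected genes and
    repeats, the fused scaffold name, the true junction position, and
    candidate junctions (true + ``n_decoys`` uniform decoys ≥ 1 Mb away).
    """
    spec = KaryotypeSpec(
        macro_lengths=(50_000_000,) * 6 if with_macros else (),
        micro_lengths=_FUSION_MICRO_LENGTHS,
    )
    a_name, b_name = "micro10", "micro11"
    overrides = {
        a_name: dict(FUSED_MICRO_OVERRIDES[0]),
        b_name: dict(FUSED_MICRO_OVERRIDES[1]),
    }
    assembly, genes, repeats = simulate_query(
        spec, CompositionParams(), seed=seed, overrides=overrides
    )
    target, truth = apply_rearrangements(assembly, [Fusion(a_name, b_name)])
    fused = f"{a_name}+{b_name}"
    true_junction = spec.lengths()[a_name]
    fused_len = spec.lengths()[a_name] + spec.lengths()[b_name]
    rng = substream(seed, "decoys")
    decoys: list[int] = []
    # decoys must be null junctions: at 1-Mb windows with 3-window flanks, a
    # candidate closer than the flank span to the true junction shares its
    # composition shift and is a confounded hypothesis, not a decoy
    while len(decoys) < n_decoys:
        pos = int(rng.integers(1_500_000, fused_len - 1_500_000))
        if abs(pos - true_junction) >= 3_500_000:
            decoys.append(pos)
    return {
        "assembly": target,
        "genes": truth.map_intervals(genes),
        "repeats": truth.map_intervals(repeats),
        "truth": truth,
        "fused_scaffold": fused,
        "true_junction": true_junction,
        "candidates": [true_junction] + decoys,
        "class_map": {
            r.id: ("macro" if r.id.startswith("macro") else "micro")
            for r in target.records
        },
    }


def fused_pair_scenario(seed: int, n_decoys: int = 10):
    """Minimal replicate of the hidden fusion: just the two composition-
    distinct micros, fused, with decoy junctions — for repeated junction-
    recovery trials where simulating the surrounding karyotype adds nothing.
    Same return structure as :func:`hidden_fusion_scenario`."""
    spec = KaryotypeSpec(macro_lengths=(), micro_lengths=(10_000_000, 9_200_000))
    a_name, b_name = "micro1", "micro2"
    overrides = {
        a_name: dict(FUSED_MICRO_OVERRIDES[0]),
        b_name: dict(FUSED_MICRO_OVERRIDES[1]),
    }
    assembly, genes, repeats = simulate_query(
        spec, CompositionParams(), seed=seed, overrides=overrides
    )
    target, truth = apply_rearrangements(assembly, [Fusion(a_name, b_name)])
    fused = f"{a_name}+{b_name}"
    true_junction = spec.lengths()[a_name]
    fused_len = target.total_length
    rng = substream(seed, "decoys")
    decoys: list[int] = []
    # decoys must be null junctions: at 1-Mb windows with 3-window flanks, a
    # candidate closer than the flank span to the true junction shares its
    # composition shift and is a confounded hypothesis, not a decoy
    while len(decoys) < n_decoys:
        pos = int(rng.integers(1_500_000, fused_len - 1_500_000))
        if abs(pos - true_junction) >= 3_500_000:
            decoys.append(pos)
    return {
        "assembly": target,
        "genes": truth.map_intervals(genes),
        "repeats": truth.map_intervals(repeats),
        "truth": truth,
        "fused_scaffold": fused,
        "true_junction": true_junction,
        "candidates": [true_junction] + decoys,
        "class_map": {fused: "micro"},
    }
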