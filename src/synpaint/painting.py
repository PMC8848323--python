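"""In-silico chromosome painting.

The query genome is partitioned into fixed-length tiles ("markers",
default 100 bp). Each marker's best homology hit on a target genome is
retained, hits below a minimum alignment length are discarded, and runs of
consecutive surviving markers that all hit the same target scaffold are
chained into syntenic blocks. A run must reach a minimum length (default
5 markers) before a block is emitted; shorter runs are treated as noise.

Marker ordinals count every tile of the partition, including tiles dropped
for containing N — a dropped tile therefore breaks a run, so blocks never
bridge assembly gaps.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io import Assembly, HitRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Marker:
    """One fixed-length tile of the query partition.

    ``index`` is the tile ordinal along the chromosome counting all tiles
    (kept and dropped), so ``start == index * marker_len``.
    """

    query_chrom: str
    index: int
    start: int
    end: int
    contains_n: bool = False

    @property
    def id(self) -> str:
        return marker_id(self.query_chrom, self.index)


def marker_id(chrom: str, index: int, pad: int = 7) -> str:
    """Canonical marker id ``<chrom>_<zero-padded ordinal>``."""
    return f"{chrom}_{index:0{pad}d}"


def parse_marker_id(mid: str) -> tuple[str, int]:
    """Invert :func:`marker_id`.

    The ordinal is always the final ``_``-separated field, so chromosome
    names containing underscores parse unambiguously; a non-numeric final
    field is rejected.
    """
    chrom, _, ordinal = mid.rpartition("_")
    if not chrom or not ordinal.isdigit():
        raise ValueError(f"not a marker id: {mid!r}")
    return chrom, int(ordinal)


@dataclass(frozen=True)
class RetainedHit:
    """The single best hit retained for one (marker, species) pair."""

    marker: Marker
    species: str
    target_scaffold: str
    target_start: int  # 0-based
    aln_length: int
    pident: float


@dataclass(frozen=True)
class SyntenyBlock:
    """A maximal chained run of consecutive markers on one target scaffold."""

    query_chrom: str
    species: str
    target_scaffold: str
    first_index: int
    last_index: int
    marker_count: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]


@dataclass(frozen=True)
class PaintingParams:
    marker_len: int = 100
    min_aln_len: int = 50
    min_run: int = 5
    drop_n: bool = True
    strict_target: bool = False


@dataclass
class PaintingTable:
    assembly_name: str
    species: list[str]
    blocks: list[SyntenyBlock]
    params: PaintingParams
    stats: dict = field(default_factory=dict)

    def blocks_for(self, species: str) -> list[SyntenyBlock]:
        return [b for b in self.blocks if b.species == species]


# ---------------------------------------------------------------------------
# operations


def generate_markers(
    assembly: Assembly, marker_len: int = 100, drop_n: bool = True
) -> list[Marker]:
    """Partition every chromosome into non-overlapping ``marker_len`` tiles.

    Tiling starts at position 0; a trailing partial tile is dropped. Tiles
    containing at least one N are dropped when ``drop_n`` (the default),
    otherwise kept with ``contains_n`` set.
    """
    if marker_len < 10:
        raise ValueError(f"marker_len {marker_len} < 10")
    markers: list[Marker] = []
    for rec in assembly.records:
        n_tiles = rec.length // marker_len
        if n_tiles == 0:
            continue
        arr = np.frombuffer(
            rec.seq[: n_tiles * marker_len].encode("ascii"), dtype=np.uint8
        ).reshape(n_tiles, marker_len)
        has_n = (arr == ord("N")).any(axis=1)
        for i in range(n_tiles):
            if has_n[i] and drop_n:
                continue
            markers.append(
                Marker(
                    query_chrom=rec.id,
                    index=i,
                    start=i * marker_len,
                    end=(i + 1) * marker_len,
                    contains_n=bool(has_n[i]),
                )
            )
    return markers


def select_best_hits(
    hits: list[HitRecord], markers: list[Marker], species: str
) -> list[RetainedHit]:
    """Reduce a hit table to at most one hit per marker.

    Ties are broken deterministically by (max aln_length, max pident,
    lexicographically smallest sseqid, smallest sstart), so the result is
    invariant under permutation of table rows. Rows whose qseqid does not
    resolve to a generated marker are dropped with a logged count.
    """
    by_id = {m.id: m for m in markers}
    best: dict[str, HitRecord] = {}
    unresolved = 0
    for h in hits:
        if h.qseqid not in by_id:
            unresolved += 1
            continue
        cur = best.get(h.qseqid)
        if cur is None or _hit_rank(h) > _hit_rank(cur):
            best[h.qseqid] = h
    if unresolved:
        logger.info("%s: %d hit rows with unknown marker ids dropped", species, unresolved)
    out = [
        RetainedHit(
            marker=by_id[q],
            species=species,
            target_scaffold=h.sseqid,
            target_start=h.sstart - 1,
            aln_length=h.length,
            pident=h.pident,
        )
        for q, h in best.items()
    ]
    out.sort(key=lambda r: (r.marker.query_chrom, r.marker.index))
    return out


def _hit_rank(h: HitRecord) -> tuple:
    # larger is better; sseqid/sstart negated lexically via inversion trick
    return (h.length, h.pident, _NegStr(h.sseqid), -h.sstart)


class _NegStr(str):
    """String with reversed ordering, for 'smallest wins' inside a max-rank."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def filter_hits(retained: list[RetainedHit], min_aln_len: int = 50) -> list[RetainedHit]:
    """Keep exactly the hits with alignment length ≥ ``min_aln_len`` (default 50 bp)."""
    return [h for h in retained if h.aln_length >= min_aln_len]


def chain_markers(
    filtered: list[RetainedHit], min_run: int = 5, strict_target: bool = False
) -> list[SyntenyBlock]:
    """Chain consecutive retained markers into syntenic blocks.

    Within each query chromosome, a run extends while marker ordinals differ
    by exactly 1 and the target scaffold is unchanged; runs of at least
    ``min_run`` markers (default 5) become blocks. Target-side collinearity
    is not required unless ``strict_target``, which additionally demands
    monotone target_start within a run.
    """
    by_chrom: dict[str, list[RetainedHit]] = defaultdict(list)
    species = None
    for h in filtered:
        if species is None:
            species = h.species
        elif h.species != species:
            raise ValueError("chain_markers expects hits from a single species")
        by_chrom[h.query_chrom if hasattr(h, "query_chrom") else h.marker.query_chrom].append(h)

    blocks: list[SyntenyBlock] = []
    for chrom in sorted(by_chrom):
        hits = sorted(by_chrom[chrom], key=lambda r: r.marker.index)
        for i in range(1, len(hits)):
            if hits[i].marker.index == hits[i - 1].marker.index:
                raise ValueError(
                    f"duplicate hit for marker {hits[i].marker.id}: "
                    "select_best_hits contract violated"
                )
        run: list[RetainedHit] = []
        direction = 0  # strict mode: sign of target_start steps within the run

        def flush() -> None:
            if len(run) >= min_run:
                starts = [r.target_start for r in run]
                ends = [r.target_start + r.aln_length for r in run]
                blocks.append(
                    SyntenyBlock(
                        query_chrom=chrom,
                        species=run[0].species,
                        target_scaffold=run[0].target_scaffold,
                        first_index=run[0].marker.index,
                        last_index=run[-1].marker.index,
                        marker_count=len(run),
                        query_span=(run[0].marker.start, run[-1].marker.end),
                        target_span=(min(starts), max(ends)),
                    )
                )

        for h in hits:
            if run:
                consecutive = h.marker.index == run[-1].marker.index + 1
                same_scaf = h.target_scaffold == run[-1].target_scaffold
                ok = consecutive and same_scaf
                if ok and strict_target:
                    step = np.sign(h.target_start - run[-1].target_start)
                    if direction == 0:
                        direction = int(step)
                    elif step != 0 and step != direction:
                        ok = False
                if not ok:
                    flush()
                    run = []
                    direction = 0
            run.append(h)
        flush()
    blocks.sort(key=lambda b: (b.species, b.query_chrom, b.first_index))
    return blocks


def paint(
    assembly: Assembly,
    hit_tables: dict[str, list[HitRecord]],
    params: PaintingParams = PaintingParams(),
) -> PaintingTable:
    """Run the full painting pipeline for every target species.

    Composition of generate_markers → select_best_hits → filter_hits →
    chain_markers, with per-species retention statistics collected in
    ``table.stats``.
    """
    species_list = list(hit_tables)
    if len(species_list) != len(set(species_list)):
        raise ValueError("species labels must be unique")
    markers = generate_markers(assembly, params.marker_len, params.drop_n)
    blocks: list[SyntenyBlock] = []
    stats: dict[str, dict[str, int]] = {}
    for sp, hits in hit_tables.items():
        retained = select_best_hits(hits, markers, sp)
        filtered = filter_hits(retained, params.min_aln_len)
        sp_blocks = chain_markers(filtered, params.min_run, params.strict_target)
        blocks.extend(sp_blocks)
        stats[sp] = {
            "markers_generated": len(markers),
            "raw_hits": len(hits),
            "retained": len(retained),
            "filtered": len(filtered),
            "blocks": len(sp_blocks),
            "markers_in_blocks": sum(b.marker_count for b in sp_blocks),
        }
        logger.info("painted %s: %s", sp, stats[sp])
    blocks.sort(key=lambda b: (b.species, b.query_chrom, b.first_index))
    return PaintingTable(
        assembly_name=assembly.name,
        species=species_list,
        blocks=blocks,
        params=params,
        stats=stats,
    )
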