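"""One-shot pipeline runs: simulate (optional) → paint → dominance → composition.

A run is described by a config mapping (usually loaded from YAML), validated
before any stage executes. Every output table is TSV with ``#``-prefixed
metadata headers; a machine-readable ``run_summary.json`` sits alongside.
One seed drives everything; stages derive named substreams from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, io as gio
from ._rng import child_seed
from .composition import build_track, compare_macro_micro
from .dominance import dominance_results, dominance_table, summarize_dominance
from .painting import PaintingParams, paint
from .simulate import (
    CompositionParams, Fission, Fusion, HitNoise, Inversion, KaryotypeSpec,
    Translocation, apply_rearrangements, emit_hits, simulate_query,
)
from .painting import generate_markers

logger = logging.getLogger(__name__)

_OP_TYPES = {
    "fusion": Fusion,
    "fission": Fission,
    "translocation": Translocation,
    "inversion": Inversion,
}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    # either simulate a scenario ...
    simulate: dict | None = None
    # ... or point at real inputs
    query_fasta: str | None = None
    hit_tables: dict[str, str] = field(default_factory=dict)
    genes_gff3: str | None = None
    repeats_bed: str | None = None
    class_tsv: str | None = None
    # stage parameters
    marker_len: int = 100
    min_aln_len: int = 50
    min_run: int = 5
    drop_n: bool = True
    window_size: int = 1_000_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None and self.query_fasta is None:
            raise ConfigError("config needs either a 'simulate' block or 'query_fasta'")
        for label, p in [
            ("query_fasta", self.query_fasta),
            ("genes_gff3", self.genes_gff3),
            ("repeats_bed", self.repeats_bed),
            ("class_tsv", self.class_tsv),
        ]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label}: file not found: {p}")
        for sp, p in self.hit_tables.items():
            if not Path(p).exists():
                raise ConfigError(f"hit table for {sp!r} not found: {p}")


def _parse_ops(raw_ops: list[dict]):
    ops = []
    for entry in raw_ops:
        entry = dict(entry)
        kind = entry.pop("op", None)
        if kind not in _OP_TYPES:
            raise ConfigError(f"unknown rearrangement op {kind!r}")
        ops.append(_OP_TYPES[kind](**entry))
    return ops


def _write_tsv(df, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# synpaint {__version__}; {header}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_all(config: RunConfig) -> Path:
    """Execute the configured stages, writing tables into ``config.outdir``.

    Any stage failure propagates after stamping a ``.partial`` marker file so
    downstream consumers never mistake an aborted run for a complete one.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial = outdir / ".partial"
    partial.touch()
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)

    try:
        # ---- inputs (simulated or loaded) -------------------------------
        if config.simulate is not None:
            sim = dict(config.simulate)
            spec = KaryotypeSpec(
                macro_lengths=tuple(sim.get("macro_lengths", (20_000_000,) * 6)),
                micro_lengths=tuple(sim.get("micro_lengths", (8_000_000,) * 11)),
            )
            assembly, genes, repeats = simulate_query(
                spec, CompositionParams(), seed=child_seed(config.seed, "simulate")
            )
            class_map = spec.class_map()
            hit_tables = {}
            for sp_entry in sim.get("species", []):
                sp = sp_entry["name"]
                target, truth = apply_rearrangements(
                    assembly, _parse_ops(sp_entry.get("ops", []))
                )
                noise = HitNoise(
                    drop_rate=sp_entry.get("drop_rate", 0.0),
                    spurious_rate=sp_entry.get("spurious_rate", 0.0),
                )
                markers = generate_markers(assembly, config.marker_len, config.drop_n)
                hit_tables[sp] = emit_hits(
                    markers, truth, noise, seed=child_seed(config.seed, "hits", sp)
                )
            gio.write_fasta(assembly, outdir / "query.fa")
            gio.write_gff3_genes(genes, outdir / "genes.gff3")
            gio.write_repeat_bed(repeats, outdir / "repeats.bed")
            summary["stages"]["simulate"] = {
                "chromosomes": len(assembly.records),
                "total_length": assembly.total_length,
                "genes": len(genes),
                "repeats": len(repeats),
                "species": sorted(hit_tables),
            }
        else:
            assembly = gio.read_fasta(config.query_fasta)
            genes = gio.read_gff3_genes(config.genes_gff3) if config.genes_gff3 else []
            repeats = (
                gio.read_repeat_intervals(config.repeats_bed) if config.repeats_bed else []
            )
            class_map = {}
            if config.class_tsv:
                for line in Path(config.class_tsv).read_text().splitlines():
                    if line and not line.startswith("#"):
                        chrom, klass = line.split("\t")[:2]
                        class_map[chrom] = klass
            hit_tables = {
                sp: gio.read_hit_table(p) for sp, p in config.hit_tables.items()
            }

        # ---- painting + dominance ---------------------------------------
        if hit_tables:
            params = PaintingParams(
                marker_len=config.marker_len, min_aln_len=config.min_aln_len,
                min_run=config.min_run, drop_n=config.drop_n,
            )
            painting = paint(assembly, hit_tables, params)
            gio.write_painting_tsv(painting, outdir / "painting.tsv")
            gio.write_painting_bed(painting, outdir / "painting.bed")
            results = dominance_results(painting)
            _write_tsv(
                dominance_table(results), outdir / "dominance.tsv",
                "per (query_chrom, species): m scaffolds, Simpson D, effective chromosomes C",
            )
            summ = summarize_dominance(
                results,
                all_chroms=[r.id for r in assembly.records],
                all_species=list(hit_tables),
            )
            _write_tsv(
                summ.per_chrom.reset_index(), outdir / "dominance_per_chrom.tsv",
                "mean/sample-SD of C per query chromosome across species",
            )
            _write_tsv(
                summ.per_species.reset_index(), outdir / "dominance_per_species.tsv",
                "cumulative SR per species",
            )
            summary["stages"]["painting"] = painting.stats
            summary["stages"]["dominance"] = {
                "pairs": len(results), "missing_pairs": summ.n_missing_pairs,
            }

        # ---- composition -------------------------------------------------
        track = build_track(
            assembly, genes, repeats, class_map, window_size=config.window_size
        )
        _write_tsv(
            track.df, outdir / "track.tsv",
            "per 1-window GC% (non-N), genic fraction, repeat fraction; "
            "coordinates 0-based half-open",
        )
        comparisons = []
        have_both = {"macro", "micro"} <= set(track.df["chrom_class"])
        if have_both:
            import pandas as pd

            rows = []
            for metric in ("gene_frac", "gc_pct", "repeat_frac"):
                c = compare_macro_micro(track, metric)
                rows.append(asdict(c))
                comparisons.append(c)
            _write_tsv(
                pd.DataFrame(rows), outdir / "comparison.tsv",
                "two-sided Wilcoxon rank-sum, macro vs micro windows; "
                "W = macro rank-sum, U = Mann-Whitney",
            )
        summary["stages"]["composition"] = {
            "windows": len(track.df),
            "comparisons": [c.metric for c in comparisons],
        }

        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    except Exception:
        logger.exception("pipeline run failed; partial outputs marked in %s", outdir)
        raise
    partial.unlink()
    return outdir
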