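"""Simpson-dominance quantification of syntenic-block dispersion.

For query chromosome *i* and target species *j*, let p_ijk be the proportion
of chromosome *i*'s painted homology (by default, markers inside accepted
syntenic blocks) that lies on target scaffold *k*. Then

    D_ij = sum_k p_ijk**2          (Simpson Dominance Index)
    C_ij = 1 / D_ij                (effective number of target chromosomes, "SR")

D ranges over [1/m, 1] and C over [1, m], where m is the number of target
scaffolds carrying any homology: C = 1 means the chromosome's blocks sit on
a single target scaffold; C = m means an even spread over m scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .painting import PaintingTable

_PTOL = 1e-9


@dataclass
class HomologyProportions:
    """Per (query chromosome, species) scaffold weights and proportions."""

    query_chrom: str
    species: str
    scaffold_weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.scaffold_weights.values()):
            raise ValueError("scaffold weights must be positive")

    @property
    def m(self) -> int:
        return len(self.scaffold_weights)

    @property
    def p(self) -> np.ndarray:
        w = np.asarray(list(self.scaffold_weights.values()), dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class DominanceResult:
    query_chrom: str
    species: str
    m: int
    D: float
    C: float


@dataclass
class DominanceSummary:
    """Cross-species summaries: per-chromosome mean/SD of C, per-species cumulative SR."""

    per_chrom: pd.DataFrame  # index query_chrom; mean_C, sd_C, n_species_with_data
    per_species: pd.DataFrame  # index species; cumulative_SR, n_chroms_with_data
    n_missing_pairs: int = 0
    missing_pairs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations


def proportions_from_blocks(
    painting: PaintingTable, weighting: str = "marker_count"
) -> list[HomologyProportions]:
    """Aggregate block weight per target scaffold for each (chromosome, species).

    ``weighting`` is ``"marker_count"`` (default) or ``"base_span"`` (query
    bases spanned; differs only at block edges). Pairs with no blocks yield
    no entry — missing data, not zero.
    """
    if weighting not in ("marker_count", "base_span"):
        raise ValueError(f"unknown weighting {weighting!r}")
    acc: dict[tuple[str, str], dict[str, float]] = {}
    for b in painting.blocks:
        w = b.marker_count if weighting == "marker_count" else b.query_span[1] - b.query_span[0]
        key = (b.query_chrom, b.species)
        acc.setdefault(key, {})
        acc[key][b.target_scaffold] = acc[key].get(b.target_scaffold, 0.0) + w
    return [
        HomologyProportions(query_chrom=qc, species=sp, scaffold_weights=weights)
        for (qc, sp), weights in sorted(acc.items())
    ]


def simpson_dominance(p) -> float:
    """D = sum(p**2) for a proportion vector summing to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no homologies: empty proportion vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("proportions must lie in (0, 1]")
    if abs(p.sum() - 1.0) > _PTOL:
        raise ValueError(f"proportions sum to {p.sum():.12f}, not 1")
    return float(np.sum(p**2))


def effective_chromosomes(D: float) -> float:
    """C = 1/D, the effective number of target chromosomes (SR)."""
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    return 1.0 / D


def dominance_results(
    painting: PaintingTable, weighting: str = "marker_count"
) -> list[DominanceResult]:
    """Compute (m, D, C) for every (query chromosome, species) pair with blocks."""
    out = []
    for hp in proportions_from_blocks(painting, weighting):
        D = simpson_dominance(hp.p)
        out.append(
            DominanceResult(
                query_chrom=hp.query_chrom,
                species=hp.species,
                m=hp.m,
                D=D,
                C=effective_chromosomes(D),
            )
        )
    return out


def summarize_dominance(
    results: list[DominanceResult],
    all_chroms: list[str] | None = None,
    all_species: list[str] | None = None,
) -> DominanceSummary:
    """Mean/SD of C per chromosome across species, and cumulative SR per species.

    SD is the sample standard deviation (n−1 denominator). (chromosome,
    species) pairs absent from ``results`` are missing data: excluded from
    means and sums, and counted when the full chromosome/species universe is
    supplied.
    """
    df = pd.DataFrame(
        [(r.query_chrom, r.species, r.C) for r in results],
        columns=["query_chrom", "species", "C"],
    )
    if df.empty:
        empty_c = pd.DataFrame(columns=["mean_C", "sd_C", "n_species_with_data"])
        empty_s = pd.DataFrame(columns=["cumulative_SR", "n_chroms_with_data"])
        return DominanceSummary(per_chrom=empty_c, per_species=empty_s)

    per_chrom = df.groupby("query_chrom")["C"].agg(
        mean_C="mean", sd_C=lambda x: x.std(ddof=1), n_species_with_data="count"
    )
    per_species = df.groupby("species")["C"].agg(
        cumulative_SR="sum", n_chroms_with_data="count"
    )
    missing: list[tuple[str, str]] = []
    if all_chroms is not None and all_species is not None:
        have = set(zip(df["query_chrom"], df["species"]))
        missing = [
            (c, s) for c in all_chroms for s in all_species if (c, s) not in have
        ]
    return DominanceSummary(
        per_chrom=per_chrom,
        per_species=per_species,
        n_missing_pairs=len(missing),
        missing_pairs=missing,
    )


def dominance_table(results: list[DominanceResult]) -> pd.DataFrame:
    """Per-pair table with columns query_chrom, species, m, D, C."""
    return pd.DataFrame(
        [(r.query_chrom, r.species, r.m, r.D, r.C) for r in results],
        columns=["query_chrom", "species", "m", "D", "C"],
    )
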