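"""Kit-quality metrics: coverage, allelic balance, consistency, noise.

Four analyses compare whole-genome-amplification conditions over a panel
of STR loci profiled in clonal single cells:

* **Loci sampled / failed cells** — the number of loci with at least one
  mapped read per cell; cells with fewer than 500 sampled loci count as
  failed amplifications.
* **Heterozygous allelic balance** — loci that are heterozygous in the
  pooled cell population (pooled coverage over 30 reads, alleles at least
  three repeat units apart, so stutter patterns do not overlap) are scored
  per cell by the fitted shorter-allele proportion ``w``; 0.5 is perfectly
  balanced, 0 or 1 is complete allelic dropout.
* **Consistency** — after virtually resampling every cell to exactly
  100,000 mapped reads (cells below that are excluded, kits with fewer
  than five surviving cells are dropped), the mean number of loci jointly
  sampled by k = 2..5 cells measures how reproducible the coverage bias is.
* **Noise** — per-cell median fitted stutter cycles (see
  :mod:`strwga.stutter_genotyping`) aggregated per kit.

All analysis constants live in :class:`ThresholdConfig`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .str_mapping import RepeatHistogram
from .stutter_genotyping import FitGrid, GenotypeCall, StutterParams, fit_genotype

__all__ = [
    "ThresholdConfig",
    "HetLocus",
    "HetLocusSet",
    "loci_sampled",
    "failed_cell_rate",
    "population_het_loci",
    "allelic_balance",
    "downsample_reads",
    "consistency_curve",
]

_POPCOUNT = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)


@dataclass(frozen=True)
class ThresholdConfig:
    """The analysis constants of the four kit-quality metrics.

    min_het_depth
        A population-heterozygous locus must be pooled-covered at *over*
        this many reads (strict).
    min_allele_sep
        Minimum repeat-unit separation between the two population alleles
        (alleles one unit apart produce overlapping stutter and are not
        confidently distinguishable).
    failed_cell_loci
        A cell with *fewer than* this many sampled loci is a failed cell.
    consistency_reads
        Virtual resampling depth for the consistency analysis.
    min_cells_per_kit
        Kits with fewer retained cells than this are excluded from the
        consistency analysis.
    correlation_min
        Minimum stutter-fit correlation for an accepted genotype call.
    min_reads_per_locus_sampled
        A locus counts as "sampled" in a cell at this many mapped reads.
    """

    min_het_depth: int = 30
    min_allele_sep: int = 3
    failed_cell_loci: int = 500
    consistency_reads: int = 100_000
    min_cells_per_kit: int = 5
    correlation_min: float = 0.95
    min_reads_per_locus_sampled: int = 1

    def __post_init__(self) -> None:
        for name in (
            "min_het_depth",
            "min_allele_sep",
            "failed_cell_loci",
            "consistency_reads",
            "min_cells_per_kit",
            "min_reads_per_locus_sampled",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.correlation_min <= 1.0:
            raise ValueError("correlation_min must be in (0, 1]")


@dataclass(frozen=True)
class HetLocus:
    locus_id: str
    a1: int
    a2: int
    pooled_total: int

    @property
    def separation(self) -> int:
        return self.a2 - self.a1


@dataclass(frozen=True)
class HetLocusSet:
    """Population-heterozygous loci passing the balance filter."""

    loci: dict[str, HetLocus]

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def __iter__(self):
        return iter(self.loci.values())

    def validate(self, cfg: ThresholdConfig) -> None:
        """Re-assert both filter clauses on every admitted locus."""
        for h in self:
            if h.separation < cfg.min_allele_sep:
                raise AssertionError(f"{h.locus_id}: separation {h.separation} admitted")
            if h.pooled_total <= cfg.min_het_depth:
                raise AssertionError(f"{h.locus_id}: pooled depth {h.pooled_total} admitted")


def loci_sampled(
    hists: Mapping[str, RepeatHistogram], cfg: ThresholdConfig | None = None
) -> int:
    """Number of loci with at least ``min_reads_per_locus_sampled`` reads."""
    cfg = cfg or ThresholdConfig()
    return sum(1 for h in hists.values() if h.total >= cfg.min_reads_per_locus_sampled)


def failed_cell_rate(
    counts_by_cell: Mapping[str, int], cfg: ThresholdConfig | None = None
) -> tuple[float, dict[str, bool]]:
    """Fraction of cells sampling fewer than ``failed_cell_loci`` loci.

    The threshold is strict: a cell at exactly the threshold is not failed.
    """
    cfg = cfg or ThresholdConfig()
    if not counts_by_cell:
        raise ValueError("need at least one cell")
    flags = {cell: n < cfg.failed_cell_loci for cell, n in counts_by_cell.items()}
    return sum(flags.values()) / len(flags), flags


def pool_histograms(
    hists_by_cell: Mapping[str, Mapping[str, RepeatHistogram]]
) -> dict[str, RepeatHistogram]:
    """Sum per-cell histograms across cells, per locus."""
    pooled: dict[str, list[RepeatHistogram]] = {}
    for hists in hists_by_cell.values():
        for locus_id, h in hists.items():
            pooled.setdefault(locus_id, []).append(h)
    return {
        lid: RepeatHistogram.merge(parts, locus_id=lid)
        for lid, parts in pooled.items()
    }


def population_calls(
    hists_by_cell: Mapping[str, Mapping[str, RepeatHistogram]],
    grid: FitGrid | None = None,
    params: StutterParams | None = None,
    min_total: int = 1,
) -> dict[str, GenotypeCall]:
    """Genotype the pooled population histogram of every locus.

    In a clonal population the pooled call establishes the two candidate
    alleles of each locus; per-cell fits are then seeded by this genotype.
    Loci pooled below ``min_total`` reads are skipped.
    """
    if not hists_by_cell:
        raise ValueError("need at least one cell")
    pooled = pool_histograms(hists_by_cell)
    return {
        lid: fit_genotype(h, grid, params)
        for lid, h in pooled.items()
        if h.total >= min_total
    }


def population_het_loci(
    hists_by_cell: Mapping[str, Mapping[str, RepeatHistogram]],
    cfg: ThresholdConfig | None = None,
    grid: FitGrid | None = None,
    params: StutterParams | None = None,
    pooled_calls: Mapping[str, GenotypeCall] | None = None,
) -> HetLocusSet:
    """Identify confidently heterozygous loci from the pooled population.

    Histograms are summed across all cells per locus and genotyped; a
    locus is admitted iff the pooled call is accepted, has two alleles at
    least ``min_allele_sep`` repeat units apart, and the pooled coverage
    strictly exceeds ``min_het_depth``.  Precomputed ``pooled_calls`` (from
    :func:`population_calls`) may be passed to avoid refitting.
    """
    cfg = cfg or ThresholdConfig()
    grid = grid or FitGrid(correlation_min=cfg.correlation_min)
    if not hists_by_cell:
        raise ValueError("need at least one cell")
    pooled = pool_histograms(hists_by_cell)
    admitted: dict[str, HetLocus] = {}
    for locus_id, merged in pooled.items():
        total = merged.total
        if total <= cfg.min_het_depth:
            continue
        if pooled_calls is not None and locus_id in pooled_calls:
            call = pooled_calls[locus_id]
        else:
            call = fit_genotype(merged, grid, params)
        if call.status != "called" or not call.is_het:
            continue
        if call.separation < cfg.min_allele_sep:
            continue
        admitted[locus_id] = HetLocus(
            locus_id=locus_id,
            a1=call.alleles[0],
            a2=call.alleles[1],
            pooled_total=total,
        )
    result = HetLocusSet(loci=admitted)
    result.validate(cfg)
    return result


def allelic_balance(
    cell_calls: Mapping[str, GenotypeCall],
    het_set: HetLocusSet,
) -> tuple[dict[str, float], float | None]:
    """Shorter-allele proportions of one cell at population-het loci.

    For every het-set locus the cell has an accepted call at, report the
    fitted shorter-allele weight ``w``.  A homozygous cell-level call at a
    population-heterozygous locus is complete allelic dropout and scores
    ``w = 1`` when the surviving allele is the population's shorter one,
    ``w = 0`` for the longer (a call matching neither allele is skipped).

    Returns ``(w by locus, median |w - 0.5|)``; the summary is None when
    no locus qualifies.
    """
    if len(het_set) == 0:
        raise ValueError("het_set must be non-empty")
    w_by_locus: dict[str, float] = {}
    for het in het_set:
        call = cell_calls.get(het.locus_id)
        if call is None or call.status != "called":
            continue
        if call.is_het:
            w_by_locus[het.locus_id] = call.proportion_shorter
        else:
            a = call.alleles[0]
            d1, d2 = abs(a - het.a1), abs(a - het.a2)
            if d1 < d2:
                w_by_locus[het.locus_id] = 1.0
            elif d2 < d1:
                w_by_locus[het.locus_id] = 0.0
            # equidistant: allele identity ambiguous, skip
    if not w_by_locus:
        return {}, None
    dev = float(np.median([abs(w - 0.5) for w in w_by_locus.values()]))
    return w_by_locus, dev


def downsample_reads(
    hists: Mapping[str, RepeatHistogram],
    cfg: ThresholdConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> dict[str, RepeatHistogram] | None:
    """Virtually resample a cell to exactly ``consistency_reads`` mapped reads.

    Cells with fewer mapped reads are excluded (returns None).  Sampling
    is without replacement across all (locus, repeat-count) read bins —
    a multivariate hypergeometric draw — and deterministic under a seed.
    """
    cfg = cfg or ThresholdConfig()
    keys: list[tuple[str, int]] = []
    colors: list[int] = []
    for locus_id in hists:
        h = hists[locus_id]
        for r in sorted(h.counts):
            keys.append((locus_id, r))
            colors.append(h.counts[r])
    total = sum(colors)
    if total < cfg.consistency_reads:
        return None
    if total == cfg.consistency_reads:
        return {
            lid: RepeatHistogram(locus_id=lid, counts=dict(h.counts))
            for lid, h in hists.items()
        }
    rng = np.random.default_rng(seed)
    draw = rng.multivariate_hypergeometric(
        np.asarray(colors, dtype=np.int64), cfg.consistency_reads, method="marginals"
    )
    out: dict[str, RepeatHistogram] = {}
    for (locus_id, r), n in zip(keys, draw):
        if n == 0:
            continue
        h = out.get(locus_id)
        if h is None:
            out[locus_id] = RepeatHistogram(locus_id=locus_id, counts={r: int(n)})
        else:
            h.add(r, int(n))
    return out


def _sampled_matrix(
    cell_hists: Sequence[Mapping[str, RepeatHistogram]], cfg: ThresholdConfig
) -> np.ndarray:
    """Boolean cells x loci matrix of sampled loci, bit-packed per row."""
    loci = sorted({lid for hists in cell_hists for lid in hists})
    pos = {lid: i for i, lid in enumerate(loci)}
    mat = np.zeros((len(cell_hists), len(loci)), dtype=bool)
    for i, hists in enumerate(cell_hists):
        for lid, h in hists.items():
            if h.total >= cfg.min_reads_per_locus_sampled:
                mat[i, pos[lid]] = True
    return np.packbits(mat, axis=1)


def consistency_curve(
    cell_hists: Sequence[Mapping[str, RepeatHistogram]],
    cfg: ThresholdConfig | None = None,
    ks: Sequence[int] = (2, 3, 4, 5),
    seed: int | np.random.SeedSequence | None = None,
    max_subsets: int = 10_000,
) -> tuple[dict[int, tuple[float, int]] | None, str | None]:
    """Mean number of jointly sampled loci among k-cell groups of one kit.

    ``cell_hists`` must already be downsampled/retained (see
    :func:`downsample_reads`).  For each k the mean intersection size is
    taken over all C(n, k) groups when that count is at most
    ``max_subsets``, otherwise over ``max_subsets`` seeded random groups.

    Returns ``(curve, excluded_reason)`` where ``curve`` maps
    k -> (mean intersection, number of groups) and is None when the kit
    has fewer than ``min_cells_per_kit`` retained cells.  The curve is
    checked to be non-increasing in k.
    """
    cfg = cfg or ThresholdConfig()
    n = len(cell_hists)
    if n < cfg.min_cells_per_kit:
        return None, f"only {n} cells with >= {cfg.consistency_reads} mapped reads"
    packed = _sampled_matrix(cell_hists, cfg)
    rng = np.random.default_rng(seed)
    curve: dict[int, tuple[float, int]] = {}
    prev = math.inf
    for k in ks:
        if k > n:
            continue
        n_groups = math.comb(n, k)
        if n_groups <= max_subsets:
            idx = np.array(list(itertools.combinations(range(n), k)))
        else:
            idx = np.array([rng.choice(n, size=k, replace=False) for _ in range(max_subsets)])
            n_groups = max_subsets
        inter = np.bitwise_and.reduce(packed[idx], axis=1)
        sizes = _POPCOUNT[inter].sum(axis=1)
        mean = float(sizes.mean())
        if mean > prev + 1e-9:
            raise AssertionError(f"consistency curve increased at k={k}")
        prev = mean
        curve[k] = (mean, int(n_groups))
    return curve, None
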