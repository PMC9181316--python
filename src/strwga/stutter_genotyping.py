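"""PCR-stutter simulation and correlation-based STR genotyping.

During amplification, polymerase slippage adds or removes whole repeat
units, so the reads covering one STR allele form a *stutter* distribution
of repeat lengths around the true allele.  This module models that
distribution as a function of the number of amplification cycles, fits
one- and two-allele stutter mixtures to observed repeat-number histograms
by Pearson correlation, and summarises per-cell amplification noise as
fitted cycle equivalents.

Model
-----
Let ``f_c`` be the expected (normalized) repeat-length distribution of the
molecule pool after ``c`` cycles.  Each cycle, every molecule is duplicated
with probability ``e`` (per-cycle efficiency); a new copy slips with
probability ``s``, removing one unit with probability ``q`` and adding one
with probability ``1 - q``.  Taking expectations:

    f_{c+1}(x) = [ (1 + e(1-s)) f_c(x)
                   + e s ( q f_c(x+1) + (1-q) f_c(x-1) ) ] / (1 + e)

with ``f_0`` a point mass at the allele and the support clipped at one
repeat (a down-slip from a single-unit tract leaves it at one unit).  The
recursion is linear, so a heterozygous locus propagates as the weighted
mixture of the two single-allele distributions.

Genotyping follows the "closest simulated pattern" rule: candidate
patterns ``w * stutter(a1, c) + (1-w) * stutter(a2, c)`` (plus single-allele
candidates) are scored by Pearson correlation against the normalized
histogram over a window spanning the observed support +/- 5 units; the
best-scoring candidate is reported, and calls with correlation below 0.95
are flagged ``no_call``.  Fitted cycles are expressed on a PCR-cycle grid
regardless of chemistry, so noise from isothermal (MDA) amplification is
reported in PCR-cycle equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .panel_io import Panel
    from .str_mapping import RepeatHistogram

__all__ = [
    "StutterParams",
    "FitGrid",
    "GenotypeCall",
    "stutter_distribution",
    "fit_genotype",
    "noise_summary",
    "sample_repeat_histogram",
    "write_calls",
    "read_calls",
]

_SCORE_TOL = 1e-9


@dataclass(frozen=True)
class StutterParams:
    """Slippage-model parameters.

    efficiency
        Per-cycle duplication probability ``e`` in (0, 1].
    slip
        Per-duplication slippage probability ``s`` in [0, 1).
    down_bias
        Probability ``q`` that a slip removes (rather than adds) one unit;
        slippage predominantly shortens the tract, hence the default 0.8.
    """

    efficiency: float = 0.95
    slip: float = 0.003
    down_bias: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must be in (0, 1]")
        if not 0.0 <= self.slip < 1.0:
            raise ValueError("slip must be in [0, 1)")
        if not 0.0 <= self.down_bias <= 1.0:
            raise ValueError("down_bias must be in [0, 1]")


@dataclass(frozen=True)
class FitGrid:
    """Search grid for the genotyper.

    allele_margin
        Candidate alleles range over the observed support widened by this
        many repeat units on each side.
    cycles
        Cycle grid (PCR-cycle equivalents).
    w_grid
        Shorter-allele weight grid for two-allele candidates; homozygous
        candidates are always included in addition.
    correlation_min
        Minimum Pearson correlation for an accepted call.
    window_pad
        Correlation window = observed support +/- window_pad.
    """

    allele_margin: int = 3
    cycles: tuple[int, ...] = tuple(range(0, 91, 2))
    w_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
    correlation_min: float = 0.95
    window_pad: int = 5

    def __post_init__(self) -> None:
        if not self.cycles or not self.w_grid:
            raise ValueError("cycle and weight grids must be non-empty")
        if not 0.0 < self.correlation_min <= 1.0:
            raise ValueError("correlation_min must be in (0, 1]")


@dataclass(frozen=True)
class GenotypeCall:
    """Result of fitting stutter mixtures to one repeat-number histogram.

    ``proportion_shorter`` is always the weight of the *shorter* allele;
    homozygous calls carry ``proportion_shorter = 1.0`` by convention.
    """

    locus_id: str
    alleles: tuple[int, ...]
    proportion_shorter: float
    cycles: int
    correlation: float
    status: str  # "called" | "no_call"

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2

    @property
    def separation(self) -> int:
        return self.alleles[-1] - self.alleles[0] if self.is_het else 0


def _propagate(f0: np.ndarray, cycles: int, params: StutterParams) -> np.ndarray:
    """Apply the per-cycle recursion to an initial length distribution.

    ``f0`` is indexed by repeat count with index 0 unused (always zero);
    the array must be long enough to hold ``cycles`` upward slips.
    """
    e, s, q = params.efficiency, params.slip, params.down_bias
    f = f0.astype(float).copy()
    stay = 1.0 + e * (1.0 - s)
    for _ in range(cycles):
        down = np.zeros_like(f)
        down[1:-1] = f[2:]  # a copy of length x+1 slipping down lands on x
        down[1] += f[1]  # clip: down-slip from one repeat stays at one
        up = np.zeros_like(f)
        up[2:] = f[1:-1]
        f = (stay * f + e * s * (q * down + (1.0 - q) * up)) / (1.0 + e)
    return f


@lru_cache(maxsize=512)
def _stutter_family(
    allele: int, max_cycles: int, params: StutterParams
) -> np.ndarray:
    """Matrix of stutter distributions, one row per cycle count 0..max_cycles.

    Row ``c`` is indexed by repeat count (index 0 unused).
    """
    size = allele + max_cycles + 2
    fam = np.zeros((max_cycles + 1, size))
    f = np.zeros(size)
    f[allele] = 1.0
    fam[0] = f
    for c in range(1, max_cycles + 1):
        f = _propagate(f, 1, params)
        fam[c] = f
    fam.setflags(write=False)
    return fam


def stutter_distribution(
    allele: int, cycles: int, params: StutterParams | None = None
) -> np.ndarray:
    """Repeat-length distribution of one allele after ``cycles`` cycles.

    Returns an array ``p`` indexed by repeat count (``p[r]`` is the
    probability of observing ``r`` repeats; ``p[0]`` is always zero).
    ``cycles = 0`` gives a point mass at the allele.
    """
    if allele < 1:
        raise ValueError("allele must be >= 1 repeat unit")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    params = params or StutterParams()
    return _stutter_family(allele, cycles, params)[cycles].copy()


def sample_repeat_histogram(
    probs: np.ndarray, n_reads: int, rng: np.random.Generator, locus_id: str = "locus"
) -> "RepeatHistogram":
    """Draw a repeat-number histogram of ``n_reads`` from a length distribution.

    ``probs`` is indexed by repeat count as returned by
    :func:`stutter_distribution` (mixtures are fine as long as it sums to 1).
    """
    from .str_mapping import RepeatHistogram

    counts = rng.multinomial(n_reads, probs / probs.sum())
    return RepeatHistogram(
        locus_id=locus_id,
        counts={int(r): int(c) for r, c in enumerate(counts) if c > 0},
    )


def _window_slice(dist: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Values of a repeat-count-indexed distribution on window [lo, hi]."""
    out = np.zeros(hi - lo + 1)
    src_lo = max(lo, 0)
    src_hi = min(hi, len(dist) - 1)
    if src_hi >= src_lo:
        out[src_lo - lo : src_hi - lo + 1] = dist[src_lo : src_hi + 1]
    return out


def fit_genotype(
    hist: "RepeatHistogram | Mapping[int, int]",
    grid: FitGrid | None = None,
    params: StutterParams | None = None,
    alleles: tuple[int, ...] | None = None,
) -> GenotypeCall:
    """Fit one- and two-allele stutter mixtures to a repeat-number histogram.

    Every candidate pattern on the grid is scored by Pearson correlation
    against the normalized histogram over the window spanning the observed
    support +/- ``grid.window_pad``; the best-scoring candidate wins.  Ties
    (within 1e-9) prefer fewer alleles, then lower cycles, then smaller
    allele separation, then the lower first allele.  A best score below
    ``grid.correlation_min`` yields ``status="no_call"`` with the best
    candidate still reported.

    When ``alleles`` is given, the candidate genotypes are restricted to
    that allele pair (or single allele) and its single-allele dropout
    cases, and only the mixture weight and cycle count are searched.  This
    is the seeded-by-genotype mode used once the population genotype of a
    clonal cell set is established: it avoids the inherent confusability
    between a lightly-stuttered single allele and an adjacent low-weight
    allele pair.
    """
    grid = grid or FitGrid()
    params = params or StutterParams()
    counts = hist.counts if hasattr(hist, "counts") else dict(hist)
    locus_id = getattr(hist, "locus_id", "locus")
    counts = {int(r): int(c) for r, c in counts.items() if c > 0}
    if not counts:
        raise ValueError("cannot genotype an empty histogram")

    obs = sorted(counts)
    lo = max(1, obs[0] - grid.window_pad)
    hi = obs[-1] + grid.window_pad
    width = hi - lo + 1
    y = np.zeros(width)
    for r, c in counts.items():
        if lo <= r <= hi:
            y[r - lo] = c
    y = y / y.sum()
    yc = y - y.mean()
    ynorm = float(np.sqrt((yc**2).sum()))

    if alleles is not None:
        if not alleles or any(a < 1 for a in alleles) or len(alleles) > 2:
            raise ValueError("allele constraint must be one or two repeat counts >= 1")
        allele_grid = np.array(sorted(set(int(a) for a in alleles)))
    else:
        allele_grid = np.arange(
            max(1, obs[0] - grid.allele_margin), obs[-1] + grid.allele_margin + 1
        )
    cycles = np.asarray(grid.cycles, dtype=int)
    max_c = int(cycles.max())
    nA, nC = len(allele_grid), len(cycles)

    # S[a, c, :]: centered candidate pattern on the window
    S = np.empty((nA, nC, width))
    for i, a in enumerate(allele_grid):
        fam = _stutter_family(int(a), max_c, params)
        for j, c in enumerate(cycles):
            S[i, j] = _window_slice(fam[c], lo, hi)
    Sc = S - S.mean(axis=2, keepdims=True)
    ydots = Sc @ yc  # (nA, nC)
    sq = np.einsum("acw,acw->ac", Sc, Sc)  # squared norms

    # -- single-allele candidates ------------------------------------------
    denom = np.sqrt(sq) * ynorm
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_single = np.where(denom > 0, ydots / np.where(denom > 0, denom, 1.0), 0.0)

    best: tuple | None = None  # (score, n_alleles, cycles, sep, a1, w, alleles)

    def consider(score, n_all, cyc, sep, a1, w, alleles_tuple):
        """Keep the higher score; break near-ties (1e-9) by fewer alleles,
        then lower cycles, then smaller separation, then lower a1."""
        nonlocal best
        if (
            best is None
            or score > best[0] + _SCORE_TOL
            or (
                score >= best[0] - _SCORE_TOL
                and (n_all, cyc, sep, a1) < (best[1], best[2], best[3], best[4])
            )
        ):
            best = (score, n_all, cyc, sep, a1, w, alleles_tuple)

    # scan all singles near the max within tolerance for deterministic ties
    smax = float(corr_single.max())
    for i, j in zip(*np.nonzero(corr_single >= smax - _SCORE_TOL)):
        consider(
            float(corr_single[i, j]), 1, int(cycles[j]), 0, int(allele_grid[i]), 1.0,
            (int(allele_grid[i]),),
        )

    # -- two-allele candidates ---------------------------------------------
    if nA >= 2:
        ii, jj = np.triu_indices(nA, k=1)  # a1 < a2
        w = np.asarray(grid.w_grid)[None, None, :]  # (1, 1, nW)
        # per-cycle cross products between centered single patterns
        G = np.einsum("acw,bcw->abc", Sc, Sc)  # (nA, nA, nC)
        num = w * ydots[ii, :, None] + (1 - w) * ydots[jj, :, None]
        den2 = (
            w**2 * sq[ii, :, None]
            + (1 - w) ** 2 * sq[jj, :, None]
            + 2 * w * (1 - w) * G[ii, jj][:, :, None]
        )
        den = np.sqrt(np.maximum(den2, 0.0)) * ynorm
        with np.errstate(invalid="ignore", divide="ignore"):
            corr_pair = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        pmax = float(corr_pair.max())
        if pmax >= best[0] - _SCORE_TOL:
            for p, j, k in zip(*np.nonzero(corr_pair >= pmax - _SCORE_TOL)):
                a1, a2 = int(allele_grid[ii[p]]), int(allele_grid[jj[p]])
                consider(
                    float(corr_pair[p, j, k]), 2, int(cycles[j]), a2 - a1, a1,
                    float(grid.w_grid[k]), (a1, a2),
                )

    score, _, cyc, _, _, w_best, alleles_tuple = best
    score = float(min(1.0, score))
    return GenotypeCall(
        locus_id=locus_id,
        alleles=alleles_tuple,
        proportion_shorter=w_best if len(alleles_tuple) == 2 else 1.0,
        cycles=cyc,
        correlation=score,
        status="called" if score >= grid.correlation_min else "no_call",
    )


def noise_summary(
    calls_by_cell: Mapping[str, Iterable[GenotypeCall]],
    panel: "Panel",
    unit_filter: str = "AC",
    min_calls: int = 20,
) -> pd.DataFrame:
    """Per-cell median fitted cycles over called loci of one repeat-unit type.

    The amplification-noise statistic compares kits on AC-type loci by
    default.  Cells with fewer than ``min_calls`` qualifying calls are
    flagged ``low_support``; cells with none get a missing median.
    """
    units = panel.units()
    rows = []
    for cell_id, calls in calls_by_cell.items():
        cyc = [
            c.cycles
            for c in calls
            if c.status == "called" and units.get(c.locus_id) == unit_filter
        ]
        rows.append(
            {
                "cell_id": cell_id,
                "median_cycles": float(np.median(cyc)) if cyc else np.nan,
                "n_calls": len(cyc),
                "low_support": len(cyc) < min_calls,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "median_cycles", "n_calls", "low_support"])


CALL_COLUMNS = ("cell_id", "locus_id", "a1", "a2", "w", "cycles", "correlation", "status")


def write_calls(
    calls_by_cell: Mapping[str, Iterable[GenotypeCall]], path
) -> None:
    """Write per-cell genotype calls as a tab-separated table."""
    rows = []
    for cell_id, calls in calls_by_cell.items():
        for c in calls:
            rows.append(
                (
                    cell_id,
                    c.locus_id,
                    c.alleles[0],
                    c.alleles[1] if c.is_het else "",
                    c.proportion_shorter,
                    c.cycles,
                    c.correlation,
                    c.status,
                )
            )
    pd.DataFrame(rows, columns=list(CALL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_calls(path) -> dict[str, list[GenotypeCall]]:
    """Read a calls table written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "locus_id": str})
    out: dict[str, list[GenotypeCall]] = {}
    for row in df.itertuples(index=False):
        a2 = getattr(row, "a2")
        het = pd.notna(a2) and str(a2) != ""
        alleles = (int(row.a1), int(float(a2))) if het else (int(row.a1),)
        out.setdefault(str(row.cell_id), []).append(
            GenotypeCall(
                locus_id=str(row.locus_id),
                alleles=alleles,
                proportion_shorter=float(row.w),
                cycles=int(row.cycles),
                correlation=float(row.correlation),
                status=str(row.status),
            )
        )
    return out
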