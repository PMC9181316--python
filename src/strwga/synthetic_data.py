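"""Clonal-population and WGA-distortion simulator with targeted-read output.

The generator stands in for a clonal human ES-cell experiment: every
simulated cell shares one diploid genotype over the STR panel (so at most
two distinct alleles exist population-wide at any locus), and each
amplification-kit profile distorts that genotype with cell-level failure,
locus and allele dropout, length-biased allelic imbalance and
cycle-dependent stutter before MIP-style single-end amplicon reads are
emitted with a per-locus ground-truth sidecar.

Kit profiles are loaded from a versioned YAML config
(:func:`preset_kit_profiles`); their numeric values are synthetic and only
their qualitative orderings are meaningful.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .panel_io import Panel, StrLocus, DEFAULT_FLANK_LEN
from .stutter_genotyping import StutterParams, stutter_distribution

__all__ = [
    "CloneTruth",
    "KitProfile",
    "CellState",
    "CellSample",
    "generate_clone",
    "simulate_wga_cell",
    "emit_reads",
    "emit_histograms",
    "preset_kit_profiles",
    "load_kit_profiles",
    "make_synthetic_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_FAILED_RETENTION_BETA = (1.0, 10.0)  # global locus-retention draw for failed cells


@dataclass(frozen=True)
class CloneTruth:
    """Ground-truth diploid genotype of the clonal population.

    ``alleles`` maps locus_id -> (a1, a2) repeat counts with a1 <= a2;
    ``capture`` maps locus_id -> probe capture efficiency in (0, 1].
    """

    alleles: dict[str, tuple[int, int]]
    capture: dict[str, float]

    def is_het(self, locus_id: str) -> bool:
        a1, a2 = self.alleles[locus_id]
        return a1 != a2

    @property
    def het_loci(self) -> list[str]:
        return [l for l in self.alleles if self.is_het(l)]


@dataclass(frozen=True)
class KitProfile:
    """Simulation parameters of one WGA condition.

    ``noise_cycles_mean``/``sd`` are in PCR-cycle equivalents;
    ``length_bias_beta`` is the per-repeat-unit relative efficiency
    penalty, so an allele of ``a`` repeats amplifies proportionally to
    ``exp(-beta * a)`` (longer alleles under-amplified);
    ``locus_dropout_systematic`` is the fraction of panel loci that fail
    reproducibly in every cell of this kit, while ``locus_dropout_prob``
    is drawn independently per cell.
    """

    name: str
    chemistry: str  # "MDA" | "PCR" | "bulk"
    cell_failure_prob: float
    locus_dropout_prob: float
    allele_dropout_prob: float
    noise_cycles_mean: float
    noise_cycles_sd: float
    length_bias_beta: float
    yield_mean: float
    yield_dispersion: float
    locus_dropout_systematic: float = 0.0

    def __post_init__(self) -> None:
        if self.chemistry not in ("MDA", "PCR", "bulk"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        for attr in (
            "cell_failure_prob",
            "locus_dropout_prob",
            "allele_dropout_prob",
            "locus_dropout_systematic",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr} must be a probability, got {v}")
        if self.noise_cycles_mean < 0 or self.noise_cycles_sd < 0:
            raise ValueError(f"{self.name}: noise cycles must be >= 0")
        if self.yield_mean < 0 or self.yield_dispersion <= 0:
            raise ValueError(f"{self.name}: yield parameters must be positive")

    def systematic_dropout(self, locus_id: str) -> bool:
        """Deterministic per-kit, per-locus reproducible failure."""
        if self.locus_dropout_systematic <= 0.0:
            return False
        u = zlib.crc32(f"{self.name}:{locus_id}".encode()) / 2**32
        return u < self.locus_dropout_systematic


@dataclass
class LocusState:
    """Post-amplification state of one locus in one cell."""

    alleles: list[tuple[int, float]]  # (repeat count, relative weight)
    cycles: int
    dist: np.ndarray  # mixed repeat-length distribution, indexed by repeat count
    capture: float


@dataclass
class CellState:
    """One amplified cell: per-locus molecule-length distributions."""

    cell_id: str
    kit: str
    profile: KitProfile
    failed: bool
    loci: dict[str, LocusState]


@dataclass
class CellSample:
    """An emitted cell: reads on disk (or histograms) plus a truth sidecar."""

    cell_id: str
    kit: str
    fastq_path: Path | None
    sidecar: pd.DataFrame
    n_reads: int


def generate_clone(
    panel: Panel,
    het_fraction: float = 0.3,
    min_sep: int = 1,
    max_sep: int = 8,
    seed: int | np.random.SeedSequence | None = None,
    capture: float | tuple[float, float] = (8.0, 2.0),
) -> CloneTruth:
    """Draw the clonal diploid genotype over a panel.

    Each locus is heterozygous with probability ``het_fraction``; a
    heterozygous locus carries two alleles centred on the reference repeat
    count and separated by a uniform draw on ``[min_sep, max_sep]`` repeat
    units.  ``capture`` is either a constant probe capture efficiency or a
    Beta(a, b) pair it is drawn from per locus.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must be in [0, 1]")
    if not 1 <= min_sep <= max_sep:
        raise ValueError("need 1 <= min_sep <= max_sep")
    rng = np.random.default_rng(seed)
    alleles: dict[str, tuple[int, int]] = {}
    capture_eff: dict[str, float] = {}
    for locus in panel:
        het = rng.random() < het_fraction
        if het:
            sep = int(rng.integers(min_sep, max_sep + 1))
            a1 = max(1, locus.ref_repeats - (sep + 1) // 2)
            alleles[locus.locus_id] = (a1, a1 + sep)
        else:
            alleles[locus.locus_id] = (locus.ref_repeats, locus.ref_repeats)
        if isinstance(capture, tuple):
            capture_eff[locus.locus_id] = float(rng.beta(*capture))
        else:
            capture_eff[locus.locus_id] = float(capture)
    return CloneTruth(alleles=alleles, capture=capture_eff)


def simulate_wga_cell(
    clone: CloneTruth,
    profile: KitProfile,
    seed: int | np.random.SeedSequence | None = None,
    cell_id: str = "cell",
    stutter_params: StutterParams | None = None,
) -> CellState:
    """Amplify one cell of the clone under a kit profile.

    Applies, in order: global cell failure (a Beta-distributed locus
    retention multiplier), systematic and random locus dropout, per-allele
    dropout, length-biased allele weighting, and stutter propagation at a
    per-locus cycle count drawn from a truncated normal.
    """
    rng = np.random.default_rng(seed)
    stutter_params = stutter_params or StutterParams()
    failed = bool(rng.random() < profile.cell_failure_prob)
    retention = float(rng.beta(*_FAILED_RETENTION_BETA)) if failed else 1.0
    loci: dict[str, LocusState] = {}
    for locus_id, (a1, a2) in clone.alleles.items():
        if profile.systematic_dropout(locus_id):
            continue
        keep_p = (1.0 - profile.locus_dropout_prob) * retention
        if rng.random() >= keep_p:
            continue
        survivors = [a for a in (a1, a2) if rng.random() >= profile.allele_dropout_prob]
        if not survivors:
            continue
        cycles = max(0, int(round(rng.normal(profile.noise_cycles_mean, profile.noise_cycles_sd))))
        weights = np.array(
            [math.exp(-profile.length_bias_beta * a) for a in survivors]
        )
        weights = weights / weights.sum()
        size = max(survivors) + cycles + 2
        dist = np.zeros(size)
        merged: dict[int, float] = {}
        for a, w in zip(survivors, weights):
            merged[a] = merged.get(a, 0.0) + float(w)
            d = stutter_distribution(a, cycles, stutter_params)
            dist[: len(d)] += w * d
        loci[locus_id] = LocusState(
            alleles=sorted(merged.items()),
            cycles=cycles,
            dist=dist,
            capture=clone.capture[locus_id],
        )
    return CellState(
        cell_id=cell_id, kit=profile.name, profile=profile, failed=failed, loci=loci
    )


def _locus_read_counts(
    cell: CellState, panel: Panel, mean_depth: float, rng: np.random.Generator
) -> dict[str, int]:
    """Per-locus read counts ~ NB(mean_depth * yield * capture, dispersion)."""
    profile = cell.profile
    counts = {}
    for locus in panel:
        state = cell.loci.get(locus.locus_id)
        if state is None:
            continue
        mu = mean_depth * profile.yield_mean * state.capture
        if mu <= 0:
            counts[locus.locus_id] = 0
            continue
        k = profile.yield_dispersion
        if math.isinf(k):
            n = int(rng.poisson(mu))
        else:
            n = int(rng.negative_binomial(k, k / (k + mu)))
        counts[locus.locus_id] = n
    return counts


def _mutate_reads(
    template: str, n: int, seq_error: float, rng: np.random.Generator
) -> list[str]:
    """``n`` copies of ``template`` with per-base substitution errors."""
    if seq_error <= 0.0 or n == 0:
        return [template] * n
    length = len(template)
    n_err = rng.binomial(length, seq_error, size=n)
    reads = []
    arr = np.frombuffer(template.encode(), dtype="S1")
    for k in n_err:
        if k == 0:
            reads.append(template)
            continue
        pos = rng.choice(length, size=int(k), replace=False)
        mutated = arr.copy()
        for p in pos:
            choices = _BASES[_BASES != mutated[p]]
            mutated[p] = choices[rng.integers(0, len(choices))]
        reads.append(mutated.tobytes().decode())
    return reads


def _sidecar_frame(cell: CellState, counts: Mapping[str, int]) -> pd.DataFrame:
    rows = []
    for locus_id, state in cell.loci.items():
        for a, w in state.alleles:
            rows.append(
                (cell.cell_id, locus_id, a, w, state.cycles, counts.get(locus_id, 0))
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "locus_id", "allele", "weight", "applied_cycles", "reads"]
    )


def emit_reads(
    cell: CellState,
    panel: Panel,
    out_fastq: str | Path,
    mean_depth: float = 40.0,
    read_len: int = 150,
    seq_error: float = 0.001,
    seed: int | np.random.SeedSequence | None = None,
    sidecar_path: str | Path | None = None,
) -> CellSample:
    """Emit single-end amplicon reads for one cell as FASTQ (+ truth sidecar).

    Each read is the amplicon sense strand ``left_flank + unit*r +
    right_flank`` truncated at ``read_len``, with ``r`` drawn from the
    locus's simulated length distribution and bases substituted at
    ``seq_error``.  Qualities are constant 'I' (Phred+33).  Output is
    byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    counts = _locus_read_counts(cell, panel, mean_depth, rng)
    total = 0
    out_fastq = Path(out_fastq)
    with open(out_fastq, "w") as fh:
        for locus in panel:
            state = cell.loci.get(locus.locus_id)
            if state is None:
                continue
            n = counts[locus.locus_id]
            if n == 0:
                continue
            p = state.dist / state.dist.sum()
            rs = rng.choice(len(p), size=n, p=p)
            order = np.sort(rs)
            # group identical repeat counts so the template is built once
            for r in np.unique(order):
                m = int((order == r).sum())
                template = locus.amplicon(int(r))[:read_len]
                qual = "I" * len(template)
                for i, seq in enumerate(_mutate_reads(template, m, seq_error, rng)):
                    fh.write(
                        f"@{cell.cell_id}|{locus.locus_id}|{r}|{total + i}\n"
                        f"{seq}\n+\n{qual}\n"
                    )
                total += m
    sidecar = _sidecar_frame(cell, counts)
    if sidecar_path is not None:
        sidecar.to_csv(sidecar_path, sep="\t", index=False)
    if total == 0:
        import warnings

        warnings.warn(f"cell {cell.cell_id}: zero reads emitted", stacklevel=2)
    return CellSample(
        cell_id=cell.cell_id, kit=cell.kit, fastq_path=out_fastq,
        sidecar=sidecar, n_reads=total,
    )


def emit_histograms(
    cell: CellState,
    panel: Panel,
    mean_depth: float = 40.0,
    seed: int | np.random.SeedSequence | None = None,
):
    """Sample per-locus repeat-number histograms directly (no reads).

    Fast error-free alternative to FASTQ emission + mapping for
    simulation studies; equivalent to mapping reads emitted with
    ``seq_error=0`` and an untruncated read length.
    """
    from .str_mapping import RepeatHistogram

    rng = np.random.default_rng(seed)
    counts = _locus_read_counts(cell, panel, mean_depth, rng)
    hists: dict[str, RepeatHistogram] = {}
    for locus in panel:
        state = cell.loci.get(locus.locus_id)
        if state is None:
            continue
        n = counts[locus.locus_id]
        if n == 0:
            continue
        p = state.dist / state.dist.sum()
        draw = rng.multinomial(n, p)
        hists[locus.locus_id] = RepeatHistogram(
            locus_id=locus.locus_id,
            counts={int(r): int(c) for r, c in enumerate(draw) if c > 0},
        )
    return hists, _sidecar_frame(cell, counts)


def load_kit_profiles(path: str | Path) -> dict[str, KitProfile]:
    """Load kit profiles from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: KitProfile(name=name, **cfg) for name, cfg in raw.items()}


def preset_kit_profiles() -> dict[str, KitProfile]:
    """The packaged eight-kit preset profiles (synthetic parameter values)."""
    ref = resources.files("strwga.data").joinpath("kit_presets.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {name: KitProfile(name=name, **cfg) for name, cfg in raw.items()}


def _random_flank(
    length: int, unit: str, rng: np.random.Generator, side: str
) -> str:
    """Random flank that does not extend the repeat tract at the boundary."""
    from .panel_io import _adjacent_unit_copies

    while True:
        flank = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=length)
        )
        if _adjacent_unit_copies(flank, unit, side) == 0:
            return flank


def make_synthetic_panel(
    n_loci: int,
    seed: int | np.random.SeedSequence | None = None,
    units: Mapping[str, float] | None = None,
    ref_repeats: tuple[int, int] = (8, 22),
    flank_len: int = DEFAULT_FLANK_LEN,
    name: str = "synthetic",
) -> tuple[Panel, dict[str, str]]:
    """Generate a synthetic STR panel and its reference chromosome.

    Loci are laid out head-to-tail on one synthetic chromosome with the
    declared flanks embedded in the reference, so the panel round-trips
    through :func:`strwga.panel_io.read_panel`.  ``units`` maps repeat unit
    -> sampling weight; the default panel is dominated by AC-type loci,
    mirroring dinucleotide-rich genome-wide STR panels.

    Returns ``(panel, {chrom: sequence})``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    units = units or {"AC": 0.8, "AG": 0.1, "AT": 0.05, "AGAT": 0.05}
    rng = np.random.default_rng(seed)
    unit_names = list(units)
    unit_p = np.array([units[u] for u in unit_names], dtype=float)
    unit_p = unit_p / unit_p.sum()
    chrom = "chrS1"
    parts: list[str] = []
    pos = 0
    loci = []
    pad = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10))
    for i in range(n_loci):
        unit = unit_names[rng.choice(len(unit_names), p=unit_p)]
        reps = int(rng.integers(ref_repeats[0], ref_repeats[1] + 1))
        left = _random_flank(flank_len, unit, rng, "left")
        right = _random_flank(flank_len, unit, rng, "right")
        tract = unit * reps
        parts.extend([pad, left, tract, right])
        start = pos + len(pad) + len(left)
        end = start + len(tract)
        pos = end + len(right)
        loci.append(
            StrLocus(
                locus_id=f"L{i:05d}",
                chrom=chrom,
                start=start,
                end=end,
                unit=unit,
                ref_repeats=reps,
                left_flank=left,
                right_flank=right,
            )
        )
    return Panel(loci=tuple(loci), name=name), {chrom: "".join(parts)}
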