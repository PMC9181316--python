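"""Flank-anchored STR-aware read mapping.

Targeted amplicon reads are assigned to panel loci by locating both flank
anchors (the ``anchor_len`` bases of each flank adjacent to the repeat
tract) and requiring the spanned interval to be an exact whole-number of
repeat units matching the locus unit.  This is output-equivalent, on
amplicon reads, to end-to-end alignment against the length-permuted
reference of :func:`strwga.panel_io.build_permuted_reference` while being
orders of magnitude cheaper; the permuted reference is retained as the
exhaustive cross-check.

Reads are tried in both orientations; a read whose candidate anchors
resolve to more than one locus is left unmapped (ambiguity is a value,
not an error), as is a read whose repeat tract is truncated by the read
end (no partial repeat counting).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel_io import Panel, DEFAULT_ANCHOR_LEN

__all__ = [
    "RepeatHistogram",
    "MappingStats",
    "AnchorIndex",
    "assign_read",
    "histograms_from_fastq",
    "write_histograms",
    "read_histograms",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnchorCollisionError(ValueError):
    """Two panel loci share a flank anchor; the message lists them."""


@dataclass
class RepeatHistogram:
    """Per-locus map repeat-count -> read count; the pipeline's central
    intermediate."""

    locus_id: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        for r, c in self.counts.items():
            if r < 0 or c < 1:
                raise ValueError(
                    f"histogram {self.locus_id}: invalid entry {r} -> {c}"
                )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, repeat_count: int, n: int = 1) -> None:
        self.counts[repeat_count] = self.counts.get(repeat_count, 0) + n

    @classmethod
    def merge(cls, hists: Iterable["RepeatHistogram"], locus_id: str | None = None):
        """Pool histograms (e.g. the same locus across cells)."""
        counts: dict[int, int] = {}
        lid = locus_id
        for h in hists:
            lid = lid or h.locus_id
            for r, c in h.counts.items():
                counts[r] = counts.get(r, 0) + c
        return cls(locus_id=lid or "pooled", counts=counts)


@dataclass
class MappingStats:
    reads_total: int = 0
    reads_mapped: int = 0
    per_locus: dict[str, int] = field(default_factory=dict)

    @property
    def mapping_rate(self) -> float:
        return self.reads_mapped / self.reads_total if self.reads_total else 0.0

    def validate(self) -> None:
        if self.reads_mapped > self.reads_total:
            raise ValueError("reads_mapped exceeds reads_total")
        if sum(self.per_locus.values()) != self.reads_mapped:
            raise ValueError("per-locus counts do not sum to reads_mapped")

    def to_json(self) -> str:
        return json.dumps(
            {
                "reads_total": self.reads_total,
                "reads_mapped": self.reads_mapped,
                "mapping_rate": self.mapping_rate,
                "per_locus": self.per_locus,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class _LocusAnchors:
    locus_id: str
    unit: str
    left_anchor: str
    right_anchor: str
    left_offset: int  # position of the left anchor in an untrimmed amplicon read


class AnchorIndex:
    """Exact-anchor lookup tables over a panel.

    Anchors must be unique across loci; collisions raise
    :class:`AnchorCollisionError` listing the offending loci.
    """

    def __init__(
        self,
        panel: Panel,
        anchor_len: int = DEFAULT_ANCHOR_LEN,
        max_mismatch: int = 1,
        max_tract_mismatch: int = 1,
    ) -> None:
        self.anchor_len = anchor_len
        self.max_mismatch = max_mismatch
        self.max_tract_mismatch = max_tract_mismatch
        self.loci: dict[str, _LocusAnchors] = {}
        self._scan: dict[str, tuple[str, str]] = {}  # anchor -> (locus_id, side)
        self._left_exact: dict[str, str] = {}
        collisions = []
        for locus in panel:
            la = locus.left_flank[-anchor_len:]
            ra = locus.right_flank[:anchor_len]
            info = _LocusAnchors(
                locus_id=locus.locus_id,
                unit=locus.unit,
                left_anchor=la,
                right_anchor=ra,
                left_offset=len(locus.left_flank) - anchor_len,
            )
            self.loci[locus.locus_id] = info
            for anchor, side in ((la, "left"), (ra, "right")):
                prev = self._scan.get(anchor)
                if prev is not None and prev[0] != locus.locus_id:
                    collisions.append((prev[0], locus.locus_id, anchor))
                self._scan[anchor] = (locus.locus_id, side)
            self._left_exact[la] = locus.locus_id
        if collisions:
            raise AnchorCollisionError(
                "anchor collisions between loci: "
                + ", ".join(f"{a}/{b} ({anc})" for a, b, anc in collisions)
            )
        self.left_offsets = sorted({i.left_offset for i in self.loci.values()})


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, early-exiting past ``limit``."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _anchor_positions(seq: str, anchor: str, limit: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where ``anchor`` occurs with <= limit
    mismatches."""
    la = len(anchor)
    out = []
    for p in range(len(seq) - la + 1):
        mm = _hamming(seq[p : p + la], anchor, limit)
        if mm <= limit:
            out.append((p, mm))
    return out


def _evaluate_locus(
    seq: str, info: _LocusAnchors, index: AnchorIndex
) -> tuple[int, int] | None:
    """Best (repeat_count, total_mismatches) for one candidate locus, or None."""
    alen = index.anchor_len
    lhits = _anchor_positions(seq, info.left_anchor, index.max_mismatch)
    if not lhits:
        return None
    rhits = _anchor_positions(seq, info.right_anchor, index.max_mismatch)
    if not rhits:
        return None
    lu = len(info.unit)
    best: tuple[int, int] | None = None  # (mismatches, repeat count)
    for pl, lmm in lhits:
        tract_start = pl + alen
        for pr, rmm in rhits:
            span = pr - tract_start
            if span < lu or span % lu:
                continue
            r = span // lu
            tmm = _hamming(seq[tract_start:pr], info.unit * r, index.max_tract_mismatch)
            if tmm > index.max_tract_mismatch:
                continue
            total = lmm + rmm + tmm
            if best is None or (total, -r) < best:
                best = (total, -r)
    if best is None:
        return None
    return (-best[1], best[0])


def _assign_orientation(seq: str, index: AnchorIndex) -> tuple[str, int] | None:
    """Unique locus hit for one read orientation, or None."""
    alen = index.anchor_len
    candidates: set[str] = set()
    for p in range(len(seq) - alen + 1):
        hit = index._scan.get(seq[p : p + alen])
        if hit is not None:
            candidates.add(hit[0])
    results = {}
    for locus_id in candidates:
        res = _evaluate_locus(seq, index.loci[locus_id], index)
        if res is not None:
            results[locus_id] = res
    if len(results) != 1:
        return None  # unmapped or ambiguous multi-locus hit
    (locus_id, (r, _)), = results.items()
    return locus_id, r


def assign_read(seq: str, index: AnchorIndex) -> tuple[str, int] | None:
    """Assign one read to ``(locus_id, repeat_count)`` or return None.

    The fast path assumes an untrimmed sense-strand amplicon (exact left
    anchor at its template offset, exact tract and right anchor); all
    other reads fall back to mismatch-tolerant anchor scanning on both
    orientations.
    """
    seq = seq.upper()
    alen = index.anchor_len
    # fast path: exact sense-strand amplicon structure
    for off in index.left_offsets:
        locus_id = index._left_exact.get(seq[off : off + alen])
        if locus_id is None:
            continue
        info = index.loci[locus_id]
        lu = len(info.unit)
        pos = off + alen
        r = 0
        while seq.startswith(info.unit, pos):
            pos += lu
            r += 1
        if r >= 1 and seq.startswith(info.right_anchor, pos):
            return locus_id, r
    fwd = _assign_orientation(seq, index)
    rev = _assign_orientation(_revcomp(seq), index)
    if fwd and rev and fwd[0] != rev[0]:
        return None  # orientations disagree on the locus
    return fwd or rev


def histograms_from_fastq(
    fastq_path: str | Path,
    panel_or_index: Panel | AnchorIndex,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = 1,
    max_tract_mismatch: int = 1,
) -> tuple[dict[str, RepeatHistogram], MappingStats]:
    """Map a FASTQ (optionally gzipped) to per-locus repeat-number histograms.

    Returns one histogram per locus with at least one mapped read, plus
    mapping statistics satisfying the conservation invariant
    ``sum(per-locus) == reads_mapped <= reads_total``.
    """
    if isinstance(panel_or_index, AnchorIndex):
        index = panel_or_index
    else:
        index = AnchorIndex(
            panel_or_index,
            anchor_len=anchor_len,
            max_mismatch=max_mismatch,
            max_tract_mismatch=max_tract_mismatch,
        )
    fastq_path = Path(fastq_path)
    opener = gzip.open if fastq_path.suffix == ".gz" else open
    hists: dict[str, RepeatHistogram] = {}
    stats = MappingStats()
    with opener(fastq_path, "rt") as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            stats.reads_total += 1
            hit = assign_read(seq, index)
            if hit is None:
                continue
            locus_id, r = hit
            stats.reads_mapped += 1
            stats.per_locus[locus_id] = stats.per_locus.get(locus_id, 0) + 1
            h = hists.get(locus_id)
            if h is None:
                hists[locus_id] = RepeatHistogram(locus_id=locus_id, counts={r: 1})
            else:
                h.add(r)
    stats.validate()
    return hists, stats


HISTOGRAM_COLUMNS = ("cell_id", "locus_id", "repeat_count", "reads")


def write_histograms(
    hists_by_cell: Mapping[str, Mapping[str, RepeatHistogram]], path: str | Path
) -> None:
    """Write per-cell histograms in long tab-separated format."""
    rows = []
    for cell_id, hists in hists_by_cell.items():
        for locus_id, h in hists.items():
            for r in sorted(h.counts):
                rows.append((cell_id, locus_id, r, h.counts[r]))
    pd.DataFrame(rows, columns=list(HISTOGRAM_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_histograms(path: str | Path) -> dict[str, dict[str, RepeatHistogram]]:
    """Read a long-format histogram table back into nested mappings."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "locus_id": str})
    out: dict[str, dict[str, RepeatHistogram]] = {}
    for row in df.itertuples(index=False):
        cell = out.setdefault(str(row.cell_id), {})
        h = cell.get(str(row.locus_id))
        if h is None:
            cell[str(row.locus_id)] = RepeatHistogram(
                locus_id=str(row.locus_id), counts={int(row.repeat_count): int(row.reads)}
            )
        else:
            h.add(int(row.repeat_count), int(row.reads))
    return out
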