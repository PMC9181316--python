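"""STR panel model and the length-permuted mapping reference.

A *panel* is an ordered collection of targeted short-tandem-repeat (STR)
loci, each described by its genomic interval, repeat unit and reference
repeat count, together with the flanking sequence a targeted amplicon
carries on either side of the repeat tract.  The panel abstraction mirrors
genome-wide MIP panels of ~12,000 STR loci; coordinates follow the BED
convention (0-based, half-open).

The module also builds the *permuted reference*: for every locus, one
FASTA record per plausible repeat count, ``left_flank + unit*r +
right_flank``.  STR-aware read mapping is equivalent to end-to-end
alignment against this reference; downstream the permuted reference is
kept as the exhaustive construction, while :mod:`strwga.str_mapping`
implements the fast flank-anchored equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

#: default flanking sequence length extracted around each repeat tract (bp)
DEFAULT_FLANK_LEN = 40
#: default anchor length used for flank-anchored mapping (bp)
DEFAULT_ANCHOR_LEN = 15
#: default half-width of the repeat-count permutation range (repeat units)
DEFAULT_PERMUTATION_HALFWIDTH = 20

PANEL_COLUMNS = ("chrom", "start", "end", "locus_id", "unit", "ref_repeats")


class PanelError(ValueError):
    """Malformed panel input (missing chromosome, bad coordinates, ...)."""


class PanelValidationError(PanelError):
    """A locus violates a structural invariant; the message names the locus."""


def is_primitive_unit(unit: str) -> bool:
    """True when ``unit`` is not itself a repetition of a shorter unit.

    E.g. ``"AC"`` is primitive while ``"ACAC"`` is not.
    """
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _adjacent_unit_copies(flank: str, unit: str, side: str) -> int:
    """Number of exact tandem copies of ``unit`` at the repeat-facing end."""
    n = 0
    lu = len(unit)
    if side == "left":  # copies at the *end* of the left flank
        while flank.endswith(unit * (n + 1)):
            n += 1
    else:  # copies at the *start* of the right flank
        while flank.startswith(unit * (n + 1)):
            n += 1
    return n


@dataclass(frozen=True)
class StrLocus:
    """One targeted STR locus.

    ``start``/``end`` delimit the repeat tract (0-based, half-open), so
    ``end - start == ref_repeats * len(unit)`` must hold.  Flanks are the
    sequences immediately outside the tract and must be long enough to
    carry a mapping anchor and free of tandem unit copies at the boundary
    (which would make the repeat-tract boundary ambiguous).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    unit: str
    ref_repeats: int
    left_flank: str
    right_flank: str

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise PanelValidationError("locus with empty locus_id")
        if self.start < 0 or self.end < self.start:
            raise PanelValidationError(
                f"locus {self.locus_id}: bad coordinates [{self.start}, {self.end})"
            )
        if not self.unit or set(self.unit) - set("ACGT"):
            raise PanelValidationError(
                f"locus {self.locus_id}: repeat unit {self.unit!r} is not a DNA string"
            )
        if self.ref_repeats < 1:
            raise PanelValidationError(
                f"locus {self.locus_id}: ref_repeats must be >= 1"
            )
        if self.end - self.start != self.ref_repeats * len(self.unit):
            raise PanelValidationError(
                f"locus {self.locus_id}: tract length {self.end - self.start} != "
                f"ref_repeats ({self.ref_repeats}) x unit length ({len(self.unit)})"
            )
        if not is_primitive_unit(self.unit):
            raise PanelValidationError(
                f"locus {self.locus_id}: unit {self.unit!r} is not primitive"
            )
        for side, flank in (("left", self.left_flank), ("right", self.right_flank)):
            if len(flank) < DEFAULT_ANCHOR_LEN:
                raise PanelValidationError(
                    f"locus {self.locus_id}: {side} flank shorter than anchor "
                    f"length ({DEFAULT_ANCHOR_LEN} bp)"
                )
            max_copies = math.ceil(DEFAULT_ANCHOR_LEN / len(self.unit))
            if _adjacent_unit_copies(flank, self.unit, side) >= max_copies:
                raise PanelValidationError(
                    f"locus {self.locus_id}: {side} flank extends the repeat tract "
                    f"with >= {max_copies} copies of {self.unit!r}"
                )

    @property
    def tract_length(self) -> int:
        return self.end - self.start

    def amplicon(self, repeats: int | None = None) -> str:
        """Amplicon sequence for a given repeat count (default: reference)."""
        r = self.ref_repeats if repeats is None else repeats
        return self.left_flank + self.unit * r + self.right_flank


@dataclass(frozen=True)
class Panel:
    """An ordered, uniquely-identified collection of STR loci."""

    loci: tuple[StrLocus, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        ids = [locus.locus_id for locus in self.loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate locus_ids in panel: {dupes}")
        object.__setattr__(self, "_by_id", {l.locus_id: l for l in self.loci})

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[StrLocus]:
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> StrLocus:
        return self._by_id[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def units(self) -> dict[str, str]:
        """Map locus_id -> repeat unit."""
        return {l.locus_id: l.unit for l in self.loci}


def _sniff_header(path: Path) -> bool:
    """True when the first non-comment line looks like a header row."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise PanelError(
                    f"{path}: expected 6 tab-separated columns, got {len(fields)}"
                )
            try:
                int(fields[1])
                return False
            except ValueError:
                return True
    raise PanelError(f"{path}: no data rows")


def read_panel(
    panel_table_path: str | Path,
    reference_path: str | Path,
    flank_len: int = DEFAULT_FLANK_LEN,
    name: str | None = None,
    verify_tract: bool = True,
) -> Panel:
    """Read a 6-column panel table and extract flanks from a reference FASTA.

    Parameters
    ----------
    panel_table_path
        Tab-separated table with columns chrom, start, end, locus_id, unit,
        ref_repeats.  ``#`` comment lines allowed; a header row is detected
        automatically.
    reference_path
        FASTA containing every chromosome named in the table.
    flank_len
        Number of bases extracted on each side of the repeat tract.
    verify_tract
        When true, additionally check that the reference sequence between
        ``start`` and ``end`` is exactly ``unit * ref_repeats``.
    """
    panel_table_path = Path(panel_table_path)
    header = _sniff_header(panel_table_path)
    df = pd.read_csv(
        panel_table_path,
        sep="\t",
        comment="#",
        header=0 if header else None,
        names=None if header else list(PANEL_COLUMNS),
        dtype={"chrom": str, "locus_id": str, "unit": str},
    )
    if header:
        missing = set(PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise PanelError(f"{panel_table_path}: missing columns {sorted(missing)}")
    reference = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference_path), "fasta")
    }
    loci = []
    for row in df.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in reference:
            raise PanelError(
                f"locus {row.locus_id}: chromosome {chrom!r} not in reference"
            )
        seq = reference[chrom]
        start, end = int(row.start), int(row.end)
        if start < 0 or end > len(seq):
            raise PanelError(
                f"locus {row.locus_id}: coordinates [{start}, {end}) out of range "
                f"for {chrom} (length {len(seq)})"
            )
        unit = str(row.unit).upper()
        if verify_tract and seq[start:end] != unit * int(row.ref_repeats):
            raise PanelValidationError(
                f"locus {row.locus_id}: reference tract does not match "
                f"{unit!r} x {int(row.ref_repeats)}"
            )
        loci.append(
            StrLocus(
                locus_id=str(row.locus_id),
                chrom=chrom,
                start=start,
                end=end,
                unit=unit,
                ref_repeats=int(row.ref_repeats),
                left_flank=seq[max(0, start - flank_len) : start],
                right_flank=seq[end : end + flank_len],
            )
        )
    return Panel(loci=tuple(loci), name=name or panel_table_path.stem)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write the 6-column tab-separated panel table."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PANEL_COLUMNS) + "\n")
        for l in panel:
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t{l.unit}\t{l.ref_repeats}\n"
            )


def permuted_record_id(locus_id: str, repeats: int) -> str:
    return f"{locus_id}|{repeats}"


def parse_permuted_record_id(record_id: str) -> tuple[str, int]:
    locus_id, _, r = record_id.rpartition("|")
    return locus_id, int(r)


def permutation_range(
    locus: StrLocus,
    min_rep: int | None = None,
    max_rep: int | None = None,
    halfwidth: int = DEFAULT_PERMUTATION_HALFWIDTH,
) -> range:
    """Repeat-count range permuted for a locus (default: ref +/- halfwidth)."""
    lo = max(1, locus.ref_repeats - halfwidth) if min_rep is None else min_rep
    hi = (locus.ref_repeats + halfwidth) if max_rep is None else max_rep
    if lo < 1 or hi < lo:
        raise PanelError(f"invalid permutation range [{lo}, {hi}]")
    return range(lo, hi + 1)


def build_permuted_reference(
    panel: Panel,
    min_rep: int | None = None,
    max_rep: int | None = None,
    halfwidth: int = DEFAULT_PERMUTATION_HALFWIDTH,
) -> Iterator[SeqRecord]:
    """Yield one FASTA record per locus per repeat-count permutation.

    With explicit ``min_rep``/``max_rep`` the same range is used for every
    locus and exactly ``len(panel) * (max_rep - min_rep + 1)`` records are
    produced; otherwise each locus is permuted over ``ref_repeats +/-
    halfwidth`` clipped at one repeat.
    """
    if len(panel) == 0:
        raise PanelError("cannot build a permuted reference from an empty panel")
    for locus in panel:
        for r in permutation_range(locus, min_rep, max_rep, halfwidth):
            yield SeqRecord(
                Seq(locus.amplicon(r)),
                id=permuted_record_id(locus.locus_id, r),
                description="",
            )


def write_permuted_reference(
    panel: Panel,
    path: str | Path,
    min_rep: int | None = None,
    max_rep: int | None = None,
    halfwidth: int = DEFAULT_PERMUTATION_HALFWIDTH,
    wrap: int = 80,
) -> int:
    """Write the permuted reference as FASTA; returns the record count."""
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        return writer.write_file(build_permuted_reference(panel, min_rep, max_rep, halfwidth))


def write_reference_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, wrap: int = 80
) -> None:
    """Write (name, sequence) pairs as a wrapped FASTA file."""
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(
            SeqRecord(Seq(seq), id=name, description="") for name, seq in records
        )
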