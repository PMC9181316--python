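"""Independent reference implementations used only to check the package.

These oracles deliberately share no code with the implementation paths
they validate: the stutter oracle is a stochastic branching-process
simulation (the implementation is a deterministic expectation recursion),
and the mapping oracle scores reads end-to-end against every record of
the length-permuted reference (the implementation is flank-anchored
counting).
"""

from __future__ import annotations

import numpy as np

from strwga.panel_io import Panel, build_permuted_reference, parse_permuted_record_id
from strwga.stutter_genotyping import StutterParams


def mc_stutter(
    allele: int,
    cycles: int,
    params: StutterParams,
    founders: int = 100_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo branching-process stutter distribution.

    ``founders`` identical molecules are amplified for ``cycles`` cycles;
    each molecule duplicates with probability ``e``, each new copy slips
    with probability ``s`` (down one unit with probability ``q``, up
    otherwise; a down-slip from one repeat stays at one).  Returns the
    normalized length distribution, indexed by repeat count.  Intended
    for moderate cycle counts (population counts must fit in int64).
    """
    rng = np.random.default_rng(seed)
    size = allele + cycles + 2
    n = np.zeros(size, dtype=np.int64)
    n[allele] = founders
    e, s, q = params.efficiency, params.slip, params.down_bias
    for _ in range(cycles):
        new = rng.binomial(n, e)
        slipped = rng.binomial(new, s)
        down = rng.binomial(slipped, q)
        up = slipped - down
        nxt = n + new - slipped
        nxt[1:-1] += down[2:]  # x -> x-1
        nxt[1] += down[1]  # clipped at one repeat
        nxt[2:] += up[1:-1]  # x -> x+1
        n = nxt
    return n / n.sum()


class PermutedReferenceAligner:
    """Brute-force end-to-end aligner against the permuted reference.

    Scores a read by Hamming distance against every permuted-reference
    record of the same length (both orientations) and reports the unique
    best hit, or None when there is no hit within ``max_total_mismatch``
    or the best distance is attained at records of different loci.
    """

    _COMP = str.maketrans("ACGT", "TGCA")

    def __init__(
        self,
        panel: Panel,
        min_rep: int | None = None,
        max_rep: int | None = None,
        max_total_mismatch: int = 3,
    ) -> None:
        self.max_total_mismatch = max_total_mismatch
        self.by_length: dict[int, list[tuple[str, int, str]]] = {}
        for rec in build_permuted_reference(panel, min_rep, max_rep):
            locus_id, r = parse_permuted_record_id(rec.id)
            seq = str(rec.seq)
            self.by_length.setdefault(len(seq), []).append((locus_id, r, seq))

    def assign(self, read: str) -> tuple[str, int] | None:
        hits: list[tuple[int, str, int]] = []
        for seq in (read, read.translate(self._COMP)[::-1]):
            for locus_id, r, ref in self.by_length.get(len(seq), []):
                d = sum(a != b for a, b in zip(seq, ref))
                if d <= self.max_total_mismatch:
                    hits.append((d, locus_id, r))
        if not hits:
            return None
        hits.sort()
        best = hits[0][0]
        top = {(l, r) for d, l, r in hits if d == best}
        if len({l for l, _ in top}) != 1:
            return None
        (locus_id, r), = top if len(top) == 1 else (sorted(top)[0],)
        return locus_id, r
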