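"""Mismatch-bounded, fixed-offset mapping of read pairs to consensus loci.

Because the insert size is pinned to the consensus length (300 bp), mates are
anchored at fixed offsets — the forward mate against consensus positions
1-101 and the reverse mate against positions 200-300 — and no positional
search is performed.  A pair maps to the reference with the minimum total
substitution count over both mates (up to the bound, default 3); ties break
deterministically to the lowest locus id.  Candidate references come from a
pigeonhole substring index over the 202 informative bases, exhaustive within
the mismatch bound; unit depth is the read pair.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import chunk_spans, hamming, percent, seq_to_idx, seq_to_u8
from .cluster import ConsensusLocus
from .reads import ReadPair


@dataclass(frozen=True)
class MappedPair:
    pair: ReadPair
    locus_id: str
    mismatches: int


class ReferenceIndex:
    """Exact-substring lookup over reference informative bases."""

    def __init__(self, references: list[ConsensusLocus],
                 max_mismatch: int = 3):
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        self.max_mismatch = max_mismatch
        self.references = sorted(references, key=lambda r: r.locus_id)
        self.by_id = {r.locus_id: r for r in self.references}
        self._arrays = [seq_to_u8(r.informative) for r in self.references]
        if self.references:
            self._spans = chunk_spans(len(self.references[0].informative),
                                      max_mismatch + 1)
        else:
            self._spans = []
        self._index: dict[tuple[int, str], list[int]] = defaultdict(list)
        for ri, ref in enumerate(self.references):
            info = ref.informative
            for i, (a, b) in enumerate(self._spans):
                self._index[(i, info[a:b])].append(ri)

    def candidates(self, cat: str) -> set[int]:
        cand: set[int] = set()
        for i, (a, b) in enumerate(self._spans):
            cand.update(self._index.get((i, cat[a:b]), ()))
        return cand


def map_pair(pair: ReadPair, index: ReferenceIndex,
             max_mismatch: int | None = None) -> MappedPair | None:
    """Best hit of one pair, or None if every reference exceeds the bound."""
    if max_mismatch is None:
        max_mismatch = index.max_mismatch
    cat = pair.fwd_seq + pair.rev_seq
    arr = seq_to_u8(cat)
    best_mm, best_ri = None, None
    for ri in index.candidates(cat):
        mm = hamming(arr, index._arrays[ri])
        if mm > max_mismatch:
            continue
        if best_mm is None or mm < best_mm or (mm == best_mm and
                                               ri < best_ri):
            best_mm, best_ri = mm, ri
    if best_mm is None:
        return None
    return MappedPair(pair, index.references[best_ri].locus_id, best_mm)


def map_all(pairs: list[ReadPair], index: ReferenceIndex
            ) -> tuple[list[MappedPair], dict[str, int], dict[str, int]]:
    """Map every pair; return hits plus per-founder mapped/total counts."""
    mapped: list[MappedPair] = []
    n_mapped: dict[str, int] = defaultdict(int)
    n_total: dict[str, int] = defaultdict(int)
    for p in pairs:
        n_total[p.founder_id] += 1
        hit = map_pair(p, index)
        if hit is not None:
            mapped.append(hit)
            n_mapped[p.founder_id] += 1
    return mapped, dict(n_mapped), dict(n_total)


class AlleleDepthTable:
    """Per (locus, offset, founder) base counts, in read-pair units.

    Offsets 0-100 cover consensus positions 1-101 and offsets 101-201 cover
    positions 200-300 (1-based); the N spacer carries no depth.
    """

    def __init__(self, founder_ids: tuple[str, ...], read_length: int = 101):
        self.founder_ids = tuple(founder_ids)
        self.read_length = read_length
        self._fidx = {f: i for i, f in enumerate(self.founder_ids)}
        self.counts: dict[str, np.ndarray] = {}
        self.pair_counts: dict[tuple[str, str], int] = defaultdict(int)

    @property
    def n_offsets(self) -> int:
        return 2 * self.read_length

    def locus_array(self, locus_id: str) -> np.ndarray:
        """(n_offsets, n_founders, 4) count array for one locus."""
        arr = self.counts.get(locus_id)
        if arr is None:
            arr = np.zeros((self.n_offsets, len(self.founder_ids), 4),
                           dtype=np.int32)
            self.counts[locus_id] = arr
        return arr

    def add(self, locus_id: str, founder_id: str, cat_seq: str,
            multiplicity: int = 1) -> None:
        arr = self.locus_array(locus_id)
        idx = seq_to_idx(cat_seq)
        arr[np.arange(self.n_offsets), self._fidx[founder_id], idx] \
            += multiplicity
        self.pair_counts[(locus_id, founder_id)] += multiplicity

    def offset_to_consensus_pos(self, offset: int) -> int:
        """1-based position on the 300-character consensus."""
        if offset < self.read_length:
            return offset + 1
        return offset + 99


def tally_alleles(mapped: list[MappedPair], founder_ids: tuple[str, ...],
                  read_length: int = 101) -> AlleleDepthTable:
    """Accumulate per-offset base depths from mapped pairs."""
    agg: dict[tuple[str, str, str], int] = defaultdict(int)
    for m in mapped:
        cat = m.pair.fwd_seq + m.pair.rev_seq
        agg[(m.locus_id, m.pair.founder_id, cat)] += 1
    table = AlleleDepthTable(founder_ids, read_length)
    for (locus_id, founder_id, cat), mult in agg.items():
        table.add(locus_id, founder_id, cat, mult)
    return table


def mapping_report(n_mapped: dict[str, int],
                   n_total: dict[str, int]) -> pd.DataFrame:
    """Per-founder mapping rates as percentages to one decimal."""
    rows = []
    for fid in sorted(n_total):
        total = n_total[fid]
        mapped = n_mapped.get(fid, 0)
        pct = percent(mapped, total) if total else None
        rows.append({"founder": fid, "n_pairs": total, "n_mapped": mapped,
                     "pct_mapped": pct})
    return pd.DataFrame(rows)
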