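"""Scoring discovered variants against the simulator's planted truth.

Simulated read identifiers encode their source fragment
(``founder:enzyme:hap:start:end:serial`` in haplotype coordinates), so a
consensus locus can be traced back to a genome region through its member
reads, consensus offsets converted to ancestral positions, and calls
compared with the truth table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .cluster import ConsensusLocus
from .simdata import (FounderGenome, SimConfig, Truth, library_inserts,
                      size_select)
from .variants import PutativeSNP, STRLocusGroup

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class ReadMeta:
    founder_id: str
    enzyme: str
    hap: int
    start: int
    end: int


def parse_read_id(read_id: str) -> ReadMeta:
    founder, enzyme, hap, start, end, _ = read_id.split(":")
    return ReadMeta(founder, enzyme, int(hap[1:]), int(start), int(end))


def locus_source(locus: ConsensusLocus) -> ReadMeta:
    """Majority source fragment of a locus's members."""
    votes = Counter(parse_read_id(p.read_id) for p in locus.members)
    return votes.most_common(1)[0][0]


def consensus_offset_to_ancestral(meta: ReadMeta, offset: int,
                                  founders: dict[str, FounderGenome],
                                  read_length: int = 101
                                  ) -> tuple[int, bool]:
    """(ancestral position, is_reverse_strand) of a consensus offset."""
    founder = founders[meta.founder_id]
    if offset < read_length:
        hap_pos = meta.start + offset
        rev = False
    else:
        hap_pos = meta.end - 1 - (offset - read_length)
        rev = True
    return founder.hap_to_anc(meta.hap, hap_pos), rev


def discoverable_snp_positions(truth: Truth, config: SimConfig
                               ) -> set[int]:
    """Segregating planted SNPs that fall in a read window of a
    size-selected ancestral fragment (the loci the design can observe)."""
    windows = []
    for enzyme in config.enzymes:
        for f in size_select(library_inserts(truth.ancestral, enzyme),
                             config.size_min, config.size_max):
            windows.append((f.start, f.start + config.read_length))
            windows.append((f.end - config.read_length, f.end))
    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    out = set()
    for pos in truth.segregating_snp_positions():
        if np.any((starts <= pos) & (pos < ends)):
            out.add(int(pos))
    return out


@dataclass
class SNPEvaluation:
    n_called: int
    n_matched: int
    n_discoverable: int
    n_recovered: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_called if self.n_called else float("nan")

    @property
    def recall(self) -> float:
        return (self.n_recovered / self.n_discoverable
                if self.n_discoverable else float("nan"))


def evaluate_snps(putative: list[PutativeSNP],
                  loci_by_id: dict[str, ConsensusLocus],
                  founders: list[FounderGenome],
                  config: SimConfig) -> SNPEvaluation:
    """Precision over called sites and recall over discoverable planted SNPs.

    A call matches when its ancestral position holds a planted SNP and the
    called allele pair equals the planted pair (complemented on the reverse
    segment).
    """
    truth = founders[0].truth
    by_id = {f.founder_id: f for f in founders}
    truth_alleles = {int(r.pos): (r.ref, r.alt)
                     for r in truth.snps.itertuples()}
    matched_positions = set()
    n_matched = 0
    for snp in putative:
        meta = locus_source(loci_by_id[snp.locus_id])
        pos, rev = consensus_offset_to_ancestral(
            meta, snp.offset, by_id, config.read_length)
        alleles = truth_alleles.get(pos)
        if alleles is None:
            continue
        called = {snp.major, snp.minor}
        if rev:
            called = {_COMP[b] for b in called}
        if called == set(alleles):
            n_matched += 1
            matched_positions.add(pos)
    discoverable = discoverable_snp_positions(truth, config)
    recovered = matched_positions & discoverable
    return SNPEvaluation(len(putative), n_matched, len(discoverable),
                         len(recovered))


@dataclass
class STREvaluation:
    n_planted: int
    n_recovered_exact: int
    n_groups: int

    @property
    def exact(self) -> bool:
        return (self.n_recovered_exact == self.n_planted
                and self.n_groups == self.n_planted)


def evaluate_strs(groups: list[STRLocusGroup],
                  loci_by_id: dict[str, ConsensusLocus],
                  founders: list[FounderGenome],
                  config: SimConfig) -> STREvaluation:
    """Exact-allele recovery of planted STR loci.

    Each merged group is traced to its ancestral host fragment; recovery is
    exact when the group's repeat-count allele set equals the planted one.
    """
    truth = founders[0].truth
    by_id = {f.founder_id: f for f in founders}
    planted = {}
    for r in truth.strs.itertuples():
        hap_cols = [c for c in truth.strs.columns
                    if c.endswith("_h1") or c.endswith("_h2")]
        counts = frozenset(int(getattr(r, c)) for c in hap_cols)
        planted[(r.enzyme, int(r.host_start))] = counts

    n_exact = 0
    seen = set()
    for g in groups:
        metas = [locus_source(loci_by_id[m.locus_id]) for m in g.members]
        anc_starts = {
            (m.enzyme, by_id[m.founder_id].hap_to_anc(m.hap, m.start))
            for m in metas}
        keys = [k for k in anc_starts if k in planted]
        if len(keys) != 1:
            continue
        key = keys[0]
        if key in seen:
            continue
        if frozenset(g.alleles) == planted[key]:
            n_exact += 1
            seen.add(key)
    return STREvaluation(len(planted), n_exact, len(groups))
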