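"""Greedy clustering of read pairs into loci and 300-bp consensus building.

Pairs of one terminal group are clustered SEED-style: no positional shifts,
distinct (forward, reverse) sequences processed in decreasing multiplicity,
each joining the earliest-founded cluster whose representative is within a
summed-substitution budget over both mates, else founding a new cluster.
Candidate clusters are found through a pigeonhole substring index
(``max_mismatch + 1`` exact chunks), which is exhaustive for substitution
distances up to the budget.

A cluster's consensus is the per-column majority of its members' mates,
joined by a 98-base N spacer into the 300-character locus reference whose
202 non-N positions are the informative bases.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import chunk_spans, hamming, seq_to_idx, seq_to_u8
from .reads import ReadPair

_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Cluster:
    representative: tuple[str, str]
    members: list[ReadPair] = field(default_factory=list, repr=False)

    @property
    def depth(self) -> int:
        return len(self.members)


@dataclass
class ConsensusLocus:
    """300-character locus reference: 101 forward + 98 N + 101 reverse."""

    locus_id: str
    group: str
    sequence: str
    depth: int
    members: list[ReadPair] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        read_len = (len(self.sequence) - 98) // 2
        spacer = self.sequence[read_len:read_len + 98]
        if set(spacer) - {"N"}:
            raise ValueError("locus spacer must be all N")

    @property
    def read_length(self) -> int:
        return (len(self.sequence) - 98) // 2

    @property
    def informative(self) -> str:
        """Forward and reverse consensus bases with the N spacer removed."""
        rl = self.read_length
        return self.sequence[:rl] + self.sequence[rl + 98:]


def cluster_pairs(pairs: list[ReadPair], max_mismatch: int = 3
                  ) -> list[Cluster]:
    """Partition pairs of one terminal group into greedy clusters.

    Distinct exact (fwd, rev) sequences are processed by decreasing
    multiplicity (ties lexicographic); each joins the first existing cluster
    whose representative differs by <= max_mismatch substitutions summed over
    both mates, else founds a new cluster.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be non-negative")
    if not pairs:
        return []
    groups: dict[tuple[str, str], list[ReadPair]] = defaultdict(list)
    for p in pairs:
        groups[(p.fwd_seq, p.rev_seq)].append(p)
    order = sorted(groups, key=lambda k: (-len(groups[k]), k))

    total_len = len(order[0][0]) + len(order[0][1])
    spans = chunk_spans(total_len, max_mismatch + 1)
    index: dict[tuple[int, str], list[int]] = defaultdict(list)
    clusters: list[Cluster] = []
    reps: list[np.ndarray] = []

    for key in order:
        cat = key[0] + key[1]
        arr = seq_to_u8(cat)
        cand: set[int] = set()
        for i, (a, b) in enumerate(spans):
            cand.update(index.get((i, cat[a:b]), ()))
        target = None
        for ci in sorted(cand):
            if hamming(arr, reps[ci]) <= max_mismatch:
                target = ci
                break
        if target is None:
            target = len(clusters)
            clusters.append(Cluster(representative=key))
            reps.append(arr)
            for i, (a, b) in enumerate(spans):
                index[(i, cat[a:b])].append(target)
        clusters[target].members.extend(groups[key])
    return clusters


def build_consensus(cluster: Cluster, locus_id: str, group: str,
                    spacer: int = 98) -> ConsensusLocus:
    """Majority-vote consensus of a cluster (ties broken A<C<G<T)."""
    if not cluster.members:
        raise ValueError("cannot build a consensus from an empty cluster")
    counts_by_seq: dict[tuple[str, str], int] = defaultdict(int)
    for p in cluster.members:
        counts_by_seq[(p.fwd_seq, p.rev_seq)] += 1
    rl = len(cluster.representative[0])
    tot = rl + len(cluster.representative[1])
    counts = np.zeros((tot, 4), dtype=np.int64)
    offsets = np.arange(tot)
    for (fwd, rev), mult in counts_by_seq.items():
        counts[offsets, seq_to_idx(fwd + rev)] += mult
    # argmax returns the first maximum, so ties resolve in A<C<G<T order
    cons = _IDX_TO_BASE[np.argmax(counts, axis=1)].tobytes().decode("ascii")
    sequence = cons[:rl] + "N" * spacer + cons[rl:]
    return ConsensusLocus(locus_id, group, sequence, cluster.depth,
                          members=list(cluster.members))


def select_references(loci: list[ConsensusLocus], min_depth: int = 10
                      ) -> tuple[list[ConsensusLocus], pd.DataFrame]:
    """Retain loci with depth >= min_depth; tabulate per-group counts."""
    kept = [loc for loc in loci if loc.depth >= min_depth]
    rows = []
    for group in sorted({loc.group for loc in loci}):
        n_all = sum(1 for loc in loci if loc.group == group)
        n_kept = sum(1 for loc in kept if loc.group == group)
        rows.append({"group": group, "n_consensus": n_all,
                     "n_reference": n_kept})
    return kept, pd.DataFrame(rows)


def write_reference_fasta(loci: list[ConsensusLocus], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(loc.sequence), id=loc.locus_id,
                  description=f"group={loc.group} depth={loc.depth}")
        for loc in loci
    ]
    seqio_write(records, path, "fasta")
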