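"""Paired FASTQ loading, N-filtering, and terminal-sequence grouping.

Read pairs are classified by their 5'-terminal sequences into three groups:
both mates starting with the HaeIII signature, both with the MboI signature,
or anything else.  HaeIII (GG^CC) leaves fragments that start with ``CC`` and
end with ``GG``, so both sequenced mates of a both-end HaeIII fragment start
with ``CC``; MboI (^GATC) fragments start with ``GATC`` at both sequenced
ends.  The match is exact — a sequencing error in the signature legitimately
sends the pair to OTHER.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

HAEIII_BOTH = "HAEIII_BOTH"
MBOI_BOTH = "MBOI_BOTH"
OTHER = "OTHER"
GROUPS = (HAEIII_BOTH, MBOI_BOTH, OTHER)

HAEIII_SIGNATURE = "CC"
MBOI_SIGNATURE = "GATC"


class FastqPairError(ValueError):
    """Malformed or desynchronised mate files."""


@dataclass(frozen=True)
class ReadPair:
    founder_id: str
    read_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str
    rev_qual: str
    group: str | None = None


def _core_id(title: str) -> str:
    """Record identifier with mate suffix (/1, /2 or space comment) removed."""
    head = title.split(None, 1)[0]
    if head.endswith("/1") or head.endswith("/2"):
        head = head[:-2]
    return head


def load_pairs(fastq_r1, fastq_r2, founder_id: str) -> Iterator[ReadPair]:
    """Stream mate-synchronised pairs from two FASTQ files.

    Raises :class:`FastqPairError` naming the offending record when the files
    desynchronise or their identifiers disagree.
    """
    with open(fastq_r1) as f1, open(fastq_r2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        n = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            n += 1
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                short = fastq_r2 if r1 is not None else fastq_r1
                raise FastqPairError(
                    f"mate files desynchronised at record {n}: "
                    f"{short} ended early")
            id1, id2 = _core_id(r1[0]), _core_id(r2[0])
            if id1 != id2:
                raise FastqPairError(
                    f"mate identifiers disagree at record {n}: "
                    f"{id1!r} vs {id2!r}")
            yield ReadPair(founder_id, id1, r1[1], r2[1], r1[2], r2[2])


def filter_pairs(pairs: Iterable[ReadPair]
                 ) -> tuple[list[ReadPair], int]:
    """Drop pairs where either mate contains an N; report the discard count."""
    kept, discarded = [], 0
    for p in pairs:
        if "N" in p.fwd_seq or "N" in p.rev_seq:
            discarded += 1
        else:
            kept.append(p)
    return kept, discarded


def classify_terminal(pair: ReadPair) -> str:
    """Terminal group of one pair (HAEIII_BOTH / MBOI_BOTH / OTHER)."""
    f, r = pair.fwd_seq, pair.rev_seq
    if f.startswith(HAEIII_SIGNATURE) and r.startswith(HAEIII_SIGNATURE):
        return HAEIII_BOTH
    if f.startswith(MBOI_SIGNATURE) and r.startswith(MBOI_SIGNATURE):
        return MBOI_BOTH
    return OTHER


def classify_pairs(pairs: Iterable[ReadPair]) -> list[ReadPair]:
    """Attach the terminal-group label to every pair."""
    return [replace(p, group=classify_terminal(p)) for p in pairs]


def quality_summary(pairs: Iterable[ReadPair],
                    discarded: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-founder read/base bookkeeping (reads = 2 x pairs).

    Columns: founder, n_reads, n_bases, n_discarded, and per-group pair
    counts.  Rows appear in founder order of first occurrence.
    """
    rows: dict[str, dict] = {}
    for p in pairs:
        row = rows.setdefault(p.founder_id, {
            "founder": p.founder_id, "n_reads": 0, "n_bases": 0,
            "n_discarded": 0, "n_haeiii_both": 0, "n_mboi_both": 0,
            "n_other": 0})
        row["n_reads"] += 2
        row["n_bases"] += len(p.fwd_seq) + len(p.rev_seq)
        group = p.group if p.group is not None else classify_terminal(p)
        key = {HAEIII_BOTH: "n_haeiii_both", MBOI_BOTH: "n_mboi_both",
               OTHER: "n_other"}[group]
        row[key] += 1
    if discarded:
        for fid, n in discarded.items():
            rows.setdefault(fid, {
                "founder": fid, "n_reads": 0, "n_bases": 0, "n_discarded": 0,
                "n_haeiii_both": 0, "n_mboi_both": 0, "n_other": 0})
            rows[fid]["n_discarded"] = n
    return pd.DataFrame(rows.values())


def pairs_from_records(records, founder_id: str,
                       quality_char: str = "I") -> list[ReadPair]:
    """Adapt simulator read records to ReadPairs without a FASTQ round trip."""
    return [
        ReadPair(founder_id, r.read_id, r.fwd, r.rev,
                 quality_char * len(r.fwd), quality_char * len(r.rev))
        for r in records
    ]
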