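"""SNP prediction and filtering, genotyping, depth-matching haplotype phasing,
and STR discovery/genotyping.

The SNP caller is a depth-based cascade.  Candidate ("predicted") SNPs are
consensus offsets with at least two observed bases and pooled depth >= 100
read pairs.  Four filters applied in order then yield the "putative" SNPs:

1. alleles with a depth of exactly 1 in a founder are zeroed in that founder;
2. sites where any founder's total depth exceeds 300 are removed (suspected
   collapsed repeats);
3. an allele is *present* in a founder when its depth exceeds 5% of that
   founder's total at the site; sites where any founder has 3+ present
   alleles, or where the pooled site does not have exactly 2 alleles, are
   removed;
4. sites where any founder carrying both alleles has an allele-depth ratio
   above 3 are removed (allele-specific artefacts and duplicated errors).

Genotypes are called from the presence rule for founders with total depth
>= 20.  Within one locus, alleles of different SNP offsets are phased into
haplotypes by depth matching: alleles whose pooled depths agree within a
tolerance (< 4 by default) are assumed to ride the same haplotype.

STRs are maximal pure tandem runs in the informative segments (di >= 8,
tri >= 5, tetra >= 4 repeat units); loci identical outside the run are
grouped, and each member consensus carries one repeat-count allele whose
depth is the read pairs mapped to it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import BASES, percent
from .cluster import ConsensusLocus
from .mapping import AlleleDepthTable

STR_THRESHOLDS = {2: 8, 3: 5, 4: 4}


# ---------------------------------------------------------------------------
# SNP prediction and the filter cascade
# ---------------------------------------------------------------------------

@dataclass
class PredictedSNP:
    """A multi-base consensus offset with pooled depth above the floor."""

    locus_id: str
    offset: int
    depths: np.ndarray  # (n_founders, 4), read-pair units

    @property
    def pooled_depth(self) -> int:
        return int(self.depths.sum())


@dataclass
class PutativeSNP:
    """A biallelic SNP surviving the four-filter cascade."""

    locus_id: str
    offset: int
    major: str
    minor: str
    depths: np.ndarray        # post-rule-1 (n_founders, 4)
    present: np.ndarray       # (n_founders, 4) presence-rule booleans

    @property
    def major_idx(self) -> int:
        return BASES.index(self.major)

    @property
    def minor_idx(self) -> int:
        return BASES.index(self.minor)

    def to_predicted(self) -> PredictedSNP:
        return PredictedSNP(self.locus_id, self.offset, self.depths.copy())


def predict_snps(table: AlleleDepthTable,
                 min_pooled_depth: int = 100) -> list[PredictedSNP]:
    """Every (locus, offset) with >=2 observed bases and pooled depth >= floor."""
    out: list[PredictedSNP] = []
    for locus_id in sorted(table.counts):
        arr = table.counts[locus_id]          # (offsets, founders, 4)
        pooled = arr.sum(axis=1)              # (offsets, 4)
        n_bases = (pooled > 0).sum(axis=1)
        depth = pooled.sum(axis=1)
        for off in np.flatnonzero((n_bases >= 2) &
                                  (depth >= min_pooled_depth)):
            out.append(PredictedSNP(locus_id, int(off),
                                    arr[off].astype(np.int64).copy()))
    return out


def _presence(depths: np.ndarray, presence_frac: float) -> np.ndarray:
    totals = depths.sum(axis=1, keepdims=True)
    return depths > presence_frac * totals


def filter_snps(predicted: list[PredictedSNP],
                max_founder_depth: int = 300,
                presence_frac: float = 0.05,
                max_ratio: float = 3.0) -> list[PutativeSNP]:
    """Apply the four filters in order; survivors carry major/minor labels.

    All comparisons are strict (> 300 removed, > 5% present, ratio > 3
    removed).  The depth cap and all later rules see post-rule-1 depths.
    """
    out: list[PutativeSNP] = []
    for site in predicted:
        d = site.depths.copy()
        d[d == 1] = 0                                   # rule 1
        founder_tot = d.sum(axis=1)
        if (founder_tot > max_founder_depth).any():     # rule 2
            continue
        present = _presence(d, presence_frac)           # rule 3
        if (present.sum(axis=1) >= 3).any():
            continue
        pooled = d.sum(axis=0)
        alleles = np.flatnonzero(pooled)
        if len(alleles) != 2:
            continue
        # rule 4: ratio between the site's two alleles, in any founder
        # carrying both at nonzero depth (a founder with one allele has no
        # ratio); this also removes sites whose only "second allele" is a
        # duplicated sequencing error riding far below the presence line
        ok = True
        both = d[:, alleles]
        for fi in range(d.shape[0]):
            lo, hi = both[fi].min(), both[fi].max()
            if lo > 0 and hi > max_ratio * lo:
                ok = False
                break
        if not ok:
            continue
        # major = larger pooled depth; tie -> lexicographically smaller base
        if pooled[alleles[0]] >= pooled[alleles[1]]:
            major_i, minor_i = alleles[0], alleles[1]
        else:
            major_i, minor_i = alleles[1], alleles[0]
        out.append(PutativeSNP(site.locus_id, site.offset,
                               BASES[major_i], BASES[minor_i], d, present))
    return out


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Complete loci x founders genotype table.

    ``df`` has columns locus_id, offset, major, minor plus one column per
    founder holding the major-allele count coding: hom_minor -> 0, het -> 1,
    hom_major -> 2.
    """

    df: pd.DataFrame
    founder_ids: tuple[str, ...]

    @property
    def codes(self) -> np.ndarray:
        return self.df[list(self.founder_ids)].to_numpy()

    @property
    def n_loci(self) -> int:
        return len(self.df)


def call_genotypes(putative: list[PutativeSNP],
                   founder_ids: tuple[str, ...],
                   min_founder_depth: int = 20) -> GenotypeMatrix:
    """Genotype matrix over SNPs with depth >= min_founder_depth in *every*
    founder; genotype follows the presence rule."""
    rows = []
    for snp in putative:
        totals = snp.depths.sum(axis=1)
        if (totals < min_founder_depth).any():
            continue
        row = {"locus_id": snp.locus_id, "offset": snp.offset,
               "major": snp.major, "minor": snp.minor}
        ok = True
        for fi, fid in enumerate(founder_ids):
            maj = bool(snp.present[fi, snp.major_idx])
            mino = bool(snp.present[fi, snp.minor_idx])
            if maj and mino:
                row[fid] = 1
            elif maj:
                row[fid] = 2
            elif mino:
                row[fid] = 0
            else:
                ok = False
                break
        if ok:
            rows.append(row)
    cols = ["locus_id", "offset", "major", "minor", *founder_ids]
    df = pd.DataFrame(rows, columns=cols)
    return GenotypeMatrix(df, tuple(founder_ids))


# ---------------------------------------------------------------------------
# depth-matching haplotype phasing
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSet:
    locus_id: str
    offsets: tuple[int, ...]
    # each haplotype: ({offset: base}, mean supporting depth)
    haplotypes: list[tuple[dict[int, str], float]]
    status: str  # "determined" | "undetermined"


def deduce_haplotypes(snps: list[PutativeSNP],
                      tolerance: float = 4.0) -> HaplotypeSet:
    """Phase the alleles of one locus's SNP offsets by pooled-depth matching.

    Records (offset, allele, pooled depth) are taken in decreasing depth; a
    record joins the earliest group whose running mean depth is within the
    tolerance and which has no allele at that offset yet, else founds a new
    group.  The locus is determined only when every group covers every offset
    exactly once and no record was depth-compatible with two or more groups
    (occupancy aside) — such a record could not be placed unambiguously.
    """
    if len(snps) < 2:
        raise ValueError("haplotype phasing needs >=2 SNP offsets in a locus")
    locus_id = snps[0].locus_id
    records = []
    for snp in snps:
        pooled = snp.depths.sum(axis=0)
        for base_i in (snp.major_idx, snp.minor_idx):
            records.append((snp.offset, BASES[base_i], int(pooled[base_i])))
    records.sort(key=lambda r: (-r[2], r[0], r[1]))

    groups: list[dict] = []
    ambiguous = False
    for offset, base, depth in records:
        compatible = [g for g in groups if abs(depth - g["mean"]) < tolerance]
        if len(compatible) >= 2:
            ambiguous = True
        target = next((g for g in compatible
                       if offset not in g["alleles"]), None)
        if target is None:
            target = {"alleles": {}, "depths": [], "mean": float(depth)}
            groups.append(target)
        target["alleles"][offset] = base
        target["depths"].append(depth)
        target["mean"] = float(np.mean(target["depths"]))

    offsets = tuple(sorted({snp.offset for snp in snps}))
    complete = all(set(g["alleles"]) == set(offsets) for g in groups)
    status = "determined" if (complete and not ambiguous) else "undetermined"
    haplotypes = [(dict(g["alleles"]), g["mean"]) for g in groups]
    return HaplotypeSet(locus_id, offsets, haplotypes, status)


def phase_all_loci(putative: list[PutativeSNP],
                   tolerance: float = 4.0) -> list[HaplotypeSet]:
    """Phase every locus carrying more than one putative SNP offset."""
    by_locus: dict[str, list[PutativeSNP]] = defaultdict(list)
    for snp in putative:
        by_locus[snp.locus_id].append(snp)
    return [deduce_haplotypes(snps, tolerance)
            for locus_id, snps in sorted(by_locus.items())
            if len(snps) >= 2]


def summarize_haplotypes(hapsets: list[HaplotypeSet]
                         ) -> tuple[pd.Series, float | None]:
    """Histogram of haplotype counts over determined loci, and the percent
    determined (one decimal; None when there are no multi-SNP loci)."""
    determined = [h for h in hapsets if h.status == "determined"]
    hist = pd.Series(
        [len(h.haplotypes) for h in determined], dtype=int
    ).value_counts().sort_index()
    hist.index.name = "n_haplotypes"
    pct = percent(len(determined), len(hapsets)) if hapsets else None
    return hist, pct


# ---------------------------------------------------------------------------
# STR detection, grouping, genotyping
# ---------------------------------------------------------------------------

def _canonical_motif(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_subperiodic(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return True
    return False


@dataclass(frozen=True)
class STRCandidate:
    locus_id: str
    segment: str          # "fwd" | "rev"
    motif: str            # canonical (lexicographically least rotation)
    count: int            # full repeat units
    start: int            # run start within the segment
    region_len: int       # maximal period-long stretch, may include a partial unit
    segment_seq: str


def _maximal_runs(seq: str, period: int):
    """Maximal stretches where seq[j] == seq[j - period]; yields
    (start, region_len, count) with count = full motif copies."""
    n = len(seq)
    j = period
    while j < n:
        if seq[j] == seq[j - period]:
            run_start = j - period
            while j < n and seq[j] == seq[j - period]:
                j += 1
            region_len = j - run_start
            yield run_start, region_len, region_len // period
        j += 1


def detect_strs(loci: list[ConsensusLocus],
                thresholds: dict[int, int] | None = None
                ) -> list[STRCandidate]:
    """Scan both informative segments of each locus for tandem repeats."""
    if thresholds is None:
        thresholds = STR_THRESHOLDS
    out: list[STRCandidate] = []
    for locus in loci:
        rl = locus.read_length
        segments = (("fwd", locus.sequence[:rl]),
                    ("rev", locus.sequence[rl + 98:]))
        for name, seg in segments:
            for period, min_count in thresholds.items():
                for start, region_len, count in _maximal_runs(seg, period):
                    if count < min_count:
                        continue
                    motif = seg[start:start + period]
                    if _is_subperiodic(motif):
                        continue
                    out.append(STRCandidate(
                        locus.locus_id, name, _canonical_motif(motif),
                        count, start, region_len, seg))
    return out


@dataclass
class STRLocusGroup:
    """Consensus loci identical outside the repeat run, merged into one STR
    locus; members carry the locus-specific repeat-count alleles."""

    group_id: str
    motif: str
    members: list[STRCandidate] = field(default_factory=list)

    @property
    def alleles(self) -> list[int]:
        return sorted({m.count for m in self.members})

    @property
    def allele_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for m in self.members:
            out[m.count].append(m.locus_id)
        return dict(out)


def _flanks_match(a: STRCandidate, b: STRCandidate,
                  max_mismatch: int) -> bool:
    la, ra = a.segment_seq[:a.start], a.segment_seq[a.start + a.region_len:]
    lb, rb = b.segment_seq[:b.start], b.segment_seq[b.start + b.region_len:]
    lmin, rmin = min(len(la), len(lb)), min(len(ra), len(rb))
    mm = sum(x != y for x, y in zip(la[len(la) - lmin:], lb[len(lb) - lmin:]))
    mm += sum(x != y for x, y in zip(ra[:rmin], rb[:rmin]))
    return mm <= max_mismatch


def group_str_loci(candidates: list[STRCandidate],
                   max_mismatch: int = 3) -> list[STRLocusGroup]:
    """Merge candidates whose motifs match and whose flanking sequence,
    aligned at the run boundaries after removing the run, differs by at most
    the mapping mismatch bound."""
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = candidates[i], candidates[j]
            if a.motif != b.motif or a.segment != b.segment:
                continue
            if _flanks_match(a, b, max_mismatch):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, list[STRCandidate]] = defaultdict(list)
    for i in range(n):
        comps[find(i)].append(candidates[i])
    groups = []
    for k, root in enumerate(sorted(comps,
                                    key=lambda r: candidates[r].locus_id)):
        members = sorted(comps[root], key=lambda c: c.locus_id)
        groups.append(STRLocusGroup(f"STRG{k:04d}", members[0].motif,
                                    members))
    return groups


def genotype_strs(groups: list[STRLocusGroup],
                  pair_counts: dict[tuple[str, str], int],
                  founder_ids: tuple[str, ...],
                  min_depth: int = 20,
                  presence_frac: float = 0.05) -> pd.DataFrame:
    """Per-founder STR genotypes from read-pair counts per member consensus.

    A founder is genotyped only where its total depth at the merged locus is
    >= min_depth; alleles follow the same >5% presence rule as SNPs.
    Genotypes are "a/b" strings; None where uncallable.
    """
    rows = []
    for g in groups:
        row: dict = {"group_id": g.group_id, "motif": g.motif,
                     "n_alleles": len(g.alleles),
                     "alleles": ",".join(map(str, g.alleles))}
        for fid in founder_ids:
            depth_by_allele = {
                allele: sum(pair_counts.get((lid, fid), 0) for lid in lids)
                for allele, lids in g.allele_members.items()}
            total = sum(depth_by_allele.values())
            row[f"{fid}_depth"] = total
            if total < min_depth:
                row[fid] = None
                continue
            present = sorted(a for a, d in depth_by_allele.items()
                             if d > presence_frac * total)
            if len(present) == 1:
                row[fid] = f"{present[0]}/{present[0]}"
            elif len(present) == 2:
                row[fid] = f"{present[0]}/{present[1]}"
            else:
                row[fid] = None
        rows.append(row)
    return pd.DataFrame(rows)


def str_allele_presence(groups: list[STRLocusGroup],
                        pair_counts: dict[tuple[str, str], int],
                        founder_ids: tuple[str, ...],
                        presence_frac: float = 0.05) -> pd.DataFrame:
    """Long-form allele presence table (group_id, allele, founder, depth,
    present) feeding founder-specific allele counting."""
    rows = []
    for g in groups:
        totals = {fid: sum(pair_counts.get((lid, fid), 0)
                           for lids in g.allele_members.values()
                           for lid in lids)
                  for fid in founder_ids}
        for allele, lids in sorted(g.allele_members.items()):
            for fid in founder_ids:
                depth = sum(pair_counts.get((lid, fid), 0) for lid in lids)
                rows.append({
                    "group_id": g.group_id, "allele": allele,
                    "founder": fid, "depth": depth,
                    "present": depth > presence_frac * totals[fid]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

def write_vcf(putative: list[PutativeSNP], founder_ids: tuple[str, ...],
              path, read_length: int = 101) -> None:
    """Putative SNPs as VCF 4.2: one 300-bp contig per consensus locus,
    REF = major, ALT = minor, presence-rule GT plus allele depths."""
    def pos(offset: int) -> int:
        return offset + 1 if offset < read_length else offset + 99

    contigs = sorted({s.locus_id for s in putative})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rrlmarkers\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length={2 * read_length + 98}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Read-pair depth per allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(founder_ids) + "\n")
        for s in sorted(putative, key=lambda s: (s.locus_id, s.offset)):
            samples = []
            for fi in range(len(founder_ids)):
                maj = bool(s.present[fi, s.major_idx])
                mino = bool(s.present[fi, s.minor_idx])
                gt = ("0/1" if maj and mino else
                      "0/0" if maj else "1/1" if mino else "./.")
                ad = (f"{int(s.depths[fi, s.major_idx])},"
                      f"{int(s.depths[fi, s.minor_idx])}")
                samples.append(f"{gt}:{ad}")
            fh.write(f"{s.locus_id}\t{pos(s.offset)}\t.\t{s.major}\t"
                     f"{s.minor}\t.\tPASS\t.\tGT:AD\t"
                     + "\t".join(samples) + "\n")
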