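"""Synthetic founder genomes and reduced-representation library (RRL) reads.

The simulator emulates the study design the pipeline targets: a handful of
diploid founder genomes that share a common ancestral sequence, restriction
digestion with HaeIII (GG^CC) and MboI (^GATC), 250-350 bp size selection,
and indexed paired-end 101-bp sequencing with a uniform per-base substitution
error rate.  Every planted difference between founders (biallelic SNPs and
length-polymorphic STRs) is recorded in a truth table so downstream discovery
can be scored exactly.

Planting is constrained so that truth stays exact:

* SNPs never fall on or next to a restriction site, and the alternate allele
  never creates one, so fragment boundaries are identical across haplotypes.
* STR runs are placed inside the forward-read window of a single size-selected
  host fragment, away from restriction sites and from the read windows of the
  other enzyme's fragments, so each STR surfaces in exactly one locus.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import revcomp, seq_to_idx

__all__ = [
    "Enzyme",
    "HAEIII",
    "MBOI",
    "SimConfig",
    "Fragment",
    "FounderGenome",
    "Truth",
    "SimulationError",
    "generate_founders",
    "digest",
    "library_inserts",
    "size_select",
    "simulate_read_pairs",
    "simulate_founder_reads",
    "simulate_library",
    "write_fastq",
]

_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

# Motifs whose runs cannot contain a HaeIII or MboI site and are not powers of
# a shorter unit.
_MOTIF_POOL = ("AC", "AG", "AT", "CT", "AAG", "AAT", "ACT", "AGG",
               "AAAG", "AAGT", "AGAT", "AATC")


class SimulationError(ValueError):
    """Configuration cannot be realised (e.g. too many STR loci to place)."""


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme with a recognition site and a cut offset.

    ``cut_offset`` is the position within the site before which the cut
    falls: HaeIII GG^CC cuts after offset 2, MboI ^GATC before offset 0.
    ``end_fill`` is the number of bases past the downstream cut that the
    library insert retains after end repair: a blunt cutter keeps none,
    while MboI's filled-in 5' GATC overhang regenerates the full site at
    both insert ends.
    """

    name: str
    site: str
    cut_offset: int
    end_fill: int = 0


HAEIII = Enzyme("HaeIII", "GGCC", 2)
MBOI = Enzyme("MboI", "GATC", 0, end_fill=4)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated RRL experiment.

    Defaults mirror the study design: 5 founders, two 4-cutter enzymes,
    250-350 bp size selection chosen so that 101-bp mates never overlap,
    ~30 read pairs per retained fragment per founder, and a small per-base
    substitution error rate.
    """

    n_founders: int = 5
    ancestral_length: int = 2_000_000
    snp_rate: float = 5e-4
    str_count: int = 12
    enzymes: tuple[Enzyme, ...] = (HAEIII, MBOI)
    size_min: int = 250
    size_max: int = 350
    read_length: int = 101
    target_depth: float = 30.0
    error_rate: float = 0.002
    # Per-locus alternate-allele frequency is drawn from Beta(a, b); a = b = 2
    # gives intermediate frequencies and founder heterozygosity near 0.4.
    allele_freq_beta: tuple[float, float] = (2.0, 2.0)
    # Pairs (src, dst) of founder indices: founder dst copies founder src's
    # genotype at a locus with probability `relatedness`.
    related_pairs: tuple[tuple[int, int], ...] = ()
    relatedness: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_min > self.size_max:
            raise ValueError("size_min must not exceed size_max")
        if self.read_length > self.size_min:
            raise ValueError(
                "read_length must not exceed size_min (mates must not overlap)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")

    @property
    def founder_ids(self) -> tuple[str, ...]:
        return tuple(chr(ord("A") + i) for i in range(self.n_founders))


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment in haplotype coordinates (0-based half-open)."""

    founder_id: str
    haplotype_index: int
    start: int
    end: int
    sequence: str
    enzyme: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Truth:
    """Planted-variant truth shared by all founders of one simulation.

    ``snps`` columns: pos (0-based ancestral), ref, alt, freq, then per
    founder ``<id>_h1``/``<id>_h2`` (0=ref, 1=alt) and ``<id>_gt`` (alt
    count).  ``strs`` columns: str_id, pos, motif, base_count, alt_count,
    enzyme, host_start, host_end, plus per-haplotype repeat counts.
    """

    ancestral: str
    founder_ids: tuple[str, ...]
    snps: pd.DataFrame
    strs: pd.DataFrame

    def segregating_snp_positions(self) -> np.ndarray:
        """Ancestral positions where the founders are not all identical."""
        if self.snps.empty:
            return np.array([], dtype=int)
        hap_cols = [c for c in self.snps.columns
                    if c.endswith("_h1") or c.endswith("_h2")]
        alleles = self.snps[hap_cols].to_numpy()
        seg = (alleles.min(axis=1) != alleles.max(axis=1))
        return self.snps.loc[seg, "pos"].to_numpy()


@dataclass
class FounderGenome:
    """One diploid founder: two haplotype sequences plus coordinate maps.

    STR length polymorphism shifts haplotype coordinates relative to the
    ancestral sequence; ``anc_to_hap``/``hap_to_anc`` convert between the two
    using the recorded breakpoints (positions at/after which a cumulative
    shift applies).
    """

    founder_id: str
    haplotype1: str
    haplotype2: str
    truth: Truth
    # per haplotype: (ancestral breakpoint positions, cumulative shifts)
    _breakpoints: tuple[tuple[np.ndarray, np.ndarray], ...] = field(repr=False,
                                                                    default=())

    @property
    def haplotypes(self) -> tuple[str, str]:
        return (self.haplotype1, self.haplotype2)

    def anc_to_hap(self, hap: int, pos: int) -> int:
        bp, shift = self._breakpoints[hap]
        i = bisect.bisect_right(bp, pos) - 1
        return pos + (int(shift[i]) if i >= 0 else 0)

    def hap_to_anc(self, hap: int, pos: int) -> int:
        bp, shift = self._breakpoints[hap]
        # breakpoints in haplotype coordinates
        hap_bp = bp + shift
        i = bisect.bisect_right(hap_bp, pos) - 1
        return pos - (int(shift[i]) if i >= 0 else 0)


# ---------------------------------------------------------------------------
# digestion and size selection
# ---------------------------------------------------------------------------

def _site_positions(sequence: str, site: str) -> list[int]:
    out, i = [], sequence.find(site)
    while i != -1:
        out.append(i)
        i = sequence.find(site, i + 1)
    return out


def digest(sequence: str, enzyme: Enzyme, founder_id: str = "",
           haplotype_index: int = 0) -> list[Fragment]:
    """Complete digest: cut at every site occurrence, return fragments in order.

    Fragments partition the input exactly; coordinates are 0-based half-open.
    """
    if not sequence:
        return []
    cuts = sorted({p + enzyme.cut_offset for p in
                   _site_positions(sequence, enzyme.site)})
    bounds = [0] + [c for c in cuts if 0 < c < len(sequence)] + [len(sequence)]
    return [
        Fragment(founder_id, haplotype_index, a, b, sequence[a:b], enzyme.name)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def library_inserts(sequence: str, enzyme: Enzyme, founder_id: str = "",
                    haplotype_index: int = 0) -> list[Fragment]:
    """Sequencing inserts of a complete digest, with end repair applied.

    Inserts ending at an interior cut keep ``enzyme.end_fill`` bases past the
    cut (the filled-in overhang), so a both-end MboI insert reads GATC at
    both termini.  Unlike :func:`digest`, inserts may therefore overlap by
    ``end_fill`` bases.
    """
    frags = digest(sequence, enzyme, founder_id, haplotype_index)
    if enzyme.end_fill == 0 or not frags:
        return frags
    out = []
    for f in frags:
        end = f.end
        if end < len(sequence):           # interior cut: fill in the overhang
            end = min(end + enzyme.end_fill, len(sequence))
        out.append(replace(f, end=end, sequence=sequence[f.start:end]))
    return out


def size_select(fragments: list[Fragment], size_min: int,
                size_max: int) -> list[Fragment]:
    """Keep fragments with size_min <= length <= size_max, order preserved."""
    if size_min > size_max:
        raise ValueError("size_min must not exceed size_max")
    return [f for f in fragments if size_min <= len(f) <= size_max]


# ---------------------------------------------------------------------------
# founder generation
# ---------------------------------------------------------------------------

def _contains_site(seq: str, enzymes) -> bool:
    return any(e.site in seq for e in enzymes)


def _snp_exclusion_mask(ancestral: str, enzymes, length: int) -> np.ndarray:
    """True at positions too close to a restriction site to host a SNP."""
    mask = np.zeros(length, dtype=bool)
    for e in enzymes:
        w = len(e.site)
        for p in _site_positions(ancestral, e.site):
            mask[max(0, p - 4):min(length, p + w + 4)] = True
    mask[:10] = True
    mask[-10:] = True
    return mask


def _alt_creates_site(ancestral: str, pos: int, alt: str, enzymes) -> bool:
    for e in enzymes:
        w = len(e.site)
        lo = max(0, pos - w + 1)
        window = ancestral[lo:pos] + alt + ancestral[pos + 1:pos + w]
        if e.site in window:
            return True
    return False


def _read_windows(fragments: list[Fragment], read_length: int
                  ) -> list[tuple[int, int]]:
    """Forward/reverse read windows of fragments, as intervals."""
    out = []
    for f in fragments:
        out.append((f.start, f.start + read_length))
        out.append((f.end - read_length, f.end))
    return out


def _overlaps_any(lo: int, hi: int, intervals: list[tuple[int, int]]) -> bool:
    return any(lo < b and a < hi for a, b in intervals)


def _plan_strs(ancestral: str, config: SimConfig, rng: np.random.Generator):
    """Choose STR hosts, motifs and allele counts; return planting records."""
    thresholds = {2: 8, 3: 5, 4: 4}
    all_digests = {e.name: library_inserts(ancestral, e)
                   for e in config.enzymes}
    digests = {name: size_select(frs, config.size_min, config.size_max)
               for name, frs in all_digests.items()}
    # exclusion windows use a padded size band: an STR length change can pull
    # a near-boundary fragment into the selected range
    windows = {name: _read_windows(
        size_select(frs, config.size_min - 8, config.size_max + 8),
        config.read_length)
        for name, frs in all_digests.items()}

    hosts = []
    for name, frs in digests.items():
        for f in frs:
            if len(f) <= config.size_max - 8:   # room for the longest allele
                hosts.append(f)
    order = rng.permutation(len(hosts))

    plans, used_regions = [], []
    motif_cycle = list(_MOTIF_POOL)
    rng.shuffle(motif_cycle)
    mi = 0
    for idx in order:
        if len(plans) >= config.str_count:
            break
        host = hosts[idx]
        motif = motif_cycle[mi % len(motif_cycle)]
        m = len(motif)
        thr = thresholds[m]
        n0 = thr + int(rng.integers(0, 2))
        d = int(rng.integers(1, 3))
        run0 = m * n0
        run_max = m * (n0 + d)
        max_off = config.read_length - run_max - 8
        if max_off <= 8:
            continue
        off = int(rng.integers(8, max_off))
        s = host.start + off
        e0 = s + run0
        region = (s - 2, e0 + m * d + 2)
        if any(lo - 1000 < region[1] and region[0] < hi + 1000
               for lo, hi in used_regions):
            continue
        # no restriction site in or next to the replaced segment, before or
        # after the edit, for either allele
        if _contains_site(ancestral[s - 5:e0 + 5], config.enzymes):
            continue
        left, right = ancestral[s - 5:s], ancestral[e0:e0 + 5]
        if any(_contains_site(left + motif * (n0 + dd) + right, config.enzymes)
               for dd in (0, d)):
            continue
        # run must be maximal: neighbours must not extend the period
        if ancestral[s - 1] == motif[-1] or ancestral[e0] == motif[0]:
            continue
        # run must not surface in any other read window
        other = [w for name2, ws in windows.items() for w in ws
                 if name2 != host.enzyme]
        own = [w for w in windows[host.enzyme]
               if not (w[0] == host.start or w[1] == host.end)]
        if _overlaps_any(region[0], region[1], other + own):
            continue
        plans.append(dict(pos=s, motif=motif, base_count=n0, alt_count=n0 + d,
                          enzyme=host.enzyme, host_start=host.start,
                          host_end=host.end))
        used_regions.append(region)
        mi += 1
    if len(plans) < config.str_count:
        raise SimulationError(
            f"could only place {len(plans)} of {config.str_count} STR loci; "
            "increase ancestral_length or reduce str_count")
    plans.sort(key=lambda p: p["pos"])
    return plans


def generate_founders(config: SimConfig) -> list[FounderGenome]:
    """Generate diploid founders sharing an ancestral sequence, with truth.

    Deterministic given ``config.seed``.  Per SNP, an alternate-allele
    frequency is drawn from Beta(a, b) and each founder haplotype samples its
    allele from it, so founders are related but distinct; ``related_pairs``
    optionally raises sharing between chosen founders.
    """
    rng = np.random.default_rng(config.seed)
    L = config.ancestral_length
    anc_arr = _IDX_TO_BASE[rng.integers(0, 4, L)]
    ancestral = anc_arr.tobytes().decode("ascii")

    str_plans = _plan_strs(ancestral, config, rng) if config.str_count else []

    # --- SNP positions -----------------------------------------------------
    excl = _snp_exclusion_mask(ancestral, config.enzymes, L)
    for p in str_plans:
        lo = max(0, p["pos"] - 400)
        hi = min(L, p["pos"] + len(p["motif"]) * p["alt_count"] + 400)
        excl[lo:hi] = True
    cand = np.flatnonzero((rng.random(L) < config.snp_rate) & ~excl)

    positions, refs, alts = [], [], []
    for pos in cand:
        ref = ancestral[pos]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        if _alt_creates_site(ancestral, int(pos), alt, config.enzymes):
            continue
        positions.append(int(pos))
        refs.append(ref)
        alts.append(alt)
    n_snp = len(positions)

    a, b = config.allele_freq_beta
    freqs = rng.beta(a, b, n_snp)
    # haplotype alleles: (snp, founder, 2)
    hap = (rng.random((n_snp, config.n_founders, 2))
           < freqs[:, None, None]).astype(np.int8)
    for src, dst in config.related_pairs:
        copy = rng.random(n_snp) < config.relatedness
        hap[copy, dst, :] = hap[copy, src, :]

    fids = config.founder_ids
    snp_cols = {"pos": positions, "ref": refs, "alt": alts, "freq": freqs}
    for i, fid in enumerate(fids):
        snp_cols[f"{fid}_h1"] = hap[:, i, 0]
        snp_cols[f"{fid}_h2"] = hap[:, i, 1]
        snp_cols[f"{fid}_gt"] = hap[:, i, 0] + hap[:, i, 1]
    snps = pd.DataFrame(snp_cols)

    # --- STR allele assignment --------------------------------------------
    str_rows = []
    str_alleles = np.zeros((len(str_plans), config.n_founders, 2), dtype=int)
    for k, plan in enumerate(str_plans):
        while True:
            q = rng.uniform(0.3, 0.7)
            is_long = rng.random((config.n_founders, 2)) < q
            if is_long.any() and not is_long.all():
                break
        counts = np.where(is_long, plan["alt_count"], plan["base_count"])
        str_alleles[k] = counts
        row = dict(str_id=f"STR{k:03d}", **plan)
        for i, fid in enumerate(fids):
            row[f"{fid}_h1"] = int(counts[i, 0])
            row[f"{fid}_h2"] = int(counts[i, 1])
        str_rows.append(row)
    strs = pd.DataFrame(str_rows)

    truth = Truth(ancestral=ancestral, founder_ids=fids, snps=snps, strs=strs)

    # --- build haplotype sequences ----------------------------------------
    founders = []
    snp_pos = np.asarray(positions, dtype=int)
    alt_bytes = np.frombuffer("".join(alts).encode(), dtype=np.uint8) \
        if alts else np.array([], dtype=np.uint8)
    for i, fid in enumerate(fids):
        haps, bps = [], []
        for h in (0, 1):
            arr = anc_arr.copy()
            if n_snp:
                carries = hap[:, i, h] == 1
                arr[snp_pos[carries]] = alt_bytes[carries]
            pieces, bp_pos, bp_shift = [], [], []
            prev, shift = 0, 0
            for k, plan in enumerate(str_plans):
                s, m = plan["pos"], len(plan["motif"])
                e0 = s + m * plan["base_count"]
                c = int(str_alleles[k, i, h])
                pieces.append(arr[prev:s].tobytes())
                pieces.append((plan["motif"] * c).encode())
                shift += (c - plan["base_count"]) * m
                bp_pos.append(e0)
                bp_shift.append(shift)
                prev = e0
            pieces.append(arr[prev:].tobytes())
            haps.append(b"".join(pieces).decode("ascii"))
            bps.append((np.asarray(bp_pos, dtype=int),
                        np.asarray(bp_shift, dtype=int)))
        founders.append(FounderGenome(fid, haps[0], haps[1], truth,
                                      tuple(bps)))
    return founders


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    fwd: str
    rev: str


def _apply_errors(base_idx: np.ndarray, n: int, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    tiled = np.tile(base_idx, (n, 1))
    if error_rate > 0:
        mask = rng.random(tiled.shape) < error_rate
        k = int(mask.sum())
        if k:
            tiled[mask] = (tiled[mask] + rng.integers(1, 4, k)) % 4
    return tiled


def simulate_read_pairs(fragments: list[Fragment], config: SimConfig,
                        rng: np.random.Generator | None = None,
                        mean_pairs: float | None = None) -> list[ReadRecord]:
    """Simulate paired-end reads for the given fragments.

    Per fragment the pair count is Poisson with mean ``mean_pairs`` (default
    ``config.target_depth``).  The forward read is the first ``read_length``
    bases of the fragment, the reverse read the reverse complement of the
    last ``read_length`` bases; substitution errors are applied uniformly at
    ``config.error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if mean_pairs is None:
        mean_pairs = config.target_depth
    rl = config.read_length
    records: list[ReadRecord] = []
    for f in fragments:
        if len(f) < rl:
            raise ValueError(
                f"fragment {f.founder_id}:{f.start}-{f.end} is shorter than "
                f"the read length ({len(f)} < {rl})")
        n = int(rng.poisson(mean_pairs))
        if n == 0:
            continue
        fwd = f.sequence[:rl]
        rev = revcomp(f.sequence[-rl:])
        base = seq_to_idx(fwd + rev)
        tiled = _apply_errors(base, n, config.error_rate, rng)
        chars = _IDX_TO_BASE[tiled]
        prefix = (f"{f.founder_id}:{f.enzyme}:h{f.haplotype_index}"
                  f":{f.start}:{f.end}")
        for j in range(n):
            row = chars[j].tobytes().decode("ascii")
            records.append(ReadRecord(f"{prefix}:{j}", row[:rl], row[rl:]))
    return records


def simulate_founder_reads(founder: FounderGenome, config: SimConfig,
                           rng: np.random.Generator
                           ) -> tuple[list[ReadRecord], list[Fragment]]:
    """Digest both haplotypes, size-select, and sequence one founder's RRL.

    The per-haplotype Poisson mean is ``target_depth / 2`` so that
    ``target_depth`` remains the expected pair count per fragment per
    (diploid) founder.
    """
    frags: list[Fragment] = []
    for h, seq in enumerate(founder.haplotypes):
        for enzyme in config.enzymes:
            frags.extend(size_select(
                library_inserts(seq, enzyme, founder.founder_id, h),
                config.size_min, config.size_max))
    records = simulate_read_pairs(frags, config, rng,
                                  mean_pairs=config.target_depth / 2)
    return records, frags


@dataclass
class SimResult:
    config: SimConfig
    founders: list[FounderGenome]
    reads: dict[str, list[ReadRecord]]
    fragments: dict[str, list[Fragment]]

    @property
    def truth(self) -> Truth:
        return self.founders[0].truth


def simulate_library(config: SimConfig) -> SimResult:
    """Full simulation: founders plus per-founder read sets. Deterministic."""
    founders = generate_founders(config)
    reads, frags = {}, {}
    for i, founder in enumerate(founders):
        rng = np.random.default_rng([config.seed, 1, i])
        r, f = simulate_founder_reads(founder, config, rng)
        reads[founder.founder_id] = r
        frags[founder.founder_id] = f
    return SimResult(config, founders, reads, frags)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fastq(records: list[ReadRecord], path_r1, path_r2,
                quality_char: str = "I") -> None:
    """Write mates to a FASTQ pair (Phred+33, constant placeholder quality)."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r in records:
            q1 = quality_char * len(r.fwd)
            q2 = quality_char * len(r.rev)
            f1.write(f"@{r.read_id}/1\n{r.fwd}\n+\n{q1}\n")
            f2.write(f"@{r.read_id}/2\n{r.rev}\n+\n{q2}\n")


def write_truth(truth: Truth, snp_path, str_path) -> None:
    """Truth tables as TSV with 1-based coordinates."""
    snps = truth.snps.copy()
    if not snps.empty:
        snps["pos"] = snps["pos"] + 1
    snps.to_csv(snp_path, sep="\t", index=False)
    strs = truth.strs.copy()
    if not strs.empty:
        for col in ("pos", "host_start", "host_end"):
            strs[col] = strs[col] + 1
    strs.to_csv(str_path, sep="\t", index=False)
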