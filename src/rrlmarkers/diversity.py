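"""Founder-level diversity statistics and multivariate similarity analyses.

All multivariate views run on the major-allele count coding of the genotype
matrix (hom_minor -> 0, het -> 1, hom_major -> 2, one column per founder):

* Pearson correlation between founder coding vectors over loci;
* PCA as the eigendecomposition of the founder correlation matrix
  (correlation-based components, loadings scaled by sqrt(eigenvalue));
* classical (Torgerson) MDS on the distance d = 1 - correlation;
* average-linkage hierarchical clustering on the same distance, with
  per-node bootstrap probability (BP) and approximately unbiased (AU)
  p-values from multiscale bootstrap resampling of loci.

The multiscale bootstrap resamples floor(n * r) loci with replacement for
scale factors r in {0.5, ..., 1.4}; BP is the node recovery frequency at
r = 1, and AU comes from the signed-distance fit
Phi^-1(1 - BP_r) = v * sqrt(r) + c / sqrt(r), AU = 1 - Phi(v - c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from ._util import percent
from .variants import GenotypeMatrix

__all__ = [
    "zygosity_summary", "snp_allele_presence", "count_specific_alleles",
    "pairwise_shared_genotypes", "founder_correlation", "pca_founders",
    "mds_founders", "hclust_founders", "extrapolate_genome",
    "representation", "PCAResult", "MDSResult", "ClusterSupport",
    "HclustResult", "SharedGenotypes",
]


# ---------------------------------------------------------------------------
# counting statistics
# ---------------------------------------------------------------------------

def zygosity_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-founder homozygous/heterozygous locus counts and % heterozygous."""
    rows = []
    codes = matrix.codes
    for i, fid in enumerate(matrix.founder_ids):
        col = codes[:, i]
        hom_major = int((col == 2).sum())
        hom_minor = int((col == 0).sum())
        het = int((col == 1).sum())
        total = hom_major + hom_minor + het
        rows.append({"founder": fid, "hom_major": hom_major,
                     "hom_minor": hom_minor, "het": het,
                     "pct_het": percent(het, total) if total else None})
    return pd.DataFrame(rows)


def snp_allele_presence(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Boolean presence of each SNP allele per founder.

    Rows are (locus_id, offset, allele-role); the major allele is present
    where the coding is >= 1, the minor where it is <= 1.
    """
    rows = []
    codes = matrix.codes
    for r, (_, site) in enumerate(matrix.df.iterrows()):
        for role, pres in (("major", codes[r] >= 1), ("minor", codes[r] <= 1)):
            row = {"locus_id": site["locus_id"], "offset": site["offset"],
                   "allele": role}
            row.update({fid: bool(p)
                        for fid, p in zip(matrix.founder_ids, pres)})
            rows.append(row)
    return pd.DataFrame(rows)


def count_specific_alleles(presence: pd.DataFrame,
                           founder_ids: tuple[str, ...]) -> pd.Series:
    """Single-founder-specific allele counts.

    ``presence`` is any table with one boolean column per founder and one row
    per allele (SNP or STR); an allele is founder-specific when present in
    exactly one founder.
    """
    flags = presence[list(founder_ids)].to_numpy(dtype=bool)
    specific = flags.sum(axis=1) == 1
    counts = flags[specific].sum(axis=0)
    return pd.Series(counts, index=list(founder_ids), name="n_specific")


@dataclass
class SharedGenotypes:
    founder_ids: tuple[str, ...]
    counts: np.ndarray  # symmetric, shared-genotype locus counts
    pct: np.ndarray     # symmetric, percent to one decimal
    n_loci: int

    def table(self) -> pd.DataFrame:
        """Mixed layout: counts above the diagonal, percents below."""
        n = len(self.founder_ids)
        out = pd.DataFrame("-", index=self.founder_ids,
                           columns=self.founder_ids, dtype=object)
        for i in range(n):
            for j in range(n):
                if i < j:
                    out.iat[i, j] = int(self.counts[i, j])
                elif i > j:
                    out.iat[i, j] = self.pct[i, j]
        return out


def pairwise_shared_genotypes(matrix: GenotypeMatrix) -> SharedGenotypes:
    """Loci with identical genotype calls for each founder pair."""
    codes = matrix.codes
    n = len(matrix.founder_ids)
    counts = np.zeros((n, n), dtype=int)
    pct = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            c = int((codes[:, i] == codes[:, j]).sum())
            counts[i, j] = c
            pct[i, j] = percent(c, matrix.n_loci)
    return SharedGenotypes(matrix.founder_ids, counts, pct, matrix.n_loci)


# ---------------------------------------------------------------------------
# correlation, PCA, MDS
# ---------------------------------------------------------------------------

def founder_correlation(matrix: GenotypeMatrix) -> np.ndarray:
    """Pearson correlation of founder major-allele count vectors."""
    codes = matrix.codes.astype(float)
    sd = codes.std(axis=0)
    for fid, s in zip(matrix.founder_ids, sd):
        if s == 0:
            raise ValueError(
                f"founder {fid} has zero variance across loci; "
                "correlation is undefined")
    return np.corrcoef(codes.T)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (determinism)."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, k]))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


@dataclass
class PCAResult:
    founder_ids: tuple[str, ...]
    coordinates: np.ndarray          # founders x components
    variance_proportion: np.ndarray  # per component, sums to 1
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


def pca_founders(matrix: GenotypeMatrix | np.ndarray,
                 founder_ids: tuple[str, ...] | None = None) -> PCAResult:
    """Correlation-based PCA of the founders.

    Eigendecomposition of the founder correlation matrix; component i
    explains eigenvalue_i / n of the variance and the founder coordinate on
    it is eigenvector_i * sqrt(eigenvalue_i).
    """
    if isinstance(matrix, GenotypeMatrix):
        corr = founder_correlation(matrix)
        founder_ids = matrix.founder_ids
    else:
        corr = np.asarray(matrix, dtype=float)
        if founder_ids is None:
            founder_ids = tuple(chr(ord("A") + i)
                                for i in range(corr.shape[0]))
    if not np.all(np.isfinite(corr)):
        raise ValueError("correlation matrix contains non-finite values")
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], _fix_signs(vecs[:, order])
    coords = vecs * np.sqrt(np.clip(vals, 0, None))
    return PCAResult(tuple(founder_ids), coords, vals / corr.shape[0],
                     vals, vecs)


@dataclass
class MDSResult:
    founder_ids: tuple[str, ...]
    coordinates: np.ndarray  # founders x dims (<= 2)
    eigenvalues: np.ndarray


def mds_founders(matrix: GenotypeMatrix | np.ndarray,
                 founder_ids: tuple[str, ...] | None = None,
                 n_dims: int = 2) -> MDSResult:
    """Classical (Torgerson) MDS on d = 1 - correlation.

    Double-centres the squared distance matrix, eigendecomposes, and returns
    the top coordinates; dimensions with non-positive eigenvalues are
    dropped with a warning.
    """
    if isinstance(matrix, GenotypeMatrix):
        corr = founder_correlation(matrix)
        founder_ids = matrix.founder_ids
    else:
        corr = np.asarray(matrix, dtype=float)
        if founder_ids is None:
            founder_ids = tuple(chr(ord("A") + i)
                                for i in range(corr.shape[0]))
    d = 1.0 - corr
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], _fix_signs(vecs[:, order])
    pos = int((vals[:n_dims] > 1e-12).sum())
    if pos < n_dims:
        warnings.warn(f"only {pos} positive eigenvalue(s); returning "
                      f"{pos} dimension(s)", stacklevel=2)
    coords = vecs[:, :pos] * np.sqrt(vals[:pos])
    return MDSResult(tuple(founder_ids), coords, vals)


# ---------------------------------------------------------------------------
# hierarchical clustering with multiscale bootstrap
# ---------------------------------------------------------------------------

def _safe_corr(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _tree_clades(x: np.ndarray) -> tuple[np.ndarray, list[frozenset[int]]]:
    """Average-linkage tree on d = 1 - corr; clades as leaf-index sets."""
    corr = _safe_corr(x)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    n = x.shape[1]
    sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    clades = []
    for a, b, _, _ in z:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        clades.append(merged)
    return z, clades


@dataclass
class ClusterSupport:
    leaves: frozenset[str]
    bp: float
    au: float


@dataclass
class HclustResult:
    founder_ids: tuple[str, ...]
    linkage: np.ndarray
    nodes: list[ClusterSupport]

    def support_for(self, leaves: set[str]) -> ClusterSupport | None:
        target = frozenset(leaves)
        return next((n for n in self.nodes if n.leaves == target), None)

    def newick(self) -> str:
        """Newick with internal nodes labelled au/bp (two decimals)."""
        n = len(self.founder_ids)
        sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        reps: list[str] = list(self.founder_ids)
        support = {frozenset(node.leaves): node for node in self.nodes}
        for a, b, dist, _ in self.linkage:
            a, b = int(a), int(b)
            merged = sets[a] | sets[b]
            leaves = frozenset(self.founder_ids[i] for i in merged)
            node = support.get(leaves)
            label = f"{node.au:.2f}_{node.bp:.2f}" if node else ""
            reps.append(f"({reps[a]},{reps[b]}){label}:{dist:.4f}")
            sets.append(merged)
        return reps[-1].rsplit(":", 1)[0] + ";"


def _au_from_scales(freqs: np.ndarray, scales: np.ndarray,
                    nboot: int) -> float:
    """AU p-value from per-scale recovery frequencies.

    Least-squares fit of Phi^-1(1 - f_r) on (sqrt(r), 1/sqrt(r)); scales
    with degenerate frequencies (0 or 1) carry no quantile information and
    are dropped.
    """
    usable = (freqs > 0) & (freqs < 1)
    if usable.sum() < 2:
        # recovered (or missed) at essentially every scale
        return 1.0 if freqs.mean() >= 0.5 else 0.0
    f = np.clip(freqs[usable], 1.0 / (nboot + 1), 1 - 1.0 / (nboot + 1))
    r = scales[usable]
    z = norm.ppf(1.0 - f)
    design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    (v, c), *_ = np.linalg.lstsq(design, z, rcond=None)
    return float(1.0 - norm.cdf(v - c))


def hclust_founders(matrix: GenotypeMatrix, nboot: int = 10_000,
                    seed: int = 0,
                    scales: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9,
                                                 1.0, 1.1, 1.2, 1.3, 1.4)
                    ) -> HclustResult:
    """Average-linkage dendrogram with AU/BP support per internal node.

    Deterministic given ``seed``.  ``nboot`` below 100 triggers a warning
    (the AU fit is unstable with so few replicates).
    """
    if len(matrix.founder_ids) < 3:
        raise ValueError("clustering needs at least 3 founders")
    if nboot < 100:
        warnings.warn("nboot < 100 gives unstable AU values", stacklevel=2)
    codes = matrix.codes.astype(float)
    n = codes.shape[0]
    z, clades = _tree_clades(codes)

    rng = np.random.default_rng(seed)
    scales_arr = np.asarray(scales, dtype=float)
    hits = np.zeros((len(scales_arr), len(clades)), dtype=np.int64)
    for si, r in enumerate(scales_arr):
        m = max(3, int(np.floor(n * r)))
        for _ in range(nboot):
            idx = rng.integers(0, n, m)
            _, boot_clades = _tree_clades(codes[idx])
            boot_set = set(boot_clades)
            for ci, clade in enumerate(clades):
                if clade in boot_set:
                    hits[si, ci] += 1
    freqs = hits / nboot

    # actual achieved scales (floor changes r slightly)
    r_eff = np.array([max(3, int(np.floor(n * r))) / n for r in scales_arr])
    nodes = []
    one = int(np.argmin(np.abs(r_eff - 1.0)))
    for ci, clade in enumerate(clades):
        leaves = frozenset(matrix.founder_ids[i] for i in clade)
        bp = float(freqs[one, ci])
        au = (1.0 if len(clade) == len(matrix.founder_ids)
              else _au_from_scales(freqs[:, ci], r_eff, nboot))
        nodes.append(ClusterSupport(leaves, bp, au))
    return HclustResult(matrix.founder_ids, z, nodes)


# ---------------------------------------------------------------------------
# genome-wide extrapolation
# ---------------------------------------------------------------------------

def extrapolate_genome(snp_count: int, consensus_count: int,
                       informative_len: int = 202,
                       genome_size: float = 1.5e9) -> float:
    """Genome-wide SNP estimate from the per-consensus SNP density."""
    if snp_count < 0 or consensus_count <= 0:
        raise ValueError("snp_count must be >= 0 and consensus_count > 0")
    return snp_count / (consensus_count * informative_len) * genome_size


def representation(consensus_count: int, informative_len: int = 202,
                   genome_size: float = 1.5e9) -> tuple[float, float]:
    """(bases covered, genome fraction) represented by the consensus set."""
    if consensus_count <= 0:
        raise ValueError("consensus_count must be positive")
    bases = consensus_count * informative_len
    return float(bases), bases / genome_size
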