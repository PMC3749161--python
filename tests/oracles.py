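"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written in the plainest possible style
(dicts, loops, full scans) and shares no code with the package internals it
checks.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np


# --- clustering -------------------------------------------------------------

def brute_force_cluster(pairs, max_mismatch: int):
    """All-pairs greedy clustering: same processing order as the package
    (multiplicity desc, lexicographic ties), but scanning every existing
    cluster representative linearly instead of using an index.

    Returns a list of clusters, each a list of pair objects.
    """
    groups = defaultdict(list)
    for p in pairs:
        groups[(p.fwd_seq, p.rev_seq)].append(p)
    order = sorted(groups, key=lambda k: (-len(groups[k]), k))
    reps, clusters = [], []
    for key in order:
        cat = key[0] + key[1]
        chosen = None
        for ci, rep in enumerate(reps):
            dist = sum(a != b for a, b in zip(cat, rep))
            if dist <= max_mismatch:
                chosen = ci
                break
        if chosen is None:
            chosen = len(clusters)
            reps.append(cat)
            clusters.append([])
        clusters[chosen].extend(groups[key])
    return clusters


# --- mapping ----------------------------------------------------------------

def exhaustive_map(pair, references, max_mismatch: int):
    """Scan every reference; minimum mismatch wins, ties to lowest locus id.

    Returns (locus_id, mismatches) or None.
    """
    cat = pair.fwd_seq + pair.rev_seq
    best = None
    for ref in sorted(references, key=lambda r: r.locus_id):
        dist = sum(a != b for a, b in zip(cat, ref.informative))
        if dist <= max_mismatch and (best is None or dist < best[1]):
            best = (ref.locus_id, dist)
    return best


# --- SNP filter cascade -----------------------------------------------------

def straight_line_filter(sites, max_founder_depth=300, presence_frac=0.05,
                         max_ratio=3.0):
    """The four-rule filter written linearly over nested dicts.

    ``sites``: list of (locus_id, offset, {founder: {base: depth}}).
    Returns list of (locus_id, offset, major, minor).
    """
    out = []
    for locus_id, offset, by_founder in sites:
        # rule 1: depth-1 alleles are ignored per founder
        d = {f: {b: (0 if c == 1 else c) for b, c in bd.items()}
             for f, bd in by_founder.items()}
        # rule 2: depth cap per founder
        if any(sum(bd.values()) > max_founder_depth for bd in d.values()):
            continue
        # rule 3: presence rule, then 3+ present alleles in a founder
        too_many = False
        for bd in d.values():
            total = sum(bd.values())
            present = [b for b, c in bd.items() if c > presence_frac * total]
            if len(present) >= 3:
                too_many = True
        if too_many:
            continue
        pooled = defaultdict(int)
        for bd in d.values():
            for b, c in bd.items():
                pooled[b] += c
        alleles = sorted(b for b, c in pooled.items() if c > 0)
        if len(alleles) != 2:
            continue
        # rule 4: allele-depth ratio in any founder carrying both alleles
        a1, a2 = alleles
        bad = False
        for bd in d.values():
            c1, c2 = bd.get(a1, 0), bd.get(a2, 0)
            if c1 > 0 and c2 > 0 and max(c1, c2) > max_ratio * min(c1, c2):
                bad = True
        if bad:
            continue
        if pooled[a1] > pooled[a2]:
            major, minor = a1, a2
        elif pooled[a2] > pooled[a1]:
            major, minor = a2, a1
        else:
            major, minor = a1, a2  # tie: lexicographically smaller base
        out.append((locus_id, offset, major, minor))
    return out


# --- symmetric eigenproblems ------------------------------------------------

def power_iteration_eig(matrix: np.ndarray, n_components: int,
                        n_iter: int = 50_000, tol: float = 1e-14):
    """Dominant eigenpairs of a symmetric matrix by power iteration with
    deflation (largest absolute eigenvalues first)."""
    a = np.array(matrix, dtype=float)
    n = a.shape[0]
    values, vectors = [], []
    rng = np.random.default_rng(12345)
    for _ in range(n_components):
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        lam = 0.0
        for _ in range(n_iter):
            w = a @ v
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            new_lam = float(w @ a @ w)
            converged = abs(new_lam - lam) < tol and abs(abs(w @ v) - 1) < tol
            v, lam = w, new_lam
            if converged:
                break
        # polish with shifted inverse iteration (quadratic convergence)
        for _ in range(5):
            try:
                w = np.linalg.solve(a - (lam + 1e-10) * np.eye(n), v)
            except np.linalg.LinAlgError:
                break
            norm = np.linalg.norm(w)
            if not np.isfinite(norm) or norm == 0:
                break
            v = w / norm
            lam = float(v @ a @ v)
        values.append(lam)
        vectors.append(v)
        a = a - lam * np.outer(v, v)
    return np.array(values), np.array(vectors).T


# --- tandem repeats ---------------------------------------------------------

def enumerate_tandem_runs(segment: str, thresholds: dict[int, int]):
    """Every maximal pure tandem run meeting the repeat-count thresholds,
    found by trying all (start, period) combinations.

    Returns a set of (start, period, count, region_len) with sub-periodic
    motifs removed.
    """
    found = set()
    n = len(segment)
    for period, min_count in thresholds.items():
        for start in range(n - period):
            # maximal region requires no extension to the left
            if start >= period and segment[start - 1] == \
                    segment[start - 1 + period]:
                continue
            if start >= 1 and segment[start - 1] == segment[start - 1 + period]:
                continue
            length = period
            while (start + length < n
                   and segment[start + length] == segment[start + length - period]):
                length += 1
            count = length // period
            if count < min_count:
                continue
            motif = segment[start:start + period]
            subperiodic = any(
                period % d == 0 and motif == motif[:d] * (period // d)
                for d in range(1, period))
            if subperiodic:
                continue
            found.add((start, period, count, length))
    return found


# --- founder-specific alleles ----------------------------------------------

def brute_force_specific_counts(presence_rows, founder_ids):
    """Count alleles present in exactly one founder, row by row."""
    counts = {f: 0 for f in founder_ids}
    for row in presence_rows:
        carriers = [f for f in founder_ids if row[f]]
        if len(carriers) == 1:
            counts[carriers[0]] += 1
    return counts
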