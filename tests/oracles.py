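"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's k-mer index, numpy batching and
rank-sum recursion: matching is an exhaustive scan over every alignment
diagonal, identity comes from a C-backed global aligner configured as unit
edit distance, and the Wilcoxon null distribution is a literal walk over
every group assignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


# ----------------------------------------------------------- read matching

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _diagonal_qualifies(read: str, target: str, diag: int, k: int,
                        min_match: int, max_mismatch_frac: float) -> bool:
    r0 = max(0, -diag)
    r1 = min(len(read), len(target) - diag)
    n = r1 - r0
    if n < min_match or n < k:
        return False
    match = [read[r0 + t] == target[r0 + diag + t] and read[r0 + t] in "ACGT"
             for t in range(n)]
    # any window [s, s+w) with w >= min_match, mismatch fraction within
    # bounds, and a k-long all-match run inside
    mism = [0]
    for m in match:
        mism.append(mism[-1] + (not m))
    run_start = [all(match[j:j + k]) for j in range(n - k + 1)]
    if not any(run_start):
        return False
    runp = [0]
    for r in run_start:
        runp.append(runp[-1] + r)
    for s in range(n - min_match + 1):
        for w in range(min_match, n - s + 1):
            e = s + w
            if mism[e] - mism[s] > max_mismatch_frac * w:
                continue
            hi = max(e - k + 1, s)
            if runp[hi] - runp[s] > 0:
                return True
    return False


def oracle_match(read: str, cds: str, k: int, min_match: int,
                 max_mismatch_frac: float) -> bool:
    """Does the read match the CDS on any strand, any ungapped offset?"""
    for target in (cds, _revcomp(cds)):
        # a qualifying window needs k consecutive matches, hence a shared
        # k-mer: skip targets sharing none (pure logical implication)
        rk = {read[i:i + k] for i in range(len(read) - k + 1)}
        tk = {target[i:i + k] for i in range(len(target) - k + 1)}
        if not (rk & tk):
            continue
        for diag in range(-(len(read) - min_match),
                          len(target) - min_match + 1):
            if _diagonal_qualifies(read, target, diag, k, min_match,
                                   max_mismatch_frac):
                return True
    return False


def oracle_count_spots(readset, catalog, k: int, min_match: int,
                       max_mismatch_frac: float) -> dict[str, int]:
    """Exhaustive per-gene distinct-spot counts."""
    per_gene = {g.gene_id: set() for g in catalog}
    for spot_id, reads in readset.spots:
        for read in reads:
            if len(read) < min_match:
                continue
            for g in catalog:
                if spot_id in per_gene[g.gene_id]:
                    continue
                if oracle_match(read, g.cds, k, min_match, max_mismatch_frac):
                    per_gene[g.gene_id].add(spot_id)
    return {g: len(s) for g, s in per_gene.items()}


# ------------------------------------------------------------- identity

_ALIGNER = None


def oracle_identity(a: str, b: str) -> float:
    """Global identity 1 - levenshtein / max(len), via a global aligner
    scored as negated unit edit distance."""
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align

        _ALIGNER = Align.PairwiseAligner()
        _ALIGNER.mode = "global"
        _ALIGNER.match_score = 0
        _ALIGNER.mismatch_score = -1
        _ALIGNER.open_gap_score = -1
        _ALIGNER.extend_gap_score = -1
    dist = -_ALIGNER.score(a, b)
    return 1.0 - dist / max(len(a), len(b))


# --------------------------------------------------------------- Wilcoxon

def oracle_wilcoxon_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p by literally enumerating every
    assignment of the pooled values to the two groups."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n1 = len(x)
    ranks = sps.rankdata(pooled, method="average")
    e0 = n1 * (len(pooled) + 1) / 2.0
    w_obs = ranks[:n1].sum()
    extreme = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - e0) >= abs(w_obs - e0) - 1e-9:
            extreme += 1
    return extreme / total


# ----------------------------------------------------- expression programs

@dataclass
class ShareOracle:
    """Closed-form expected category shares under an expression program."""

    catalog: object
    program: object

    def expected_share(self, caste: str, categories: tuple[str, ...]) -> float:
        lam = self.program.abundance[caste]
        load = self.program.load(caste)
        total = sel = 0.0
        for g in self.catalog:
            w = lam.get(g.gene_id, 0.0) * (load if g.category == "protein" else 1.0)
            total += w
            if g.category in categories:
                sel += w
        return sel / total
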