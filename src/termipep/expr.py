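"""Normalisation, caste comparison tables, correlations and sample QC.

Two normalisations are computed side by side:

* spots per million, ``m_g = 1e6 * c_g / N_total`` — simple library-size
  scaling, which is confounded by caste-dependent composition shifts (a
  caste loaded with vitellogenin or hexamerin transcripts dilutes every
  neuropeptide and fakes a fold difference);
* neuropeptide fraction, ``f_g = c_g / sum over D of c_h``, where D is the
  set of centrally expressed neuropeptide genes — the compositional measure
  that cancels the structural-protein load.  Peripherally expressed
  peptides (IGF, atirpin, brovirpin, AKH) are removed from the denominator
  in samples where they dominate, since their counts reflect non-CNS
  tissue content rather than brain expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import BRAIN_MARKERS, OVARY_MARKERS, Catalog
from .spots import SpotCountTable

DEFAULT_TAU = 0.25          # peripheral-gene share of raw NP total triggering exclusion
DEFAULT_PSEUDOCOUNT = 0.5   # count-scale pseudocount for fold differences
DEFAULT_GAP_LOG2 = 1.0      # single-linkage gap (log2) separating caste groups


@dataclass
class ExpressionProfile:
    """Normalised expression values for one read set."""

    set_id: str
    spm: dict[str, float]                 # spots per million, all genes
    frac: dict[str, float] | None        # neuropeptide fractions over D (None if undefined)
    excluded: set[str]                   # peripheral genes dropped from the denominator
    tau: float
    labels: dict = field(default_factory=dict)

    @property
    def frac_defined(self) -> bool:
        return self.frac is not None

    def value(self, gene_id: str, measure: str = "frac") -> float:
        if measure == "frac":
            if self.frac is None:
                return float("nan")
            return self.frac.get(gene_id, float("nan"))
        if measure in ("spm", "spots-per-million"):
            return self.spm.get(gene_id, float("nan"))
        raise ValueError(f"unknown measure {measure!r}")


def normalize(counts: SpotCountTable, catalog: Catalog,
              tau: float = DEFAULT_TAU) -> ExpressionProfile:
    """Compute spots-per-million and neuropeptide fractions for one sample.

    The exclusion set E contains the peripheral genes whose share of the
    *raw* neuropeptide total (all neuropeptide + ilp genes, before any
    exclusion) exceeds ``tau``; fractions are then renormalised over the
    remaining denominator set D.  If D's total is zero the fractions are
    flagged undefined rather than fabricated.
    """
    if counts.n_total <= 0:
        raise ValueError("N_total must be > 0")
    eff = counts.effective_counts()
    spm = {g: 1e6 * c / counts.n_total for g, c in eff.items()}

    np_genes = [g for g in catalog.neuropeptide_ids() if g in eff]
    raw_total = sum(eff[g] for g in np_genes)
    excluded: set[str] = set()
    if raw_total > 0:
        for g in np_genes:
            if catalog[g].peripheral and eff[g] / raw_total > tau:
                excluded.add(g)
    denom_genes = [g for g in np_genes if g not in excluded]
    denom = sum(eff[g] for g in denom_genes)
    frac = {g: eff[g] / denom for g in denom_genes} if denom > 0 else None
    return ExpressionProfile(set_id=counts.set_id, spm=spm, frac=frac,
                             excluded=excluded, tau=tau)


# ------------------------------------------------------- caste comparison

@dataclass
class CasteComparison:
    """Per-gene caste group means, fold differences and three-way grouping."""

    measure: str
    pseudocount: float
    gap_log2: float
    table: pd.DataFrame  # index gene; columns: mean per caste, fold, defined
    groups: dict[str, dict[str, str]]  # gene -> caste -> highest/intermediate/lowest
    replicates: dict[str, int]


def _three_way_groups(means: dict[str, float], pseudocount: float,
                      gap_log2: float) -> dict[str, str]:
    """Assign castes to highest/intermediate/lowest by single-linkage gaps
    of log2(mean + pseudocount); clusters split at the (up to two) largest
    gaps >= ``gap_log2``."""
    castes = sorted(means, key=lambda c: -means[c])
    logs = np.log2(np.array([means[c] for c in castes]) + pseudocount)
    gaps = logs[:-1] - logs[1:]
    cut_idx = [i for i in np.argsort(gaps)[::-1] if gaps[i] >= gap_log2][:2]
    cuts = sorted(cut_idx)
    clusters: list[list[str]] = []
    prev = 0
    for c in cuts:
        clusters.append(castes[prev:c + 1])
        prev = c + 1
    clusters.append(castes[prev:])
    names = (["highest", "lowest"] if len(clusters) == 2
             else ["highest", "intermediate", "lowest"] if len(clusters) == 3
             else ["highest"])
    out = {}
    for cluster, name in zip(clusters, names):
        for caste in cluster:
            out[caste] = name
    return out


def caste_table(profiles_by_caste: dict[str, list[ExpressionProfile]],
                genes: list[str] | None = None, measure: str = "frac",
                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                gap_log2: float = DEFAULT_GAP_LOG2) -> CasteComparison:
    """Group means per caste and fold differences between the extreme groups.

    The fold difference of a gene is the mean of the caste means in its
    *highest* group over the mean in its *lowest* group (pseudocount added
    to both).  With pseudocount 0 and a zero lowest mean the fold is
    undefined and flagged rather than infinite.
    """
    for caste, profs in profiles_by_caste.items():
        if not profs:
            raise ValueError(f"caste {caste!r} has zero replicates")
    castes = list(profiles_by_caste)
    if genes is None:
        seen: dict[str, None] = {}
        for profs in profiles_by_caste.values():
            for p in profs:
                source = p.frac if (measure == "frac" and p.frac) else p.spm
                for g in source:
                    seen.setdefault(g)
        genes = list(seen)

    rows = []
    groups: dict[str, dict[str, str]] = {}
    for g in genes:
        means = {}
        for caste in castes:
            vals = [p.value(g, measure) for p in profiles_by_caste[caste]]
            means[caste] = float(np.nanmean(vals)) if vals else float("nan")
        defined = all(np.isfinite(v) for v in means.values()) and \
            (pseudocount > 0 or all(v > 0 for v in means.values()))
        grp = _three_way_groups(means, pseudocount, gap_log2) if defined else {}
        groups[g] = grp
        if defined:
            hi = np.mean([means[c] for c in grp if grp[c] == "highest"])
            lo_name = "lowest" if "lowest" in grp.values() else "highest"
            lo = np.mean([means[c] for c in grp if grp[c] == lo_name])
            if lo + pseudocount > 0:
                fold = (hi + pseudocount) / (lo + pseudocount)
            else:
                fold, defined = float("nan"), False
        else:
            fold = float("nan")
        rows.append({"gene_id": g, **{f"mean_{c}": means[c] for c in castes},
                     "fold": fold, "defined": defined})
    table = pd.DataFrame(rows).set_index("gene_id")
    return CasteComparison(
        measure=measure, pseudocount=pseudocount, gap_log2=gap_log2,
        table=table, groups=groups,
        replicates={c: len(profiles_by_caste[c]) for c in castes},
    )


# ------------------------------------------------------------ correlation

@dataclass
class CorrelationResult:
    gene_x: str
    gene_y: str
    n: int
    rho: float
    pairs: list[tuple[float, float]]
    defined: bool


def correlate(profiles: list[ExpressionProfile], gene_x: str, gene_y: str,
              measure: str = "spm") -> CorrelationResult:
    """Spearman rank correlation of two genes across samples.

    Rank-based because archive counts are heavy-tailed and the biological
    claims of interest (e.g. atirpin falling as vitellogenin rises) are
    monotone, not linear.  Constant vectors give an undefined, flagged
    result.
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 profiles")
    if measure == "raw":
        measure = "spm"
    xs = [p.value(gene_x, measure) for p in profiles]
    ys = [p.value(gene_y, measure) for p in profiles]
    pairs = list(zip(xs, ys))
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        return CorrelationResult(gene_x, gene_y, len(pairs), float("nan"),
                                 pairs, defined=False)
    rho = float(sps.spearmanr(xs, ys).statistic)
    return CorrelationResult(gene_x, gene_y, len(pairs), rho, pairs, defined=True)


# -------------------------------------------------------------------- QC

@dataclass
class QCFlags:
    set_id: str
    flags: set[str]
    support: dict[str, dict[str, float]]


def qc_flags(counts: SpotCountTable, catalog: Catalog,
             species_gene_blacklist: set[str] | None = None,
             min_marker_spots: int = 5, depth_floor: int = 100_000,
             brain_markers: tuple[str, ...] = BRAIN_MARKERS,
             ovary_markers: tuple[str, ...] = OVARY_MARKERS) -> QCFlags:
    """Flag likely mislabeled or contaminated samples from counts alone.

    A deep sample with none of the four brain/corpus-cardiacum markers
    (neuroparsin, AKH, SIFamide, SMYamide) cannot be a head or whole-body
    library; one loaded with brovirpin and vitellogenin-receptor spots
    carries an ovary signature; spots for a gene known to be absent from
    the species point at cross-contamination.
    """
    eff = counts.effective_counts()
    flags: set[str] = set()
    support: dict[str, dict[str, float]] = {}

    brain = {g: eff.get(g, 0.0) for g in brain_markers if g in catalog}
    if counts.n_total >= depth_floor and brain and \
            all(v < min_marker_spots for v in brain.values()):
        flags.add("missing_brain_markers")
        support["missing_brain_markers"] = brain

    ovary = {g: eff.get(g, 0.0) for g in ovary_markers if g in catalog}
    if ovary and all(v >= min_marker_spots for v in ovary.values()):
        flags.add("ovary_signature")
        support["ovary_signature"] = ovary

    blacklist = {g: eff.get(g, 0.0) for g in (species_gene_blacklist or set())}
    hot = {g: v for g, v in blacklist.items() if v >= min_marker_spots}
    if hot:
        flags.add("foreign_gene_contamination")
        support["foreign_gene_contamination"] = hot

    if counts.n_total < depth_floor:
        flags.add("low_depth")
        support["low_depth"] = {"N_total": counts.n_total}

    return QCFlags(set_id=counts.set_id, flags=flags, support=support)


def profiles_to_frame(profiles: list[ExpressionProfile]) -> pd.DataFrame:
    """Long-format table of both normalisations for a list of profiles."""
    rows = []
    for p in profiles:
        for g, v in p.spm.items():
            rows.append({"set_id": p.set_id, "gene_id": g, "measure": "spm",
                         "value": v, "excluded": g in p.excluded})
        if p.frac:
            for g, v in p.frac.items():
                rows.append({"set_id": p.set_id, "gene_id": g, "measure": "frac",
                             "value": v, "excluded": False})
    return pd.DataFrame(rows)
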