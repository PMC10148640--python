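"""Synthetic data with exported ground truth.

This module fabricates the three kinds of input the quantification pipeline
consumes, each with a known generating process:

* gene catalogs — nucleotide coding sequences annotated with a category
  (neuropeptide / ilp / protein / household) and a peripheral-expression
  flag, mutually dissimilar (< 60 % identity) so that read matching has an
  unambiguous answer;
* transcriptome read sets — polyA-selected-style spot collections in which
  fragment starts are biased towards the 3' end of the transcript, a
  configurable fraction of spots are duplicate re-emissions, and per-caste
  expression programs control gene abundances (structural proteins can be
  loaded up per caste to emulate composition shifts between castes);
* genome read sets — uniform shotgun reads over supplied contigs at a target
  coverage, for the gene presence/absence caller.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")

CATEGORIES = ("neuropeptide", "ilp", "protein", "household")

#: Genes the normalisation step treats as peripherally expressed: three of
#: the insulin-like peptides plus AKH are produced outside the CNS and can
#: swamp the neuropeptide total in some samples.
PERIPHERAL_GENES = ("igf", "atirpin", "brovirpin", "akh")

#: Brain / corpus cardiacum markers used for mislabeling QC.
BRAIN_MARKERS = ("neuroparsin", "akh", "sifamide", "smyamide")

#: Ovary signature genes.
OVARY_MARKERS = ("brovirpin", "vitellogenin-receptor")

# Fixed inventory: (gene_id, name, category, peripheral, cds_len, utr3_len).
# Neuropeptide and ilp CDS are short; structural-protein CDS are >= 5x the
# longest neuropeptide CDS so that 3'-bias undercounting has something to
# bite on.
_FIXED_INVENTORY = [
    ("gonadulin", "gonadulin", "ilp", False, 330, 150),
    ("igf", "IGF", "ilp", True, 360, 200),
    ("dilp7", "dilp7 ortholog", "ilp", False, 330, 150),
    ("atirpin", "atirpin", "ilp", True, 300, 120),
    ("birpin", "birpin", "ilp", False, 300, 120),
    ("cirpin", "cirpin", "ilp", False, 300, 120),
    ("brovirpin", "brovirpin", "ilp", True, 300, 120),
    ("akh", "AKH", "neuropeptide", True, 210, 100),
    ("neuroparsin", "neuroparsin", "neuropeptide", False, 270, 120),
    ("sifamide", "SIFamide", "neuropeptide", False, 210, 100),
    ("smyamide", "SMYamide", "neuropeptide", False, 240, 100),
    ("allatostatin-a", "allatostatin A", "neuropeptide", False, 360, 150),
    ("hansolin", "hansolin", "neuropeptide", False, 270, 120),
    ("cnmamide", "CNMamide", "neuropeptide", False, 240, 100),
    ("vitellogenin", "vitellogenin", "protein", False, 3600, 500),
    ("hexamerin", "hexamerin", "protein", False, 2100, 400),
    ("vitellogenin-receptor", "vitellogenin receptor", "protein", False, 3000, 400),
]

_NP_EXTRA_LEN = (150, 360)       # random neuropeptide CDS length range (nt)
_PROT_EXTRA_LEN = (1800, 3600)   # random structural-protein CDS length range
_HH_EXTRA_LEN = (600, 1200)      # household gene CDS length range

MAX_IDENTITY = 0.60
_MAX_RETRIES = 60

# Seed-stream namespaces: generators called with the same integer seed must
# not replay one another's random byte stream (a catalog and a read set
# built from the same master seed would otherwise share subsequences).
_STREAM_CATALOG, _STREAM_RNASEQ, _STREAM_GENOME = 11, 13, 17


class CatalogError(Exception):
    """Raised when catalog construction cannot satisfy its constraints."""


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    name: str
    cds: str
    category: str
    peripheral: bool
    utr3_len: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.cds) < 150 or len(self.cds) % 3:
            raise ValueError("cds must be >= 150 nt and divisible by 3")
        if set(self.cds) - set("ACGT"):
            raise ValueError("cds must contain only ACGT")
        if self.utr3_len < 0:
            raise ValueError("utr3_len must be >= 0")


class Catalog:
    """An ordered collection of gene records with unique ids."""

    def __init__(self, genes: list[GeneRecord]):
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_ids must be unique within a catalog")
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in genes}

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def category_ids(self, *categories: str) -> list[str]:
        return [g.gene_id for g in self.genes if g.category in categories]

    def neuropeptide_ids(self) -> list[str]:
        """Genes that count towards the neuropeptide-fraction denominator
        (classical neuropeptides plus the insulin-like peptides)."""
        return self.category_ids("neuropeptide", "ilp")


@dataclass
class ExpressionProgram:
    """Per-caste relative transcript abundances.

    ``abundance[caste][gene_id]`` is the expected relative abundance
    (lambda) of that gene's transcript; ``structural_load[caste]`` is a
    multiplier >= 1 applied on top of lambda for ``category == "protein"``
    genes, emulating castes that synthesise bulk structural proteins
    (vitellogenin in queens, hexamerins in pre-soldiers) and thereby dilute
    everything else in the library.
    """

    abundance: dict[str, dict[str, float]]
    structural_load: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for caste, lam in self.abundance.items():
            if any(v < 0 or not np.isfinite(v) for v in lam.values()):
                raise ValueError(f"negative or non-finite abundance in caste {caste!r}")
            if not any(v > 0 for v in lam.values()):
                raise ValueError(f"all abundances zero for caste {caste!r}")
        for caste, m in self.structural_load.items():
            if m < 1 or not np.isfinite(m):
                raise ValueError(f"structural_load must be finite and >= 1 ({caste!r})")

    def load(self, caste: str) -> float:
        return self.structural_load.get(caste, 1.0)


@dataclass
class ReadSet:
    """A simulated sequence read archive: a list of spots plus labels.

    Each spot is ``(spot_id, reads)`` with one (single-end) or two
    (paired-end) fixed-length read sequences.  ``truth`` carries the
    generating ground truth when the set was simulated.
    """

    set_id: str
    spots: list[tuple[str, tuple[str, ...]]]
    labels: dict = field(default_factory=dict)
    truth: dict | None = None

    def __len__(self):
        return len(self.spots)

    def n_distinct_spots(self) -> int:
        return len({sid for sid, _ in self.spots})


# ------------------------------------------------------------------ helpers

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_cds(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def sequence_identity(a: str, b: str) -> float:
    """Global identity 1 - levenshtein(a, b) / max(len)."""
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


# ------------------------------------------------------------------ catalog

def make_catalog(n_neuropeptides: int = 0, n_proteins: int = 0,
                 n_household: int = 5, seed: int = 0,
                 igf_splice_variant: bool = False) -> Catalog:
    """Build a deterministic gene catalog.

    The catalog always contains the 17 fixed named genes (the seven
    insulin-like peptides, seven CNS neuropeptides and three structural
    proteins) and optionally extra anonymous genes per category.  CDS are
    random sequences rejection-sampled so that every pair of distinct genes
    is below 60 % global identity, which makes read-to-gene assignment
    unambiguous by construction.  ``igf_splice_variant`` adds a second IGF
    record sharing the IGF CDS (the two-alternative-transcripts situation),
    deliberately exempt from the dissimilarity constraint so that
    multi-gene spot assignment is exercised.
    """
    if min(n_neuropeptides, n_proteins, n_household) < 0:
        raise ValueError("gene counts must be >= 0")
    rng = np.random.default_rng([seed, _STREAM_CATALOG])
    genes: list[GeneRecord] = []

    def admit(gene_id, name, category, peripheral, cds_len, utr3_len):
        for _ in range(_MAX_RETRIES):
            cds = _random_cds(rng, cds_len)
            if all(sequence_identity(cds, g.cds) < MAX_IDENTITY for g in genes):
                genes.append(GeneRecord(gene_id, name, cds, category,
                                        peripheral, utr3_len))
                return
        raise CatalogError(
            f"could not draw a CDS for {gene_id!r} below "
            f"{MAX_IDENTITY:.0%} identity after {_MAX_RETRIES} tries"
        )

    for gene_id, name, category, peripheral, cds_len, utr3_len in _FIXED_INVENTORY:
        admit(gene_id, name, category, peripheral, cds_len, utr3_len)
    for i in range(n_neuropeptides):
        ln = 3 * int(rng.integers(_NP_EXTRA_LEN[0] // 3, _NP_EXTRA_LEN[1] // 3 + 1))
        admit(f"np{i:02d}", f"neuropeptide {i}", "neuropeptide", False,
              ln, int(rng.integers(50, 250)))
    for i in range(n_proteins):
        ln = 3 * int(rng.integers(_PROT_EXTRA_LEN[0] // 3, _PROT_EXTRA_LEN[1] // 3 + 1))
        admit(f"prot{i:02d}", f"structural protein {i}", "protein", False,
              ln, int(rng.integers(200, 600)))
    for i in range(n_household):
        ln = 3 * int(rng.integers(_HH_EXTRA_LEN[0] // 3, _HH_EXTRA_LEN[1] // 3 + 1))
        admit(f"hh{i:02d}", f"household gene {i}", "household", False,
              ln, int(rng.integers(100, 400)))
    if igf_splice_variant:
        igf = next(g for g in genes if g.gene_id == "igf")
        genes.append(GeneRecord("igf-b", "IGF isoform B", igf.cds, "ilp",
                                True, igf.utr3_len))
    return Catalog(genes)


def uniform_program(catalog: Catalog, castes: list[str],
                    neuropeptide_level: float = 1.0,
                    protein_level: float = 10.0,
                    household_level: float = 5.0,
                    structural_load: dict[str, float] | None = None) -> ExpressionProgram:
    """Convenience program: one abundance per category, identical across
    castes except for the per-caste structural load."""
    level = {"neuropeptide": neuropeptide_level, "ilp": neuropeptide_level,
             "protein": protein_level, "household": household_level}
    abundance = {c: {g.gene_id: level[g.category] for g in catalog} for c in castes}
    return ExpressionProgram(abundance, structural_load or {})


# ------------------------------------------------------------ RNA-seq spots

def _start_distribution(tlen: int, read_len: int, bias: float) -> np.ndarray:
    """Fragment-start weights over 0..tlen-read_len.

    PolyA selection plus random mRNA breakage enriches fragments from the
    3' end; a single-parameter power law w(p) = ((p+1)/tlen)**bias captures
    the direction with an analytically tractable shape (bias=0 is uniform).
    """
    n = tlen - read_len + 1
    if n <= 0:
        raise ValueError("transcript shorter than read length")
    if bias == 0:
        return np.full(n, 1.0 / n)
    w = ((np.arange(n) + 1.0) / tlen) ** bias
    return w / w.sum()


def simulate_rnaseq(catalog: Catalog, program: ExpressionProgram, caste: str,
                    n_spots: int, bias: float = 1.5, dup_rate: float = 0.0,
                    error_rate: float = 0.0, seed: int = 0,
                    read_len: int = 100, paired: bool = False,
                    dup_same_id: bool = False,
                    set_id: str | None = None) -> ReadSet:
    """Simulate one polyA-selected transcriptome read set for a caste.

    Each original spot picks a gene proportionally to its programmed
    abundance (structural load applied to protein-category genes), a
    fragment start with 3'-biased weight, and emits one read (or a pair:
    5'-mate plus reverse-complemented adjacent 3'-mate) with independent
    per-base substitution errors.  A ``dup_rate`` fraction of the final
    spots are re-emissions of earlier spots — under fresh spot ids by
    default (the PCR-duplicate analog the spot-id dedup cannot see), or
    under the original id when ``dup_same_id`` is set, to exercise dedup.

    Ground truth (per-gene original spot counts, per-spot origins and
    fragment starts, duplicate provenance) is attached as ``truth``.
    """
    if caste not in program.abundance:
        raise ValueError(f"caste {caste!r} not in program")
    if n_spots <= 0:
        raise ValueError("n_spots must be > 0")
    if not 0 <= dup_rate < 1:
        raise ValueError("dup_rate must be in [0, 1)")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng([seed, _STREAM_RNASEQ])

    lam = program.abundance[caste]
    load = program.load(caste)
    genes = [g for g in catalog if lam.get(g.gene_id, 0.0) > 0]
    weights = np.array(
        [lam[g.gene_id] * (load if g.category == "protein" else 1.0) for g in genes]
    )
    if not genes:
        raise ValueError(f"all abundances zero for caste {caste!r}")
    probs = weights / weights.sum()

    # Transcript = CDS + random 3' UTR (drawn once per gene per simulation).
    transcripts, tarrs, start_dists = [], [], []
    for g in genes:
        t = g.cds + _random_cds(rng, g.utr3_len)
        transcripts.append(t)
        tarrs.append(np.frombuffer(t.encode(), dtype=np.uint8))
        start_dists.append(_start_distribution(len(t), read_len, bias))

    n_dup = int(round(dup_rate * n_spots))
    n_orig = n_spots - n_dup
    gene_draw = rng.choice(len(genes), size=n_orig, p=probs)

    # Fragment starts, drawn per gene in one vectorised call each.
    starts = np.zeros(n_orig, dtype=np.int64)
    for gi in range(len(genes)):
        idx = np.nonzero(gene_draw == gi)[0]
        if idx.size:
            starts[idx] = rng.choice(start_dists[gi].size, size=idx.size,
                                     p=start_dists[gi])
    flips = rng.random(n_orig) < 0.5  # unstranded library

    def mutate(arr: np.ndarray) -> str:
        if error_rate > 0:
            hit = rng.random(arr.size) < error_rate
            if hit.any():
                arr = arr.copy()
                # substitute with a uniformly random *different* base
                cur = np.searchsorted(_BASES, arr[hit])
                arr[hit] = _BASES[(cur + rng.integers(1, 4, size=hit.sum())) % 4]
        return arr.tobytes().decode()

    spots: list[tuple[str, tuple[str, ...]]] = []
    origins: list[dict] = []
    counts: dict[str, int] = {g.gene_id: 0 for g in catalog}
    for i in range(n_orig):
        gi = int(gene_draw[i])
        g = genes[gi]
        tlen = len(transcripts[gi])
        p = int(starts[i])
        reads = [mutate(tarrs[gi][p:p + read_len])]
        if paired:
            q = min(p + read_len, tlen - read_len)
            mate = mutate(tarrs[gi][q:q + read_len])
            reads.append(reverse_complement(mate))
        if flips[i]:
            reads = [reverse_complement(r) for r in reads]
        sid = f"spot{i:07d}"
        spots.append((sid, tuple(reads)))
        origins.append({"spot_id": sid, "gene": g.gene_id, "start": p,
                        "tlen": tlen, "dup_of": None})
        counts[g.gene_id] += 1

    dup_of = rng.integers(0, n_orig, size=n_dup) if n_dup else np.array([], dtype=int)
    for j in range(n_dup):
        src = int(dup_of[j])
        sid = spots[src][0] if dup_same_id else f"spot{n_orig + j:07d}"
        spots.append((sid, spots[src][1]))
        origins.append({"spot_id": sid, "gene": origins[src]["gene"],
                        "start": origins[src]["start"],
                        "tlen": origins[src]["tlen"],
                        "dup_of": spots[src][0]})

    truth = {
        "caste": caste,
        "seed": seed,
        "bias": bias,
        "read_len": read_len,
        "paired": paired,
        "counts": counts,
        "n_duplicates": n_dup,
        "dup_same_id": dup_same_id,
        "origins": origins,
    }
    return ReadSet(
        set_id=set_id or f"{caste}-seed{seed}",
        spots=spots,
        labels={"species": "synthetic", "caste": caste, "tissue": "whole-body"},
        truth=truth,
    )


def matchable_truth_counts(readset: ReadSet, catalog: Catalog,
                           min_overlap: int) -> dict[str, int]:
    """Per-gene distinct-spot counts a CDS matcher can possibly recover.

    A single-end spot is matchable when its fragment overlaps its source
    gene's CDS by at least ``min_overlap`` nt; fragments entirely (or almost
    entirely) inside the 3' UTR are invisible to CDS matching — that
    undercount is the very artefact the 3'-bias model emulates.  Duplicate
    re-emissions under fresh spot ids count; re-listings under the original
    id collapse.  Defined for error-free, single-end simulations.
    """
    if readset.truth is None:
        raise ValueError("read set carries no ground truth")
    counted: dict[str, set[str]] = {}
    for o in readset.truth["origins"]:
        cds_len = len(catalog[o["gene"]].cds)
        if cds_len - o["start"] >= min_overlap:
            counted.setdefault(o["gene"], set()).add(o["spot_id"])
    return {g.gene_id: len(counted.get(g.gene_id, ())) for g in catalog}


# ------------------------------------------------------------- genome reads

def simulate_genome_reads(contigs: dict[str, str], coverage: float,
                          read_len: int = 100, seed: int = 0,
                          embedded_genes: dict[str, list[str]] | None = None,
                          set_id: str = "genome") -> ReadSet:
    """Uniform shotgun reads over contigs at a target mean per-base coverage.

    ``embedded_genes`` maps contig name -> gene ids whose exons the contig
    carries; it is passed through into the truth record so presence/absence
    calls can be validated.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    for name, seq in contigs.items():
        if len(seq) < read_len:
            raise ValueError(f"contig {name!r} shorter than read_len")
    rng = np.random.default_rng([seed, _STREAM_GENOME])
    spots = []
    origins = []
    i = 0
    for name in contigs:
        seq = contigs[name]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n_reads = int(round(coverage * len(seq) / read_len))
        starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
        flips = rng.random(n_reads) < 0.5
        for p, flip in zip(starts, flips):
            read = arr[p:p + read_len].tobytes().decode()
            if flip:
                read = reverse_complement(read)
            sid = f"g{i:07d}"
            spots.append((sid, (read,)))
            origins.append({"spot_id": sid, "contig": name, "start": int(p)})
            i += 1
    truth = {
        "seed": seed,
        "coverage": coverage,
        "read_len": read_len,
        "contig_lengths": {n: len(s) for n, s in contigs.items()},
        "embedded_genes": embedded_genes or {},
        "origins": origins,
    }
    return ReadSet(set_id=set_id, spots=spots,
                   labels={"species": "synthetic", "caste": "na", "tissue": "genome"},
                   truth=truth)
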