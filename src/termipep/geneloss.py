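"""Gene presence/absence calls from unassembled genome reads.

Rationale: a receptor gene may diverge enough to dodge nucleotide searches,
but if a genome is sequenced many-fold it is statistically impossible for
the transmembrane region of its GPCR to leave no read at all.  The query
protein region is therefore cut into pieces corresponding to its coding
exons (so that no piece straddles an intron in the genome reads), each
piece is searched against six-frame translations of the reads with a
peptide seed-and-extend, and every hit is competitively re-scored against a
panel of paralogous receptors.  A hit only supports the queried gene when
that gene is its unique best assignment — reads from a surviving paralog
(LGR5, say, when LGR3 is queried) are recognised and discounted, which is
exactly how concomitant receptor loss is distinguished from search failure.

An *absent* verdict additionally requires adequate sequencing depth: at
coverage well below ~5x, finding no read proves nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .synth import ReadSet

MIN_PIECE_LEN = 8       # aa; shorter exon pieces are merged with a neighbour
SEED_LEN = 4            # aa; exact peptide seed
SCORE_THRESHOLD = 25.0  # bit score to report a hit
MIN_ALN_LEN = 10        # aa
DEPTH_FLOOR = 5.0       # mean coverage below which "absent" is not callable

# Ungapped Karlin-Altschul parameters for BLOSUM62: raw scores are converted
# to bit scores so the reporting threshold has a search-space-free meaning
# (random 100 nt reads top out near 20 bits; 45 %-identity paralog fragments
# land above 25).
_KA_LAMBDA = 0.267
_KA_K = 0.041


def bit_score(raw: float) -> float:
    return (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2.0)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_IDX = {a: i for i, a in enumerate(_AA)}
_SCORE = np.zeros((len(_AA), len(_AA)), dtype=np.float64)
for _a in _AA:
    for _b in _AA:
        try:
            _SCORE[_AA_IDX[_a], _AA_IDX[_b]] = _BLOSUM62[_a, _b]
        except IndexError:
            _SCORE[_AA_IDX[_a], _AA_IDX[_b]] = -4.0


@dataclass(frozen=True)
class ExonPeptidePiece:
    parent_gene: str
    piece_index: int
    peptide: str
    span: tuple[int, int]  # aa offsets in the query region, 0-based half-open


@dataclass
class Hit:
    read_id: str
    frame: int              # 0..5 (3 forward, 3 reverse)
    score: float            # bit score
    raw_score: float        # BLOSUM62 ungapped sum
    identity: float
    aln_len: int
    piece_span: tuple[int, int]
    read_peptide: str       # aligned read-side peptide
    stop_adjacent: bool     # alignment truncated by an in-frame stop codon


@dataclass
class PresenceCall:
    gene: str
    verdict: str                         # present | absent | ambiguous
    pieces_supported: int
    pieces_total: int
    piece_hits: dict[int, list[Hit]]     # supporting hits per piece index
    reassigned: dict[str, int]           # panel gene -> hits it won instead
    depth: float | None
    stop_codon_hint: bool = False
    notes: list[str] = field(default_factory=list)


# --------------------------------------------------------------- splitting

def split_pieces(protein: str, exon_boundaries: list[int],
                 parent_gene: str = "query") -> list[ExonPeptidePiece]:
    """Cut a protein region at its coding-exon boundaries.

    Boundaries are strictly increasing internal aa offsets.  Pieces shorter
    than ``MIN_PIECE_LEN`` are merged with their left neighbour (or right,
    for a leading fragment), so every returned piece is searchable.
    """
    n = len(protein)
    if any(b <= 0 or b >= n for b in exon_boundaries):
        raise ValueError("exon boundary outside sequence")
    if list(exon_boundaries) != sorted(set(exon_boundaries)):
        raise ValueError("exon boundaries must be strictly increasing")
    cuts = [0, *exon_boundaries, n]
    spans = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and (e - s < MIN_PIECE_LEN or
                       merged[-1][1] - merged[-1][0] < MIN_PIECE_LEN):
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [
        ExonPeptidePiece(parent_gene, i, protein[s:e], (s, e))
        for i, (s, e) in enumerate(merged)
    ]


# ----------------------------------------------------------- translation

def six_frame_segments(read: str) -> list[tuple[int, int, str, bool]]:
    """Translate a read in all six frames and split at stop codons.

    Returns ``(frame, aa_offset_in_frame, peptide, ends_at_stop)`` for each
    stop-free segment.
    """
    out = []
    seqs = [read, str(Seq(read).reverse_complement())]
    for strand, s in enumerate(seqs):
        for off in range(3):
            frame = 3 * strand + off
            codons = (len(s) - off) // 3
            if codons <= 0:
                continue
            pep = str(Seq(s[off:off + 3 * codons]).translate())
            start = 0
            while start < len(pep):
                stop = pep.find("*", start)
                if stop == -1:
                    out.append((frame, start, pep[start:], False))
                    break
                if stop > start:
                    out.append((frame, start, pep[start:stop], True))
                start = stop + 1
    return out


def _extend(piece: str, seg: str, p0: int, s0: int) -> tuple[float, int, int, int]:
    """Best-scoring ungapped extension around an exact seed.

    The seed occupies ``piece[p0:p0+SEED_LEN]`` aligned to
    ``seg[s0:s0+SEED_LEN]``.  Returns (score, piece_start, seg_start, length)
    of the maximal-score contiguous alignment containing the seed.
    """
    pa = np.frombuffer(piece.encode(), dtype=np.uint8)
    sa = np.frombuffer(seg.encode(), dtype=np.uint8)
    # per-position scores along the diagonal
    lo = min(p0, s0)
    hi = min(len(piece) - p0, len(seg) - s0)
    pi = np.array([_AA_IDX.get(chr(c), _AA_IDX["X"]) for c in pa[p0 - lo:p0 + hi]])
    si = np.array([_AA_IDX.get(chr(c), _AA_IDX["X"]) for c in sa[s0 - lo:s0 + hi]])
    sc = _SCORE[pi, si]
    seed_a, seed_b = lo, lo + SEED_LEN  # seed indices within sc

    left = sc[:seed_a][::-1]
    lcum = np.concatenate(([0.0], np.cumsum(left)))
    lbest = int(np.argmax(lcum))
    right = sc[seed_b:]
    rcum = np.concatenate(([0.0], np.cumsum(right)))
    rbest = int(np.argmax(rcum))
    score = float(sc[seed_a:seed_b].sum() + lcum[lbest] + rcum[rbest])
    start = seed_a - lbest
    length = (seed_b + rbest) - start
    return score, p0 - lo + start, s0 - lo + start, length


def translated_search(piece: ExonPeptidePiece, reads: ReadSet,
                      score_threshold: float = SCORE_THRESHOLD,
                      min_aln_len: int = MIN_ALN_LEN) -> list[Hit]:
    """tblastn-style search of one exon peptide piece against a read set.

    Every read is translated in six frames (stops truncate segments); exact
    4-aa seeds against the piece are extended without gaps under BLOSUM62;
    alignments reaching >= ``score_threshold`` bits over >= ``min_aln_len``
    residues are reported (best alignment per read).
    """
    if len(piece.peptide) < SEED_LEN:
        raise ValueError("piece shorter than the peptide seed")
    seeds: dict[str, list[int]] = {}
    for i in range(len(piece.peptide) - SEED_LEN + 1):
        seeds.setdefault(piece.peptide[i:i + SEED_LEN], []).append(i)

    hits: dict[str, Hit] = {}
    for read_id, read_seqs in reads.spots:
        best: Hit | None = None
        for read in read_seqs:
            for frame, aa_off, pep, ends_at_stop in six_frame_segments(read):
                if len(pep) < SEED_LEN:
                    continue
                tried: set[tuple[int, int]] = set()
                for j in range(len(pep) - SEED_LEN + 1):
                    for i in seeds.get(pep[j:j + SEED_LEN], ()):
                        diag = (i - j, frame)
                        if diag in tried:
                            continue
                        tried.add(diag)
                        raw, ps, ss, ln = _extend(piece.peptide, pep, i, j)
                        bits = bit_score(raw)
                        if bits < score_threshold or ln < min_aln_len:
                            continue
                        ident = float(np.mean([
                            piece.peptide[ps + t] == pep[ss + t] for t in range(ln)
                        ]))
                        stop_adj = ends_at_stop and (ss + ln == len(pep)) \
                            and (ps + ln < len(piece.peptide))
                        h = Hit(read_id=read_id, frame=frame, score=bits,
                                raw_score=raw, identity=ident, aln_len=ln,
                                piece_span=(ps, ps + ln),
                                read_peptide=pep[ss:ss + ln],
                                stop_adjacent=stop_adj)
                        if best is None or h.score > best.score:
                            best = h
        if best is not None:
            hits[read_id] = best
    return list(hits.values())


# ------------------------------------------------------------ presence call

def _best_panel_score(read_pep: str, panel_protein: str) -> float:
    """Best ungapped seed-extended score of an aligned read peptide against
    a panel protein (0 when no seed exists)."""
    if len(read_pep) < SEED_LEN:
        return 0.0
    best = 0.0
    tried: set[int] = set()
    index: dict[str, list[int]] = {}
    for i in range(len(panel_protein) - SEED_LEN + 1):
        index.setdefault(panel_protein[i:i + SEED_LEN], []).append(i)
    for j in range(len(read_pep) - SEED_LEN + 1):
        for i in index.get(read_pep[j:j + SEED_LEN], ()):
            diag = i - j
            if diag in tried:
                continue
            tried.add(diag)
            score, *_ = _extend(panel_protein, read_pep, i, j)
            best = max(best, score)
    return best


def estimate_depth(reads: ReadSet, control_sequences: dict[str, str]) -> float:
    """Mean per-base coverage over control single-copy sequences, estimated
    by exact k-mer matching of reads to the controls."""
    from .spots import KmerIndex, MatchParams, match_read
    from .synth import Catalog, GeneRecord

    genes = []
    for name, seq in control_sequences.items():
        trimmed = seq[: len(seq) - len(seq) % 3]
        genes.append(GeneRecord(name, name, trimmed, "household", False, 0))
    catalog = Catalog(genes)
    params = MatchParams()
    index = KmerIndex(catalog, params.k)
    matched_bases = 0
    for _, read_seqs in reads.spots:
        for r in read_seqs:
            if len(r) >= params.min_match and match_read(r, index, params):
                matched_bases += len(r)
    total_len = sum(len(g.cds) for g in genes)
    return matched_bases / total_len if total_len else 0.0


def call_presence(gene: str, pieces: list[ExonPeptidePiece], reads: ReadSet,
                  paralog_panel: dict[str, str], depth: float | None = None,
                  depth_floor: float = DEPTH_FLOOR,
                  support_fraction: float = 0.5,
                  score_threshold: float = SCORE_THRESHOLD,
                  min_aln_len: int = MIN_ALN_LEN) -> PresenceCall:
    """Decide present / absent / ambiguous for one gene.

    Each piece is searched against the reads; every hit is re-scored
    against all panel members (the queried gene's own protein must be in
    the panel) and supports the queried gene only when that gene is its
    unique best assignment.  Verdicts: *present* when >= half the pieces
    are supported; *absent* when no piece is supported and the depth
    estimate clears the floor; *ambiguous* otherwise.  Panel order never
    affects the outcome.
    """
    if not paralog_panel:
        raise ValueError("paralog panel is empty")
    if gene not in paralog_panel:
        raise ValueError("panel must include the queried gene's own protein")
    panel = dict(sorted(paralog_panel.items()))

    piece_hits: dict[int, list[Hit]] = {}
    reassigned: dict[str, int] = {g: 0 for g in panel}
    stop_hint = False
    for piece in pieces:
        supporting = []
        for hit in translated_search(piece, reads, score_threshold, min_aln_len):
            scores = {g: _best_panel_score(hit.read_peptide, prot)
                      for g, prot in panel.items()}
            best = max(scores.values())
            winners = sorted(g for g, s in scores.items() if s >= best - 1e-9)
            if winners == [gene]:
                supporting.append(hit)
                if hit.stop_adjacent and hit.identity >= 0.8:
                    stop_hint = True
            elif len(winners) == 1:
                reassigned[winners[0]] += 1
        if supporting:
            piece_hits[piece.piece_index] = supporting

    supported = len(piece_hits)
    total = len(pieces)
    notes = []
    if supported >= support_fraction * total and total > 0:
        verdict = "present"
    elif supported == 0:
        if depth is not None and depth >= depth_floor:
            verdict = "absent"
        else:
            verdict = "ambiguous"
            notes.append("no supported pieces but depth below floor or unknown")
    else:
        verdict = "ambiguous"
        notes.append(f"only {supported}/{total} pieces supported")
    if stop_hint:
        notes.append("high-identity hits truncated by in-frame stop codons "
                     "(possible pseudogene)")
    return PresenceCall(gene=gene, verdict=verdict, pieces_supported=supported,
                        pieces_total=total, piece_hits=piece_hits,
                        reassigned={g: n for g, n in reassigned.items() if n},
                        depth=depth, stop_codon_hint=stop_hint, notes=notes)
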