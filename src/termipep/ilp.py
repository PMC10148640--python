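"""Insulin-like precursor annotation and structural classification.

Insulin-family precursors are organised signal peptide - B chain -
C peptide - A chain, with the chains excised at dibasic (KR/RR/KK) or
tetrabasic prohormone-convertase sites.  The A chain carries four framework
cysteines; the spacing between the second and third of them separates the
IGF/atirpin type (three intervening residues) from the other short
IGF-related peptides (sirps: birpin, cirpin, brovirpin — four residues).
Precursors lacking clean dibasic sites between B and A chains (IGF,
atirpin) are hinted as substrates of the constitutive secretory pathway.

All rules here are deterministic sequence rules, not predictors; where a
precursor does not fit the template it is reported unclassifiable rather
than guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

BASIC = set("KR")
DIBASIC_MOTIFS = {"KR", "RR", "KK"}   # RK is a poor convertase substrate
MIN_PRECURSOR_LEN = 40

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
SIGNAL_WINDOW = 19
SIGNAL_THRESHOLD = 1.6
SIGNAL_SEARCH_LIMIT = 35
SIGNAL_ANCHOR_START = 5   # hydrophobic window starting after here hints an anchor

CLASS_IGF_LIKE = "IGF-like/atirpin-like"
CLASS_OTHER_SIRP = "other-sirp"
CLASS_UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class CleavageSite:
    position: int    # cleavage point: index of the first residue after the motif
    motif: str
    kind: str        # "dibasic" | "tetrabasic"


@dataclass
class PrecursorAnnotation:
    precursor_id: str
    signal_span: tuple[int, int] | None
    signal_anchor_hint: bool
    chain_spans: dict[str, tuple[int, int] | None]  # B, C, A
    cleavage_sites: list[CleavageSite]
    a_chain_cysteines: list[int] | None   # absolute offsets of the 4 framework cys
    cys2_cys3_gap: int | None
    ilp_class: str
    processing_hint: str                  # "regulated" | "constitutive" | "unknown"
    reason: str = ""


# ------------------------------------------------------------ cleavage sites

def find_cleavage_sites(precursor: str) -> list[CleavageSite]:
    """Locate candidate prohormone-convertase sites.

    Maximal runs of K/R are interpreted longest-match: a run of >= 4 basic
    residues is a single tetrabasic site (not several dibasic ones); runs
    of 2-3 contribute one dibasic site at their rightmost valid KR/RR/KK
    pair.  The cleavage position is C-terminal to the motif.  Non-standard
    residues interrupt runs and are skipped with a warning.
    """
    if len(precursor) < MIN_PRECURSOR_LEN:
        raise ValueError(f"precursor shorter than {MIN_PRECURSOR_LEN} aa")
    for i, aa in enumerate(precursor):
        if aa not in _KD and aa not in "UX*":
            warnings.warn(f"non-standard residue {aa!r} at {i}; position skipped")
    sites: list[CleavageSite] = []
    i, n = 0, len(precursor)
    while i < n:
        if precursor[i] in BASIC:
            j = i
            while j < n and precursor[j] in BASIC:
                j += 1
            run = precursor[i:j]
            if len(run) >= 4:
                sites.append(CleavageSite(j, run, "tetrabasic"))
            else:
                for s in range(len(run) - 2, -1, -1):  # rightmost valid pair
                    pair = run[s:s + 2]
                    if pair in DIBASIC_MOTIFS:
                        sites.append(CleavageSite(i + s + 2, pair, "dibasic"))
                        break
            i = j
        else:
            i += 1
    return sites


# ---------------------------------------------------------------- signal

def _signal_region(precursor: str) -> tuple[tuple[int, int] | None, bool]:
    """First 19-aa Kyte-Doolittle window with mean hydropathy >= 1.6 within
    the N-terminal 35 residues; a window starting late hints at an
    uncleaved signal anchor.  Approximate by design."""
    limit = min(SIGNAL_SEARCH_LIMIT, len(precursor))
    for start in range(0, limit - SIGNAL_WINDOW + 1):
        window = precursor[start:start + SIGNAL_WINDOW]
        vals = [_KD[a] for a in window if a in _KD]
        if len(vals) == SIGNAL_WINDOW and sum(vals) / SIGNAL_WINDOW >= SIGNAL_THRESHOLD:
            return (0, start + SIGNAL_WINDOW), start > SIGNAL_ANCHOR_START
    return None, False


# --------------------------------------------------------------- annotation

def annotate(precursor_id: str, precursor: str) -> PrecursorAnnotation:
    """Annotate one precursor: signal region, chains, cleavage sites,
    A-chain cysteine framework and structural class.

    The B chain is the first post-signal segment (between cleavage sites)
    containing a cysteine; the A chain is the last segment containing at
    least four.  When the precursor has no internal cleavage sites the
    whole mature region is one segment carrying both chains (the
    constitutive, IGF-like layout) and the four A-chain framework
    cysteines are taken as the last four.  ``cys2_cys3_gap`` counts the
    residues strictly between the 2nd and 3rd framework cysteines
    ("CXXXC" has a gap of 3).
    """
    sites = find_cleavage_sites(precursor)
    signal_span, anchor_hint = _signal_region(precursor)
    mature_start = signal_span[1] if signal_span else 0

    def unclassifiable(reason):
        return PrecursorAnnotation(
            precursor_id=precursor_id, signal_span=signal_span,
            signal_anchor_hint=anchor_hint,
            chain_spans={"B": None, "C": None, "A": None},
            cleavage_sites=sites, a_chain_cysteines=None, cys2_cys3_gap=None,
            ilp_class=CLASS_UNCLASSIFIABLE, processing_hint="unknown",
            reason=reason)

    n_cys_mature = precursor.count("C", mature_start)
    if n_cys_mature < 6:
        return unclassifiable(f"only {n_cys_mature} cysteines after the signal region")

    # segments of the mature chain between cleavage points
    cuts = [mature_start] + [s.position for s in sites
                             if mature_start < s.position < len(precursor)] \
        + [len(precursor)]
    cuts = sorted(set(cuts))
    segments = [(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]

    def cys_positions(span):
        return [i for i in range(span[0], span[1]) if precursor[i] == "C"]

    b_span = next((s for s in segments if cys_positions(s)), None)
    a_span = next((s for s in reversed(segments) if len(cys_positions(s)) >= 4), None)
    if a_span is None:
        return unclassifiable("no segment with >= 4 A-chain cysteines")

    a_cys = cys_positions(a_span)[-4:]
    gap = a_cys[2] - a_cys[1] - 1
    if gap == 3:
        ilp_class = CLASS_IGF_LIKE
    elif gap == 4:
        ilp_class = CLASS_OTHER_SIRP
    else:
        ilp_class = CLASS_UNCLASSIFIABLE

    if b_span == a_span or b_span is None:
        chain_spans = {"B": None, "C": None, "A": a_span}
    else:
        c_span = (b_span[1], a_span[0]) if a_span[0] > b_span[1] else None
        chain_spans = {"B": b_span, "C": c_span, "A": a_span}

    between = [s for s in sites
               if b_span and b_span[1] <= s.position <= a_span[0]]
    hint = "regulated" if between else "constitutive"
    return PrecursorAnnotation(
        precursor_id=precursor_id, signal_span=signal_span,
        signal_anchor_hint=anchor_hint, chain_spans=chain_spans,
        cleavage_sites=sites, a_chain_cysteines=a_cys, cys2_cys3_gap=gap,
        ilp_class=ilp_class, processing_hint=hint,
        reason="" if ilp_class != CLASS_UNCLASSIFIABLE
        else f"cys2-cys3 gap {gap} matches no class")


def classify_catalog(precursors: list[tuple[str, str]]) -> pd.DataFrame:
    """Annotate a list of ``(id, sequence)`` precursors; one row each, plus
    per-class counts available via ``df["class"].value_counts()``."""
    if not precursors:
        raise ValueError("no precursors given")
    rows = []
    for pid, seq in precursors:
        ann = annotate(pid, seq)
        rows.append({
            "precursor_id": pid,
            "signal_span": ann.signal_span,
            "B_span": ann.chain_spans["B"],
            "C_span": ann.chain_spans["C"],
            "A_span": ann.chain_spans["A"],
            "n_cleavage_sites": len(ann.cleavage_sites),
            "cys2_cys3_gap": ann.cys2_cys3_gap,
            "class": ann.ilp_class,
            "processing_hint": ann.processing_hint,
            "reason": ann.reason,
        })
    return pd.DataFrame(rows)


def annotation_to_gff3(ann: PrecursorAnnotation) -> str:
    """Render chain features as GFF3 lines on the precursor coordinate
    system (0-based half-open internally, 1-based inclusive in GFF3)."""
    lines = ["##gff-version 3"]

    def feat(ftype, span, attrs):
        lines.append("\t".join([
            ann.precursor_id, "termipep", ftype,
            str(span[0] + 1), str(span[1]), ".", "+", ".", attrs,
        ]))

    if ann.signal_span:
        feat("signal_peptide", ann.signal_span,
             f"ID={ann.precursor_id}:signal")
    for chain in ("B", "C", "A"):
        span = ann.chain_spans.get(chain)
        if span:
            feat("mature_protein_region", span,
                 f"ID={ann.precursor_id}:{chain}-chain;Name={chain} chain")
    for site in ann.cleavage_sites:
        feat("cleavage_site", (site.position - len(site.motif), site.position),
             f"Note={site.kind} {site.motif}")
    return "\n".join(lines) + "\n"


# ------------------------------------------------- designed test precursors

_SIGNAL = "MKTVLLLAVLLAVLAVSFA"      # 19-aa hydrophobic signal peptide
_B_CHAIN = "GVDQ" + "C" + "GSHLVEALYLV" + "C" + "GDNGFYS"   # 2 cysteines
_C_PEP = "EAEDLQVGQVELGGGPGAGSLQ"
_A_TAIL = "SLYQLENY"


def _a_chain(gap: int) -> str:
    spacer = ("TSIHGPAS" * 2)[:gap]  # no K/R/C in the spacer
    return "GIVEQ" + "CC" + spacer + "C" + _A_TAIL + "C" + "N"


def make_ilp_precursors(seed: int = 0) -> list[tuple[str, str]]:
    """Synthetic insulin-like precursor set with designed Cys2-Cys3 gaps.

    Stand-ins for real termite precursor sequences (which are not bundled):
    IGF and atirpin are built with a three-residue gap and no dibasic sites
    between their chains; the other sirps with a four-residue gap and KR
    sites flanking the C peptide.  The layout, not the residue detail, is
    what the classifier consumes.
    """
    gaps = {"gonadulin": 4, "igf": 3, "dilp7": 4,
            "atirpin": 3, "birpin": 4, "cirpin": 4, "brovirpin": 4}
    constitutive = {"igf", "atirpin"}
    out = []
    for name, gap in gaps.items():
        a = _a_chain(gap)
        if name in constitutive:
            seq = _SIGNAL + _B_CHAIN + "GG" + _C_PEP + "GG" + a
        else:
            seq = _SIGNAL + _B_CHAIN + "KR" + _C_PEP + "KR" + a
        out.append((name, seq))
    return out
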