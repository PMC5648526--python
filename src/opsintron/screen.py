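"""Diagnostic opsin screening in bovine rhodopsin numbering.

Opsins are rhodopsin-like GPCRs whose functional hallmarks sit at fixed
positions of the bovine rod opsin (UniProt P08100), the field's universal
positional reference: the retinal-binding lysine at position 296, the
NPxxY motif at 302-306, and the tripeptide at 310-312 that shapes
G-protein coupling (NKQ in c-opsins and some xenopsins, HPK in r-opsins).
The C-terminal VxPx motif is a ciliary trafficking signal of vertebrate
visual opsins.

Candidate residues are assigned bovine positions through a global
pairwise alignment (BLOSUM62, affine gaps, open 10 / extend 1 — classic
defaults), yielding a monotone one-to-one residue correspondence. Each
check then reads the candidate residue aligned to the reference position;
a reference position falling in a candidate gap yields "unaligned", never
a spurious call. Candidates shorter than 160 residues are excluded as
likely fragments before any phylogenetic use.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "NumberingMap",
    "ScreenRecord",
    "bovine_rhodopsin",
    "build_reference_map",
    "residue_at",
    "check_chromophore_lysine",
    "classify_tripeptide",
    "check_npxxy",
    "check_vxpx_cterm",
    "screen_candidates",
    "read_domain_calls",
    "LYS_POSITION",
    "NPXXY_SPAN",
    "TRIPEPTIDE_SPAN",
]

LYS_POSITION = 296
NPXXY_SPAN = (302, 306)
TRIPEPTIDE_SPAN = (310, 312)

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")

# Fraction of the reference self-alignment score below which a numbering
# map is flagged low-confidence. Shuffled sequences of opsin composition
# score well under 10% of the self-score; genuine opsins score far above.
LOW_CONFIDENCE_FRACTION = 0.1


class ScreenError(ValueError):
    pass


def bovine_rhodopsin() -> str:
    """The packaged bovine rod opsin reference sequence (UniProt P08100)."""
    ref = resources.files("opsintron.data") / "bovine_rhodopsin.fasta"
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


@dataclass
class NumberingMap:
    """Candidate-residue to reference-position correspondence.

    ``pairs`` lists (candidate residue index, reference position), both
    1-based, one pair per aligned (non-gap) column; the mapping is
    strictly monotone in both coordinates.
    """

    candidate_id: str
    pairs: list[tuple[int, int]]
    score: float
    low_confidence: bool
    candidate_seq: str
    reference_seq: str

    def __post_init__(self):
        self._by_ref = {ref: cand for cand, ref in self.pairs}


@lru_cache(maxsize=8)
def _aligner(gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def build_reference_map(
    candidate: str,
    reference: str,
    candidate_id: str = "candidate",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    matrix: str = "BLOSUM62",
) -> NumberingMap:
    """Globally align a candidate to the reference and record the map.

    The map is flagged low-confidence when the alignment score falls
    below ``LOW_CONFIDENCE_FRACTION`` of the reference self-alignment
    score, as happens for unrelated or scrambled sequences.
    """
    candidate = candidate.upper().rstrip("*")
    reference = reference.upper().rstrip("*")
    if not candidate or not reference:
        raise ScreenError(f"{candidate_id}: empty sequence")
    for name, seq in (("candidate", candidate), ("reference", reference)):
        bad = set(seq) - VALID_AA
        if bad:
            raise ScreenError(
                f"{candidate_id}: non-amino-acid characters in {name}: {sorted(bad)}"
            )
    aligner = _aligner(gap_open, gap_extend, matrix)
    alignment = aligner.align(candidate, reference)[0]
    pairs = []
    for (c_start, c_end), (r_start, r_end) in zip(*alignment.aligned):
        for k in range(c_end - c_start):
            pairs.append((c_start + k + 1, r_start + k + 1))
    self_score = aligner.score(reference, reference)
    return NumberingMap(
        candidate_id=candidate_id,
        pairs=pairs,
        score=float(alignment.score),
        low_confidence=alignment.score < LOW_CONFIDENCE_FRACTION * self_score,
        candidate_seq=candidate,
        reference_seq=reference,
    )


def residue_at(numbering: NumberingMap, ref_position: int) -> str:
    """Candidate residue aligned to a reference position, or "unaligned"."""
    if not 1 <= ref_position <= len(numbering.reference_seq):
        raise ScreenError(
            f"reference position {ref_position} outside "
            f"[1,{len(numbering.reference_seq)}]"
        )
    cand = numbering._by_ref.get(ref_position)
    if cand is None:
        return "unaligned"
    return numbering.candidate_seq[cand - 1]


def check_chromophore_lysine(numbering: NumberingMap) -> str:
    """Is the retinal-binding lysine present at reference position 296?"""
    res = residue_at(numbering, LYS_POSITION)
    if res == "unaligned":
        return "unaligned"
    return "present" if res == "K" else "absent"


def classify_tripeptide(numbering: NumberingMap) -> tuple[str, str]:
    """Read positions 310-312 and classify the G-protein tripeptide.

    Returns (tripeptide string with "." for unaligned positions, class):
    NKQ -> "c-type", HPK -> "r-type", anything else (including partial
    reads) -> "other".
    """
    chars = []
    for pos in range(TRIPEPTIDE_SPAN[0], TRIPEPTIDE_SPAN[1] + 1):
        res = residue_at(numbering, pos)
        chars.append("." if res == "unaligned" else res)
    tri = "".join(chars)
    if tri == "NKQ":
        cls = "c-type"
    elif tri == "HPK":
        cls = "r-type"
    else:
        cls = "other"
    return tri, cls


def check_npxxy(numbering: NumberingMap) -> str:
    """NPxxY motif at reference positions 302-306."""
    residues = [
        residue_at(numbering, pos)
        for pos in range(NPXXY_SPAN[0], NPXXY_SPAN[1] + 1)
    ]
    if "unaligned" in residues:
        return "unaligned"
    n, p, _, _, y = residues
    return "present" if (n == "N" and p == "P" and y == "Y") else "absent"


def scan_npxxy(candidate: str) -> list[int]:
    """Positions (1-based) of any NPxxY occurrence in the raw sequence."""
    return [m.start() + 1 for m in re.finditer(r"NP..Y", candidate.upper())]


def check_vxpx_cterm(candidate: str, tail_window: int = 2) -> tuple[bool, Optional[str]]:
    """C-terminal VxPx motif, ending within ``tail_window`` of the end.

    Returns (flag, matched 4-mer or None).
    """
    seq = candidate.upper().rstrip("*")
    if len(seq) < 4:
        raise ScreenError("sequence shorter than the VxPx motif")
    for start in range(len(seq) - 4, -1, -1):
        window = seq[start : start + 4]
        if window[0] == "V" and window[2] == "P":
            if len(seq) - (start + 4) <= tail_window:
                return True, window
    return False, None


def read_domain_calls(source: str | os.PathLike) -> dict[str, bool]:
    """Read an external 7tm_1 domain-call table: id<TAB>true/false."""
    out = {}
    with open(source) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            sid, flag = ln.split("\t")[:2]
            out[sid] = flag.strip().lower() in ("true", "1", "yes")
    return out


@dataclass
class ScreenRecord:
    candidate_id: str
    length: int
    passes_length: bool
    lys296: str
    npxxy: str
    tripeptide_310_312: str
    tripeptide_class: str
    vxpx_cterm: bool
    vxpx_match: Optional[str]
    alignment_score: float
    low_confidence: bool
    external_domain_call: Optional[bool]
    retained: bool
    exclusion_reasons: str


def screen_candidates(
    candidates: "dict[str, str] | Iterable[tuple[str, str]]",
    reference: Optional[str] = None,
    min_length: int = 160,
    tail_window: int = 2,
    domain_calls: Optional[dict[str, bool]] = None,
    npxxy_scan: bool = False,
) -> pd.DataFrame:
    """Screen candidate sequences; returns one row per candidate.

    ``candidates`` maps id to sequence, or is an iterable of (id,
    sequence) pairs; duplicate ids are an error. The retention verdict
    requires the length filter and the lysine-296 check; when an
    external 7tm_1 domain-call table is supplied the domain call is
    required too, otherwise that criterion is recorded as not evaluated.
    NPxxY, tripeptide class and VxPx are recorded but do not gate
    retention — they characterise, rather than define, opsins.
    """
    if reference is None:
        reference = bovine_rhodopsin()
    pairs = (
        list(candidates.items())
        if hasattr(candidates, "items")
        else list(candidates)
    )
    ids = [cid for cid, _ in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ScreenError(f"duplicate candidate ids: {dupes}")

    records = []
    for cid, raw_seq in pairs:
        seq = raw_seq.upper().rstrip("*")
        numbering = build_reference_map(seq, reference, candidate_id=cid)
        lys = check_chromophore_lysine(numbering)
        npxxy = check_npxxy(numbering)
        if npxxy != "present" and npxxy_scan and scan_npxxy(seq):
            npxxy = "present(scan)"
        tri, tri_class = classify_tripeptide(numbering)
        vxpx, vxpx_match = (
            check_vxpx_cterm(seq, tail_window) if len(seq) >= 4 else (False, None)
        )
        passes_length = len(seq) >= min_length
        reasons = []
        if not passes_length:
            reasons.append(f"length<{min_length}")
        if lys != "present":
            reasons.append(f"lys296:{lys}")
        domain = domain_calls.get(cid) if domain_calls is not None else None
        if domain_calls is not None and not domain:
            reasons.append("7tm_1:absent" if domain is False else "7tm_1:no-call")
        records.append(
            ScreenRecord(
                candidate_id=cid,
                length=len(seq),
                passes_length=passes_length,
                lys296=lys,
                npxxy=npxxy,
                tripeptide_310_312=tri,
                tripeptide_class=tri_class,
                vxpx_cterm=vxpx,
                vxpx_match=vxpx_match,
                alignment_score=numbering.score,
                low_confidence=numbering.low_confidence,
                external_domain_call=domain,
                retained=not reasons,
                exclusion_reasons=";".join(reasons),
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])
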