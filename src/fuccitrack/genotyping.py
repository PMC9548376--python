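"""CRISPR amplicon genotyping of resolved single-allele sequences.

Each cloned allele is globally aligned to the reference amplicon; the net
gap length near the predicted cut site classifies it as wild type,
insertion(+n), deletion(-n) or complex.  The allele census tests the
wt/mutant split against the 1:1 ratio expected for a heterozygous edit
(exact binomial), and a frameshifted allele can be scanned for the first
novel in-frame premature stop codon.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align
from scipy.stats import binomtest

__all__ = [
    "AlleleCall",
    "CensusResult",
    "StopReport",
    "classify_allele",
    "allele_census",
    "find_premature_stop",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
HET_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class AlleleCall:
    """Classification of one sequenced allele.

    ``call`` is one of ``wt``, ``insertion``, ``deletion``, ``complex``;
    ``size`` is the net indel length (0 for wt/complex) and ``offset`` the
    position of the first indel relative to the cut site.
    """

    seq_id: str
    call: str
    size: int = 0
    offset: Optional[int] = None

    @property
    def label(self) -> str:
        if self.call == "insertion":
            return f"insertion(+{self.size})"
        if self.call == "deletion":
            return f"deletion(-{self.size})"
        return self.call


@dataclass(frozen=True)
class CensusResult:
    n_total: int
    n_wt: int
    n_mut: int
    n_other: int
    p_binomial: float
    verdict: str  # "consistent with heterozygous" | "not consistent"
    by_class: dict


@dataclass(frozen=True)
class StopReport:
    found: bool
    distance_bp: Optional[int]  # edit site to first novel in-frame stop
    codon_index: Optional[int]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _indel_events(ref: str, seq: str) -> list:
    """(ref_position, signed_length) for every gap in the best alignment."""
    aligner = _make_aligner()
    aln = aligner.align(ref, seq)[0]
    ref_blocks, seq_blocks = aln.aligned
    events = []
    for i in range(1, len(ref_blocks)):
        ref_gap = ref_blocks[i][0] - ref_blocks[i - 1][1]
        seq_gap = seq_blocks[i][0] - seq_blocks[i - 1][1]
        pos = int(ref_blocks[i - 1][1])
        if seq_gap > ref_gap:
            events.append((pos, int(seq_gap - ref_gap)))   # insertion
        elif ref_gap > seq_gap:
            events.append((pos, -int(ref_gap - seq_gap)))  # deletion
    # terminal gaps (length differences at the ends)
    lead_ref, lead_seq = ref_blocks[0][0], seq_blocks[0][0]
    if lead_ref != lead_seq:
        events.insert(0, (0, int(lead_seq - lead_ref)))
    tail_ref = len(ref) - ref_blocks[-1][1]
    tail_seq = len(seq) - seq_blocks[-1][1]
    if tail_ref != tail_seq:
        events.append((int(ref_blocks[-1][1]), int(tail_seq - tail_ref)))
    return events


def classify_allele(seq: str, ref: str, cut_site: int,
                    window_bp: int = 20, seq_id: str = "") -> AlleleCall:
    """Classify one allele sequence against the reference amplicon.

    A zero-difference sequence is wild type.  Otherwise the net gap length
    within ``window_bp`` of ``cut_site`` defines the class; sequences with
    no net indel near the cut site (substitutions only, balanced or
    distant indels) are ``complex``.
    """
    if not seq or not ref:
        raise ValueError("seq and ref must be non-empty")
    if not (0 <= cut_site < len(ref)):
        raise ValueError("cut_site must lie within the reference")
    if window_bp < 10:
        raise ValueError("window_bp must be >= 10")
    seq = seq.upper()
    ref = ref.upper()
    if seq == ref:
        return AlleleCall(seq_id, "wt")
    events = [(pos, n) for pos, n in _indel_events(ref, seq)
              if abs(pos - cut_site) <= window_bp]
    net = sum(n for _, n in events)
    offset = events[0][0] - cut_site if events else None
    if net > 0:
        return AlleleCall(seq_id, "insertion", net, offset)
    if net < 0:
        return AlleleCall(seq_id, "deletion", -net, offset)
    return AlleleCall(seq_id, "complex", 0, offset)


def allele_census(calls: Sequence[AlleleCall]) -> CensusResult:
    """Count allele classes and test the wt:mutant split against 1:1.

    ``n_mut`` counts clean indel alleles (insertion/deletion); complex
    calls are ``n_other``.  The two-sided exact binomial p (sum of outcome
    probabilities no larger than the observed count's) is computed for
    n_mut out of n_wt + n_mut against 0.5; p >= 0.05 is reported as
    consistent with a heterozygous mutation.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("need at least one allele call")
    by_class: dict = {}
    for c in calls:
        by_class[c.label] = by_class.get(c.label, 0) + 1
    n_wt = sum(1 for c in calls if c.call == "wt")
    n_mut = sum(1 for c in calls if c.call in ("insertion", "deletion"))
    n_other = len(calls) - n_wt - n_mut
    if n_wt + n_mut == 0:
        p = 1.0
    else:
        p = float(binomtest(n_mut, n_wt + n_mut, 0.5).pvalue)
    verdict = ("consistent with heterozygous" if p >= HET_P_THRESHOLD
               else "not consistent")
    return CensusResult(len(calls), n_wt, n_mut, n_other, p, verdict, by_class)


def _first_stop_from(seq: str, codon_start: int) -> Optional[int]:
    for i in range(codon_start, len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return i
    return None


def find_premature_stop(edited_seq: str, ref_seq: str, cds_frame_offset: int,
                        edit_pos: int) -> StopReport:
    """Locate the first novel in-frame stop codon downstream of an edit.

    Translation is scanned in the frame starting at ``cds_frame_offset``,
    beginning with the codon containing ``edit_pos``.  The stop is novel if
    the reference, scanned from the corresponding codon, does not place its
    first stop at the same distance from the edit site.  Returns the
    distance in bp from the edit site to the start of the stop codon.
    """
    if cds_frame_offset not in (0, 1, 2):
        raise ValueError("cds_frame_offset must be 0, 1 or 2")
    if not (0 <= edit_pos < len(edited_seq)):
        raise ValueError("edit_pos must lie within the sequence")
    edited_seq = edited_seq.upper()
    ref_seq = ref_seq.upper()
    codon_start = edit_pos - ((edit_pos - cds_frame_offset) % 3)
    stop_e = _first_stop_from(edited_seq, max(codon_start, cds_frame_offset))
    if stop_e is None:
        return StopReport(False, None, None)
    ref_start = min(max(codon_start, cds_frame_offset), len(ref_seq) - 1)
    stop_r = _first_stop_from(ref_seq, ref_start)
    dist_e = stop_e - edit_pos
    if stop_r is not None and (stop_r - edit_pos) == dist_e and \
            edited_seq[stop_e:stop_e + 3] == ref_seq[stop_r:stop_r + 3]:
        return StopReport(False, None, None)  # stop pre-exists in reference
    return StopReport(True, max(dist_e, 0), (stop_e - cds_frame_offset) // 3)
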