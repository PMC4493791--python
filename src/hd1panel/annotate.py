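"""Splice, translate and classify alleles.

Classification codes follow the published convention: F functional, R
revertant (6 bp excision footprint with intact reading frame), N
non-functional, Mk carrying a MITE insertion of family k.  "ORF intact"
means no stop codon before the reference terminal stop and a CDS length
congruent to the reference length modulo 3 — both printed loss-of-function
mechanisms (a 1 bp insertion; a MITE-introduced stop codon) reduce to these
two tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .mite import FootprintReport, global_alignment
from .model import AlleleCode, CandidateStatus, GeneModel, InsertionCandidate

_VALID = set("ACGTN")


@dataclass
class OrfReport:
    cds: str
    protein: str
    premature_stop: bool
    stop_position: int | None
    frameshift: bool
    length_aa: int = field(init=False)

    def __post_init__(self) -> None:
        self.length_aa = len(self.protein)

    @property
    def intact(self) -> bool:
        return not self.premature_stop and not self.frameshift


def _ref_to_query_maps(alignment):
    """Boundary maps ref coord -> query coord, sized len(ref)+1.

    ``map_left[r]`` is the query coordinate just before any insertion placed
    at reference boundary r; ``map_right[r]`` the coordinate just after.
    Interval lifting with [map_right[s], map_left[e]) therefore keeps
    insertions strictly inside [s, e) and drops insertions at either boundary.
    """
    tgt, qry = alignment.coordinates
    ref_len = int(tgt[-1])
    map_left = [None] * (ref_len + 1)
    map_right = [None] * (ref_len + 1)

    def set_left(r, q):
        if map_left[r] is None:
            map_left[r] = q

    map_left[0] = 0
    for k in range(1, len(tgt)):
        t0, t1 = int(tgt[k - 1]), int(tgt[k])
        q0, q1 = int(qry[k - 1]), int(qry[k])
        if t1 > t0 and q1 > q0:  # aligned block
            for off in range(1, t1 - t0 + 1):
                set_left(t0 + off, q0 + off)
                map_right[t0 + off] = q0 + off
        elif t1 > t0:  # deletion in query
            for off in range(1, t1 - t0 + 1):
                set_left(t0 + off, q0)
                map_right[t0 + off] = q0
        else:  # insertion in query at boundary t0
            map_right[t0] = q1
    if map_right[0] is None:
        map_right[0] = map_left[0]
    for r in range(ref_len + 1):
        if map_right[r] is None:
            map_right[r] = map_left[r]
    return map_left, map_right


def splice_cds(
    allele_sequence: str, gene_model: GeneModel, alignment=None
) -> str:
    """Lift the reference coding intervals onto the allele and concatenate.

    Insertions inside coding exon portions are retained; intronic and UTR
    insertions are excluded.  Raises when a coding-exon boundary cannot be
    lifted (for example, deleted in the allele).
    """
    if alignment is None:
        alignment = global_alignment(gene_model.reference_sequence, allele_sequence)
    map_left, map_right = _ref_to_query_maps(alignment)
    parts = []
    for idx, (s, e) in enumerate(gene_model.cds_intervals(), start=1):
        qs, qe = map_right[s], map_left[e]
        if qs is None or qe is None or qs > qe:
            raise ValueError(f"exon {idx} boundary unalignable")
        parts.append(allele_sequence[qs:qe])
    return "".join(parts)


def translate(cds: str) -> str:
    """Standard-code translation from position 0; internal stops rendered '*',
    ambiguous (N-containing) codons rendered 'X'."""
    cds = cds.upper()
    bad = set(cds) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN characters in CDS: {sorted(bad)}")
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def orf_report(cds: str, gene_model: GeneModel) -> OrfReport:
    """Translate an allele CDS and test reading-frame integrity against the
    reference gene model."""
    protein = translate(cds)
    ref_cds_len = gene_model.cds_length()
    ref_terminal_codon = ref_cds_len // 3 - 1  # codon index of the reference stop
    stop_position = protein.find("*")
    stop_position = None if stop_position == -1 else stop_position
    premature = stop_position is not None and stop_position < ref_terminal_codon
    frameshift = (len(cds) - ref_cds_len) % 3 != 0
    return OrfReport(
        cds=cds,
        protein=protein,
        premature_stop=premature,
        stop_position=stop_position,
        frameshift=frameshift,
    )


def classify_allele(
    orf: OrfReport,
    mite_hits: list[InsertionCandidate],
    footprint: FootprintReport | None = None,
) -> tuple[AlleleCode, bool]:
    """Assign the allele classification code.

    Decision order: (1) a MITE hit of family k -> code Mk, functional iff
    the ORF is intact (loss-of-function M1 vs harmless intronic/UTR
    insertions such as functional M5); (2) an excision footprint with intact
    ORF -> R; (3) a footprint with a disrupted ORF is not a revertant -> N;
    (4) disrupted ORF -> N; (5) otherwise F.  The result does not depend on
    the listing order of ``mite_hits``.
    """
    mites = sorted(
        (h for h in mite_hits if h.status is CandidateStatus.MITE),
        key=lambda h: (h.reference_position, h.family or ""),
    )
    if mites:
        family = mites[0].family or "MITE?"
        number = "".join(ch for ch in family if ch.isdigit()) or "?"
        try:
            code = AlleleCode(f"M{number}")
        except ValueError:
            code = AlleleCode.N
        return code, orf.intact
    if footprint is not None and footprint.found:
        return (AlleleCode.R, True) if orf.intact else (AlleleCode.N, False)
    if not orf.intact:
        return AlleleCode.N, False
    return AlleleCode.F, True
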