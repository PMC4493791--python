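"""MITE insertion discovery between alleles.

The discovery rule: align a query allele globally against a functional
reference; every insertion gap shorter than 500 bp whose ends carry terminal
inverted repeats (TIRs) and whose flanks carry a target site duplication
(TSD) is a MITE.  Superfamilies follow the terminal-structure criteria:
8 bp TSD with TIR > 5 bp -> hAT; 3 bp TSD with TIR > 4 bp -> PIF/Harbinger.
Elements are grouped into families by sequence identity, and 6 bp excision
footprints (the hallmark of revertant alleles) are detected at known
insertion sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .model import CandidateStatus, InsertionCandidate, MiteElement, Superfamily

#: Alignment scoring: affine gaps with open >> extend so a planted element
#: aligns as one contiguous gap.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -2.0, -10.0, -0.5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def global_alignment(reference: str, query: str) -> Align.Alignment:
    if not reference or not query:
        raise ValueError("cannot align empty sequences")
    return make_aligner().align(reference, query)[0]


# ---------------------------------------------------------------------------
# terminal-structure primitives


def detect_tir(
    inserted_sequence: str, min_len: int = 4, max_mismatch: int = 1
) -> int | None:
    """Longest terminal inverted repeat length, or None below ``min_len``.

    Returns the largest k <= len/2 such that the first k bases equal the
    reverse complement of the last k bases with at most ``max_mismatch``
    mismatches.
    """
    seq = inserted_sequence.upper()
    if len(seq) < 2 * min_len:
        return None
    for k in range(len(seq) // 2, min_len - 1, -1):
        head = seq[:k]
        tail_rc = revcomp(seq[-k:])
        mismatches = sum(a != b for a, b in zip(head, tail_rc))
        if mismatches <= max_mismatch:
            return k
    return None


def detect_tsd(
    left_flank: str, right_flank: str, min_len: int = 2, max_len: int = 12
) -> str | None:
    """Longest exact direct repeat shared by the element's flanks.

    Returns the longest L in [min_len, max_len] such that the last L bases of
    ``left_flank`` equal the first L bases of ``right_flank``; ties break by
    the longest L.
    """
    left = left_flank.upper()
    right = right_flank.upper()
    top = min(max_len, len(left), len(right))
    for L in range(top, min_len - 1, -1):
        if left[-L:] == right[:L]:
            return left[-L:]
    return None


def classify_superfamily(tsd_length: int, tir_length: int) -> Superfamily:
    """Superfamily from terminal structure: (8, >5) hAT; (3, >4) PIF/Harbinger."""
    if tsd_length == 8 and tir_length > 5:
        return Superfamily.HAT
    if tsd_length == 3 and tir_length > 4:
        return Superfamily.PIF_HARBINGER
    return Superfamily.UNCLASSIFIED


# ---------------------------------------------------------------------------
# insertion scanning


@dataclass
class ScanConfig:
    max_mite_len: int = 500  # strict: < 500 bp
    tsd_min: int = 2
    tsd_max: int = 12
    tir_min: int = 4
    tir_max_mismatch: int = 1


def _raw_insertions(reference: str, query: str) -> list[tuple[int, int, int]]:
    """Maximal query-only runs as (ref_pos, q_start, q_end)."""
    alignment = global_alignment(reference, query)
    tgt, qry = alignment.coordinates
    runs = []
    for k in range(1, len(tgt)):
        if tgt[k] == tgt[k - 1] and qry[k] > qry[k - 1]:
            runs.append((int(tgt[k]), int(qry[k - 1]), int(qry[k])))
    return runs


def _placements(reference: str, query: str, ref_pos: int, q_start: int, q_end: int):
    """Equivalent gap placements (rotation ambiguity) as (ref_pos, q_start)."""
    placements = [(ref_pos, q_start)]
    p, s = ref_pos, q_start
    while p > 0 and s > 0 and reference[p - 1] == query[s + (q_end - q_start) - 1]:
        # shift left: the base before the gap slides into it
        p -= 1
        s -= 1
        placements.append((p, s))
        q_end -= 1
        q_start -= 1
    p, s = ref_pos, q_start
    e = q_end
    while (
        p < len(reference)
        and e < len(query)
        and reference[p] == query[s]
    ):
        p += 1
        s += 1
        e += 1
        placements.append((p, s))
    return placements


def scan_insertions(
    reference: str,
    query: str,
    query_allele_id: str = "query",
    config: ScanConfig | None = None,
) -> list[InsertionCandidate]:
    """Discover insertion candidates in ``query`` relative to ``reference``.

    Each maximal insertion gap becomes one candidate.  Gaps of length
    >= 500 bp are plain insertions by rule; shorter gaps are called MITEs
    when a TSD (exact, 2-12 bp) and a TIR (>= 4 bp, one mismatch tolerated)
    are found; 6 bp gaps without MITE structure are possible excision
    footprints.  Gap placement is ambiguous when flank and element termini
    share bases, so every equivalent placement is examined and the reading
    maximising (TIR length, TSD length) wins; the placement interval is kept
    on the candidate for site comparisons.
    """
    cfg = config or ScanConfig()
    out: list[InsertionCandidate] = []
    for ref_pos, q_start, q_end in _raw_insertions(reference, query):
        length = q_end - q_start
        placements = _placements(reference, query, ref_pos, q_start, q_end)
        pmin = min(p for p, _ in placements)
        pmax = max(p for p, _ in placements)
        leftmost_q = min(s for _, s in placements)
        leftmost_ins = query[leftmost_q : leftmost_q + length]
        # On diverged queries the aligner's optimal gap placement can sit a
        # few bases away from the biological insertion point (flank
        # substitutions shift the match-maximising placement), so terminal
        # structure is read over a window around the equivalent placements.
        seen = {p for p, _ in placements}
        for p in range(max(pmin - cfg.tsd_max, 0), min(pmax + cfg.tsd_max, len(reference)) + 1):
            s = q_start + (p - ref_pos)
            if p not in seen and 0 <= s and s + length <= len(query):
                placements.append((p, s))

        # Gap placement is ambiguous, so several (placement, TSD) readings of
        # the same gap can show terminal structure: shifting the element
        # window by one flank base trades TSD length against TIR length in
        # either direction, and such alternative parses can be structurally
        # genuine.  Readings are ranked by (1) whether (TSD, TIR) satisfies a
        # known superfamily criterion — the prior an annotator applies —
        # then (2) combined exact evidence 2*TIR + TSD, then exact TIR.
        best = None
        if length < cfg.max_mite_len:
            for p, s in placements:
                ins = query[s : s + length]
                left_q = query[:s]
                right_q = query[s + length :]
                for t in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
                    if t >= length:
                        continue
                    readings = []
                    if ins[:t] == right_q[:t]:
                        readings.append((ins[t:], ins[:t], p + t))
                    if ins[-t:] == left_q[-t:]:
                        readings.append((ins[:-t], ins[-t:], p))
                    for element, tsd, elem_pos in readings:
                        tir = detect_tir(element, cfg.tir_min, cfg.tir_max_mismatch)
                        if tir is None:
                            continue
                        exact = detect_tir(element, 2, 0) or 0
                        conforming = (
                            classify_superfamily(t, tir)
                            is not Superfamily.UNCLASSIFIED
                        )
                        cand = (
                            (int(conforming), 2 * exact + t, exact, t),
                            tir, element, tsd, elem_pos,
                        )
                        if best is None or cand[0] > best[0]:
                            best = cand
        if best is not None:
            _score, tir, element, tsd, elem_pos = best
            out.append(
                InsertionCandidate(
                    query_allele_id=query_allele_id,
                    reference_position=elem_pos,
                    length=length,
                    inserted_sequence=leftmost_ins,
                    status=CandidateStatus.MITE,
                    tir_length=tir,
                    tsd_sequence=tsd,
                    element_sequence=element,
                    placement_range=(min(pmin, elem_pos), max(pmax, elem_pos)),
                    query_start=leftmost_q,
                )
            )
        else:
            status = (
                CandidateStatus.FOOTPRINT
                if length == 6
                else CandidateStatus.PLAIN_INSERTION
            )
            out.append(
                InsertionCandidate(
                    query_allele_id=query_allele_id,
                    reference_position=pmin,
                    length=length,
                    inserted_sequence=leftmost_ins,
                    status=status,
                    placement_range=(pmin, pmax),
                    query_start=leftmost_q,
                )
            )
    out.sort(key=lambda c: c.reference_position)
    return out


# ---------------------------------------------------------------------------
# family clustering


def _ungapped_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def cluster_families(
    elements: list[str], identity_threshold: float = 0.8
) -> list[str]:
    """Single-linkage family grouping of element sequences.

    Returns a family name per input element; families are numbered MITE1,
    MITE2, ... by order of first appearance in the input.
    """
    if not elements:
        raise ValueError("no elements to cluster")
    n = len(elements)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _ungapped_identity(elements[i], elements[j]) >= identity_threshold:
                parent[find(j)] = find(i)

    names: dict[int, str] = {}
    out = []
    for i in range(n):
        r = find(i)
        if r not in names:
            names[r] = f"MITE{len(names) + 1}"
        out.append(names[r])
    return out


def build_family_elements(
    candidates: list[InsertionCandidate], identity_threshold: float = 0.8
) -> dict[str, MiteElement]:
    """Cluster MITE candidates into named families and annotate them in place."""
    mites = [c for c in candidates if c.status is CandidateStatus.MITE]
    if not mites:
        return {}
    fams = cluster_families(
        [c.element_sequence or "" for c in mites], identity_threshold
    )
    families: dict[str, MiteElement] = {}
    for cand, fam in zip(mites, fams):
        cand.family = fam
        if fam not in families:
            families[fam] = MiteElement(
                family_name=fam,
                superfamily=classify_superfamily(
                    len(cand.tsd_sequence or ""), cand.tir_length or 0
                ),
                consensus=cand.element_sequence or "",
                tsd_length=len(cand.tsd_sequence or ""),
                tir_length=cand.tir_length or 0,
            )
    return families


# ---------------------------------------------------------------------------
# excision footprints


@dataclass
class FootprintReport:
    found: bool
    hexamer: str | None = None
    position: int | None = None


def detect_footprint(
    reference_functional: str, query: str, known_site: int, tolerance: int = 8
) -> FootprintReport:
    """Report whether ``query`` carries exactly a 6 bp insertion at the known
    (historical) element insertion site relative to the functional reference.

    Placement ambiguity is honoured: the footprint matches when the known
    site falls inside the candidate's equivalent-placement interval, widened
    by ``tolerance`` bases because substitutions adjacent to the site shift
    the optimal gap placement by a few columns.
    """
    if not 0 <= known_site <= len(reference_functional):
        raise ValueError("known_site outside the reference")
    for cand in scan_insertions(reference_functional, query):
        if cand.length != 6 or cand.status is CandidateStatus.MITE:
            continue
        lo, hi = cand.placement_range or (
            cand.reference_position,
            cand.reference_position,
        )
        if lo - tolerance <= known_site <= hi + tolerance:
            # read the hexamer at the placement matching the known site, so
            # rotation of the leftmost-normalised gap does not scramble it
            shift = min(max(known_site, lo), hi) - lo
            hexamer = cand.inserted_sequence
            if cand.query_start is not None:
                hexamer = query[cand.query_start + shift : cand.query_start + shift + 6]
            return FootprintReport(
                found=True,
                hexamer=hexamer,
                position=cand.reference_position,
            )
    return FootprintReport(found=False)
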