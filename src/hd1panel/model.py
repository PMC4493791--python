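"""Domain types shared by every stage of the Hd1 allele-panel analysis.

The analysis revolves around a small set of objects: accession metadata
(provenance, heading dates), a reference gene model (two exons, one intron,
a ~400 aa coding sequence), per-allele records carrying a locus assignment
and a functional classification code, and discovered transposable-element
insertions (MITEs) with their terminal structures.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field


class Region(str, enum.Enum):
    """Broad geographic grouping used in the regional contrasts."""

    JAPAN = "japan"
    MAINLAND = "mainland"
    OTHER = "other"


#: Countries mapped to regions: the Japanese archipelago vs the Asian mainland
#: (China and the Korean peninsula).
_REGION_BY_COUNTRY = {
    "japan": Region.JAPAN,
    "china": Region.MAINLAND,
    "korea": Region.MAINLAND,
    "south korea": Region.MAINLAND,
}


def region_from_country(country: str) -> Region:
    return _REGION_BY_COUNTRY.get(country.strip().lower(), Region.OTHER)


class Locus(str, enum.Enum):
    HD1A = "Hd1a"
    HD1B = "Hd1b"
    UNASSIGNED = "unassigned"


class AlleleCode(str, enum.Enum):
    """Allele classification codes.

    F functional, R revertant (excision footprint with restored frame),
    N non-functional, M1-M5 MITE-insertion alleles (family-numbered).
    """

    F = "F"
    R = "R"
    N = "N"
    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"
    M5 = "M5"

    @property
    def mite_family(self) -> int | None:
        return int(self.value[1:]) if self.value.startswith("M") else None


class _DidNotHead:
    """Sentinel for accessions that never headed in a given season."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "DID_NOT_HEAD"


DID_NOT_HEAD = _DidNotHead()

#: A heading observation: a calendar date, missing (None), or DID_NOT_HEAD.
HeadingValue = _dt.date | None | _DidNotHead


@dataclass
class AccessionMeta:
    accession_id: str
    species: str
    country: str
    region: Region
    latitude: float | None
    longitude: float | None
    heading_date_by_year: dict[int, HeadingValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"latitude {self.latitude} outside [-90, 90] for {self.accession_id}"
            )
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(
                f"longitude {self.longitude} outside [-180, 180] for {self.accession_id}"
            )


_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneModel:
    """Reference coordinate frame for the Hd1 homologue.

    ``exons`` are 0-based half-open intervals on ``reference_sequence``
    (single + strand); ``coding_start`` is the ATG offset within the spliced
    transcript; ``polya_offset`` is the polyadenylation site, in bases
    downstream of the stop codon.
    """

    reference_sequence: str
    exons: tuple[tuple[int, int], ...]
    coding_start: int
    polya_offset: int = 159

    def __post_init__(self) -> None:
        self.reference_sequence = self.reference_sequence.upper()
        prev_end = -1
        for s, e in self.exons:
            if not 0 <= s < e <= len(self.reference_sequence):
                raise ValueError(f"exon interval ({s}, {e}) out of bounds")
            if s <= prev_end:
                raise ValueError("exons must be non-overlapping and ascending")
            prev_end = e
        if len(self.cds()) % 3 != 0:
            raise ValueError("spliced coding length must be divisible by 3")

    def spliced(self) -> str:
        """Concatenated exonic sequence (the transcript, + strand)."""
        return "".join(self.reference_sequence[s:e] for s, e in self.exons)

    def cds_length(self) -> int:
        """Length of the coding sequence including the terminal stop codon."""
        tx = self.spliced()
        for i in range(self.coding_start, len(tx) - 2, 3):
            if tx[i : i + 3] in _STOP_CODONS:
                return i + 3 - self.coding_start
        raise ValueError("no in-frame stop codon downstream of coding_start")

    def cds(self) -> str:
        tx = self.spliced()
        return tx[self.coding_start : self.coding_start + self.cds_length()]

    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Genomic (reference) intervals of the coding portion of each exon."""
        start_tx = self.coding_start
        end_tx = self.coding_start + self.cds_length()
        out = []
        offset = 0
        for s, e in self.exons:
            exon_len = e - s
            lo = max(start_tx, offset)
            hi = min(end_tx, offset + exon_len)
            if lo < hi:
                out.append((s + lo - offset, s + hi - offset))
            offset += exon_len
        return tuple(out)


@dataclass
class AlleleRecord:
    """One cloned allele: sequence (may be empty for code-only records),
    locus assignment, and functional classification."""

    allele_id: str
    accession_id: str
    sequence: str = ""
    locus: Locus = Locus.UNASSIGNED
    code: AlleleCode | None = None
    functional: bool | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        has_lof_note = "footprint+LOF" in self.notes
        if self.code in (AlleleCode.F, AlleleCode.R) and has_lof_note:
            raise ValueError(
                f"{self.allele_id}: a footprint+LOF allele must carry code N"
            )
        if self.code in (AlleleCode.F, AlleleCode.R) and self.functional is False:
            raise ValueError(f"{self.allele_id}: code {self.code.value} implies functional")
        if self.code is AlleleCode.M1 and self.functional:
            raise ValueError(f"{self.allele_id}: code M1 implies non-functional")


@dataclass
class PanelTable:
    """An allele panel: accession metadata plus per-allele calls."""

    accessions: list[AccessionMeta]
    calls: list[AlleleRecord]

    def __post_init__(self) -> None:
        ids = [a.accession_id for a in self.accessions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate accession ids")
        known = set(ids)
        for call in self.calls:
            if call.accession_id not in known:
                raise ValueError(
                    f"allele {call.allele_id} references unknown accession "
                    f"{call.accession_id}"
                )

    def accession(self, accession_id: str) -> AccessionMeta:
        for a in self.accessions:
            if a.accession_id == accession_id:
                return a
        raise KeyError(accession_id)

    def calls_for(self, accession_id: str) -> list[AlleleRecord]:
        return [c for c in self.calls if c.accession_id == accession_id]


class CandidateStatus(str, enum.Enum):
    MITE = "mite"
    PLAIN_INSERTION = "plain_insertion"
    FOOTPRINT = "footprint"


class Superfamily(str, enum.Enum):
    HAT = "hAT"
    PIF_HARBINGER = "PIF_Harbinger"
    UNCLASSIFIED = "unclassified"


@dataclass
class InsertionCandidate:
    """A query-only insertion relative to the reference.

    ``reference_position`` is the 0-based reference offset where the inserted
    material begins (for MITE-status candidates: where the *element* begins,
    i.e. after the 5' TSD copy).  ``placement_range`` is the closed interval of
    reference offsets over which the insertion can be placed equivalently
    (gap-placement ambiguity); site comparisons should use it.
    """

    query_allele_id: str
    reference_position: int
    length: int
    inserted_sequence: str
    status: CandidateStatus
    tir_length: int | None = None
    tsd_sequence: str | None = None
    element_sequence: str | None = None
    family: str | None = None
    placement_range: tuple[int, int] | None = None
    #: query offset of the inserted run at the leftmost equivalent placement
    query_start: int | None = None

    def __post_init__(self) -> None:
        if self.status is CandidateStatus.MITE:
            if self.length >= 500:
                raise ValueError("MITE status requires insertion length < 500")
            if self.tir_length is None or self.tir_length < 4:
                raise ValueError("MITE status requires tir_length >= 4")
            if not self.tsd_sequence:
                raise ValueError("MITE status requires a TSD")
        if self.status is CandidateStatus.FOOTPRINT and self.length != 6:
            raise ValueError("footprint status requires length == 6")


@dataclass
class MiteElement:
    """A MITE family representative: consensus interior plus terminal structure."""

    family_name: str
    superfamily: Superfamily
    consensus: str
    tsd_length: int
    tir_length: int
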