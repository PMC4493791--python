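"""Synthetic allele-panel generator with ground truth.

Emulates the evolutionary scenario the analysis assumes: a ~2.2 kb
flowering-time gene (two exons, one intron, ~400 aa product) duplicated into
two diverged loci.  The second locus is pseudogenized by a shared 1 bp exonic
insertion plus a MITE in its 5' UTR.  Alleles of the functional locus carry
region-dependent events: a loss-of-function MITE insertion in exon 1
(Japanese accessions), a 6 bp excision footprint restoring the frame
(revertants, typical of mainland accessions), independent 1 bp frameshifts,
or a harmless intronic MITE.  Heading dates follow a latitudinal cline.

Every planted event is recorded in a truth table so downstream discovery and
classification can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .model import (
    AccessionMeta,
    AlleleCode,
    AlleleRecord,
    GeneModel,
    Locus,
    PanelTable,
    Region,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_TRANSITION = str.maketrans("AGCT", "GATC")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: In-frame footprint of a proline + aspartate codon pair; when inserted at a
#: codon boundary the protein gains exactly P and D.
FOOTPRINT_PD = "CCAGAT"


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class HeadingModel:
    """Linear latitudinal cline for heading day-of-year (northern accessions
    head earlier when grown in a common garden)."""

    intercept: float = 430.0  # day-of-year at latitude 0
    slope: float = -5.2  # days per degree latitude
    noise_sd: float = 12.0  # between-year / residual spread, days


@dataclass
class PanelConfig:
    seed: int = 0
    n_accessions_per_region: dict[Region, int] = field(
        default_factory=lambda: {Region.JAPAN: 23, Region.MAINLAND: 17}
    )
    protein_length: int = 400
    intron_length: int = 600
    utr5_length: int = 150
    utr3_length: int = 200
    substitution_rate: float = 0.005  # expected substitutions/site per allele lineage
    ts_tv_ratio: float = 2.0
    locus_divergence: float = 0.08  # between the Hd1a and Hd1b ancestors
    outgroup_divergence: float = 0.15
    # per-region event probabilities for alleles of the functional locus;
    # defaults mirror the published panel's proportions
    p_m1_insertion: dict[Region, float] = field(
        default_factory=lambda: {Region.JAPAN: 0.25, Region.MAINLAND: 0.0}
    )
    p_footprint: dict[Region, float] = field(
        default_factory=lambda: {Region.JAPAN: 0.03, Region.MAINLAND: 0.37}
    )
    p_frameshift: dict[Region, float] = field(
        default_factory=lambda: {Region.JAPAN: 0.22, Region.MAINLAND: 0.0}
    )
    p_m5_insertion: dict[Region, float] = field(
        default_factory=lambda: {Region.JAPAN: 0.0, Region.MAINLAND: 0.04}
    )
    p_hd1b: dict[Region, float] = field(
        default_factory=lambda: {Region.JAPAN: 0.35, Region.MAINLAND: 0.5}
    )
    alleles_per_accession_range: tuple[int, int] = (2, 5)
    heading_model: HeadingModel = field(default_factory=HeadingModel)
    latitude_range: dict[Region, tuple[float, float]] = field(
        default_factory=lambda: {
            Region.JAPAN: (26.0, 44.0),
            Region.MAINLAND: (19.0, 42.0),
        }
    )

    def validate(self) -> None:
        for name in ("p_m1_insertion", "p_footprint", "p_frameshift",
                     "p_m5_insertion", "p_hd1b"):
            for region, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{region.value}]={p} outside [0, 1]")
        lo, hi = self.alleles_per_accession_range
        if not 2 <= lo <= hi <= 5:
            raise ValueError("alleles_per_accession_range must lie within [2, 5]")
        if self.protein_length < 50:
            raise ValueError("protein_length must be >= 50")
        if self.intron_length < 10:
            raise ValueError("intron_length too short for canonical splice sites")
        if self.utr3_length < 165:
            raise ValueError("utr3_length must contain the polyA site (159 bp)")

    def event_prob(self, name: str, region: Region) -> float:
        return getattr(self, name).get(region, 0.0)

    _REGION_KEYED = (
        "n_accessions_per_region", "p_m1_insertion", "p_footprint",
        "p_frameshift", "p_m5_insertion", "p_hd1b", "latitude_range",
    )

    @classmethod
    def from_dict(cls, spec: dict) -> "PanelConfig":
        """Build a config from plain (e.g. JSON-loaded) data: region-keyed
        dicts may use region names, heading_model may be a mapping."""
        spec = dict(spec)
        for name in cls._REGION_KEYED:
            if name in spec:
                spec[name] = {
                    (k if isinstance(k, Region) else Region(k)): v
                    for k, v in spec[name].items()
                }
        if "latitude_range" in spec:
            spec["latitude_range"] = {
                k: tuple(v) for k, v in spec["latitude_range"].items()
            }
        if "alleles_per_accession_range" in spec:
            spec["alleles_per_accession_range"] = tuple(
                spec["alleles_per_accession_range"]
            )
        hm = spec.get("heading_model")
        if isinstance(hm, dict):
            spec["heading_model"] = HeadingModel(**hm)
        return cls(**spec)


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class PlantedEvent:
    kind: str  # mite_insertion | footprint | frameshift_1bp | substitution
    position: int  # reference (ancestor-frame) offset
    element_name: str | None = None
    tir_length: int | None = None
    tsd_sequence: str | None = None
    length: int | None = None


@dataclass
class AlleleTruth:
    allele_id: str
    accession_id: str
    region: Region
    locus: Locus
    expected_code: AlleleCode
    functional: bool
    events: list[PlantedEvent] = field(default_factory=list)


@dataclass
class PanelTruth:
    alleles: dict[str, AlleleTruth] = field(default_factory=dict)
    sites: dict[str, int] = field(default_factory=dict)  # named event sites
    family_elements: dict[str, str] = field(default_factory=dict)  # name -> sequence


@dataclass
class PlantedInsertion:
    """Where and what was inserted (element coordinates on the host sequence)."""

    site: int  # host offset of the element start
    element: str
    tsd_len: int
    tir_len: int
    family_name: str


@dataclass
class SimulatedPanel:
    gene_model: GeneModel
    alleles: list[tuple[str, str]]
    outgroup: tuple[str, str]
    panel: PanelTable
    truth: PanelTruth


# ---------------------------------------------------------------------------
# sequence primitives


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_k2p(
    seq: str, rate: float, ts_tv_ratio: float, rng: np.random.Generator
) -> str:
    """Apply a Kimura two-parameter substitution process.

    ``rate`` is the expected number of substitutions per site along the
    lineage; the per-site transition/transversion outcome probabilities are
    the exact K2P transition probabilities at that divergence, so the K2P
    distance estimator is consistent for ``rate``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return seq
    R = ts_tv_ratio
    alpha_t = rate * R / (R + 1.0)
    beta_t = rate / (2.0 * (R + 1.0))
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    p_tv = 0.5 - 0.5 * np.exp(-4.0 * beta_t)
    u = rng.random(len(seq))
    pick = rng.integers(0, 2, size=len(seq))  # which transversion target
    out = list(seq)
    tv_map = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    for i, base in enumerate(seq):
        if u[i] < p_ts:
            out[i] = base.translate(_TRANSITION)
        elif u[i] < p_ts + p_tv:
            out[i] = tv_map[base][pick[i]]
    return "".join(out)


def _cds_positions(model: GeneModel) -> list[int]:
    return [p for s, e in model.cds_intervals() for p in range(s, e)]


def mutate_functional(
    seq: str,
    model: GeneModel,
    rate: float,
    ts_tv_ratio: float,
    rng: np.random.Generator,
) -> str:
    """K2P substitutions under purifying selection on the reading frame:
    substitutions that create a premature in-frame stop codon, or destroy the
    terminal stop, are reverted (functional-lineage alleles stay translatable,
    as the classification assumes)."""
    mutated = list(mutate_k2p(seq, rate, ts_tv_ratio, rng))
    pos = _cds_positions(model)
    n_codons = len(pos) // 3
    for c in range(n_codons):
        idx = pos[3 * c : 3 * c + 3]
        codon = "".join(mutated[i] for i in idx)
        original = "".join(seq[i] for i in idx)
        is_terminal = c == n_codons - 1
        if (codon in _STOPS) != is_terminal and original != codon:
            for i in idx:
                mutated[i] = seq[i]
    return "".join(mutated)


def make_element(
    rng: np.random.Generator, tir_len: int, element_length: int
) -> str:
    """A MITE-like element: exact reverse-complement TIRs around a random core."""
    if element_length < 2 * tir_len:
        raise ValueError("element shorter than its two TIRs")
    tir = _random_seq(rng, tir_len)
    core = _random_seq(rng, element_length - 2 * tir_len)
    return tir + core + _revcomp(tir)


def plant_mite(
    sequence: str,
    site: int,
    tsd_len: int,
    tir_len: int,
    element_length: int,
    seed: int | None = None,
    element: str | None = None,
    family_name: str = "MITE",
) -> tuple[str, PlantedInsertion]:
    """Insert a MITE at ``site``, duplicating the ``tsd_len`` bases to its left
    immediately after the element (total inserted length =
    element_length + tsd_len)."""
    if element_length <= 0:
        raise ValueError("element_length must be positive")
    if not 0 <= site <= len(sequence):
        raise ValueError("site outside the sequence")
    if site < tsd_len:
        raise ValueError("site within tsd_len of the sequence start")
    if element is None:
        element = make_element(np.random.default_rng(seed), tir_len, element_length)
    if len(element) != element_length:
        raise ValueError("element sequence does not match element_length")
    tsd = sequence[site - tsd_len : site]
    new_seq = sequence[:site] + element + tsd + sequence[site:]
    return new_seq, PlantedInsertion(
        site=site,
        element=element,
        tsd_len=tsd_len,
        tir_len=tir_len,
        family_name=family_name,
    )


def excise_to_footprint(
    sequence_with_element: str,
    insertion: PlantedInsertion,
    footprint: str = FOOTPRINT_PD,
) -> str:
    """Remove a planted element (and its TSD copy), leaving a 6 bp footprint."""
    if len(footprint) != 6:
        raise ValueError("footprint must be exactly 6 bp")
    site = insertion.site
    span = len(insertion.element) + insertion.tsd_len
    expected = insertion.element + sequence_with_element[site - insertion.tsd_len : site]
    if sequence_with_element[site : site + span] != expected:
        raise ValueError("element not found at the recorded site")
    return (
        sequence_with_element[:site]
        + footprint
        + sequence_with_element[site + span :]
    )


# ---------------------------------------------------------------------------
# reference and locus construction


def build_reference(config: PanelConfig, rng: np.random.Generator | None = None) -> GeneModel:
    """Random two-exon gene model: UTR5 + exon1(part of CDS) + intron (GT..AG)
    + exon2 (rest of CDS + UTR3); single clean ORF of ``protein_length``."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    aa = config.protein_length
    codon_idx = rng.integers(0, len(_NONSTOP_CODONS), size=aa - 1)
    cds = "ATG" + "".join(_NONSTOP_CODONS[i] for i in codon_idx) + "TGA"
    assert len(cds) == 3 * (aa + 1)
    utr5 = _random_seq(rng, config.utr5_length)
    utr3 = _random_seq(rng, config.utr3_length)
    intron = "GT" + _random_seq(rng, config.intron_length - 4) + "AG"
    split = (len(cds) // 2) // 3 * 3  # codon boundary near the CDS midpoint
    exon1_end = config.utr5_length + split
    exon2_start = exon1_end + config.intron_length
    reference = utr5 + cds[:split] + intron + cds[split:] + utr3
    model = GeneModel(
        reference_sequence=reference,
        exons=((0, exon1_end), (exon2_start, len(reference))),
        coding_start=config.utr5_length,
        polya_offset=159,
    )
    assert model.cds() == cds
    return model


def _event_sites(config: PanelConfig, model: GeneModel) -> dict[str, int]:
    """Named reference offsets for planted events (all in exon 1 CDS, the
    intron, or the 5' UTR)."""
    u5 = config.utr5_length
    exon1_end = model.exons[0][1]
    m1 = u5 + 150  # codon boundary inside exon 1 coding sequence
    fs_extra = u5 + 211  # independent 1 bp frameshift site (exon 1)
    m5 = exon1_end + config.intron_length // 2  # intron interior
    m2 = 60  # 5' UTR (pseudogene lineage)
    fs_b = u5 + 90  # the shared pseudogenizing 1 bp insertion
    assert m1 < exon1_end and fs_extra < exon1_end and fs_b < exon1_end
    return {"m1": m1, "fs_extra": fs_extra, "m5": m5, "m2": m2, "fs_b": fs_b}


#: Canonical family terminal structures: (tsd_len, tir_len, element_length).
#: MITE1/MITE5 are hAT-like (8 bp TSD), MITE2 is PIF/Harbinger-like (3 bp TSD).
FAMILY_STRUCTURE = {
    "MITE1": (8, 10, 180),
    "MITE2": (3, 12, 250),
    "MITE5": (8, 12, 120),
}


def _family_elements(rng: np.random.Generator) -> dict[str, str]:
    return {
        name: make_element(rng, tir, length)
        for name, (tsd, tir, length) in FAMILY_STRUCTURE.items()
    }


def make_locus_b(
    ancestor: GeneModel,
    config: PanelConfig,
    rng: np.random.Generator | None = None,
    events: bool = True,
    family_elements: dict[str, str] | None = None,
) -> tuple[str, list[PlantedEvent]]:
    """The pseudogene-lineage sequence: the ancestor diverged by
    ``locus_divergence`` carrying (when ``events``) a 5'-UTR MITE2 insertion
    and the shared 1 bp exonic insertion that creates a premature stop."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if family_elements is None:
        family_elements = _family_elements(np.random.default_rng(config.seed + 2))
    seq = mutate_k2p(
        ancestor.reference_sequence, config.locus_divergence, config.ts_tv_ratio, rng
    )
    planted: list[PlantedEvent] = []
    if events:
        seq, planted = _plant_hd1b_events(seq, config, ancestor, family_elements)
    return seq, planted


def _plant_hd1b_events(
    seq: str, config: PanelConfig, model: GeneModel, family_elements: dict[str, str]
) -> tuple[str, list[PlantedEvent]]:
    sites = _event_sites(config, model)
    tsd, tir, length = FAMILY_STRUCTURE["MITE2"]
    # plant the higher-coordinate event first so recorded offsets stay in the
    # ancestor frame
    seq = seq[: sites["fs_b"]] + "A" + seq[sites["fs_b"] :]
    seq, _ = plant_mite(
        seq, sites["m2"], tsd, tir, length,
        element=family_elements["MITE2"], family_name="MITE2",
    )
    return seq, [
        PlantedEvent(kind="frameshift_1bp", position=sites["fs_b"], length=1),
        PlantedEvent(
            kind="mite_insertion", position=sites["m2"], element_name="MITE2",
            tir_length=tir, tsd_sequence=seq[sites["m2"] - tsd : sites["m2"]],
            length=length,
        ),
    ]


# ---------------------------------------------------------------------------
# panel simulation


def _doy_to_date(doy: float, year: int) -> date:
    d = int(round(doy))
    d = max(1, min(d, 365))
    return date(year, 1, 1) + timedelta(days=d - 1)


def simulate_panel(config: PanelConfig) -> SimulatedPanel:
    """Simulate a full allele panel with truth labels.

    One seeded random stream is consumed in a fixed, documented order:
    family elements, reference, pseudogene lineage, outgroup, then accessions
    region by region in creation order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    family_elements = _family_elements(rng)
    # the constructed reference is the duplication-point ancestor: the two
    # locus ancestors each diverge by half the locus distance, and the
    # outgroup diverges from the same point (the duplication postdates the
    # split from the outgroup lineage), so the true tree has an internal
    # edge separating the two locus clades with the outgroup between them
    model = build_reference(config, rng)
    ref = model.reference_sequence
    sites = _event_sites(config, model)
    half = config.locus_divergence / 2.0
    hd1a_ancestor = mutate_functional(ref, model, half, config.ts_tv_ratio, rng)
    locus_b_base = mutate_k2p(ref, half, config.ts_tv_ratio, rng)
    outgroup_seq = mutate_functional(
        ref, model, config.outgroup_divergence, config.ts_tv_ratio, rng
    )

    truth = PanelTruth(sites=dict(sites), family_elements=dict(family_elements))
    accessions: list[AccessionMeta] = []
    calls: list[AlleleRecord] = []
    fasta: list[tuple[str, str]] = []

    prefix = {Region.JAPAN: "JPN", Region.MAINLAND: "MLD", Region.OTHER: "OTH"}
    lon_range = {Region.JAPAN: (127.0, 145.0), Region.MAINLAND: (105.0, 129.0),
                 Region.OTHER: (100.0, 150.0)}
    hm = config.heading_model
    lo_alleles, hi_alleles = config.alleles_per_accession_range

    for region, n_acc in config.n_accessions_per_region.items():
        lat_lo, lat_hi = config.latitude_range.get(region, (20.0, 45.0))
        for i in range(n_acc):
            acc_id = f"{prefix[region]}{i + 1:03d}"
            lat = float(rng.uniform(lat_lo, lat_hi))
            lon = float(rng.uniform(*lon_range[region]))
            mean_doy = hm.intercept + hm.slope * lat
            heading = {
                year: _doy_to_date(mean_doy + rng.normal(0.0, hm.noise_sd), year)
                for year in (2012, 2014)
            }
            accessions.append(
                AccessionMeta(
                    accession_id=acc_id,
                    species="M. sinensis",
                    country={"japan": "Japan", "mainland": "China"}[region.value]
                    if region is not Region.OTHER else "Other",
                    region=region,
                    latitude=lat,
                    longitude=lon,
                    heading_date_by_year=heading,
                )
            )
            n_total = int(rng.integers(lo_alleles, hi_alleles + 1))
            has_b = rng.random() < config.event_prob("p_hd1b", region)
            n_a = n_total - (1 if has_b else 0)
            for k in range(n_a):
                allele_id = f"{acc_id}_a{k + 1}"
                seq, at = _simulate_hd1a_allele(
                    allele_id, acc_id, region, hd1a_ancestor, model, sites,
                    family_elements, config, rng,
                )
                truth.alleles[allele_id] = at
                fasta.append((allele_id, seq))
                calls.append(
                    AlleleRecord(
                        allele_id=allele_id, accession_id=acc_id, sequence=seq,
                        locus=Locus.HD1A, code=at.expected_code,
                        functional=at.functional,
                        notes=["footprint+LOF"]
                        if at.expected_code is AlleleCode.N
                        and any(e.kind == "footprint" for e in at.events)
                        else [],
                    )
                )
            if has_b:
                allele_id = f"{acc_id}_b1"
                base = mutate_k2p(
                    locus_b_base, config.substitution_rate, config.ts_tv_ratio, rng
                )
                seq, events = _plant_hd1b_events(base, config, model, family_elements)
                at = AlleleTruth(
                    allele_id=allele_id, accession_id=acc_id, region=region,
                    locus=Locus.HD1B, expected_code=AlleleCode.M2,
                    functional=False, events=events,
                )
                truth.alleles[allele_id] = at
                fasta.append((allele_id, seq))
                calls.append(
                    AlleleRecord(
                        allele_id=allele_id, accession_id=acc_id, sequence=seq,
                        locus=Locus.HD1B, code=AlleleCode.M2, functional=False,
                    )
                )

    panel = PanelTable(accessions=accessions, calls=calls)
    return SimulatedPanel(
        gene_model=model,
        alleles=fasta,
        outgroup=("Sorghum_outgroup", outgroup_seq),
        panel=panel,
        truth=truth,
    )


def _simulate_hd1a_allele(
    allele_id: str,
    acc_id: str,
    region: Region,
    ancestor_seq: str,
    model: GeneModel,
    sites: dict[str, int],
    family_elements: dict[str, str],
    config: PanelConfig,
    rng: np.random.Generator,
) -> tuple[str, AlleleTruth]:
    seq = mutate_functional(
        ancestor_seq, model, config.substitution_rate, config.ts_tv_ratio, rng,
    )
    p_m1 = config.event_prob("p_m1_insertion", region)
    p_fp = config.event_prob("p_footprint", region)
    p_fs = config.event_prob("p_frameshift", region)
    p_m5 = config.event_prob("p_m5_insertion", region)
    u = rng.random()
    events: list[PlantedEvent] = []
    code, functional = AlleleCode.F, True

    if u < p_m1:
        tsd, tir, length = FAMILY_STRUCTURE["MITE1"]
        seq, _ = plant_mite(
            seq, sites["m1"], tsd, tir, length,
            element=family_elements["MITE1"], family_name="MITE1",
        )
        events.append(
            PlantedEvent(
                kind="mite_insertion", position=sites["m1"], element_name="MITE1",
                tir_length=tir, tsd_sequence=seq[sites["m1"] - tsd : sites["m1"]],
                length=length,
            )
        )
        code, functional = AlleleCode.M1, False
    elif u < p_m1 + p_fp:
        # a revertant: excision footprint at the MITE1 site; occasionally with
        # an additional independent loss-of-function mutation
        extra_lof = rng.random() < p_fs
        if extra_lof:
            seq = seq[: sites["fs_extra"]] + "A" + seq[sites["fs_extra"] :]
            events.append(
                PlantedEvent(kind="frameshift_1bp", position=sites["fs_extra"], length=1)
            )
        seq = seq[: sites["m1"]] + FOOTPRINT_PD + seq[sites["m1"] :]
        events.append(
            PlantedEvent(kind="footprint", position=sites["m1"], length=6)
        )
        code, functional = (
            (AlleleCode.N, False) if extra_lof else (AlleleCode.R, True)
        )
    elif u < p_m1 + p_fp + p_fs:
        seq = seq[: sites["fs_extra"]] + "A" + seq[sites["fs_extra"] :]
        events.append(
            PlantedEvent(kind="frameshift_1bp", position=sites["fs_extra"], length=1)
        )
        code, functional = AlleleCode.N, False
    elif u < p_m1 + p_fp + p_fs + p_m5:
        tsd, tir, length = FAMILY_STRUCTURE["MITE5"]
        seq, _ = plant_mite(
            seq, sites["m5"], tsd, tir, length,
            element=family_elements["MITE5"], family_name="MITE5",
        )
        events.append(
            PlantedEvent(
                kind="mite_insertion", position=sites["m5"], element_name="MITE5",
                tir_length=tir, tsd_sequence=seq[sites["m5"] - tsd : sites["m5"]],
                length=length,
            )
        )
        code, functional = AlleleCode.M5, True

    return seq, AlleleTruth(
        allele_id=allele_id, accession_id=acc_id, region=region,
        locus=Locus.HD1A, expected_code=code, functional=functional,
        events=events,
    )
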