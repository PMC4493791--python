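"""End-to-end analysis: scan, annotate, tree, partition, summarize.

Mirrors the published workflow: every allele is aligned to a functional
reference, MITE insertions are discovered by terminal structure and grouped
into families, alleles are classified (F/R/N/Mk), a reference-anchored
alignment feeds K2P + Neighbor-Joining with bootstrap supports, the tree is
rooted on the outgroup and split into the two locus clades, and regional
functional-allele fractions plus heading-date correlations are tallied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import annotate as _annotate
from . import mite as _mite
from . import phylo as _phylo
from . import summary as _summary
from .model import (
    AlleleCode,
    AlleleRecord,
    CandidateStatus,
    GeneModel,
    InsertionCandidate,
    Locus,
    MiteElement,
    PanelTable,
    Region,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    panel: PanelTable  # input panel with codes replaced by pipeline calls
    candidates: dict[str, list[InsertionCandidate]]
    families: dict[str, MiteElement]
    records: list[AlleleRecord]
    tree: _phylo.PhyloTree | None
    rooted_tree: _phylo.PhyloTree | None
    locus_clades: tuple[frozenset[str], frozenset[str]] | None
    locus_concordance: float | None
    region_summaries: list = field(default_factory=list)


def reference_anchored_alignment(
    reference: str, records: list[tuple[str, str]]
) -> tuple[list[str], list[str]]:
    """Assemble a reference-column alignment from pairwise alignments.

    Every allele is aligned to the reference; its base at each reference
    column is kept (deletions become gaps, insertions are dropped).  The
    result has one equal-length row per allele — distances computed on it
    ignore indels, matching the distance model.
    """
    labels, rows = [], []
    for rid, seq in records:
        alignment = _mite.global_alignment(reference, seq)
        row = ["-"] * len(reference)
        tgt, qry = alignment.coordinates
        for k in range(1, len(tgt)):
            t0, t1 = int(tgt[k - 1]), int(tgt[k])
            q0, q1 = int(qry[k - 1]), int(qry[k])
            if t1 > t0 and q1 > q0:
                row[t0:t1] = seq[q0:q1]
        labels.append(rid)
        rows.append("".join(row))
    return labels, rows


def _in_cds(gene_model: GeneModel, position: int) -> bool:
    return any(s <= position < e for s, e in gene_model.cds_intervals())


def _renumber_families(
    candidates: list[InsertionCandidate],
    families: dict[str, MiteElement],
    gene_model: GeneModel,
) -> dict[str, MiteElement]:
    """Stable presentation numbering: families inserted into the coding
    sequence come first (so low family numbers carry the loss-of-function
    association of the published naming), then by first appearance."""
    order: list[str] = []
    for cand in candidates:
        if cand.family and cand.family not in order:
            order.append(cand.family)
    exonic_first = sorted(
        order,
        key=lambda f: (
            0 if any(
                _in_cds(gene_model, c.reference_position)
                for c in candidates
                if c.family == f and c.status is CandidateStatus.MITE
            ) else 1,
            order.index(f),
        ),
    )
    mapping = {old: f"MITE{i + 1}" for i, old in enumerate(exonic_first)}
    renamed: dict[str, MiteElement] = {}
    for old, new in mapping.items():
        element = families[old]
        element.family_name = new
        renamed[new] = element
    for cand in candidates:
        if cand.family:
            cand.family = mapping[cand.family]
    return renamed


def annotate_panel(
    gene_model: GeneModel,
    alleles: list[tuple[str, str]],
    scan_config: _mite.ScanConfig | None = None,
) -> tuple[list[AlleleRecord], dict[str, list[InsertionCandidate]], dict[str, MiteElement]]:
    """Scan and classify every allele against the reference gene model."""
    reference = gene_model.reference_sequence
    candidates: dict[str, list[InsertionCandidate]] = {}
    for rid, seq in alleles:
        candidates[rid] = _mite.scan_insertions(reference, seq, rid, scan_config)
    all_mites = [
        c for cands in candidates.values() for c in cands
        if c.status is CandidateStatus.MITE
    ]
    families = _mite.build_family_elements(all_mites)
    if families:
        families = _renumber_families(all_mites, families, gene_model)
    known_sites = sorted({c.reference_position for c in all_mites})

    records: list[AlleleRecord] = []
    for rid, seq in alleles:
        cds = _annotate.splice_cds(seq, gene_model)
        orf = _annotate.orf_report(cds, gene_model)
        mite_hits = [
            c for c in candidates[rid] if c.status is CandidateStatus.MITE
        ]
        footprint = None
        if not mite_hits:
            footprint = _footprint_at_known_sites(candidates[rid], known_sites)
        code, functional = _annotate.classify_allele(orf, mite_hits, footprint)
        notes = []
        if code is AlleleCode.N and footprint is not None and footprint.found:
            notes.append("footprint+LOF")
        if len(mite_hits) > 1:
            notes.extend(f"also {c.family}" for c in mite_hits[1:] if c.family)
        records.append(
            AlleleRecord(
                allele_id=rid,
                accession_id=rid.rsplit("_", 1)[0],
                sequence=seq,
                code=code,
                functional=functional,
                notes=notes,
            )
        )
    return records, candidates, families


def _footprint_at_known_sites(
    cands: list[InsertionCandidate],
    known_sites: list[int],
    tolerance: int = 8,
) -> _mite.FootprintReport:
    """Footprint call against historical insertion sites, reusing the
    allele's existing insertion scan (same rule as ``detect_footprint``)."""
    for cand in cands:
        if cand.length != 6 or cand.status is CandidateStatus.MITE:
            continue
        lo, hi = cand.placement_range or (
            cand.reference_position, cand.reference_position
        )
        for site in known_sites:
            if lo - tolerance <= site <= hi + tolerance:
                return _mite.FootprintReport(
                    found=True,
                    hexamer=cand.inserted_sequence,
                    position=cand.reference_position,
                )
    return _mite.FootprintReport(found=False)


def run_pipeline(
    gene_model: GeneModel,
    alleles: list[tuple[str, str]],
    panel: PanelTable,
    outgroup: tuple[str, str] | None = None,
    bootstrap_replicates: int = 200,
    seed: int | None = None,
    build_tree: bool = True,
) -> PipelineResult:
    """Run the full analysis on an allele panel.

    ``panel`` provides accession metadata (region, heading dates); its allele
    codes are replaced by the pipeline's own calls.  When an outgroup is
    given and ``build_tree`` is set, the NJ tree is built, bootstrapped,
    rooted, and split into the two locus clades; alleles carrying the most
    common diagnostic insertion family of the minority clade serve as locus
    markers.
    """
    records, candidates, families = annotate_panel(gene_model, alleles)
    by_id = {r.allele_id: r for r in records}

    tree = rooted = None
    clades = None
    concordance = None
    if build_tree and outgroup is not None:
        labels, rows = reference_anchored_alignment(
            gene_model.reference_sequence, list(alleles) + [outgroup]
        )
        logger.info("bootstrap: %d replicates on %d sequences", bootstrap_replicates, len(labels))
        tree = _phylo.bootstrap_support(
            labels, rows, replicates=bootstrap_replicates, seed=seed
        )
        rooted = _phylo.root_with_outgroup(tree, outgroup[0])
        # markers: alleles whose MITE family sits in the 5' region shared by
        # the pseudogene locus — operationally, the family carried by the
        # clade minority; concordance is reported against those markers
        marker_family = _pseudogene_marker_family(candidates, families, gene_model)
        markers = {
            rid for rid, cands in candidates.items()
            if any(c.family == marker_family for c in cands)
        } if marker_family else None
        a, b, concordance = _phylo.partition_loci(rooted, markers)
        clades = (a, b)
        # assign loci: the clade richer in marker alleles is the pseudogene
        if markers:
            b_is_pseudo = len(markers & b) >= len(markers & a)
            pseudo = b if b_is_pseudo else a
            for rid, rec in by_id.items():
                rec.locus = Locus.HD1B if rid in pseudo else Locus.HD1A
    if all(r.locus is Locus.UNASSIGNED for r in records):
        for rec in records:
            rec.locus = Locus.HD1A

    called_panel = PanelTable(accessions=panel.accessions, calls=records)
    summaries = [
        _summary.tally_hd1a(called_panel, region)
        for region in (Region.JAPAN, Region.MAINLAND)
    ]
    return PipelineResult(
        panel=called_panel,
        candidates=candidates,
        families=families,
        records=records,
        tree=tree,
        rooted_tree=rooted,
        locus_clades=clades,
        locus_concordance=concordance,
        region_summaries=summaries,
    )


def _pseudogene_marker_family(
    candidates: dict[str, list[InsertionCandidate]],
    families: dict[str, MiteElement],
    gene_model: GeneModel,
) -> str | None:
    """The family diagnostic of the pseudogene locus: the commonest family
    inserted upstream of the coding region (the shared 5'-UTR element);
    None when no such family exists."""
    if not families:
        return None
    coding_start = min(s for s, _ in gene_model.cds_intervals())
    counts: dict[str, int] = {}
    for cands in candidates.values():
        for c in cands:
            if (
                c.status is CandidateStatus.MITE
                and c.family
                and c.reference_position < coding_start
            ):
                counts[c.family] = counts.get(c.family, 0) + 1
    if not counts:
        return None
    return max(counts, key=lambda f: (counts[f], f))
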