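"""Regional allele tallies, locus-number bounds, and heading-date analyses.

The headline contrast: alleles of the functional locus (Hd1a) are tallied per
region and split into functional vs non-functional; mainland accessions carry
only functional alleles while about half the Japanese alleles are
loss-of-function.  Heading dates (day-of-year) are compared between years and
regressed against latitude of origin.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import DID_NOT_HEAD, Locus, PanelTable, Region

logger = logging.getLogger(__name__)


@dataclass
class RegionSummary:
    region: Region
    total_alleles: int
    functional: int
    non_functional: int
    percent_functional: float

    def __post_init__(self) -> None:
        assert self.functional + self.non_functional == self.total_alleles


def tally_hd1a(
    panel: PanelTable, region: Region, species: str = "M. sinensis"
) -> RegionSummary:
    """Count functional vs non-functional Hd1a alleles for one region.

    Only accessions of ``species`` (default M. sinensis, as in the published
    tallies) contribute.  A region without accessions yields a zero summary.
    """
    acc_ids = {
        a.accession_id
        for a in panel.accessions
        if a.region is region and a.species == species
    }
    total = functional = 0
    for call in panel.calls:
        if call.accession_id in acc_ids and call.locus is Locus.HD1A:
            total += 1
            functional += bool(call.functional)
    return RegionSummary(
        region=region,
        total_alleles=total,
        functional=functional,
        non_functional=total - functional,
        percent_functional=100.0 * functional / total if total else 0.0,
    )


def allele_count_bounds(
    panel: PanelTable, species_filter: str = "M. sinensis", ploidy: int = 2
) -> tuple[int, int, int]:
    """(min, max) distinct alleles per accession and the implied lower bound
    on locus number, ceil(max / ploidy)."""
    counts = [
        len(panel.calls_for(a.accession_id))
        for a in panel.accessions
        if a.species == species_filter
    ]
    counts = [c for c in counts if c > 0]
    if not counts:
        raise ValueError(f"no accessions match species {species_filter!r}")
    return min(counts), max(counts), math.ceil(max(counts) / ploidy)


def day_of_year(d: _dt.date) -> int:
    """1-based ordinal day within the year (leap-aware)."""
    if not isinstance(d, _dt.date):
        raise ValueError(f"not a date: {d!r}")
    return d.timetuple().tm_yday


def pearson(x, y) -> float:
    """Sample Pearson correlation; raises on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(x, y).statistic)


def _heading_doys(panel: PanelTable) -> dict[str, dict[int, float]]:
    """Per accession, recorded heading day-of-year by year; did-not-head
    seasons are excluded (with a warning)."""
    out: dict[str, dict[int, float]] = {}
    for acc in panel.accessions:
        per_year: dict[int, float] = {}
        for year, value in acc.heading_date_by_year.items():
            if value is None:
                continue
            if value is DID_NOT_HEAD:
                logger.warning(
                    "%s did not head in %d; excluded from correlations",
                    acc.accession_id, year,
                )
                continue
            per_year[year] = float(day_of_year(value))
        if per_year:
            out[acc.accession_id] = per_year
    return out


def heading_year_correlation(
    panel: PanelTable, years: tuple[int, int] = (2012, 2014)
) -> float:
    """Pearson r of heading day-of-year between two trial years, over
    accessions recorded in both."""
    doys = _heading_doys(panel)
    pairs = [
        (d[years[0]], d[years[1]])
        for d in doys.values()
        if years[0] in d and years[1] in d
    ]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 accessions recorded in both years")
    x, y = zip(*pairs)
    return pearson(x, y)


def heading_latitude_cline(panel: PanelTable) -> float:
    """Pearson r between latitude of origin and mean heading day-of-year over
    whichever years were recorded."""
    doys = _heading_doys(panel)
    lats, means = [], []
    for acc in panel.accessions:
        if acc.accession_id in doys and acc.latitude is not None:
            lats.append(acc.latitude)
            means.append(float(np.mean(list(doys[acc.accession_id].values()))))
    return pearson(lats, means)


def region_summaries(panel: PanelTable) -> list[RegionSummary]:
    return [tally_hd1a(panel, r) for r in (Region.JAPAN, Region.MAINLAND)]
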