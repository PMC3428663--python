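"""Detection and outline error estimates (DOEE) for one scan.

Agreement between two raters' ROI sets is split into two error types
routed by the region classification: a region drawn by only one rater
contributes its whole area to the Detection Error (DE); a region drawn by
both contributes its union-minus-intersection area to the Outline Error
(OE).  Either DE or OE is accrued for a region, never both.

With MTA = (|R1| + |R2|) / 2 the mean total area, the similarity index
(Dice coefficient)

    SI = 2 |R1 ∩ R2| / (|R1| + |R2|)

decomposes exactly as

    SI = 1 - OE / (2 MTA) - DE / (2 MTA) = 1 - OER/2 - DE/(2 MTA),

where OER = OE / MTA is the outline error rate.  Replacing DE and OER by
their study means gives a two-parameter prediction of SI as a function of
lesion burden,

    SI_est(MTA) = 1 - meanOER/2 - meanDE / (2 MTA),

which explains why raw SI rewards high-burden scans: the detection term
shrinks as 1/MTA while the outline term is burden-free.

SI relates to the Jaccard index by SI = 2 JI / (1 + JI), and is the limit
of Cohen's kappa as the frame grows to include ever more pixels marked by
neither rater.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateScanError, DomainError, ValidationError
from .masks_io import RaterMaskPair
from .region_partition import ConnectedRegion, partition_regions, region_counts

logger = logging.getLogger(__name__)

__all__ = [
    "ScanAgreement",
    "detection_error",
    "outline_error",
    "scan_agreement",
    "score_pair",
    "si_estimate",
    "si_from_ji",
    "ji_from_si",
    "kappa_on_frame",
    "agreements_to_table",
]


@dataclass(frozen=True)
class ScanAgreement:
    """Per-scan agreement record: areas in mm^2, indices dimensionless."""

    scan_id: str
    mta: float
    de: float
    oe: float
    oer: float
    si: float
    ji: float
    n_cr1: int
    n_cr2: int
    n_cr12: int


def detection_error(regions: Iterable[ConnectedRegion]) -> float:
    """Total area (mm^2) of single-rater (CR1 and CR2) regions."""
    return float(sum(r.area_union for r in regions if r.label in ("CR1", "CR2")))


def outline_error(regions: Iterable[ConnectedRegion]) -> float:
    """Summed union-minus-intersection area (mm^2) over CR12 regions."""
    return float(
        sum(r.area_union - r.area_intersection for r in regions if r.label == "CR12")
    )


def scan_agreement(
    regions: Sequence[ConnectedRegion],
    totals: tuple[float, float] | None = None,
    scan_id: str | None = None,
) -> ScanAgreement:
    """Aggregate a scan's region table into its DOEE agreement record.

    The similarity index is computed both from the intersection/MTA form
    and from the DE/OE decomposition; the two must agree to 1e-12 relative
    tolerance (they are algebraically identical) and the intersection form
    is stored.

    Parameters
    ----------
    regions : sequence of ConnectedRegion
        All regions of one scan.
    totals : (|R1|, |R2|), optional
        Per-rater total areas, for cross-checking against the region sums.
    scan_id : str, optional
        Defaults to the regions' shared scan id.
    """
    if scan_id is None:
        scan_id = regions[0].scan_id if regions else ""
    area_r1 = sum(r.area_r1 for r in regions)
    area_r2 = sum(r.area_r2 for r in regions)
    if totals is not None:
        t1, t2 = totals
        if not (np.isclose(t1, area_r1) and np.isclose(t2, area_r2)):
            raise ValidationError(
                f"scan {scan_id!r}: supplied totals ({t1}, {t2}) disagree with region sums "
                f"({area_r1}, {area_r2})"
            )
    mta = 0.5 * (area_r1 + area_r2)
    if mta <= 0:
        raise DegenerateScanError(f"scan {scan_id!r}: both raters empty, MTA = 0")
    de = detection_error(regions)
    oe = outline_error(regions)
    intersection = sum(r.area_intersection for r in regions)
    union = sum(r.area_union for r in regions)
    si = intersection / mta  # 2|R1 ∩ R2| / (|R1| + |R2|)
    si_decomp = 1.0 - 0.5 * oe / mta - 0.5 * de / mta
    if not np.isclose(si, si_decomp, rtol=1e-12, atol=1e-12):
        raise AssertionError(
            f"scan {scan_id!r}: SI forms disagree ({si} vs {si_decomp}); region table corrupt"
        )
    ji = intersection / union if union > 0 else 0.0
    n1, n2, n12 = region_counts(regions)
    return ScanAgreement(
        scan_id=scan_id,
        mta=float(mta),
        de=de,
        oe=oe,
        oer=oe / mta,
        si=float(si),
        ji=float(ji),
        n_cr1=n1,
        n_cr2=n2,
        n_cr12=n12,
    )


def score_pair(pair: RaterMaskPair, connectivity: int = 8) -> ScanAgreement:
    """Partition a mask pair and aggregate it in one step."""
    return scan_agreement(partition_regions(pair, connectivity), scan_id=pair.scan_id)


def si_estimate(mean_de: float, mean_oer: float, mta: float | np.ndarray) -> float | np.ndarray:
    """Two-parameter similarity prediction 1 - meanOER/2 - meanDE/(2 MTA).

    May be negative for very small MTA; the value is returned as-is (the
    model is honest about its domain) and plotting code may clamp.
    """
    mta = np.asarray(mta, dtype=float)
    if np.any(mta <= 0):
        raise DomainError("si_estimate requires MTA > 0")
    out = 1.0 - 0.5 * mean_oer - 0.5 * mean_de / mta
    return float(out) if out.ndim == 0 else out


def si_from_ji(ji: float) -> float:
    """SI = 2 JI / (1 + JI); bijective on [0, 1]."""
    ji = float(ji)
    if not 0.0 <= ji <= 1.0:
        raise DomainError(f"JI must lie in [0, 1], got {ji}")
    return 2.0 * ji / (1.0 + ji)


def ji_from_si(si: float) -> float:
    """Inverse of si_from_ji: JI = SI / (2 - SI)."""
    si = float(si)
    if not 0.0 <= si <= 1.0:
        raise DomainError(f"SI must lie in [0, 1], got {si}")
    return si / (2.0 - si)


def kappa_on_frame(pair: RaterMaskPair, background_pixels: int) -> float:
    """Cohen's kappa for lesion/non-lesion over a finite pixel frame.

    The frame holds every pixel of the two raters' union plus
    ``background_pixels`` pixels marked by neither rater, counted at the
    pair's analysis resolution.  As the background grows, kappa increases
    towards SI.
    """
    n11 = int((pair.rater1 & pair.rater2).sum())
    n10 = int((pair.rater1 & ~pair.rater2).sum())
    n01 = int((~pair.rater1 & pair.rater2).sum())
    n_union = n11 + n10 + n01
    if background_pixels < n_union:
        raise DomainError(
            f"background ({background_pixels} px) smaller than the union ({n_union} px)"
        )
    n00 = background_pixels
    n = n11 + n10 + n01 + n00
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n00 + n01) * (n00 + n10)) / n**2
    if pe == 1.0:  # both raters empty on the whole frame: perfect agreement
        return 1.0
    return (po - pe) / (1.0 - pe)


def agreements_to_table(scans: Sequence[ScanAgreement], path: str | Path | None = None):
    """Per-scan agreement table as a DataFrame; optional TSV export
    (areas at 1 decimal, indices at 3)."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "scan_id": s.scan_id,
                "MTA": s.mta,
                "DE": s.de,
                "OE": s.oe,
                "OER": s.oer,
                "SI": s.si,
                "JI": s.ji,
                "n_cr1": s.n_cr1,
                "n_cr2": s.n_cr2,
                "n_cr12": s.n_cr12,
            }
            for s in scans
        ],
        columns=["scan_id", "MTA", "DE", "OE", "OER", "SI", "JI", "n_cr1", "n_cr2", "n_cr12"],
    )
    if path is not None:
        out = df.copy()
        for col in ("MTA", "DE", "OE"):
            out[col] = out[col].round(1)
        for col in ("OER", "SI", "JI"):
            out[col] = out[col].round(3)
        out.to_csv(path, sep="\t", index=False)
    return df
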