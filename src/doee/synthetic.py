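"""Synthetic paired rater segmentations with known error structure.

The generator emulates the statistical shape of a multi-scan inter-rater
lesion study: per-scan lesion burden (MTA) spans a wide, log-uniform range;
detection disagreement is concentrated in a population of small
"ambiguous" lesions whose expected number is constant across scans, so the
detection error (DE) stays roughly flat as burden grows; outline
disagreement is a per-lesion fractional boundary perturbation, so the
outline error (OE) grows roughly in proportion to burden and the outline
error rate (OER) stays flat near the configured target.

Mechanics per scan:

1. a target burden is drawn log-uniformly from ``mta_range``;
2. ambiguous lesions (Poisson count, small lognormal areas) are placed,
   then larger "burden" lesions are added until the target area is reached;
3. each rater independently omits each lesion with probability
   ``expit(a - b ln area)`` (small lesions missed more often);
4. each rater's outline of a kept lesion is the lesion dilated or eroded
   by a signed normal offset, realized by thresholding the signed
   Euclidean distance transform, so the two outlines are nested and the
   per-lesion outline error is their area difference.

The offset scale is set analytically from the lesion's area and perimeter
so that the expected per-lesion fractional outline error equals
``jitter_strength``; :func:`calibrate_jitter` can refine the global scale
by simulation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.special import expit

from .doee_metrics import ScanAgreement, score_pair, si_estimate
from .errors import DomainError, ValidationError
from .masks_io import PixelGeometry, RaterMaskPair

__all__ = [
    "SyntheticConfig",
    "generate_study",
    "generate_si_vs_mta_table",
    "calibrate_jitter",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the paired-ROI generator.

    Defaults describe a 17-scan study with burdens spanning roughly
    850–18000 mm^2, a constant pool of small miss-prone lesions, and a
    target outline error rate of about 0.4.
    """

    seed: int = 0
    n_scans: int = 17
    slice_shape: tuple[int, int] = (192, 192)
    slices_per_scan: int = 8
    #: Poisson mean of the per-scan count of small ambiguous lesions.
    lesion_count_mean: float = 60.0
    #: (mu, sigma) of log area (mm^2) for burden lesions.
    lesion_area_lognormal: tuple[float, float] = (math.log(150.0), 0.9)
    #: burden lesion areas are resampled above this floor (mm^2) so they do
    #: not re-enter the miss-prone size range the ambiguous pool models.
    burden_area_floor: float = 60.0
    #: (mu, sigma) of log area (mm^2) for the ambiguous pool.
    ambiguous_area_lognormal: tuple[float, float] = (math.log(18.0), 0.5)
    #: (a, b): P(one rater omits a lesion) = expit(a - b ln area_mm2);
    #: steep in log-area so detection disagreement stays confined to the
    #: ambiguous pool and DE is burden-free.
    miss_model: tuple[float, float] = (17.3, 6.0)
    #: target expected fractional outline perturbation per lesion (~ OER).
    jitter_strength: float = 0.4
    #: global multiplier on the analytic jitter scale (see calibrate_jitter).
    jitter_scale: float = 1.0
    geometry: PixelGeometry = PixelGeometry(0.94, 0.94)
    #: per-scan target burden range, mm^2 (log-uniform sampling).
    mta_range: tuple[float, float] = (850.0, 18000.0)

    def __post_init__(self) -> None:
        if self.mta_range[0] >= self.mta_range[1]:
            raise ValidationError("mta_range must satisfy low < high")
        if self.jitter_strength < 0 or self.lesion_count_mean < 0:
            raise ValidationError("rates must be non-negative")
        if self.n_scans < 1 or self.slices_per_scan < 1:
            raise ValidationError("need at least one scan and one slice")


def _miss_probability(area_mm2: float, miss_model: tuple[float, float]) -> float:
    a, b = miss_model
    return float(expit(a - b * math.log(max(area_mm2, 1e-12))))


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float, sa: float, sb: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    u = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    v = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    return (u / sa) ** 2 + (v / sb) ** 2 <= 1.0


def _signed_offset(mask: np.ndarray, delta: float) -> np.ndarray:
    """Dilate (delta > 0) or erode (delta < 0) by thresholding the signed EDT.

    EDT values are center-to-center distances, so the region boundary sits
    about half a pixel from the nearest centers; the half-pixel shift makes
    the realized area respond to sub-pixel offsets without bias.
    """
    if delta == 0 or not mask.any():
        return mask
    if delta > 0:
        return mask | (distance_transform_edt(~mask) <= delta + 0.5)
    return mask & (distance_transform_edt(mask) >= 0.5 - delta)


def _ellipse_perimeter(sa: float, sb: float) -> float:
    # Ramanujan's approximation
    h = ((sa - sb) / (sa + sb)) ** 2
    return math.pi * (sa + sb) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


@dataclass
class LesionFate:
    """Ground truth for one generated lesion."""

    scan_id: str
    slice_index: int
    area_mm2: float
    center: tuple[float, float]
    missed_by_r1: bool
    missed_by_r2: bool
    delta_r1_px: float
    delta_r2_px: float


def generate_study(
    config: SyntheticConfig,
) -> tuple[list[RaterMaskPair], dict]:
    """Generate paired rater masks for a whole study.

    Returns the list of mask pairs and a ground-truth record holding the
    generator parameters, every lesion's per-rater fate, and the realized
    per-scan agreement (DE, OE, MTA, SI) measured by the scoring pipeline.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    px_area = config.geometry.pixel_area
    px_lin = math.sqrt(px_area)  # isotropic pixel scale, mm per px
    rows, cols = config.slice_shape
    lo, hi = config.mta_range

    pairs: list[RaterMaskPair] = []
    fates: list[LesionFate] = []
    per_scan_truth = []

    for i_scan in range(config.n_scans):
        scan_id = f"synth{i_scan:03d}"
        target = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        n_amb = int(rng.poisson(config.lesion_count_mean))
        mu_a, sd_a = config.ambiguous_area_lognormal
        areas = list(rng.lognormal(mu_a, sd_a, size=n_amb))
        mu_b, sd_b = config.lesion_area_lognormal
        while sum(areas) < target:
            draw = float(rng.lognormal(mu_b, sd_b))
            if draw >= config.burden_area_floor:
                areas.append(draw)

        r1 = np.zeros((config.slices_per_scan, rows, cols), dtype=bool)
        r2 = np.zeros((config.slices_per_scan, rows, cols), dtype=bool)
        # occupied disks per slice, to place lesions without overlap
        placed: list[list[tuple[float, float, float]]] = [
            [] for _ in range(config.slices_per_scan)
        ]

        # largest first eases collision-free packing
        for area_mm2 in sorted(areas, reverse=True):
            area_px = area_mm2 / px_area
            r_eq = math.sqrt(area_px / math.pi)
            aspect = float(rng.uniform(1.0, 2.0))
            sa, sb = r_eq * math.sqrt(aspect), r_eq / math.sqrt(aspect)
            theta = float(rng.uniform(0.0, math.pi))
            perim = _ellipse_perimeter(sa, sb)
            # offset scale: E|A1 - A2| ~ P * 2*sigma/sqrt(pi) = jitter * A
            sigma = config.jitter_scale * config.jitter_strength * area_px * math.sqrt(math.pi) / (2.0 * perim)
            margin = sa + 3.0 * sigma + 2.0
            if 2 * margin >= min(rows, cols):
                raise DomainError(
                    f"lesion of {area_mm2:.0f} mm^2 cannot fit the {rows}x{cols} slice"
                )
            reach = sa + 3.0 * sigma + 1.0
            for _attempt in range(60):
                z = int(rng.integers(config.slices_per_scan))
                cy = float(rng.uniform(margin, rows - margin))
                cx = float(rng.uniform(margin, cols - margin))
                if all(
                    (cy - py) ** 2 + (cx - px) ** 2 > (reach + pr) ** 2
                    for py, px, pr in placed[z]
                ):
                    break
            else:
                raise DomainError(
                    f"could not place a {area_mm2:.0f} mm^2 lesion without overlap; "
                    "the configured burden exceeds the slice capacity"
                )
            placed[z].append((cy, cx, reach))

            p_miss = _miss_probability(area_mm2, config.miss_model)
            miss1 = bool(rng.random() < p_miss)
            miss2 = bool(rng.random() < p_miss)
            # erosion beyond ~0.6 r_eq would annihilate the lesion
            d1 = float(np.clip(rng.normal(0.0, sigma), -0.6 * sb, 3.0 * sigma))
            d2 = float(np.clip(rng.normal(0.0, sigma), -0.6 * sb, 3.0 * sigma))
            fates.append(
                LesionFate(scan_id, z, area_mm2, (cy, cx), miss1, miss2, d1, d2)
            )
            if miss1 and miss2:
                continue
            # local window: base ellipse plus room for the largest dilation
            pad = int(math.ceil(sa + max(d1, d2, 0.0) + 2.0))
            y0, y1 = max(0, int(cy) - pad), min(rows, int(cy) + pad + 1)
            x0, x1 = max(0, int(cx) - pad), min(cols, int(cx) + pad + 1)
            base = _ellipse_mask((y1 - y0, x1 - x0), cy - y0, cx - x0, sa, sb, theta)
            if not base.any():
                base[int(round(cy - y0)), int(round(cx - x0))] = True
            if not miss1:
                r1[z, y0:y1, x0:x1] |= _signed_offset(base, d1)
            if not miss2:
                r2[z, y0:y1, x0:x1] |= _signed_offset(base, d2)

        pairs.append(RaterMaskPair(r1, r2, config.geometry, scan_id))
        per_scan_truth.append({"scan_id": scan_id, "target_mta": target, "n_lesions": len(areas)})

    from .errors import DegenerateScanError

    realized: list[ScanAgreement] = []
    for pair, rec in zip(pairs, per_scan_truth):
        try:
            agg = score_pair(pair)
        except DegenerateScanError:
            rec.update({"MTA": 0.0, "DE": 0.0, "OE": 0.0, "OER": 0.0, "SI": math.nan})
            continue
        realized.append(agg)
        rec.update(
            {"MTA": agg.mta, "DE": agg.de, "OE": agg.oe, "OER": agg.oer, "SI": agg.si}
        )

    truth = {
        "config": dataclasses.asdict(config),
        "per_scan": per_scan_truth,
        "lesions": [dataclasses.asdict(f) for f in fates],
        "mean_de": float(np.mean([a.de for a in realized])) if realized else 0.0,
        "mean_oer": float(np.mean([a.oer for a in realized])) if realized else 0.0,
    }
    return pairs, truth


def calibrate_jitter(
    config: SyntheticConfig, n_scans: int = 60, n_iter: int = 2
) -> SyntheticConfig:
    """Refine the jitter scale by simulation so the realized mean OER
    matches ``jitter_strength``; returns an adjusted copy of the config.

    Runs ``n_iter`` probe studies of ``n_scans`` scans on independent seed
    streams derived from the config seed, each time rescaling by the ratio
    of target to measured mean OER.
    """
    out = config
    for it in range(n_iter):
        probe = dataclasses.replace(
            out, n_scans=n_scans, seed=(config.seed + 7919 * (it + 1)) % 2**31
        )
        _, truth = generate_study(probe)
        measured = truth["mean_oer"]
        if measured <= 0:
            raise DomainError("calibration study produced zero outline error")
        out = dataclasses.replace(
            out, jitter_scale=out.jitter_scale * out.jitter_strength / measured
        )
    return out


def generate_si_vs_mta_table(
    mean_de: float,
    mean_oer: float,
    n: int,
    noise_sd: float,
    mta_range: tuple[float, float] = (850.0, 18000.0),
    seed: int | np.random.Generator = 0,
):
    """Forward-simulate a per-scan (MTA, SI) table from the two-parameter
    similarity model, with Gaussian SI noise clamped to [0, 1].

    Each scan also carries consistent per-scan DE and OER records
    (DE held at ``mean_de``; OER absorbs the noise) so a study refit can
    recover the generator parameters: with ``noise_sd = 0`` the recovery
    is exact and the model's residuals vanish.
    """
    if not 0.0 <= mean_oer <= 2.0:
        raise DomainError(f"meanOER must lie in [0, 2], got {mean_oer}")
    if mean_de < 0:
        raise DomainError("meanDE must be non-negative")
    lo, hi = mta_range
    if not 0 < lo < hi:
        raise DomainError("mta_range must satisfy 0 < low < high")
    if si_estimate(mean_de, mean_oer, hi) <= 0:
        raise DomainError("parameters leave no scan with positive expected SI")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mta = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    si = si_estimate(mean_de, mean_oer, mta) + rng.normal(0.0, noise_sd, size=n)
    si = np.clip(si, 0.0, 1.0)
    oer = 2.0 * (1.0 - si) - mean_de / mta  # keeps SI = 1 - OER/2 - DE/(2 MTA) exact
    import pandas as pd

    return pd.DataFrame(
        {
            "scan_id": [f"sim{i:03d}" for i in range(n)],
            "MTA": mta,
            "SI": si,
            "DE": np.full(n, float(mean_de)),
            "OE": oer * mta,
            "OER": oer,
        }
    )
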