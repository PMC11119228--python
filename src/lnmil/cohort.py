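"""Synthetic T1-colorectal-cancer cohort and H&E-like slide generator.

The generator stands in for a private institutional dataset of T1 CRC patients
with two specimen types: *endoscopic* resections (partial submucosal tissue,
high-risk patients sent to additional surgery) and *surgical* resections
(full-thickness specimens).  Each patient carries a binary lymph-node-metastasis
(LNM) label; default per-stratum prevalences are 17.8% (endoscopic) and 6.6%
(surgical).  Positive patients' slides contain a planted minority "evidence"
texture (dense dark nuclei-like speckle, emulating tumour budding /
micropapillary foci) occupying a small fraction of the tissue; negative slides
contain only the smooth "normal gland" texture.  The evidence mask is the
ground truth that lets tests measure whether attention localizes the signal.

Covariates are sampled independently per stratum (no dependence structure);
they are cosmetic except for the optional ``informative_covariates`` mode which
enriches lymphovascular invasion and tumour budding in LNM-positive patients so
a clinicopathologic random-forest baseline can beat chance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .util import nearest_int, round_half_up

ENDOSCOPIC = "endoscopic"
SURGICAL = "surgical"

#: Fixed column order of the cohort CSV.
COHORT_COLUMNS = [
    "patient_id",
    "specimen_type",
    "lnm_label",
    "age",
    "sex",
    "bmi",
    "comorbidity",
    "family_history",
    "smoking",
    "alcohol",
    "tumor_location",
    "cancer_size_mm",
    "sm_depth_um",
    "sm_tier",
    "differentiation",
    "lvi",
    "budding",
    "margin_positive",
    "msi",
    "n_slides",
]


@dataclass
class PatientRecord:
    """One patient: identifiers, specimen stratum, LNM label and covariates."""

    patient_id: str
    specimen_type: str
    lnm_label: int
    age: int
    sex: str
    bmi: float
    comorbidity: int
    family_history: int
    smoking: str
    alcohol: str
    tumor_location: str
    cancer_size_mm: float
    sm_depth_um: float
    sm_tier: str
    differentiation: str
    lvi: int
    budding: int
    margin_positive: int
    msi: str
    n_slides: int = 1

    def __post_init__(self):
        if self.specimen_type not in (ENDOSCOPIC, SURGICAL):
            raise ValueError(f"unknown specimen_type {self.specimen_type!r}")
        if self.lnm_label not in (0, 1):
            raise ValueError("lnm_label must be 0 or 1")
        if self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")
        if self.specimen_type == SURGICAL and self.margin_positive:
            raise ValueError("surgical specimens cannot be margin-positive")


# Per-stratum covariate parameters (marginal proportions / location-scale).
_SMOKING = (["never", "ex", "current"], [0.712, 0.157, 0.131])
_ALCOHOL = (["never", "ex", "current"], [0.632, 0.055, 0.313])
_DIFF = (["well", "moderate", "poor"], [0.593, 0.379, 0.028])
_MSI = {
    ENDOSCOPIC: (["stable", "unstable", "unknown"], [0.250, 0.025, 0.725]),
    SURGICAL: (["stable", "unstable", "unknown"], [0.855, 0.088, 0.057]),
}
# lvi / budding rates by (stratum, label) used in informative mode, else marginal.
_LVI = {(ENDOSCOPIC, 0): 0.261, (ENDOSCOPIC, 1): 0.310, (SURGICAL, 0): 0.114, (SURGICAL, 1): 0.535}
_BUDDING = {(ENDOSCOPIC, 0): 0.122, (ENDOSCOPIC, 1): 0.127, (SURGICAL, 0): 0.145, (SURGICAL, 1): 0.347}
_LVI_MARGINAL = 0.196
_BUDDING_MARGINAL = 0.154
_TWO_SLIDE_RATE = 0.10


def _sample_record(rng: np.random.Generator, pid: str, stratum: str, label: int,
                   informative: bool) -> PatientRecord:
    age = int(np.clip(np.round(rng.normal(60.0, 10.0)), 25, 95))
    sex = "M" if rng.random() < 0.596 else "F"
    bmi = float(np.round(np.clip(rng.normal(24.2, 2.9), 15.0, 45.0), 1))
    size_median = 10.0 if stratum == ENDOSCOPIC else 20.0
    size_sigma = 0.48 if stratum == ENDOSCOPIC else 0.38
    size = float(np.round(np.clip(size_median * np.exp(rng.normal(0.0, size_sigma)), 2.0, 80.0), 1))
    depth = float(np.round(np.clip(1775.0 * np.exp(rng.normal(0.0, 0.45)), 200.0, 6000.0)))
    tier = "SM1" if depth < 1000 else ("SM2" if depth < 2000 else "SM3")
    if informative:
        p_lvi, p_bud = _LVI[(stratum, label)], _BUDDING[(stratum, label)]
    else:
        p_lvi, p_bud = _LVI_MARGINAL, _BUDDING_MARGINAL
    return PatientRecord(
        patient_id=pid,
        specimen_type=stratum,
        lnm_label=label,
        age=age,
        sex=sex,
        bmi=bmi,
        comorbidity=int(rng.random() < 0.379),
        family_history=int(rng.random() < 0.108),
        smoking=str(rng.choice(_SMOKING[0], p=_SMOKING[1])),
        alcohol=str(rng.choice(_ALCOHOL[0], p=_ALCOHOL[1])),
        tumor_location="left" if rng.random() < 0.713 else "right",
        cancer_size_mm=size,
        sm_depth_um=depth,
        sm_tier=tier,
        differentiation=str(rng.choice(_DIFF[0], p=_DIFF[1])),
        lvi=int(rng.random() < p_lvi),
        budding=int(rng.random() < p_bud),
        margin_positive=int(stratum == ENDOSCOPIC and rng.random() < 0.285),
        msi=str(rng.choice(_MSI[stratum][0], p=_MSI[stratum][1])),
        n_slides=1 + int(rng.random() < _TWO_SLIDE_RATE),
    )


def generate_cohort(
    n_endoscopic: int,
    n_surgical: int,
    prev_endo: float = 0.178,
    prev_surg: float = 0.066,
    seed: int = 0,
    binomial: bool = False,
    informative_covariates: bool = True,
) -> list[PatientRecord]:
    """Generate a two-stratum cohort with the requested LNM prevalences.

    Positive counts per stratum are ``nearest_int(n * prev)`` by default so the
    realized prevalence is exact; with ``binomial=True`` they are binomial
    draws.  Deterministic given ``seed``.
    """
    if n_endoscopic < 0 or n_surgical < 0:
        raise ValueError("patient counts must be non-negative")
    for p in (prev_endo, prev_surg):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    cohort: list[PatientRecord] = []
    for stratum, prefix, n, prev in (
        (ENDOSCOPIC, "E", n_endoscopic, prev_endo),
        (SURGICAL, "S", n_surgical, prev_surg),
    ):
        if n == 0:
            continue
        n_pos = int(rng.binomial(n, prev)) if binomial else nearest_int(n * prev)
        n_pos = min(n_pos, n)
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=n_pos, replace=False)] = 1
        for i in range(n):
            cohort.append(
                _sample_record(rng, f"{prefix}{i:04d}", stratum, int(labels[i]), informative_covariates)
            )
    return cohort


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in cohort]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def save_cohort(cohort: list[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def load_cohort(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    return [PatientRecord(**{k: row[k] for k in COHORT_COLUMNS}) for _, row in df.iterrows()]


def cohort_summary(cohort: list[PatientRecord], ln_positive: int | None = None,
                   ln_total: int | None = None) -> dict:
    """Prevalence summary plus the lymph-node ratio (positive/retrieved LNs).

    Percentages are rounded half-up: one decimal for prevalences, two for the
    LN ratio, matching clinical-table precision.  Empty cohorts produce a
    defined all-zero summary.
    """
    if ln_positive is not None and ln_total is not None:
        if not 0 <= ln_positive <= ln_total:
            raise ValueError("need ln_total >= ln_positive >= 0")
    out: dict = {"n_patients": len(cohort), "strata": {}}
    for stratum in (ENDOSCOPIC, SURGICAL):
        recs = [r for r in cohort if r.specimen_type == stratum]
        pos = sum(r.lnm_label for r in recs)
        out["strata"][stratum] = {
            "n": len(recs),
            "n_positive": pos,
            "prevalence_pct": round_half_up(100.0 * pos / len(recs), 1) if recs else 0.0,
        }
    total_pos = sum(r.lnm_label for r in cohort)
    out["n_positive"] = total_pos
    out["overall_prevalence_pct"] = (
        round_half_up(100.0 * total_pos / len(cohort), 1) if cohort else 0.0
    )
    if ln_positive is not None and ln_total is not None:
        out["ln_ratio_pct"] = round_half_up(100.0 * ln_positive / ln_total, 2) if ln_total else 0.0
    return out


# ---------------------------------------------------------------------------
# slide rendering


@dataclass
class SlideParams:
    """Generator settings for one synthetic slide raster.

    ``size`` is the square raster edge in pixels; ``patch_size`` is only used
    to validate that at least one patch fits.  Tissue extent ranges encode that
    endoscopic specimens contain only part of the submucosal layer and hence
    less tissue than full-thickness surgical specimens.
    """

    size: int = 2048
    patch_size: int = 256
    evidence_fraction: float = 0.05
    tissue_extent_endoscopic: tuple[float, float] = (0.10, 0.25)
    tissue_extent_surgical: tuple[float, float] = (0.30, 0.60)
    evidence_blob_weights: tuple[float, ...] = (0.65, 0.35)
    # label-irrelevant dark foci (inflammation-like) present in both classes;
    # they share coarse statistics with the evidence texture so that only the
    # finer colour/density signature carries the label
    # every slide spends the same dark-foci "budget" (fraction of tissue area)
    # on salient dark speckle regions; negatives fill it entirely with the
    # label-irrelevant distractor texture, positives with evidence_fraction of
    # evidence texture plus distractor for the remainder.  Total salient area
    # is therefore identically distributed in both classes and only the finer
    # colour/density signature carries the label.
    dark_foci_budget: tuple[float, float] = (0.05, 0.09)


@dataclass
class SyntheticSlide:
    slide_id: str
    patient_id: str
    pixels: np.ndarray  # (S, S, 3) uint8
    evidence_mask: np.ndarray  # (S, S) bool
    tissue_mask: np.ndarray  # (S, S) bool (generator ground truth)
    tissue_extent: float


def _place_disks(rng: np.random.Generator, dist: np.ndarray, total_area: float,
                 weights: tuple[float, ...], S: int) -> np.ndarray:
    """Union of non-overlapping disks of given area weights, placed where the
    tissue distance transform allows the full disk to fit."""
    mask = np.zeros((S, S), dtype=bool)
    centers: list[tuple[int, int, float]] = []
    for w in weights:
        r = max(4.0, np.sqrt(w * total_area / np.pi))
        candidates = np.flatnonzero(dist.ravel() >= r)
        if candidates.size == 0:
            candidates = np.array([int(np.argmax(dist))])
        cy, cx = np.unravel_index(int(rng.choice(candidates)), (S, S))
        for _try in range(30):  # rejection-sample to keep planted area exact
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr) ** 2 for py, px, pr in centers):
                break
            cy, cx = np.unravel_index(int(rng.choice(candidates)), (S, S))
        centers.append((cy, cx, r))
    for cy, cx, r in centers:
        y0, y1 = max(0, int(cy - r) - 1), min(S, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(S, int(cx + r) + 2)
        by, bx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (by - cy) ** 2 + (bx - cx) ** 2 <= r * r
    return mask


def _smooth_field(rng: np.random.Generator, size: int) -> np.ndarray:
    """Low-frequency random field in [~-1, 1] at full resolution (cheap)."""
    base = ndimage.gaussian_filter(rng.standard_normal((64, 64)), 6.0)
    return np.asarray(ndimage.zoom(base, size / 64.0, order=1), dtype=np.float32)


def render_slide(record: PatientRecord, params: SlideParams | None = None,
                 seed: int = 0) -> SyntheticSlide:
    """Render one H&E-like slide for ``record``.

    Background is near-white (low saturation); tissue is a smooth pink blob
    with a low-frequency "normal gland" texture.  For LNM-positive patients a
    fraction ``evidence_fraction`` of the tissue area is overwritten with a
    dense dark-speckle "evidence" texture placed as a few compact disks well
    inside the tissue, and recorded in ``evidence_mask``.
    """
    params = params or SlideParams()
    S = params.size
    if S < params.patch_size:
        raise ValueError(f"raster size {S} smaller than one patch ({params.patch_size})")
    rng = np.random.default_rng(seed)

    lo, hi = (
        params.tissue_extent_endoscopic
        if record.specimen_type == ENDOSCOPIC
        else params.tissue_extent_surgical
    )
    extent = rng.uniform(lo, hi)
    fld = _smooth_field(rng, S)[:S, :S]
    tissue = fld >= np.quantile(fld, 1.0 - extent)

    # per-slide appearance variation emulating stain/scanner variability:
    # overall stain strength, a small colour tint, gland wavelength and the
    # density of scattered dark nuclei all vary from slide to slide
    stain = float(rng.normal(1.0, 0.06))
    tint = rng.normal(0.0, 0.02, size=3).astype(np.float32)
    wavelength = float(rng.uniform(64.0, 160.0))
    nuclei_density = float(rng.uniform(0.002, 0.006))

    img = np.empty((S, S, 3), dtype=np.float32)
    img[:] = 0.96 + float(rng.normal(0.0, 0.01))
    img += rng.normal(0.0, 0.012, size=(S, S, 1)).astype(np.float32)

    yy, xx = np.mgrid[0:S, 0:S].astype(np.float32)
    gland = 0.05 * np.sin(2 * np.pi * xx / wavelength + rng.uniform(0, 2 * np.pi)) * np.sin(
        2 * np.pi * yy / wavelength + rng.uniform(0, 2 * np.pi)
    )
    pink = np.array([0.86, 0.60, 0.74], dtype=np.float32) * stain + tint
    tex = pink[None, None, :] + gland[:, :, None]
    tex += rng.normal(0.0, 0.02, size=(S, S, 1)).astype(np.float32)
    sparse_nuclei = rng.random((S, S)) < nuclei_density
    tex[sparse_nuclei] *= 0.55
    img[tissue] = tex[tissue]

    dist = ndimage.distance_transform_edt(tissue) if tissue.any() else None

    def speckle_texture(base_rgb, dot_density, dot_scale):
        t = np.tile(np.asarray(base_rgb, dtype=np.float32) * stain + tint, (S, S, 1))
        t += rng.normal(0.0, 0.03, size=(S, S, 1)).astype(np.float32)
        t[rng.random((S, S)) < dot_density] *= dot_scale
        return t

    budget = rng.uniform(*params.dark_foci_budget)
    frac = params.evidence_fraction if record.lnm_label == 1 else 0.0
    dfrac = max(0.0, budget - frac)

    # distractor foci: matched to the evidence texture in coarse statistics
    # (dot density, darkness, focal geometry) but a bluer hue; label-irrelevant
    if dist is not None and dfrac > 0:
        dmask = _place_disks(rng, dist, dfrac * tissue.sum(), (0.6, 0.4), S)
        dmask &= tissue
        dtex = speckle_texture([0.42, 0.30, 0.58], rng.uniform(0.28, 0.40), 0.42)
        img[dmask] = dtex[dmask]

    evidence = np.zeros((S, S), dtype=bool)
    if frac > 0 and dist is not None:
        evidence = _place_disks(rng, dist, frac * tissue.sum(),
                                params.evidence_blob_weights, S)
        evidence &= tissue
        # evidence differs from the distractor texture only in hue, by about
        # the magnitude of inter-slide stain variation: learnable from patch
        # supervision, but not a salient axis for an unrefined encoder
        etex = speckle_texture([0.48, 0.24, 0.50], rng.uniform(0.28, 0.40), 0.42)
        img[evidence] = etex[evidence]

    pixels = (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    return SyntheticSlide(
        slide_id=f"{record.patient_id}-W0",
        patient_id=record.patient_id,
        pixels=pixels,
        evidence_mask=evidence,
        tissue_mask=tissue,
        tissue_extent=float(tissue.mean()),
    )


def slide_seed(base_seed: int, index: int) -> int:
    """Stable per-slide child seed below 2**31."""
    return (base_seed * 1_000_003 + 7919 * index + 1) % (2**31)


def iter_slides(cohort: list[PatientRecord], params: SlideParams | None = None,
                seed: int = 0):
    """Yield every slide of the cohort (``n_slides`` per patient), deterministically."""
    idx = 0
    for rec in cohort:
        for k in range(rec.n_slides):
            s = render_slide(rec, params, seed=slide_seed(seed, idx))
            s.slide_id = f"{rec.patient_id}-W{k}"
            yield s
            idx += 1


def write_slides(cohort: list[PatientRecord], outdir: str | Path,
                 params: SlideParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Render all slides to PNG (+ 0/255 evidence-mask PNGs) and return the manifest."""
    outdir = Path(outdir)
    (outdir / "slides").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    by_pid = {r.patient_id: r for r in cohort}
    rows = []
    for s in iter_slides(cohort, params, seed):
        spath = outdir / "slides" / f"{s.slide_id}.png"
        mpath = outdir / "masks" / f"{s.slide_id}.png"
        Image.fromarray(s.pixels).save(spath)
        Image.fromarray((s.evidence_mask * 255).astype(np.uint8)).save(mpath)
        rec = by_pid[s.patient_id]
        rows.append(
            {
                "slide_id": s.slide_id,
                "path": str(spath.relative_to(outdir)),
                "mask_path": str(mpath.relative_to(outdir)),
                "patient_id": s.patient_id,
                "lnm_label": rec.lnm_label,
                "specimen_type": rec.specimen_type,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
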