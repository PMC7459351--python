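"""Synthetic OCTA-like images and CKD-like cohorts with known ground truth.

Two generators make the whole pipeline testable without any clinical data:

* :func:`generate_vessel_image` draws a fovea-centered vascular network —
  bright branching trunk vessels entering from the border, a faint
  interconnecting capillary mesh, a central avascular disc (the FAZ) and
  optional focal nonperfusion lesions of exactly known rasterized area —
  then adds speckle-like texture and quantizes to 8 bits.
* :func:`generate_cohort` draws a case/control cohort whose per-patient
  blood-pressure series (visit counts, within-patient variability) drive
  retinal outcomes through a configurable linear effect model, so partial
  correlations of known size can be planted and recovered.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import norm
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .image import DEFAULT_SCALE_MM_PER_PX, DEFAULT_SIZE_PX, AngiogramImage, Plexus, RegionSpec

__all__ = [
    "ImageSimConfig",
    "ImageGroundTruth",
    "generate_vessel_image",
    "lesion_spec_for_area",
    "CohortSimConfig",
    "CohortGroundTruth",
    "SimulatedCohort",
    "generate_cohort",
    "simulate_partial_corr_data",
]


# ---------------------------------------------------------------------------
# vessel images


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters of the synthetic angiogram generator.

    Lesions are (row_offset_mm, col_offset_mm, radius_mm) relative to the
    image center.  Intensity levels are chosen so that avascular tissue is
    the darkest structure, perfused inter-capillary tissue is intermediate,
    capillaries are faint, and trunk vessels are bright — the ordering the
    multi-pass equalization relies on.
    """

    size_px: int = DEFAULT_SIZE_PX
    scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX
    morphology: str = "branching_SVP"  # or "vortex_DVP"
    faz_area_mm2: float = 0.31
    lesions: tuple[tuple[float, float, float], ...] = ()
    n_trees: int = 8
    capillary_coverage: float = 0.15  # target fraction of pixels on capillaries
    trunk_intensity: float = 230.0
    capillary_intensity: float = 118.0
    perfused_bg: float = 70.0
    perfused_bg_sd: float = 12.0
    avascular_bg: float = 28.0
    avascular_bg_sd: float = 7.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.faz_area_mm2 < 0:
            raise ValueError("faz_area_mm2 must be >= 0")
        half = self.size_px * self.scale_mm_per_px / 2.0
        for dy, dx, r in self.lesions:
            if r <= 0:
                raise ValueError("lesion radius must be positive")
            if abs(dy) + r > half or abs(dx) + r > half:
                raise ValueError("lesion extends outside the image")


@dataclass(frozen=True)
class ImageGroundTruth:
    """Exact rasterized truth accompanying a generated angiogram."""

    vessel_mask: np.ndarray
    avascular_mask: np.ndarray
    faz_mask: np.ndarray
    faz_area_mm2: float
    parafoveal_void_area_mm2: float  # annulus ∩ avascular, FAZ component excluded
    lesion_areas_mm2: tuple[float, ...]  # per lesion, annulus-intersected, FAZ excluded


def _draw_thick_segment(mask: np.ndarray, p0, p1, width: int) -> None:
    n = mask.shape[0]
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    r0, c0 = np.clip(r0, 0, n - 1), np.clip(c0, 0, n - 1)
    r1, c1 = np.clip(r1, 0, n - 1), np.clip(c1, 0, n - 1)
    rr, cc = draw_line(r0, c0, r1, c1)
    mask[rr, cc] = True
    for off in range(1, (width + 1) // 2 + 1):
        for dr, dc in ((off, 0), (-off, 0), (0, off), (0, -off)):
            rr2 = np.clip(rr + dr, 0, n - 1)
            cc2 = np.clip(cc + dc, 0, n - 1)
            if 2 * off <= width:
                mask[rr2, cc2] = True


def _grow_tree(rng, mask, p0, angle, length, width, depth) -> None:
    """Recursive midpoint-displaced branching: one trunk segment, then two
    jittered daughters with reduced length and caliber."""
    if depth <= 0 or length < 6 or width < 1:
        return
    jitter = rng.normal(0.0, 0.25)
    a = angle + jitter
    p1 = (p0[0] + length * np.sin(a), p0[1] + length * np.cos(a))
    _draw_thick_segment(mask, p0, p1, width)
    n_children = 2 if rng.random() < 0.8 else 1
    for _ in range(n_children):
        branch = a + rng.normal(0.0, 0.55)
        _grow_tree(
            rng,
            mask,
            p1,
            branch,
            length * rng.uniform(0.7, 0.9),
            max(width - 1, 1) if rng.random() < 0.5 else width,
            depth - 1,
        )


def _svp_trunks(rng, n_px: int, n_trees: int) -> np.ndarray:
    mask = np.zeros((n_px, n_px), dtype=bool)
    for _ in range(n_trees):
        side = rng.integers(4)
        t = rng.uniform(0.1, 0.9) * n_px
        if side == 0:
            p0, angle = (0.0, t), np.pi / 2  # from top, heading down
        elif side == 1:
            p0, angle = (n_px - 1.0, t), -np.pi / 2
        elif side == 2:
            p0, angle = (t, 0.0), 0.0
        else:
            p0, angle = (t, n_px - 1.0), np.pi
        _grow_tree(rng, mask, p0, angle, length=rng.uniform(30, 45), width=3, depth=6)
    return mask


def _dvp_vortices(rng, n_px: int, n_centers: int = 14) -> np.ndarray:
    """Converging capillary vortices: short arcs spiralling into epicenters."""
    mask = np.zeros((n_px, n_px), dtype=bool)
    for _ in range(n_centers):
        cy, cx = rng.uniform(0.1, 0.9, size=2) * n_px
        for _ in range(18):
            theta = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(10, 40)
            steps = 8
            pts = []
            for s in range(steps + 1):
                rr = r * (1 - 0.85 * s / steps)
                th = theta + 1.8 * s / steps
                pts.append((cy + rr * np.sin(th), cx + rr * np.cos(th)))
            for a, b in zip(pts[:-1], pts[1:]):
                _draw_thick_segment(mask, a, b, 1)
    return mask


def _capillary_mesh(rng, n_px: int, coverage: float) -> np.ndarray:
    """Random short cross-linking capillary segments at a target coverage."""
    mask = np.zeros((n_px, n_px), dtype=bool)
    target = coverage * n_px * n_px
    mean_len = 18.0
    n_seg = int(target / mean_len)
    for _ in range(n_seg):
        p0 = rng.uniform(0, n_px - 1, size=2)
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(10, 26)
        p1 = (p0[0] + length * np.sin(angle), p0[1] + length * np.cos(angle))
        _draw_thick_segment(mask, p0, p1, 1)
    return mask


def generate_vessel_image(cfg: ImageSimConfig) -> tuple[AngiogramImage, ImageGroundTruth]:
    """Draw one synthetic en-face angiogram plus its exact ground truth.

    The FAZ is realized as a central avascular disc whose radius matches the
    configured area target; each lesion removes all vessels inside its disc.
    Ground-truth areas are rasterized pixel counts times scale², with the
    connected avascular component containing the image center booked as FAZ
    and excluded from the parafoveal void total (also when a lesion overlaps
    and merges with it).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.size_px
    scale = cfg.scale_mm_per_px

    if cfg.morphology == "branching_SVP":
        trunks = _svp_trunks(rng, n, cfg.n_trees)
        plexus = Plexus.SVP
    elif cfg.morphology == "vortex_DVP":
        trunks = _dvp_vortices(rng, n)
        plexus = Plexus.DVP
    else:
        raise ValueError(f"unknown morphology {cfg.morphology!r}")
    capillaries = _capillary_mesh(rng, n, cfg.capillary_coverage)

    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    avascular = np.zeros((n, n), dtype=bool)
    if cfg.faz_area_mm2 > 0:
        r_px = np.sqrt(cfg.faz_area_mm2 / np.pi) / scale
        rr, cc = draw_disk(center, r_px, shape=(n, n))
        avascular[rr, cc] = True
    lesion_masks = []
    for dy, dx, r_mm in cfg.lesions:
        lm = np.zeros((n, n), dtype=bool)
        rr, cc = draw_disk(
            (center[0] + dy / scale, center[1] + dx / scale), r_mm / scale, shape=(n, n)
        )
        lm[rr, cc] = True
        lesion_masks.append(lm)
        avascular |= lm

    img = rng.normal(cfg.perfused_bg, cfg.perfused_bg_sd, size=(n, n))
    cap_only = capillaries & ~trunks
    img[cap_only] = rng.normal(cfg.capillary_intensity, 15.0, size=int(cap_only.sum()))
    img[trunks] = rng.normal(cfg.trunk_intensity, 10.0, size=int(trunks.sum()))
    img[avascular] = rng.normal(
        cfg.avascular_bg, cfg.avascular_bg_sd, size=int(avascular.sum())
    )
    img += rng.normal(0.0, cfg.noise_sd, size=(n, n))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    vessel_mask = (trunks | capillaries) & ~avascular

    # ground-truth bookkeeping: FAZ = center-connected avascular component
    labels, _ = ndimage.label(avascular, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    c_lab = labels[int(round(center[0])), int(round(center[1]))]
    faz_mask = labels == c_lab if c_lab > 0 else np.zeros((n, n), dtype=bool)
    region = RegionSpec(center=center)
    annulus = region.annulus_mask((n, n), scale)
    px_area = scale**2
    void_truth = avascular & annulus & ~faz_mask
    lesion_areas = tuple(
        float((lm & annulus & ~faz_mask).sum()) * px_area for lm in lesion_masks
    )
    gt = ImageGroundTruth(
        vessel_mask=vessel_mask,
        avascular_mask=avascular,
        faz_mask=faz_mask,
        faz_area_mm2=float(faz_mask.sum()) * px_area,
        parafoveal_void_area_mm2=float(void_truth.sum()) * px_area,
        lesion_areas_mm2=lesion_areas,
    )
    return AngiogramImage(pixels=pixels, scale_mm_per_px=scale, plexus=plexus), gt


def lesion_spec_for_area(
    area_mm2: float, angle_deg: float = 0.0, center_radius_mm: float = 0.95
) -> tuple[float, float, float]:
    """Lesion (dy, dx, radius) of a given area placed inside the annulus.

    At the default placement radius a disc of up to ~0.6 mm² stays fully
    inside the 0.5–1.5 mm parafoveal annulus and clear of the image border.
    """
    r_mm = float(np.sqrt(area_mm2 / np.pi))
    a = np.deg2rad(angle_deg)
    return (center_radius_mm * np.sin(a), center_radius_mm * np.cos(a), r_mm)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the synthetic case/control cohort.

    BP visits per CKD patient follow a rounded normal clipped at
    ``visit_count_min``; the latent mean is re-centered so the *realized*
    mean visit count matches ``visit_count_mean``.  Retinal outcomes follow
    a linear effect model: the SVP flow-void area loads positively on the
    realized within-patient SD of SBP with planted partial correlation
    ``r_flow_void_sd_sbp``; SVP vessel density loads negatively on the
    realized 1-year maximum SBP with planted partial correlation
    ``r_svp_density_max_sbp``; DVP density carries no BP effect.  Covariate
    effects (age, diabetes) enter every linked outcome so that covariate
    control is exercised.
    """

    n_ckd: int = 256
    n_control: int = 70
    visit_count_mean: float = 8.7
    visit_count_sd: float = 6.1
    visit_count_min: int = 3
    sbp_level_mean: float = 135.0  # distribution of per-patient mean SBP
    sbp_level_sd: float = 16.0
    sbp_sd_mean: float = 14.0  # distribution of per-patient within-SD of SBP
    sbp_sd_sd: float = 6.6
    sbp_sd_min: float = 2.0
    dbp_level_mean: float = 76.0
    dbp_level_sd: float = 11.0
    dbp_sd_mean: float = 7.3
    dbp_sd_sd: float = 3.2
    dbp_sd_min: float = 1.0
    age_mean: float = 62.4
    age_sd: float = 9.9
    control_age_mean: float = 63.0
    control_age_sd: float = 8.9
    male_prop: float = 0.58
    control_male_prop: float = 0.5
    dm_prop: float = 0.43
    axial_mean: float = 23.72
    axial_sd: float = 1.1
    control_axial_mean: float = 23.89
    control_axial_sd: float = 0.9
    iop_mean: float = 15.1
    iop_sd: float = 2.5
    control_iop_mean: float = 15.3
    control_iop_sd: float = 2.4
    svp_density_mean: float = 46.9
    svp_density_sd: float = 4.5
    control_svp_density_mean: float = 49.0
    control_svp_density_sd: float = 3.7
    dvp_density_mean: float = 50.9
    dvp_density_sd: float = 3.9
    control_dvp_density_mean: float = 52.0
    control_dvp_density_sd: float = 3.1
    flow_void_mean: float = 0.307
    flow_void_sd: float = 0.236
    control_flow_void_mean: float = 0.142
    control_flow_void_sd: float = 0.084
    faz_mean: float = 0.329
    faz_sd: float = 0.121
    control_faz_mean: float = 0.312
    control_faz_sd: float = 0.121
    r_flow_void_sd_sbp: float = 0.244  # planted partial correlation
    r_svp_density_max_sbp: float = -0.186
    gamma_age_flow_void: float = 0.002  # mm² per year of age
    gamma_dm_flow_void: float = 0.05  # mm² for diabetics
    gamma_age_svp_density: float = -0.08  # % per year of age
    gamma_dm_svp_density: float = -1.5  # % for diabetics
    enrollment_date: date = date(2019, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("visit_count_sd", "sbp_level_sd", "sbp_sd_sd", "dbp_level_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        k_covariates = 5
        if min(self.n_ckd, self.n_control) < k_covariates + 3:
            raise ValueError("group sizes must exceed the covariate count + 2")
        if not -1 < self.r_flow_void_sd_sbp < 1:
            raise ValueError("planted partial correlations must lie in (-1, 1)")


@dataclass(frozen=True)
class CohortGroundTruth:
    """Generator bookkeeping for round-trip and recovery tests."""

    mu_sbp: np.ndarray  # per-CKD-patient latent mean SBP
    sigma_sbp: np.ndarray  # per-CKD-patient latent within-SD of SBP
    n_visits: np.ndarray
    eligible: np.ndarray  # n_visits >= 3
    bp_features: pd.DataFrame  # generator's own feature computation
    beta_flow_void: float
    beta_svp_density: float
    r_flow_void_sd_sbp: float
    r_svp_density_max_sbp: float


@dataclass(frozen=True)
class SimulatedCohort:
    table: pd.DataFrame  # one row per patient: covariates, outcomes, features
    bp_series: list  # BPSeries for every CKD patient (incl. ineligible)
    ground_truth: CohortGroundTruth


def _latent_visit_mean(target_mean: float, sd: float, vmin: int) -> float:
    """Latent normal mean such that E[max(vmin, N(mu, sd))] = target."""

    if sd == 0:
        return max(target_mean, float(vmin))

    def clipped_mean(mu):
        z = (vmin - mu) / sd
        return vmin * norm.cdf(z) + mu * norm.sf(z) + sd * norm.pdf(z)

    if clipped_mean(target_mean) <= target_mean:  # no clipping bias
        return target_mean
    return float(
        optimize.brentq(lambda m: clipped_mean(m) - target_mean, target_mean - 6 * sd, target_mean)
    )


def generate_cohort(cfg: CohortSimConfig = CohortSimConfig()) -> SimulatedCohort:
    """Draw a full case/control cohort with planted BP→microvasculature effects.

    Returns the per-patient table (covariates, 1-year BP features for CKD
    patients, retinal outcomes), the raw visit series, and the generator's
    own bookkeeping.  Patients with fewer than 3 in-window visits (possible
    when ``visit_count_min < 3``) are generated but flagged ineligible.
    """
    from .bp import BPSeries, BPVisit  # local import to avoid cycle at module load

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_ckd

    mu_lat = _latent_visit_mean(cfg.visit_count_mean, cfg.visit_count_sd, cfg.visit_count_min)
    n_visits = np.maximum(
        cfg.visit_count_min, np.rint(rng.normal(mu_lat, cfg.visit_count_sd, n))
    ).astype(int)
    mu_sbp = rng.normal(cfg.sbp_level_mean, cfg.sbp_level_sd, n)
    sig_sbp = np.maximum(cfg.sbp_sd_min, rng.normal(cfg.sbp_sd_mean, cfg.sbp_sd_sd, n))
    mu_dbp = rng.normal(cfg.dbp_level_mean, cfg.dbp_level_sd, n)
    sig_dbp = np.maximum(cfg.dbp_sd_min, rng.normal(cfg.dbp_sd_mean, cfg.dbp_sd_sd, n))

    series_list = []
    feat_rows = []
    for i in range(n):
        m = n_visits[i]
        # day offsets sorted descending so visit dates (and value arrays) run
        # in ascending date order, matching the feature module's ordering
        days = np.sort(rng.choice(np.arange(1, 365), size=min(m, 364), replace=False))[::-1]
        sbp = np.clip(np.rint(rng.normal(mu_sbp[i], sig_sbp[i], len(days))), 80, 250)
        dbp = np.clip(np.rint(rng.normal(mu_dbp[i], sig_dbp[i], len(days))), 40, 150)
        dbp = np.minimum(dbp, sbp - 5)
        sbp_e = float(np.clip(np.rint(rng.normal(mu_sbp[i], sig_sbp[i])), 80, 250))
        dbp_e = float(
            min(np.clip(np.rint(rng.normal(mu_dbp[i], sig_dbp[i])), 40, 150), sbp_e - 5)
        )
        pid = f"ckd{i:04d}"
        visits = [
            BPVisit(date=cfg.enrollment_date - timedelta(days=int(d)), sbp=int(s), dbp=int(b))
            for d, s, b in zip(days, sbp, dbp)
        ]
        visits.append(BPVisit(date=cfg.enrollment_date, sbp=int(sbp_e), dbp=int(dbp_e)))
        series_list.append(
            BPSeries(patient_id=pid, enrollment_date=cfg.enrollment_date, visits=tuple(visits))
        )
        # generator's own feature bookkeeping, from the date-sorted in-window values
        sbp_sorted = sbp.astype(float)  # days already sorted ascending
        dbp_sorted = dbp.astype(float)
        feat_rows.append(
            {
                "patient_id": pid,
                "n_measurements": len(days),
                "avg_sbp": float(np.mean(sbp_sorted)),
                "avg_dbp": float(np.mean(dbp_sorted)),
                "max_sbp": float(np.max(sbp_sorted)),
                "max_dbp": float(np.max(dbp_sorted)),
                "sd_sbp": float(np.std(sbp_sorted, ddof=1)) if len(days) > 1 else 0.0,
                "sd_dbp": float(np.std(dbp_sorted, ddof=1)) if len(days) > 1 else 0.0,
                "prop_high_sbp": float(np.mean(sbp_sorted > 140)),
                "sbp_enroll": sbp_e,
                "dbp_enroll": dbp_e,
            }
        )
    feats = pd.DataFrame(feat_rows)

    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    male = (rng.random(n) < cfg.male_prop).astype(int)
    dm = (rng.random(n) < cfg.dm_prop).astype(int)
    axial = rng.normal(cfg.axial_mean, cfg.axial_sd, n)
    iop = rng.normal(cfg.iop_mean, cfg.iop_sd, n)
    covs = np.column_stack([age, male, dm, axial, iop])
    design = np.column_stack([np.ones(n), covs])

    def _beta_and_noise(x: np.ndarray, r: float, target_sd: float, gamma_var: float):
        """Effect size and noise SD planting partial correlation r while
        keeping the total outcome SD near its target."""
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        x_res = x - design @ coef
        sd_x_res = float(np.std(x_res, ddof=1))
        var_avail = max(target_sd**2 - gamma_var, 0.25 * target_sd**2)
        beta = r * np.sqrt(var_avail) / sd_x_res
        sd_eps = float(np.sqrt((1.0 - r**2) * var_avail))
        return beta, sd_eps

    x_sd = feats["sd_sbp"].to_numpy()
    x_max = feats["max_sbp"].to_numpy()
    gv_fv = (cfg.gamma_age_flow_void * cfg.age_sd) ** 2 + cfg.gamma_dm_flow_void**2 * (
        cfg.dm_prop * (1 - cfg.dm_prop)
    )
    gv_d = (cfg.gamma_age_svp_density * cfg.age_sd) ** 2 + cfg.gamma_dm_svp_density**2 * (
        cfg.dm_prop * (1 - cfg.dm_prop)
    )
    beta_fv, sd_eps_fv = _beta_and_noise(x_sd, cfg.r_flow_void_sd_sbp, cfg.flow_void_sd, gv_fv)
    beta_d, sd_eps_d = _beta_and_noise(
        x_max, cfg.r_svp_density_max_sbp, cfg.svp_density_sd, gv_d
    )

    flow_void = (
        cfg.flow_void_mean
        + beta_fv * (x_sd - x_sd.mean())
        + cfg.gamma_age_flow_void * (age - age.mean())
        + cfg.gamma_dm_flow_void * (dm - dm.mean())
        + rng.normal(0.0, sd_eps_fv, n)
    )
    svp_density = (
        cfg.svp_density_mean
        + beta_d * (x_max - x_max.mean())
        + cfg.gamma_age_svp_density * (age - age.mean())
        + cfg.gamma_dm_svp_density * (dm - dm.mean())
        + rng.normal(0.0, sd_eps_d, n)
    )
    dvp_density = rng.normal(cfg.dvp_density_mean, cfg.dvp_density_sd, n)
    faz = rng.normal(cfg.faz_mean, cfg.faz_sd, n)

    ckd = pd.DataFrame(
        {
            "patient_id": feats["patient_id"],
            "group": "CKD",
            "age": age,
            "male": male,
            "dm": dm,
            "axial_length": axial,
            "iop": iop,
            "svp_density": svp_density,
            "dvp_density": dvp_density,
            "flow_void_area": flow_void,
            "faz_area": faz,
        }
    ).join(feats.drop(columns=["patient_id"]))

    m = cfg.n_control
    ctrl = pd.DataFrame(
        {
            "patient_id": [f"ctl{i:04d}" for i in range(m)],
            "group": "control",
            "age": rng.normal(cfg.control_age_mean, cfg.control_age_sd, m),
            "male": (rng.random(m) < cfg.control_male_prop).astype(int),
            "dm": np.zeros(m, dtype=int),
            "axial_length": rng.normal(cfg.control_axial_mean, cfg.control_axial_sd, m),
            "iop": rng.normal(cfg.control_iop_mean, cfg.control_iop_sd, m),
            "svp_density": rng.normal(
                cfg.control_svp_density_mean, cfg.control_svp_density_sd, m
            ),
            "dvp_density": rng.normal(
                cfg.control_dvp_density_mean, cfg.control_dvp_density_sd, m
            ),
            "flow_void_area": np.maximum(
                0.0, rng.normal(cfg.control_flow_void_mean, cfg.control_flow_void_sd, m)
            ),
            "faz_area": rng.normal(cfg.control_faz_mean, cfg.control_faz_sd, m),
            "sbp_enroll": np.rint(rng.normal(134, 16, m)),
            "dbp_enroll": np.rint(rng.normal(75, 10, m)),
        }
    )
    table = pd.concat([ckd, ctrl], ignore_index=True)

    gt = CohortGroundTruth(
        mu_sbp=mu_sbp,
        sigma_sbp=sig_sbp,
        n_visits=feats["n_measurements"].to_numpy(),
        eligible=feats["n_measurements"].to_numpy() >= 3,
        bp_features=feats,
        beta_flow_void=float(beta_fv),
        beta_svp_density=float(beta_d),
        r_flow_void_sd_sbp=cfg.r_flow_void_sd_sbp,
        r_svp_density_max_sbp=cfg.r_svp_density_max_sbp,
    )
    return SimulatedCohort(table=table, bp_series=series_list, ground_truth=gt)


def simulate_partial_corr_data(
    n: int, k: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x, y, Z) whose population partial correlation given Z is exactly rho.

    x and y share a bivariate-normal core with correlation rho; independent
    linear loadings on the k standard-normal covariates are added to both,
    which leaves the partial (but not the marginal) correlation at rho.
    """
    z = rng.standard_normal((n, k))
    core = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    bx = rng.uniform(-0.5, 0.5, k)
    by = rng.uniform(-0.5, 0.5, k)
    return core[:, 0] + z @ bx, core[:, 1] + z @ by, z
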