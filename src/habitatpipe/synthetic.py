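"""Seeded synthetic CT cohorts with planted habitat / peritumoral / clinical structure.

The generator emulates the data a portal-venous-phase liver-CT response study
assumes, so that every downstream stage (habitat clustering, shell geometry,
radiomics, selection, modeling, survival) is testable without patient data:

* a liver with Normal(100, 15) HU background, fully inside the standard liver
  window (level 45, width 200);
* a hypodense ellipsoidal tumor whose voxels split into ``n_habitats_true``
  concentric (or sectoral) subpopulations with distinct mean HU and
  Gaussian-random-field texture;
* a peritumoral rim whose texture amplitude carries a per-patient latent score
  that enters the response model, so rim texture differs between responders
  and non-responders when ``rim_effect_size`` is nonzero;
* serum AFP (log-normal) with a log-odds effect on response;
* a binary objective-response (ORR) label from a logistic model in
  (standardized log-AFP, rim score, habitat-2 score), with the intercept
  calibrated to ``orr_prevalence``;
* exponential progression-free survival with the non-responder hazard
  multiplied by ``hazard_ratio_highrisk``, plus independent uniform censoring.

Everything is generated on an isotropic 1 mm grid and is bitwise deterministic
given the spec (one ``SeedSequence`` child per patient).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .imaging import CTVolume, RegionMask, write_nifti

__all__ = ["SyntheticCohortSpec", "SyntheticPatient", "generate_cohort", "write_cohort"]

CLINICAL_COLUMNS = [
    "patient_id", "center", "Age", "Gender", "BMI", "ECOG", "Child_Pugh",
    "BCLC", "Tumor_size_cm", "AFP", "ALB", "PLT", "ORR", "PFS_months",
    "PFS_event",
]


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    ``rim_effect_size``, ``afp_effect`` and ``habitat_effect_size`` are
    log-odds coefficients of the (unit-variance) latent rim score, the
    standardized log-AFP and the latent habitat-2 score in the response model;
    0 means no effect. The realized standardized mean difference of the rim
    texture score between classes is a monotone function of
    ``rim_effect_size`` (≈ 0.6 × the coefficient at the defaults).
    """

    n_patients: int = 40
    seed: int = 0
    image_shape_mm: tuple[float, float, float] = (48.0, 48.0, 48.0)
    tumor_radius_range_mm: tuple[float, float] = (8.0, 12.0)
    n_habitats_true: int = 3
    habitat_mean_hu: tuple[float, ...] = (30.0, 65.0, 100.0)
    habitat_texture_scale: tuple[float, ...] = (5.0, 3.0, 1.5)
    habitat_sd_hu: float = 10.0
    rim_effect_size: float = 1.5
    afp_effect: float = -0.8
    habitat_effect_size: float = 1.0
    orr_prevalence: float = 0.52
    hazard_ratio_highrisk: float = 2.0
    censor_rate: float = 0.25
    median_pfs_responder_months: float = 11.0
    geometry: str = "concentric"  # or "sectoral"
    habitat_radial_cuts: tuple[float, ...] | None = None  # ρ cut points; None = equal volumes
    boundary_softness_mm: float = 1.0  # partial-volume transition width
    center: int = 1

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_habitats_true < 1:
            raise ValueError("n_habitats_true must be >= 1")
        if len(self.habitat_mean_hu) != self.n_habitats_true:
            raise ValueError("habitat_mean_hu length must equal n_habitats_true")
        if len(self.habitat_texture_scale) != self.n_habitats_true:
            raise ValueError("habitat_texture_scale length must equal n_habitats_true")
        if not (0.0 < self.orr_prevalence < 1.0):
            raise ValueError("orr_prevalence must lie strictly in (0, 1)")
        if any(s <= 0 for s in self.image_shape_mm):
            raise ValueError(f"image_shape_mm must be positive, got {self.image_shape_mm}")
        lo, hi = self.tumor_radius_range_mm
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid tumor radius range {self.tumor_radius_range_mm}")
        if hi >= min(self.image_shape_mm) / 2 - 4:
            raise ValueError("tumor radius too large for the image: no room for liver margin")
        if self.geometry not in ("concentric", "sectoral"):
            raise ValueError(f"geometry must be 'concentric' or 'sectoral', got {self.geometry!r}")


@dataclass
class SyntheticPatient:
    patient_id: str
    center: int
    volume: CTVolume
    tumor_mask: RegionMask
    liver_mask: RegionMask
    exclusion_mask: RegionMask
    true_habitat_labels: np.ndarray
    afp: float
    orr_label: int
    pfs_time: float
    pfs_event: int
    clinical: dict = field(default_factory=dict)
    latent: dict = field(default_factory=dict)


def _grf(rng: np.random.Generator, shape, scale_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field, correlation length ``scale_mm``."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=max(scale_mm, 1e-6))
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return rho2 <= 1.0


def _habitat_labels(shape, center, radii, k, geometry, tumor,
                    radial_cuts=None) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    labels = np.zeros(shape, dtype=np.int16)
    if geometry == "concentric":
        rho = np.sqrt(sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)))
        if radial_cuts is None:
            # cut points give equal sub-volumes of the ellipsoid
            cuts = ((np.arange(1, k + 1) / k) ** (1.0 / 3.0))
        else:
            cuts = np.concatenate([np.asarray(radial_cuts, dtype=float), [1.0]])
        lab = np.minimum(np.searchsorted(cuts, rho, side="left") + 1, k)
        labels = np.where(tumor, lab, 0).astype(np.int16)
    else:  # sectoral: equal angular sectors in the x-y plane
        x = np.arange(shape[0])[:, None, None] - center[0]
        y = np.arange(shape[1])[None, :, None] - center[1]
        theta = np.arctan2(np.broadcast_to(y, shape), np.broadcast_to(x, shape))
        sector = np.floor((theta + np.pi) / (2 * np.pi) * k).astype(np.int16) + 1
        labels = np.where(tumor, np.minimum(sector, k), 0).astype(np.int16)
    return labels


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept b0 with mean(sigmoid(b0 + eta)) == prevalence."""

    def f(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta))))) - prevalence

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def generate_cohort(spec: SyntheticCohortSpec) -> list[SyntheticPatient]:
    """Generate a deterministic cohort of :class:`SyntheticPatient`.

    Latent scores and covariates for all patients are drawn first so the
    response-model intercept can be calibrated to ``orr_prevalence`` on the
    realized linear predictors; images are then rendered per patient from
    independent seed streams.
    """
    ss = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    n = spec.n_patients

    z_rim = cohort_rng.standard_normal(n)
    z_h2 = cohort_rng.standard_normal(n)
    log_afp = cohort_rng.normal(np.log(200.0), 1.2, size=n)
    z_afp = (log_afp - np.log(200.0)) / 1.2

    eta = (
        spec.afp_effect * z_afp
        + spec.rim_effect_size * z_rim
        + spec.habitat_effect_size * z_h2
    )
    b0 = _calibrate_intercept(eta, spec.orr_prevalence)
    p_resp = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    orr = (cohort_rng.uniform(size=n) < p_resp).astype(int)

    # survival: exponential PFS, non-responders at hazard_ratio_highrisk
    lam_r = np.log(2.0) / spec.median_pfs_responder_months
    lam = np.where(orr == 1, lam_r, lam_r * spec.hazard_ratio_highrisk)
    t_event = cohort_rng.exponential(1.0 / lam)
    censored = cohort_rng.uniform(size=n) < spec.censor_rate
    u = cohort_rng.uniform(size=n)
    pfs_time = np.where(censored, np.maximum(u * t_event, 1e-3), t_event)
    pfs_event = (~censored).astype(int)

    # outcome-independent clinical covariates (baseline-table noise)
    age = cohort_rng.normal(56.0, 11.0, size=n)
    bmi = cohort_rng.normal(23.0, 3.5, size=n)
    gender = (cohort_rng.uniform(size=n) < 0.88).astype(int)  # 1 = male
    ecog = (cohort_rng.uniform(size=n) < 0.75).astype(int)  # 1 = ECOG 1
    child = (cohort_rng.uniform(size=n) < 0.18).astype(int)  # 1 = grade B
    bclc = (cohort_rng.uniform(size=n) < 0.65).astype(int)  # 1 = stage C
    alb = cohort_rng.normal(38.0, 5.0, size=n)
    plt_ = cohort_rng.normal(160.0, 75.0, size=n).clip(30, None)

    shape = tuple(int(round(s)) for s in spec.image_shape_mm)  # 1 mm grid
    patient_seeds = ss.spawn(n + 1)[1:]
    patients: list[SyntheticPatient] = []
    for i in range(n):
        rng = np.random.default_rng(patient_seeds[i])
        center_vox = tuple((s - 1) / 2.0 + rng.uniform(-1.5, 1.5) for s in shape)
        lo, hi = spec.tumor_radius_range_mm
        radii = rng.uniform(lo, hi, size=3)

        liver = _ellipsoid(shape, tuple((s - 1) / 2.0 for s in shape),
                           tuple(s / 2.0 - 1.5 for s in shape))
        tumor = _ellipsoid(shape, center_vox, radii)
        tumor &= liver
        labels = _habitat_labels(shape, center_vox, radii, spec.n_habitats_true,
                                 spec.geometry, tumor, spec.habitat_radial_cuts)

        # regions: (mask, mean HU, noise SD, correlation length). Means are
        # assembled then blurred (sigma 1 mm) to emulate CT partial-volume
        # softening; noise fields are cross-faded with the blurred indicators.
        dist = ndimage.distance_transform_edt(~tumor, sampling=(1.0, 1.0, 1.0))
        rim = (dist > 0) & (dist <= 3.0) & liver
        rim_sd = 15.0 * np.exp(0.3 * z_rim[i])
        regions = [(~liver, 30.0, 12.0, 1.0),
                   (liver & ~rim & ~tumor, 100.0, 15.0, 1.0),
                   (rim, 100.0, rim_sd, 1.0)]
        for h in range(1, spec.n_habitats_true + 1):
            mean_h = spec.habitat_mean_hu[h - 1]
            if h == 2 and spec.n_habitats_true >= 2:
                mean_h = mean_h + 6.0 * z_h2[i]
            regions.append((labels == h, mean_h, spec.habitat_sd_hu,
                            spec.habitat_texture_scale[h - 1]))
        soft = max(spec.boundary_softness_mm, 1e-6)
        mean_map = np.zeros(shape)
        vol = np.zeros(shape)
        for mask, mean_r, sd_r, scale_r in regions:
            mean_map += mean_r * mask
            weight = ndimage.gaussian_filter(mask.astype(np.float64), soft)
            vol += weight * sd_r * _grf(rng, shape, scale_r)
        vol += ndimage.gaussian_filter(mean_map, soft)

        # a vessel-like exclusion cylinder through the liver, clear of the tumor
        xs = np.arange(shape[0])[:, None, None]
        ys = np.arange(shape[1])[None, :, None]
        r_off = max(radii) + 5.0
        cyl = ((xs - (center_vox[0] + r_off)) ** 2 + (ys - center_vox[1]) ** 2) <= 2.0 ** 2
        exclusion = np.broadcast_to(cyl, shape) & liver & ~tumor

        spacing = (1.0, 1.0, 1.0)
        patients.append(SyntheticPatient(
            patient_id=f"C{spec.center}P{i:04d}",
            center=spec.center,
            volume=CTVolume(vol, spacing),
            tumor_mask=RegionMask(tumor, spacing),
            liver_mask=RegionMask(liver, spacing),
            exclusion_mask=RegionMask(exclusion, spacing),
            true_habitat_labels=labels,
            afp=float(np.exp(log_afp[i])),
            orr_label=int(orr[i]),
            pfs_time=float(pfs_time[i]),
            pfs_event=int(pfs_event[i]),
            clinical={
                "Age": float(age[i]), "Gender": int(gender[i]), "BMI": float(bmi[i]),
                "ECOG": int(ecog[i]), "Child_Pugh": int(child[i]), "BCLC": int(bclc[i]),
                "Tumor_size_cm": float(2 * np.mean(radii) / 10.0),
                "AFP": float(np.exp(log_afp[i])), "ALB": float(alb[i]),
                "PLT": float(plt_[i]),
            },
            latent={"z_rim": float(z_rim[i]), "z_h2": float(z_h2[i]),
                    "p_response": float(p_resp[i])},
        ))
    return patients


def cohort_table(patients: list[SyntheticPatient]):
    """Clinical covariates + labels as a pandas DataFrame (CohortTable)."""
    import pandas as pd

    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id, "center": p.center}
        row.update(p.clinical)
        row.update({"ORR": p.orr_label, "PFS_months": p.pfs_time,
                    "PFS_event": p.pfs_event})
        rows.append(row)
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


def write_spec(spec: SyntheticCohortSpec, path) -> str:
    """Serialize a cohort spec as YAML (tuples stored as lists)."""
    import yaml
    from dataclasses import asdict

    raw = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(spec).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
    return str(path)


def read_spec(path) -> SyntheticCohortSpec:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for k, v in raw.items():
        if isinstance(v, list):
            raw[k] = tuple(v)
    return SyntheticCohortSpec(**raw)


def write_cohort(patients: list[SyntheticPatient], directory,
                 spec: SyntheticCohortSpec | None = None) -> str:
    """Write NIfTI images/masks, the clinical CSV and a manifest CSV.

    Returns the manifest path. Round-trips losslessly through
    :func:`habitatpipe.imaging.read_nifti` (volumes stored as float32).
    When ``spec`` is given it is serialized alongside as ``spec.yaml``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if spec is not None:
        write_spec(spec, directory / "spec.yaml")
    manifest_path = directory / "manifest.csv"
    clin = cohort_table(patients)
    clin.to_csv(directory / "clinical.csv", index=False)

    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "ct", "tumor", "liver", "exclusion", "habitats"])
        for p in patients:
            paths = {}
            for key, obj in [
                ("ct", p.volume), ("tumor", p.tumor_mask), ("liver", p.liver_mask),
                ("exclusion", p.exclusion_mask),
            ]:
                path = directory / f"{p.patient_id}_{key}.nii.gz"
                write_nifti(obj, path)
                paths[key] = path.name
            hab_path = directory / f"{p.patient_id}_habitats.nii.gz"
            write_nifti(
                CTVolume(p.true_habitat_labels.astype(np.float64),
                         p.volume.spacing, p.volume.origin),
                hab_path,
            )
            writer.writerow([p.patient_id, paths["ct"], paths["tumor"],
                             paths["liver"], paths["exclusion"], hab_path.name])
    return str(manifest_path)
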