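"""Two-center synthetic tumor-phantom cohort with planted subregional signal.

The generator emulates the structure of a dual-center gastric-GIST study:
two classes (mitotic index <=5 vs >5), center sizes 239 and 129 with class
splits 195/44 and 108/21, tumors 2-5 cm. Each phantom is a (possibly
rotated) superellipsoid with three nested intensity components — a dense
outer shell, an intermediate shell, and a hypodense core — so that
intensity clustering has a well-defined ground truth. Class-dependent
effects are planted in three latent parameters:

* ``core_fraction`` — volume share of the hypodense core (larger in the
  high-mitotic class, emulating necrosis/cystic change);
* ``skewness_target`` — asymmetry of the core's intensity distribution
  (left-skewed in the high class);
* ``flatness_target`` — least/largest principal-axis ratio (high-class
  lesions are more flattened).

The venous phase shares the geometry but adds a smooth enhancement field
that partially homogenizes the core, attenuating the subregional signal —
contrast enhancement can mask intratumoral heterogeneity.

Intensities are abstract z-score-like units, not Hounsfield units; the
pipeline z-normalizes every volume anyway. Clinical covariates are drawn
from class/center-conditional marginals (no between-covariate correlation).
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .habitat import SubregionLabelMap
from .volume import ImageVolume, TumorMask, save_nifti

__all__ = [
    "PhantomSpec",
    "ClinicalRecord",
    "CohortConfig",
    "PhantomCase",
    "CohortManifest",
    "DegeneratePhantomError",
    "generate_phantom",
    "sample_clinical",
    "sample_phantom_spec",
    "build_cohort",
    "generate_cohort",
    "clairvoyant_auc",
    "design_auc",
]


class DegeneratePhantomError(ValueError):
    """Spacing incompatible with the requested diameter (mask < 100 voxels)."""


PHASES = ("unenhanced", "venous")


# component mean intensities (abstract units), density-descending.
# Outer and intermediate shells share the remaining volume equally, so a
# core-free tumor has a symmetric (zero-skew) intensity mixture and the
# within-mask skewness magnitude grows monotonically with core_fraction.
MU_OUTER, MU_MIDDLE, MU_CORE = 1.10, 0.65, 0.45
COMPONENT_SD = 0.18
ENHANCEMENT = 0.90           # venous-phase additive enhancement inside the tumor
HOMOGENIZATION = 0.55        # fraction of the core signal pulled toward the middle shell
PERFUSION_AMPLITUDE = 0.25   # smooth venous perfusion-heterogeneity field
VENOUS_NOISE_FACTOR = 1.15


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one phantom; deterministic given ``seed``."""

    diameter_mm: float
    class_label: str                     # "low" | "high" mitotic class
    core_fraction: float = 0.15
    skewness_target: float = 0.0         # skewness of the core intensity component
    flatness_target: float = 0.75        # least/largest semi-axis ratio, in (0, 1]
    noise_sd: float = 0.12
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    # secondary geometry (defaults give an axis-aligned ellipsoid)
    b_ratio: float | None = None         # middle/largest semi-axis; None -> (1+flatness)/2
    exponent: float = 2.0                # superellipsoid exponent (2 = ellipsoid)
    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # per-case biological variability: offsets of the three component mean
    # densities (outer, middle, core). Location shifts corrupt whole-tumor
    # histogram features but leave the core's skewness untouched.
    mu_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 20.0 <= self.diameter_mm <= 50.0:
            raise ValueError("diameter_mm must be in [20, 50] (2-5 cm inclusion rule)")
        if self.class_label not in ("low", "high"):
            raise ValueError("class_label must be 'low' or 'high'")
        if not 0.0 <= self.core_fraction < 1.0:
            raise ValueError("core_fraction must be in [0, 1)")
        if not 0.0 < self.flatness_target <= 1.0:
            raise ValueError("flatness_target must be in (0, 1]")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")


def _component_labels(spec: PhantomSpec):
    """Voxel grid, mask and truth component labels for a spec's geometry."""
    a = spec.diameter_mm / 2.0
    flat = spec.flatness_target
    b = a * (spec.b_ratio if spec.b_ratio is not None else (1.0 + flat) / 2.0)
    c = a * flat
    sp = np.asarray(spec.spacing_mm, dtype=float)
    margin = 6
    shape = tuple(int(np.ceil(2.0 * a / s)) + 2 * margin for s in sp)
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, sp)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz])
    if any(abs(e) > 1e-12 for e in spec.euler_deg):
        rot = Rotation.from_euler("xyz", spec.euler_deg, degrees=True).as_matrix()
        pts = np.einsum("ij,jabc->iabc", rot.T, pts)
    e = spec.exponent
    rho = (
        np.abs(pts[0] / a) ** e + np.abs(pts[1] / b) ** e + np.abs(pts[2] / c) ** e
    ) ** (1.0 / e)
    mask = rho <= 1.0
    if mask.sum() < 100:
        raise DegeneratePhantomError(
            f"mask has {int(mask.sum())} voxels (<100) for spacing {spec.spacing_mm}"
        )
    # nested similar shapes: volume scales as t^3 in the radial coordinate;
    # outer and intermediate shells split the non-core volume equally
    cf = spec.core_fraction
    t_core = cf ** (1.0 / 3.0)
    t_mid = ((1.0 + cf) / 2.0) ** (1.0 / 3.0)
    truth = np.zeros(shape, dtype=np.int16)
    truth[mask] = 1                                   # dense outer shell
    truth[mask & (rho <= t_mid)] = 2                  # intermediate shell
    if cf > 0:
        truth[mask & (rho <= t_core)] = 3             # hypodense core
    return mask, truth


CLIP_SD = 2.5  # tissue densities are bounded; same bound for every class


def _skewed_draws(rng: np.random.Generator, n: int, skew: float) -> np.ndarray:
    """Draws with the requested skewness (gamma-based), clipped to +-2.5 SD.

    The clip bound is identical for all skewness values, so the planted
    class effect lives in the distribution's asymmetry (third moment), not
    in its extremes or range.
    """
    if abs(skew) < 1e-8:
        draws = rng.standard_normal(n)
    else:
        k = (2.0 / abs(skew)) ** 2  # gamma(k) has skewness 2/sqrt(k)
        g = rng.gamma(k, 1.0, size=n)
        draws = np.sign(skew) * (g - k) / np.sqrt(k)
    return np.clip(draws, -CLIP_SD, CLIP_SD)


def _smooth_within(base: np.ndarray, inside: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that does not mix across the mask boundary.

    Normalized convolution applied separately inside and outside the mask,
    so boundary voxels are not dragged toward the (dark) background — which
    would otherwise plant a spurious left tail in every mask histogram.
    """
    m = inside.astype(np.float64)
    num_in = gaussian_filter(base * m, sigma=sigma)
    den_in = gaussian_filter(m, sigma=sigma)
    num_all = gaussian_filter(base, sigma=sigma)
    out = np.empty_like(base)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[inside] = (num_in / den_in)[inside]
        out[~inside] = ((num_all - num_in) / (1.0 - den_in))[~inside]
    return np.nan_to_num(out)


def generate_phantom(spec: PhantomSpec, phases: tuple[str, ...] = PHASES):
    """Generate one phantom: (unenhanced, venous, mask, truth).

    ``truth`` records which intensity component every tumor voxel was drawn
    from, density-descending (1 = dense shell, 2 = intermediate, 3 = core);
    its centroids are the empirical mean unit-rescaled unenhanced
    intensities per component. Identical specs give bit-identical output;
    a phase omitted from ``phases`` is returned as None (the random stream
    for each phase is independent, so the others are unaffected).
    """
    comp_seed, unenh_seed, venous_seed = np.random.SeedSequence(spec.seed).spawn(3)
    rng = np.random.default_rng(comp_seed)
    mask, truth = _component_labels(spec)
    shape = mask.shape

    off = spec.mu_offsets
    mu_core = MU_CORE + off[2]
    base = rng.normal(0.0, 0.25, size=shape)          # soft-tissue background
    for lbl, mu in ((1, MU_OUTER + off[0]), (2, MU_MIDDLE + off[1])):
        sel = truth == lbl
        base[sel] = mu + COMPONENT_SD * _skewed_draws(rng, int(sel.sum()), 0.0)
    core = truth == 3
    n_core = int(core.sum())
    if n_core:
        base[core] = mu_core + COMPONENT_SD * _skewed_draws(rng, n_core, spec.skewness_target)

    unenh = venous = None
    if "unenhanced" in phases:
        u_rng = np.random.default_rng(unenh_seed)
        unenh = _smooth_within(base, mask, 0.5) + u_rng.normal(0.0, spec.noise_sd, size=shape)
    if "venous" in phases:
        v_rng = np.random.default_rng(venous_seed)
        base_v = base.copy()
        base_v[mask] += ENHANCEMENT
        if n_core:  # enhancement partially homogenizes the hypodense core
            base_v[core] = (
                ENHANCEMENT
                + (1.0 - HOMOGENIZATION) * base[core]
                + HOMOGENIZATION * (MU_MIDDLE + off[1])
            )
        perfusion = PERFUSION_AMPLITUDE * gaussian_filter(
            v_rng.standard_normal(shape), sigma=4.0
        )
        venous = (
            _smooth_within(base_v + perfusion, mask, 0.5)
            + v_rng.normal(0.0, spec.noise_sd * VENOUS_NOISE_FACTOR, size=shape)
        )

    spacing = spec.spacing_mm
    labels_present = sorted(int(v) for v in np.unique(truth[mask]))
    ref = unenh if unenh is not None else venous
    inroi = ref[mask]
    lo, hi = inroi.min(), inroi.max()
    rescaled = (ref - lo) / (hi - lo) if hi > lo else np.zeros_like(ref)
    centroids = np.array([rescaled[truth == l].mean() for l in labels_present])
    order = np.argsort(-centroids, kind="stable")
    truth_map = SubregionLabelMap(
        labels=truth,
        centroids=centroids[order],
        n=len(labels_present),
    )
    return (
        ImageVolume(unenh, spacing) if unenh is not None else None,
        ImageVolume(venous, spacing) if venous is not None else None,
        TumorMask(mask.astype(np.uint8), spacing),
        truth_map,
    )


# --------------------------------------------------------------------------
# clinical covariates: class/center-conditional marginals
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalRecord:
    center: int
    sex: str                      # "M" | "F"
    age: float                    # years
    bmi: float                    # kg/m^2
    cea: float                    # ng/mL
    afp: float                    # ng/mL
    ca199: float                  # IU/mL
    ca125: float                  # U/mL
    location: str                 # cardia | fundus | body | antrum
    size_cm: float
    label: str                    # "low" | "high"

    def __post_init__(self) -> None:
        if not 2.0 <= self.size_cm <= 5.0:
            raise ValueError("size_cm must be in [2, 5]")
        for name in ("cea", "afp", "ca199", "ca125"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


LOCATIONS = ("cardia", "fundus", "body", "antrum")

# (mean, sd) of continuous covariates and categorical counts per
# (center, class); defaults mirror a two-center summary table.
CLINICAL_DEFAULTS: dict[tuple[int, str], dict] = {
    (1, "low"): dict(
        n=195, age=(62.39, 10.73), bmi=(23.83, 3.35), cea=(2.49, 1.70),
        afp=(2.84, 1.68), ca199=(12.60, 17.94), ca125=(10.65, 7.82),
        size=(3.29, 0.86), male=102, location=(2, 68, 102, 23),
    ),
    (1, "high"): dict(
        n=44, age=(58.41, 10.96), bmi=(23.46, 2.54), cea=(2.32, 1.41),
        afp=(3.75, 4.69), ca199=(13.66, 13.58), ca125=(10.45, 3.44),
        size=(3.55, 0.89), male=20, location=(2, 20, 19, 3),
    ),
    (2, "low"): dict(
        n=108, age=(60.97, 9.39), bmi=(23.30, 3.53), cea=(2.42, 1.62),
        afp=(2.95, 1.49), ca199=(7.35, 6.34), ca125=(12.36, 8.92),
        size=(3.19, 0.90), male=67, location=(4, 38, 59, 7),
    ),
    (2, "high"): dict(
        n=21, age=(56.71, 10.82), bmi=(23.30, 3.93), cea=(1.78, 0.92),
        afp=(2.41, 0.81), ca199=(5.16, 3.61), ca125=(10.33, 6.62),
        size=(3.65, 0.88), male=11, location=(1, 11, 7, 2),
    ),
}


def sample_clinical(label: str, center: int, seed) -> ClinicalRecord:
    """Draw one clinical record from the class/center-conditional marginals.

    ``seed`` may be an integer or a ``numpy.random.Generator``. Continuous
    covariates are normal with the configured mean/SD, clipped to plausible
    ranges (age 18-100, assays >= 0, size 2-5 cm); sex and location follow
    the configured categorical frequencies.
    """
    if label not in ("low", "high"):
        raise ValueError("label must be 'low' or 'high'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = CLINICAL_DEFAULTS[(center, label)]

    def norm(key, lo=0.0, hi=np.inf):
        mu, sd = p[key]
        return float(np.clip(rng.normal(mu, sd), lo, hi))

    sex = "M" if rng.random() < p["male"] / p["n"] else "F"
    loc_p = np.asarray(p["location"], float)
    location = LOCATIONS[rng.choice(4, p=loc_p / loc_p.sum())]
    return ClinicalRecord(
        center=center,
        sex=sex,
        age=norm("age", 18.0, 100.0),
        bmi=norm("bmi", 12.0, 60.0),
        cea=norm("cea"),
        afp=norm("afp"),
        ca199=norm("ca199"),
        ca125=norm("ca125"),
        location=location,
        size_cm=float(np.clip(rng.normal(*p["size"]), 2.0, 5.0)),
        label=label,
    )


# --------------------------------------------------------------------------
# class-conditional phantom parameters (the planted effects)
# --------------------------------------------------------------------------

# (mean, sd, clip_lo, clip_hi) per class
EFFECTS = {
    "core_fraction": {"low": (0.18, 0.05, 0.05, 0.45), "high": (0.25, 0.06, 0.05, 0.45)},
    "flatness":      {"low": (0.76, 0.09, 0.25, 0.95), "high": (0.60, 0.10, 0.25, 0.95)},
    "skewness":      {"low": (0.0, 0.15, -0.45, 0.45), "high": (-2.0, 0.20, -2.6, -1.1)},
}


def _sample_effect(name: str, label: str, rng: np.random.Generator) -> float:
    mu, sd, lo, hi = EFFECTS[name][label]
    return float(np.clip(rng.normal(mu, sd), lo, hi))


def sample_phantom_spec(
    label: str,
    size_cm: float,
    seed: int,
    noise_sd: float = 0.12,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PhantomSpec:
    """Draw one phantom parameterization for a case of the given class."""
    rng = np.random.default_rng(seed)
    return PhantomSpec(
        diameter_mm=float(np.clip(size_cm * 10.0, 20.0, 50.0)),
        class_label=label,
        core_fraction=_sample_effect("core_fraction", label, rng),
        skewness_target=_sample_effect("skewness", label, rng),
        flatness_target=_sample_effect("flatness", label, rng),
        noise_sd=noise_sd,
        spacing_mm=spacing_mm,
        seed=int(rng.integers(0, 2**31)),
        exponent=float(rng.uniform(1.9, 2.3)),
        euler_deg=tuple(rng.uniform(0.0, 180.0, size=3)),
        # component densities vary between patients (biological nuisance);
        # within-core distribution shape stays informative because it is
        # location-invariant
        mu_offsets=tuple(rng.normal(0.0, [0.025, 0.025, 0.03])),
    )


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Per-center class counts and shared generator settings."""

    center1_low: int = 195
    center1_high: int = 44
    center2_low: int = 108
    center2_high: int = 21
    noise_sd: float = 0.12
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_total(self) -> int:
        return self.center1_low + self.center1_high + self.center2_low + self.center2_high

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "spacing_mm" in d:
            d["spacing_mm"] = tuple(d["spacing_mm"])
        return cls(**d)


@dataclass
class PhantomCase:
    """One cohort member: identity, clinical record and phantom parameters.

    Volumes are regenerated on demand from ``spec`` (cheap and exactly
    reproducible), so a cohort can be used fully in memory.
    """

    case_id: str
    center: int
    clinical: ClinicalRecord
    spec: PhantomSpec
    path_unenhanced: str = ""
    path_venous: str = ""
    path_mask: str = ""

    @property
    def label(self) -> str:
        return self.clinical.label

    def generate(self, phases: tuple[str, ...] = PHASES):
        return generate_phantom(self.spec, phases)


@dataclass
class CohortManifest:
    cases: list[PhantomCase]
    config: CohortConfig
    root: str = ""   # set when the cohort is written; manifest CSV stores
                     # paths relative to it (byte-identical across runs)

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases])

    def subset(self, center: int) -> list[PhantomCase]:
        return [c for c in self.cases if c.center == center]

    def to_frame(self) -> pd.DataFrame:
        def rel(p: str) -> str:
            if p and self.root:
                from os.path import relpath
                return relpath(p, self.root)
            return p

        rows = []
        for c in self.cases:
            cl = c.clinical
            rows.append(
                dict(
                    case_id=c.case_id, center=c.center, label=cl.label,
                    path_unenhanced=rel(c.path_unenhanced), path_venous=rel(c.path_venous),
                    path_mask=rel(c.path_mask), sex=cl.sex, age=round(cl.age, 4),
                    bmi=round(cl.bmi, 4), cea=round(cl.cea, 4), afp=round(cl.afp, 4),
                    ca199=round(cl.ca199, 4), ca125=round(cl.ca125, 4),
                    location=cl.location, size_cm=round(cl.size_cm, 4),
                )
            )
        return pd.DataFrame(rows)

    def validate(self, check_files: bool = True) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids are not unique")
        if check_files:
            for c in self.cases:
                for p in (c.path_unenhanced, c.path_venous, c.path_mask):
                    if p and not Path(p).exists():
                        raise FileNotFoundError(p)


def build_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortManifest:
    """Assemble an in-memory cohort (no files written); pure in (config, seed)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    plan = [
        (1, "low", config.center1_low), (1, "high", config.center1_high),
        (2, "low", config.center2_low), (2, "high", config.center2_high),
    ]
    idx = {1: 0, 2: 0}
    for center, label, count in plan:
        for _ in range(count):
            idx[center] += 1
            clin_seed = int(rng.integers(0, 2**31))
            spec_seed = int(rng.integers(0, 2**31))
            clinical = sample_clinical(label, center, clin_seed)
            spec = sample_phantom_spec(
                label, clinical.size_cm, spec_seed,
                noise_sd=config.noise_sd, spacing_mm=config.spacing_mm,
            )
            cases.append(
                PhantomCase(
                    case_id=f"C{center}-{idx[center]:04d}",
                    center=center, clinical=clinical, spec=spec,
                )
            )
    return CohortManifest(cases=cases, config=config)


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0, out_dir=None
) -> CohortManifest:
    """Build a cohort and, if ``out_dir`` is given, write NIfTI volumes,
    masks and the manifest CSV. File output is byte-deterministic."""
    manifest = build_cohort(config, seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest.root = str(out_dir)
        try:
            (out_dir / "images").mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
        for case in manifest.cases:
            unenh, venous, mask, _ = case.generate()
            base = out_dir / "images" / case.case_id
            case.path_unenhanced = str(base) + "_pl.nii.gz"
            case.path_venous = str(base) + "_vp.nii.gz"
            case.path_mask = str(base) + "_mask.nii.gz"
            save_nifti(case.path_unenhanced, unenh.voxels.astype(np.float32), unenh.spacing_mm)
            save_nifti(case.path_venous, venous.voxels.astype(np.float32), venous.spacing_mm)
            save_nifti(case.path_mask, mask.voxels, mask.spacing_mm)
        manifest.to_frame().to_csv(out_dir / "manifest.csv", index=False)
        manifest.validate(check_files=True)
    return manifest


def file_checksums(out_dir) -> dict[str, str]:
    """SHA-256 of every file under ``out_dir`` (determinism checks)."""
    out = {}
    for p in sorted(Path(out_dir).rglob("*")):
        if p.is_file():
            out[str(p.relative_to(out_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


# --------------------------------------------------------------------------
# clairvoyant separability: the cohort's designed class signal
# --------------------------------------------------------------------------

def clairvoyant_auc(manifest: CohortManifest, seed: int = 0) -> float:
    """AUC of a logistic model on the true latent (core_fraction, flatness),
    trained on center 1 and scored on center 2 — an upper reference for any
    image-based model on the same cohort."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    def xy(cases):
        x = np.array([[c.spec.core_fraction, c.spec.flatness_target] for c in cases])
        y = np.array([1 if c.label == "high" else 0 for c in cases])
        return x, y

    x1, y1 = xy(manifest.subset(1))
    x2, y2 = xy(manifest.subset(2))
    lr = LogisticRegression(max_iter=1000).fit(x1, y1)
    return float(roc_auc_score(y2, lr.predict_proba(x2)[:, 1]))


def design_auc(n_mc: int = 200_000, seed: int = 12345) -> float:
    """Large-sample Monte-Carlo AUC of the optimal linear score on the true
    class-conditional (core_fraction, flatness) distributions — the
    generator's designed separability."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    half = n_mc // 2
    x, y = [], []
    for label, cls in (("low", 0), ("high", 1)):
        cf = np.clip(rng.normal(*EFFECTS["core_fraction"][label][:2], half),
                     *EFFECTS["core_fraction"][label][2:])
        fl = np.clip(rng.normal(*EFFECTS["flatness"][label][:2], half),
                     *EFFECTS["flatness"][label][2:])
        x.append(np.column_stack([cf, fl]))
        y.append(np.full(half, cls))
    x, y = np.vstack(x), np.concatenate(y)
    lr = LogisticRegression(max_iter=1000).fit(x, y)
    return float(roc_auc_score(y, lr.predict_proba(x)[:, 1]))
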