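"""Synthetic metastatic-lesion cohorts with known ground-truth heterogeneity.

No patient imaging is distributed with the package, so every downstream
stage is exercised on synthetic data built here.  Two generators exist:

* an *imaging* generator producing binary lesion masks (perturbed
  ellipsoids) with correlated Gaussian intensity fields, organized into
  patient cohorts that mimic the three study populations — an extensively
  annotated lung-cancer-like cohort (3 patients, 25-69 lesions each), an
  oligometastatic cohort (2-5 lesions/patient) and a multimetastatic
  cohort (>=15 lesions/patient);
* a *feature-table* generator producing nonnegative unit-norm lesion
  feature vectors at controlled angles to a patient base direction, so the
  expected cosine dissimilarity is a known closed-form function of the
  angular spread (see :func:`expected_average_heterogeneity`).

Site labels are metadata only: they never alter intensity statistics, so
per-site sampling strategies can be tested independently of feature shifts.
One root seed drives everything; per-patient and per-lesion streams are
split off with ``numpy.random.SeedSequence.spawn`` so cohorts are stable
under reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, DegenerateLesionError

SITE_LABELS = (
    "bone", "lung", "lymphnode", "liver", "pleural",
    "peritoneum", "soft_tissue", "adrenal", "other",
)

#: Overall lesion-site frequencies of the study populations (approximate).
DEFAULT_SITE_DISTRIBUTION = {
    "bone": 0.045, "lung": 0.33, "lymphnode": 0.31, "liver": 0.16,
    "pleural": 0.01, "peritoneum": 0.05, "soft_tissue": 0.07,
    "adrenal": 0.013, "other": 0.012,
}


@dataclass(frozen=True)
class LesionGenParams:
    """Generative parameters for a single synthetic lesion."""

    radii_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    surface_noise: float = 0.1
    intensity_mean: float = 40.0
    intensity_sd: float = 15.0
    texture_corr_len_mm: float = 2.0
    site_label: str = "lung"

    def __post_init__(self):
        if any(r <= 0 for r in self.radii_mm):
            raise ConfigurationError("radii must be positive")
        if self.surface_noise < 0 or self.intensity_sd < 0:
            raise ConfigurationError("noise levels must be nonnegative")
        if self.texture_corr_len_mm < 0:
            raise ConfigurationError("correlation length must be nonnegative")
        if self.site_label not in SITE_LABELS:
            raise ConfigurationError(f"unknown site label {self.site_label!r}")


@dataclass
class LesionCase:
    """One lesion: binary mask + intensity grid + metadata."""

    mask: np.ndarray
    image: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""
    lesion_id: str = ""
    site_label: str = "lung"


@dataclass
class PatientCase:
    patient_id: str
    lesions: list[LesionCase]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation settings.

    ``heterogeneity_level`` in [0, 1] scales the between-lesion divergence
    of lesion parameters within a patient; 0 clones the patient's base
    parameters into every lesion.
    """

    n_patients: int
    lesions_per_patient: tuple[int, int]
    heterogeneity_level: float = 0.5
    site_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_DISTRIBUTION)
    )
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesions_per_patient
        if lo < 2 or hi < lo:
            raise ConfigurationError("lesions_per_patient lower bound must be >= 2")
        if not self.site_distribution:
            raise ConfigurationError("empty site distribution")
        bad = set(self.site_distribution) - set(SITE_LABELS)
        if bad:
            raise ConfigurationError(f"unknown site labels: {bad}")
        if abs(sum(self.site_distribution.values()) - 1.0) > 1e-9:
            raise ConfigurationError("site probabilities must sum to 1")
        if not 0.0 <= self.heterogeneity_level <= 1.0:
            raise ConfigurationError("heterogeneity_level must be in [0, 1]")


#: Study-condition presets: an exhaustively annotated 3-patient cohort
#: (25-69 lesions each), an oligometastatic cohort (18 patients, 2-5
#: lesions) and a multimetastatic cohort (22 patients, >=15 lesions).
PRESETS = {
    "L": dict(n_patients=3, lesions_per_patient=(25, 69)),
    "M-oligo": dict(n_patients=18, lesions_per_patient=(2, 5)),
    "M-multi": dict(n_patients=22, lesions_per_patient=(15, 25)),
}


def preset_spec(name: str, seed: int = 0, heterogeneity_level: float = 0.5,
                n_patients: int | None = None) -> CohortSpec:
    """Build the CohortSpec for one of the named study presets."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    if n_patients is not None:
        kw["n_patients"] = n_patients
    return CohortSpec(seed=seed, heterogeneity_level=heterogeneity_level, **kw)


# ---------------------------------------------------------------------------
# Single lesion
# ---------------------------------------------------------------------------

def _surface_field(u, rng):
    # low-order angular perturbation: random degree-1 + traceless degree-2 term
    a = rng.standard_normal(3)
    a /= np.linalg.norm(a)
    B = rng.standard_normal((3, 3))
    B = 0.5 * (B + B.T)
    B -= np.eye(3) * np.trace(B) / 3.0
    B /= np.linalg.norm(B)
    lin = np.tensordot(u, a, axes=([0], [0]))
    quad = np.einsum("i...,ij,j...->...", u, B, u)
    return (lin + quad) / math.sqrt(2.0)


def generate_lesion(params: LesionGenParams, spacing=(1.0, 1.0, 1.0),
                    rng=None) -> LesionCase:
    """Generate one lesion: a perturbed-ellipsoid mask with a textured
    Gaussian intensity field.

    The mask is the largest 26-connected component of the voxels whose
    normalized radius satisfies ``rho <= 1 + surface_noise * f(u)`` with
    ``f`` a smooth low-order angular field.  Intensities are white noise
    smoothed with an isotropic Gaussian kernel of sd
    ``texture_corr_len_mm`` then shifted/scaled to the target mean/sd.
    """
    rng = np.random.default_rng(rng)
    spacing = tuple(float(s) for s in spacing)
    radii = np.asarray(params.radii_mm, dtype=np.float64)
    if any(r < 2.0 * s for r, s in zip(radii, spacing)):
        raise DegenerateLesionError(
            f"radii {tuple(radii)} too small for spacing {spacing}"
        )

    margin = 3
    half = np.ceil(radii * (1.0 + 2.0 * params.surface_noise) / spacing).astype(int) + margin
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([zz / radii[0], yy / radii[1], xx / radii[2]])
    rho = np.sqrt((coords**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(rho > 0, coords / rho, 0.0)

    if params.surface_noise > 0:
        boundary = 1.0 + params.surface_noise * _surface_field(u, rng)
    else:
        boundary = 1.0
    mask = rho <= boundary

    # keep the largest 26-connected component so the mask is guaranteed connected
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n_comp == 0:
        raise DegenerateLesionError("surface perturbation removed all voxels")
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))

    white = rng.standard_normal(mask.shape)
    if params.texture_corr_len_mm > 0:
        sigma = [params.texture_corr_len_mm / s for s in spacing]
        smooth = ndimage.gaussian_filter(white, sigma=sigma)
    else:
        smooth = white
    inside = smooth[mask]
    sd = inside.std()
    if sd > 0:
        g = (smooth - inside.mean()) / sd
    else:
        g = np.zeros_like(smooth)
    image = params.intensity_mean + params.intensity_sd * g
    return LesionCase(mask=mask, image=image, spacing=spacing,
                      site_label=params.site_label)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _base_params(rng) -> LesionGenParams:
    r = rng.uniform(4.0, 9.0)
    aniso = rng.uniform(0.8, 1.2, size=3)
    return LesionGenParams(
        radii_mm=tuple(np.round(r * aniso, 3)),
        surface_noise=rng.uniform(0.05, 0.2),
        intensity_mean=rng.uniform(-20.0, 80.0),
        intensity_sd=rng.uniform(8.0, 25.0),
        texture_corr_len_mm=rng.uniform(1.0, 3.0),
    )


def _diverge(base: LesionGenParams, level: float, site: str, rng) -> LesionGenParams:
    if level == 0:
        return replace(base, site_label=site)
    radii = tuple(
        float(np.clip(r * math.exp(level * rng.normal(0.0, 0.4)), 2.5, 14.0))
        for r in base.radii_mm
    )
    return LesionGenParams(
        radii_mm=radii,
        surface_noise=base.surface_noise,
        intensity_mean=base.intensity_mean + level * rng.normal(0.0, 40.0),
        intensity_sd=float(base.intensity_sd * math.exp(level * rng.normal(0.0, 0.5))),
        texture_corr_len_mm=float(
            np.clip(base.texture_corr_len_mm * math.exp(level * rng.normal(0.0, 0.5)),
                    0.5, 5.0)
        ),
        site_label=site,
    )


def generate_cohort(spec: CohortSpec, rng=None) -> list[PatientCase]:
    """Generate a cohort of patients with per-lesion parameter divergence.

    Per patient, the lesion count is uniform in ``lesions_per_patient``;
    each lesion's parameters are the patient's base parameters diverged by
    an amount scaled by ``heterogeneity_level``, and site labels are drawn
    i.i.d. from ``site_distribution``.
    """
    if rng is None:
        root = np.random.SeedSequence(spec.seed)
    elif isinstance(rng, np.random.SeedSequence):
        root = rng
    else:
        root = np.random.SeedSequence(np.random.default_rng(rng).integers(2**31))
    sites = sorted(spec.site_distribution)
    probs = np.array([spec.site_distribution[s] for s in sites])
    patients = []
    for p, pseq in enumerate(root.spawn(spec.n_patients)):
        prng = np.random.default_rng(pseq)
        base = _base_params(prng)
        lo, hi = spec.lesions_per_patient
        n_lesions = int(prng.integers(lo, hi + 1))
        lesion_seqs = pseq.spawn(n_lesions)
        pid = f"P{p:03d}"
        lesions = []
        for i, lseq in enumerate(lesion_seqs):
            lrng = np.random.default_rng(lseq)
            site = sites[lrng.choice(len(sites), p=probs)]
            params = _diverge(base, spec.heterogeneity_level, site, lrng)
            case = generate_lesion(params, rng=lrng)
            case.patient_id = pid
            case.lesion_id = f"{pid}_L{i:03d}"
            lesions.append(case)
        patients.append(PatientCase(patient_id=pid, lesions=lesions))
    return patients


# ---------------------------------------------------------------------------
# Direct feature tables with analytic ground truth
# ---------------------------------------------------------------------------

def expected_average_heterogeneity(angular_spread: float) -> float:
    """Closed-form expected pairwise cosine dissimilarity of the angular
    construction.

    With lesion angles theta_i i.i.d. Uniform(0, s) on a 2D coordinate
    plane, ``E[1 - cos(theta_i - theta_j)] = 1 - 2(1 - cos s)/s^2``.
    """
    s = float(angular_spread)
    if s == 0:
        return 0.0
    return 1.0 - 2.0 * (1.0 - math.cos(s)) / s**2


def _orthonormal_pair(n_features: int, rng):
    """Two nonnegative orthonormal vectors with disjoint support halves."""
    h = n_features // 2
    b1 = np.zeros(n_features)
    b2 = np.zeros(n_features)
    b1[:h] = rng.uniform(0.2, 1.0, size=h)
    b2[h:] = rng.uniform(0.2, 1.0, size=n_features - h)
    return b1 / np.linalg.norm(b1), b2 / np.linalg.norm(b2)


def generate_feature_table(
    n_patients: int,
    n_lesions: int,
    angular_spread: float,
    n_features: int = 8,
    rng=None,
    site_distribution: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Feature table with analytically known expected heterogeneity.

    Construction (the basis of the closed-form oracle): per patient, two
    nonnegative orthonormal directions ``b1, b2`` with disjoint feature
    support are drawn; lesion *i* gets the unit vector
    ``cos(theta_i) b1 + sin(theta_i) b2`` with
    ``theta_i ~ Uniform(0, angular_spread)``.  The cosine dissimilarity of
    two lesions is exactly ``1 - cos(theta_i - theta_j)``, so the expected
    average tumoral heterogeneity is
    :func:`expected_average_heterogeneity` and an angular spread of 0
    makes every pairwise dissimilarity 0.
    """
    if not 0.0 <= angular_spread <= math.pi / 2:
        raise ConfigurationError("angular_spread must be in [0, pi/2]")
    if n_lesions < 2 or n_features < 2:
        raise ConfigurationError("need n_lesions >= 2 and n_features >= 2")
    rng = np.random.default_rng(rng)
    dist = site_distribution or DEFAULT_SITE_DISTRIBUTION
    sites = sorted(dist)
    probs = np.array([dist[s] for s in sites])
    probs = probs / probs.sum()

    rows = []
    cols = [f"f{i}" for i in range(n_features)]
    for p in range(n_patients):
        b1, b2 = _orthonormal_pair(n_features, rng)
        thetas = rng.uniform(0.0, angular_spread, size=n_lesions) if angular_spread > 0 \
            else np.zeros(n_lesions)
        for i, th in enumerate(thetas):
            v = math.cos(th) * b1 + math.sin(th) * b2
            rows.append({
                "patient_id": f"P{p:03d}",
                "lesion_id": f"P{p:03d}_L{i:03d}",
                "site_label": sites[rng.choice(len(sites), p=probs)],
                **dict(zip(cols, v)),
            })
    return pd.DataFrame(rows)


def orthogonal_lesion_pair(n_features: int = 2, rng=None) -> pd.DataFrame:
    """Two lesions of one patient whose feature vectors are orthogonal
    nonnegative unit vectors — the configuration attaining the cosine
    dissimilarity supremum of 1.0."""
    rng = np.random.default_rng(rng)
    b1, b2 = _orthonormal_pair(max(2, n_features), rng)
    cols = [f"f{i}" for i in range(len(b1))]
    return pd.DataFrame([
        {"patient_id": "P000", "lesion_id": "P000_L000", "site_label": "lung",
         **dict(zip(cols, b1))},
        {"patient_id": "P000", "lesion_id": "P000_L001", "site_label": "liver",
         **dict(zip(cols, b2))},
    ])


def generate_clustered_feature_table(
    n_lesions: int = 60,
    n_clusters: int = 8,
    n_features: int = 27,
    noise_sd: float = 0.05,
    rng=None,
):
    """Feature table with a planted correlation-cluster structure.

    Each feature is a scaled copy of one of ``n_clusters`` independent
    latent factors plus Gaussian noise, so hierarchical clustering on
    ``1 - |r|`` should recover the planted partition.  Returns
    ``(table, labels)`` with ``labels[feature_name] = planted cluster``.
    """
    if n_features < n_clusters:
        raise ConfigurationError("need at least one feature per cluster")
    rng = np.random.default_rng(rng)
    factors = rng.standard_normal((n_lesions, n_clusters))
    assign = np.arange(n_features) % n_clusters
    cols, labels = {}, {}
    for j in range(n_features):
        name = f"f{j:02d}"
        scale = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
        cols[name] = scale * factors[:, assign[j]] + noise_sd * rng.standard_normal(n_lesions)
        labels[name] = int(assign[j])
    table = pd.DataFrame({
        "patient_id": "P000",
        "lesion_id": [f"L{i:03d}" for i in range(n_lesions)],
        "site_label": "lung",
        **cols,
    })
    return table, labels
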