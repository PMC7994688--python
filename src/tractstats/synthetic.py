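"""Synthetic three-group cohort generator.

Builds everything the analysis pipeline consumes, with no external data:
parametric curved skeleton sheets for the eleven tracts, subject-level
vertex FA fields with planted group decrements on geodesic disks, white
matter lesion allocations, demographics, and neurocognitive scaled scores
with a controllable correlation to corpus-callosum mean FA.

The generator emulates the statistical structure of a 21/26/19
control / patient / anemic-control design: scaled scores on the mean-10 /
SD-3 scale, localized FA decrements on tract sheets, and FA-score
correlations in the 0.2-0.6 range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, NotPositiveSemidefiniteError
from .mesh import (
    TRACT_NAMES,
    SkeletonMesh,
    check_tract_names,
    geodesic_disk,
    radius_for_fraction,
)
from .projection import VertexDataset
from .tensor import DiffusionTensorField, DwiProtocol, tensors_to_matrices

log = logging.getLogger(__name__)

GROUPS = ("CTL", "SCD", "ACTL")
SEXES = ("F", "M")
WMH_REGIONS = ("frontal", "parietal", "temporal", "other")
HEMISPHERES = ("L", "R")

#: The nine neurocognitive measures, as scaled scores (mean 10, SD 3).
MEASURES = (
    "symbol_search",
    "coding",
    "digit_span",
    "inhibition",
    "inhibition_switch",
    "trail_making",
    "category_switch",
    "letter_fluency",
    "category_fluency",
)

#: Default target FA-score correlations (generator calibration points).
DEFAULT_SCORE_RHO = {
    "symbol_search": 0.30,
    "coding": 0.34,
    "digit_span": 0.27,
    "inhibition": 0.51,
    "inhibition_switch": 0.57,
    "trail_making": 0.29,
    "category_switch": 0.25,
    "letter_fluency": 0.23,
    "category_fluency": 0.24,
}

#: Default lesion weights per (region, hemisphere) cell.  The listed
#: frontal/parietal/temporal counts are 47/39, 8/10 and 2/2 out of a total
#: of 132; the remainder is spread over an "other" cell pair.
DEFAULT_WMH_WEIGHTS = {
    ("frontal", "L"): 47,
    ("frontal", "R"): 39,
    ("parietal", "L"): 8,
    ("parietal", "R"): 10,
    ("temporal", "L"): 2,
    ("temporal", "R"): 2,
    ("other", "L"): 12,
    ("other", "R"): 12,
}

# Axis-aligned sampling boxes (|x|, y, z ranges in mm) per lesion region;
# the hemisphere flips the sign of x.
_REGION_BOXES = {
    "frontal": ((5, 45), (20, 70), (-10, 50)),
    "parietal": ((5, 45), (-60, -20), (20, 60)),
    "temporal": ((25, 65), (-30, 20), (-40, 0)),
    "other": ((0, 45), (-60, 70), (-40, 60)),
}


@dataclass(frozen=True)
class Lesion:
    """One white-matter lesion: region, hemisphere, centre (mm) and radius."""

    region: str
    hemisphere: str
    center: tuple
    radius: float

    def __post_init__(self):
        if self.region not in WMH_REGIONS:
            raise ConfigError(f"unknown lesion region {self.region!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ConfigError(f"unknown hemisphere {self.hemisphere!r}")
        if self.radius <= 0:
            raise ConfigError("lesion radius must be positive")


@dataclass
class SubjectRecord:
    """One study participant."""

    subject_id: str
    group: str
    age: float
    sex: str
    wmh_present: bool = False
    wmh_lesions: list = field(default_factory=list)
    scores: dict = field(default_factory=dict)
    transfused: bool | None = None  # optional; no default asserted

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConfigError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ConfigError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age <= 0:
            raise ConfigError("age must be positive")
        if self.scores and set(self.scores) != set(MEASURES):
            raise ConfigError("scores must cover exactly the nine study measures")


@dataclass(frozen=True)
class DiskSpec:
    """Geodesic disk on a tract sheet receiving the planted FA decrement.

    ``center`` defaults to the mesh's central vertex; ``radius_mm`` defaults
    to the radius capturing ``fraction`` of the vertices.
    """

    center: int | None = None
    radius_mm: float | None = None
    fraction: float = 0.10

    def resolve(self, mesh: SkeletonMesh) -> np.ndarray:
        center = mesh.central_vertex() if self.center is None else self.center
        if not 0 <= center < mesh.n_vertices:
            raise ConfigError(
                f"effect center {center} is not a vertex of tract {mesh.name!r}"
            )
        radius = self.radius_mm
        if radius is None:
            radius = radius_for_fraction(mesh, center, self.fraction)
        return geodesic_disk(mesh, center, radius)


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults mirror the study design."""

    n_ctl: int = 21
    n_scd: int = 26
    n_actl: int = 19
    age_mean_sd: dict = field(default_factory=lambda: {
        "CTL": (22.6, 8.9), "SCD": (24.2, 9.7), "ACTL": (26.1, 11.7)})
    female_fraction: dict = field(default_factory=lambda: {
        "CTL": 13 / 21, "SCD": 0.5, "ACTL": 0.5})
    fa_baseline: float = 0.5
    fa_sd: float = 0.05
    effect_delta: float = 0.05
    effects: dict = field(default_factory=lambda: {"CC": DiskSpec()})
    actl_effect_tracts: tuple = ("CC", "IFO_L")
    age_slope: float = 0.0
    sex_offset: float = 0.0
    score_rho: object = field(default_factory=lambda: dict(DEFAULT_SCORE_RHO))
    score_mean: float = 10.0
    score_sd: float = 3.0
    reference_tract: str = "CC"
    wmh_total: int = 132
    wmh_region_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_WMH_WEIGHTS))
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def group_sizes(self) -> dict:
        return {"CTL": self.n_ctl, "SCD": self.n_scd, "ACTL": self.n_actl}

    def rho_for(self, measure: str) -> float:
        if isinstance(self.score_rho, dict):
            return float(self.score_rho.get(measure, 0.0))
        return float(self.score_rho)

    def validate(self):
        for g, n in self.group_sizes().items():
            if n < 2:
                raise ConfigError(f"group {g} needs at least 2 subjects, got {n}")
        if not 0.0 <= self.fa_baseline <= 1.0:
            raise ConfigError("fa_baseline must lie in [0, 1]")
        if self.fa_sd < 0 or self.effect_delta < 0:
            raise ConfigError("fa_sd and effect_delta must be non-negative")
        for g, f in self.female_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"female_fraction[{g}] must lie in [0, 1]")
        for m in MEASURES:
            if not abs(self.rho_for(m)) < 1.0:
                raise ConfigError(f"|score_rho| must be < 1 for {m}")
        if self.score_sd <= 0:
            raise ConfigError("score_sd must be positive")
        if self.wmh_total < 0:
            raise ConfigError("wmh_total must be non-negative")


def generate_skeletons(tract_names=TRACT_NAMES, resolution: int = 14,
                       seed: int = 0) -> dict:
    """Parametric curved rectangular sheets, one per tract.

    Each sheet is a ``resolution`` x ``resolution`` vertex grid bent by a
    smooth bump, with analytically derived unit normals and a smoothly
    varying positive half-thickness.  Geometry parameters are drawn
    deterministically per tract from ``seed``, so the same seed always
    yields bitwise-identical meshes regardless of the order tracts are
    requested in.
    """
    tract_names = check_tract_names(tract_names)
    if resolution < 4:
        raise ConfigError("resolution must be at least 4 vertices per side")

    meshes = {}
    for name in tract_names:
        idx = TRACT_NAMES.index(name)
        rng = np.random.default_rng(np.random.SeedSequence((seed, idx)))
        length = rng.uniform(45.0, 65.0)
        width = rng.uniform(22.0, 32.0)
        amp = rng.uniform(2.0, 6.0)
        h0 = rng.uniform(1.0, 1.5)
        h1 = rng.uniform(0.5, 1.0)

        # Distinct centre per tract; left/right pairs mirrored in x.
        side = -1.0 if name.endswith("_L") else (1.0 if name.endswith("_R") else 0.0)
        center = np.array([35.0 * side, 40.0 * (idx % 4) - 60.0, 30.0 * (idx // 4)])
        # Mild random in-plane rotation so sheets are not axis-aligned.
        theta = rng.uniform(-0.3, 0.3)
        a1 = np.array([np.cos(theta), np.sin(theta), 0.0])
        a2 = np.array([-np.sin(theta), np.cos(theta), 0.0])
        a3 = np.array([0.0, 0.0, 1.0])

        u, v = np.meshgrid(
            np.linspace(0.0, 1.0, resolution),
            np.linspace(0.0, 1.0, resolution),
            indexing="ij",
        )
        u, v = u.ravel(), v.ravel()
        bump = np.sin(np.pi * u) * np.sin(np.pi * v)
        verts = (
            center
            + np.outer((u - 0.5) * length, a1)
            + np.outer((v - 0.5) * width, a2)
            + np.outer(amp * bump, a3)
        )
        du = (
            np.outer(np.full(u.size, length), a1)
            + np.outer(amp * np.pi * np.cos(np.pi * u) * np.sin(np.pi * v), a3)
        )
        dv = (
            np.outer(np.full(u.size, width), a2)
            + np.outer(amp * np.pi * np.sin(np.pi * u) * np.cos(np.pi * v), a3)
        )
        normals = np.cross(du, dv)
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        half = h0 + h1 * bump

        r = resolution
        i, j = np.meshgrid(np.arange(r - 1), np.arange(r - 1), indexing="ij")
        v00 = (i * r + j).ravel()
        v10, v01, v11 = v00 + r, v00 + 1, v00 + r + 1
        tris = np.concatenate(
            [np.stack([v00, v10, v11], axis=1), np.stack([v00, v11, v01], axis=1)]
        )
        meshes[name] = SkeletonMesh(name, verts, tris, normals, half)
    return meshes


def _group_term(config: CohortConfig, skeletons: dict) -> dict:
    """Per-tract planted decrement maps {tract: {group: (V,) array}}."""
    terms = {}
    for tract, spec in config.effects.items():
        if tract not in skeletons:
            raise ConfigError(
                f"effect tract {tract!r} has no skeleton mesh"
            )
        disk = spec.resolve(skeletons[tract])
        terms[tract] = disk
    return terms


def generate_cohort(config: CohortConfig, skeletons: dict):
    """Generate subject records and per-tract vertex FA datasets.

    Vertex FA is ``fa_baseline + age_slope*(age - mean age) +
    sex_offset*[sex==F] - effect_delta*[vertex in planted disk]`` for
    affected groups, plus independent Gaussian noise, clamped to [0, 1].
    The SCD group receives the decrement on every configured tract; the
    ACTL group only on ``actl_effect_tracts``.

    Scaled scores are built by an exact bivariate-normal construction: the
    subject's reference-tract (CC) mean FA, standardized within group, is
    the shared latent, so the within-group population correlation with each
    measure equals the configured ``score_rho``.
    """
    config.validate()
    if not skeletons:
        raise ConfigError("skeletons must be non-empty")
    disks = _group_term(config, skeletons)

    root = np.random.SeedSequence(config.seed)
    demo_rng, fa_rng, score_rng = map(np.random.default_rng, root.spawn(3))

    groups, ages, sexes = [], [], []
    for g in GROUPS:
        n = config.group_sizes()[g]
        mean, sd = config.age_mean_sd[g]
        a = np.clip(demo_rng.normal(mean, sd, n), 6.0, None)
        n_f = int(np.floor(config.female_fraction[g] * n + 0.5))
        s = np.array(["F"] * n_f + ["M"] * (n - n_f))
        demo_rng.shuffle(s)
        groups += [g] * n
        ages.append(a)
        sexes.append(s)
    ages = np.concatenate(ages)
    sexes = np.concatenate(sexes)
    groups = np.array(groups)
    n_total = len(groups)
    subject_ids = [f"S{i + 1:03d}" for i in range(n_total)]

    is_f = (sexes == "F").astype(float)
    subject_base = (
        config.fa_baseline
        + config.age_slope * (ages - ages.mean())
        + config.sex_offset * is_f
    )

    datasets = {}
    for tract in sorted(skeletons):
        mesh = skeletons[tract]
        values = np.repeat(subject_base[:, None], mesh.n_vertices, axis=1)
        if tract in disks:
            disk = disks[tract]
            affected = groups == "SCD"
            if tract in config.actl_effect_tracts:
                affected = affected | (groups == "ACTL")
            values[np.ix_(affected, disk)] -= config.effect_delta
        if config.fa_sd > 0:
            values += fa_rng.normal(0.0, config.fa_sd, values.shape)
        datasets[tract] = VertexDataset(
            tract, subject_ids, np.clip(values, 0.0, 1.0)
        )

    ref = config.reference_tract
    if ref not in datasets:
        ref = sorted(datasets)[0]
        log.warning("reference tract %r absent; using %r for score coupling",
                    config.reference_tract, ref)
    ref_mean = datasets[ref].values.mean(axis=1)

    z = np.zeros(n_total)
    for g in GROUPS:
        sel = groups == g
        sd = ref_mean[sel].std(ddof=1)
        if sd < 1e-12:
            log.warning("group %s has constant mean FA; score_rho unachievable", g)
        else:
            z[sel] = (ref_mean[sel] - ref_mean[sel].mean()) / sd

    score_matrix = {}
    for m in MEASURES:
        rho = config.rho_for(m)
        eps = score_rng.normal(0.0, 1.0, n_total)
        score_matrix[m] = config.score_mean + config.score_sd * (
            rho * z + np.sqrt(1.0 - rho**2) * eps
        )

    records = [
        SubjectRecord(
            subject_id=subject_ids[i],
            group=groups[i],
            age=float(ages[i]),
            sex=sexes[i],
            scores={m: float(score_matrix[m][i]) for m in MEASURES},
        )
        for i in range(n_total)
    ]
    return records, datasets


def planted_disk(config: CohortConfig, skeletons: dict, tract: str) -> np.ndarray:
    """Vertex indices of the planted decrement disk on ``tract``."""
    return _group_term(config, skeletons)[tract]


def generate_wmh(records, total_count: int = 132, region_weights=None,
                 seed: int = 0):
    """Allocate ``total_count`` lesions multinomially over (region, hemisphere).

    Each lesion gets a radius uniform in [1.5, 2.5] mm (3-5 mm diameter), a
    centre sampled in its region box, and a uniformly chosen host record;
    ``wmh_present`` flags are updated.  Records are modified in place and
    returned.
    """
    if total_count < 0:
        raise ConfigError("total_count must be non-negative")
    weights = dict(DEFAULT_WMH_WEIGHTS if region_weights is None else region_weights)
    for cell, w in weights.items():
        if w < 0:
            raise ConfigError(f"negative lesion weight for cell {cell}")
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ConfigError("lesion weights must have a positive sum")

    cells = sorted(weights)
    p = np.array([weights[c] for c in cells], dtype=float) / total_w
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_count, p)

    for r in records:
        r.wmh_lesions = list(r.wmh_lesions)
    for (region, hemi), k in zip(cells, counts):
        (xlo, xhi), (ylo, yhi), (zlo, zhi) = _REGION_BOXES[region]
        for _ in range(int(k)):
            x = rng.uniform(xlo, xhi) * (-1.0 if hemi == "L" else 1.0)
            center = (float(x), float(rng.uniform(ylo, yhi)),
                      float(rng.uniform(zlo, zhi)))
            lesion = Lesion(region, hemi, center, float(rng.uniform(1.5, 2.5)))
            host = records[rng.integers(len(records))]
            host.wmh_lesions.append(lesion)
    for r in records:
        r.wmh_present = len(r.wmh_lesions) > 0
    return records


def generate_dwi(tensor_field, protocol: DwiProtocol, snr: float = np.inf,
                 seed: int = 0, s0: float = 1.0) -> np.ndarray:
    """Simulate single-shell DWI signals from a tensor field.

    Per volume the noise-free signal is ``S = S0 * exp(-b g^T D g)``;
    finite ``snr`` adds Rician noise (magnitude of the complex signal with
    i.i.d. Gaussian components of SD ``S0/snr``).

    Returns an array with one trailing axis per protocol volume.
    """
    if isinstance(tensor_field, DiffusionTensorField):
        tensors = tensor_field.matrices()
    else:
        tensors = np.asarray(tensor_field, dtype=float)
        if tensors.shape[-1] == 6:
            tensors = tensors_to_matrices(tensors)
        elif tensors.shape[-2:] != (3, 3):
            raise ConfigError("tensor input must be (..., 6) or (..., 3, 3)")
    if not (snr > 0):
        raise ConfigError("snr must be positive (or infinite)")

    lam = np.linalg.eigvalsh(tensors)
    scale = max(np.abs(lam).max(), 1e-30)
    if lam.min() < -1e-9 * scale:
        raise NotPositiveSemidefiniteError(
            f"tensor has negative eigenvalue {lam.min():.3e}"
        )

    g = protocol.directions
    quad = np.einsum("ni,...ij,nj->...n", g, tensors, g)
    signal = s0 * np.exp(-protocol.b_values * quad)
    if np.isinf(snr):
        return signal
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    real = signal + rng.normal(0.0, sigma, signal.shape)
    imag = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(real, imag)
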