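"""Synthetic multisite cohorts and toy diffusivity volumes.

Cohorts are drawn from the same location/scale batch-effect model that ComBat
fits: the observed value of feature v for subject j on scanner i is

    y(i,j,v) = alpha_v + X(i,j)·beta_v + gamma_i + delta_i · eps(i,j,v)

with eps ~ N(0, sigma_v²).  Biological covariates are age (linear, per year)
and diagnostic group (AD indicator), optionally sex; per-scanner effects are
an additive shift gamma_i (index units) and a multiplicative noise scaling
delta_i.  Ground-truth components are stored per subject so recovery tests
compare against the draw itself, never a re-derivation.

Toy volumes emulate the geometry the ALPS index relies on: axis-aligned boxes
stand in for the projection area (dominant fibers along z, so Dzz is boosted)
and the association area (dominant fibers along y, so Dyy is boosted), with a
configurable perivascular x-axis diffusivity inside both.  They exist to make
the volume → ROI → index path testable end to end; they make no attempt at
anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alps import DiffusivityMaps, ROISet

FEATURES = ("alps_left", "alps_right")
GROUPS = ("CN", "AD")

#: scanner labels used by the default multisite configuration
DEFAULT_SCANNERS = ("Discovery_MR750", "Signa_HDxt", "Prisma_Fit")


@dataclass(frozen=True)
class ScannerEffect:
    """One batch: label, additive shift gamma (index units), noise scale delta."""

    label: str
    gamma: float
    delta: float


def _per_feature(value, name: str) -> dict[str, float]:
    """Broadcast a scalar to both features, or validate a per-feature mapping."""
    if np.isscalar(value):
        return {f: float(value) for f in FEATURES}
    out = {f: float(value[f]) for f in FEATURES}
    if set(value) != set(FEATURES):
        raise ValueError(f"{name} must have keys {FEATURES}, got {set(value)}")
    return out


@dataclass
class SimulationConfig:
    """Generative settings for a multisite case/control cohort.

    Defaults emulate a three-scanner AD/CN study of elderly men: observed ALPS
    indices around 1.4–1.55 (intercept 1.90 less the age decline at ages
    60–85), subject noise SD 0.2 index units, an AD deficit of 0.15, and
    scanner offsets/scalings of the size seen across 3T scanner models (the
    Prisma-like scanner reads highest, the HDxt-like lowest).
    """

    n_per_cell: int = 50
    scanners: Sequence[ScannerEffect] = (
        ScannerEffect("Discovery_MR750", gamma=0.0, delta=1.0),
        ScannerEffect("Signa_HDxt", gamma=-0.05, delta=0.8),
        ScannerEffect("Prisma_Fit", gamma=0.10, delta=1.2),
    )
    alpha: float | dict = 1.90
    beta_age: float | dict = -0.005  # index units per year
    beta_group: float | dict = -0.15  # AD minus CN, index units
    beta_sex: float | dict | None = None  # optional male-indicator effect; off = all-male cohort
    age_range: tuple[float, float] = (60.0, 85.0)
    sigma: float | dict = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        self.scanners = tuple(
            s if isinstance(s, ScannerEffect) else ScannerEffect(*s)
            for s in self.scanners
        )
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for s in self.scanners:
            if s.delta <= 0:
                raise ValueError(
                    f"multiplicative effect delta must be > 0, got "
                    f"{s.delta} for scanner {s.label!r}"
                )
        for feat, sd in _per_feature(self.sigma, "sigma").items():
            if sd <= 0:
                raise ValueError(
                    f"noise sd sigma must be > 0, got {sd} for feature {feat!r}"
                )
        if self.age_range[1] < self.age_range[0]:
            raise ValueError("age_range must be (low, high) with low <= high")


@dataclass
class SyntheticCohort:
    """Cohort table plus the configuration that generated it.

    ``table`` has one row per subject with the observed features and, per
    feature f, ground-truth columns ``truth_cov_f`` (alpha + X·beta),
    ``truth_gamma``, ``truth_delta``, and ``truth_noise_f`` (the raw N(0,σ²)
    draw), so that observed = truth_cov + truth_gamma + truth_delta·truth_noise
    holds exactly.
    """

    table: pd.DataFrame
    config: SimulationConfig

    def to_csv(self, path) -> Path:
        self.table.to_csv(path, index=False)
        return Path(path)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a balanced multisite cohort from the location/scale batch model."""
    rng = np.random.default_rng(config.seed)
    alpha = _per_feature(config.alpha, "alpha")
    beta_age = _per_feature(config.beta_age, "beta_age")
    beta_group = _per_feature(config.beta_group, "beta_group")
    beta_sex = (
        None if config.beta_sex is None else _per_feature(config.beta_sex, "beta_sex")
    )
    sigma = _per_feature(config.sigma, "sigma")

    rows = []
    sid = 0
    for scanner in config.scanners:
        for group in GROUPS:
            ages = rng.uniform(*config.age_range, size=config.n_per_cell)
            sexes = (
                rng.integers(0, 2, size=config.n_per_cell)
                if beta_sex is not None
                else np.ones(config.n_per_cell, dtype=int)
            )
            noise = {
                f: rng.normal(0.0, sigma[f], size=config.n_per_cell)
                for f in FEATURES
            }
            for k in range(config.n_per_cell):
                row = {
                    "subject_id": f"S{sid:05d}",
                    "scanner": scanner.label,
                    "group": group,
                    "age": ages[k],
                    "sex": int(sexes[k]),
                    "truth_gamma": scanner.gamma,
                    "truth_delta": scanner.delta,
                }
                for f in FEATURES:
                    cov = alpha[f] + beta_age[f] * ages[k] + beta_group[f] * (
                        group == "AD"
                    )
                    if beta_sex is not None:
                        cov += beta_sex[f] * sexes[k]
                    row[f"truth_cov_{f}"] = cov
                    row[f"truth_noise_{f}"] = noise[f][k]
                    row[f] = cov + scanner.gamma + scanner.delta * noise[f][k]
                rows.append(row)
                sid += 1
    table = pd.DataFrame(rows)
    if beta_sex is None:
        table = table.drop(columns=["sex"])
    return SyntheticCohort(table=table, config=config)


@dataclass(frozen=True)
class Box:
    """Half-open axis-aligned voxel-index box [x0,x1) × [y0,y1) × [z0,z1)."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.x), slice(*self.y), slice(*self.z))

    def inside(self, shape: tuple[int, ...]) -> bool:
        for (lo, hi), n in zip((self.x, self.y, self.z), shape):
            if not (0 <= lo < hi <= n):
                return False
        return True

    def overlaps(self, other: "Box") -> bool:
        for (a_lo, a_hi), (b_lo, b_hi) in zip(
            (self.x, self.y, self.z), (other.x, other.y, other.z)
        ):
            if a_hi <= b_lo or b_hi <= a_lo:
                return False
        return True


def _default_boxes() -> dict[tuple[str, str], Box]:
    # 40×40×20 grid: left hemisphere at low x, right at high x; projection
    # boxes medial (near the ventricle body), association boxes lateral.
    return {
        ("projection", "left"): Box((8, 13), (18, 23), (9, 12)),
        ("association", "left"): Box((2, 7), (18, 23), (9, 12)),
        ("projection", "right"): Box((27, 32), (18, 23), (9, 12)),
        ("association", "right"): Box((33, 38), (18, 23), (9, 12)),
    }


@dataclass
class ToyVolumeSpec:
    """Settings for toy diffusivity volumes with projection/association boxes.

    ``baseline`` (mm²/s) is the diffusivity perpendicular to fibers and fixes
    the denominator of the downstream ALPS index; ``perivascular_dxx`` fixes
    its numerator, so the noise-free index is perivascular_dxx / baseline.
    ``dominant_boost`` is added to Dzz inside projection boxes and to Dyy
    inside association boxes (the dominant fiber direction of each area).
    """

    shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size_mm: float = 2.0
    boxes: dict = field(default_factory=_default_boxes)
    baseline: float = 0.8e-3
    dominant_boost: float = 0.8e-3
    perivascular_dxx: float = 1.2e-3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        from .alps import ROI_KEYS

        missing = [k for k in ROI_KEYS if k not in self.boxes]
        if missing:
            raise ValueError(f"boxes missing for {missing}")
        keys = list(self.boxes)
        for k in keys:
            if not self.boxes[k].inside(self.shape):
                raise ValueError(f"box {k} is not inside grid {self.shape}")
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                if self.boxes[keys[a]].overlaps(self.boxes[keys[b]]):
                    raise ValueError(f"boxes {keys[a]} and {keys[b]} overlap")
        if self.baseline < 0 or self.perivascular_dxx < 0:
            raise ValueError("diffusivities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_diffusivity_volumes(
    spec: ToyVolumeSpec,
) -> tuple[DiffusivityMaps, ROISet]:
    """Build Dxx/Dyy/Dzz toy volumes and the matching ROI masks.

    Inside projection boxes Dzz carries the dominant-fiber boost; inside
    association boxes Dyy does.  Dxx carries the configured perivascular
    signal inside all four boxes.  Gaussian voxel noise is added everywhere
    and values are clipped at zero (diffusivities are non-negative).
    """
    rng = np.random.default_rng(spec.seed)
    base = np.full(spec.shape, spec.baseline, dtype=float)
    dxx, dyy, dzz = base.copy(), base.copy(), base.copy()

    masks = {}
    for (region, hemi), box in spec.boxes.items():
        sl = box.slices()
        dxx[sl] = spec.perivascular_dxx
        if region == "projection":
            dzz[sl] = spec.baseline + spec.dominant_boost
        else:
            dyy[sl] = spec.baseline + spec.dominant_boost
        m = np.zeros(spec.shape, dtype=bool)
        m[sl] = True
        masks[(region, hemi)] = m

    if spec.noise_sd > 0:
        for vol in (dxx, dyy, dzz):
            vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)
            np.clip(vol, 0.0, None, out=vol)

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    maps = DiffusivityMaps(dxx=dxx, dyy=dyy, dzz=dzz, affine=affine)
    rois = ROISet(
        masks=masks,
        provenance={k: {"kind": "toy_box", "box": v} for k, v in spec.boxes.items()},
    )
    return maps, rois
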