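"""Synthetic MRI-like uterine phantoms with known placental ground truth.

Each phantom is an 8-bit axial-style image of an elliptical uterus: a
myometrial band (a ring between two concentric ellipses) around a central
cavity, with a bright crescent-shaped placental region attached to the
lower inner wall.  The crescent protrudes into — or through — the band by
``invasion_depth_fraction``, encoding the three clinical grades of
placenta accreta:

* ``adhesive``    (fraction < 0.2): villi adhere to the myometrium;
* ``implantable`` (0.2 <= fraction < 0.8): villi invade into the band;
* ``penetrated``  (fraction >= 0.8): villi cross the serosal (outer)
  boundary.  Depths are scaled so the 0.8 grade boundary is exactly the
  depth at which the crescent reaches the serosa; deeper values bulge past.

Realism knobs are additive Gaussian noise and a smooth multiplicative
second-order polynomial bias field, both applied after rendering and
before clipping to [0, 255].  The ground-truth mask is the noiseless
placental region.  Everything is a pure function of its parameters and
seed.

The module also simulates paired diagnostic reader calls (two modalities
scored against a pathology gold standard) with a Gaussian-copula
within-case correlation, for exercising the paired statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "GRADES",
    "GRADE_ADHESIVE",
    "GRADE_IMPLANTABLE",
    "GRADE_PENETRATED",
    "GRADE_NONE",
    "PhantomParams",
    "PhantomCase",
    "SimulatedCalls",
    "grade_of_depth",
    "make_phantom",
    "make_cohort",
    "simulate_reader_calls",
]

GRADE_ADHESIVE = "adhesive"
GRADE_IMPLANTABLE = "implantable"
GRADE_PENETRATED = "penetrated"
GRADE_NONE = "none"
GRADES = (GRADE_ADHESIVE, GRADE_IMPLANTABLE, GRADE_PENETRATED)

#: invasion_depth_fraction boundaries between the three grades.
ADHESIVE_MAX = 0.2
PENETRATED_MIN = 0.8

#: Depth intervals the cohort sampler draws from, per grade (kept slightly
#: inside the grade boundaries so jitter cannot flip a label).
_GRADE_DEPTH_RANGES = {
    GRADE_ADHESIVE: (0.02, 0.18),
    GRADE_IMPLANTABLE: (0.25, 0.75),
    GRADE_PENETRATED: (0.82, 1.0),
}


def grade_of_depth(invasion_depth_fraction: float) -> str:
    if invasion_depth_fraction < ADHESIVE_MAX:
        return GRADE_ADHESIVE
    if invasion_depth_fraction < PENETRATED_MIN:
        return GRADE_IMPLANTABLE
    return GRADE_PENETRATED


@dataclass(frozen=True)
class PhantomParams:
    """Rendering parameters; defaults are the reference study conditions."""

    width: int = 256
    height: int = 256
    background_mean: float = 40.0
    myometrium_mean: float = 110.0
    placenta_mean: float = 180.0
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    invasion_depth_fraction: float = 0.5
    seed: int = 0
    # geometry, as fractions of the image size / outer ellipse
    center_y_fraction: float = 0.5
    center_x_fraction: float = 0.5
    semi_axis_y_fraction: float = 0.38
    semi_axis_x_fraction: float = 0.42
    band_inner_fraction: float = 0.70
    placenta_wall_fraction: float = 0.12

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError(
                f"geometry too small to render all structures: "
                f"{self.width}x{self.height} (minimum 64x64)"
            )
        if not (self.background_mean < self.myometrium_mean < self.placenta_mean):
            raise ValueError("tissue means must satisfy background < myometrium < placenta")
        for name in ("background_mean", "myometrium_mean", "placenta_mean"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must be in [0, 1)")
        if not (0 <= self.invasion_depth_fraction <= 1):
            raise ValueError("invasion_depth_fraction must be in [0, 1]")
        if not (0.3 <= self.band_inner_fraction <= 0.9):
            raise ValueError("band_inner_fraction must be in [0.3, 0.9]")


@dataclass(frozen=True)
class PhantomCase:
    """A rendered phantom with its ground truth and provenance."""

    image: np.ndarray
    truth_mask: np.ndarray
    grade: str
    params: PhantomParams
    case_id: str = "phantom"
    geometry: dict[str, float] = field(default_factory=dict)


def _elliptical_radius(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Normalized elliptical radius grid (outer boundary at rho = 1) and dy."""
    cy = params.center_y_fraction * params.height
    cx = params.center_x_fraction * params.width
    a = params.semi_axis_y_fraction * params.height
    b = params.semi_axis_x_fraction * params.width
    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    rho = np.sqrt(((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2)
    return rho, yy - cy


def _bias_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth second-order polynomial surface normalized to max |B| = 1."""
    h, w = shape
    u = np.linspace(-1.0, 1.0, h)[:, None]
    v = np.linspace(-1.0, 1.0, w)[None, :]
    c = rng.uniform(-1.0, 1.0, size=5)
    surface = c[0] * u + c[1] * v + c[2] * u * v + c[3] * u**2 + c[4] * v**2
    peak = np.max(np.abs(surface))
    if peak < 1e-12:
        return np.zeros(shape)
    return surface / peak


def make_phantom(params: PhantomParams) -> PhantomCase:
    """Render one phantom; deterministic in ``params`` (including the seed)."""
    rng = np.random.default_rng(params.seed)
    rho, dy = _elliptical_radius(params)
    rho_in = params.band_inner_fraction

    image = np.full((params.height, params.width), params.background_mean, dtype=float)
    band = (rho >= rho_in) & (rho <= 1.0)
    image[band] = params.myometrium_mean

    # crescent on the lower inner wall; depth scaled so the penetrated-grade
    # boundary reaches the serosa (rho = 1) exactly
    d = params.invasion_depth_fraction
    reach = rho_in + (d / PENETRATED_MIN) * (1.0 - rho_in)
    reach = min(reach, 1.04)
    inner = rho_in - params.placenta_wall_fraction
    placenta = (rho >= inner) & (rho <= reach) & (dy > 0)
    if not placenta.any():
        raise ValueError("geometry too small to render the placental region")
    image[placenta] = params.placenta_mean

    if params.bias_amplitude > 0:
        image = image * (1.0 + params.bias_amplitude * _bias_field(image.shape, rng))
    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma, size=image.shape)

    image = np.clip(np.floor(np.abs(image) + 0.5) * np.sign(image), 0, 255).astype(np.uint8)
    return PhantomCase(
        image=image,
        truth_mask=placenta.astype(np.uint8),
        grade=grade_of_depth(d),
        params=params,
        geometry={"rho_inner": rho_in, "rho_reach": reach, "rho_placenta_inner": inner},
    )


def make_cohort(
    n: int,
    grade_mix: Sequence[float] = (0.4, 0.4, 0.2),
    template: PhantomParams | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """A seeded cohort of phantoms with multinomial grades and jittered geometry.

    ``grade_mix`` gives the (adhesive, implantable, penetrated) proportions
    and must sum to 1.  Per-case invasion depths are drawn uniformly within
    the sampled grade's depth interval; the uterine center, semi-axes and
    band thickness receive small independent jitters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(grade_mix, dtype=float)
    if mix.size != 3 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"grade_mix must be 3 nonnegative proportions summing to 1, got {grade_mix}")
    if template is None:
        template = PhantomParams()
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for i in range(n):
        grade = GRADES[int(rng.choice(3, p=mix))]
        depth = float(rng.uniform(*_GRADE_DEPTH_RANGES[grade]))
        params = replace(
            template,
            invasion_depth_fraction=depth,
            center_y_fraction=template.center_y_fraction + float(rng.uniform(-0.03, 0.03)),
            center_x_fraction=template.center_x_fraction + float(rng.uniform(-0.03, 0.03)),
            semi_axis_y_fraction=template.semi_axis_y_fraction * float(rng.uniform(0.92, 1.08)),
            semi_axis_x_fraction=template.semi_axis_x_fraction * float(rng.uniform(0.92, 1.08)),
            band_inner_fraction=template.band_inner_fraction + float(rng.uniform(-0.03, 0.03)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case = make_phantom(params)
        cases.append(replace(case, case_id=f"case{i:03d}"))
    return cases


@dataclass(frozen=True)
class SimulatedCalls:
    """Paired per-case diagnostic outcomes for two modalities.

    ``gold`` is True for diseased (PA) cases, False for controls;
    ``correct_a`` / ``correct_b`` say whether each modality called the case
    correctly; ``grades`` carries the per-case grade labels (``"none"`` for
    controls).
    """

    gold: np.ndarray
    correct_a: np.ndarray
    correct_b: np.ndarray
    grades: tuple[str, ...]


def simulate_reader_calls(
    cohort: Sequence[PhantomCase] | int,
    sens_a: float,
    spec_a: float,
    sens_b: float,
    spec_b: float,
    correlation: float = 0.0,
    control_fraction: float = 0.0,
    seed: int = 0,
) -> SimulatedCalls:
    """Simulate paired modality calls with the stated marginal accuracies.

    Each case draws a bivariate standard normal with the given correlation;
    modality M calls the case correctly iff its normal CDF value falls below
    the per-case probability of a correct call (sensitivity for diseased
    cases, specificity for controls).  This Gaussian copula induces a
    within-case correlation while preserving the marginals; at
    ``correlation = 1`` with equal marginals the two modalities agree on
    every case.

    ``cohort`` is either a list of phantoms (all diseased, carrying grades)
    or an integer number of diseased cases.  ``control_fraction`` is the
    fraction of the final case list made up of disease-free controls.
    """
    for name, rate in (
        ("sens_a", sens_a), ("spec_a", spec_a), ("sens_b", sens_b), ("spec_b", spec_b)
    ):
        if not (0 <= rate <= 1):
            raise ValueError(f"{name}={rate} outside [0, 1]")
    if not (0 <= correlation <= 1):
        raise ValueError(
            f"correlation={correlation} outside the feasible range [0, 1] "
            "for the Gaussian-copula pairing"
        )
    if not (0 <= control_fraction < 1):
        raise ValueError("control_fraction must be in [0, 1)")

    if isinstance(cohort, int):
        n_pos = cohort
        pos_grades = [GRADE_IMPLANTABLE] * n_pos
    else:
        n_pos = len(cohort)
        pos_grades = [case.grade for case in cohort]
    if n_pos < 1:
        raise ValueError("need at least one diseased case")
    n_neg = int(round(n_pos * control_fraction / (1.0 - control_fraction)))

    gold = np.concatenate([np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)])
    grades = tuple(pos_grades + [GRADE_NONE] * n_neg)
    p_a = np.where(gold, sens_a, spec_a)
    p_b = np.where(gold, sens_b, spec_b)

    rng = np.random.default_rng(seed)
    n = gold.size
    z1 = rng.standard_normal(n)
    if correlation >= 1.0:
        z2 = z1
    else:
        z2 = correlation * z1 + np.sqrt(1.0 - correlation**2) * rng.standard_normal(n)
    correct_a = norm.cdf(z1) < p_a
    correct_b = norm.cdf(z2) < p_b
    return SimulatedCalls(gold=gold, correct_a=correct_a, correct_b=correct_b, grades=grades)
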