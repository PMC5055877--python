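"""Synthetic data with the statistical structure the analysis assumes.

Two generators:

* :func:`gen_ccd_responses` -- responses over a central composite design as a
  known quadratic surface plus i.i.d. homoscedastic Gaussian noise, the error
  structure ordinary least squares assumes;
* :func:`gen_timecourses` -- fermentation trajectories from the closed-form
  logistic / Luedeking-Piret models plus additive Gaussian noise per series
  (biomass clipped at zero).

:func:`study_fixtures` packages the published study's ground-truth objects --
the five-factor level table (both the tabulated temperature levels and the
narrative 20/25/30 C variant), the five reported quadratic coefficient sets
(one per indicator organism), and the reported kinetic parameter sets -- so
every stage of the pipeline is exercisable without external data.

All randomness flows from a single seed through spawned
``numpy.random.SeedSequence`` children, so any fixture is reproducible from
(name, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doe import DesignSpec, DesignTable, FactorSpec, generate_ccfd
from .kinetics import (
    KineticParams,
    TimeCourse,
    lilp_product,
    limlp_substrate,
    logistic_biomass,
)
from .response_surface import QuadraticModel

__all__ = [
    "SurfaceTruth",
    "KineticTruth",
    "gen_ccd_responses",
    "gen_timecourses",
    "study_fixtures",
    "ORGANISMS",
    "fixture_manifest",
]

#: Indicator organisms of the antimicrobial assay, in canonical order.
ORGANISMS = ("saureus", "bsubtilis", "xcampestris", "paeruginosa", "calbicans")

ORGANISM_LABELS = {
    "saureus": "Staphylococcus aureus",
    "bsubtilis": "Bacillus subtilis",
    "xcampestris": "Xanthomonas campestris",
    "paeruginosa": "Pseudomonas aeruginosa",
    "calbicans": "Candida albicans",
}


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground truth behind a simulated design/response table."""

    model: QuadraticModel
    noise_sd: float
    seed: int

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class KineticTruth:
    """Ground truth behind a simulated fermentation time-course.

    With ``proportional=False`` (default) each ``noise_sd_*`` is an absolute
    additive Gaussian standard deviation in the series' units; with
    ``proportional=True`` it is a fraction of the instantaneous noise-free
    signal (e.g. 0.02 for 2% per-point multiplicative-style noise).
    """

    params: KineticParams
    times: np.ndarray
    noise_sd_x: float = 0.0
    noise_sd_s: float = 0.0
    noise_sd_p: float = 0.0
    proportional: bool = False
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0) or (t.size and t[0] < 0):
            raise ValueError("times must be a strictly increasing 1-D array starting >= 0")
        object.__setattr__(self, "times", t)
        for name in ("noise_sd_x", "noise_sd_s", "noise_sd_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_ccd_responses(design: DesignTable, truth: SurfaceTruth) -> np.ndarray:
    """Per-run responses: truth-model prediction plus seeded Gaussian noise."""
    if design.n_factors != truth.model.n_factors:
        raise ValueError(
            f"design has {design.n_factors} factors but truth model has "
            f"{truth.model.n_factors}"
        )
    mean = truth.model.predict(design.coded)
    rng = np.random.default_rng(truth.seed)
    return mean + rng.normal(scale=truth.noise_sd, size=design.n_runs)


def gen_timecourses(truth: KineticTruth) -> TimeCourse:
    """Sample a trajectory from the closed-form kinetics plus noise.

    Biomass is clipped at zero; a substrate/product series is included only
    when the corresponding parameters make it meaningful (always, here, since
    the closed forms are defined for all valid parameter sets).
    """
    t = truth.times
    p = truth.params
    child = np.random.SeedSequence(truth.seed).spawn(3)
    rx, rs, rp = (np.random.default_rng(c) for c in child)
    x_mean = logistic_biomass(t, p)
    s_mean = limlp_substrate(t, p, warn_negative=False)
    p_mean = lilp_product(t, p)

    def noisy(rng, mean, sd):
        scale = sd * np.abs(mean) if truth.proportional else np.full(t.size, sd)
        return mean + rng.normal(size=t.size) * scale

    x = noisy(rx, x_mean, truth.noise_sd_x)
    s = noisy(rs, s_mean, truth.noise_sd_s)
    prod = noisy(rp, p_mean, truth.noise_sd_p)
    return TimeCourse(times=t, biomass=np.clip(x, 0.0, None), substrate=s, product=prod)


# ---------------------------------------------------------------------------
# packaged study fixtures
#
# The coefficient lists below are the published fitted quadratic equations (in
# coded factors) for the five indicator-organism responses, in canonical term
# order: intercept; linear A..E; pairwise AB, AC, AD, AE, BC, BD, BE, CD, CE,
# DE; quadratic A^2..E^2.  Factor key: A incubation time (days), B pH,
# C temperature (C), D sucrose (% w/v), E soya peptone (% w/v).

_SURFACE_COEFFICIENTS = {
    "saureus": [
        20.924,
        0.0957321, -0.195509, 0.0896271, 0.189804, 0.0898044,
        0.00453468, -0.00453468, -0.00591517, -0.00591517, 0.0110212,
        0.0108328, 0.0108328, -0.0108328, -0.0108328, -0.0110212,
        -0.54795, -0.14795, -0.34795, -1.04795, -0.94795,
    ],
    "bsubtilis": [
        20.3477,
        0.127445, 0.145469, 0.313355, 0.167851, 0.285498,
        0.0333395, 0.0291605, -0.00675795, -0.00675795, 0.0483105,
        0.0279083, 0.0279083, -0.0154083, -0.0154083, 0.0141895,
        -0.545489, -0.545489, -0.945489, -0.145489, -0.345489,
    ],
    "xcampestris": [
        22.7623,
        0.3, 0.10183, 0.0540524, 0.3, -0.3,
        1.80021e-15, 2.57419e-15, 0.00777721, 0.00777721, 0.0019443,
        1.8162e-15, 2.3339e-15, 2.2161e-15, 2.35407e-15, -0.0019443,
        -0.924567, -1.12457, -0.374567, -1.12457, -1.52457,
    ],
    "paeruginosa": [
        19.5911,
        5.58251e-16, 0.000670037, 0.09933, 5.20199e-16, -0.1,
        -6.15544e-16, -8.10404e-16, 0.00284766, 0.00284766, 0.000711914,
        -5.92518e-16, -3.0522e-16, -6.59243e-16, -1.44794e-15, -0.000711914,
        -0.682226, -0.682226, -0.582226, -0.482226, -0.782226,
    ],
    "calbicans": [
        17.8007,
        -0.00142264, -0.208914, 0.100091, 0.000523031, 0.409347,
        0.00151156, -0.00151156, -0.000385869, -0.000385869, -9.64674e-05,
        -0.00055572, -0.00055572, 0.00055572, 0.00055572, 9.64674e-05,
        -0.501358, -0.151358, -0.401358, -0.301358, -0.351358,
    ],
}

# Shared logistic growth parameters of the producing strain and per-organism
# Luedeking-Piret coefficients (product side), plus the substrate pair.
_LOGISTIC = dict(mu_max=0.7431, x0=0.005, xm=0.226)
_SUBSTRATE = dict(gamma=4.8774, eta=2.566371681)
_ALPHA = {
    "saureus": 87.224,
    "bsubtilis": 81.246,
    "xcampestris": 124.62,
    "paeruginosa": 79.93,
    "calbicans": 100.24,
}
_BETA = {
    "saureus": 8.8496,
    "bsubtilis": 8.8496,
    "xcampestris": 4.4248,
    "paeruginosa": 8.8496,
    "calbicans": 4.4248,
}

#: Reported maximum inhibition zones (mm) at the 11-day harvest:
#: experimental plate readings and the closed-form model values.
REPORTED_MAX_ZONES = {
    "experimental": {"saureus": 30.0, "bsubtilis": 27.0, "xcampestris": 32.0,
                     "paeruginosa": 29.0, "calbicans": 30.0},
    "model_fitted": {"saureus": 30.81, "bsubtilis": 29.5, "xcampestris": 33.08,
                     "paeruginosa": 29.21, "calbicans": 27.76},
}

#: Canonical harvest / evaluation time (days): end of the stationary phase,
#: when the maximum zone of inhibition was recorded.
EVALUATION_TIME_DAYS = 11.0

FACTOR_NAMES = ("A", "B", "C", "D", "E")


def _factor_set(temperature_levels) -> tuple[FactorSpec, ...]:
    lo, mid, hi = temperature_levels
    return (
        FactorSpec("A", 10.0, 11.0, 12.0),     # incubation time, days
        FactorSpec("B", 7.0, 8.0, 9.0),        # pH
        FactorSpec("C", lo, mid, hi),          # temperature, C
        FactorSpec("D", 1.0, 2.0, 3.0),        # sucrose, % w/v
        FactorSpec("E", 0.5, 1.0, 1.5),        # soya peptone, % w/v
    )


def study_fixtures() -> dict:
    """Packaged ground-truth objects of the published study.

    Returns a dict with:

    ``factors``
        Five-factor level set as tabulated (temperature 25/30/35 C).
    ``factors_narrative``
        Variant with the narrative temperature levels 20/25/30 C (the source
        reports both; the design modules do not arbitrate).
    ``models``
        ``{organism: QuadraticModel}`` -- the five fitted quadratic response
        equations in coded factors.
    ``kinetics``
        ``{organism: KineticParams}`` -- shared logistic growth parameters
        with per-organism alpha/beta, the substrate pair gamma/eta, s0 = 20
        g/L (2% w/v sucrose) and p0 = 0 mm (no zone at inoculation).
    ``design_spec``
        The five-factor, eight-center-replicate design specification
        (50 runs).
    ``evaluation_time_days``, ``reported_max_zones``
        The 11-day harvest time and the reported experimental / model-fitted
        maximum inhibition zones.
    """
    models = {
        org: QuadraticModel.from_vector(np.array(coefs), 5, FACTOR_NAMES)
        for org, coefs in _SURFACE_COEFFICIENTS.items()
    }
    kinetics = {
        org: KineticParams(
            **_LOGISTIC, **_SUBSTRATE,
            alpha=_ALPHA[org], beta=_BETA[org],
            s0=20.0, p0=0.0,
        )
        for org in ORGANISMS
    }
    factors = _factor_set((25.0, 30.0, 35.0))
    return {
        "factors": factors,
        "factors_narrative": _factor_set((20.0, 25.0, 30.0)),
        "models": models,
        "kinetics": kinetics,
        "design_spec": DesignSpec(factors=factors, n_center=8),
        "evaluation_time_days": EVALUATION_TIME_DAYS,
        "reported_max_zones": {k: dict(v) for k, v in REPORTED_MAX_ZONES.items()},
        "organism_labels": dict(ORGANISM_LABELS),
    }


def fixture_manifest() -> list[dict]:
    """Names and provenance notes of the packaged fixtures."""
    entries = [
        {"name": "factors", "provenance": "published factor-level table (temperature 25/30/35 C)"},
        {"name": "factors_narrative", "provenance": "narrative temperature levels 20/25/30 C"},
        {"name": "design_spec", "provenance": "five-factor face-centered CCD, 8 center replicates (50 runs)"},
    ]
    for org in ORGANISMS:
        entries.append({
            "name": f"models[{org}]",
            "provenance": f"published quadratic coefficient set, {ORGANISM_LABELS[org]} response",
        })
        entries.append({
            "name": f"kinetics[{org}]",
            "provenance": f"published kinetic parameter set, {ORGANISM_LABELS[org]} product proxy",
        })
    entries.append({
        "name": "reported_max_zones",
        "provenance": "published experimental and model-fitted maximum inhibition zones (mm, day 11)",
    })
    return entries


def demo_design(randomize: bool = False, seed: int | None = None) -> DesignTable:
    """The study's 50-run face-centered CCD (convenience wrapper)."""
    return generate_ccfd(study_fixtures()["design_spec"], randomize=randomize, seed=seed)
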