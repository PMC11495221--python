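"""Synthetic grey-matter volumes and DIAN-like cohorts with known ground truth.

Two families of generators back the test surface of the whole pipeline:

* Volumes: a cube-community model in which every cube of the parcellation grid
  belongs to one community; cubes of the same community share a latent
  intensity pattern, so their pairwise Pearson correlation has the closed-form
  intraclass value s^2 / (s^2 + sigma^2).  A null variant draws i.i.d. voxels
  with no spatial structure at all, which calibrates the permutation
  threshold.

* Cohorts: two groups — mutation carriers (MC) and non-carrier family
  controls (NC) — on a shared estimated-years-to-onset (EYO) timeline, with
  family clustering, log-normal CSF analytes whose MC means depart from the
  flat NC means after a configurable per-analyte divergence EYO (a
  piecewise-linear hinge on the log scale), a declining small-world
  coefficient, CDR stages assigned from EYO, and per-analyte missingness
  completely at random.

Every generator is a pure function of its spec (including the seed) and emits
its ground truth alongside the data so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .network import GreyMatterVolume

__all__ = [
    "ANALYTES",
    "LOG_ANALYTES",
    "VolumeSimSpec",
    "CohortSimSpec",
    "simulate_volume",
    "simulate_null_volume",
    "simulate_cohort",
]

#: All CSF analyte column names, in the panel's conventional order.
ANALYTES = (
    "ab42", "ab40", "ptau", "ttau",
    "snap25", "ng", "nfl", "vilip1", "ykl40", "strem2",
)

#: Analytes that are log-transformed before modelling (all but the amyloid
#: peptides, whose ratio is analyzed untransformed).
LOG_ANALYTES = ("ptau", "ttau", "snap25", "ng", "nfl", "vilip1", "ykl40", "strem2")

# NC-group assay means and SDs (pg/ml except ykl40 ng/ml, strem2 relative
# units) used to place the log-normal baselines at realistic values.
_NC_BASELINES = {
    "ab42": (1407.0, 466.0),
    "ab40": (15698.0, 4418.0),
    "ptau": (14.0, 5.0),
    "ttau": (169.0, 55.0),
    "snap25": (3.6, 1.3),
    "ng": (1563.0, 741.0),
    "nfl": (793.0, 544.0),
    "vilip1": (133.0, 50.0),
    "ykl40": (133.0, 66.0),
    "strem2": (0.47, 0.22),
}

# Default divergence EYO (years) and MC departure (standardized log units at
# the anchor EYO) per analyte: amyloid and tau markers first, synaptic and
# neuronal-injury markers next, axonal/inflammatory markers around the
# small-world divergence, microglial and Abeta40 changes after it.
_DEFAULT_DIVERGENCE = {
    "ab42": -22.0, "ptau": -19.0, "ttau": -17.0, "snap25": -15.0,
    "ng": -14.0, "vilip1": -13.0, "nfl": -7.0, "ykl40": -7.0,
    "strem2": 0.0, "ab40": 2.0,
}
_DEFAULT_EFFECT = {
    "ab42": -1.5, "ptau": 2.5, "ttau": 1.8, "snap25": 1.0,
    "ng": 1.0, "vilip1": 0.9, "nfl": 2.0, "ykl40": 1.3,
    "strem2": 0.8, "ab40": -0.5,
}

# Missingness fractions chosen so the synthetic availability pattern matches
# the panel structure (NfL and sTREM2 assayed in roughly half the sample).
_DEFAULT_MISSING = {
    "ab42": 0.0, "ab40": 0.0, "ptau": 0.0, "ttau": 0.0,
    "snap25": 0.07, "ng": 0.07, "vilip1": 0.07, "ykl40": 0.07,
    "nfl": 0.53, "strem2": 0.54,
}


@dataclass
class VolumeSimSpec:
    """Spec for the cube-community grey-matter volume generator.

    ``community_signal`` is the latent-signal SD expressed as a ratio to
    ``noise_sd``: the expected within-community cube correlation is
    r = c^2 / (c^2 + 1) with c = community_signal.
    """

    shape: tuple[int, int, int] = (30, 30, 30)
    n_communities: int = 5
    community_signal: float = 2.0
    noise_sd: float = 0.05
    gm_baseline: float = 0.5
    cube_edge: int = 3
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.community_signal < 0:
            raise ValueError("community_signal must be >= 0")
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if any(s < 2 * self.cube_edge for s in self.shape):
            raise ValueError(
                f"each axis of shape {self.shape} must be >= 2*cube_edge"
            )


def simulate_volume(spec: VolumeSimSpec) -> tuple[GreyMatterVolume, dict]:
    """Generate a volume whose cubes carry community-structured covariance.

    Voxel value = clip(gm_baseline + community latent + voxel noise, 0, 1).
    The latent is a per-community vector over the cube's voxel positions with
    SD ``community_signal * noise_sd``, shared by every cube of that
    community, so cube pairs within a community correlate while pairs across
    communities do not.

    Returns the volume and a ground-truth dict with the community label of
    every cube (C-order over the cube grid) and the analytic within-community
    correlation.
    """
    rng = np.random.default_rng(spec.seed)
    e = spec.cube_edge
    nx, ny, nz = (s // e for s in spec.shape)
    n_cubes = nx * ny * nz
    labels = rng.integers(0, spec.n_communities, size=n_cubes)
    latent_sd = spec.community_signal * spec.noise_sd
    # one latent intensity pattern (length e^3) per community
    latents = rng.normal(0.0, latent_sd, size=(spec.n_communities, e**3))

    values = rng.normal(spec.gm_baseline, spec.noise_sd, size=spec.shape)
    trimmed = np.ascontiguousarray(values[: nx * e, : ny * e, : nz * e])
    blocks = (
        trimmed.reshape(nx, e, ny, e, nz, e)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(n_cubes, e**3)
    )
    blocks = blocks + latents[labels]
    values[: nx * e, : ny * e, : nz * e] = (
        blocks.reshape(nx, ny, nz, e, e, e)
        .transpose(0, 3, 1, 4, 2, 5)
        .reshape(nx * e, ny * e, nz * e)
    )
    np.clip(values, 0.0, 1.0, out=values)

    truth = {
        "community_labels": labels.tolist(),
        "cube_grid_shape": [nx, ny, nz],
        "cube_edge": e,
        "within_community_correlation": float(
            spec.community_signal**2 / (spec.community_signal**2 + 1.0)
        ),
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
    }
    return GreyMatterVolume(values=values, spacing=spec.spacing), truth


def simulate_null_volume(
    shape: tuple[int, int, int] = (30, 30, 30),
    seed: int = 0,
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> GreyMatterVolume:
    """A volume of i.i.d. uniform voxel values with no spatial structure.

    Under this null every cube-pair Pearson correlation is a chance-level
    draw (SD about 1/sqrt(n_voxels_per_cube - 1)), which is exactly the regime
    the permutation threshold is built to calibrate against.
    """
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, 1.0, size=shape)
    return GreyMatterVolume(values=values, spacing=spacing)


@dataclass
class CohortSimSpec:
    """Spec for the DIAN-like two-group cohort generator.

    Analyte departures are hinges on the standardized log scale: flat at the
    NC mean before ``divergence_eyo[a]``, then linear in EYO, scaled so the
    departure equals ``mc_effect[a]`` standardized units at the anchor EYO
    (0 for analytes diverging well before symptom onset, divergence + 10
    years otherwise).  ``family_sd`` and ``residual_sd`` are on the same
    standardized log scale; their squares should sum to about 1 for the
    marginal SD to match the assay baselines.
    """

    n_mc: int = 216
    n_nc: int = 136
    n_families: int = 40
    eyo_range: tuple[float, float] = (-30.0, 10.0)
    onset_age_window: tuple[float, float] = (40.0, 55.0)
    divergence_eyo: dict = field(default_factory=lambda: dict(_DEFAULT_DIVERGENCE))
    mc_effect: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECT))
    family_sd: float = 0.3
    residual_sd: float = 0.95
    shared_factor_sd: float = 0.0
    missing_fraction: dict = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    male_fraction: float = 0.42
    cdr_cutpoints: tuple[float, float, float, float] = (-3.0, 3.0, 7.0, 11.0)
    smallworld_baseline: float = 1.62
    smallworld_sd: float = 0.05
    smallworld_divergence_eyo: float = -6.0
    smallworld_decline_per_year: float = 0.015
    gm_volume_mean: float = 620.0
    gm_volume_sd: float = 55.0
    gm_divergence_eyo: float = -8.0
    gm_decline_per_year: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > self.n_mc + self.n_nc:
            raise ValueError("n_families cannot exceed the number of subjects")
        if self.family_sd < 0 or self.residual_sd <= 0:
            raise ValueError("family_sd must be >= 0 and residual_sd > 0")
        for a, f in self.missing_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"missing_fraction[{a!r}] = {f} outside [0, 1]")


def _hinge_anchor(div: float) -> float:
    """EYO at which the configured departure is anchored."""
    return 0.0 if div <= -1.0 else div + 10.0


def hinge_effect(eyo: np.ndarray, divergence_eyo: float, effect: float) -> np.ndarray:
    """Standardized MC departure at given EYOs: 0 before the divergence EYO,
    linear after, equal to ``effect`` at the anchor EYO."""
    anchor = _hinge_anchor(divergence_eyo)
    slope = effect / (anchor - divergence_eyo)
    return slope * np.maximum(0.0, np.asarray(eyo, dtype=float) - divergence_eyo)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _cdr_from_eyo(eyo: np.ndarray, carrier: np.ndarray,
                  cuts: tuple[float, float, float, float]) -> np.ndarray:
    """Monotone EYO -> CDR map for carriers; non-carriers stay CDR 0."""
    stages = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
    idx = np.searchsorted(np.asarray(cuts), eyo, side="right")
    cdr = stages[idx]
    return np.where(carrier, cdr, 0.0)


def simulate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, dict]:
    """Generate one cross-sectional DIAN-like cohort table plus ground truth.

    Subjects are assigned round-robin to families; each family draws a mean
    onset age from ``onset_age_window`` and each subject an EYO uniform over
    ``eyo_range``, so visit age = family onset age + EYO (the defining EYO
    identity).  Analytes are log-normal with family intercepts shared across
    siblings; MC means depart after each analyte's divergence EYO.  The
    small-world coefficient and total grey-matter volume decline linearly for
    MCs after their own divergence EYOs.  Missingness is applied completely
    at random per analyte; the pTau/Abeta42 and Abeta42/40 ratios are computed
    after missingness so a ratio is present exactly when both components are.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_mc + spec.n_nc
    carrier = np.zeros(n, dtype=bool)
    carrier[: spec.n_mc] = True
    rng.shuffle(carrier)

    family_idx = np.arange(n) % spec.n_families
    rng.shuffle(family_idx)
    onset_age = rng.uniform(*spec.onset_age_window, size=spec.n_families)
    eyo = rng.uniform(*spec.eyo_range, size=n)
    age = onset_age[family_idx] + eyo
    sex = np.where(rng.random(n) < spec.male_fraction, "M", "F")

    # standardized latent pieces shared across analytes
    fam_u = rng.normal(0.0, 1.0, size=(spec.n_families, len(ANALYTES)))
    shared_g = rng.normal(0.0, 1.0, size=n)

    data: dict[str, np.ndarray] = {}
    truth_analytes: dict[str, dict] = {}
    for j, a in enumerate(ANALYTES):
        mu, s_log = _lognormal_params(*_NC_BASELINES[a])
        div = spec.divergence_eyo[a]
        eff = spec.mc_effect[a]
        z = (
            spec.family_sd * fam_u[family_idx, j]
            + spec.shared_factor_sd * shared_g
            + spec.residual_sd * rng.normal(0.0, 1.0, size=n)
        )
        depart = np.where(carrier, hinge_effect(eyo, div, eff), 0.0)
        data[a] = np.exp(mu + s_log * (z + depart))
        anchor = _hinge_anchor(div)
        truth_analytes[a] = {
            "divergence_eyo": div,
            "mc_effect": eff,
            "anchor_eyo": anchor,
            "slope_per_year_std": eff / (anchor - div),
            "log_mu": float(mu),
            "log_sd": float(s_log),
        }

    sw_depart = np.where(
        carrier,
        spec.smallworld_decline_per_year
        * np.maximum(0.0, eyo - spec.smallworld_divergence_eyo),
        0.0,
    )
    # family intercepts act on the biomarkers; the small-world noise keeps a
    # family share too so the trajectory random effect has signal to recover
    sw_fam = rng.normal(0.0, 1.0, size=spec.n_families)
    small_world = (
        spec.smallworld_baseline
        - sw_depart
        + spec.smallworld_sd
        * (spec.family_sd * sw_fam[family_idx]
           + spec.residual_sd * rng.normal(0.0, 1.0, size=n))
    )
    gm_depart = np.where(
        carrier,
        spec.gm_decline_per_year
        * np.maximum(0.0, eyo - spec.gm_divergence_eyo),
        0.0,
    )
    total_gm = (
        spec.gm_volume_mean - gm_depart + rng.normal(0.0, spec.gm_volume_sd, size=n)
    )

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "family_id": [f"F{f:03d}" for f in family_idx],
            "mutation_status": np.where(carrier, "carrier", "non-carrier"),
            "sex": sex,
            "age": age,
            "eyo": eyo,
            "cdr": _cdr_from_eyo(eyo, carrier, spec.cdr_cutpoints),
            **data,
            "small_world": small_world,
            "total_gm_volume": total_gm,
        }
    )

    for a in ANALYTES:
        frac = spec.missing_fraction.get(a, 0.0)
        if frac > 0:
            miss = rng.random(n) < frac
            table.loc[miss, a] = np.nan
    table["ratio_ab4240"] = table["ab42"] / table["ab40"]
    table["ratio_ptau_ab42"] = table["ptau"] / table["ab42"]

    truth = {
        "analytes": truth_analytes,
        "small_world": {
            "divergence_eyo": spec.smallworld_divergence_eyo,
            "decline_per_year": spec.smallworld_decline_per_year,
            "baseline": spec.smallworld_baseline,
            "sd": spec.smallworld_sd,
        },
        "total_gm_volume": {
            "divergence_eyo": spec.gm_divergence_eyo,
            "decline_per_year": spec.gm_decline_per_year,
        },
        "family_sd": spec.family_sd,
        "residual_sd": spec.residual_sd,
        "n_mc": spec.n_mc,
        "n_nc": spec.n_nc,
        "onset_age_by_family": onset_age.tolist(),
    }
    return table, truth
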