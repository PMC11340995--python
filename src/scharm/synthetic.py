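"""Seedable synthetic connectome cohorts with known ground truth.

The generator emulates the statistical structure the harmonization model
assumes, so every other module can be exercised without restricted
neuroimaging data:

* a *group skeleton* — a shared set of present connections with
  heavy-tailed (log-normal) mean fiber counts at a reference setting;
* *subject fingerprints* — additive per-(subject, edge) offsets that are
  stable across settings, the signal fingerprinting relies on;
* *acquisition effects* — per-edge linear shifts in resolution, b-value
  and their interaction, applied to a configurable fraction of skeleton
  edges (the rest stay null so false-positive control is testable in the
  same cohort);
* optionally a *quadratic b-value term*, the controlled model violation
  behind extrapolation-failure experiments;
* Gaussian observation noise, then rounding (half away from zero) and
  clamping at zero — the same observation rule harmonization applies.

Effect magnitudes are parameterized as fiber-count shifts across the
span of the settings grid (not raw regression slopes), so "an effect of
15" means a typical 15-fiber difference between the extreme settings.
Internally they are converted to slopes in raw physical units; the truth
object stores those raw slopes for direct comparison with fitted models.

All randomness flows from a single seed through one generator in a fixed
draw order (skeleton, group means, effect edges, effect sizes, subject
effects, noise), so identical configs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scharm.core_io import (
    AcquisitionSetting,
    Cohort,
    Connectome,
    Parcellation,
    devectorize,
    upper_triangle_index,
)
from scharm.errors import DesignError
from scharm.harmonization import build_design, round_half_away

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ContinuousScan",
    "ExtrapolationScenario",
    "HCP_GRID",
    "generate",
    "generate_continuous",
    "make_2x2_hcp_like",
    "make_extrapolation_scenario",
    "write_truth",
]

# the 2x2 resampled acquisition grid: res 1.25/2.3 mm, bval 1000/3000 s/mm^2
HCP_GRID = (
    AcquisitionSetting(res=1.25, bval=1000.0),
    AcquisitionSetting(res=1.25, bval=3000.0),
    AcquisitionSetting(res=2.3, bval=1000.0),
    AcquisitionSetting(res=2.3, bval=3000.0),
)
HBHR = AcquisitionSetting(res=1.25, bval=3000.0)  # higher bval, higher res
LBLR = AcquisitionSetting(res=2.3, bval=1000.0)   # lower bval, lower res


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for a synthetic cohort.

    Defaults describe a desk-scale analogue of a traveling-subject
    resampling study: every subject observed at all four settings of the
    2x2 grid, acquisition shifts larger than the subject fingerprint,
    fingerprint larger than scan noise.
    """

    n_regions: int = 60
    n_subjects: int = 30
    density: float = 0.35          # fraction of edges in the group skeleton
    settings_grid: tuple[AcquisitionSetting, ...] = HCP_GRID
    design: str = "traveling"      # "traveling" | "single"
    reference_setting: AcquisitionSetting = HBHR
    mean_count_scale: float = 50.0  # median fiber count on skeleton edges
    subject_sd: float = 5.0        # fingerprint strength, fibers
    effect_sd_res: float = 10.0    # count shift across the res span
    effect_sd_bval: float = 15.0   # count shift across the bval span
    effect_sd_interaction: float = 5.0
    nonlinearity: float = 0.0      # count shift at |bval - ref bval| = 1000
    noise_sd: float = 2.0          # per-observation scan noise, fibers
    effect_edge_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.density <= 1):
            raise DesignError(f"density must be in (0, 1], got {self.density}")
        if not self.settings_grid:
            raise DesignError("settings_grid must be nonempty")
        if self.design not in ("traveling", "single"):
            raise DesignError(f"design must be 'traveling' or 'single', got {self.design!r}")
        for name in ("subject_sd", "effect_sd_res", "effect_sd_bval",
                     "effect_sd_interaction", "noise_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be non-negative")
        if not (0 <= self.effect_edge_fraction <= 1):
            raise DesignError("effect_edge_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generative ground truth paired with a synthetic cohort."""

    skeleton_mask: np.ndarray          # (n_edges,) bool
    group_means: np.ndarray            # (n_edges,) counts at the reference setting
    subject_effects: np.ndarray        # (n_subjects, n_edges)
    true_betas: np.ndarray             # (n_edges, 3): slopes for res, bval, res*bval
    effect_mask: np.ndarray            # edges carrying nonzero acquisition effects
    config: SimulationConfig
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ContinuousScan:
    """Pre-rounding observation: one subject at one setting, edge-vector form."""

    subject_id: str
    session: str
    setting: AcquisitionSetting
    values: np.ndarray


def _setting_shifts(config: SimulationConfig, betas: np.ndarray,
                    setting: AcquisitionSetting) -> np.ndarray:
    """Per-edge mean shift of ``setting`` relative to the reference setting."""
    ref = config.reference_setting
    d_r = setting.res - ref.res
    d_b = setting.bval - ref.bval
    d_rb = setting.res * setting.bval - ref.res * ref.bval
    shift = betas[:, 0] * d_r + betas[:, 1] * d_b + betas[:, 2] * d_rb
    if config.nonlinearity != 0.0:
        shift = shift + config.nonlinearity * (d_b / 1000.0) ** 2
    return shift


def _draw_truth(config: SimulationConfig, rng: np.random.Generator,
                extra_settings: tuple[AcquisitionSetting, ...] = ()
                ) -> SyntheticTruth:
    index = upper_triangle_index(config.n_regions)
    n_edges = index.n_edges

    skeleton = rng.random(n_edges) < config.density
    # heavy-tailed fiber counts: log-normal around the median scale
    group_means = np.zeros(n_edges)
    group_means[skeleton] = rng.lognormal(
        mean=np.log(config.mean_count_scale), sigma=1.0, size=int(skeleton.sum())
    )

    skeleton_edges = np.flatnonzero(skeleton)
    n_effect = int(round(config.effect_edge_fraction * skeleton_edges.size))
    effect_edges = rng.choice(skeleton_edges, size=n_effect, replace=False)
    effect_mask = np.zeros(n_edges, dtype=bool)
    effect_mask[effect_edges] = True

    grid = config.settings_grid
    res_span = max(s.res for s in grid) - min(s.res for s in grid)
    bval_span = max(s.bval for s in grid) - min(s.bval for s in grid)
    # degenerate spans (single level) leave the corresponding slope at 0
    betas = np.zeros((n_edges, 3))
    if res_span > 0:
        betas[effect_edges, 0] = rng.normal(0.0, config.effect_sd_res, n_effect) / res_span
    if bval_span > 0:
        betas[effect_edges, 1] = rng.normal(0.0, config.effect_sd_bval, n_effect) / bval_span
    if res_span > 0 and bval_span > 0:
        betas[effect_edges, 2] = (
            rng.normal(0.0, config.effect_sd_interaction, n_effect)
            / (res_span * bval_span)
        )

    subject_effects = np.zeros((config.n_subjects, n_edges))
    if config.subject_sd > 0:
        subject_effects[:, skeleton] = rng.normal(
            0.0, config.subject_sd, (config.n_subjects, int(skeleton.sum()))
        )

    truth = SyntheticTruth(
        skeleton_mask=skeleton,
        group_means=group_means,
        subject_effects=subject_effects,
        true_betas=betas,
        effect_mask=effect_mask,
        config=config,
    )
    _, rank = build_design(list(grid) + list(extra_settings))
    if rank < 4:
        truth.warnings.append(
            f"settings grid yields a rank-{rank} design; the harmonization "
            "model cannot be fitted on this cohort"
        )
    return truth


def _assignments(config: SimulationConfig) -> list[tuple[int, AcquisitionSetting]]:
    """(subject index, setting) pairs in deterministic order."""
    grid = config.settings_grid
    if config.design == "traveling":
        return [(s, g) for s in range(config.n_subjects) for g in grid]
    # single-setting balanced assignment: round-robin over the grid
    return [(s, grid[s % len(grid)]) for s in range(config.n_subjects)]


def _continuous_values(config: SimulationConfig, truth: SyntheticTruth,
                       rng: np.random.Generator,
                       assignments: list[tuple[int, AcquisitionSetting]]
                       ) -> list[np.ndarray]:
    skeleton = truth.skeleton_mask
    out = []
    for subj, setting in assignments:
        y = truth.group_means + truth.subject_effects[subj]
        y = y + np.where(skeleton, _setting_shifts(config, truth.true_betas, setting), 0.0)
        if config.noise_sd > 0:
            noise = np.zeros_like(y)
            noise[skeleton] = rng.normal(0.0, config.noise_sd, int(skeleton.sum()))
            y = y + noise
        out.append(y)
    return out


def _subject_ids(config: SimulationConfig) -> list[str]:
    width = max(3, len(str(config.n_subjects)))
    return [f"S{i + 1:0{width}d}" for i in range(config.n_subjects)]


def generate(config: SimulationConfig) -> tuple[Cohort, SyntheticTruth]:
    """Draw a cohort of integer connectomes plus its generative truth.

    One connectome per (subject, assigned setting); matrices are
    symmetric, zero-diagonal, non-negative integers.  Identical configs
    (including the seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    assignments = _assignments(config)
    values = _continuous_values(config, truth, rng, assignments)
    index = upper_triangle_index(config.n_regions)
    parc = Parcellation.generic(config.n_regions)
    ids = _subject_ids(config)
    cohort = Cohort()
    for (subj, setting), y in zip(assignments, values):
        counts = np.maximum(round_half_away(y), 0.0).astype(np.int64)
        counts[~truth.skeleton_mask] = 0  # clamping cannot create connections
        cohort.add(Connectome(
            matrix=devectorize(counts, index),
            subject_id=ids[subj],
            session="1",
            setting=setting,
            parcellation=parc,
        ))
    return cohort, truth


def generate_continuous(config: SimulationConfig
                        ) -> tuple[list[ContinuousScan], SyntheticTruth]:
    """Pre-rounding variant of :func:`generate` for exact-recovery tests.

    Returns edge-vector observations with the rounding/clamping step
    skipped; draw order matches :func:`generate`, so the same seed
    produces the continuous counterparts of the integer cohort.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    assignments = _assignments(config)
    values = _continuous_values(config, truth, rng, assignments)
    ids = _subject_ids(config)
    scans = [
        ContinuousScan(subject_id=ids[subj], session="1", setting=setting, values=y)
        for (subj, setting), y in zip(assignments, values)
    ]
    return scans, truth


def make_2x2_hcp_like(**overrides) -> tuple[Cohort, SyntheticTruth]:
    """Convenience preset: the 2x2 grid (1.25/2.3 mm, 1000/3000 s/mm^2),
    traveling design, reference at the higher-bval higher-res corner."""
    config = SimulationConfig(**{
        "settings_grid": HCP_GRID,
        "design": "traveling",
        "reference_setting": HBHR,
        **overrides,
    })
    return generate(config)


@dataclass
class ExtrapolationScenario:
    """Cohort with a quadratic b-value term and held-out target settings.

    Training settings stay at bval <= 3000 where the linear model is a
    good local approximation; ``near_target`` sits inside that range,
    ``far_target`` far outside it, where the quadratic term dominates and
    linear harmonization is expected to fail.
    """

    cohort: Cohort
    truth: SyntheticTruth
    training_settings: tuple[AcquisitionSetting, ...]
    near_target: AcquisitionSetting
    far_target: AcquisitionSetting


def make_extrapolation_scenario(**overrides) -> ExtrapolationScenario:
    """Cohort emulating harmonization toward a much higher b-value.

    Subjects travel over the standard 2x2 grid plus two held-out
    settings at 2.0 mm: bval 2000 (near, interpolation) and bval 8000
    (far, extrapolation).  ``nonlinearity`` defaults to a quadratic
    b-value shift that is negligible within the grid but large at 8000.
    """
    near = AcquisitionSetting(res=2.0, bval=2000.0)
    far = AcquisitionSetting(res=2.0, bval=8000.0)
    params = {"nonlinearity": 4.0, **overrides}
    config = SimulationConfig(**{
        **params,
        "settings_grid": HCP_GRID + (near, far),
        "design": "traveling",
        "reference_setting": HBHR,
    })
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    assignments = _assignments(config)
    values = _continuous_values(config, truth, rng, assignments)
    index = upper_triangle_index(config.n_regions)
    parc = Parcellation.generic(config.n_regions)
    ids = _subject_ids(config)
    cohort = Cohort()
    for (subj, setting), y in zip(assignments, values):
        counts = np.maximum(round_half_away(y), 0.0).astype(np.int64)
        counts[~truth.skeleton_mask] = 0
        cohort.add(Connectome(
            matrix=devectorize(counts, index),
            subject_id=ids[subj],
            session="1",
            setting=setting,
            parcellation=parc,
        ))
    gap = abs(config.nonlinearity) * (
        ((far.bval - config.reference_setting.bval) / 1000.0) ** 2
        - ((near.bval - config.reference_setting.bval) / 1000.0) ** 2
    )
    truth.warnings.append(
        f"linear-model misspecification gap between far and near targets: "
        f"{gap:.1f} fibers per affected edge"
    )
    return ExtrapolationScenario(
        cohort=cohort,
        truth=truth,
        training_settings=HCP_GRID,
        near_target=near,
        far_target=far,
    )


# ---------------------------------------------------------------------------
# Truth persistence (TSV; companion to core_io manifests)
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    """Write per-edge ground truth as TSV (edge, skeleton, mean, slopes)."""
    index = upper_triangle_index(truth.config.n_regions)
    with open(path, "w") as fh:
        c = truth.config
        fh.write(f"# n_regions: {c.n_regions}\n# n_subjects: {c.n_subjects}\n")
        fh.write(f"# seed: {c.seed}\n# design: {c.design}\n")
        fh.write(f"# reference_setting: res={c.reference_setting.res!r} "
                 f"bval={c.reference_setting.bval!r}\n")
        fh.write("edge_i\tedge_j\tskeleton\tgroup_mean\tbeta_res\tbeta_bval\tbeta_interaction\n")
        for e, (i, j) in enumerate(zip(index.rows, index.cols)):
            gm = float(truth.group_means[e])
            b1, b2, b3 = (float(x) for x in truth.true_betas[e])
            fh.write(
                f"{i}\t{j}\t{int(truth.skeleton_mask[e])}\t{gm!r}"
                f"\t{b1!r}\t{b2!r}\t{b3!r}\n"
            )
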