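"""Seeded synthetic datasets with the statistical structure each method assumes.

The generators emulate the three experimental designs around a single ground
truth -- the intact cell's internal osmolarity -- so that the full analysis
pipelines can be validated by parameter recovery:

* protoplast volume populations obeying the Boyle-Van't Hoff law
  ``V = m0 / C_total + b0`` with lognormal cell-to-cell spread;
* cytoplasmic-marker intensities inversely proportional to the population
  volume, with per-slide multiplicative calibration factors and an additive
  background, plus intact calibration cells on every slide;
* 2D Brownian cytGEMs tracks at 100 fps whose diffusion follows the Phillies
  law in sorbitol concentration, with optional static localization noise.

All generators are deterministic under a fixed scenario seed and satisfy
their governing laws exactly in the zero-noise limit.  They emit the exact
CSV schemas consumed by the method pipelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rheology import D0_WATER_40NM

#: Intact-cell cytGEMs mobility the default scenarios reproduce, um^2/s
#: (the wild-type fission-yeast value).
DEFAULT_INTACT_DEFF = 0.40


@dataclass
class StudyScenario:
    """Ground truth and design of one synthetic study.

    ``true_internal_osmolarity`` is the intact cell's total internal
    osmolarity (mol/L); since protoplasts equilibrate with the *total*
    external concentration, the isotonic added-sorbitol truth is
    ``true_internal_osmolarity - medium_baseline_conc``.

    ``n_cells_per_condition`` and ``n_tracks_per_condition`` are totals per
    condition, split across ``n_replicates``.  The intact population is
    generated like any other condition (zero sorbitol, walls on).
    """

    strain_label: str = "synthetic_pombe_like"
    true_internal_osmolarity: float = 0.70
    medium_baseline_conc: float = 0.30
    sorbitol_grid: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60)
    n_cells_per_condition: int = 100
    n_replicates: int = 2
    # volume model
    intact_median_volume_um3: float = 100.0
    nonosmotic_fraction: float = 0.30
    volume_noise_cv: float = 0.25
    # intensity model
    intensity_scale: float = 500.0
    intensity_background_level: float = 100.0
    intensity_noise_cv: float = 0.05
    slide_factors: tuple[float, ...] = (0.85, 1.15)
    intensity_fit_window: tuple[float, float] | None = None
    # rheology model
    phillies_beta: float | None = None
    d0: float = D0_WATER_40NM
    n_tracks_per_condition: int = 1000
    frames_per_track: int = 500
    frame_interval_s: float = 0.01
    localization_noise_sd_um: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_internal_osmolarity <= self.medium_baseline_conc:
            raise ValueError(
                "internal osmolarity must exceed the medium baseline "
                "(otherwise the cell bears no turgor)"
            )
        if not 0 <= self.nonosmotic_fraction < 1:
            raise ValueError("nonosmotic_fraction must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.phillies_beta is None:
            # choose beta so intact-cell tracers diffuse at the reference
            # wild-type mobility
            self.phillies_beta = (
                math.log(self.d0 / DEFAULT_INTACT_DEFF)
                / self.true_internal_osmolarity
            )
        truth = self.true_isotonic_sorbitol
        if not (min(self.sorbitol_grid) <= truth <= max(self.sorbitol_grid)):
            warnings.warn(
                f"sorbitol grid {self.sorbitol_grid} does not span the isotonic "
                f"truth {truth:.3g} mol/L; inversions will extrapolate",
                stacklevel=2,
            )

    # ---- derived ground truth ------------------------------------------
    @property
    def true_isotonic_sorbitol(self) -> float:
        return self.true_internal_osmolarity - self.medium_baseline_conc

    @property
    def b0(self) -> float:
        """Non-osmotic volume, um^3."""
        return self.nonosmotic_fraction * self.intact_median_volume_um3

    @property
    def m0(self) -> float:
        """BVH slope chosen so the isotonic point sits at the scenario truth."""
        return self.true_internal_osmolarity * (
            self.intact_median_volume_um3 - self.b0
        )

    def median_volume_at(self, c_total: float) -> float:
        """Population median protoplast volume at total concentration."""
        return self.m0 / c_total + self.b0

    def d_true(self, c_sorbitol: float) -> float:
        """Protoplast tracer diffusion at added sorbitol ``c_sorbitol``."""
        return self.d0 * math.exp(
            -self.phillies_beta * (c_sorbitol + self.medium_baseline_conc)
        )

    @property
    def d_eff_intact_true(self) -> float:
        """Intact-cell tracer diffusion implied by the internal osmolarity."""
        return self.d0 * math.exp(
            -self.phillies_beta * self.true_internal_osmolarity
        )

    # ---- helpers --------------------------------------------------------
    def _split_counts(self, total: int) -> list[int]:
        base, rem = divmod(total, self.n_replicates)
        return [base + (1 if r < rem else 0) for r in range(self.n_replicates)]

    def _conditions(self) -> list[tuple[float, bool]]:
        """(sorbitol, is_protoplast) pairs: intact first, then the grid."""
        return [(0.0, False)] + [(c, True) for c in self.sorbitol_grid]


def default_volume_scenario(seed: int = 0) -> StudyScenario:
    """Fission-yeast-like volume study: isotonic truth 0.40 mol/L sorbitol."""
    return StudyScenario(true_internal_osmolarity=0.70, seed=seed)


def default_intensity_scenario(seed: int = 0) -> StudyScenario:
    """Fission-yeast-like intensity study: isotonic truth 0.37 mol/L sorbitol.

    The fit window restricts the linear regression to the four grid
    conditions bracketing the intact-cell intensity, where the
    inverse-volume response is locally linear.
    """
    return StudyScenario(
        true_internal_osmolarity=0.67,
        intensity_fit_window=(0.18, 0.52),
        seed=seed,
    )


def default_rheology_scenario(seed: int = 0) -> StudyScenario:
    """Fission-yeast-like rheology study: isotonic truth 0.43 mol/L sorbitol."""
    return StudyScenario(true_internal_osmolarity=0.73, seed=seed)


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative lognormal noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, n))


def gen_volume_dataset(scenario: StudyScenario) -> pd.DataFrame:
    """Per-cell volume table for the intact population and every sorbitol condition.

    Protoplast volumes are lognormal around the BVH median
    ``m0 / C_total + b0``; intact volumes are lognormal around the intact
    median.  Columns match the volume-table schema.
    """
    s = scenario
    rng = np.random.default_rng([s.seed, 1])
    rows: list[pd.DataFrame] = []
    cell_counter = 0
    for c_sorb, is_proto in s._conditions():
        if is_proto:
            median = s.median_volume_at(c_sorb + s.medium_baseline_conc)
        else:
            median = s.intact_median_volume_um3
        for rep, n_rep in enumerate(s._split_counts(s.n_cells_per_condition), 1):
            volumes = median * _lognormal_factors(rng, n_rep, s.volume_noise_cv)
            rows.append(
                pd.DataFrame(
                    {
                        "strain": s.strain_label,
                        "replicate": rep,
                        "is_protoplast": is_proto,
                        "sorbitol_mol_per_L": c_sorb,
                        "medium_baseline_mol_per_L": s.medium_baseline_conc,
                        "cell_id": np.arange(cell_counter, cell_counter + n_rep),
                        "volume_um3": volumes,
                    }
                )
            )
            cell_counter += n_rep
    return pd.concat(rows, ignore_index=True)


def gen_intensity_dataset(scenario: StudyScenario) -> pd.DataFrame:
    """Per-cell intensity table with slide calibration structure.

    The cytoplasmic marker is an intensive property: its concentration is
    the same in every cell of a condition (cell-cycle invariant) and scales
    inversely with the population volume, so the corrected signal is
    ``slide_factor * intensity_scale * V_intact / V(C_total)`` times
    per-cell multiplicative measurement noise, on top of an additive
    background.  One slide per replicate; intact cells appear on every
    slide so each can be self-calibrated.
    """
    s = scenario
    rng = np.random.default_rng([s.seed, 2])
    rows: list[pd.DataFrame] = []
    cell_counter = 0
    for c_sorb, is_proto in s._conditions():
        if is_proto:
            conc_rel = s.intact_median_volume_um3 / s.median_volume_at(
                c_sorb + s.medium_baseline_conc
            )
        else:
            conc_rel = 1.0
        for rep, n_rep in enumerate(s._split_counts(s.n_cells_per_condition), 1):
            factor = s.slide_factors[(rep - 1) % len(s.slide_factors)]
            signal = (
                factor
                * s.intensity_scale
                * conc_rel
                * _lognormal_factors(rng, n_rep, s.intensity_noise_cv)
            )
            rows.append(
                pd.DataFrame(
                    {
                        "strain": s.strain_label,
                        "replicate": rep,
                        "slide_id": f"slide{rep}",
                        "is_protoplast": is_proto,
                        "sorbitol_mol_per_L": c_sorb,
                        "medium_baseline_mol_per_L": s.medium_baseline_conc,
                        "cell_id": np.arange(cell_counter, cell_counter + n_rep),
                        "roi_mean": s.intensity_background_level + signal,
                        "background_mean": s.intensity_background_level,
                    }
                )
            )
            cell_counter += n_rep
    return pd.concat(rows, ignore_index=True)


def brownian_positions(
    rng: np.random.Generator,
    n_tracks: int,
    n_frames: int,
    frame_interval_s: float,
    d: float,
    localization_noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble of 2D Gaussian random walks with optional localization noise.

    Returns ``(times, xs, ys)`` with position arrays of shape
    ``(n_tracks, n_frames)``; per-step variance is ``2 D dt`` per axis, and
    localization noise adds an independent Gaussian error to every stored
    position (producing the static 4 sigma^2 MSD offset).
    """
    if d < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    step_sd = math.sqrt(2.0 * d * frame_interval_s)
    steps = rng.normal(0.0, 1.0, (n_tracks, n_frames - 1, 2)) * step_sd
    pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    if localization_noise_sd > 0:
        pos = pos + rng.normal(0.0, localization_noise_sd, pos.shape)
    times = np.arange(n_frames) * frame_interval_s
    return times, pos[:, :, 0], pos[:, :, 1]


def gen_brownian_tracks(scenario: StudyScenario) -> pd.DataFrame:
    """Track table for intact cells and every sorbitol condition.

    Protoplast tracks diffuse at the Phillies prediction for their sorbitol
    concentration; intact-cell tracks diffuse at the rate implied by the
    scenario's internal osmolarity.  Columns match the track-table schema.
    """
    s = scenario
    rng = np.random.default_rng([s.seed, 3])
    n_frames = s.frames_per_track
    frames = np.arange(n_frames)
    times = frames * s.frame_interval_s
    # accumulate whole columns; a single DataFrame construction is much
    # cheaper than concatenating per-condition frames at millions of rows
    cols: dict[str, list[np.ndarray]] = {
        k: [] for k in ("replicate", "is_protoplast", "sorbitol_mol_per_L",
                        "track_id", "x_um", "y_um")
    }
    track_counter = 0
    n_blocks = 0
    for c_sorb, is_proto in s._conditions():
        d = s.d_true(c_sorb) if is_proto else s.d_eff_intact_true
        for rep, n_rep in enumerate(s._split_counts(s.n_tracks_per_condition), 1):
            _, xs, ys = brownian_positions(
                rng, n_rep, n_frames, s.frame_interval_s, d,
                s.localization_noise_sd_um,
            )
            track_ids = np.arange(track_counter, track_counter + n_rep)
            n = n_rep * n_frames
            cols["replicate"].append(np.full(n, rep, dtype=np.int64))
            cols["is_protoplast"].append(np.full(n, is_proto, dtype=bool))
            cols["sorbitol_mol_per_L"].append(np.full(n, c_sorb, dtype=float))
            cols["track_id"].append(np.repeat(track_ids, n_frames))
            cols["x_um"].append(xs.ravel())
            cols["y_um"].append(ys.ravel())
            track_counter += n_rep
            n_blocks += 1
    total = track_counter * n_frames
    return pd.DataFrame(
        {
            "strain": np.full(total, s.strain_label, dtype=object),
            "replicate": np.concatenate(cols["replicate"]),
            "is_protoplast": np.concatenate(cols["is_protoplast"]),
            "sorbitol_mol_per_L": np.concatenate(cols["sorbitol_mol_per_L"]),
            "medium_baseline_mol_per_L": np.full(total, s.medium_baseline_conc),
            "track_id": np.concatenate(cols["track_id"]),
            "frame": np.tile(frames, track_counter),
            "t_s": np.tile(times, track_counter),
            "x_um": np.concatenate(cols["x_um"]),
            "y_um": np.concatenate(cols["y_um"]),
        }
    )
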