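"""Table readers/writers, study configuration, pipeline driver and reports.

File conventions (no implicit unit inference): concentrations in mol/L,
temperatures in K, volumes in um^3, coordinates in um, times in s.  The
three tabular schemas are plain CSV/TSV with one row per cell (volume,
intensity) or per localization (tracks).  Reports are emitted both as
machine-readable JSON and as a human-readable markdown table with one row
per method plus the cross-method average.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import intensity as intensity_mod
from . import rheology as rheology_mod
from . import volume as volume_mod
from .core import (
    DEFAULT_TEMPERATURE_K,
    IsotonicEstimate,
    OsmoticCondition,
    TurgorResult,
    combine_isotonic,
    combine_methods,
    round_sig,
    turgor_from_isotonic,
)
from .wall import WallGeometry, wall_tension, young_modulus

logger = logging.getLogger(__name__)

VOLUME_COLUMNS = (
    "strain",
    "replicate",
    "is_protoplast",
    "sorbitol_mol_per_L",
    "medium_baseline_mol_per_L",
    "cell_id",
    "volume_um3",
)
INTENSITY_COLUMNS = (
    "strain",
    "replicate",
    "slide_id",
    "is_protoplast",
    "sorbitol_mol_per_L",
    "medium_baseline_mol_per_L",
    "cell_id",
    "roi_mean",
    "background_mean",
)
TRACK_COLUMNS = (
    "strain",
    "replicate",
    "is_protoplast",
    "sorbitol_mol_per_L",
    "medium_baseline_mol_per_L",
    "track_id",
    "frame",
    "t_s",
    "x_um",
    "y_um",
)


class SchemaError(ValueError):
    """A table is missing required columns or is structurally invalid."""


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {sorted(missing)}")
    return df


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False}
    return series.astype(str).str.strip().str.lower().map(mapping)


def _drop_bad_rows(
    df: pd.DataFrame, bad: pd.Series, path: str | Path, reason: str
) -> pd.DataFrame:
    if bad.any():
        # +2: header line plus 1-based counting
        lines = [int(i) + 2 for i in df.index[bad][:10]]
        logger.warning(
            "%s: rejected %d row(s) (%s), e.g. file line(s) %s",
            Path(path).name,
            int(bad.sum()),
            reason,
            lines,
        )
        df = df[~bad]
    return df


def _validate_common(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    df = df.copy()
    df["is_protoplast"] = _coerce_bool(df["is_protoplast"])
    for col in ("sorbitol_mol_per_L", "medium_baseline_mol_per_L"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (
        df["is_protoplast"].isna()
        | df["sorbitol_mol_per_L"].isna()
        | (df["sorbitol_mol_per_L"] < 0)
        | df["medium_baseline_mol_per_L"].isna()
        | (df["medium_baseline_mol_per_L"] < 0)
    )
    return _drop_bad_rows(df, bad, path, "invalid condition annotation")


def read_volume_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell volume table; malformed rows are dropped."""
    df = _validate_common(_read_table(path, VOLUME_COLUMNS), path)
    df["volume_um3"] = pd.to_numeric(df["volume_um3"], errors="coerce")
    df = _drop_bad_rows(
        df, df["volume_um3"].isna() | (df["volume_um3"] <= 0), path,
        "non-positive or non-numeric volume",
    )
    logger.info("%s: %d cell rows retained", Path(path).name, len(df))
    return df.reset_index(drop=True)


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell intensity table; malformed rows are dropped."""
    df = _validate_common(_read_table(path, INTENSITY_COLUMNS), path)
    for col in ("roi_mean", "background_mean"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _drop_bad_rows(
        df, df["roi_mean"].isna() | df["background_mean"].isna(), path,
        "non-numeric intensity",
    )
    logger.info("%s: %d cell rows retained", Path(path).name, len(df))
    return df.reset_index(drop=True)


def read_track_table(path: str | Path, dt_rtol: float = 1e-3) -> pd.DataFrame:
    """Read and validate a particle-track table.

    Frames must increase within each track and the frame interval must be
    uniform within ``dt_rtol``; a track mixing intervals is a validation
    error (it would corrupt the MSD lag grid).
    """
    df = _validate_common(_read_table(path, TRACK_COLUMNS), path)
    for col in ("frame", "t_s", "x_um", "y_um"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _drop_bad_rows(
        df,
        df[["frame", "t_s", "x_um", "y_um"]].isna().any(axis=1),
        path,
        "non-numeric track row",
    )
    df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    same_track = df["track_id"].eq(df["track_id"].shift())
    dt = df["t_s"].diff()
    if (same_track & (dt <= 0)).any():
        raise SchemaError(f"{Path(path).name}: non-increasing times within a track")
    first_dt = df.groupby("track_id")["t_s"].transform(lambda t: t.diff().iloc[1] if len(t) > 1 else np.nan)
    mixed = same_track & first_dt.notna() & ((dt - first_dt).abs() > dt_rtol * first_dt)
    if mixed.any():
        bad_tracks = sorted(df.loc[mixed, "track_id"].unique()[:5].tolist())
        raise SchemaError(
            f"{Path(path).name}: mixed frame intervals within track(s) {bad_tracks}"
        )
    logger.info(
        "%s: %d localizations in %d tracks retained",
        Path(path).name,
        len(df),
        df["track_id"].nunique(),
    )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV (or TSV for a .tsv suffix), no index column."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


def _single_baseline(df: pd.DataFrame) -> float:
    baselines = df["medium_baseline_mol_per_L"].unique()
    if len(baselines) != 1:
        raise ValueError(
            f"expected one medium baseline per table, found {sorted(baselines)}"
        )
    return float(baselines[0])


# ---------------------------------------------------------------------------
# method drivers
# ---------------------------------------------------------------------------

def run_volume_method(
    df: pd.DataFrame, statistic: str = "median"
) -> tuple[IsotonicEstimate, volume_mod.BVHFit]:
    """Volume pipeline: per-condition summaries -> BVH fit -> inversion.

    Protoplast replicates of each condition enter the fit as distinct
    points; the intact-cell target is the mean of per-replicate summaries
    with their SD as its spread.
    """
    baseline = _single_baseline(df)
    strain = str(df["strain"].iloc[0])
    proto = df[df["is_protoplast"]]
    intact = df[~df["is_protoplast"]]
    if proto.empty or intact.empty:
        raise ValueError("volume table needs both protoplast and intact rows")

    populations = []
    for (c_sorb, _rep), group in proto.groupby(["sorbitol_mol_per_L", "replicate"]):
        cond = OsmoticCondition(
            strain_label=strain,
            sorbitol_conc=float(c_sorb),
            medium_baseline_conc=baseline,
            is_protoplast=True,
        )
        populations.append(
            volume_mod.VolumePopulation.from_volumes(
                cond, group["volume_um3"].to_numpy(), statistic
            )
        )
    fit = volume_mod.fit_boyle_vant_hoff(populations)
    target, spread = volume_mod.summarize_population(
        intact["volume_um3"].to_numpy(),
        statistic,
        replicate_labels=intact["replicate"].to_numpy(),
    )
    estimate = volume_mod.invert_bvh(
        fit, target, baseline, target_volume_spread=spread, n=len(proto)
    )
    return estimate, fit


def run_intensity_method(
    df: pd.DataFrame, window: tuple[float, float] | None = None
) -> tuple[IsotonicEstimate, intensity_mod.IntensityLinearFit]:
    """Intensity pipeline: slide calibration -> normalization -> fit -> inversion."""
    baseline = _single_baseline(df)
    strain = str(df["strain"].iloc[0])
    intact = df[~df["is_protoplast"]]
    proto = df[df["is_protoplast"]]
    if proto.empty or intact.empty:
        raise ValueError("intensity table needs both protoplast and intact rows")

    calibrations = {}
    for slide, group in intact.groupby("slide_id"):
        corrected = (group["roi_mean"] - group["background_mean"]).to_numpy()
        calibrations[str(slide)] = intensity_mod.IntensityCalibration(
            slide_id=str(slide), intact_mean=float(corrected.mean())
        )

    def records_of(sub: pd.DataFrame) -> list[intensity_mod.IntensityRecord]:
        return [
            intensity_mod.IntensityRecord(
                condition=OsmoticCondition(
                    strain_label=strain,
                    sorbitol_conc=float(r.sorbitol_mol_per_L),
                    medium_baseline_conc=baseline,
                    is_protoplast=bool(r.is_protoplast),
                ),
                slide_id=str(r.slide_id),
                cell_id=str(r.cell_id),
                roi_mean=float(r.roi_mean),
                background_mean=float(r.background_mean),
            )
            for r in sub.itertuples()
        ]

    norm_proto = intensity_mod.correct_and_normalize(records_of(proto), calibrations)
    norm_intact = intensity_mod.correct_and_normalize(records_of(intact), calibrations)

    fit = intensity_mod.fit_intensity_vs_concentration(
        proto["sorbitol_mol_per_L"].to_numpy(), norm_proto, window=window
    )
    kept_intact = norm_intact[np.isfinite(norm_intact)]
    intact_var = (
        float(np.var(kept_intact, ddof=1) / kept_intact.size)
        if kept_intact.size > 1
        else 0.0
    )
    n_used = int(np.isfinite(norm_proto).sum())
    estimate = intensity_mod.invert_intensity(
        fit, intact_normalized_target=1.0, intact_var=intact_var, n=n_used
    )
    return estimate, fit


def _deff_from_arrays(
    tid: np.ndarray,
    frame: np.ndarray,
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    n_points: int,
    min_track_length: int,
    intercept: bool = False,
) -> rheology_mod.DeffEstimate:
    """Per-condition D_eff; vectorizes when all tracks share one length."""
    order = np.lexsort((frame, tid))
    tid = tid[order]
    t = t[order]
    x = x[order]
    y = y[order]
    ids, starts, counts = np.unique(tid, return_index=True, return_counts=True)

    min_needed = max(min_track_length, n_points + 1)
    if np.all(counts == counts[0]) and counts[0] >= min_needed:
        length = int(counts[0])
        curves = rheology_mod.msd_curves_from_arrays(
            t[:length], x.reshape(-1, length), y.reshape(-1, length), n_points
        )
    else:
        curves = []
        n_short = 0
        for i, start in enumerate(starts):
            stop = start + counts[i]
            if counts[i] < min_needed:
                n_short += 1
                continue
            track = rheology_mod.Track(
                track_id=str(ids[i]),
                times=tuple(t[start:stop]),
                x=tuple(x[start:stop]),
                y=tuple(y[start:stop]),
            )
            curves.append(rheology_mod.compute_msd(track, n_points))
        if n_short:
            logger.warning(
                "excluded %d/%d tracks shorter than %d frames",
                n_short,
                len(ids),
                min_needed,
            )
    return rheology_mod.fit_deff(curves, n_points, intercept=intercept)


def run_rheology_method(
    df: pd.DataFrame,
    n_points: int = rheology_mod.DEFAULT_MSD_POINTS,
    min_track_length: int = rheology_mod.DEFAULT_MIN_TRACK_LENGTH,
    d0: float = rheology_mod.D0_WATER_40NM,
    space: str = "log",
    intercept: bool = False,
) -> tuple[IsotonicEstimate, rheology_mod.PhilliesFit, dict[float, rheology_mod.DeffEstimate]]:
    """Rheology pipeline: per-condition MSD/D_eff -> Phillies fit -> inversion."""
    baseline = _single_baseline(df)
    is_proto = df["is_protoplast"].to_numpy()
    if not is_proto.any() or is_proto.all():
        raise ValueError("track table needs both protoplast and intact rows")
    c_sorb_all = df["sorbitol_mol_per_L"].to_numpy()
    tid = df["track_id"].to_numpy()
    frame = df["frame"].to_numpy()
    t = df["t_s"].to_numpy()
    x = df["x_um"].to_numpy()
    y = df["y_um"].to_numpy()

    def deff_of(mask: np.ndarray) -> rheology_mod.DeffEstimate:
        return _deff_from_arrays(
            tid[mask], frame[mask], t[mask], x[mask], y[mask],
            n_points, min_track_length, intercept,
        )

    per_condition: dict[float, rheology_mod.DeffEstimate] = {}
    for c_sorb in np.unique(c_sorb_all[is_proto]):
        est = deff_of(is_proto & (c_sorb_all == c_sorb))
        per_condition[float(c_sorb)] = est
        logger.info(
            "condition %.3g mol/L: D_eff = %.4g +/- %.2g um^2/s (%d tracks)",
            c_sorb, est.d_eff, est.sem, est.n_tracks,
        )
    d_intact = deff_of(~is_proto)

    concentrations = sorted(per_condition)
    fit = rheology_mod.fit_phillies(
        concentrations,
        [per_condition[c] for c in concentrations],
        c0_medium=baseline,
        d0=d0,
        space=space,
    )
    estimate = rheology_mod.invert_phillies(fit, d_intact)
    # report the protoplast track count as the estimate's problem size
    n_proto_tracks = sum(e.n_tracks for e in per_condition.values())
    estimate = replace(estimate, n=n_proto_tracks)
    return estimate, fit, per_condition


# ---------------------------------------------------------------------------
# study configuration and report
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Configuration of one study run (one strain)."""

    strain: str
    medium_baseline_mol_per_L: float
    temperature_K: float = DEFAULT_TEMPERATURE_K
    volume_table: Path | None = None
    intensity_table: Path | None = None
    track_table: Path | None = None
    volume_statistic: str = "median"
    intensity_window: tuple[float, float] | None = None
    msd_n_points: int = rheology_mod.DEFAULT_MSD_POINTS
    min_track_length: int = rheology_mod.DEFAULT_MIN_TRACK_LENGTH
    phillies_d0: float = rheology_mod.D0_WATER_40NM
    phillies_space: str = "log"
    geometry: WallGeometry | None = None
    output_dir: Path = Path(".")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature must be > 0 K")
        for attr in ("volume_table", "intensity_table", "track_table"):
            value = getattr(self, attr)
            if value is not None:
                setattr(self, attr, Path(value))
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        inputs = raw.get("inputs", {})
        options = raw.get("options", {})
        geometry = raw.get("geometry")

        def resolve(p):
            if p is None:
                return None
            p = Path(p)
            return p if p.is_absolute() else path.parent / p

        window = options.get("intensity_window")
        return cls(
            strain=raw["strain"],
            medium_baseline_mol_per_L=float(raw["medium_baseline_mol_per_L"]),
            temperature_K=float(raw.get("temperature_K", DEFAULT_TEMPERATURE_K)),
            volume_table=resolve(inputs.get("volume_table")),
            intensity_table=resolve(inputs.get("intensity_table")),
            track_table=resolve(inputs.get("track_table")),
            volume_statistic=options.get("volume_statistic", "median"),
            intensity_window=tuple(window) if window else None,
            msd_n_points=int(options.get("msd_n_points", rheology_mod.DEFAULT_MSD_POINTS)),
            min_track_length=int(
                options.get("min_track_length", rheology_mod.DEFAULT_MIN_TRACK_LENGTH)
            ),
            phillies_d0=float(options.get("phillies_d0", rheology_mod.D0_WATER_40NM)),
            phillies_space=options.get("phillies_space", "log"),
            geometry=(
                WallGeometry(
                    radius_um=float(geometry["radius_um"]),
                    thickness_nm=float(geometry["thickness_nm"]),
                    elastic_strain=float(geometry["strain"]),
                )
                if geometry
                else None
            ),
            output_dir=resolve(raw.get("output_dir", ".")) or path.parent,
            seed=int(raw.get("seed", 0)),
        )


def _method_entry(estimate: IsotonicEstimate, turgor: TurgorResult, **extra) -> dict:
    entry = {
        "c_iso_mol_per_L": estimate.c_iso,
        "c_iso_err_mol_per_L": estimate.c_iso_err,
        "n": estimate.n,
        "pressure_MPa": turgor.pressure_MPa,
        "pressure_err_MPa": turgor.pressure_err_MPa,
    }
    if estimate.note:
        entry["note"] = estimate.note
    entry.update(extra)
    return entry


def run_pipeline(config: StudyConfig) -> dict:
    """Execute every method whose input table is configured; build the report.

    With two or more methods the report carries the cross-method average row
    (mean with the between-method SD); with one method the average is
    omitted with a notice.  Raises if no method is runnable.
    """
    estimates: list[IsotonicEstimate] = []
    methods: dict[str, dict] = {}

    if config.volume_table is not None:
        df = read_volume_table(config.volume_table)
        est, fit = run_volume_method(df, statistic=config.volume_statistic)
        estimates.append(est)
        methods["volume"] = _method_entry(
            est,
            turgor_from_isotonic(est, config.temperature_K),
            bvh_m0=fit.m0,
            bvh_b0=fit.b0,
            bvh_r_squared=fit.r_squared,
        )
    if config.intensity_table is not None:
        df = read_intensity_table(config.intensity_table)
        est, fit = run_intensity_method(df, window=config.intensity_window)
        estimates.append(est)
        methods["intensity"] = _method_entry(
            est,
            turgor_from_isotonic(est, config.temperature_K),
            slope=fit.slope,
            intercept=fit.intercept,
            fit_window=list(fit.fit_window),
        )
    if config.track_table is not None:
        df = read_track_table(config.track_table)
        est, fit, _ = run_rheology_method(
            df,
            n_points=config.msd_n_points,
            min_track_length=config.min_track_length,
            d0=config.phillies_d0,
            space=config.phillies_space,
        )
        estimates.append(est)
        methods["rheology"] = _method_entry(
            est,
            turgor_from_isotonic(est, config.temperature_K),
            phillies_beta=fit.beta,
            phillies_d0=fit.d0,
        )

    if not methods:
        raise ValueError("no method runnable: configure at least one input table")

    report: dict = {
        "strain": config.strain,
        "temperature_K": config.temperature_K,
        "medium_baseline_mol_per_L": config.medium_baseline_mol_per_L,
        "methods": methods,
        "average": None,
        "notice": None,
    }
    if len(estimates) >= 2:
        avg_c = combine_isotonic(estimates)
        avg_p = combine_methods(
            [turgor_from_isotonic(e, config.temperature_K) for e in estimates]
        )
        report["average"] = {
            "c_iso_mol_per_L": avg_c.c_iso,
            "c_iso_err_mol_per_L": avg_c.c_iso_err,
            "pressure_MPa": avg_p.pressure_MPa,
            "pressure_err_MPa": avg_p.pressure_err_MPa,
        }
    else:
        report["notice"] = "single method available; cross-method average omitted"

    if config.geometry is not None and report["average"] is not None:
        p = report["average"]["pressure_MPa"]
        g = config.geometry
        report["wall"] = {
            "radius_um": g.radius_um,
            "thickness_nm": g.thickness_nm,
            "elastic_strain": g.elastic_strain,
            "young_modulus_MPa": young_modulus(
                p, g.radius_um, g.thickness_nm, g.elastic_strain
            ),
            "tension_N_per_m": wall_tension(p, g.radius_um),
        }
    return report


def render_report_markdown(report: dict) -> str:
    """Human-readable table mirroring the per-method / average layout.

    Concentrations and pressures are shown at two decimals; the JSON
    report keeps full precision.
    """
    lines = [
        f"# Turgor report: {report['strain']}",
        "",
        f"Temperature: {report['temperature_K']} K; medium baseline: "
        f"{report['medium_baseline_mol_per_L']} mol/L",
        "",
        "| Method | c_iso (mol/L) | Turgor (MPa) | n |",
        "|---|---|---|---|",
    ]
    for name, entry in report["methods"].items():
        lines.append(
            f"| {name} | {entry['c_iso_mol_per_L']:.2f} +/- "
            f"{entry['c_iso_err_mol_per_L']:.2f} | "
            f"{entry['pressure_MPa']:.2f} +/- "
            f"{entry['pressure_err_MPa']:.2f} | {entry['n']} |"
        )
    avg = report.get("average")
    if avg is not None:
        lines.append(
            f"| average | {avg['c_iso_mol_per_L']:.2f} +/- "
            f"{avg['c_iso_err_mol_per_L']:.2f} | "
            f"{avg['pressure_MPa']:.2f} +/- "
            f"{avg['pressure_err_MPa']:.2f} | |"
        )
    if report.get("notice"):
        lines += ["", f"Note: {report['notice']}"]
    wall = report.get("wall")
    if wall is not None:
        lines += [
            "",
            f"Wall mechanics (R = {wall['radius_um']} um, h = "
            f"{wall['thickness_nm']} nm, strain = {wall['elastic_strain']}): "
            f"Y = {round_sig(wall['young_modulus_MPa'], 2):g} MPa, "
            f"T = {round_sig(wall['tension_N_per_m'], 2):g} N/m",
        ]
    return "\n".join(lines) + "\n"


def write_report(report: dict, output_dir: str | Path) -> tuple[Path, Path]:
    """Serialize the report as JSON and markdown; returns the two paths."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    json_path = output_dir / "turgor_report.json"
    md_path = output_dir / "turgor_report.md"
    json_path.write_text(json.dumps(report, indent=2) + "\n")
    md_path.write_text(render_report_markdown(report))
    return json_path, md_path
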