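"""Configuration, CSV I/O and pipeline orchestration.

Binds the stages together: beam + jig → per-column dose/LET (with sensitivity
error bars) → synthetic or measured colony counts → survival fractions → LQ
fits → RBE-vs-LET report.  All outputs are CSV with a comment header that
records the package version, the seed and a hash of the configuration, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clonogenics import (PLATE_ROWS, LQFit, PlateCounts, fit_lq, lod_filter,
                          per_well_survival, plating_efficiency, rbe_let_table,
                          survival_fractions)
from .errors import (FitFailureError, InsufficientDataError, InvalidInputError,
                     SchemaError)
from .physics import (BeamSpec, ColumnCondition, JigGeometry, column_conditions,
                      default_jig)
from .sensitivity import SetupTolerances, column_conditions_with_uncertainty
from .synthdata import (H460_LQ_PARAMS, H460_PHOTON_PARAMS, H1437_LQ_PARAMS,
                        H1437_PHOTON_PARAMS, ExperimentDesign, simulate_experiment)

CELL_LINES = {
    "H460": (H460_LQ_PARAMS, H460_PHOTON_PARAMS),
    "H1437": (H1437_LQ_PARAMS, H1437_PHOTON_PARAMS),
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config; with no path, the packaged default reproducing the
    published setup."""
    if path is None:
        text = resources.files("braggmap.data").joinpath(
            "default_config.yaml").read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise InvalidInputError(f"config file not found: {p}")
        text = p.read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def beam_from_config(cfg: dict) -> BeamSpec:
    b = cfg.get("beam", {})
    return BeamSpec(
        nominal_energy=b.get("nominal_energy_MeV", 79.7),
        energy_spread_sigma=b.get("energy_spread_sigma_MeV", 0.677),
        spot_fwhm=b.get("spot_fwhm_cm", 3.3),
        spot_spacing=b.get("spot_spacing_cm", 1.0),
        dose_per_painting_col1=b.get("dose_per_painting_cGy", 2.6),
        mu_per_painting=b.get("mu_per_painting", 17.64),
    )


def jig_from_config(cfg: dict, beam: BeamSpec) -> JigGeometry:
    j = cfg.get("jig", {})
    template = JigGeometry(
        step_thicknesses=(0.0,) * 12,
        n_films=j.get("n_films", 3),
        film_thickness=j.get("film_thickness_cm", 0.0268),
        plate_bottom_thickness=j.get("plate_bottom_thickness_cm", 0.1),
        cell_layer_um=j.get("cell_layer_um", 5.0),
    )
    if "step_thicknesses_cm" in j:
        return replace(template, step_thicknesses=tuple(j["step_thicknesses_cm"]))
    base = default_jig(beam)
    return replace(template, step_thicknesses=base.step_thicknesses)


def tolerances_from_config(cfg: dict) -> SetupTolerances:
    t = cfg.get("tolerances", {})
    return SetupTolerances(
        step_thickness_cm=t.get("step_thickness_cm", 3e-4),
        film_thickness_rel=t.get("film_thickness_rel", 0.01),
        plate_bottom_cm=t.get("plate_bottom_cm", 5e-3),
        density_rel=t.get("density_rel", 0.005),
    )


def design_from_config(cfg: dict, seed: int | None = None) -> ExperimentDesign:
    d = cfg.get("design", {})
    line = d.get("cell_line", "H460")
    if line not in CELL_LINES:
        raise InvalidInputError(f"unknown cell line {line!r}; options {list(CELL_LINES)}")
    params, photon = CELL_LINES[line]
    return ExperimentDesign(
        cell_line_params=dict(params),
        photon_params=photon,
        seeded_per_well=d.get("seeded_per_well", 100),
        plating_efficiency=d.get("plating_efficiency", 0.8),
        dose_levels=tuple(d.get("dose_levels_Gy",
                                (0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 6.0))),
        plates_per_dose=d.get("plates_per_dose", 2),
        random_seed=seed if seed is not None else cfg.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _header(meta: dict | None) -> str:
    meta = meta or {}
    pairs = ", ".join(f"{k}={v}" for k, v in meta.items())
    return f"# braggmap {__version__}" + (f" | {pairs}" if pairs else "") + "\n"


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def column_table(conditions: list[ColumnCondition],
                 with_uncertainty: bool = False) -> pd.DataFrame:
    rows = []
    for c in conditions:
        row = {
            "column": c.column,
            "thickness_cm": c.step_thickness,
            "dose_rel": c.dose_relative,
            "dose_cGy_per_painting": c.dose_per_painting,
            "LET_d_keV_um": c.let_d,
            "beyond_range": int(c.beyond_range),
        }
        if with_uncertainty:
            row["dose_unc_cGy"] = c.dose_uncertainty
            row["LET_unc_keV_um"] = c.let_uncertainty
        rows.append(row)
    return pd.DataFrame(rows)


def write_plates_csv(plates: list[PlateCounts], counts_path: str | Path,
                     conditions_path: str | Path, meta: dict | None = None):
    """Counts as (plate, row, column, count); per-plate condition maps as
    (plate, column, dose_Gy, LET_keV_um)."""
    count_rows, cond_rows = [], []
    for plate in plates:
        pid = f"{plate.plate_id}-r{plate.replicate_id}"
        for i, row_letter in enumerate(PLATE_ROWS):
            for j in range(12):
                count_rows.append({"plate": pid, "row": row_letter,
                                   "column": j + 1,
                                   "count": int(plate.counts[i, j])})
        for col, (dose, let) in sorted(plate.conditions.items()):
            cond_rows.append({"plate": pid, "column": col,
                              "dose_Gy": dose, "LET_keV_um": let})
    write_table(pd.DataFrame(count_rows), counts_path, meta)
    write_table(pd.DataFrame(cond_rows), conditions_path, meta)


def read_plates_csv(counts_path: str | Path, conditions_path: str | Path,
                    seeded_per_well: int = 100) -> list[PlateCounts]:
    """Inverse of :func:`write_plates_csv` (lossless round trip)."""
    counts = read_table(counts_path)
    conds = read_table(conditions_path)
    for need, df, path in (({"plate", "row", "column", "count"}, counts, counts_path),
                           ({"plate", "column", "dose_Gy", "LET_keV_um"}, conds,
                            conditions_path)):
        missing = need - set(df.columns)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    plates = []
    for pid, group in counts.groupby("plate", sort=False):
        grid = np.zeros((8, 12), dtype=int)
        for idx, rec in group.iterrows():
            try:
                i = PLATE_ROWS.index(str(rec["row"]).strip().upper())
                j = int(rec["column"]) - 1
                if not 0 <= j < 12:
                    raise ValueError
                grid[i, j] = int(rec["count"])
            except (ValueError, IndexError) as exc:
                raise SchemaError(
                    f"{counts_path}: malformed row at index {idx}: "
                    f"{rec.to_dict()}") from exc
        cmap_rows = conds[conds["plate"] == pid]
        cmap = {int(r["column"]): (float(r["dose_Gy"]), float(r["LET_keV_um"]))
                for _, r in cmap_rows.iterrows()}
        base, _, rep = str(pid).rpartition("-r")
        plates.append(PlateCounts(
            counts=grid, conditions=cmap, seeded_per_well=seeded_per_well,
            plate_id=base or str(pid),
            replicate_id=int(rep) if rep.isdigit() else 1))
    return plates


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def fit_survival_by_let(plates: list[PlateCounts], pe: float,
                        seeded_per_well: int,
                        non_negative: bool = False) -> dict[float, LQFit]:
    """LQ fit per LET condition from per-well survival with LOD filtering."""
    wells = per_well_survival(plates, pe)
    fits = {}
    for let in sorted({p.let_d for p in wells}):
        pts = [p for p in wells if p.let_d == let]
        pts = lod_filter(pts, seeded_per_well, pe)
        try:
            fits[let] = fit_lq(pts, non_negative=non_negative,
                               label=f"LET {let:g}")
        except (InsufficientDataError, FitFailureError) as exc:
            warnings.warn(f"LET {let:g} keV/um condition not fittable "
                          f"({exc}); skipped")
    return fits


def run_pipeline(cfg: dict | None = None, outdir: str | Path = "braggmap_out",
                 seed: int | None = None) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle.

    Stages: transport (column conditions + sensitivity error bars), synthetic
    proton and photon clonogenic experiments, plating-efficiency and survival
    analysis, per-LET LQ fits, and the RBE-vs-LET table.  Returns the mapping
    of report name to file path.
    """
    cfg = cfg if cfg is not None else load_config()
    seed = seed if seed is not None else cfg.get("seed", 0)
    outdir = Path(outdir)
    meta = {"config": config_hash(cfg), "seed": seed}
    paths: dict[str, Path] = {}

    def _stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrap

    beam = _stage("beam")(beam_from_config, cfg)
    jig = _stage("geometry")(jig_from_config, cfg, beam)
    tol = tolerances_from_config(cfg)
    conditions = _stage("transport")(column_conditions_with_uncertainty, beam, jig, tol)

    paths["column_conditions"] = outdir / "column_conditions.csv"
    write_table(column_table(conditions), paths["column_conditions"], meta)
    paths["sensitivity"] = outdir / "sensitivity.csv"
    write_table(column_table(conditions, with_uncertainty=True),
                paths["sensitivity"], meta)

    design = design_from_config(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    plates = _stage("simulate-proton")(simulate_experiment, design, conditions, rng)
    paths["plate_counts"] = outdir / "plate_counts.csv"
    paths["plate_conditions"] = outdir / "plate_conditions.csv"
    write_plates_csv(plates, paths["plate_counts"], paths["plate_conditions"], meta)

    # photon reference: same dose levels, flat field, no jig
    photon_design = replace(design,
                            cell_line_params={0.0: design.photon_params})
    photon_conditions = [replace(c, dose_relative=1.0,
                                 dose_per_painting=beam.dose_per_painting_col1,
                                 let_d=0.0, beyond_range=False)
                         for c in conditions]
    photon_plates = _stage("simulate-photon")(
        simulate_experiment, photon_design, photon_conditions, rng)

    controls = [p for p in plates + photon_plates
                if max(d for d, _ in p.conditions.values()) == 0.0]
    control_wells = np.concatenate([p.counts.ravel() for p in controls])
    pe, _ = _stage("plating-efficiency")(
        plating_efficiency, control_wells, design.seeded_per_well)

    analysis = cfg.get("analysis", {})
    level = analysis.get("survival_level", 0.10)
    non_neg = analysis.get("non_negative", False)

    points = _stage("survival")(survival_fractions, plates, pe)
    surv = pd.DataFrame([{"dose_Gy": p.dose, "LET_keV_um": p.let_d, "sf": p.sf,
                          "sem": p.sem, "n_wells": p.n_wells} for p in points])
    paths["survival"] = outdir / "survival.csv"
    write_table(surv, paths["survival"], meta)

    fits = _stage("lq-fits")(fit_survival_by_let, plates, pe,
                             design.seeded_per_well, non_neg)
    photon_fit = _stage("lq-fits")(fit_survival_by_let, photon_plates, pe,
                                   design.seeded_per_well, non_neg)[0.0]
    table = _stage("rbe-table")(rbe_let_table, fits, photon_fit, level)
    paths["rbe_table"] = outdir / "rbe_vs_let.csv"
    write_table(table.round({"alpha_Gy-1": 3, "beta_Gy-2": 3, "rbe": 2,
                             "rbe_sd": 2}), paths["rbe_table"], meta)

    paths["log"] = outdir / "run_log.txt"
    with open(paths["log"], "w") as fh:
        fh.write(_header(meta))
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"plating efficiency (pooled controls): {pe:.4f}\n")
        fh.write(f"photon fit: alpha={photon_fit.alpha:.3f} "
                 f"beta={photon_fit.beta:.3f}\n")
        fh.write(f"stages complete: {', '.join(sorted(paths))}\n")
    return paths
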