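"""File formats, run configuration and the end-to-end pipeline runner.

All tables are plain CSV (UTF-8, comma separator, '.' decimal):

* plot table: trial, year, location, row, column, genotype, replicate,
  plot id and one column per trait (1-based integer field coordinates);
* spectra table: first column ``sample_id``, remaining columns numeric
  wavenumber headers;
* marker table: genotype rows, marker-id columns, values in {-1, 0, 1}
  (empty = missing), plus a companion chromosome map (marker, chrom);
* relationship matrices: square CSV with genotype labels as header row
  and first column.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, kinship, phenoadjust, spectra as spectra_mod
from .kinship import MarkerMatrix
from .phenoadjust import FieldTrial
from .spectra import RelationshipMatrix, SpectraSet

__all__ = [
    "read_plot_table", "write_plot_table",
    "read_spectra", "write_spectra",
    "read_markers", "write_markers",
    "read_relationship", "write_relationship",
    "RunConfig", "run_pipeline",
]

logger = logging.getLogger(__name__)

REQUIRED_PLOT_COLUMNS = ("trial", "year", "location", "row", "column",
                         "genotype", "plot_id")


def read_plot_table(path) -> list[FieldTrial]:
    """Read a plot CSV into one FieldTrial per (year, location)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot table missing required column(s): {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby(["year", "location", "genotype"]).cumcount() + 1
    trait_cols = [c for c in df.columns
                  if c not in REQUIRED_PLOT_COLUMNS + ("replicate",)]
    trials = []
    for (year, loc), sub in df.groupby(["year", "location"], sort=True):
        dup = sub.duplicated(subset=["row", "column"], keep=False)
        if dup.any():
            ids = sub.loc[dup, "plot_id"].tolist()
            raise ValueError(
                f"duplicate (row, column) in trial {loc}/{year}: plots {ids}")
        data = sub.rename(columns={"column": "col"})[
            ["plot_id", "genotype", "row", "col", "replicate"] + trait_cols
        ].reset_index(drop=True)
        trials.append(FieldTrial(data=data, year=str(year), location=str(loc),
                                 trait_names=trait_cols))
    return trials


def write_plot_table(trials: list[FieldTrial], path) -> None:
    frames = []
    for t in trials:
        f = t.data.rename(columns={"col": "column"}).copy()
        f.insert(0, "trial", f"{t.location}_{t.year}")
        f.insert(1, "year", t.year)
        f.insert(2, "location", t.location)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra(path) -> SpectraSet:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("first spectra column must be 'sample_id'")
    try:
        grid = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber header: {exc}") from exc
    return SpectraSet(values=df.iloc[:, 1:].to_numpy(dtype=float), grid=grid,
                      sample_ids=df["sample_id"].to_numpy())


def write_spectra(s: SpectraSet, path) -> None:
    s.to_frame().to_csv(path, index=False)


def read_markers(path, map_path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    v = df.to_numpy(dtype=float)
    bad = ~(np.isnan(v) | np.isin(v, (-1.0, 0.0, 1.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-trinary marker value {v[i, j]!r} at genotype "
            f"{df.index[i]!r}, marker {df.columns[j]!r}")
    cmap = pd.read_csv(map_path)
    chrom = pd.Series(cmap["chrom"].to_numpy(), index=cmap["marker"])
    return MarkerMatrix(values=df, chrom=chrom)


def write_markers(m: MarkerMatrix, path, map_path) -> None:
    m.values.to_csv(path)
    pd.DataFrame({"marker": m.chrom.index, "chrom": m.chrom.to_numpy()}
                 ).to_csv(map_path, index=False)


def read_relationship(path) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(values=df.to_numpy(dtype=float),
                              labels=df.index.to_numpy(),
                              source=f"file:{path}",
                              n_predictors=0)


def write_relationship(K: RelationshipMatrix, path) -> None:
    K.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end run.

    Either ``simulate`` is set (synthetic study parameters) or the input
    paths must point at existing files.  Seeds are explicit: there is no
    wall-clock fallback.
    """

    out_dir: str
    seed: int | None = None
    simulate: dict | None = None
    plot_csv: str | None = None
    spectra_csv: str | None = None
    marker_csv: str | None = None
    chrom_map_csv: str | None = None
    pretreatment: str = "sg1"
    sg_window: int = 37
    maf_threshold: float = 0.05
    impute_method: str = "column_mode"
    cv_sizes: list = dc_field(default_factory=lambda: [100, 200, 300, 400])
    cv_reps: int = 20
    cv_folds: int = 5
    traits: list = dc_field(default_factory=lambda: ["GY"])
    secondary_trait: str = "PC"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if self.simulate is None:
            for name in ("plot_csv", "spectra_csv", "marker_csv",
                         "chrom_map_csv"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when not simulating")
                if not Path(p).exists():
                    raise ValueError(f"{name}: no such file {p!r}")
        if self.pretreatment not in spectra_mod.PRETREATMENTS:
            raise ValueError(f"unknown pretreatment {self.pretreatment!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> pretreat -> adjust -> kinship -> cv
    -> bias -> indices, writing every artifact plus a manifest."""
    from . import simdata

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed, "inputs": {}}
    rng = np.random.default_rng(config.seed)

    # -- stage: inputs ------------------------------------------------------
    if config.simulate is not None:
        study = simdata.scenario_default(seed=config.seed, **config.simulate)
        trials = study.trials
        markers = study.markers
        write_plot_table(trials, out / "plots.csv")
        write_markers(markers, out / "markers.csv", out / "chrom_map.csv")
        manifest["stages"].append({"stage": "simulate",
                                   "seed": config.seed,
                                   "params": config.simulate})
    else:
        trials = read_plot_table(config.plot_csv)
        all_spec = read_spectra(config.spectra_csv)
        spec_idx = pd.Series(np.arange(all_spec.n_samples),
                             index=all_spec.sample_ids)
        for t in trials:
            rows = spec_idx.loc[t.data["plot_id"]].to_numpy()
            t.spectra = spectra_mod.snv_normalize(SpectraSet(
                values=all_spec.values[rows], grid=all_spec.grid,
                sample_ids=t.data["plot_id"].to_numpy()))
        markers = read_markers(config.marker_csv, config.chrom_map_csv)
        for name in ("plot_csv", "spectra_csv", "marker_csv", "chrom_map_csv"):
            manifest["inputs"][name] = _sha256(getattr(config, name))
        manifest["stages"].append({"stage": "load"})

    # -- stage: adjust (traits + spectra) -----------------------------------
    traits = [t for t in config.traits if t in trials[0].trait_names]
    need = set(traits) | {config.secondary_trait}
    adj = phenoadjust.two_stage_adjust(trials, sorted(need))
    for loc, f in adj.location_blues.items():
        f.to_csv(out / f"blues_{loc}.csv")
    adj.repeatability.to_csv(out / "repeatability.csv", index=False)
    adj.heritability.to_csv(out / "heritability.csv", index=False)
    spec_adj = phenoadjust.adjust_spectra(trials)
    manifest["stages"].append({
        "stage": "adjust",
        "substituted_wavenumbers": len(spec_adj.substitutions)})

    # -- stage: kinship ------------------------------------------------------
    m = kinship.impute_markers(markers, config.impute_method)
    m = kinship.maf_filter(m, config.maf_threshold)
    G = kinship.vanraden_g(m)
    write_relationship(G, out / "G.csv")
    manifest["stages"].append({"stage": "kinship",
                               "n_markers": m.n_markers})

    # -- stage: pretreat + H ------------------------------------------------
    H_by_loc = {}
    for loc in spec_adj.blues:
        s = spec_adj.spectra_set(loc)
        s = spectra_mod.pretreat(s, config.pretreatment,
                                 window=config.sg_window)
        s = spectra_mod.standardize_for_kernel(s)
        H = spectra_mod.build_h_matrix(s, source=loc)
        H_by_loc[loc] = H
        write_relationship(H, out / f"H_{config.pretreatment}_{loc}.csv")
    manifest["stages"].append({"stage": "pretreat",
                               "filter": config.pretreatment})

    # -- stage: cv + bias ----------------------------------------------------
    reports = []
    Gf = G.to_frame()
    for loc, blues in adj.location_blues.items():
        common = blues.index.intersection(pd.Index(G.labels))
        design = evaluation.make_cv_design(
            common.to_numpy(), sizes=config.cv_sizes, n_reps=config.cv_reps,
            k=config.cv_folds, seed=int(rng.integers(2**31)))
        Hf = H_by_loc[loc].to_frame()
        for trait in traits:
            y = blues[trait].dropna()
            sec = blues[config.secondary_trait]
            for model_tag, Kf in (("GBLUP", Gf), ("HBLUP", Hf)):
                preds = evaluation.run_cv(design, y, K=Kf.loc[common, common],
                                          tag=model_tag)
                rep = evaluation.cv_bias_report(
                    preds, sec, y, sec, location=loc, trait=trait)
                reports.append(rep)
    records = pd.concat([r.records for r in reports], ignore_index=True)
    records.to_csv(out / "cv_records.csv", index=False)
    summary = evaluation.summarize_cv(reports)
    summary.to_csv(out / "cv_summary.csv", index=False)
    manifest["stages"].append({"stage": "cv",
                               "n_records": int(len(records))})

    # -- stage: indices ------------------------------------------------------
    index_rows = []
    for loc, blues in adj.location_blues.items():
        if {"GY", config.secondary_trait} <= set(blues.columns):
            idx = evaluation.compute_indices(blues["GY"],
                                             blues[config.secondary_trait])
            f = idx.values.copy()
            f["location"] = loc
            index_rows.append(f)
    if index_rows:
        pd.concat(index_rows).to_csv(out / "indices.csv")
        manifest["stages"].append({"stage": "indices"})

    manifest["stages"].append({"stage": "report"})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
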