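"""End-to-end orchestration: data -> cleaning -> color models -> inference.

A run is fully described by a :class:`RunConfig` (readable from YAML)
plus nothing else: given the same config and seed, every stage is a pure
function and the outputs are byte-identical.  Each run writes its
artifacts (cleaned spectra, color points, distances, fraction tables,
model reports) into the output directory together with a manifest
recording the config hash, seed and library versions needed to
reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discriminability import pairwise_distances, study_means, summarize_study
from .colorspaces import color_point
from .spectra_io import clean_dataset, read_spectra, write_spectra
from .stats_analysis import (
    fit_saturation_model,
    fit_variation_model,
    regress_across_spaces,
    regroup_mixed_systems,
    saturation_table,
    variation_table,
)
from .synthetic_flora import ParameterJitter, StudyConfig, simulate_study
from .visual_systems import build_viewer, d65, flat_illuminant, quantum_catches

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("floravision")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    source: str = "synthetic"  # "synthetic" | "files"
    spectra_path: str | None = None
    metadata_path: str | None = None
    study: Mapping[str, Any] = field(default_factory=dict)  # StudyConfig overrides
    viewers: tuple[str, ...] = ("bee", "bird_VS")
    illuminant: str = "D65"
    thresholds: Mapping[str, float] = field(default_factory=dict)
    scheme: str = "main"
    bird_viewer: str = "bird_VS"
    out_dir: str = "floravision_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("synthetic", "files"):
            raise ValueError("source must be 'synthetic' or 'files'")
        if not self.viewers:
            raise ValueError("at least one viewer required")
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValueError("thresholds must be positive")
        if self.source == "files" and not (self.spectra_path and self.metadata_path):
            raise ValueError("file source requires spectra_path and metadata_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "viewers" in raw:
            raw["viewers"] = tuple(raw["viewers"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["viewers"] = list(self.viewers)
        d["study"] = dict(self.study)
        d["thresholds"] = dict(self.thresholds)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _study_config(c: RunConfig) -> StudyConfig:
    kwargs = dict(c.study)
    if "jitter" in kwargs:
        kwargs["jitter"] = {
            kind: ParameterJitter(**params) for kind, params in kwargs["jitter"].items()
        }
    kwargs.setdefault("seed", c.seed)
    return StudyConfig(**kwargs)


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
    return out


def run_pipeline(c: RunConfig) -> dict:
    """Execute a full run and return the manifest (also written to disk)."""
    out = Path(c.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if c.source == "synthetic":
        ds = _stage("simulate", simulate_study, _study_config(c))
    else:
        ds = _stage("read", read_spectra, c.spectra_path, c.metadata_path)
    ds = _stage("clean", clean_dataset, ds)
    ds.validate()

    write_spectra(ds, out / "cleaned_spectra.csv", out / "metadata.csv")

    ill = d65(ds.common_grid()) if c.illuminant == "D65" else flat_illuminant(ds.common_grid())
    viewers = []
    for label in c.viewers:
        kw = {}
        if label in c.thresholds:
            kw["threshold"] = c.thresholds[label]
        viewers.append(build_viewer(label, **kw))

    # per-flower color points
    pts = []
    for v in viewers:
        for fid, s in ds.spectra.items():
            p = color_point(quantum_catches(s, v, ill), v)
            pts.append(
                {
                    "flower_id": fid,
                    "viewer": v.label,
                    "space": p.space,
                    "coords": " ".join(f"{x:.6g}" for x in p.coords),
                    "hue": p.hue,
                    "saturation": p.saturation,
                }
            )
    pd.DataFrame(pts).to_csv(out / "color_points.csv", index=False)

    # pairwise distance matrices, long format
    dist_rows = []
    for pop_id in ds.populations():
        for v in viewers:
            dm = pairwise_distances(ds, pop_id, v, ill)
            iu = np.triu_indices(dm.n_flowers, k=1)
            for i, j in zip(*iu):
                dist_rows.append(
                    {
                        "population_id": pop_id,
                        "viewer": v.label,
                        "flower_a": dm.flower_ids[i],
                        "flower_b": dm.flower_ids[j],
                        "distance": dm.distances[i, j],
                    }
                )
    pd.DataFrame(dist_rows).to_csv(out / "distances.csv", index=False)

    pop_table, species_table = _stage("fractions", summarize_study, ds, viewers, ill)
    pop_table.to_csv(out / "fractions.csv", index=False)
    species_table.to_csv(out / "species_summary.csv", index=False)
    means = study_means(pop_table, species_table)
    means.to_csv(out / "study_means.csv", index=False)

    report: dict[str, Any] = {"study_means": means.to_dict(orient="records")}
    try:
        vt = regroup_mixed_systems(variation_table(pop_table, c.bird_viewer), c.scheme)
        fit = _stage("variation_model", fit_variation_model, vt, c.scheme)
        report["variation_model"] = {
            "grouping_scheme": fit.grouping_scheme,
            "lrt": fit.lrt.to_dict(orient="records"),
            "contrasts": fit.contrasts.to_dict(orient="records"),
            "cell_means": fit.cell_means.to_dict(orient="records"),
            "loglik": fit.loglik,
            "aicc": fit.aicc,
            "n_obs": fit.n_obs,
            "df_method": fit.df_method,
        }
        report["cross_space_regression"] = regress_across_spaces(vt).to_dict(orient="records")
        sat = regroup_mixed_systems(
            saturation_table(ds, viewers, ill).rename(columns={"viewer": "viewer_label"}),
            c.scheme,
        )
        sat = sat[sat["visual_system"].isin(["bee", "bird"])]
        sat = sat[sat["viewer_label"].isin(["bee", c.bird_viewer])]
        satfit = _stage("saturation_model", fit_saturation_model, sat)
        report["saturation_model"] = {
            "lrt": satfit.lrt.to_dict(orient="records"),
            "contrasts": satfit.contrasts.to_dict(orient="records"),
            "cell_means": satfit.cell_means.to_dict(orient="records"),
        }
    except ValueError as exc:
        # e.g. single pollination system: fractions still useful, models are not
        report["variation_model"] = {"skipped": str(exc)}

    (out / "model_report.json").write_text(json.dumps(report, indent=2, default=float))

    manifest = {
        "package_version": __version__,
        "config": c.to_dict(),
        "config_hash": c.config_hash(),
        "seed": c.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_flowers": ds.n_flowers,
        "n_populations": len(ds.populations()),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
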