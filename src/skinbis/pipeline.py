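"""End-to-end orchestration: simulate -> DRT -> pairs -> features -> train -> evaluate.

A :class:`RunConfig` bundles the geometry, grid, DRT and training settings
plus one global seed; :func:`run_end_to_end` executes the whole flow and
writes all artifacts (dataset CSV, DRT JSON + ranked-pair CSV per injection
pattern, per-pair model JSON, evaluation report JSON) into the output
directory.  Every artifact records the config hash and seed, and a re-run
with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import (
    DELTA_B,
    DatasetBuilder,
    GridConfig,
    LabeledDataset,
    assemble_dataset,
    generate_grid,
    STUDY_FREQS_KHZ,
)
from .dielectric import InvalidInputError, default_skin_stack, load_dielectric_config
from .drt import (
    fit_drt,
    find_relaxation_features,
    select_frequency_pairs,
    write_pairs_csv,
)
from .features import profile_components
from .fnn import TrainConfig, kfold_validate, save_model, train
from .forward_cem import MeshResolution, sweep_spectrum, write_spectrum_csv

__all__ = ["RunConfig", "run_end_to_end", "predict_rows"]


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end run."""

    grid: GridConfig = field(default_factory=GridConfig)
    resolution: MeshResolution = field(default_factory=MeshResolution)
    gap_m: float = 1e-3
    contact_impedance_ohm: float = 50.0
    current_a: float = 1e-3
    dielectric_file: str | None = None  # YAML stack; default tables otherwise
    balancing: str = "class-weights"
    # DRT settings: dense baseline sweep for pair ranking
    drt_sweep_hz: tuple[float, float, int] = (1e3, 3e5, 25)
    drt_lambda: float = 1e-3
    drt_points_per_decade: int = 10
    drt_extension_decades: float = 1.0
    # training
    training: TrainConfig = field(default_factory=TrainConfig)
    profile: str = "Z+theta+R+X"
    kfold: int = 5
    seed: int = 42
    outdir: str = "skinbis_out"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        try:
            kw = dict(doc)
            if "grid" in kw:
                g = kw.pop("grid")
                kw["grid"] = GridConfig(
                    patterns=tuple(g.get("patterns", GridConfig.patterns)),
                    delta_b=tuple(g.get("delta_b", GridConfig.delta_b)),
                    psi=tuple(g.get("psi", GridConfig.psi)),
                    dsigma=tuple(g.get("dsigma", GridConfig.dsigma)),
                    pairs_khz=tuple(tuple(p) for p in g.get("pairs_khz", GridConfig.pairs_khz)),
                )
            if "resolution" in kw:
                r = kw.pop("resolution")
                kw["resolution"] = MeshResolution(**{
                    k: tuple(v) if k == "layer_rows" else v for k, v in r.items()
                })
            if "training" in kw:
                kw["training"] = TrainConfig(**kw.pop("training"))
            if "drt_sweep_hz" in kw:
                kw["drt_sweep_hz"] = tuple(kw["drt_sweep_hz"])
            return RunConfig(**kw)
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"{path}: invalid run config: {exc}") from exc

    def digest(self) -> str:
        blob = json.dumps(
            {"grid": asdict(self.grid), "resolution": asdict(self.resolution),
             "gap_m": self.gap_m, "zc": self.contact_impedance_ohm,
             "current": self.current_a, "dielectric": self.dielectric_file,
             "balancing": self.balancing, "drt": [self.drt_sweep_hz,
                                                  self.drt_lambda,
                                                  self.drt_points_per_decade,
                                                  self.drt_extension_decades],
             "training": asdict(self.training), "profile": self.profile,
             "kfold": self.kfold, "seed": self.seed},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed,
            "skinbis_version": __version__}


def run_end_to_end(config: RunConfig, log=print) -> dict:
    """Execute the full flow; returns a summary dict (also written to report.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stack = (load_dielectric_config(config.dielectric_file)
             if config.dielectric_file else default_skin_stack())
    prov = _provenance(config)
    stage = "simulate-dataset"
    try:
        t0 = time.perf_counter()
        cases = generate_grid(config.grid)
        builder = DatasetBuilder(
            stack=stack, gap=config.gap_m,
            contact_impedance=config.contact_impedance_ohm,
            current=config.current_a, resolution=config.resolution,
        )
        features_df = builder.build(cases)
        dataset = assemble_dataset(features_df, policy=config.balancing,
                                   seed=config.seed)
        dataset.to_csv(out / "dataset.csv")
        log(f"[{stage}] {len(dataset)} rows, {builder.n_solves} field solves, "
            f"{time.perf_counter() - t0:.1f}s")

        stage = "drt-pairs"
        t0 = time.perf_counter()
        ranked_best: dict[str, tuple[float, float]] = {}
        flo, fhi, nf = config.drt_sweep_hz
        dense_f = np.logspace(np.log10(flo), np.log10(fhi), int(nf))
        for phi in config.grid.patterns:
            d_e = DELTA_B[config.grid.delta_b[0]]
            spec = sweep_spectrum(
                stack, builder._array(d_e), builder._pattern(phi), dense_f,
                meta={"phi": phi, "purpose": "drt_baseline"},
            )
            write_spectrum_csv(spec, out / f"baseline_spectrum_{phi}.csv")
            res = fit_drt(spec, lam=config.drt_lambda,
                          points_per_decade=config.drt_points_per_decade,
                          extension_decades=config.drt_extension_decades)
            res.to_json(out / f"drt_{phi}.json")
            feats = find_relaxation_features(res)
            candidates = [f * 1e3 for f in STUDY_FREQS_KHZ]
            ranked = select_frequency_pairs(feats, candidates)
            write_pairs_csv(ranked, out / f"pairs_{phi}.csv")
            # best ranked pair that is part of the configured grid
            grid_pairs = {(p[0] * 1e3, p[1] * 1e3) for p in config.grid.pairs_khz}
            best = next((p for p in ranked if (p.f_low, p.f_high) in grid_pairs),
                        ranked[0])
            ranked_best[phi] = (best.f_low, best.f_high)
        log(f"[{stage}] best pairs {ranked_best}, {time.perf_counter() - t0:.1f}s")

        stage = "train-evaluate"
        t0 = time.perf_counter()
        comps = profile_components(config.profile)
        reports = {}
        for phi, pair in ranked_best.items():
            sub = dataset.select(phi=phi, pair_hz=pair)
            X, y, w = sub.matrices(comps)
            rep = kfold_validate(X, y, k=config.kfold, seed=config.seed,
                                 config=config.training, sample_weight=w)
            net = train(X, y, config.training, seed=config.seed, sample_weight=w)
            pair_khz = (pair[0] / 1e3, pair[1] / 1e3)
            model_meta = {**prov, "phi": phi, "pair_hz": list(pair),
                          "profile": config.profile}
            save_model(net, out / f"model_{phi}_{pair_khz[0]:g}&{pair_khz[1]:g}.json",
                       meta=model_meta)
            reports[phi] = {"pair_hz": list(pair), **rep.to_dict()}
        log(f"[{stage}] {time.perf_counter() - t0:.1f}s")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    summary = {**prov, "n_cases": len(dataset), "best_pairs_hz": {
        k: list(v) for k, v in ranked_best.items()}, "reports": reports}
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def predict_rows(net, meta: dict, features_df: pd.DataFrame) -> pd.DataFrame:
    """Predictions (scores + class names) for rows in the dataset CSV dialect.

    Refuses feature rows whose frequency pair disagrees with the model's.
    """
    from .fnn import predict, CLASS_NAMES
    comps = profile_components(meta.get("profile", "Z+theta+R+X"))
    pair = meta.get("pair_hz")
    if pair is not None and {"f_low_hz", "f_high_hz"} <= set(features_df.columns):
        ok = (np.isclose(features_df["f_low_hz"], pair[0])
              & np.isclose(features_df["f_high_hz"], pair[1]))
        if not ok.all():
            raise InvalidInputError(
                "feature rows use a different frequency pair than the model "
                f"(model pair {pair})"
            )
    missing = [c for c in comps if c not in features_df.columns]
    if missing:
        raise InvalidInputError(f"feature file lacks columns {missing}")
    X = features_df[list(comps)].to_numpy(dtype=float)
    ks = predict(net, X)
    out = features_df.copy()
    out["predicted_k"] = ks
    out["predicted_class"] = [CLASS_NAMES[k] for k in ks]
    return out
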