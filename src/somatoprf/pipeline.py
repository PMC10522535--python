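"""End-to-end pipeline: simulate -> preprocess -> TW -> pRF fits -> reports.

Each stage reads and writes flat TSV artefacts in a run directory so the
pipeline can be resumed or inspected stage by stage; ``run_pipeline`` runs
the stages in order and records a manifest (seed, thresholds, versions).
All randomness is owned by the config seed; results are deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage import CoverageMapper
from .evaluation import aic_preference_matrix, dice_matrix, discretize_preferred
from .fitting import PRFEstimator, preprocess_timeseries
from .grid import write_sequence_tsv
from .io import read_matrix, read_table, write_matrix, write_table
from .models import MODEL_FAMILIES
from .roi import aggregate_prf_size, compare_groups, roi_volume
from .synth import SimulationConfig, generate_patch, simulate_session
from .tw import TravelingWaveAnalyzer

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "patch": {"shape": [12, 12]},
    "simulation": {},
    "fit": {"models": ["2d_gaussian"]},
    "thresholds": {"adjusted_r2": 0.0, "coherence": 0.3, "alpha": 0.05},
    "coverage": {"upsample_size": 20, "frame": 60, "n_components": 3},
}


def _merged(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def stage_simulate(cfg: dict, out: Path):
    patch_cfg = dict(cfg["patch"])
    patch_cfg["shape"] = tuple(patch_cfg.get("shape", (12, 12)))
    patch = generate_patch(**patch_cfg)
    sim_cfg = SimulationConfig(**{**cfg["simulation"], "seed": int(cfg["seed"])})
    session = simulate_session(patch, sim_cfg)
    write_table(session.truth, out / "truth.tsv")
    write_matrix(session.data, out / "data.tsv")
    write_sequence_tsv(session.seq, out / "stimulus.tsv")
    runs = [
        {"paradigm": p, "direction": d, "start": a, "stop": b}
        for p, d, (a, b) in session.run_info
    ]
    write_table(pd.DataFrame(runs), out / "runs.tsv")
    return session


def _load_session(out: Path):
    data = read_matrix(out / "data.tsv")
    runs = read_table(out / "runs.tsv")
    return data, runs


def stage_tw(cfg: dict, out: Path):
    data, runs = _load_session(out)
    tr = cfg["simulation"].get("tr", 2.0)
    results = {}
    for paradigm, name in (("between", "tw_digit"), ("within", "tw_pd")):
        sub = runs[runs["paradigm"] == paradigm]
        fwd = [r for r in sub.itertuples() if r.direction == "forward"]
        rev = [r for r in sub.itertuples() if r.direction == "reverse"]
        if not fwd:
            continue

        def run_psc(r):
            raw = data[:, r.start : r.stop]
            return preprocess_timeseries(raw, tr)

        fwd_ts = np.mean([run_psc(r) for r in fwd], axis=0)
        rev_ts = np.mean([run_psc(r) for r in rev], axis=0) if rev else None
        n = fwd[0].stop - fwd[0].start
        cycle_tp = n // cfg["simulation"].get("n_cycles", 12)
        analyzer = TravelingWaveAnalyzer(
            cycle_len_tp=cycle_tp, alpha=cfg["thresholds"]["alpha"]
        )
        analyzer.fit(fwd_ts, rev_ts)
        df = analyzer.results_frame()
        write_table(df, out / f"{name}.tsv")
        results[name] = df
    return results


def stage_fit(cfg: dict, out: Path):
    data, runs = _load_session(out)
    tr = cfg["simulation"].get("tr", 2.0)
    sim_cfg = SimulationConfig(**{**cfg["simulation"], "seed": int(cfg["seed"])})
    from .synth import _session_sequences
    from .grid import GridSpec

    session_seq, _ = _session_sequences(sim_cfg, GridSpec())
    psc = preprocess_timeseries(data, tr, run_boundaries=session_seq.run_boundaries)
    tables = {}
    for model in cfg["fit"].get("models", ["2d_gaussian"]):
        if model not in MODEL_FAMILIES:
            raise ValueError(f"fit stage: unknown model family {model!r}")
        est = PRFEstimator(
            seq=session_seq, model=model, max_nfev=cfg["fit"].get("max_nfev")
        )
        est.fit(psc)
        df = est.results_frame()
        write_table(df, out / f"fit_{model}.tsv")
        write_matrix(est.params_, out / f"params_{model}.tsv")
        tables[model] = df
    return tables


def stage_evaluate(cfg: dict, out: Path):
    results = {}
    aics = {}
    thr = cfg["thresholds"]["adjusted_r2"]
    for model in cfg["fit"].get("models", ["2d_gaussian"]):
        fit = read_table(out / f"fit_{model}.tsv")
        aics[model] = fit["aic"].to_numpy()
        for tw_name, col in (("tw_digit", "preferred_digit"), ("tw_pd", "preferred_pd")):
            path = out / f"{tw_name}.tsv"
            if not path.exists():
                continue
            tw = read_table(path)
            keep = (fit["adjusted_r2"] > thr).to_numpy() & (
                tw["coherence"] > cfg["thresholds"]["coherence"]
            ).to_numpy()
            mat = dice_matrix(
                tw["label"].to_numpy()[keep],
                discretize_preferred(fit[col].to_numpy()[keep]),
            )
            write_matrix(mat, out / f"dice_{tw_name}_{model}.tsv")
            results[f"dice_{tw_name}_{model}"] = mat
    if len(aics) > 1:
        mat, fams = aic_preference_matrix(aics)
        df = pd.DataFrame(mat, index=fams, columns=fams)
        df.to_csv(out / "aic_preference.tsv", sep="\t")
        results["aic_preference"] = df
    return results


def stage_coverage(cfg: dict, out: Path):
    truth = read_table(out / "truth.tsv")
    model = "2d_gaussian"
    path = out / f"fit_{model}.tsv"
    if not path.exists():
        return {}
    fit = read_table(path)
    params = read_matrix(out / f"params_{model}.tsv")
    from .models import PRF2DParams

    cov_cfg = cfg["coverage"]
    mapper = CoverageMapper(
        upsample_size=cov_cfg["upsample_size"],
        frame=cov_cfg["frame"],
        n_components=cov_cfg["n_components"],
    )
    thr = cfg["thresholds"]["adjusted_r2"]
    keep = fit["adjusted_r2"] > thr
    results = {}
    for area, sub in truth[keep.to_numpy()].groupby("area"):
        objs = [PRF2DParams(*params[v, :4]) for v in sub["voxel"]]
        cov, evr = mapper.roi_map(objs, sub["subject"].to_numpy(), roi=str(area))
        write_matrix(cov.extrapolated, out / f"coverage_{area}.tsv")
        results[str(area)] = (cov, evr)
    return results


def stage_report(cfg: dict, out: Path):
    truth = read_table(out / "truth.tsv")
    labels = truth[["voxel", "digit", "pd", "area", "subject"]]
    results = {}
    for model in cfg["fit"].get("models", ["2d_gaussian"]):
        fit = read_table(out / f"fit_{model}.tsv")
        for scheme in ("pd", "area"):
            agg = aggregate_prf_size(
                fit, labels, scheme, cfg["thresholds"]["adjusted_r2"]
            )
            write_table(agg, out / f"size_{scheme}_{model}.tsv")
            results[f"size_{scheme}_{model}"] = agg
            key = "pd" if scheme == "pd" else "area"
            size_col = "sigma_pd" if model == "1d_wd" else "sigma_d"
            groups = {
                str(g): v[size_col].to_numpy()
                for g, v in agg.groupby(key)
                if len(v) >= 2
            }
            if len(groups) >= 2:
                stats = compare_groups(groups)
                write_table(stats["tukey"], out / f"tukey_{scheme}_{model}.tsv")
                results[f"anova_{scheme}_{model}"] = {
                    "F": stats["F"],
                    "p": stats["p"],
                }
    vol = roi_volume(labels, scheme="area")
    write_table(vol, out / "roi_volume.tsv")
    results["roi_volume"] = vol
    return results


_STAGES = {
    "simulate": stage_simulate,
    "tw": stage_tw,
    "fit": stage_fit,
    "evaluate": stage_evaluate,
    "coverage": stage_coverage,
    "report": stage_report,
}


def run_pipeline(config: dict | None, out_dir, stages=None) -> dict:
    """Run pipeline stages in order, writing artefacts to ``out_dir``.

    Raises a stage-named error on failure; artefacts written before the
    failure are preserved.  Returns a dict of stage results.
    """
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "somatoprf": __version__,
        "numpy": np.__version__,
        "seed": int(cfg["seed"]),
        "thresholds": cfg["thresholds"],
        "config": {k: v for k, v in cfg.items() if k != "thresholds"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results = {}
    for name in stages or list(_STAGES):
        try:
            results[name] = _STAGES[name](cfg, out)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return results
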