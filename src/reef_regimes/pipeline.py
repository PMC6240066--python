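"""One-command orchestration of the full regime analysis.

Sequences the stages — synthesize (or load), harmonize, fit/select, assign,
community statistics, transitions — on either synthetic or user-supplied
survey tables, writing every stage's outputs as CSV plus a JSON run manifest
with seeds, row counts and checksums. A stage failure is recorded in the
manifest, completed outputs are left in place, and a resume marker points at
the failing stage.

Run as a script: ``python -m reef_regimes.pipeline --config run.yaml``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, harmonization as hz, regimes, transitions as tr
from .synthetic import GROUP_COLUMNS, GeneratorConfig, generate_profiles, \
    generate_surveys, generate_time_series

log = logging.getLogger(__name__)

STAGES = ("synthesize", "harmonize", "fit_regimes", "assign",
          "community_stats", "transitions")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``generator`` (synthetic mode) or the three input CSV paths must
    be provided. All randomness flows from ``seed`` via named substreams."""

    outdir: str = "results/run"
    generator: GeneratorConfig | None = None
    fish_csv: str | None = None
    benthic_csv: str | None = None
    meta_csv: str | None = None
    depth_min: float = 0.0
    depth_max: float = 30.0
    radius_m: float = 300.0
    k_min: int = 1
    k_max: int = 9
    min_prob: float = 0.95
    min_years: int = 3
    fit_drivers: bool = False
    nmds_max_sites: int = 300
    nmds_starts: int = 50
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        if self.generator is None and not (self.fish_csv and self.benthic_csv and self.meta_csv):
            raise ValueError("provide either a generator config or input CSV paths")
        if not (0 < self.min_prob <= 1):
            raise ValueError("min_prob must be in (0, 1]")
        if self.min_years < 2:
            raise ValueError("min_years must be >= 2")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("k range must satisfy 1 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        gen = payload.pop("generator", None)
        cfg = cls(**payload)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "seed": config.seed,
            "config": _config_dict(config),
            "stages": [],
        }
        self.profiles: pd.DataFrame | None = None
        self.model: regimes.RegimeModel | None = None
        self.state: hz.TransformState | None = None
        self.assignments: pd.DataFrame | None = None
        self.ts_profiles: pd.DataFrame | None = None

    def write(self, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False)
        return path

    def record(self, stage: str, outputs: list[Path], n_rows: int | None) -> None:
        self.manifest["stages"].append(
            {
                "name": stage,
                "status": "complete",
                "n_rows": n_rows,
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    gen = d.get("generator")
    if gen:
        for k, v in gen.items():
            if isinstance(v, np.ndarray):
                gen[k] = v.tolist()
            elif isinstance(v, dict):
                gen[k] = {kk: np.asarray(vv).tolist() for kk, vv in v.items()}
    return d


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_synthesize(run: _Run) -> None:
    cfg = run.config
    outputs: list[Path] = []
    if cfg.generator is None:
        run.manifest["stages"].append(
            {"name": "synthesize", "status": "skipped (user data)", "outputs": {}}
        )
        run._fish_csv, run._benthic_csv, run._meta_csv = (
            cfg.fish_csv, cfg.benthic_csv, cfg.meta_csv)
        return
    gen = dataclasses.replace(cfg.generator, seed=cfg.generator.seed + cfg.seed)
    profiles, truth = generate_profiles(gen)
    fish, benthic = generate_surveys(profiles, gen)
    meta = profiles.drop(columns=list(GROUP_COLUMNS))
    ts_profiles, ts_truth = generate_time_series(gen)
    outputs.append(run.write("fish.csv", fish))
    outputs.append(run.write("benthic.csv", benthic))
    outputs.append(run.write("meta.csv", meta))
    outputs.append(run.write("ts_profiles.csv", ts_profiles))
    # ground truth written for scoring only; analysis stages never read it
    outputs.append(run.write("ground_truth.csv", truth))
    outputs.append(run.write("ts_ground_truth.csv", ts_truth))
    run.ts_profiles = ts_profiles
    run._fish_csv = str(run.outdir / "fish.csv")
    run._benthic_csv = str(run.outdir / "benthic.csv")
    run._meta_csv = str(run.outdir / "meta.csv")
    run.record("synthesize", outputs, len(profiles))


def _stage_harmonize(run: _Run) -> None:
    cfg = run.config
    fish = pd.read_csv(run._fish_csv)
    benthic = pd.read_csv(run._benthic_csv)
    meta = pd.read_csv(run._meta_csv)
    for req, df in (("site_id", fish), ("site_id", benthic), ("site_id", meta)):
        if req not in df.columns:
            raise ValueError(f"input table lacks required column {req!r}")
    fish = hz.filter_exclusions(fish)
    fish, cap_report = hz.cap_outliers(fish)
    fish = hz.compute_biomass(fish)
    methods = fish["method"].unique()
    if len(methods) > 1:
        target = "belt" if "belt" in methods else methods[0]
        source = [m for m in methods if m != target][0]
        paired_sites = (
            fish.groupby("site_id")["method"].nunique().pipe(lambda s: s[s > 1]).index
        )
        paired = fish[fish["site_id"].isin(paired_sites)]
        factors = hz.derive_calibration(paired, target_method=target, source_method=source)
        fish = hz.apply_calibration(fish, factors, source_method=source)
        run.write("calibration_factors.csv", factors)
    profiles = hz.build_profile_matrix(fish, benthic)
    profiles = profiles.merge(meta, on="site_id", how="left")
    if "depth_m" in profiles:
        profiles = hz.filter_depth(profiles, cfg.depth_min, cfg.depth_max)
    if {"lat", "lon"} <= set(profiles.columns):
        profiles = hz.aggregate_spatial(profiles, radius_m=cfg.radius_m)
    run.profiles = profiles
    outputs = [run.write("profiles.csv", profiles), run.write("capping_report.csv", cap_report)]
    run.record("harmonize", outputs, len(profiles))


def _stage_fit(run: _Run) -> None:
    cfg = run.config
    X, state = hz.transform(run.profiles)
    model, table = regimes.select_model(
        X, k_range=range(cfg.k_min, cfg.k_max + 1),
        columns=[c for c in GROUP_COLUMNS],
    )
    run.model, run.state = model, state
    mpath = run.outdir / "model.yaml"
    regimes.save_model_yaml(model, state, mpath)
    outputs = [run.write("bic_table.csv", table), mpath]
    run.record("fit_regimes", outputs, len(table))


def _stage_assign(run: _Run) -> None:
    X = run.state.apply(run.profiles)
    assignments = regimes.assign_regimes(run.model, X,
                                         ids=run.profiles["site_id"].to_numpy())
    run.assignments = assignments
    raw_means = regimes.regime_means_raw(run.model, run.state)
    outputs = [run.write("assignments.csv", assignments),
               run.write("regime_means_raw.csv", raw_means)]
    run.record("assign", outputs, len(assignments))


def _stage_community(run: _Run) -> None:
    cfg = run.config
    rng = np.random.default_rng(cfg.seed + 101)
    prof = run.profiles
    X = prof[[c for c in GROUP_COLUMNS]].to_numpy(dtype=float) ** 0.25
    labels = run.assignments["regime"].to_numpy()
    idx = np.arange(len(prof))
    if len(idx) > cfg.nmds_max_sites:
        idx = np.sort(rng.choice(idx, size=cfg.nmds_max_sites, replace=False))
    D = community.bray_curtis(X[idx])
    ord_res = community.nmds(D, n_starts=cfg.nmds_starts, seed=cfg.seed + 102)
    coords = pd.DataFrame(ord_res.coordinates, columns=["nmds1", "nmds2"])
    coords.insert(0, "site_id", prof["site_id"].to_numpy()[idx])
    coords["regime"] = labels[idx]
    disp = community.dispersion_test(D, labels[idx], n_perm=cfg.n_perm,
                                     seed=cfg.seed + 103)
    summaries = community.regime_summaries(run.assignments, prof)
    outputs = [run.write("nmds_coordinates.csv", coords)]
    disp_df = disp.group_distances.rename_axis("regime").reset_index()
    disp_df["f_statistic"], disp_df["p_value"] = disp.f_statistic, disp.p_value
    outputs.append(run.write("dispersion.csv", disp_df))
    for key in ("island_by_regime", "shore_by_regime"):
        if key in summaries:
            outputs.append(run.write(f"{key}.csv", summaries[key].reset_index()))
    for key in ("depth_contrasts", "complexity_contrasts"):
        if key in summaries:
            outputs.append(run.write(f"{key}.csv", summaries[key].pairwise))
    meta_df = pd.DataFrame([{"nmds_stress": ord_res.stress,
                             "dispersion_F": disp.f_statistic,
                             "dispersion_p": disp.p_value}])
    outputs.append(run.write("community_summary.csv", meta_df))
    run.record("community_stats", outputs, len(coords))


def _stage_transitions(run: _Run) -> None:
    cfg = run.config
    if run.ts_profiles is None:
        run.manifest["stages"].append(
            {"name": "transitions", "status": "skipped (no time series)", "outputs": {}}
        )
        return
    ts = run.ts_profiles
    preds = regimes.predict_regime(run.model, ts, run.state,
                                   ids=ts["site_id"].to_numpy())
    preds = preds.rename(columns={"observation_id": "site_id"})
    preds["year"] = ts["year"].to_numpy()
    for d in ("pop_density", "dhw"):
        if d in ts:
            preds[d] = ts[d].to_numpy()
    retained = tr.filter_predictions(preds, min_prob=cfg.min_prob,
                                     min_years=cfg.min_years)
    recs = tr.transition_records(retained)
    outputs = []
    if len(recs):
        matrix = tr.build_transition_matrix(recs, n_regimes=run.model.n_components)
        for name, df in (("transition_counts", matrix.counts),
                         ("transition_row_proportions", matrix.row_proportions),
                         ("transition_overall_proportions", matrix.overall_proportions),
                         ("transition_wilson_lower", matrix.wilson_lower),
                         ("transition_wilson_upper", matrix.wilson_upper)):
            outputs.append(run.write(f"{name}.csv", df.reset_index()))
        outputs.append(run.write("transition_records.csv", recs))
        if cfg.fit_drivers:
            driver_rows = []
            K = run.model.n_components
            for i in range(1, K + 1):
                for j in range(1, K + 1):
                    for d in ("pop_density", "dhw"):
                        if d not in recs:
                            continue
                        res = tr.fit_driver_model(recs, (i, j), d,
                                                  seed=cfg.seed + 1000 + 10 * i + j)
                        row = {"transition": f"{i}->{j}", "driver": d,
                               "skipped": res.skipped, "reason": res.reason,
                               "n_occurrences": res.n_occurrences}
                        if not res.skipped:
                            row |= {"beta_lower": res.beta_interval[0],
                                    "beta_upper": res.beta_interval[1],
                                    "beta_mean": float(res.draws["beta"].mean()),
                                    "rhat_beta": res.rhat["beta"]}
                        driver_rows.append(row)
            outputs.append(run.write("driver_models.csv", pd.DataFrame(driver_rows)))
    run.record("transitions", outputs, len(recs))


_STAGE_FUNCS = {
    "synthesize": _stage_synthesize,
    "harmonize": _stage_harmonize,
    "fit_regimes": _stage_fit,
    "assign": _stage_assign,
    "community_stats": _stage_community,
    "transitions": _stage_transitions,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    On a stage failure the manifest records the failing stage and error, the
    completed stages' outputs remain on disk, and ``resume.json`` marks where
    to pick up."""
    run = _Run(config)
    for stage in STAGES:
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:  # noqa: BLE001 — failure is part of the manifest
            log.exception("stage %s failed", stage)
            run.manifest["stages"].append(
                {"name": stage, "status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            )
            (run.outdir / "resume.json").write_text(
                json.dumps({"resume_from": stage}, indent=2)
            )
            break
    with open(run.outdir / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=2, default=str)
    return run.manifest


def main(argv: list[str] | None = None) -> int:
    import argparse

    parser = argparse.ArgumentParser(description="Run the reef-regime pipeline")
    parser.add_argument("--config", required=True, help="RunConfig YAML")
    args = parser.parse_args(argv)
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    manifest = run_pipeline(RunConfig.from_yaml(args.config))
    failed = [s for s in manifest["stages"] if s.get("status") == "failed"]
    return 1 if failed else 0


if __name__ == "__main__":
    raise SystemExit(main())
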