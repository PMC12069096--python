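"""Configuration, file schemas and the end-to-end pipeline.

Stage order: simulate -> concentrations -> intake -> usual -> shortterm ->
hq -> disparities.  Every stage reads and writes plain CSV (UTF-8, comma,
header row, '.' decimal, empty string for missing) plus YAML for
configuration, ground truth and fitted parameters.  All randomness flows
from the single configured seed through named substreams, so a repeated run
with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concentrations as conc
from . import dietary_intake as dint
from . import exposure_metrics as expm
from .design import cohort_of_age
from .disparities import (BrrDesign, build_replicate_weights, fay_variance,
                          median_intake_ratio, intake_ratio_table,
                          BrrEstimate)
from .synthdata import TruthConfig, generate_all
from .twopart import TwoPartMixedModel, simulate_usual_intake, \
    summarize_groups

__all__ = ["PipelineConfig", "validate_and_load", "run_pipeline"]

log = logging.getLogger("hgpintake.pipeline")

PERCENTILE_CONVENTION = "weighted-hazen-interpolated"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated pipeline settings with defaults filled in."""

    seed: int = 0
    n_persons: int = 2000
    n_strata: int = 16
    weight_dispersion: float = 0.4
    n_foods: int = 40
    analytes: list | None = None          # None -> detection-rule selection
    scenarios: tuple = ("typical", "high", "max")
    min_detections: int = 10
    combine_testosterone: bool = True
    n_sim: int = 100
    n_quad: int = 15
    gtol: float = 1e-4
    max_starts: int = 3
    lam_bounds: tuple = (0.01, 1.0)
    brr_replicates: int = 32
    fay_factor: float = 0.3
    brr_mode: str = "refit"               # "refit" | "summary"
    disparity_analyte: str = "MGA"
    disparity_scenario: str = "typical"
    draws_output: tuple = (("MGA", "typical"),)
    adi_file: str | None = None
    make_plots: bool = False
    percentile_convention: str = PERCENTILE_CONVENTION

    def truth_config(self) -> TruthConfig:
        return TruthConfig(
            n_persons=self.n_persons, n_strata=self.n_strata,
            weight_dispersion=self.weight_dispersion, n_foods=self.n_foods,
            seed=self.seed)

    def brr_design(self) -> BrrDesign:
        return BrrDesign(n_replicates=self.brr_replicates,
                         fay_factor=self.fay_factor)


_KNOWN_KEYS = {
    "seed", "n_persons", "n_strata", "weight_dispersion", "n_foods",
    "analytes", "scenarios", "min_detections", "combine_testosterone",
    "n_sim", "n_quad", "gtol", "max_starts", "lam_bounds",
    "brr_replicates", "fay_factor", "brr_mode",
    "disparity_analyte", "disparity_scenario", "draws_output",
    "adi_file", "make_plots", "percentile_convention",
}


def validate_and_load(path) -> PipelineConfig:
    """Parse + validate a YAML config; all violations reported at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: top level must be a mapping")
    for key in sorted(set(raw) - _KNOWN_KEYS):
        log.warning("config %s: unknown key %r ignored", path, key)
        raw.pop(key)
    cfg = PipelineConfig(**{k: v for k, v in raw.items()
                            if k in _KNOWN_KEYS})
    errs = []
    for name in ("seed", "n_persons", "n_strata", "n_foods", "n_sim",
                 "n_quad", "max_starts", "brr_replicates",
                 "min_detections"):
        v = getattr(cfg, name)
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            errs.append(f"{name} must be an integer (got {v!r})")
        elif name != "seed" and v <= 0:
            errs.append(f"{name} must be positive (got {v})")
    if not 0 <= cfg.fay_factor < 1:
        errs.append(f"fay_factor must lie in [0, 1) (got {cfg.fay_factor})")
    if cfg.brr_mode not in ("refit", "summary"):
        errs.append(f"brr_mode must be 'refit' or 'summary' "
                    f"(got {cfg.brr_mode!r})")
    bad = [s for s in cfg.scenarios if s not in conc.SCENARIOS]
    if bad:
        errs.append(f"unknown scenarios {bad}; valid: {list(conc.SCENARIOS)}")
    lb = tuple(cfg.lam_bounds)
    if len(lb) != 2 or not 0 <= lb[0] < lb[1] <= 1:
        errs.append(f"lam_bounds must be (lo, hi) with 0 <= lo < hi <= 1 "
                    f"(got {cfg.lam_bounds!r})")
    cfg.lam_bounds = lb
    cfg.scenarios = tuple(cfg.scenarios)
    cfg.draws_output = tuple(tuple(x) for x in cfg.draws_output)
    if cfg.adi_file is not None and not Path(cfg.adi_file).exists():
        errs.append(f"adi_file {cfg.adi_file!r} does not exist")
    if errs:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errs))
    return cfg


# ---------------------------------------------------------------------------
# Seed fan-out and event log
# ---------------------------------------------------------------------------

def _derive_seed(master: int, *tags) -> int:
    import zlib
    key = tuple(zlib.crc32(t.encode()) if isinstance(t, str) else int(t)
                for t in tags)
    ss = np.random.SeedSequence(master, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


class _EventLog:
    def __init__(self, outdir: Path):
        self.path = outdir / "events.jsonl"
        self._fh = open(self.path, "w")

    def emit(self, stage, **fields):
        rec = {"stage": stage, **fields}
        self._fh.write(json.dumps(rec, sort_keys=True) + "\n")
        self._fh.flush()
        log.info("[%s] %s", stage, fields)

    def close(self):
        self._fh.close()


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, na_rep="")


def read_assays(path) -> pd.DataFrame:
    """Assay CSV reader: empty concentration -> NaN (censored), empty
    paired_parent_id -> '' (unpaired)."""
    return pd.read_csv(path, keep_default_na=False,
                       na_values={"concentration_pg_mg": [""],
                                  "true_pg_mg": [""]},
                       dtype={"paired_parent_id": str})


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path, ev: _EventLog):
    data = generate_all(cfg.truth_config())
    _write_csv(data.persons, outdir / "persons.csv")
    _write_csv(data.recipes, outdir / "recipes.csv")
    _write_csv(data.recalls, outdir / "recalls.csv")
    _write_csv(data.assays, outdir / "assays.csv")
    truth = {
        "two_part": {c: p.to_dict() for c, p in data.truth.two_part.items()},
        "mean_beef_fat_proportion": data.truth.mean_beef_fat_proportion,
        "subgroup_median_ratios": {
            "|".join(k): v
            for k, v in data.truth.subgroup_median_ratios.items()},
        "seed": cfg.seed,
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    ev.emit("simulate", n_persons=len(data.persons),
            n_recall_items=len(data.recalls), n_assay_rows=len(data.assays))
    return data


def stage_concentrations(cfg: PipelineConfig, outdir: Path, ev: _EventLog):
    assays = read_assays(outdir / "assays.csv")
    selected, counts = conc.select_analytes(
        assays, cfg.min_detections, return_counts=True)
    if cfg.analytes is not None:
        selected = [a for a in cfg.analytes if a in selected]
    summaries = conc.summarize_by_tissue(assays, selected)
    scenario_tables = conc.build_scenario_tables(summaries)
    _write_csv(summaries, outdir / "table1_summaries.csv")
    _write_csv(scenario_tables, outdir / "scenario_tables.csv")
    tests = []
    for analyte in selected:
        pairs = conc.paired_values(assays, analyte)
        if pairs:
            w, p = conc.paired_fat_meat_test(pairs)
            tests.append({"analyte": analyte, "n_pairs": len(pairs),
                          "w_plus": w, "p_two_sided": p})
    _write_csv(pd.DataFrame(tests), outdir / "paired_fat_meat_tests.csv")
    ev.emit("concentrations", analytes=selected,
            detections={a: int(c) for a, c in counts.items()})
    return summaries, scenario_tables, selected


def stage_intake(cfg: PipelineConfig, outdir: Path, ev: _EventLog,
                 analytes):
    recalls = pd.read_csv(outdir / "recalls.csv")
    recipes = pd.read_csv(outdir / "recipes.csv")
    persons = pd.read_csv(outdir / "persons.csv")
    scen = pd.read_csv(outdir / "scenario_tables.csv")
    daily = dint.compute_daily_intakes(recalls, recipes, persons, scen,
                                       analytes=analytes,
                                       scenarios=cfg.scenarios)
    if cfg.combine_testosterone and {"T", "EpiT"} <= set(analytes):
        keys = ["person_id", "recall_day", "scenario"]
        t = daily[daily["analyte"] == "T"].set_index(keys)
        e = daily[daily["analyte"] == "EpiT"].set_index(keys)
        combo = t.copy()
        combo["ug_per_kg_day"] = expm.combined_testosterone(
            t["ug_per_kg_day"], e["ug_per_kg_day"].reindex(t.index))
        combo["analyte"] = "T+EpiT"
        daily = pd.concat([daily, combo.reset_index()], ignore_index=True)
    _write_csv(daily, outdir / "daily_intakes.csv")
    ev.emit("intake", n_rows=len(daily))
    return daily


def _modelling_frame(daily, recalls, persons, analyte, scenario):
    day_attrs = (recalls.groupby(["person_id", "recall_day"])
                 [["end_of_week", "second_recall"]].first().reset_index())
    sub = daily[(daily["analyte"] == analyte)
                & (daily["scenario"] == scenario)]
    df = (sub.merge(day_attrs, on=["person_id", "recall_day"], how="left")
          .merge(persons[["person_id", "gender", "age", "weight"]],
                 on="person_id", how="inner"))
    df[["end_of_week", "second_recall"]] = \
        df[["end_of_week", "second_recall"]].fillna(0)
    return df


def stage_usual(cfg: PipelineConfig, outdir: Path, ev: _EventLog, analytes):
    daily = pd.read_csv(outdir / "daily_intakes.csv")
    recalls = pd.read_csv(outdir / "recalls.csv")
    persons = pd.read_csv(outdir / "persons.csv")
    cohorts = cohort_of_age(persons["age"].to_numpy())
    eaters = (daily[daily["scenario"] == cfg.scenarios[0]]
              .assign(pos=lambda d: d["ug_per_kg_day"] > 0)
              .groupby("person_id")["pos"].sum())
    both = persons["person_id"].map(eaters).fillna(0) >= 2

    all_summaries = []
    draw_frames = []
    results = {}
    for analyte in analytes:
        for scenario in cfg.scenarios:
            frame = _modelling_frame(daily, recalls, persons, analyte,
                                     scenario)
            for cohort in ("child", "adult"):
                pmask = cohorts == cohort
                sub = frame[frame["person_id"].isin(
                    persons.loc[pmask, "person_id"])]
                if sub["person_id"].nunique() < 20:
                    continue
                model = TwoPartMixedModel.from_dataframe(
                    sub, cohort, amount_col="ug_per_kg_day",
                    lam_bounds=cfg.lam_bounds, n_quad=cfg.n_quad,
                    amount_scale="auto")
                res = model.fit(max_starts=cfg.max_starts, gtol=cfg.gtol,
                                seed=_derive_seed(cfg.seed, "fit", analyte,
                                                  scenario, cohort))
                results[(analyte, scenario, cohort)] = res
                fname = (f"params_{cohort}_{analyte}_{scenario}.yaml"
                         .replace("+", "plus"))
                with open(outdir / fname, "w") as fh:
                    yaml.safe_dump({
                        "params": res.params.to_dict(),
                        "llf": res.llf, "converged": res.converged,
                        "n_persons": model.n_persons,
                        "n_both_day_consumers": model.n_both_day_consumers,
                    }, fh, sort_keys=True)
                cp = persons[pmask].reset_index(drop=True)
                draws = simulate_usual_intake(
                    res.params, cp, n_sim=cfg.n_sim,
                    seed=_derive_seed(cfg.seed, "sim", analyte, scenario,
                                      cohort))
                summ = summarize_groups(draws, cp,
                                        both_day_eaters=both[pmask]
                                        .to_numpy())
                summ.insert(0, "scenario", scenario)
                summ.insert(0, "analyte", analyte)
                all_summaries.append(summ)
                if (analyte, scenario) in cfg.draws_output:
                    f = draws.to_frame()
                    f.insert(2, "scenario", scenario)
                    f.insert(2, "analyte", analyte)
                    draw_frames.append(f)
    summaries = pd.concat(all_summaries, ignore_index=True)
    _write_csv(summaries, outdir / "usual_summaries.csv")
    if draw_frames:
        _write_csv(pd.concat(draw_frames, ignore_index=True),
                   outdir / "usual_draws.csv")
    ev.emit("usual", n_models=len(results),
            combos=[f"{a}/{s}/{c}" for a, s, c in results])
    return results, summaries


def stage_shortterm(cfg: PipelineConfig, outdir: Path, ev: _EventLog):
    daily = pd.read_csv(outdir / "daily_intakes.csv")
    persons = pd.read_csv(outdir / "persons.csv")
    two_day = expm.two_day_average(daily)
    summaries = expm.summarize_two_day(two_day, persons)
    _write_csv(two_day, outdir / "two_day_averages.csv")
    _write_csv(summaries, outdir / "shortterm_summaries.csv")
    ev.emit("shortterm", n_persons=two_day["person_id"].nunique())
    return summaries


def stage_hq(cfg: PipelineConfig, outdir: Path, ev: _EventLog):
    registry = expm.AdiRegistry()
    if cfg.adi_file:
        with open(cfg.adi_file) as fh:
            registry = expm.AdiRegistry.from_dict(yaml.safe_load(fh))
    usual = pd.read_csv(outdir / "usual_summaries.csv")
    short = pd.read_csv(outdir / "shortterm_summaries.csv")
    report = pd.concat([
        expm.hq_report(usual, registry, kind="usual"),
        expm.hq_report(short, registry, kind="shortterm"),
    ], ignore_index=True)
    _write_csv(report, outdir / "hq_report.csv")
    with open(outdir / "adi.yaml", "w") as fh:
        yaml.safe_dump(registry.to_dict(), fh, sort_keys=True)
    ev.emit("hq", n_rows=len(report))
    return report


def _refit_ratio_estimates(cfg, outdir, persons, daily, recalls,
                           design) -> pd.DataFrame:
    """Full-refit BRR: refit the usual-intake model per replicate."""
    from .disparities import _DIMENSIONS, _cohort_masks

    analyte, scenario = cfg.disparity_analyte, cfg.disparity_scenario
    frame = _modelling_frame(daily, recalls, persons, analyte, scenario)
    masks = _cohort_masks(persons)
    reps_full = build_replicate_weights(persons.reset_index(drop=True),
                                        design)
    rows = []
    for set_name, cohort in (("children", "child"), ("women", "adult")):
        base = masks[set_name]
        if base.sum() == 0:
            continue
        sub_p = persons[base].reset_index(drop=True)
        reps = reps_full[base]
        wmap = dict(zip(sub_p["person_id"], range(len(sub_p))))
        sub_f = frame[frame["person_id"].isin(wmap)].reset_index(drop=True)
        sim_seed = _derive_seed(cfg.seed, "brr-sim", analyte, scenario,
                                set_name)
        fit_seed = _derive_seed(cfg.seed, "brr-fit", analyte, scenario,
                                set_name)

        def draws_under(weights, start=None):
            f = sub_f.copy()
            f["weight"] = f["person_id"].map(
                dict(zip(sub_p["person_id"], weights)))
            model = TwoPartMixedModel.from_dataframe(
                f, cohort, amount_col="ug_per_kg_day",
                lam_bounds=cfg.lam_bounds, n_quad=cfg.n_quad,
                amount_scale="auto")
            res = model.fit(start_params=start, max_starts=cfg.max_starts,
                            gtol=cfg.gtol, seed=fit_seed, warn_small=False)
            d = simulate_usual_intake(res.params, sub_p, n_sim=cfg.n_sim,
                                      seed=sim_seed)
            return d.draws, res

        base_w = sub_p["weight"].to_numpy(dtype=float)
        full_draws, full_res = draws_under(base_w)
        rep_draws = []
        failed = 0
        for r in range(reps.shape[1]):
            try:
                d, _ = draws_under(reps[:, r], start=full_res.params)
                rep_draws.append((r, d))
            except Exception as exc:  # noqa: BLE001
                failed += 1
                log.warning("BRR replicate %d refit failed: %s", r + 1, exc)
        if failed > design.max_failed_fraction * reps.shape[1]:
            raise RuntimeError(f"{failed} BRR replicate refits failed")
        for dim in _DIMENSIONS[set_name]:
            for cat in sorted(sub_p[dim].unique()):
                mask = (sub_p[dim] == cat).to_numpy()
                if mask.sum() == 0:
                    continue
                theta = median_intake_ratio(full_draws, mask, base_w)
                rep_est = [median_intake_ratio(d, mask, reps[:, r])
                           for r, d in rep_draws]
                var = fay_variance(rep_est, theta, design.fay_factor)
                se_log = np.sqrt(var) / theta if theta > 0 else np.inf
                from scipy import stats as st
                z = np.log(theta) / se_log if se_log > 0 else 0.0
                rows.append({
                    "cohort": set_name, "dimension": dim, "subgroup": cat,
                    "ratio": theta,
                    "ci_low": theta * np.exp(-1.959963984540054 * se_log),
                    "ci_high": theta * np.exp(1.959963984540054 * se_log),
                    "p_value": float(2 * st.norm.sf(abs(z))),
                    "n_replicates_used": len(rep_est),
                    "n_replicates_failed": failed,
                    "n_subgroup": int(mask.sum()),
                })
    return pd.DataFrame(rows)


def stage_disparities(cfg: PipelineConfig, outdir: Path, ev: _EventLog):
    persons = pd.read_csv(outdir / "persons.csv")
    design = cfg.brr_design()
    if cfg.brr_mode == "refit":
        daily = pd.read_csv(outdir / "daily_intakes.csv")
        recalls = pd.read_csv(outdir / "recalls.csv")
        table = _refit_ratio_estimates(cfg, outdir, persons, daily, recalls,
                                       design)
    else:
        draws = pd.read_csv(outdir / "usual_draws.csv")
        sub = draws[(draws["analyte"] == cfg.disparity_analyte)
                    & (draws["scenario"] == cfg.disparity_scenario)]
        if len(sub) == 0:
            raise RuntimeError(
                f"usual_draws.csv lacks {cfg.disparity_analyte}/"
                f"{cfg.disparity_scenario}; add it to draws_output")
        wide = sub.pivot_table(index="person_id", columns="draw",
                               values="usual_ug_per_kg_day")
        aligned = persons.set_index("person_id").join(wide, how="inner")
        mat = aligned[wide.columns].to_numpy()
        pframe = aligned.reset_index()[persons.columns]
        table = intake_ratio_table(mat, pframe, design)
    _write_csv(table, outdir / "intake_ratios.csv")
    if cfg.make_plots and len(table):
        from .disparities import plot_intake_ratios
        ax = plot_intake_ratios(table)
        ax.figure.savefig(outdir / "intake_ratios.png", dpi=150)
    ev.emit("disparities", n_rows=len(table), mode=cfg.brr_mode)
    return table


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "concentrations", "intake", "usual", "shortterm",
           "hq", "disparities")


def run_pipeline(cfg: PipelineConfig, outdir, stages=_STAGES) -> dict:
    """Run the configured stages in order; outputs land in ``outdir``.

    Returns a dict of the principal stage outputs.  A stage failure aborts
    with the stage name; outputs of completed stages remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev = _EventLog(outdir)
    ev.emit("start", seed=cfg.seed, stages=list(stages),
            percentile_convention=cfg.percentile_convention)
    out = {}
    analytes = cfg.analytes
    try:
        for stage in stages:
            t0 = time.perf_counter()
            if stage == "simulate":
                out["data"] = stage_simulate(cfg, outdir, ev)
            elif stage == "concentrations":
                _, scen, selected = stage_concentrations(cfg, outdir, ev)
                out["scenario_tables"] = scen
                analytes = selected
            elif stage == "intake":
                if analytes is None:
                    analytes = sorted(pd.read_csv(
                        outdir / "scenario_tables.csv")["analyte"].unique())
                out["daily"] = stage_intake(cfg, outdir, ev, analytes)
            elif stage == "usual":
                model_analytes = [a for a in
                                  sorted(pd.read_csv(
                                      outdir / "daily_intakes.csv")
                                      ["analyte"].unique())]
                out["usual"] = stage_usual(cfg, outdir, ev, model_analytes)
            elif stage == "shortterm":
                out["shortterm"] = stage_shortterm(cfg, outdir, ev)
            elif stage == "hq":
                out["hq"] = stage_hq(cfg, outdir, ev)
            elif stage == "disparities":
                out["ratios"] = stage_disparities(cfg, outdir, ev)
            else:
                raise ValueError(f"unknown stage {stage!r}")
            ev.emit(stage, elapsed_s=round(time.perf_counter() - t0, 3),
                    status="done")
    except Exception:
        ev.emit("abort", failed_stage=stage)
        ev.close()
        raise
    ev.emit("finish")
    ev.close()
    return out
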