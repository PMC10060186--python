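"""Config-driven orchestration: simulate -> score -> evaluate -> survival ->
repertoire, with a reproducible seed and a hashed output manifest.

``run_pipeline`` is a pure function of (config, input files): rerunning
with the same seed reproduces byte-identical outputs, which the manifest's
SHA-256 hashes make checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import evaluate_windows, orr, table1_csv
from .repertoire import cell_tables_by_timepoint, frequent_til, match_to_blood, \
    combined_frequency, morisita_horn, tracking_table
from .scoring import read_biomarker_csv, score_table, write_score_csv
from .survival import km_fit, logrank, univariate_screen
from .synthetic import CohortConfig, RepertoireConfig, generate_cohort, \
    generate_repertoires, read_clinical_csv, write_cohort_csv, \
    write_repertoire_files

log = logging.getLogger("cx3track")

__all__ = ["RunConfig", "run_pipeline", "demo_config"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Either simulation configs (``cohort``, ``repertoire``) or paths to
    existing input tables may be given; simulation is used when paths are
    absent.  ``theta`` is the score cutoff in percentage points;
    ``windows`` are the evaluation windows in weeks.
    """

    out_dir: str = "cx3track_out"
    seed: int = 0
    theta: float = 10.0
    windows: tuple = (3, 4, 6, 9)
    response_window_weeks: float = 12.0
    alpha: float = 0.05
    screen_alpha: float = 0.10
    biomarker_csv: str | None = None
    clinical_csv: str | None = None
    tumor_tsv: str | None = None
    cells_tsv: str | None = None
    cohort: CohortConfig = None
    repertoire: RepertoireConfig = None

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not self.windows:
            raise ValueError("windows must be non-empty")
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        if self.repertoire is None:
            self.repertoire = RepertoireConfig(seed=self.seed + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = raw.pop("cohort", None)
        rep = raw.pop("repertoire", None)
        cfg = cls(**raw)
        if cohort:
            cfg.cohort = CohortConfig(**cohort)
        if rep:
            cfg.repertoire = RepertoireConfig(**rep)
        return cfg


def demo_config(out_dir: str = "cx3track_demo", seed: int = 29) -> RunConfig:
    """The bundled demonstration run: 29 simulated patients, fixed seed."""
    return RunConfig(out_dir=out_dir, seed=seed,
                     cohort=CohortConfig(n_patients=29, seed=seed),
                     repertoire=RepertoireConfig(seed=seed + 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the report bundle to ``config.out_dir``.

    Outputs: score_table.csv, performance_table.csv (per-window 2x2
    metrics), diagnostics.json, survival_table.csv (per-covariate HRs),
    km_curves.csv, tracking_table.tsv, venn_counts.json and manifest.json.
    Returns a dict of in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    _stage("simulate/load")
    if config.biomarker_csv and config.clinical_csv:
        series_list = read_biomarker_csv(config.biomarker_csv)
        records = read_clinical_csv(config.clinical_csv)
    else:
        series_list, records = generate_cohort(config.cohort)
        write_cohort_csv(series_list, records, out / "biomarker.csv",
                         out / "clinical.csv")
    results["cohort"] = (series_list, records)

    _stage("score")
    scores = score_table(series_list, windows=config.windows,
                         thetas=(config.theta, 20.0))
    write_score_csv(scores, out / "score_table.csv")
    results["scores"] = scores

    _stage("evaluate")
    windows = evaluate_windows(series_list, records, windows=config.windows,
                               theta=config.theta)
    cols = {f"wk{w:g} (n={res['n']})": res["metrics"]
            for w, res in windows.items() if res["metrics"] is not None}
    table1_csv(cols, out / "performance_table.csv")
    orr_res = orr(records)
    diag_json = {
        "orr": orr_res,
        "windows": {
            str(w): {
                "n": res["n"], "flag": res["flag"],
                "metrics": (res["metrics"].as_dict(percent=True)
                            if res["metrics"] else None),
                "fisher_p": (res["fisher"].p_two_sided if res["fisher"] else None),
                "fisher_or_cmle": (res["fisher"].odds_ratio if res["fisher"] else None),
            }
            for w, res in windows.items()
        },
    }
    (out / "diagnostics.json").write_text(
        json.dumps(diag_json, indent=2, sort_keys=True, default=float) + "\n")
    results["diagnostics"] = windows
    results["orr"] = orr_res

    _stage("survival")
    max_w = max(config.windows)
    by_id = {r.patient_id: r for r in records}
    rows = []
    for s in series_list:
        from .scoring import classify, max_score_by

        res = max_score_by(s, max_w)
        rec = by_id[s.patient_id]
        if not res.evaluable:
            continue
        rows.append({
            "patient_id": s.patient_id,
            "score_high": int(classify(res, config.theta) == "high"),
            "pfs_months": rec.pfs_months, "pfs_event": int(rec.pfs_event),
            "os_months": rec.os_months, "os_event": int(rec.os_event),
            **{k: v for k, v in (rec.covariates or {}).items()
               if isinstance(v, (int, float, np.integer, np.floating))},
        })
    surv = pd.DataFrame(rows)
    surv_out = []
    km_rows = []
    for endpoint, (tcol, ecol) in {"pfs": ("pfs_months", "pfs_event"),
                                   "os": ("os_months", "os_event")}.items():
        t = surv[tcol].to_numpy()
        e = surv[ecol].to_numpy().astype(bool)
        g = surv["score_high"].to_numpy()
        for grp in (0, 1):
            sel = g == grp
            if sel.sum() == 0 or not e[sel].any():
                continue
            km = km_fit(t[sel], e[sel])
            for tt, ss, se_, nr in zip(km.event_times, km.survival, km.se,
                                       km.n_at_risk):
                km_rows.append({"endpoint": endpoint, "group": grp, "time": tt,
                                "survival": ss, "se": se_, "n_at_risk": nr})
        try:
            chi2, df_, p = logrank(t, e, g)
        except ValueError:
            chi2 = p = float("nan")
        covars = ["score_high"] + [c for c in surv.columns
                                   if c not in ("patient_id", "score_high",
                                                "pfs_months", "pfs_event",
                                                "os_months", "os_event")]
        screen = univariate_screen(t, e, surv[covars],
                                   alpha_keep=config.screen_alpha)
        for name, fit in screen["univariate"].items():
            ci = fit.hr_ci[0]
            surv_out.append({"endpoint": endpoint, "variable": name,
                             "model": "univariate", "HR": fit.hr[0],
                             "HR_lo95": ci[0], "HR_hi95": ci[1],
                             "p": fit.p_wald[0]})
        if screen["multivariable"] is not None:
            m = screen["multivariable"]
            for j, name in enumerate(m.names):
                surv_out.append({"endpoint": endpoint, "variable": name,
                                 "model": "multivariable", "HR": m.hr[j],
                                 "HR_lo95": m.hr_ci[j, 0],
                                 "HR_hi95": m.hr_ci[j, 1],
                                 "p": m.p_wald[j]})
        surv_out.append({"endpoint": endpoint, "variable": "score_high",
                         "model": "logrank", "HR": float("nan"),
                         "HR_lo95": float("nan"), "HR_hi95": float("nan"),
                         "p": p})
        results[f"screen_{endpoint}"] = screen
    pd.DataFrame(surv_out).to_csv(out / "survival_table.csv", index=False)
    pd.DataFrame(km_rows).to_csv(out / "km_curves.csv", index=False)
    results["survival_table"] = pd.DataFrame(surv_out)

    _stage("repertoire")
    if config.tumor_tsv and config.cells_tsv:
        from .repertoire import read_cell_table, read_clonotypes

        tumor = read_clonotypes(config.tumor_tsv, "airr")
        cells = read_cell_table(config.cells_tsv)
        blood = cell_tables_by_timepoint(cells)
    else:
        tumor, blood, cells, _truth = generate_repertoires(config.repertoire)
        write_repertoire_files(tumor, cells, out / "tumor_clonotypes.tsv",
                               out / "blood_cells.tsv")
    freq = frequent_til(tumor)
    match = match_to_blood(freq["keys"], blood)
    weeks = sorted(blood)
    baseline_wk, contrast_wk = weeks[0], weeks[-2] if len(weeks) > 2 else weeks[-1]
    track = tracking_table(tumor, blood, cells, baseline_week=baseline_wk,
                           contrast_week=contrast_wk, alpha=config.alpha)
    track_out = track.copy()
    track_out.to_csv(out / "tracking_table.tsv", sep="\t", index=False)
    venn = {
        "n_tumor_clonotypes": freq["n_total"],
        "n_frequent_til": freq["n_frequent"],
        "pct_frequent": freq["pct"],
        "n_matched_blood": match["n_matched"],
        "pct_of_frequent_in_blood": match["pct_of_frequent"],
        "combined_frequency_by_week": {
            str(w): combined_frequency(freq["keys"], blood[w]) for w in weeks
        },
        "morisita_horn_vs_baseline": {
            str(w): morisita_horn(blood[weeks[0]], blood[w]) for w in weeks
        },
        "n_expanded": int(track["expanded"].sum()),
    }
    (out / "venn_counts.json").write_text(
        json.dumps(venn, indent=2, sort_keys=True, default=float) + "\n")
    results["repertoire"] = {"frequent": freq, "match": match, "venn": venn,
                             "tracking": track}

    _stage("manifest")
    artifacts = sorted(p.name for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "cx3track",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "hashes": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("cohort", "repertoire"):
        sub = d[key]
        for k, v in list(sub.items()):
            if isinstance(v, tuple):
                sub[k] = list(v)
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
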