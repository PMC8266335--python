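"""Full-pipeline driver: fit, derive, test, subgroup, diagnose, serialize.

``run_full_analysis`` chains the stages of a complete diagnostic-accuracy
meta-analysis -- bivariate fit, summary measures, SROC/AUC, per-margin
heterogeneity, threshold-effect test, Deeks' test, Fagan updating,
subgroup refits, meta-regression and influence diagnostics -- into an
:class:`AnalysisReport` that serializes deterministically to JSON (no
timestamps) and round-trips.  Stage failures are recorded in the report
rather than aborting, except a failed primary fit which is fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from . import bivariate_model as bm
from . import sroc as sroc_mod
from .bias_posttest import deeks_test, fagan, scattergram
from .heterogeneity import cochran_q, threshold_test
from .influence import influence_analysis
from .moderators import meta_regression, subgroup_analysis
from .study_data import read_panel

DEFAULT_CONFIG: dict[str, Any] = {
    "n_quad": 21,
    "seed": 0,
    "pretest": [0.20],
    "subgroups": ["design", "n_patients", "mean_age", "field_strength",
                  "b_value", "measure"],
    "plr_threshold": 10.0,
    "nlr_threshold": 0.1,
    "outlier_z": 2.0,
    "influence_quantile": 0.9,
}


@dataclass
class AnalysisReport:
    provenance: dict[str, Any]
    summary: dict[str, Any]
    sroc: dict[str, Any]
    heterogeneity: dict[str, Any]
    threshold: dict[str, Any]
    deeks: dict[str, Any]
    fagan: list[dict[str, Any]]
    scattergram: dict[str, Any]
    subgroups: dict[str, Any]
    meta_regression: dict[str, Any]
    influence: dict[str, Any]
    errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "AnalysisReport":
        d = json.loads(text)
        required = [f.name for f in dataclasses.fields(AnalysisReport)
                    if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING]
        missing = [k for k in required if k not in d]
        if missing:
            raise ValueError(f"report JSON missing section(s): {missing}")
        return AnalysisReport(**d)


def _jsonable(x: Any) -> Any:
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _round(x: Any, nd: int = 6) -> Any:
    x = _jsonable(x)
    if isinstance(x, float):
        return round(x, nd)
    if isinstance(x, list):
        return [_round(v, nd) for v in x]
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    return x


def load_config(path: Optional[str | Path]) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg.update(user)
    return cfg


def _measures_dict(m: bm.SummaryMeasures) -> dict[str, Any]:
    return _round({
        "sens": m.sens, "sens_ci": m.sens_ci,
        "spec": m.spec, "spec_ci": m.spec_ci,
        "plr": m.plr, "plr_ci": m.plr_ci,
        "nlr": m.nlr, "nlr_ci": m.nlr_ci,
        "dor": m.dor, "dor_ci": m.dor_ci,
    })


def run_full_analysis(
    panel_path: str | Path,
    config_path: Optional[str | Path] = None,
    config: Optional[dict[str, Any]] = None,
) -> AnalysisReport:
    """Execute the whole pipeline on the panel CSV at ``panel_path``."""
    cfg = config if config is not None else load_config(config_path)
    panel_path = Path(panel_path)
    panel = read_panel(panel_path)
    digest = hashlib.sha256(panel_path.read_bytes()).hexdigest()
    errors: dict[str, str] = {}

    fit_res = bm.fit(panel, n_quad=int(cfg["n_quad"]))  # fatal on raise
    measures = bm.summary_measures(fit_res)
    p = fit_res.params

    summary = _measures_dict(measures)
    summary.update(_round({
        "mu_A": p.mu_A, "mu_B": p.mu_B,
        "sigma_A": p.sigma_A, "sigma_B": p.sigma_B, "rho": p.rho,
        "loglik": fit_res.loglik, "converged": fit_res.converged,
        "n_studies": fit_res.n_studies,
    }))

    sroc_block: dict[str, Any] = {}
    try:
        hs = sroc_mod.to_hsroc(p)
        curve = sroc_mod.sroc_curve(p)
        sroc_block = _round({
            "auc": curve.auc,
            "summary_point_fpr": curve.summary_point[0],
            "summary_point_tpr": curve.summary_point[1],
            "Lambda": hs.Lambda, "beta": hs.beta, "Theta": hs.Theta,
        })
    except Exception as e:
        errors["sroc"] = str(e)

    het: dict[str, Any] = {}
    try:
        for margin in ("sensitivity", "specificity"):
            h = cochran_q(panel, margin=margin)
            het[margin] = _round({"Q": h.Q, "df": h.df, "p": h.p, "I2": h.I2})
    except Exception as e:
        errors["heterogeneity"] = str(e)

    thr: dict[str, Any] = {}
    try:
        t = threshold_test(panel)
        thr = _round({"r": t.r, "p": t.p, "n": t.n})
    except Exception as e:
        errors["threshold"] = str(e)

    deeks_block: dict[str, Any] = {}
    try:
        dk = deeks_test(panel)
        deeks_block = _round({
            "slope": dk.slope, "intercept": dk.intercept,
            "t": dk.t, "df": dk.df, "p": dk.p,
        })
    except Exception as e:
        errors["deeks"] = str(e)

    fagan_block: list[dict[str, Any]] = []
    try:
        for pre in cfg["pretest"]:
            f = fagan(float(pre), measures.plr, measures.nlr)
            fagan_block.append(_round({
                "pretest": f.pretest,
                "posttest_plr": f.posttest_plr,
                "posttest_nlr": f.posttest_nlr,
            }))
    except Exception as e:
        errors["fagan"] = str(e)

    scat_block: dict[str, Any] = {}
    try:
        sc = scattergram(
            measures, plr_threshold=float(cfg["plr_threshold"]),
            nlr_threshold=float(cfg["nlr_threshold"]), panel=panel,
        )
        scat_block = _round({
            "quadrant": sc.quadrant,
            "plr_threshold": sc.plr_threshold,
            "nlr_threshold": sc.nlr_threshold,
            "study_quadrants": sc.study_quadrants,
        })
    except Exception as e:
        errors["scattergram"] = str(e)

    sub_block: dict[str, Any] = {}
    mr_block: dict[str, Any] = {}
    for var in cfg["subgroups"]:
        try:
            rep = subgroup_analysis(panel, var, n_quad=int(cfg["n_quad"]))
            sub_block[var] = {
                "dropped": rep.dropped,
                "levels": {
                    lv: {
                        "n_rows": L.n_rows,
                        "auc": _round(L.auc),
                        "unstable": L.unstable,
                        "note": L.note,
                        "measures": _measures_dict(L.measures) if L.measures else None,
                    }
                    for lv, L in rep.levels.items()
                },
            }
        except Exception as e:
            errors[f"subgroup:{var}"] = str(e)
        try:
            mr = meta_regression(panel, var, n_quad=int(cfg["n_quad"]))
            mr_block[var] = _round({
                "lr_stat": mr.lr_stat, "p": mr.p,
                "var_explained_sens": mr.var_explained_sens,
                "var_explained_spec": mr.var_explained_spec,
                "delta_A": mr.delta[0], "delta_B": mr.delta[1],
                "n_rows": mr.n_rows,
            })
        except Exception as e:
            errors[f"meta_regression:{var}"] = str(e)

    infl_block: dict[str, Any] = {}
    try:
        rep = influence_analysis(
            panel, fit_res, seed=int(cfg["seed"]),
            outlier_z=float(cfg["outlier_z"]),
            influence_quantile=float(cfg["influence_quantile"]),
        )
        infl_block = _round({
            "study_id": rep.study_id,
            "cook_d": rep.cook_d,
            "resid_sens": rep.resid_sens,
            "resid_spec": rep.resid_spec,
            "flagged_outlier": [bool(b) for b in rep.flagged_outlier],
            "flagged_influential": [bool(b) for b in rep.flagged_influential],
        })
    except Exception as e:
        errors["influence"] = str(e)

    return AnalysisReport(
        provenance={
            "input": panel_path.name,
            "sha256": digest,
            "seed": int(cfg["seed"]),
            "n_quad": int(cfg["n_quad"]),
            "version": __version__,
        },
        summary=summary,
        sroc=sroc_block,
        heterogeneity=het,
        threshold=thr,
        deeks=deeks_block,
        fagan=fagan_block,
        scattergram=scat_block,
        subgroups=sub_block,
        meta_regression=mr_block,
        influence=infl_block,
        errors=errors,
    )


def write_outputs(report: AnalysisReport, out_dir: str | Path) -> None:
    """Write report.json plus summary/subgroups/influence TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")

    with (out / "summary.tsv").open("w") as fh:
        fh.write("measure\tvalue\tci_lo\tci_hi\n")
        for k in ("sens", "spec", "plr", "nlr", "dor"):
            ci = report.summary.get(f"{k}_ci") or [None, None]
            fh.write(f"{k}\t{report.summary[k]}\t{ci[0]}\t{ci[1]}\n")
        fh.write(f"auc\t{report.sroc.get('auc')}\t\t\n")

    with (out / "subgroups.tsv").open("w") as fh:
        fh.write("variable\tlevel\tn_rows\tsens\tspec\tplr\tnlr\tdor\tauc\n")
        for var, blk in report.subgroups.items():
            for lv, L in blk["levels"].items():
                m = L["measures"] or {}
                fh.write(
                    f"{var}\t{lv}\t{L['n_rows']}\t{m.get('sens')}\t{m.get('spec')}"
                    f"\t{m.get('plr')}\t{m.get('nlr')}\t{m.get('dor')}\t{L['auc']}\n"
                )

    if report.influence:
        with (out / "influence.tsv").open("w") as fh:
            fh.write("study_id\tcook_d\tresid_sens\tresid_spec\toutlier\tinfluential\n")
            infl = report.influence
            for i, sid in enumerate(infl["study_id"]):
                fh.write(
                    f"{sid}\t{infl['cook_d'][i]}\t{infl['resid_sens'][i]}"
                    f"\t{infl['resid_spec'][i]}\t{infl['flagged_outlier'][i]}"
                    f"\t{infl['flagged_influential'][i]}\n"
                )
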