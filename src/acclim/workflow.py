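"""End-to-end pipeline: simulate -> reduce -> analyse -> report.

CSV is the single interchange format. Every file this module writes starts
with a comment header line ``# seed=<seed> config_sha=<hash> acclim=<version>``
so any table can be traced back to the run that produced it; readers pass
``comment='#'``. A ``manifest.json`` records the seed, config digest, library
versions and row counts, and re-running with the same seed reproduces every
table byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_sha
from .errors import SchemaError
from .inference import (adjusted_means, condition_factor, homogeneity_of_slopes,
                        mass_exponent, tukey_hsd, two_way_ancova, two_way_anova)
from .respirometry import process_study
from .synth import simulate_ctm_study, simulate_respirometry_study
from .thermal import ctm_table

log = logging.getLogger("acclim")

__all__ = ["run_pipeline", "read_table", "write_table", "check_columns",
           "RESPONSES", "analyze_response"]

#: response -> (needs mass covariate, log10 response) for the standard report
RESPONSES: dict[str, tuple[bool, bool]] = {
    "ctm": (False, False),
    "rmr": (True, True),
    "mmr": (True, True),
    "scope": (True, True),
    "recovery_slope": (True, False),  # slopes are negative; kept on raw scale
    "mass": (False, True),
    "fork_length": (False, False),
    "condition": (False, True),
}


def check_columns(df: pd.DataFrame, required: set[str], name: str) -> None:
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def read_table(path: str | Path, required: set[str] | None = None,
               name: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface as schema problem
        raise SchemaError(f"{path}: cannot parse as CSV ({exc})") from exc
    if required is not None:
        check_columns(df, required, name or str(path))
    return df


def write_table(df: pd.DataFrame, path: str | Path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def _analysis_dataset(fish: pd.DataFrame, summary: pd.DataFrame) -> pd.DataFrame:
    data = fish.merge(summary, on="fish_id", how="inner", validate="1:1")
    data["condition"] = condition_factor(data["mass"].to_numpy(),
                                         data["fork_length"].to_numpy())
    return data


def analyze_response(data: pd.DataFrame, response: str, *,
                     use_covariate: bool, log10_response: bool,
                     reference_mass: float, alpha: float = 0.05,
                     ss_type: int = 1) -> dict:
    """Fit the factorial model for one response and assemble its tables.

    Tukey HSD is run for a factor only when its omnibus F is significant at
    ``alpha``. Covariate models also report the homogeneity-of-slopes screen
    and the fitted mass exponent (log10 responses only).
    """
    covariate_kw = {}
    if use_covariate:
        fit = two_way_ancova(data, response, log10_response=log10_response,
                             log10_covariate=log10_response, ss_type=ss_type)
        hf, hp = homogeneity_of_slopes(data, response,
                                       log10_response=log10_response,
                                       log10_covariate=log10_response)
        covariate_kw = {"homogeneity_F": hf, "homogeneity_p": hp}
        if log10_response:
            b, se = mass_exponent(data, response)
            covariate_kw.update({"mass_exponent": b, "mass_exponent_se": se})
    else:
        fit = two_way_anova(data, response, log10_response=log10_response,
                            ss_type=ss_type)
    anova = fit.anova_table
    means = {}
    tukeys = {}
    for factor in ("population", "acclimation_temp"):
        means[factor] = adjusted_means(
            fit, factor, reference_mass=reference_mass if use_covariate else None)
        if fit.term_p(factor) < alpha:
            tukeys[factor] = tukey_hsd(
                fit, factor, alpha=alpha,
                reference_mass=reference_mass if use_covariate else None)
    return {"fit": fit, "anova": anova, "means": means, "tukey": tukeys,
            **covariate_kw}


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the whole study end to end and write all artefacts to ``outdir``.

    Stages: simulate the respirometry and thermal-challenge studies, reduce
    traces/recovery series to per-fish summaries, extract per-fish CTmax,
    analyse the eight standard responses, and write tables, a plain-text
    report and a manifest. Deterministic for a fixed seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sha = config_sha(config)
    header = f"# seed={config.seed} config_sha={sha} acclim={__version__}"

    log.info("simulating respirometry study (seed=%d)", config.seed)
    resp = simulate_respirometry_study(config.respirometry, config.seed)
    log.info("simulating thermal-challenge study")
    ctm_study = simulate_ctm_study(config.ctm, config.seed + 1)

    for name, df in (("fish", resp["fish"]), ("traces", resp["traces"]),
                     ("blanks", resp["blanks"]), ("recovery", resp["recovery"]),
                     ("ctm_fish", ctm_study["fish"]),
                     ("ctm_events", ctm_study["events"])):
        write_table(df, outdir / f"{name}.csv", header)

    log.info("reducing %d fish traces", resp["fish"].shape[0])
    summary = process_study(resp["fish"], resp["traces"], resp["recovery"],
                            resp["blanks"],
                            chamber_volume=config.respirometry.chamber_volume,
                            fish_density=config.respirometry.fish_density,
                            eval_time=config.eval_time)
    write_table(summary, outdir / "summary.csv", header)

    ctms = ctm_table(ctm_study["trials"])
    write_table(ctms, outdir / "ctm_values.csv", header)

    resp_data = _analysis_dataset(resp["fish"], summary)
    ctm_data = ctm_study["fish"].merge(ctms[["fish_id", "ctm_C"]], on="fish_id")
    ctm_data = ctm_data.rename(columns={"ctm_C": "ctm"})

    analyses = {}
    qc = summary.loc[summary["qc_flags"] != "", ["fish_id", "qc_flags"]]
    for response, (use_cov, log10_resp) in RESPONSES.items():
        data = ctm_data if response == "ctm" else resp_data
        if log10_resp and (data[response] <= 0).any():
            n_drop = int((data[response] <= 0).sum())
            log.warning("%s: dropping %d nonpositive value(s) before log10",
                        response, n_drop)
            data = data[data[response] > 0]
        log.info("analysing response %r (n=%d)", response, len(data))
        res = analyze_response(data, response, use_covariate=use_cov,
                               log10_response=log10_resp,
                               reference_mass=config.reference_mass,
                               alpha=config.alpha, ss_type=config.ss_type)
        adir = outdir / "analysis"
        write_table(res["anova"].reset_index(names="term"),
                    adir / f"{response}_anova.csv", header)
        for factor, tbl in res["means"].items():
            write_table(tbl, adir / f"{response}_means_{factor}.csv", header)
        for factor, tbl in res["tukey"].items():
            write_table(tbl, adir / f"{response}_tukey_{factor}.csv", header)
        analyses[response] = res

    design = (resp_data.groupby(["population", "acclimation_temp"])
              .size().unstack(fill_value=0))
    report_lines = _report_lines(config, sha, resp_data, ctm_data, design,
                                 analyses, qc)
    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n",
                                       encoding="utf-8")

    manifest = {
        "seed": config.seed, "config_sha": sha, "acclim": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "statsmodels": _statsmodels_version()},
        "n_respirometry_fish": int(len(resp_data)),
        "n_ctm_fish": int(len(ctm_data)),
        "responses": list(RESPONSES),
        "config": config.to_dict(),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n",
        encoding="utf-8")
    return {"analyses": analyses, "summary": summary, "ctm": ctm_data,
            "respirometry_data": resp_data, "design": design,
            "manifest": manifest}


def _statsmodels_version() -> str:
    import statsmodels
    return statsmodels.__version__


def _report_lines(config, sha, resp_data, ctm_data, design, analyses, qc):
    lines = [
        "acclim run report",
        "=================",
        f"seed: {config.seed}   config_sha: {sha}   version: {__version__}",
        "",
        f"respirometry cohort: {len(resp_data)} fish; "
        f"thermal challenge cohort: {len(ctm_data)} fish",
        "",
        "design (respirometry fish per cell):",
        design.to_string(),
        "",
        f"QC flags: {len(qc)} fish flagged"
        + ("" if qc.empty else " -> " + "; ".join(
            f"{r.fish_id}:{r.qc_flags}" for r in qc.itertuples())),
        "",
    ]
    for response, res in analyses.items():
        lines.append(f"--- {response} ---")
        lines.append(res["anova"].to_string())
        if "mass_exponent" in res:
            lines.append(f"mass exponent: {res['mass_exponent']:.3f} "
                         f"+/- {res['mass_exponent_se']:.3f} SE")
        if "homogeneity_p" in res:
            lines.append(f"homogeneity of slopes: F={res['homogeneity_F']:.3f}, "
                         f"p={res['homogeneity_p']:.3f}")
        for factor, tbl in res["means"].items():
            lines.append(f"adjusted means by {factor}:")
            lines.append(tbl.to_string(index=False))
        for factor, tbl in res["tukey"].items():
            lines.append(f"Tukey HSD ({factor}):")
            lines.append(tbl.to_string(index=False))
        lines.append("")
    return lines
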