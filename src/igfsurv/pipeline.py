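"""End-to-end orchestration: simulate/ingest -> score -> classify ->
cut-points -> clusters -> MCA -> report, with attrition accounting.

Every run writes a self-contained directory of CSV/JSON artifacts stamped
with a hash of the configuration and the master seed, and an attrition
report reconciling patient counts at every stage (input, scoreable per
marker, classifiable, analyzable per analysis).  Runs are deterministic
given the seed; a failed stage preserves the artifacts produced so far and
names itself in the summary.
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

from igfsurv import constants
from igfsurv.clusters import (
    CONTROL_CLUSTERS,
    PRIMARY_CLUSTERS,
    run_cluster_analysis,
)
from igfsurv.cohort import Cohort, read_cohort, write_cohort
from igfsurv.cutpoints import (
    decile_scan,
    internal_cross_validation,
    quantile_candidates,
    validate_candidate,
)
from igfsurv.mca import inverse_association_check, mca_fit
from igfsurv.scoring import dichotomize, score_cohort
from igfsurv.subtypes import SUBTYPES, classify_cohort, subtype_table
from igfsurv.synthetic import SimulationConfig, generate_cohort

log = logging.getLogger("igfsurv")

SCORE_COLUMNS = {
    "IGF1Ra": "IGF1Ra_IRS",
    "IGF1Rb": "IGF1Rb_IRS",
    "IGF2R": "IGF2R_IRS",
    "IGFBP2": "IGFBP2_H",
}

DEFAULT_STRATA = ["nodes", "surgery", "subtype", "taxane"]


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    input_path: str | None = None          # cohort CSV; None -> simulate
    n_patients: int = 1021                 # simulated cohort size
    markers: list[str] = field(default_factory=lambda: list(SCORE_COLUMNS))
    endpoints: list[str] = field(default_factory=lambda: ["dfs", "os"])
    cutoff_quantile: float = 0.5           # median by default
    cv_replications: int = 100
    cv_ratio: float = 0.5
    strata: list[str] = field(default_factory=lambda: list(DEFAULT_STRATA))
    run_decile_scan: bool = True
    run_clusters: bool = True
    run_mca: bool = True
    out_dir: str = "igfsurv_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [m for m in self.markers if m not in SCORE_COLUMNS]
        if unknown:
            raise ValueError(
                f"unknown marker(s) {unknown}; available: {list(SCORE_COLUMNS)}"
            )
        bad = [e for e in self.endpoints if e not in ("dfs", "os")]
        if bad:
            raise ValueError(f"unknown endpoint(s) {bad}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d.pop("log_level")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _endpoint_arrays(df: pd.DataFrame, name: str):
    return (
        df[f"{name}_months"].to_numpy(dtype=float),
        df[f"{name}_event"].to_numpy(dtype=float).astype(int),
    )


def _build_adjust(df: pd.DataFrame):
    """Clinical design matrix for multivariate models, with dummy blocks.

    Missing yes/no treatment flags fall to the reference level (treated),
    so no patient is dropped from the adjusted model for an unreported flag.
    """
    X = pd.DataFrame(index=df.index)
    X["surgery_BCS"] = (df["surgery"] == "BCS").astype(float)
    X["nodes_0_3"] = df["nodes"].isin(["0", "1-3"]).astype(float)
    X["size_le2cm"] = (df["size"] == "le2cm").astype(float)
    X["grade_III"] = (df["grade"] == "III").astype(float)
    X["hist_ductal"] = (df["histology"] == "ductal").astype(float)
    X["hist_lobular"] = (df["histology"] == "lobular").astype(float)
    X["hist_other"] = (df["histology"] == "other").astype(float)
    X["radiotherapy_no"] = (df["radiotherapy"] == "no").astype(float)
    blocks = {
        "surgery": ["surgery_BCS"],
        "nodes": ["nodes_0_3"],
        "size": ["size_le2cm"],
        "grade": ["grade_III"],
        "histology": ["hist_ductal", "hist_lobular", "hist_other"],
        "radiotherapy": ["radiotherapy_no"],
    }
    return X, blocks


def run_pipeline(config: RunConfig) -> Path:
    """Execute every enabled stage; returns the run directory path."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    attrition: dict = {}
    stage = "ingest"
    try:
        # ---- ingest or simulate -------------------------------------------
        if config.input_path:
            cohort = read_cohort(config.input_path)
        else:
            sim = SimulationConfig(n_patients=config.n_patients, seed=config.seed)
            cohort = generate_cohort(sim).cohort
        write_cohort(cohort, out / "cohort.csv")
        df = cohort.df
        attrition["input"] = len(df)
        summary["stages"].append(stage)

        # ---- scoring ------------------------------------------------------
        stage = "score"
        scores = score_cohort(cohort)
        attrition["scoreable"] = {
            m: int(scores[SCORE_COLUMNS[m]].notna().sum()) for m in config.markers
        }
        summary["stages"].append(stage)

        # ---- classify -----------------------------------------------------
        stage = "classify"
        subtype = classify_cohort(scores)
        scores["subtype"] = subtype
        scores.to_csv(out / "scores.csv", index=False, na_rep="NA")
        attrition["classifiable"] = int(subtype.isin(SUBTYPES).sum())
        table = subtype_table(subtype)
        table.to_csv(out / "subtype_table.csv")
        summary["subtype_counts"] = table["n"].to_dict()
        summary["stages"].append(stage)

        strata_df = df.copy()
        strata_df["subtype"] = subtype.to_numpy()

        # ---- cut-point selection ------------------------------------------
        stage = "cutpoints"
        cut_summary: dict = {}
        cutoffs: dict = {}
        seed_seq = np.random.SeedSequence(config.seed)
        marker_seeds = seed_seq.generate_state(len(config.markers)) % (2**31)
        for i, marker in enumerate(config.markers):
            col = SCORE_COLUMNS[marker]
            s = scores[col].astype("Float64").astype(float)
            cands = quantile_candidates(s, marker=marker)
            entry: dict = {
                "candidates": {n: v for n, v in cands.candidates},
                "degenerate": cands.degenerate,
                "cv": {},
            }
            if config.run_decile_scan:
                endpoints = {
                    e: _endpoint_arrays(df, e) for e in config.endpoints
                }
                scan = decile_scan(s, endpoints, marker=marker)
                scan.deciles.to_csv(
                    out / f"decile_scan_{marker}.csv", index=False
                )
                entry["decile_argmin"] = {
                    "dfs": scan.argmin_dfs, "os": scan.argmin_os,
                }
            for j, endpoint in enumerate(config.endpoints):
                t, e = _endpoint_arrays(df, endpoint)
                rep = internal_cross_validation(
                    strata_df, s, t, e,
                    marker=marker, endpoint=endpoint,
                    n_replications=config.cv_replications,
                    ratio=config.cv_ratio,
                    strata=config.strata,
                    seed=int(marker_seeds[i]) + j,
                    quantile=config.cutoff_quantile,
                )
                rep.replications.to_csv(
                    out / f"cv_{marker}_{endpoint}.csv", index=False
                )
                try:
                    decision = validate_candidate(rep)
                    accepted, rationale = decision.accepted, decision.rationale
                except ValueError as why:
                    accepted, rationale = False, f"candidate unusable: {why}"
                entry["cv"][endpoint] = rep.to_dict() | {
                    "accepted": accepted,
                    "rationale": rationale,
                }
            # the pre-defined cut-off: median of training medians (first endpoint's CV)
            final = entry["cv"][config.endpoints[0]]["final_cutoff"]
            entry["final_cutoff"] = final
            # a cut-off at/below the minimum score cannot split; fall back to
            # a present-vs-absent dichotomy at the next attainable value
            observed = np.sort(s.dropna().unique())
            applied = final
            if final <= observed[0] and len(observed) > 1:
                applied = float(observed[1])
                entry["cutoff_adjusted"] = (
                    "median-of-medians equals the minimum score; applied "
                    "present-vs-absent split instead"
                )
            cutoffs[col] = applied
            entry["applied_cutoff"] = applied
            cut_summary[marker] = entry
        _write_json(cut_summary, out / "cutpoints.json")
        summary["cutoffs"] = cutoffs
        summary["stages"].append(stage)

        # ---- biomarker clusters -------------------------------------------
        if config.run_clusters:
            stage = "clusters"
            adjust, blocks = _build_adjust(df)
            endpoints = {e: _endpoint_arrays(df, e) for e in config.endpoints}
            cluster_out = {}
            for definition in PRIMARY_CLUSTERS + CONTROL_CLUSTERS:
                res = run_cluster_analysis(
                    df, scores, subtype, definition, cutoffs, endpoints,
                    adjust=adjust, adjust_blocks=blocks,
                )
                cluster_out[definition.name] = res.to_dict()
            _write_json(cluster_out, out / "clusters.json")
            summary["clusters"] = {
                k: {
                    "n_member": v["n_member"],
                    "logrank_p": v["logrank_p"],
                }
                for k, v in cluster_out.items()
            }
            summary["stages"].append(stage)

        # ---- MCA ----------------------------------------------------------
        if config.run_mca:
            stage = "mca"
            cat = pd.DataFrame(index=df.index)
            for marker in config.markers:
                col = SCORE_COLUMNS[marker]
                s = scores[col].astype("Float64").astype(float)
                cat[marker] = dichotomize(s, cutoffs[col]).astype(object)
            egfr = scores["EGFR_status"]
            cat["EGFR"] = egfr.where(egfr.notna(), other=pd.NA).map(
                {"positive": "high", "negative": "low"}
            )
            result = mca_fit(cat)
            result.coordinates.to_csv(out / "mca_coordinates.csv")
            mca_json = {
                "n_rows": result.n_rows,
                "n_dropped": result.n_dropped,
                "Q": result.Q,
                "J": result.J,
                "total_inertia": result.total_inertia,
                "eigenvalues": result.eigenvalues.tolist(),
                "inertia_pct": result.inertia_pct.tolist(),
                "cumulative_inertia_pct": result.cumulative_inertia_pct().tolist(),
            }
            if "IGF2R" in config.markers:
                others = [m for m in cat.columns if m != "IGF2R"]
                mca_json["igf2r_associations"] = {
                    m: {
                        "cosine": chk.cosine,
                        "direction": chk.direction,
                    }
                    for m in others
                    for chk in [inverse_association_check(result, ("IGF2R", m))]
                }
            _write_json(mca_json, out / "mca.json")
            summary["mca_total_inertia"] = result.total_inertia
            summary["stages"].append(stage)

        analyzable: dict = {}
        if config.run_clusters:
            analyzable["clusters"] = {
                k: v["n_member"] + v["n_comparator"] for k, v in cluster_out.items()
            }
        if config.run_mca:
            analyzable["mca_complete_cases"] = result.n_rows
        attrition["analyzable"] = analyzable
    except Exception as exc:  # preserve partial outputs, name the stage
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        log.error("stage %s failed: %s", stage, exc)
        summary["attrition"] = attrition
        _write_json(summary, out / "summary.json")
        raise

    summary["attrition"] = attrition
    _write_json(attrition, out / "attrition.json")
    _write_json(summary, out / "summary.json")
    return out


# --------------------------------------------------------------------------
# Reporting


def summarize_run(run_dir) -> str:
    """Assemble a human-readable report from a completed run directory.

    Pure function of the artifact files: regenerating the report from the
    same directory yields the identical text; missing artifacts are listed
    as absent rather than crashing.
    """
    run_dir = Path(run_dir)
    lines = ["# igfsurv run report", ""]

    def load_json(name):
        p = run_dir / name
        return json.loads(p.read_text()) if p.exists() else None

    summary = load_json("summary.json")
    if summary is None:
        return "# igfsurv run report\n\n(summary.json absent)\n"
    lines += [
        f"- config hash: {summary['config_hash']}",
        f"- seed: {summary['seed']}",
        "",
    ]
    if "failed_stage" in summary:
        lines += [f"**FAILED at stage {summary['failed_stage']}**: {summary['error']}", ""]

    sub = run_dir / "subtype_table.csv"
    lines.append("## Immunophenotype subtypes")
    if sub.exists():
        tab = pd.read_csv(sub, index_col=0)
        lines.append(tab.to_string())
    else:
        lines.append("(absent)")
    lines.append("")

    cut = load_json("cutpoints.json")
    lines.append("## Cut-point selection and internal cross-validation")
    if cut:
        for marker, entry in cut.items():
            lines.append(f"### {marker}")
            lines.append(f"- quartile candidates: {entry['candidates']}")
            lines.append(f"- final cut-off (median of training medians): {entry['final_cutoff']}")
            for ep, cv in entry["cv"].items():
                lines.append(
                    f"- {ep.upper()}: {cv['pct_valid_ci_crossing_1']:.0f}% of "
                    f"validation CIs cross HR=1; {cv['rationale']}"
                )
            if "decile_argmin" in entry:
                lines.append(f"- decile scan argmin: {entry['decile_argmin']}")
    else:
        lines.append("(absent)")
    lines.append("")

    clusters = load_json("clusters.json")
    lines.append("## Combined biomarker clusters")
    if clusters:
        for name, res in clusters.items():
            lines.append(f"### {name}")
            lines.append(
                f"- members {res['n_member']} vs comparators {res['n_comparator']} "
                f"(unassessable {res['n_unassessable']})"
            )
            for ep, rates in res.get("rates_4yr", {}).items():
                lr = res["logrank_p"].get(ep)
                uni = res["univariate"].get(ep) or {}
                lines.append(
                    f"- {ep.upper()}: 4-year rates {100 * rates['member']:.1f}% vs "
                    f"{100 * rates['comparator']:.1f}%; log-rank p = {lr:.4g}; "
                    f"HR = {uni.get('hr', float('nan')):.3f} "
                    f"(95% CI {uni.get('ci', [float('nan')] * 2)[0]:.3f}-"
                    f"{uni.get('ci', [float('nan')] * 2)[1]:.3f})"
                )
    else:
        lines.append("(skipped or absent)")
    lines.append("")

    mca = load_json("mca.json")
    lines.append("## Multiple correspondence analysis")
    if mca:
        lines.append(
            f"- {mca['Q']} variables, {mca['J']} categories, total inertia "
            f"{mca['total_inertia']:.4f} (complete cases: {mca['n_rows']}, "
            f"dropped: {mca['n_dropped']})"
        )
        pcts = ", ".join(f"{p:.2f}%" for p in mca["inertia_pct"][:4])
        lines.append(f"- leading inertia percentages: {pcts}")
        for m, a in mca.get("igf2r_associations", {}).items():
            lines.append(f"- IGF2R vs {m}: {a['direction']} (cosine {a['cosine']:.3f})")
    else:
        lines.append("(skipped or absent)")
    lines.append("")
    return "\n".join(lines) + "\n"
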