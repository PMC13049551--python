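"""End-to-end orchestration: simulate -> preprocess -> extract -> couple ->
score -> stats, with tabular/JSON reports and a run manifest.

The run is streaming: each synthetic session is generated, pushed through
both preprocessing paths, reduced to its extracted time courses and
coupling values, and discarded, so the full cohort never sits in memory.
Reports are deterministic given (config, seed); only the manifest carries
timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NETWORKS, WAB_SUBTESTS, AnalysisConfig, SimulationConfig
from .coupling import cross_correlation, derivative_coupling, network_coupling_table
from .extract import extract_timecourses, lesion_volume
from .io import write_tsv
from .preprocess import CSF_STAGES, GBOLD_STAGES, preprocess_csf, preprocess_gbold
from .simulate import generate_imaging_cohort, generate_wab_cohort
from . import stats as st
from .wab import DOMAINS, delta_scores, score_table

__all__ = [
    "RunManifest",
    "run_pipeline",
    "couple_cohort",
    "stats_report",
    "cohort_mean_coupling_curves",
]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seed: int
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    partial: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                manifest.partial = True
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            manifest.stages.append(name)
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# cohort-level coupling
# ---------------------------------------------------------------------------

def couple_cohort(sim: SimulationConfig, ana: AnalysisConfig) -> dict:
    """Generate the imaging cohort and compute per-session coupling.

    Returns a dict with the per-session coupling table, per-session
    timecourse frames, and the cohort-mean cross-correlation functions
    (gBOLD vs CSF, and -d(gBOLD)/dt vs CSF).
    """
    logger.info("gBOLD path stages: %s", " -> ".join(GBOLD_STAGES))
    logger.info("CSF path stages: %s", " -> ".join(CSF_STAGES))
    rows = []
    tc_frames = []
    ccf_sum = None
    dccf_sum = None
    lag_grid = dlag_grid = None
    n_sessions = 0
    for rec in generate_imaging_cohort(sim):
        vol, labels, motion = rec["volume"], rec["labels"], rec["motion"]
        g_vol = preprocess_gbold(
            vol, labels, motion, slice_order=None,
            band_hz=ana.band_hz, filter_order=ana.filter_order,
        )
        c_vol = preprocess_csf(
            vol, slice_order=None, band_hz=ana.band_hz, filter_order=ana.filter_order
        )
        tc = extract_timecourses(
            g_vol, c_vol, labels, rec["subject_id"], rec["session"]
        )
        les_mm3 = lesion_volume(
            labels.mask("lesion").astype(np.uint8), sim.voxel_size_mm
        )
        values = network_coupling_table(
            tc, max_lag_s=ana.max_lag_s, lag_s=ana.coupling_lag_s
        )
        row = {
            "subject_id": rec["subject_id"],
            "group": rec["group"],
            "condition": rec["condition"],
            "session": rec["session"],
            "age": rec["age"],
            "sex": rec["sex"],
            "lesion_volume_mm3": les_mm3,
        }
        for cv in values:
            key = "coupling" if cv.network == "whole_brain" else f"coupling_{cv.network}"
            row[key] = cv.value
        rows.append(row)

        ccf = cross_correlation(tc.gbold, tc.csf, ana.max_lag_s, tc.tr_s)
        dccf = derivative_coupling(tc.gbold, tc.csf, ana.max_lag_s, tc.tr_s)
        ccf_sum = ccf.r if ccf_sum is None else ccf_sum + ccf.r
        dccf_sum = dccf.r if dccf_sum is None else dccf_sum + dccf.r
        lag_grid, dlag_grid = ccf.lags_s, dccf.lags_s
        n_sessions += 1

        frame = pd.DataFrame(
            {"t_s": np.arange(tc.gbold.size) * tc.tr_s,
             "gbold": tc.gbold, "csf": tc.csf,
             **{f"gbold_{n}": s for n, s in tc.networks.items()}}
        )
        frame.insert(0, "session", rec["session"])
        frame.insert(0, "subject_id", rec["subject_id"])
        tc_frames.append(frame)

    coupling_table = pd.DataFrame(rows)
    mean_ccf = pd.DataFrame({"lag_s": lag_grid, "mean_r": ccf_sum / n_sessions})
    mean_dccf = pd.DataFrame({"lag_s": dlag_grid, "mean_r": dccf_sum / n_sessions})
    return {
        "coupling_table": coupling_table,
        "timecourses": pd.concat(tc_frames, ignore_index=True),
        "mean_ccf": mean_ccf,
        "mean_dccf": mean_dccf,
        "n_sessions": n_sessions,
    }


def cohort_mean_coupling_curves(
    sim: SimulationConfig,
    ana: AnalysisConfig | None = None,
    n_subjects: int = 20,
    condition: str = "HC",
) -> dict:
    """Cohort-mean cross-correlation curves for n subjects of one condition.

    Each subject is generated from its own seeded substream, pushed through
    both preprocessing paths, and reduced to its gBOLD-vs-CSF and
    derivative-vs-CSF cross-correlation functions; the per-lag correlations
    are averaged over the cohort. Returns the two mean curves plus the
    per-subject coupling values at the analysis lag.
    """
    from .coupling import coupling_at_lag
    from .simulate import generate_subject
    from ._utils import rng_for

    ana = ana or AnalysisConfig()
    ccf_sum = dccf_sum = None
    lags = dlags = None
    values = []
    for i in range(n_subjects):
        rng = rng_for(sim.seed, i, 1)
        vol, labels, motion = generate_subject(sim, condition, rng)
        g_vol = preprocess_gbold(
            vol, labels, motion, band_hz=ana.band_hz, filter_order=ana.filter_order
        )
        c_vol = preprocess_csf(vol, band_hz=ana.band_hz, filter_order=ana.filter_order)
        tc = extract_timecourses(g_vol, c_vol, labels, f"sub-{i + 1:03d}")
        ccf = cross_correlation(tc.gbold, tc.csf, ana.max_lag_s, tc.tr_s)
        dccf = derivative_coupling(tc.gbold, tc.csf, ana.max_lag_s, tc.tr_s)
        values.append(coupling_at_lag(ccf, ana.coupling_lag_s).value)
        ccf_sum = ccf.r if ccf_sum is None else ccf_sum + ccf.r
        dccf_sum = dccf.r if dccf_sum is None else dccf_sum + dccf.r
        lags, dlags = ccf.lags_s, dccf.lags_s
    mean_ccf = pd.DataFrame({"lag_s": lags, "mean_r": ccf_sum / n_subjects})
    mean_dccf = pd.DataFrame({"lag_s": dlags, "mean_r": dccf_sum / n_subjects})
    return {
        "mean_ccf": mean_ccf,
        "mean_dccf": mean_dccf,
        "coupling_values": np.asarray(values),
        "n_subjects": n_subjects,
    }


# ---------------------------------------------------------------------------
# behavioural scoring
# ---------------------------------------------------------------------------

def behavioural_tables(sim: SimulationConfig, coupling_table: pd.DataFrame) -> dict:
    """WAB raw/scored/change tables driven by the measured coupling changes."""
    pre = coupling_table.query("condition == 'PSA_pre'").set_index("subject_id")
    post = coupling_table.query("condition == 'PSA_post'").set_index("subject_id")
    treated = sorted(set(pre.index) & set(post.index))
    delta = pd.DataFrame({"subject_id": treated})
    for net in NETWORKS:
        delta[f"delta_{net}"] = (
            post.loc[treated, f"coupling_{net}"].to_numpy()
            - pre.loc[treated, f"coupling_{net}"].to_numpy()
        )
    delta["delta_coupling"] = (
        post.loc[treated, "coupling"].to_numpy()
        - pre.loc[treated, "coupling"].to_numpy()
    )
    raw = generate_wab_cohort(sim, delta)
    # the raw subtest and the scaled domain share the name "repetition";
    # keep the domain under a distinct column
    scored_pre = score_table(raw, suffix="_pre").rename(
        columns={"repetition_pre": "repetition_domain_pre"}
    )
    scored_post = score_table(raw, suffix="_post").rename(
        columns={"repetition_post": "repetition_domain_post"}
    )
    pre_cols = raw[["subject_id"] + [c for c in raw.columns if c.endswith("_pre")]]
    post_cols = raw[["subject_id"] + [c for c in raw.columns if c.endswith("_post")]]
    pre_all = pre_cols.merge(scored_pre, on="subject_id")
    post_all = post_cols.merge(scored_post, on="subject_id")
    pre_all.columns = [c.removesuffix("_pre") for c in pre_all.columns]
    post_all.columns = [c.removesuffix("_post") for c in post_all.columns]
    change = delta_scores(pre_all, post_all)
    return {
        "wab_raw": raw,
        "wab_pre": pre_all,
        "wab_post": post_all,
        "wab_change": change,
        "delta_coupling": delta,
    }


# ---------------------------------------------------------------------------
# statistics report
# ---------------------------------------------------------------------------

def _result_dict(res: st.ModelResult) -> dict:
    d = {
        "estimate": res.estimate, "se": res.se,
        "ci_low": res.ci_low, "ci_high": res.ci_high,
        "statistic": res.statistic, "p": res.p, "n": res.n,
        "formula": res.formula,
    }
    if res.p_adj is not None:
        d["p_adj"] = res.p_adj
        d["adjust_method"] = res.adjust_method
    d.update(res.extra)
    return d


def stats_report(
    sim: SimulationConfig,
    ana: AnalysisConfig,
    coupling_table: pd.DataFrame,
    behaviour: dict,
) -> dict:
    """The full statistical battery as a JSON-serializable dict."""
    report: dict = {}
    baseline = coupling_table.query("condition in ('HC', 'PSA_pre')")

    # group comparison at baseline, adjusted for age and sex
    report["baseline_group"] = _result_dict(
        st.BaselineGroupModel(baseline).fit()
    )

    # longitudinal mixed model with Holm-corrected contrasts
    lmm = st.LongitudinalCouplingModel(coupling_table).fit()
    report["longitudinal"] = {
        "converged": lmm.converged,
        "variance_structure": lmm.variance_structure,
        "contrasts": lmm.contrasts.to_dict(orient="records"),
    }

    # age association, controlling sex and lesion volume (0 for controls)
    r_age, p_age = st.partial_correlation(
        baseline["age"].to_numpy(),
        baseline["coupling"].to_numpy(),
        baseline[["sex", "lesion_volume_mm3"]].to_numpy(),
    )
    report["age_partial_correlation"] = {"r": r_age, "p": p_age, "n": len(baseline)}

    # normality diagnostics per condition (reported, not used as a gate)
    report["shapiro"] = {}
    for cond, sub in coupling_table.groupby("condition"):
        if 3 <= len(sub) <= 5000 and sub["coupling"].std() > 0:
            w, p = st.shapiro_wilk(sub["coupling"].to_numpy())
            report["shapiro"][cond] = {"W": w, "p": p, "n": len(sub)}

    # pre-vs-post paired t per network (FDR across the network family)
    pre = coupling_table.query("condition == 'PSA_pre'").set_index("subject_id")
    post = coupling_table.query("condition == 'PSA_post'").set_index("subject_id")
    treated = sorted(set(pre.index) & set(post.index))
    net_rows = []
    for net in NETWORKS:
        res = st.paired_t(
            pre.loc[treated, f"coupling_{net}"], post.loc[treated, f"coupling_{net}"]
        )
        net_rows.append(
            {"network": net, **{k: v for k, v in _result_dict(res).items()
                                if k != "formula"}}
        )
    net_p = st.fdr_adjust([r["p"] for r in net_rows])
    for row, q in zip(net_rows, net_p):
        row["p_fdr"] = float(q)
    report["network_pre_post"] = net_rows

    # WAB change per domain and AQ (paired t)
    change = behaviour["wab_change"]
    wab_pre, wab_post = behaviour["wab_pre"], behaviour["wab_post"]
    report["wab_change"] = {}
    domain_cols = [d if d != "repetition" else "repetition_domain" for d in DOMAINS]
    for col in domain_cols + ["AQ"]:
        res = st.paired_t(wab_pre[col], wab_post[col])
        report["wab_change"][col] = {
            k: v for k, v in _result_dict(res).items() if k != "formula"
        }

    # association screen: networks x language measures, FDR over the family
    delta = behaviour["delta_coupling"].set_index("subject_id").loc[treated]
    measures = sorted({m for m in sim.assoc_measure.values() if m})
    assoc_rows = []
    for net in NETWORKS:
        for meas in measures:
            res = st.association_model(
                change.set_index("subject_id").loc[treated, meas].to_numpy(),
                delta[f"delta_{net}"].to_numpy(),
                age=pre.loc[treated, "age"].to_numpy(),
                baseline_score=wab_pre.set_index("subject_id")
                .loc[treated, meas].to_numpy(),
                lesion_volume=pre.loc[treated, "lesion_volume_mm3"].to_numpy(),
            )
            assoc_rows.append(
                {"network": net, "measure": meas,
                 "partial_r": res.extra["partial_r"], "r2": res.extra["r2"],
                 "estimate": res.estimate, "p": res.p, "n": res.n}
            )
    q = st.fdr_adjust([r["p"] for r in assoc_rows])
    for row, qv in zip(assoc_rows, q):
        row["p_fdr"] = float(qv)
    report["association_screen"] = assoc_rows

    # lesion-size heterogeneity screen (patients only)
    psa_pre = coupling_table.query("condition == 'PSA_pre'")
    if len(psa_pre) >= 4 and psa_pre["lesion_volume_mm3"].std() > 0:
        screen = st.lesion_coupling_screen(
            psa_pre, psa_pre["lesion_volume_mm3"].to_numpy()
        )
        report["lesion_screen"] = screen.to_dict(orient="records")

    # a-priori power for the configured behavioural effects
    report["power"] = {
        sub: st.paired_t_power(d, ana.alpha, ana.power_target, ana.power_tails)
        for sub, d in sim.behavior_effects.items() if d > 0
    }
    return report


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_pipeline(
    sim: SimulationConfig,
    ana: AnalysisConfig | None = None,
    out_dir: str | Path = "gboldcsf_run",
    seed: int | None = None,
) -> RunManifest:
    """Run every stage and write tabular/JSON reports under ``out_dir``."""
    ana = ana or AnalysisConfig()
    if seed is not None:
        sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": seed})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=sim.config_hash(), seed=sim.seed, started=time.time()
    )

    def save(name: str, fname: str, table: pd.DataFrame) -> None:
        path = write_tsv(out / fname, table)
        manifest.outputs[name] = str(path)

    with _stage(manifest, "simulate+preprocess+extract+couple"):
        res = couple_cohort(sim, ana)
        save("coupling_table", "coupling.tsv", res["coupling_table"])
        save("timecourses", "timecourses.tsv", res["timecourses"])
        save("mean_ccf", "mean_ccf.tsv", res["mean_ccf"])
        save("mean_derivative_ccf", "mean_derivative_ccf.tsv", res["mean_dccf"])

    with _stage(manifest, "score-wab"):
        behaviour = behavioural_tables(sim, res["coupling_table"])
        save("wab_raw", "wab_raw.tsv", behaviour["wab_raw"])
        save("wab_pre", "wab_pre.tsv", behaviour["wab_pre"])
        save("wab_post", "wab_post.tsv", behaviour["wab_post"])
        save("wab_change", "wab_change.tsv", behaviour["wab_change"])
        save("delta_coupling", "delta_coupling.tsv", behaviour["delta_coupling"])

    with _stage(manifest, "stats"):
        report = stats_report(sim, ana, res["coupling_table"], behaviour)
        report_path = out / "stats_report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest.outputs["stats_report"] = str(report_path)

    # participants table (BIDS-style)
    with _stage(manifest, "participants"):
        ct = res["coupling_table"]
        base = ct.query("session == 'pre'")[
            ["subject_id", "group", "condition", "age", "sex", "lesion_volume_mm3"]
        ]
        save("participants", "participants.tsv", base)

    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
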