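"""Choice-table I/O and the end-to-end analysis pipeline.

The canonical on-disk form of a dataset is a long-format CSV with one row per
alternative per decision:

    participant_id, condition, decision_index, position, alternative,
    distance, occupancy, desirability, chosen, schedule, completed

``chosen`` is 0/1 with exactly one 1 per decision; ``schedule`` is the
participant's planned sequence as a string of labels (empty outside schedule
conditions).  External datasets with different headers are adapted through a
column-mapping dict rather than code changes; an ``attempt`` column, when
present, is filtered to first attempts only.

``run_pipeline`` reproduces the full analysis on configured cohorts:
per-condition calibration with bootstrap intervals and random-model AICs,
the three hypothesis tests (schedule effect, chosen-vs-given schedules,
open-vs-closed layout), both clustering procedures with clustered-vs-
aggregate AIC comparison, and the schedule-adherence summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import clustering as cl
from .adherence import adherence_summary
from .calibration import fit_mle, random_model_aic
from .inference import bootstrap_ci, likelihood_ratio_test, permutation_test
from .model import (
    SCHEDULE_CONDITIONS,
    Alternative,
    DecisionContext,
    ParticipantTrajectory,
    Schedule,
)
from .simulate import CohortSpec, simulate_cohort

__all__ = [
    "CANONICAL_COLUMNS",
    "ParseError",
    "read_choice_data",
    "write_choice_data",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("destchoice")

CANONICAL_COLUMNS = (
    "participant_id",
    "condition",
    "decision_index",
    "position",
    "alternative",
    "distance",
    "occupancy",
    "desirability",
    "chosen",
)


class ParseError(ValueError):
    """A choice table violates the canonical-format invariants."""


def write_choice_data(
    trajectories: Iterable[ParticipantTrajectory], path: str | Path
) -> None:
    """Write trajectories as the canonical long-format CSV."""
    rows = []
    for t in trajectories:
        sched = "".join(t.schedule) if t.schedule is not None else ""
        for ctx in t.decisions:
            for alt in ctx.alternatives:
                rows.append({
                    "participant_id": t.participant_id,
                    "condition": t.condition,
                    "decision_index": ctx.decision_index,
                    "position": ctx.position,
                    "alternative": alt.label,
                    "distance": alt.distance,
                    "occupancy": alt.occupancy,
                    "desirability": alt.desirability,
                    "chosen": int(alt.label == ctx.chosen),
                    "schedule": sched,
                    "completed": int(t.completed),
                })
    pd.DataFrame(rows, columns=[*CANONICAL_COLUMNS, "schedule", "completed"]).to_csv(
        path, index=False
    )


def read_choice_data(
    path: str | Path, mapping: Mapping[str, str] | None = None
) -> list[ParticipantTrajectory]:
    """Read a long-format choice table into validated trajectories.

    ``mapping`` translates the file's headers to the canonical names
    (``{"canonical": "file_header", ...}``).  Structural violations —
    duplicate (participant, decision, alternative) rows, decisions without
    exactly one chosen row, revisits — raise :class:`ParseError` with the
    offending CSV line numbers.  An empty file yields an empty cohort with a
    warning.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        log.warning("choice table %s is empty; returning empty cohort", path)
        return []
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing canonical columns {missing}")
    if df.empty:
        log.warning("choice table %s has no rows; returning empty cohort", path)
        return []
    if "attempt" in df.columns:
        df = df[df["attempt"] == 1]  # analysis uses first attempts only
    # CSV line number = dataframe index + 2 (header + 1-based)
    df = df.reset_index(drop=False).rename(columns={"index": "_row"})
    df["_line"] = df["_row"] + 2

    dup = df.duplicated(
        subset=["participant_id", "decision_index", "alternative"], keep=False
    )
    if dup.any():
        lines = df.loc[dup, "_line"].tolist()[:5]
        raise ParseError(
            f"{path}: duplicate (participant, decision, alternative) rows "
            f"at lines {lines}"
        )
    trajectories: list[ParticipantTrajectory] = []
    for pid, pdf in df.groupby("participant_id", sort=True):
        conditions = pdf["condition"].unique()
        if len(conditions) != 1:
            raise ParseError(f"{path}: participant {pid!r} spans conditions {list(conditions)}")
        condition = conditions[0]
        sched = None
        if "schedule" in pdf.columns:
            raw = pdf["schedule"].dropna().unique()
            raw = [s for s in raw if str(s).strip()]
            if raw:
                sched = Schedule(str(raw[0]))
        completed = True
        if "completed" in pdf.columns:
            completed = bool(pdf["completed"].iloc[0])
        decisions = []
        for j, ddf in pdf.groupby("decision_index", sort=True):
            n_chosen = int(ddf["chosen"].sum())
            if n_chosen != 1:
                raise ParseError(
                    f"{path}: participant {pid!r} decision {j} has {n_chosen} "
                    f"chosen rows (lines {ddf['_line'].tolist()[:6]})"
                )
            alts = tuple(
                Alternative(
                    label=str(r.alternative),
                    distance=float(r.distance),
                    occupancy=float(r.occupancy),
                    desirability=float(r.desirability),
                )
                for r in ddf.itertuples()
            )
            chosen = str(ddf.loc[ddf["chosen"] == 1, "alternative"].iloc[0])
            position = str(ddf["position"].iloc[0])
            try:
                decisions.append(
                    DecisionContext(
                        decision_index=int(j), position=position,
                        alternatives=alts, chosen=chosen,
                    )
                )
            except ValueError as exc:
                raise ParseError(
                    f"{path}: participant {pid!r} decision {j} invalid "
                    f"(lines {ddf['_line'].tolist()[:6]}): {exc}"
                ) from exc
        try:
            trajectories.append(
                ParticipantTrajectory(
                    participant_id=str(pid),
                    condition=str(condition),
                    decisions=tuple(decisions),
                    schedule=sched,
                    completed=completed,
                )
            )
        except ValueError as exc:
            lines = pdf["_line"].tolist()
            raise ParseError(
                f"{path}: participant {pid!r} (lines {lines[0]}-{lines[-1]}) "
                f"violates trajectory invariants: {exc}"
            ) from exc
    return trajectories


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis.

    ``cohorts`` maps condition name -> either a :class:`CohortSpec` to
    simulate or a path to a canonical CSV to load.  Schedule conditions are
    fitted with the three-parameter model, others with the two-parameter
    model.  Resampling sizes default to small values suitable for smoke runs;
    raise them for production analyses.
    """

    cohorts: dict[str, CohortSpec | str | Path] = field(default_factory=dict)
    column_mapping: Mapping[str, str] | None = None
    bootstrap_B: int = 200
    n_permutations: int = 200
    seed: int = 0
    choice_set_policy: str = "shrinking"
    random_model_k: int = 0
    cluster_bins: int = 20
    cluster_cut_height: float = 1.75
    linkage_method: str = "complete"
    fit_method: str = "nelder-mead"
    output_dir: str | Path | None = None


def _model_spec_for(condition: str) -> str:
    return "three_param" if condition in SCHEDULE_CONDITIONS else "two_param"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and return the report bundle.

    Stage failures are isolated: a failing stage records its error in the
    report and the stages depending on it are skipped with an explicit
    notice.  Every stochastic step's seed is logged in the report.
    """
    report: dict = {"settings": {
        "seed": config.seed,
        "bootstrap_B": config.bootstrap_B,
        "n_permutations": config.n_permutations,
        "choice_set_policy": config.choice_set_policy,
        "cluster_cut_height": config.cluster_cut_height,
    }, "conditions": {}, "tests": {}, "clustering": {}, "adherence": None,
        "errors": {}}

    data: dict[str, list[ParticipantTrajectory]] = {}
    for name, source in config.cohorts.items():
        try:
            if isinstance(source, CohortSpec):
                trajectories, _ = simulate_cohort(source)
                # condition-qualified ids keep participants distinct across
                # simulated cohorts (the permutation test requires it)
                trajectories = [
                    replace(t, participant_id=f"{name}:{t.participant_id}")
                    for t in trajectories
                ]
            else:
                trajectories = read_choice_data(source, mapping=config.column_mapping)
            data[name] = trajectories
            log.info("condition %s: %d participants, %d decisions", name,
                     len(trajectories), sum(len(t.decisions) for t in trajectories))
        except Exception as exc:  # stage isolation
            report["errors"][f"load:{name}"] = str(exc)

    # --- per-condition calibration -------------------------------------
    for name, trajectories in data.items():
        if not trajectories:
            report["errors"][f"fit:{name}"] = "empty cohort; skipped"
            continue
        try:
            spec = _model_spec_for(name)
            fit = fit_mle(trajectories, model_spec=spec, method=config.fit_method)
            boot = bootstrap_ci(
                trajectories, model_spec=spec, B=config.bootstrap_B,
                seed=config.seed,
            )
            report["conditions"][name] = {
                "model_spec": spec,
                "fit": fit.to_dict(),
                "random_aic": random_model_aic(
                    trajectories, choice_set_policy=config.choice_set_policy,
                    k_random=config.random_model_k,
                ),
                "bootstrap": {
                    "B": boot.B, "level": boot.level, "seed": boot.seed,
                    "unit": boot.unit, "intervals": boot.intervals,
                },
                "n_participants": len(trajectories),
            }
        except Exception as exc:
            report["errors"][f"fit:{name}"] = str(exc)

    # --- hypothesis tests ----------------------------------------------
    def have(*names: str) -> bool:
        return all(data.get(n) for n in names)

    # schedule effect: desirability term improves fit (LRT on pooled schedule data)
    try:
        pooled = [t for n in SCHEDULE_CONDITIONS for t in data.get(n, [])]
        if pooled:
            full = fit_mle(pooled, model_spec="three_param", method=config.fit_method)
            nested = fit_mle(pooled, model_spec="two_param", method=config.fit_method)
            lrt = likelihood_ratio_test(full, nested)
            report["tests"]["schedule_effect_lrt"] = {
                "statistic": lrt.statistic, "df": lrt.df, "p_value": lrt.p_value,
            }
        else:
            report["errors"]["test:schedule_effect_lrt"] = "no schedule cohorts; skipped"
    except Exception as exc:
        report["errors"]["test:schedule_effect_lrt"] = str(exc)

    # chosen vs given schedules
    if have("schedule_chosen", "schedule_given"):
        try:
            perm = permutation_test(
                data["schedule_chosen"], data["schedule_given"],
                model_spec="three_param", n_perm=config.n_permutations,
                seed=config.seed,
            )
            report["tests"]["chosen_vs_given_permutation"] = {
                "statistic": perm.observed_statistic,
                "n_permutations": perm.n_permutations,
                "p_value": perm.p_value, "seed": perm.seed,
            }
        except Exception as exc:
            report["errors"]["test:chosen_vs_given"] = str(exc)
    else:
        report["errors"]["test:chosen_vs_given"] = "missing cohorts; skipped"

    # open vs closed layout
    if have("base", "closed"):
        try:
            perm = permutation_test(
                data["base"], data["closed"], model_spec="two_param",
                n_perm=config.n_permutations, seed=config.seed,
            )
            report["tests"]["base_vs_closed_permutation"] = {
                "statistic": perm.observed_statistic,
                "n_permutations": perm.n_permutations,
                "p_value": perm.p_value, "seed": perm.seed,
            }
        except Exception as exc:
            report["errors"]["test:base_vs_closed"] = str(exc)
    else:
        report["errors"]["test:base_vs_closed"] = "missing cohorts; skipped"

    # --- clustering ------------------------------------------------------
    for name, trajectories in data.items():
        if not trajectories or len(trajectories) < 10:
            continue
        spec = _model_spec_for(name)
        entry: dict = {}
        try:
            for quantity in ("distance", "occupancy"):
                values = {
                    t.participant_id: cl.normalized_cumulative(t, quantity)
                    for t in trajectories
                }
                thr = cl.estimate_bimodal_threshold(
                    list(values.values()), bins=config.cluster_bins
                )
                q_entry: dict = {"threshold": thr}
                if thr is not None:
                    assignment = cl.threshold_clusters(values, thr)
                    comparison = cl.clustered_model_comparison(
                        trajectories, assignment, model_spec=spec,
                        method=config.fit_method,
                    )
                    q_entry.update({
                        "sizes": assignment.sizes(),
                        "clustered_aic": comparison.clustered_aic,
                        "aggregate_aic": comparison.aggregate_aic,
                    })
                entry[f"threshold_{quantity}"] = q_entry
            estimates = cl.per_individual_fits(trajectories, model_spec=spec)
            assignment = cl.hierarchical_clusters(
                estimates, cut_height=config.cluster_cut_height,
                linkage_method=config.linkage_method,
            )
            # non-convergent individual fits drop out of the assignment
            assigned = [t for t in trajectories
                        if t.participant_id in assignment.labels]
            comparison = cl.clustered_model_comparison(
                assigned, assignment, model_spec=spec, method=config.fit_method,
            )
            sizes = assignment.sizes()
            n = len(assignment.labels)
            entry["hierarchical"] = {
                "cut_height": config.cluster_cut_height,
                "n_clusters": len(sizes),
                "sizes": sizes,
                "sizable_clusters": {c: s for c, s in sizes.items() if s >= 0.05 * n},
                "clustered_aic": comparison.clustered_aic,
                "aggregate_aic": comparison.aggregate_aic,
            }
            report["clustering"][name] = entry
        except Exception as exc:
            report["errors"][f"clustering:{name}"] = str(exc)

    # --- schedule adherence ----------------------------------------------
    if data.get("schedule_chosen"):
        try:
            summary = adherence_summary(data["schedule_chosen"])
            report["adherence"] = {
                "mean": summary.mean,
                "histogram": summary.histogram,
                "n": len(summary.distances),
                "n_excluded": len(summary.excluded),
            }
        except Exception as exc:
            report["errors"]["adherence"] = str(exc)
    else:
        report["errors"]["adherence"] = "no schedule_chosen cohort; skipped"

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        for name, trajectories in data.items():
            write_choice_data(trajectories, out / f"{name}.csv")
    return report
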