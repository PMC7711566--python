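"""End-to-end orchestration: simulate -> unimodal -> stacked/cybernetic ->
workflow optimization -> permutation tests -> model comparison.

One global seed expands deterministically into per-stage seeds via
``numpy.random.SeedSequence([global_seed, stage_index])``, so every
stage is independently rerunnable. All tabular artifacts are TSV and
embed a hash of the effective configuration.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from .cohort import Cohort, CohortConfig, generate_cohort, load_cohort, save_cohort
from .comparison import PerformanceMatrix, posthoc_pairwise, quade_test
from .stability import condense_model, stability_map, subsample_stability_weights
from .stacking import StackSpec, stack
from .validation import make_losocv_folds, permutation_test, train_unimodal
from .workflow import evaluate_workflow, optimize_workflow, WorkflowSpec

log = logging.getLogger("seqrisk")

__all__ = ["RunConfig", "run_full_analysis", "stage_seed"]

_STAGE_NAMES = (
    "simulate",
    "folds",
    "unimodal",
    "stacking",
    "workflow",
    "permutation",
    "comparison",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = _STAGE_NAMES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Configuration of a full analysis run (fail-fast validated)."""

    cohort_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    modalities: tuple[str, ...] = ("clinical", "prs", "smri")
    n_inner_folds: int = 10
    repeats: int = 1
    workflow_entry: str = "clinical"
    workflow_additions: tuple[str, ...] = ("rater", "prs", "smri")
    gammas: tuple[float, ...] = (0.0, 0.5, 1.0)
    cutoff_grid: tuple[float, ...] = tuple(np.arange(0.0, 100.1, 12.5))
    n_permutations: int = 100
    permutation_models: tuple[str, ...] = ("clinical",)
    condense_modality: str | None = "clinical"
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.cohort_dir is None:
            self.cohort.validate()
            known = set(self.cohort.block_dims)
        else:
            p = Path(self.cohort_dir)
            if not (p / "subjects.tsv").exists():
                raise ValueError(f"cohort_dir {p} has no subjects.tsv")
            known = {f.stem[len("block_"):] for f in p.glob("block_*.tsv")}
        for m in self.modalities:
            if m not in known:
                raise ValueError(f"unknown modality {m!r}; cohort provides {sorted(known)}")
        if self.workflow_entry not in self.modalities:
            raise ValueError("workflow_entry must be one of the trained modalities")
        for a in self.workflow_additions:
            if a != "rater" and a not in self.modalities:
                raise ValueError(f"workflow addition {a!r} is neither 'rater' nor a modality")
        for m in self.permutation_models:
            if m not in self.modalities:
                raise ValueError(f"permutation model {m!r} is not a trained modality")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        for g in self.gammas:
            if not (0 <= g <= 1):
                raise ValueError("gamma values must lie in [0, 1]")

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # where artifacts land does not change the science
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _model_row(name, pred, labels, scores=None):
    c = M.confusion_counts(pred, labels)
    m = M.prognostic_metrics(c).rounded()
    row = {
        "model": name,
        "tp": c.tp,
        "tn": c.tn,
        "fp": c.fp,
        "fn": c.fn,
        "n": c.n,
        "n_missing": c.n_missing,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "bac": m.bac,
        "ppv": m.ppv,
        "npv": m.npv,
        "psi": m.psi,
        "positive_lr": m.positive_lr,
    }
    if scores is not None:
        keep = ~np.isnan(np.asarray(scores, dtype=float))
        row["auc"] = round(M.auc(np.asarray(scores)[keep], np.asarray(labels)[keep]), 2)
    return row


def _per_site_bac(pred, labels, sites) -> dict[str, float]:
    out = {}
    for s in dict.fromkeys(np.asarray(sites).tolist()):
        mask = np.asarray(sites) == s
        out[s] = M.bac_score(np.asarray(labels)[mask], np.asarray(pred)[mask])
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns the report bundle as a dict.

    Stages: simulate/load -> LOSOCV plan -> unimodal calculators ->
    stacked and cybernetic fusion -> sequential-workflow optimization
    over the gamma ladder -> label-permutation significance -> Quade
    omnibus comparison with FDR post hocs. Artifacts are written under
    ``config.out_dir`` when set.
    """
    config.validate()
    chash = config.config_hash()
    t0 = time.time()
    bundle: dict = {"config_hash": chash, "seed": config.seed}

    # --- cohort -----------------------------------------------------------
    if config.cohort_dir is not None:
        cohort = load_cohort(config.cohort_dir)
    else:
        cc = config.cohort
        cohort = generate_cohort(
            CohortConfig(**{**asdict(cc), "seed": stage_seed(config.seed, "simulate")})
        )
    y = cohort.labels
    log.info("cohort: n=%d, events=%d, sites=%d", cohort.n, y.sum(), len(set(cohort.sites)))

    # --- shared fold plan -------------------------------------------------
    plan = make_losocv_folds(
        cohort.sites, y, config.n_inner_folds, config.repeats,
        seed=stage_seed(config.seed, "folds"),
    )

    # --- unimodal calculators --------------------------------------------
    estimators, oof = {}, {}
    rows = [_model_row("rater", cohort.rater_estimates, y)]
    fold_bac = {"rater": _per_site_bac(cohort.rater_estimates, y, cohort.sites)}
    for m in config.modalities:
        est, o = train_unimodal(cohort, m, plan=plan)
        estimators[m], oof[m] = est, o
        rows.append(_model_row(m, o.predicted, y, o.scores))
        fold_bac[m] = dict(est.fold_bac_)
        log.info("unimodal %s: BAC %.1f", m, rows[-1]["bac"])

    # --- condensed entry model -------------------------------------------
    if config.condense_modality:
        # selection votes come from a small-subsample ensemble (near-
        # independent signs); the CV-fold weights stay available on the
        # estimator for cross-validation-ratio reporting
        W_sel = subsample_stability_weights(
            cohort.blocks[config.condense_modality], y,
            seed=stage_seed(config.seed, "folds"),
        )
        smap = stability_map(W_sel)
        bundle["stability"] = smap
        if smap.n_selected > 0:
            sel, est_c, oof_c = condense_model(
                cohort, config.condense_modality, smap,
                n_inner_folds=config.n_inner_folds, repeats=config.repeats,
                seed=stage_seed(config.seed, "folds"),
            )
            rows.append(
                _model_row(f"condensed_{config.condense_modality}", oof_c.predicted, y, oof_c.scores)
            )
            bundle["condensed_features"] = sel
        else:
            log.warning("condensation skipped: no feature passed selection")

    # --- stacked and cybernetic fusion -----------------------------------
    stacked_spec = StackSpec(inputs=tuple(config.modalities))
    est_stack, oof_stack = stack(oof, y, plan, stacked_spec)
    rows.append(_model_row("stacked", oof_stack.predicted, y, oof_stack.scores))
    fold_bac["stacked"] = dict(est_stack.fold_bac_)

    cyber_spec = StackSpec(inputs=tuple(config.modalities), include_rater=True)
    est_cyber, oof_cyber = stack(oof, y, plan, cyber_spec, rater=cohort.rater_estimates)
    rows.append(_model_row("cybernetic", oof_cyber.predicted, y, oof_cyber.scores))
    fold_bac["cybernetic"] = dict(est_cyber.fold_bac_)

    # --- cumulative stage stacks for the workflow search ------------------
    entry = config.workflow_entry
    additions = list(config.workflow_additions)
    stage_scores = {entry: oof[entry].scores}
    for r in range(1, len(additions) + 1):
        for combo in itertools.combinations(additions, r):
            sid = "+".join([entry, *combo])
            mods = tuple(m for m in (entry, *combo) if m != "rater")
            spec = StackSpec(inputs=mods, include_rater="rater" in combo)
            _, o = stack(oof, y, plan, spec, rater=cohort.rater_estimates)
            stage_scores[sid] = o.scores
    order = {a: i for i, a in enumerate(additions)}
    sequences = [
        tuple(
            "+".join([entry, *sorted(perm[:k], key=order.get)]) if k else entry
            for k in range(len(additions) + 1)
        )
        for perm in itertools.permutations(additions)
    ]

    workflows = {}
    for g in config.gammas:
        spec, trace = optimize_workflow(
            list(stage_scores), stage_scores, y, g, config.cutoff_grid,
            sequences=sequences,
        )
        workflows[g] = (spec, trace)
        rows.append(_model_row(f"workflow_gamma={g:g}", trace.final_labels.astype(float), y))
        rows[-1]["fraction_full_battery"] = round(trace.fraction_full_battery, 3)
        rows[-1]["mean_assessments"] = round(trace.mean_assessments, 2)
        log.info(
            "workflow gamma=%.2f: %s cutoffs (%.1f, %.1f) BAC %.1f full-battery %.1f%%",
            g, "->".join(spec.sequence), spec.lower_pct, spec.upper_pct,
            trace.metrics.bac, 100 * trace.fraction_full_battery,
        )
    bundle["workflows"] = workflows

    # --- permutation significance ----------------------------------------
    perms = {}
    if config.n_permutations > 0:
        pseed = stage_seed(config.seed, "permutation")
        for m in config.permutation_models:
            X = cohort.blocks[m]

            def _evaluate(labels_perm, _X=X, _sites=cohort.sites):
                est = train_unimodal(
                    _SimpleCohortView(_X, _sites, labels_perm, m), m,
                    n_inner_folds=config.n_inner_folds, seed=pseed,
                )[0]
                return M.bac_score(labels_perm, (est.oof_.scores > 0).astype(int))

            res = permutation_test(_evaluate, y, config.n_permutations, seed=pseed)
            perms[m] = res
            log.info("permutation %s: observed %.1f, p=%.4g", m, res.observed, res.p)
        raw_p = np.array([perms[m].p for m in config.permutation_models])
        from .stability import fdr_adjust

        adj, _ = fdr_adjust(raw_p)
        for m, pa in zip(config.permutation_models, adj):
            for row in rows:
                if row["model"] == m:
                    row["p_fdr"] = float(pa)
    bundle["permutations"] = perms

    # --- omnibus comparison ----------------------------------------------
    models_cmp = [m for m in fold_bac if len(fold_bac[m]) >= 2]
    sites_order = list(fold_bac[models_cmp[0]])
    perf = PerformanceMatrix(
        values=np.array([[fold_bac[m][s] for m in models_cmp] for s in sites_order]),
        model_labels=tuple(models_cmp),
    )
    Fq, dfq, pq = quade_test(perf)
    p_mat, diff_mat = posthoc_pairwise(perf)
    bundle["comparison"] = {
        "models": models_cmp,
        "quade_F": Fq,
        "quade_df": dfq,
        "quade_p": pq,
        "posthoc_p_fdr": p_mat,
        "mean_diff": diff_mat,
        "performance": perf,
    }

    report = pd.DataFrame(rows)
    bundle["report"] = report
    bundle["fold_bac"] = fold_bac
    bundle["oof"] = oof
    bundle["cohort"] = cohort
    bundle["plan"] = plan
    bundle["runtime_s"] = time.time() - t0

    if config.out_dir is not None:
        _persist(bundle, config)
    return bundle


class _SimpleCohortView:
    """Minimal cohort stand-in used by the permutation closure."""

    def __init__(self, X, sites, labels, modality):
        self.blocks = {modality: X}
        self.sites = sites
        self.labels = np.asarray(labels, dtype=int)
        self.rater_estimates = None
        self.subject_ids = [str(i) for i in range(len(self.labels))]


def _persist(bundle: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={bundle['config_hash']} seed={bundle['seed']}\n"

    def write_tsv(df: pd.DataFrame, name: str) -> None:
        with open(out / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    write_tsv(bundle["report"], "report.tsv")
    cohort: Cohort = bundle["cohort"]
    save_cohort(cohort, out / "cohort")
    oof_df = pd.DataFrame({m: o.scores for m, o in bundle["oof"].items()})
    oof_df.insert(0, "subject_id", cohort.subject_ids)
    write_tsv(oof_df, "oof_scores.tsv")
    if "stability" in bundle:
        s = bundle["stability"]
        write_tsv(
            pd.DataFrame(
                {
                    "mean_weight": s.mean_weight,
                    "cv_ratio": s.cv_ratio,
                    "sign_z": s.sign_z,
                    "p_raw": s.p_raw,
                    "p_fdr": s.p_fdr,
                    "selected": s.selected.astype(int),
                }
            ),
            "stability_map.tsv",
        )
    wf = {
        f"gamma={g:g}": {
            "sequence": list(spec.sequence),
            "lower_pct": spec.lower_pct,
            "upper_pct": spec.upper_pct,
            "bac": trace.metrics.bac,
            "fraction_full_battery": trace.fraction_full_battery,
            "mean_assessments": trace.mean_assessments,
        }
        for g, (spec, trace) in bundle["workflows"].items()
    }
    (out / "workflows.json").write_text(
        json.dumps({"config_hash": bundle["config_hash"], "workflows": wf}, indent=2)
    )
    cmp_ = bundle["comparison"]
    write_tsv(
        pd.DataFrame(cmp_["posthoc_p_fdr"], columns=cmp_["models"]).assign(model=cmp_["models"]),
        "posthoc_p_fdr.tsv",
    )
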