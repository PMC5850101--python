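"""End-to-end orchestration: read -> align -> prefilter -> split ->
replacement-method ladder -> final fit -> validation battery ->
applicability domain -> classification, with every stage's report written
as delimited text and a single key-value summary mirroring the statistics
block a QSAR publication prints for its selected model.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import domain, prefilter, rm, validate
from .split import BsmConfig, balance_diagnostics
from .split import split as bsm_split
from .data import (ActivitySet, DescriptorMatrix, LinearModel, SubsetPartition,
                   align, read_activity_table, read_descriptor_table,
                   read_partition, write_partition)
from .mlr import fit_ols, max_pairwise_r2, predict, subset_stats, vif_and_corr
from .synthetic import SyntheticSpec, generate

logger = logging.getLogger("rmqsar")


@dataclass
class PipelineConfig:
    descriptors_path: str | None = None
    activities_path: str | None = None
    partition_path: str | None = None  # overrides BSM when given
    ic50_given: bool = True
    delimiter: str | None = None
    near_const_frac: float = prefilter.DEFAULT_NEAR_CONST_FRAC
    collinear_r2: float = prefilter.DEFAULT_COLLINEAR_R2
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    k_clusters: int | None = None
    d_range: tuple[int, ...] = tuple(range(1, 10))
    n_starts: int = 30
    max_sweeps: int = 50
    selection_tol: float = 0.01
    lno_pct: float = 0.30
    lno_cases: int = 5000
    yrand_permutations: int = 2000
    threshold_nm: float = classify_mod.DEFAULT_THRESHOLD_NM
    out_dir: str | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    partition: SubsetPartition
    prefilter_report: prefilter.PrefilterReport
    ladder: pd.DataFrame
    selected_d: int
    model: LinearModel
    summary: dict[str, object]
    validation: validate.ValidationReport
    ad_report: domain.ADReport
    williams: pd.DataFrame
    classification: classify_mod.ClassificationReport
    balance: pd.DataFrame


def _summary_lines(summary: dict[str, object]) -> str:
    lines = []
    for k, v in summary.items():
        if isinstance(v, float):
            lines.append(f"{k}\t{v:.6g}")
        else:
            lines.append(f"{k}\t{v}")
    return "\n".join(lines) + "\n"


def run_pipeline(
    cfg: PipelineConfig,
    dm: DescriptorMatrix | None = None,
    act: ActivitySet | None = None,
) -> PipelineResult:
    """Execute the full modeling workflow.

    Inputs come from ``cfg`` paths unless ``dm``/``act`` are passed
    in-memory (as the synthetic driver does). Every stochastic stage
    derives its seed from ``cfg.seed``; two runs with identical inputs and
    seed produce byte-identical outputs.
    """
    # --- stage: read + align ---
    if dm is None:
        if cfg.descriptors_path is None or cfg.activities_path is None:
            raise ValueError("descriptors_path and activities_path are required")
        dm = read_descriptor_table(cfg.descriptors_path, delimiter=cfg.delimiter)
        act = read_activity_table(cfg.activities_path, ic50_given=cfg.ic50_given,
                                  delimiter=cfg.delimiter)
    assert act is not None
    dm, act = align(dm, act)
    logger.info("aligned dataset: %d compounds x %d descriptors",
                dm.n_compounds, dm.n_descriptors)

    # --- stage: prefilter ---
    pool, pre_rep = prefilter.prefilter_pool(
        dm, near_const_frac=cfg.near_const_frac, r2_threshold=cfg.collinear_r2)
    logger.info("prefilter: pool %d -> %d columns",
                pre_rep.pool_size_before, pre_rep.pool_size_after)

    # --- stage: split (a provided partition overrides BSM) ---
    if cfg.partition_path:
        part = read_partition(cfg.partition_path)
        order = {cid: i for i, cid in enumerate(part.compound_ids)}
        missing = [c for c in pool.compound_ids if c not in order]
        if missing:
            raise ValueError(f"partition file lacks {len(missing)} compounds")
        part = SubsetPartition(
            list(pool.compound_ids),
            [part.labels[order[c]] for c in pool.compound_ids])
        clusters = np.zeros(pool.n_compounds, dtype=int)
    else:
        bsm = BsmConfig(fractions=cfg.fractions,
                        k_clusters=cfg.k_clusters, seed=cfg.seed)
        part, clusters = bsm_split(pool, bsm)
    balance = balance_diagnostics(part, act)

    y = act.log10_ic50
    idx = {s: part.indices(s) for s in ("train", "val", "test")}
    train_dm = pool.select_rows(idx["train"])
    val_dm = pool.select_rows(idx["val"])
    test_dm = pool.select_rows(idx["test"])
    y_tr, y_v, y_te = y[idx["train"]], y[idx["val"]], y[idx["test"]]

    # --- stage: RM ladder + selection ---
    rm_cfg = rm.RmConfig(n_starts=cfg.n_starts, max_sweeps=cfg.max_sweeps,
                         seed=cfg.seed + 1000)
    ladder, models, selected_d = rm.model_ladder(
        train_dm, y_tr, list(cfg.d_range), rm_cfg, val_dm, y_v,
        test_dm, y_te, selection_tol=cfg.selection_tol)
    model = models[selected_d]
    d = model.d

    # --- stage: final fit statistics ---
    X_tr = train_dm.matrix(model.descriptor_names)
    model, fstats = fit_ols(X_tr, y_tr, names=model.descriptor_names)
    r2_val, s_val = subset_stats(y_v, predict(model, val_dm), d)
    r2_test, s_test = subset_stats(y_te, predict(model, test_dm), d)
    if d >= 2:
        vifs, _ = vif_and_corr(X_tr)
        vif_max = float(np.max(vifs))
        rij2_max = max_pairwise_r2(X_tr)
    else:
        vif_max = 1.0
        rij2_max = 0.0

    # --- stage: validation battery ---
    rep = validate.ValidationReport()
    rep.r2_loo, rep.s_loo = validate.loo_cv(X_tr, y_tr)
    rep.lno_pct, rep.lno_cases = cfg.lno_pct, cfg.lno_cases
    rep.r2_lno, rep.s_lno = validate.leave_n_pct_out(
        X_tr, y_tr, pct=cfg.lno_pct, n_cases=cfg.lno_cases, seed=cfg.seed + 2000)
    rep.n_permutations = cfg.yrand_permutations
    rep.r2_rand, rep.s_rand, rep.yrand_pass = validate.y_randomization(
        X_tr, y_tr, n_permutations=cfg.yrand_permutations,
        seed=cfg.seed + 3000, s_train=fstats.s)
    rep.gt = validate.golbraikh_tropsha(y_te, predict(model, test_dm))
    train_ids = [act.compound_ids[i] for i in idx["train"]]
    rep.o3_count, rep.o3_ids = validate.count_outliers(
        fstats.residuals, fstats.s, ids=train_ids)

    # --- stage: applicability domain (test set as the query block) ---
    ad_rep = domain.assess_ad(model, train_dm, test_dm)
    williams = domain.williams_table(model, pool, act, part, fstats.s)

    # --- stage: classification at the activity cutoff ---
    cls = classify_mod.classify_and_score(
        y_te, predict(model, test_dm), threshold_nm=cfg.threshold_nm)

    gt = rep.gt
    summary: dict[str, object] = {
        "n_train": int(idx["train"].size), "r2_train": fstats.r2, "s_train": fstats.s,
        "rij2_max": rij2_max, "vif_max": vif_max, "o3": rep.o3_count,
        "r2_rand": rep.r2_rand, "s_rand": rep.s_rand,
        "r2_loo": rep.r2_loo, "s_loo": rep.s_loo,
        "r2_l30o": rep.r2_lno, "s_l30o": rep.s_lno,
        "n_val": int(idx["val"].size), "r2_val": r2_val, "s_val": s_val,
        "n_test": int(idx["test"].size), "r2_test": r2_test, "s_test": s_test,
        "gt_k": gt.k, "gt_k_prime": gt.k_prime, "gt_r0sq": gt.r0sq,
        "gt_r0sq_prime": gt.r0sq_prime, "gt_rm2": gt.rm2,
        "gt_pass": gt.passes,
        "h_star": ad_rep.h_star,
        "test_outside_leverage": int(np.sum(~ad_rep.inside_leverage)),
        "test_outside_standardization": int(np.sum(~ad_rep.inside_standardization)),
        "accuracy_pct": cls.accuracy_pct, "sensitivity": cls.sensitivity,
        "specificity": cls.specificity, "mcc": cls.mcc,
        "selected_d": selected_d,
        "descriptors": ";".join(model.descriptor_names),
        "pool_before": pre_rep.pool_size_before,
        "pool_after": pre_rep.pool_size_after,
        "seed": cfg.seed,
    }

    result = PipelineResult(
        config=cfg, partition=part, prefilter_report=pre_rep, ladder=ladder,
        selected_d=selected_d, model=model, summary=summary, validation=rep,
        ad_report=ad_rep, williams=williams, classification=cls, balance=balance,
    )
    model.train_stats = (fstats.r2, fstats.s)
    if cfg.out_dir:
        _write_bundle(result, Path(cfg.out_dir))
    return result


def _write_bundle(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.txt").write_text(_summary_lines(res.summary), encoding="utf-8")
    res.ladder.to_csv(out / "ladder.csv", index=False)
    write_partition(res.partition, out / "partition.csv")
    res.prefilter_report.to_frame().to_csv(out / "prefilter.csv", index=False)
    res.balance.to_csv(out / "balance.csv", index=False)
    res.ad_report.table.to_csv(out / "ad_test.csv", index=False)
    res.williams.to_csv(out / "williams.csv", index=False)
    pd.DataFrame({
        "descriptor": res.model.descriptor_names + ["(intercept)"],
        "coefficient": list(res.model.coefficients) + [res.model.intercept],
    }).to_csv(out / "model.csv", index=False)
    (out / "model.txt").write_text(res.model.equation() + "\n", encoding="utf-8")
    cls = res.classification
    pd.DataFrame(
        [[cls.tp, cls.fn], [cls.fp, cls.tn]],
        index=["obs_active", "obs_inactive"],
        columns=["pred_active", "pred_inactive"],
    ).to_csv(out / "confusion.csv")
    cfg_echo = {k: str(v) for k, v in dataclasses.asdict(res.config).items()}
    (out / "config_echo.txt").write_text(_summary_lines(cfg_echo), encoding="utf-8")


def run_synthetic(
    spec: SyntheticSpec, cfg: PipelineConfig
) -> tuple[PipelineResult, "object"]:
    """Generate a synthetic dataset and run the full pipeline on it.

    Returns the pipeline result and the planted truth, so callers can
    score descriptor recovery against the generating model.
    """
    dm, act, truth = generate(spec)
    result = run_pipeline(cfg, dm=dm, act=act)
    return result, truth
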