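"""Validation battery for the selected model.

Internal: leave-one-out and leave-30%-out cross-validation (fixed
descriptor subset), Y-randomization (2,000 scrambles; a real model must
have S_rand well above S_train). External: Golbraikh-Tropsha criteria on
the test set and the o3 training-outlier count.
"""

from common import RESULTS, SEED, load_model, load_partition, \
    load_pool_and_activities

import rmqsar as rq
from rmqsar.validate import (count_outliers, golbraikh_tropsha,
                             leave_n_pct_out, loo_cv, y_randomization)


def main() -> None:
    pool, act = load_pool_and_activities()
    part = load_partition()
    model = load_model()
    y = act.log10_ic50
    tr = part.indices("train")
    te = part.indices("test")
    X = pool.matrix(model.descriptor_names)
    _, stats = rq.fit_ols(X[tr], y[tr], names=model.descriptor_names)

    r2_loo, s_loo = loo_cv(X[tr], y[tr])
    r2_lno, s_lno = leave_n_pct_out(X[tr], y[tr], pct=0.30, n_cases=5000,
                                    seed=SEED)
    r2_rand, s_rand, ok = y_randomization(X[tr], y[tr], n_permutations=2000,
                                          seed=SEED, s_train=stats.s)
    gt = golbraikh_tropsha(y[te], rq.predict(model, pool)[te])
    o3, o3_ids = count_outliers(stats.residuals, stats.s,
                                ids=[act.compound_ids[i] for i in tr])

    lines = [
        ("r2_train", stats.r2), ("s_train", stats.s),
        ("r2_loo", r2_loo), ("s_loo", s_loo),
        ("r2_l30o", r2_lno), ("s_l30o", s_lno),
        ("r2_rand", r2_rand), ("s_rand", s_rand), ("yrand_pass", ok),
        ("gt_k", gt.k), ("gt_k_prime", gt.k_prime),
        ("gt_r0sq", gt.r0sq), ("gt_rm2", gt.rm2), ("gt_pass", gt.passes),
        ("o3", o3), ("o3_ids", ";".join(o3_ids)),
    ]
    text = "\n".join(f"{k}\t{v:.4f}" if isinstance(v, float) else f"{k}\t{v}"
                     for k, v in lines)
    (RESULTS / "validation.txt").write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
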