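"""Applicability domain of the selected model.

Scores every test-set compound with both AD definitions — leverage
against h* = 3(d+1)/n_train and the standardization rule (max |s_ik| <= 3
with the s_new fallback) — and writes the Williams-plot table for the
whole dataset.
"""

import numpy as np

from common import RESULTS, load_model, load_partition, \
    load_pool_and_activities

import rmqsar as rq
from rmqsar.domain import assess_ad, williams_table


def main() -> None:
    pool, act = load_pool_and_activities()
    part = load_partition()
    model = load_model()
    y = act.log10_ic50
    tr = part.indices("train")
    X = pool.matrix(model.descriptor_names)
    _, stats = rq.fit_ols(X[tr], y[tr], names=model.descriptor_names)

    rep = assess_ad(model, pool.select_rows(tr),
                    pool.select_rows(part.indices("test")))
    rep.table.to_csv(RESULTS / "ad_test.csv", index=False)
    wt = williams_table(model, pool, act, part, stats.s)
    wt.to_csv(RESULTS / "williams.csv", index=False)

    n_out_lev = int(np.sum(~rep.inside_leverage))
    n_out_std = int(np.sum(~rep.inside_standardization))
    print(f"h* = {rep.h_star:.4f}")
    print(f"test compounds outside leverage AD: {n_out_lev}")
    print(f"test compounds outside standardization AD: {n_out_std}")
    print(f"approach agreement on test set: {100 * rep.agreement:.1f}%")
    print(f"compounds breaching |std residual| > 3: "
          f"{int(wt['residual_outlier'].sum())}")


if __name__ == "__main__":
    main()
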