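"""Replacement-method search: best 1- to 9-descriptor models.

For each size d, RM minimizes the training standard deviation S over the
prefiltered pool; the reported ladder mirrors the training/validation/
test statistics per size. The selected model is the smallest d whose
validation S is within 0.01 of the ladder minimum (parsimony rule), and
its recovery of the planted descriptors is scored against the truth file.
"""

import pandas as pd

from common import MODEL, RESULTS, SEED, TRUTH, load_partition, \
    load_pool_and_activities

import rmqsar as rq
from rmqsar.rm import RmConfig, model_ladder
from rmqsar.synthetic import read_truth


def main() -> None:
    pool, act = load_pool_and_activities()
    part = load_partition()
    y = act.log10_ic50
    idx = {s: part.indices(s) for s in ("train", "val", "test")}
    table, models, sel = model_ladder(
        pool.select_rows(idx["train"]), y[idx["train"]],
        range(1, 10), RmConfig(seed=SEED),
        pool.select_rows(idx["val"]), y[idx["val"]],
        pool.select_rows(idx["test"]), y[idx["test"]])
    table.to_csv(RESULTS / "ladder.csv", index=False)
    model = models[sel]
    pd.DataFrame({
        "descriptor": model.descriptor_names + ["(intercept)"],
        "coefficient": list(model.coefficients) + [model.intercept],
    }).to_csv(MODEL, index=False)
    (RESULTS / "model.txt").write_text(model.equation() + "\n")

    print(table.drop(columns="descriptors").to_string(
        index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\nselected d = {sel}: {model.equation()}")
    truth = read_truth(TRUTH)
    rec = set(model.descriptor_names) & set(truth.signal_names)
    print(f"planted descriptors recovered: {len(rec)}/{len(truth.signal_names)}")


if __name__ == "__main__":
    main()
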