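"""Regression-to-classification scoring on the test set.

Compounds at or below 1000 nM observed IC50 count as highly active; the
regression's predictions are thresholded the same way and scored with the
Cooper statistics (accuracy, sensitivity, specificity) and MCC.
"""

import pandas as pd

from common import RESULTS, load_model, load_partition, \
    load_pool_and_activities

import rmqsar as rq


def main() -> None:
    pool, act = load_pool_and_activities()
    part = load_partition()
    model = load_model()
    te = part.indices("test")
    y_obs = act.log10_ic50[te]
    y_pred = rq.predict(model, pool)[te]
    rep = rq.classify_and_score(y_obs, y_pred, threshold_nm=1000.0)

    pd.DataFrame(
        [[rep.tp, rep.fn], [rep.fp, rep.tn]],
        index=["obs_active", "obs_inactive"],
        columns=["pred_active", "pred_inactive"],
    ).to_csv(RESULTS / "confusion.csv")
    print(f"test set, threshold {rep.threshold_nm:.0f} nM:")
    print(f"  TP={rep.tp} FP={rep.fp} TN={rep.tn} FN={rep.fn}")
    print(f"  A% = {rep.accuracy_pct:.1f}  SE = {rep.sensitivity:.2f}  "
          f"SP = {rep.specificity:.2f}  MCC = {rep.mcc:.2f}")


if __name__ == "__main__":
    main()
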