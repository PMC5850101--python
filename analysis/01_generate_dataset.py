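"""Generate the study dataset.

Emits a synthetic stand-in for a curated kinase-inhibitor descriptor set:
530 compounds, a 2,000-column descriptor pool contaminated with constant,
near-constant, missing-valued and collinear columns, and IC50 activities
spanning 0.8-145,000 nM driven by a planted 8-descriptor linear model
with 0.8 log-unit noise. The planted truth is recorded so later steps can
score recovery.
"""

from common import ACTIVITIES, DATA, DESCRIPTORS, SEED, TRUTH

import rmqsar as rq
from rmqsar.data import write_activity_table, write_descriptor_table
from rmqsar.synthetic import write_truth


def main() -> None:
    spec = rq.SyntheticSpec(seed=SEED)
    dm, act, truth = rq.generate(spec)
    DATA.mkdir(parents=True, exist_ok=True)
    write_descriptor_table(dm, DESCRIPTORS)
    write_activity_table(act, ACTIVITIES)
    write_truth(truth, TRUTH)
    print(f"dataset: {dm.n_compounds} compounds x {dm.n_descriptors} descriptors")
    print(f"activity range: {act.log10_ic50.min():.2f} .. "
          f"{act.log10_ic50.max():.2f} log10 nM")
    print(f"planted model: {len(truth.signal_names)} descriptors, "
          f"noise {truth.noise_sd} log units -> {DATA}")


if __name__ == "__main__":
    main()
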