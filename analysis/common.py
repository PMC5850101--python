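"""Shared paths and loaders for the numbered analysis scripts.

The scripts form a chain: each reads what the previous one wrote under
``results/``. Run them in order from the repository root, e.g.::

    python analysis/01_generate_dataset.py
    python analysis/02_prefilter_pool.py
    ...

``SEED`` fixes every stochastic stage of the chain.
"""

from pathlib import Path

import rmqsar as rq

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

DESCRIPTORS = DATA / "descriptors.csv"
ACTIVITIES = DATA / "activities.csv"
TRUTH = DATA / "truth.txt"
POOL = RESULTS / "pool.csv"
PARTITION = RESULTS / "partition.csv"
MODEL = RESULTS / "model.csv"


def load_pool_and_activities():
    dm = rq.read_descriptor_table(POOL)
    act = rq.read_activity_table(ACTIVITIES)
    return rq.align(dm, act)


def load_model() -> rq.LinearModel:
    import pandas as pd

    df = pd.read_csv(MODEL)
    rows = df[df["descriptor"] != "(intercept)"]
    intercept = float(df.loc[df["descriptor"] == "(intercept)",
                             "coefficient"].iloc[0])
    return rq.LinearModel(rows["descriptor"].tolist(),
                          rows["coefficient"].to_numpy(), intercept)


def load_partition():
    from rmqsar.data import read_partition

    return read_partition(PARTITION)
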