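"""Reduce the raw descriptor pool to informative, linearly independent columns.

Removes columns with missing values, constant and near-constant columns
(modal frequency >= 0.95), then collinear pairs (pairwise r^2 >= 0.998,
earlier column kept). Writes the reduced pool and the removal report.
"""

from common import DESCRIPTORS, POOL, RESULTS

import rmqsar as rq
from rmqsar.data import write_descriptor_table


def main() -> None:
    dm = rq.read_descriptor_table(DESCRIPTORS)
    pool, rep = rq.prefilter_pool(dm)
    RESULTS.mkdir(parents=True, exist_ok=True)
    write_descriptor_table(pool, POOL)
    rep.to_frame().to_csv(RESULTS / "prefilter.csv", index=False)
    print(f"pool: {rep.pool_size_before} -> {rep.pool_size_after} columns")
    print(f"  missing: {len(rep.removed_missing)}, "
          f"constant: {len(rep.removed_constant)}, "
          f"near-constant: {len(rep.removed_near_constant)}, "
          f"collinear: {len(rep.removed_collinear)}")


if __name__ == "__main__":
    main()
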