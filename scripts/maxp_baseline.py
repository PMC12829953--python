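"""Joint-significance (max-p) baseline for benchmark comparisons.

Reads a coefficient-summary table exported by the benchmark hook (columns
p_alpha, p_beta with two-sided normal p-values per margin), forms the
joint-significance statistic p_max = max(p_alpha, p_beta), applies
Benjamini-Hochberg at the requested level, and writes a table with a
``rejected`` flag per unit.  This is the classical p-value-based screen the
lfdr method is benchmarked against; it treats the composite null through
the max statistic and is conservative under the double null.

Usage: python scripts/maxp_baseline.py SUMMARY_TSV OUT_TSV [--alpha A]
"""

import argparse

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("summary")
    ap.add_argument("out")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    df = pd.read_csv(args.summary, sep="\t", comment="#")
    p_max = np.maximum(df["p_alpha"].to_numpy(), df["p_beta"].to_numpy())
    reject, *_ = multipletests(p_max, alpha=args.alpha, method="fdr_bh")
    out = pd.DataFrame({"unit_id": df["unit_id"], "rejected": reject.astype(int)})
    out.to_csv(args.out, sep="\t", index=False)


if __name__ == "__main__":
    main()
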