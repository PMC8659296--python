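"""Log-decade load categories per stage for every simulated CFU dataset.

Reads the results/cfu_*.csv tables and writes one tidy category table
(stage x load class x proportion) per dataset — the numbers behind
stacked category plots of bacterial persistence through metamorphosis.
"""

import argparse
from pathlib import Path

from pupamp.cfu import category_proportions
from pupamp.config import log
from pupamp.io import read_cfu_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    for path in sorted(args.out_dir.glob("cfu_*.csv")):
        if path.name.startswith("cfu_categories"):
            continue
        data = read_cfu_table(path)
        table = category_proportions(data)
        out = args.out_dir / f"categories_{path.stem.removeprefix('cfu_')}.csv"
        table.to_csv(out, index=False)
        cleared = table[(table.category == "0-10")].set_index("stage")["proportion"]
        log(f"{path.name}: culture-low (0-10) fraction "
            f"P0 {cleared.get('P0', 0):.2f} -> pharate {cleared.get('pharate', 0):.2f}")


if __name__ == "__main__":
    main()
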