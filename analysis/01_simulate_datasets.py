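"""Generate the synthetic datasets every later analysis step consumes.

Writes, under results/:

* CFU plating tables for a control-like condition (bacterial loads fall
  between pupariation and the pharate adult stage) and an EcRDN-like
  condition (ecdysone signalling disabled, loads rise), one per bacterium;
* a qPCR CT table with a planted pupariation expression peak for drs in the
  control genotype only;
* a ground-truth JSON recording the generating parameters.
"""

import argparse
import json
from pathlib import Path

from pupamp.config import log
from pupamp.io import write_cfu_table, write_ct_table
from pupamp.synthetic import (
    CtSimSpec,
    control_like_spec,
    ecrdn_like_spec,
    simulate_ct_dataset,
    simulate_zinb_counts,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    truth = {"seed": args.seed, "cfu": {}, "ct": {}}
    for maker in (control_like_spec, ecrdn_like_spec):
        for bacterium in ("Lactobacillus", "Acetobacter"):
            spec = maker(bacterium)
            data = simulate_zinb_counts(spec, seed=args.seed)
            name = f"cfu_{spec.genotype}_{bacterium}.csv"
            write_cfu_table(data, args.out_dir / name)
            truth["cfu"][name] = {
                "P0": vars(spec.p0), "pharate": vars(spec.pharate),
                "n_per_stage": spec.n_per_stage,
            }
            log(f"{name}: {len(data)} individuals, "
                f"{(data.cfu_per_pupa == 0).mean():.0%} culture-negative")

    ct_spec = CtSimSpec(
        genotypes=("control", "EcRDN"),
        genes=("drs", "drsl2", "drsl5"),
        effects={
            ("control", "P0", "drs"): 6.0,
            ("control", "P0", "drsl2"): 5.0,
            ("control", "P0", "drsl5"): 5.0,
            # ecdysone-insensitive fat body: systemic drs peak lost, local
            # drsl2/drsl5 induction retained
            ("EcRDN", "P0", "drs"): 0.5,
            ("EcRDN", "P0", "drsl2"): 5.0,
            ("EcRDN", "P0", "drsl5"): 5.0,
        },
    )
    ct = simulate_ct_dataset(ct_spec, seed=args.seed)
    write_ct_table(ct, args.out_dir / "ct_table.csv")
    truth["ct"] = {str(k): v for k, v in ct_spec.effects.items()}
    log(f"ct_table.csv: {len(ct)} CT measurements")

    (args.out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")


if __name__ == "__main__":
    main()
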