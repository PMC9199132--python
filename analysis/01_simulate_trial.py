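"""Simulate one full breeding-trial dataset at the real crossing design.

Emits the 21-parent / 42-family / 120-progeny pedigree, the true
breeding values, and 4 years x 3 cuts x 2 replicates of plot records
for DFY, H, CD (all cuts) and NS, FL (spring only), at the published
component scale.  Downstream scripts read these files.
"""

import argparse
import json
from pathlib import Path

from forageblup.pedigree import write_pedigree_csv
from forageblup.simulate import DEFAULT_SEED, SimulationTruth, simulate_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = ap.parse_args()

    truth = SimulationTruth(seed=args.seed)
    ds = simulate_dataset(truth)
    args.out.mkdir(parents=True, exist_ok=True)
    write_pedigree_csv(ds.pedigree, args.out / "pedigree.csv")
    ds.phenotypes.to_csv(args.out / "phenotypes.csv", index=False)
    ds.true_bv.rename_axis("id").to_csv(args.out / "true_breeding_values.csv")
    (args.out / "truth.json").write_text(
        json.dumps(
            {
                tr: {
                    "sigma2_A": truth.trait_truth[tr].sigma2_A,
                    "sigma2_pe": truth.trait_truth[tr].sigma2_pe,
                    "sigma2_e": truth.trait_truth[tr].sigma2_e,
                }
                for tr in truth.traits
            },
            indent=2,
        )
    )
    n_obs = int(ds.phenotypes[list(truth.traits)].notna().to_numpy().sum())
    print(
        f"simulated {ds.pedigree.n} individuals "
        f"({len(ds.pedigree.founders)} parents, {ds.pedigree.n - len(ds.pedigree.founders)} progenies), "
        f"{len(ds.phenotypes)} plot records, {n_obs} trait observations -> {args.out}"
    )


if __name__ == "__main__":
    main()
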