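"""Yield stability across years and PCA screening of entity sets.

Computes Eberhart-Russell slopes of spring yield on the yearly
environmental index, separately for parents, full-sib families (family
means) and progenies, plus correlation-matrix PCA with biplots per set.
"""

import argparse
from pathlib import Path

import pandas as pd

from forageblup import studydesign as sd
from forageblup.stability import eberhart_russell, pca_biplot, plot_biplot
from forageblup.studydesign import family_of


def entity_sets(pheno: pd.DataFrame) -> dict[str, pd.DataFrame]:
    df = pheno.copy()
    df["family"] = df["genotype"].map(lambda g: family_of(str(g)))
    parents = df[df["family"].isna()]
    progenies = df[df["family"].notna()]
    return {"parents": parents, "families": progenies.assign(genotype=progenies["family"]),
            "progenies": progenies}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out", type=Path, default=Path("results/stability"))
    args = ap.parse_args()

    pheno = pd.read_csv(args.data / "phenotypes.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    for name, sub in entity_sets(pheno).items():
        spring = sub[sub["harvest"] == "spring"]
        ym = spring.pivot_table(index="genotype", columns="year", values="DFY", aggfunc="mean")
        stab = eberhart_russell(ym)
        stab.rename_axis("entity").to_csv(args.out / f"stability_{name}.csv")

        tm = sub.pivot_table(index="genotype", values=list(sd.TRAITS), aggfunc="mean")
        pca = pca_biplot(tm)
        pca.scores.rename_axis("entity").to_csv(args.out / f"pca_scores_{name}.csv")
        pca.loadings.rename_axis("trait").to_csv(args.out / f"pca_loadings_{name}.csv")
        plot_biplot(pca, args.out / f"pca_biplot_{name}.png", title=name)
        print(
            f"{name:10s}: {len(stab)} entities, mean b = {stab['b'].mean():.3f}, "
            f"{int(stab['significant_vs_1'].sum())} slopes differ from 1 (5% level), "
            f"PC1+PC2 = {pca.var_explained[:2].sum():.1f}% of variation"
        )
    print(f"\ntables and biplots in {args.out}")


if __name__ == "__main__":
    main()
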