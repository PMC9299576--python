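#!/usr/bin/env python
"""Cross-sample statistics over the panel's fragmentomic profiles.

Three analyses: (1) PCA of the 3'-end 4-mer motif matrix — biofluids
with different RNase activity should order along PC1; (2) Pearson
correlation between each sample's short-fragment (<50 nt) rate and its
3' pyrimidine/purine ratio — both are downstream of the same cleavage
activity, so a strong positive correlation is expected; (3) the
PNK-on/PNK-off contrast of 3'-end pyrimidine content with the
significance tiers used throughout.
"""

from pathlib import Path

import pandas as pd

from cfrna.stats import pca, pearson, stars

FRAG = Path("results/fragmentomics")
OUT = Path("results/stats")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = pd.read_csv(FRAG / "fragment_summary.tsv", sep="\t")
    motifs = pd.read_csv(FRAG / "end_motifs_3p.tsv", sep="\t", index_col=0)

    fluids = summary[~summary["sample"].str.startswith("uhrr")]

    res = pca(motifs[fluids["sample"]].to_numpy().T, n_components=2)
    scores = pd.DataFrame(
        res.scores, index=list(fluids["sample"]), columns=["PC1", "PC2"]
    )
    scores.to_csv(OUT / "motif_pca_scores.tsv", sep="\t", index_label="sample")
    print("motif PCA (explained variance ratio "
          f"{res.explained_variance_ratio[0]:.2f}, "
          f"{res.explained_variance_ratio[1]:.2f}):")
    print(scores.to_string())

    r, p = pearson(fluids["frac_lt50"], fluids["py_pu_ratio_3p"])
    print(f"\nshort-fragment rate vs 3' py/pu ratio: "
          f"r = {r:.3f}, p = {p:.3g} {stars(p)}")
    pd.DataFrame(
        [{"comparison": "frac_lt50_vs_py_pu_ratio_3p", "r": r, "p": p,
          "stars": stars(p)}]
    ).to_csv(OUT / "correlations.tsv", sep="\t", index=False)

    uhrr = summary[summary["sample"].str.startswith("uhrr")]
    on = uhrr.loc[uhrr["sample"] == "uhrr_pnk_on", "py_pu_ratio_3p"].item()
    off = uhrr.loc[uhrr["sample"] == "uhrr_pnk_off", "py_pu_ratio_3p"].item()
    print(f"\nPNK contrast (3' py/pu ratio): on = {on:.3f}, off = {off:.3f}, "
          f"enrichment = {on / off:.2f}x")
    pd.DataFrame(
        [{"condition": "pnk_on", "py_pu_ratio_3p": on},
         {"condition": "pnk_off", "py_pu_ratio_3p": off}]
    ).to_csv(OUT / "pnk_contrast.tsv", sep="\t", index=False)
    print(f"\ntables -> {OUT}")


if __name__ == "__main__":
    main()
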