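#!/usr/bin/env python
"""3 × 2 repeated-measures ANOVA (Emotion × Mouth) on the P100 and N170
amplitude tables, with F, p and both η² variants per fixed effect."""

import argparse
from pathlib import Path

import pandas as pd

from erpface.anova import fit_both_components

def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    p100 = pd.read_csv(args.results / "peaks_p100.tsv", sep="\t")
    n170 = pd.read_csv(args.results / "peaks_n170.tsv", sep="\t")
    t_p100, t_n170 = fit_both_components(p100, n170)
    for name, tab in (("p100", t_p100), ("n170", t_n170)):
        tab.reset_index().to_csv(
            args.results / f"anova_{name}.tsv", sep="\t", index=False, float_format="%.6g"
        )
        print(f"\n{name.upper()} amplitude ANOVA:")
        for effect in ("Emotion", "Mouth", "Emotion:Mouth"):
            row = tab.loc[effect]
            print(
                f"  {effect:<13} df={row['df']:>2.0f}  SS={row['SS']:8.3f}  "
                f"F={row['F']:7.3f}  p={row['p']:.4f}  eta2={row['eta2']:.4f}"
            )


if __name__ == "__main__":
    main()
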