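#!/usr/bin/env python
"""Spearman drug-sensitivity association screen across cell lines.

First screens the prognostic network genes (mirroring a candidate-driven
drug-target analysis), then the full gene panel, so the planted
gene-drug relations are exercised too.  Pairs with BH FDR < 0.05 are
flagged; negative rho (higher expression, lower IC50) means sensitizing.
"""

from pathlib import Path

import pandas as pd

from cernet import drugs, simulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = simulate.load_bundle(ROOT / "results" / "synthetic")
    out = ROOT / "results" / "drugs"
    out.mkdir(parents=True, exist_ok=True)

    screen_file = ROOT / "results" / "survival" / "survival_screen.tsv"
    prognostic = []
    if screen_file.exists():
        table = pd.read_csv(screen_file, sep="\t")
        prognostic = sorted(table.loc[table["significant"].fillna(False), "gene_id"])

    expr = bundle.matrices["cell_lines"]
    if prognostic:
        cand = drugs.drug_gene_screen(expr, bundle.drugs, prognostic)
        drugs.write_assoc_tsv(cand, out / "drug_associations_prognostic.tsv")
        print(f"prognostic genes screened: {len(prognostic)}; "
              f"flagged pairs: {int(cand['flagged'].sum())}")

    full = drugs.drug_gene_screen(expr, bundle.drugs)
    drugs.write_assoc_tsv(full, out / "drug_associations_full.tsv")
    flagged = full[full["flagged"]]
    print(f"full panel: {int(full['p_value'].notna().sum())} pairs tested, "
          f"{len(flagged)} flagged at FDR < 0.05 "
          f"(at the planted effect size, |rho| ~ 0.6 at n = 30 rarely survives "
          f"BH across the whole panel)")
    for _, row in flagged.iterrows():
        print(f"  {row['gene_id']} ~ {row['drug_id']}: rho = {row['rho']:.2f} "
              f"({row['direction']}), FDR = {row['fdr']:.3g}")

    # planted relations: sign and raw significance, regardless of panel-wide FDR
    indexed = full.set_index(["gene_id", "drug_id"])
    ok = 0
    for pair in bundle.manifest.drug_pairs:
        row = indexed.loc[(pair["gene"], pair["drug"])]
        sign_ok = (row["rho"] < 0) == (pair["slope_sign"] < 0)
        ok += sign_ok and row["p_value"] < 0.05
        print(f"  planted {pair['gene']} ~ {pair['drug']}: rho = {row['rho']:.2f} "
              f"(planted sign {pair['slope_sign']:+d}), raw p = {row['p_value']:.3g}")
    print(f"planted pairs with correct sign at raw p < 0.05: {ok}/{len(bundle.manifest.drug_pairs)}")


if __name__ == "__main__":
    main()
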