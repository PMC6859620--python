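"""Hypoxia-signature enrichment of the tumor-vs-paratumor expression ranking.

Ranks genes by log2 fold change (tumor over paratumor, CPM scale) and
scores the built-in 14-gene hypoxia metagene signature with the weighted
running-sum statistic and a gene-label permutation null.
"""

import argparse
from pathlib import Path

from m6akit import io
from m6akit.gsea import load_hypoxia_signature, nes_and_pvalue, rank_from_expression
from m6akit.workflow import expression_conditions


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results/gsea"))
    ap.add_argument("--permutations", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    expression = io.read_expression(args.cohort / "expression.tsv")
    ranked = rank_from_expression(expression, expression_conditions(expression.columns))
    sig = load_hypoxia_signature()
    res = nes_and_pvalue(ranked, sig, n_permutations=args.permutations, seed=args.seed)
    print(f"{sig.name}: ES={res.es:.3f} NES={res.nes:.3f} "
          f"p={res.p_value:.4g} ({res.n_hits}/{len(sig.members)} genes in ranking)")
    io.write_json({"gene_set": sig.name, "es": res.es, "nes": res.nes,
                   "p_value": res.p_value, "n_permutations": res.n_permutations,
                   "n_hits": res.n_hits, "seed": res.seed},
                  args.outdir / "enrichment.json")


if __name__ == "__main__":
    main()
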