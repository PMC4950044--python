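"""Alpha diversity along the transect: richness estimators and the
latitudinal diversity gradient.

Computes per-sample Shannon, Simpson, Chao1 and ACE from the sequencing
counts and summarizes how Shannon diversity varies with latitude band.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import RESULTS, default_survey  # noqa: E402

from aoamacro.alpha import diversity_table, rarefaction_curve  # noqa: E402


def main():
    _, _, counts, _, meta = default_survey()
    div = diversity_table(counts)
    div = div.merge(meta[["sample_id", "latitude", "province", "layer"]], on="sample_id")
    div.to_csv(RESULTS / "diversity.tsv", sep="\t", index=False)

    by_province = div.groupby("province")["shannon_h"].mean().sort_values()
    print("mean Shannon H' by province (low to high):")
    for prov, h in by_province.items():
        print(f"  {prov:5s} {h:.3f}")

    sample = counts.values[0]
    curve = rarefaction_curve(sample, [10, 100, 500, 1000, 2000])
    print(f"rarefaction for {counts.sample_ids[0]}: "
          + ", ".join(f"E[S({n})]={e:.1f}" for n, e in curve))
    print(f"diversity table written to {RESULTS / 'diversity.tsv'}")


if __name__ == "__main__":
    main()
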