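"""Shared-OTU biogeography and the hemisphere diversity-gradient ANCOVA.

Counts OTUs shared between ocean provinces (and between depth layers), and
tests whether the latitudinal Shannon-diversity slope differs between
hemispheres (slope homogeneity would support a bipolar pattern).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import RESULTS, default_survey  # noqa: E402

from aoamacro.alpha import diversity_table  # noqa: E402
from aoamacro.macroecology import diversity_gradient_ancova, shared_otus  # noqa: E402
from aoamacro.tables import align_samples  # noqa: E402


def main():
    _, _, counts, fingerprint, meta = default_survey()
    sub, msub = align_samples(fingerprint, meta)

    by_prov = shared_otus(sub, msub, "province")
    by_layer = shared_otus(sub, msub, "layer")
    by_prov.to_csv(RESULTS / "shared_otus_province.tsv", sep="\t", index=False)
    by_layer.to_csv(RESULTS / "shared_otus_layer.tsv", sep="\t", index=False)
    arct = by_prov[by_prov["focal_group"] == "ARCT"].set_index("other_group")
    print("proportion of ARCT OTUs shared with:")
    for other, row in arct.iterrows():
        print(f"  {other:5s} {row['proportion']:.2f} ({row['n_shared']}/{row['n_focal']})")

    div = diversity_table(counts)
    anc = diversity_gradient_ancova(div, msub)
    print(f"diversity gradient slopes: N {anc['slope_N']:+.4f}, "
          f"S {anc['slope_S']:+.4f} H' per deg |lat|; "
          f"slope-homogeneity P = {anc['interaction_p']:.3f}")
    verdict = "indistinguishable (bipolar-consistent)" \
        if anc["interaction_p"] >= 0.05 else "different between hemispheres"
    print(f"hemisphere slopes are {verdict}")


if __name__ == "__main__":
    main()
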