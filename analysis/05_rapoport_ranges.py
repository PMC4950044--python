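"""Rapoport patterns: OTU latitudinal ranges vs latitude, abundance classes.

Computes per-OTU latitudinal and temperature ranges, the per-sample Stevens
mean range, and regresses the Stevens mean on absolute latitude per
hemisphere; a positive significant slope is Rapoport-consistent.  Also
contrasts the mean range of high- vs low-abundance OTUs.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import RESULTS, default_survey  # noqa: E402

from aoamacro.macroecology import (  # noqa: E402
    abundance_class_ranges,
    otu_ranges,
    range_vs_latitude,
)


def main():
    _, _, counts, fingerprint, meta = default_survey()
    per_otu, per_sample = otu_ranges(counts, meta, axis="latitude")
    per_otu.to_csv(RESULTS / "otu_latitude_ranges.tsv", sep="\t", index=False)
    per_sample.to_csv(RESULTS / "stevens_mean_ranges.tsv", sep="\t", index=False)

    for hemi in ("N", "S"):
        fit = range_vs_latitude(per_sample, meta, hemi)
        flag = "*" if fit.significant else "NS"
        print(f"hemisphere {hemi}: Stevens slope {fit.slope:+.3f} deg range per "
              f"deg |lat| ({flag}, r2 = {fit.r_squared:.2f}, n = {fit.n})")

    temp_otu, _ = otu_ranges(counts, meta, axis="temperature")
    temp_otu.to_csv(RESULTS / "otu_temperature_ranges.tsv", sep="\t", index=False)

    classes = abundance_class_ranges(fingerprint, meta)
    classes.to_csv(RESULTS / "abundance_class_ranges.tsv", sep="\t", index=False)
    by = classes.set_index("abundance_class")["mean_range"]
    print(f"mean latitudinal range: HA {by['HA']:.1f} deg vs LA (excl.) "
          f"{by['LA_exclusive']:.1f} deg")


if __name__ == "__main__":
    main()
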