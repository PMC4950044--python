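"""T-RFLP fingerprint processing and in-silico restriction digestion.

Community fingerprints are built from the lengths of fluorescently labelled
terminal restriction fragments: an amplicon labelled at one end is digested
(MboI, RsaI or HaeIII here), and only the fragment carrying the label is
detected.  Peaks below a relative height threshold (default 0.5% of the
sample's total peak height) are discarded and the survivors renormalized;
peaks are binned by fragment length per (enzyme, dye) channel to form OTU
columns.  A simple greedy sequence clusterer at 98% pairwise identity is
provided for synthetic marker sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .tables import OtuTable

__all__ = [
    "Peak",
    "PeakProfile",
    "ENZYMES",
    "digest_terminal",
    "threshold_and_normalize",
    "bin_peaks",
    "greedy_cluster",
]

#: Restriction enzymes: recognition site and cut offset on the strand read
#: 5'->3' (fragment length = site position + offset).  MboI cuts before the
#: G of GATC (^GATC, 5' overhang); RsaI GT^AC and HaeIII GG^CC cut centrally
#: (blunt).
ENZYMES = {
    "MboI": ("GATC", 0),
    "RsaI": ("GTAC", 2),
    "HaeIII": ("GGCC", 2),
}

DYES = ("FAM", "VIC")


@dataclass(frozen=True)
class Peak:
    fragment_length: float
    dye: str
    enzyme: str
    height: float


@dataclass
class PeakProfile:
    """All detected peaks of one sample across enzyme/dye channels."""

    sample_id: str
    peaks: list

    def __post_init__(self):
        for p in self.peaks:
            if p.height < 0:
                raise ValueError(f"{self.sample_id}: negative peak height")
            if p.fragment_length <= 0:
                raise ValueError(f"{self.sample_id}: non-positive fragment length")
            if p.enzyme not in ENZYMES:
                raise ValueError(f"{self.sample_id}: unknown enzyme {p.enzyme!r}")
            if p.dye not in DYES:
                raise ValueError(f"{self.sample_id}: unknown dye {p.dye!r}")


def digest_terminal(sequence: str, enzyme: str, labeled_end: str = "five_prime"):
    """Length (bp) of the labelled terminal fragment, or ``None`` if uncut.

    ``five_prime`` measures from the 5' end of the given strand to the first
    cut on it.  ``three_prime`` measures the fragment detected when the
    *other* end is labelled, i.e. the first cut encountered on the
    complementary strand from its 5' end — computed by digesting the reverse
    complement.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"ambiguous/invalid bases {bad} in sequence")
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    if labeled_end == "three_prime":
        return digest_terminal(str(Seq(seq).reverse_complement()), enzyme, "five_prime")
    if labeled_end != "five_prime":
        raise ValueError(f"labeled_end must be five_prime or three_prime, got {labeled_end!r}")
    site, offset = ENZYMES[enzyme]
    pos = seq.find(site)
    if pos == -1:
        return None
    return pos + offset


def threshold_and_normalize(profile: PeakProfile, threshold: float = 0.005) -> dict:
    """Discard peaks below ``threshold`` of the total peak height; renormalize.

    Peaks at exactly the threshold are kept (>= rule).  Returns a mapping
    ``(enzyme, dye, fragment_length) -> relative height`` summing to 1.
    Raises ``ValueError`` if no peak survives.
    """
    total = sum(p.height for p in profile.peaks)
    if total <= 0:
        raise ValueError(f"{profile.sample_id}: no positive peaks")
    kept = {
        (p.enzyme, p.dye, p.fragment_length): p.height
        for p in profile.peaks
        if p.height / total >= threshold
    }
    if not kept:
        raise ValueError(f"{profile.sample_id}: all peaks below threshold {threshold}")
    kept_total = sum(kept.values())
    return {k: v / kept_total for k, v in kept.items()}


def bin_peaks(profiles: list, bin_width: float = 1.0, threshold: float = 0.005) -> OtuTable:
    """Bin thresholded peak profiles into a relative-mode OtuTable.

    Fragment lengths are binned into ``[k*bin_width, (k+1)*bin_width)``
    intervals within each (enzyme, dye) channel; OTU ids are ``enzyme-dye-bin``
    triples.  Each sample's heights are normalized per channel and the
    channels averaged with equal weight (composite fingerprint), so every
    row sums to 1.
    """
    if not profiles:
        raise ValueError("no peak profiles given")
    binned = []  # per sample: {(enzyme, dye, bin): height}
    for prof in profiles:
        rel = threshold_and_normalize(prof, threshold)
        acc = Counter()
        for (enzyme, dye, length), h in rel.items():
            # bins are [k*w, (k+1)*w); 100.3 and 100.6 share bin 100 at w=1
            b = np.floor(length / bin_width) * bin_width
            acc[(enzyme, dye, b)] += h
        binned.append(acc)

    channels = sorted({(e, d) for acc in binned for (e, d, _) in acc})
    otu_keys = sorted({k for acc in binned for k in acc})
    otu_ids = [f"{e}-{d}-{g:g}" for e, d, g in otu_keys]
    values = np.zeros((len(profiles), len(otu_keys)))
    for i, acc in enumerate(binned):
        present = {(e, d) for (e, d, _) in acc}
        for j, (e, d, g) in enumerate(otu_keys):
            if (e, d) not in present:
                continue
            chan_total = sum(h for (ee, dd, _), h in acc.items() if (ee, dd) == (e, d))
            values[i, j] = acc.get((e, d, g), 0.0) / chan_total / len(present)
    return OtuTable([p.sample_id for p in profiles], otu_ids, values, "relative")


def _identity(aligner: PairwiseAligner, a: str, b: str) -> float:
    """Matches / alignment length under global pairwise alignment."""
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return matches / len(s1)


def greedy_cluster(records, identity: float = 0.98) -> dict:
    """Abundance-sorted greedy incremental clustering of sequences.

    ``records`` is an iterable of Bio.SeqRecord (or a FASTA path).  Unique
    sequences are processed in order of decreasing abundance (duplicate
    count), ties broken by input order; each joins the first existing seed
    with global-alignment identity >= ``identity``, else founds a new OTU.
    Returns a mapping sequence id -> OTU id.
    """
    if isinstance(records, str):
        records = list(SeqIO.parse(records, "fasta"))
    else:
        records = list(records)
    if not records:
        raise ValueError("no sequences given")
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")

    by_seq: dict = {}
    for order, rec in enumerate(records):
        s = str(rec.seq).upper()
        by_seq.setdefault(s, {"ids": [], "order": order})["ids"].append(rec.id)
    uniques = sorted(by_seq.items(), key=lambda kv: (-len(kv[1]["ids"]), kv[1]["order"]))

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1

    seeds = []  # (sequence, otu_id)
    assignment = {}
    for seq, info in uniques:
        otu = None
        for seed_seq, seed_otu in seeds:
            if seq == seed_seq or _identity(aligner, seed_seq, seq) >= identity:
                otu = seed_otu
                break
        if otu is None:
            otu = f"OTU{len(seeds) + 1}"
            seeds.append((seq, otu))
        for rid in info["ids"]:
            assignment[rid] = otu
    return assignment
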