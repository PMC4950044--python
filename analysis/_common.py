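"""Shared configuration for the numbered analysis scripts.

Every script regenerates the same default transect survey (51 stations,
55S-64N, 7 depths, 300 OTUs, seed 1) so each can be run independently;
outputs go under results/analysis/.
"""

from pathlib import Path

from aoamacro.synthetic import SurveyConfig, build_metacommunity, simulate_survey

RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 1


def default_survey():
    cfg = SurveyConfig(seed=SEED)
    mc = build_metacommunity(cfg)
    counts, fingerprint, meta = simulate_survey(mc, cfg)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return cfg, mc, counts, fingerprint, meta
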