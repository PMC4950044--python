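"""End-to-end analysis pipeline: survey tables in, pattern statistics out.

``run_pipeline`` executes the full chain — simulate (or load) community
tables, alpha diversity, Bray-Curtis distances, distance-decay segments,
Rapoport range regressions, shared-OTU proportions, the hemisphere ANCOVA,
two-way ANOSIM, CCA and environment/space/time variation partitioning —
writing tidy TSVs with stable names, one machine-readable JSON summary, and
a run log (package version, seed, dropped samples).  All randomness flows
from the single config seed: the generator uses its own substreams and the
permutation tests use a child stream of the same seed.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import diversity_table
from .beta import bray_curtis, pcoa
from .community import anosim_twoway, cca, rda, variation_partitioning
from .macroecology import (
    abundance_class_ranges,
    decay_segments,
    diversity_gradient_ancova,
    otu_ranges,
    range_vs_latitude,
    reference_similarity_profile,
    shared_otus,
)
from .synthetic import SurveyConfig, build_metacommunity, simulate_survey
from .tables import (
    LAYER_NAMES,
    OtuTable,
    align_samples,
    read_metadata,
    read_otu_table,
    write_metadata,
    write_otu_table,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "alpha", "beta", "decay", "rapoport", "shared", "gradient",
    "anosim", "cca", "partition",
)

ENV_VARS = ("temperature_c", "salinity", "oxygen_umol_kg", "nitrite_umol_l",
            "thaum_16s_per_ml", "lac_hac_ratio")
SPACE_VARS = ("latitude", "abs_latitude", "depth_m")


@dataclass
class PipelineConfig:
    """One reproducible pipeline run.

    Exactly one of ``survey`` (a :class:`~aoamacro.synthetic.SurveyConfig`
    for simulated input) or ``input_paths`` (dict with keys ``counts`` and/or
    ``fingerprint`` plus ``metadata``) must be set.
    """

    survey: SurveyConfig = None
    input_paths: dict = None
    outdir: str = "results/pipeline"
    seed: int = 0
    stages: tuple = ALL_STAGES
    n_permutations: int = 999
    presence_threshold: float = 0.0
    low_cut: float = 0.005
    high_cut: float = 0.05

    def validate(self) -> None:
        if (self.survey is None) == (self.input_paths is None):
            raise ValueError("set exactly one of survey / input_paths")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


def _constraint_frame(meta: pd.DataFrame) -> pd.DataFrame:
    x = meta[list(ENV_VARS)].copy()
    x["thaum_16s_per_ml"] = np.log10(x["thaum_16s_per_ml"])
    x["latitude"] = meta["latitude"]
    x["depth_m"] = meta["depth_m"]
    return x


def _space_frame(meta: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "latitude": meta["latitude"],
            "abs_latitude": meta["latitude"].abs(),
            "depth_m": meta["depth_m"],
        }
    )


def _time_frame(meta: pd.DataFrame) -> pd.DataFrame:
    days = (
        pd.to_datetime(meta["date_iso"]) - pd.Timestamp("2010-01-01")
    ).dt.days.astype(float)
    return pd.DataFrame({"day_of_cruise": days})


def _round(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the JSON-ready summary dict.

    Outputs are written under ``config.outdir`` with stable names
    (``counts.tsv``, ``fingerprint.tsv``, ``metadata.tsv``,
    ``diversity.tsv``, ``bray_curtis_fingerprint.tsv``, per-stage TSVs,
    ``summary.json``, ``run.log``).  Any stage error removes the partial
    outputs and re-raises with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    handler.setLevel(logging.INFO)
    root = logging.getLogger("aoamacro")
    old_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def emit(name, writer):
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    summary = {"seed": config.seed, "version": __version__, "stages": list(config.stages)}
    logger.info("pipeline start: seed=%d python=%s numpy=%s aoamacro=%s",
                config.seed, platform.python_version(), np.__version__, __version__)
    stage = "input"
    try:
        # ---------------- input ----------------
        if config.survey is not None:
            meta_otus = build_metacommunity(config.survey)
            counts, fingerprint, meta = simulate_survey(meta_otus, config.survey)
            summary["input"] = {"kind": "synthetic", "n_otus": len(meta_otus),
                                "n_stations": config.survey.n_stations}
        else:
            paths = config.input_paths
            meta = read_metadata(paths["metadata"])
            counts = (
                read_otu_table(paths["counts"], "counts") if "counts" in paths else None
            )
            fingerprint = (
                read_otu_table(paths["fingerprint"], "relative")
                if "fingerprint" in paths else None
            )
            summary["input"] = {"kind": "files"}
        if fingerprint is None:
            fingerprint = counts.relative()
        emit("metadata.tsv", lambda p: write_metadata(meta, p))
        if counts is not None:
            emit("counts.tsv", lambda p: write_otu_table(counts, p))
        emit("fingerprint.tsv", lambda p: write_otu_table(fingerprint, p))

        fp_aligned, fp_meta = align_samples(fingerprint, meta)

        # ---------------- alpha ----------------
        if "alpha" in config.stages:
            stage = "alpha"
            div_source = counts if counts is not None else fingerprint
            div = diversity_table(div_source)
            emit("diversity.tsv", lambda p: div.to_csv(p, sep="\t", index=False))
            summary["alpha"] = {
                "mean_shannon": float(div["shannon_h"].mean()),
                "mean_simpson": float(div["simpson"].mean()),
                "mean_s_obs": float(div["s_obs"].mean()),
            }

        # ---------------- beta ----------------
        if "beta" in config.stages:
            stage = "beta"
            dmat = bray_curtis(fp_aligned)
            frame = pd.DataFrame(dmat.values, index=dmat.labels, columns=dmat.labels)
            emit("bray_curtis_fingerprint.tsv",
                 lambda p: frame.to_csv(p, sep="\t", index_label="sample_id"))
            ordn = pcoa(dmat)
            scores = pd.DataFrame(
                ordn.site_scores[:, :2], index=dmat.labels, columns=["PCo1", "PCo2"]
            )
            emit("pcoa_scores.tsv", lambda p: scores.to_csv(p, sep="\t", index_label="sample_id"))
            summary["beta"] = {
                "pcoa_prop_axis1": float(ordn.prop_explained[0]),
                "pcoa_prop_axis2": float(ordn.prop_explained[1]),
            }

        # ---------------- decay ----------------
        if "decay" in config.stages:
            stage = "decay"
            decay_rows, decay_summary = [], {}
            for layer in LAYER_NAMES:
                try:
                    south, trends_s = reference_similarity_profile(
                        fp_aligned, fp_meta, layer, "southernmost")
                    north, _ = reference_similarity_profile(
                        fp_aligned, fp_meta, layer, "northernmost")
                    fits = decay_segments(south, north)
                except ValueError as exc:
                    logger.info("decay: layer %s skipped (%s)", layer, exc)
                    continue
                decay_summary[layer] = {
                    seg: fit.to_dict() for seg, fit in fits.items()
                }
                decay_summary[layer]["similarity_trends_south_ref"] = trends_s
                for seg, fit in fits.items():
                    decay_rows.append({"layer": layer, "segment": seg, **fit.to_dict()})
            decay_df = pd.DataFrame(decay_rows)
            emit("decay_segments.tsv", lambda p: decay_df.to_csv(p, sep="\t", index=False))
            summary["decay"] = decay_summary

        # ---------------- rapoport ----------------
        if "rapoport" in config.stages:
            stage = "rapoport"
            per_otu, per_sample = otu_ranges(
                fp_aligned, fp_meta, "latitude", config.presence_threshold)
            emit("otu_ranges.tsv", lambda p: per_otu.to_csv(p, sep="\t", index=False))
            emit("stevens_ranges.tsv", lambda p: per_sample.to_csv(p, sep="\t", index=False))
            rap = {}
            for hemi in ("N", "S"):
                try:
                    rap[hemi] = range_vs_latitude(per_sample, fp_meta, hemi).to_dict()
                except ValueError as exc:
                    logger.info("rapoport: hemisphere %s skipped (%s)", hemi, exc)
            classes = abundance_class_ranges(
                fp_aligned, fp_meta, config.low_cut, config.high_cut)
            emit("abundance_class_ranges.tsv",
                 lambda p: classes.to_csv(p, sep="\t", index=False))
            rap["abundance_classes"] = {
                row["abundance_class"]: row["mean_range"]
                for _, row in classes.iterrows()
            }
            summary["rapoport"] = rap

        # ---------------- shared ----------------
        if "shared" in config.stages:
            stage = "shared"
            by_prov = shared_otus(fp_aligned, fp_meta, "province")
            by_layer = shared_otus(fp_aligned, fp_meta, "layer")
            emit("shared_otus_province.tsv", lambda p: by_prov.to_csv(p, sep="\t", index=False))
            emit("shared_otus_layer.tsv", lambda p: by_layer.to_csv(p, sep="\t", index=False))
            summary["shared"] = {
                "province_pairs": len(by_prov),
                "layer_pairs": len(by_layer),
            }

        # ---------------- gradient ----------------
        if "gradient" in config.stages:
            stage = "gradient"
            div_fp = diversity_table(fp_aligned)
            try:
                summary["gradient"] = diversity_gradient_ancova(div_fp, fp_meta)
            except ValueError as exc:
                logger.info("gradient skipped (%s)", exc)

        # ---------------- anosim ----------------
        if "anosim" in config.stages:
            stage = "anosim"
            dmat = bray_curtis(fp_aligned)
            res_p, res_l = anosim_twoway(
                dmat,
                fp_meta["province"].to_numpy(),
                fp_meta["layer"].to_numpy(),
                n_perm=config.n_permutations,
                seed=np.random.SeedSequence(config.seed, spawn_key=(10,)).generate_state(1)[0],
                names=("province", "layer"),
            )
            summary["anosim"] = {
                r.factor_name: {"R": r.R, "p_value": r.p_value,
                                "n_permutations": r.n_permutations}
                for r in (res_p, res_l)
            }

        # ---------------- cca ----------------
        if "cca" in config.stages:
            stage = "cca"
            nonzero = fp_aligned.values.sum(axis=0) > 0
            yv = fp_aligned.values[:, nonzero]
            res = cca(
                OtuTable(fp_aligned.sample_ids,
                         [o for o, k in zip(fp_aligned.otu_ids, nonzero) if k],
                         yv, "relative"),
                _constraint_frame(fp_meta),
            )
            prop = res.extras["prop_explained_constrained"]
            summary["cca"] = {
                "total_inertia": res.extras["total_inertia"],
                "constrained_inertia": res.extras["constrained_inertia"],
                "prop_axis12_of_constrained": float(prop[:2].sum()) if len(prop) >= 2 else None,
                "prop_axis12_of_total": float(res.prop_explained[:2].sum()),
            }

        # ---------------- partition ----------------
        if "partition" in config.stages:
            stage = "partition"
            part = variation_partitioning(
                fp_aligned.values,
                _constraint_frame(fp_meta)[list(ENV_VARS)],
                _space_frame(fp_meta),
                _time_frame(fp_meta),
            )
            summary["partition"] = {
                "fractions": part.fractions,
                "residual": part.residual,
                "total_explained": part.total_explained,
                "negative_flagged": part.negative_flagged,
            }

        stage = "summary"
        payload = json.dumps(_round(summary), indent=2, sort_keys=True)
        (outdir / "summary.json").write_text(payload + "\n")
        written.append(outdir / "summary.json")
        logger.info("pipeline done: %d files written", len(written))
        return summary
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
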