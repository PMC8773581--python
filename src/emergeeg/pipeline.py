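"""End-to-end study replica on a synthetic cohort.

``run_study`` orchestrates: cohort simulation -> per-subject trends (DSA,
band power, permutation entropy, depth index) -> paired LOR statistics ->
emergence AUC maps between groups -> paired ROR statistics per group ->
index-above-threshold durations with Kruskal-Wallis/Dunn -> demographics
exact tests -> manifest.  Stage outputs are files so any stage can be
re-inspected in isolation; one master seed governs every stochastic stage
and re-running with the same config reproduces every table bit-identically.

All relative-time coordinates are seconds, event-anchored, negative before
the event (ROR at 0 in emergence outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as recio
from .depthindex import DEFAULT_INDEX_MAPPING, IndexMapping, index_trend
from .groupcompare import (
    DEFAULT_CLUSTER_MIN,
    DEFAULT_NEIGHBOR_MIN,
    align_to_event,
    auc_map,
    duration_above,
    freeman_halton,
    kruskal_dunn,
)
from .ordent import OrdinalConfig, peen_trend
from .spectral import Spectrogram, band_power, dsa
from .synthcohort import CohortConfig, simulate_cohort
from .transitionstats import (
    auc_two_sample,
    bootstrap_ci,
    build_paired_set,
    paired_test,
    results_table,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunConfig", "run_study", "read_recording"]

read_recording = recio.read_recording  # re-exported pipeline entry point

# Worked-example demographic tables (2 x 3 counts across the three groups)
# used as the default input of the demographics stage.
DEFAULT_DEMOGRAPHICS = {
    "sex_m_f": [[7, 9, 11], [8, 6, 4]],
    "asa_i_ii": [[10, 8, 10], [5, 7, 5]],
}


@dataclass
class AnalysisConfig:
    window_s: float = 10.0
    hop_s: float = 1.0
    pre_offset_s: float = -15.0
    post_offset_s: float = 30.0
    reporting_band: tuple[float, float] = (6.0, 30.0)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    span_s: float = 600.0
    n_boot_scalar: int = 10000
    n_boot_map: int = 1000
    cluster_min: int = DEFAULT_CLUSTER_MIN
    neighbor_min: int = DEFAULT_NEIGHBOR_MIN
    index_threshold: float = 80.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("reporting_band", "alpha_band", "beta_band"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d) -> "AnalysisConfig":
        d = dict(d)
        for key in ("reporting_band", "alpha_band", "beta_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "study_out"
    seed: int = 0
    log_level: str = "INFO"
    write_recordings: bool = False
    demographics: dict = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "analysis": self.analysis.to_dict(),
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "write_recordings": self.write_recordings,
            "demographics": {k: [list(r) for r in v] for k, v in self.demographics.items()},
        }

    @classmethod
    def from_dict(cls, d) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "analysis" in d:
            d["analysis"] = AnalysisConfig.from_dict(d["analysis"])
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _reporting_spec(spec: Spectrogram, band) -> Spectrogram:
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    return Spectrogram(
        spec.times, spec.freqs[sel], spec.power[:, sel],
        spec.window_s, spec.hop_s, spec.normalized, spec.norm_band,
    )


def _stage_seed(master: int, stage: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return np.random.default_rng(np.random.SeedSequence(
        int.from_bytes(digest[:8], "little")
    ))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig) -> dict:
    """Run the full synthetic study; returns a result dict with file paths."""
    config.cohort.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cohort_cfg = config.cohort.replace(seed=config.seed)
    ana = config.analysis
    outputs: dict[str, Path] = {}
    results: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    # stage 1: cohorts -------------------------------------------------------
    logger.info("stage simulate: %d subjects/group x %d groups",
                cohort_cfg.n_per_group, len(cohort_cfg.group_labels))
    emergence = simulate_cohort(cohort_cfg, phase="emergence")
    induction = simulate_cohort(cohort_cfg, phase="induction")
    outputs["manifest_emergence"] = recio.write_manifest(emergence, out / "cohort_emergence.csv")
    outputs["manifest_induction"] = recio.write_manifest(induction, out / "cohort_induction.csv")
    if config.write_recordings:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in emergence + induction:
            phase = "emergence" if "ROR" in rec.events else "induction"
            recio.write_csv(rec, rec_dir / f"{rec.subject_id}_{phase}.csv")

    # stage 2: per-subject trends -------------------------------------------
    logger.info("stage trends")
    trend_dir = out / "trends"
    trend_dir.mkdir(exist_ok=True)
    emg_specs: dict[str, list] = {}
    emg_index: dict[str, object] = {}
    emg_peen: dict[str, object] = {}
    ror_times: dict[str, float] = {}
    for rec in emergence:
        spec = dsa(rec, ana.window_s, ana.hop_s)
        rep = _reporting_spec(spec, ana.reporting_band)
        emg_specs.setdefault(rec.group, []).append((rec.subject_id, rep))
        it = index_trend(rec, window_s=ana.window_s, hop_s=ana.hop_s)
        pt = peen_trend(rec, OrdinalConfig(), ana.window_s, ana.hop_s)
        emg_index[rec.subject_id] = it
        emg_peen[rec.subject_id] = pt
        ror_times[rec.subject_id] = rec.events["ROR"]
        frame = it.to_frame()
        frame["peen_bits"] = pt.values
        for band, name in ((ana.alpha_band, "alpha_power"), (ana.beta_band, "beta_power")):
            frame[name] = band_power(rep, band).values
        frame.to_csv(trend_dir / f"{rec.subject_id}_emergence.csv", index=False)

    ind_index: dict[str, object] = {}
    ind_peen: dict[str, object] = {}
    ind_groups: dict[str, str] = {}
    lor_times: dict[str, float] = {}
    for rec in induction:
        it = index_trend(rec, window_s=ana.window_s, hop_s=ana.hop_s)
        pt = peen_trend(rec, OrdinalConfig(), ana.window_s, ana.hop_s)
        ind_index[rec.subject_id] = it.as_param_trend()
        ind_peen[rec.subject_id] = pt
        ind_groups[rec.subject_id] = rec.group
        lor_times[rec.subject_id] = rec.events["LOR"]
        frame = it.to_frame()
        frame["peen_bits"] = pt.values
        frame.to_csv(trend_dir / f"{rec.subject_id}_induction.csv", index=False)

    # stage 3: paired LOR statistics (all subjects pooled) -------------------
    logger.info("stage LOR paired statistics")
    paired_results = []
    rng = _stage_seed(config.seed, "lor")
    for name, trends in (("peen_bits", ind_peen), ("csi_like", ind_index)):
        pairs = build_paired_set(
            trends, lor_times, "LOR", name,
            ana.pre_offset_s, ana.post_offset_s,
        )
        paired_results.append(paired_test(pairs, n_boot=ana.n_boot_scalar, seed=rng))

    # stage 4: paired ROR statistics per group -------------------------------
    logger.info("stage ROR paired statistics")
    rng = _stage_seed(config.seed, "ror")
    for group in cohort_cfg.group_labels:
        sel_ids = [r.subject_id for r in emergence if r.group == group]
        for name, trends in (
            ("peen_bits", {s: emg_peen[s] for s in sel_ids}),
            ("csi_like", {s: emg_index[s].as_param_trend() for s in sel_ids}),
        ):
            pairs = build_paired_set(
                trends, {s: ror_times[s] for s in sel_ids}, "ROR", name,
                ana.pre_offset_s, ana.post_offset_s, group=group,
            )
            paired_results.append(paired_test(pairs, n_boot=ana.n_boot_scalar, seed=rng))
    table = results_table(paired_results)
    outputs["paired_stats"] = out / "paired_stats.csv"
    table.to_csv(outputs["paired_stats"], index=False)

    # stage 5: emergence AUC maps -------------------------------------------
    logger.info("stage AUC maps")
    aligned: dict[str, list] = {}
    for group, pairs_list in emg_specs.items():
        for sid, spec in pairs_list:
            try:
                aligned.setdefault(group, []).append(
                    align_to_event(spec, ror_times[sid], ana.span_s)
                )
            except ValueError as exc:
                logger.info("dropped %s from AUC map: %s", sid, exc)
    rng = _stage_seed(config.seed, "maps")
    comparisons = [
        ("isoflurane", "propofol"),
        ("sevoflurane", "propofol"),
        ("isoflurane", "sevoflurane"),
    ]
    map_summary = []
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for ga, gb in comparisons:
        if ga not in aligned or gb not in aligned:
            continue
        m = auc_map(
            aligned[ga], aligned[gb],
            n_boot=ana.n_boot_map, seed=rng,
            cluster_min=ana.cluster_min, labels=(ga, gb),
        )
        stem = f"aucmap_{ga}_vs_{gb}"
        path = out / f"{stem}.csv"
        m.to_csv(path)
        outputs[stem] = path
        map_summary.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_sig_pixels": int(m.sig_mask.sum()),
                "n_cluster_pixels": int(m.cluster_mask.sum()),
                "n_clusters": m.n_clusters,
                "significant_clusters": bool(m.cluster_mask.any()),
            }
        )
        from .plotting import plot_auc_map

        ax = plot_auc_map(m)
        ax.figure.savefig(fig_dir / f"{stem}.png", dpi=120)
        import matplotlib.pyplot as plt

        plt.close(ax.figure)
    outputs["map_summary"] = out / "aucmap_summary.csv"
    pd.DataFrame(map_summary).to_csv(outputs["map_summary"], index=False)

    # stage 6: index-above-threshold durations ------------------------------
    logger.info("stage durations")
    dur_rows = []
    for rec in emergence:
        d = duration_above(
            emg_index[rec.subject_id], ror_times[rec.subject_id],
            threshold=ana.index_threshold,
            subject_id=rec.subject_id, group=rec.group,
        )
        dur_rows.append(
            {
                "subject_id": d.subject_id,
                "group": d.group,
                "duration_s": d.duration_s,
                "at_ror_below": int(d.at_ror_below),
            }
        )
    durations = pd.DataFrame(dur_rows)
    outputs["durations"] = out / "durations.csv"
    durations.to_csv(outputs["durations"], index=False)
    groups = [
        durations.loc[durations.group == g, "duration_s"].to_numpy()
        for g in cohort_cfg.group_labels
    ]
    kd = kruskal_dunn(groups, labels=list(cohort_cfg.group_labels))
    outputs["duration_tests"] = out / "duration_tests.csv"
    kd.to_frame().to_csv(outputs["duration_tests"], index=False)
    rng = _stage_seed(config.seed, "durations")
    dur_auc = {}
    for ga, gb in (("isoflurane", "propofol"), ("sevoflurane", "propofol")):
        a = durations.loc[durations.group == ga, "duration_s"].to_numpy()
        b = durations.loc[durations.group == gb, "duration_s"].to_numpy()
        if len(a) and len(b):
            val = auc_two_sample(b, a)  # P(volatile duration > propofol duration)
            ci = bootstrap_ci(
                lambda x, y: auc_two_sample(x, y), (b, a),
                n_boot=ana.n_boot_scalar, seed=rng,
            )
            dur_auc[f"{ga}_vs_{gb}"] = {"auc": val, "ci": list(ci)}
    results["duration_auc"] = dur_auc

    from .plotting import plot_duration_box

    ax = plot_duration_box(durations, threshold=ana.index_threshold)
    ax.figure.savefig(fig_dir / "durations.png", dpi=120)
    import matplotlib.pyplot as plt

    plt.close(ax.figure)

    # stage 7: demographics --------------------------------------------------
    logger.info("stage demographics")
    demo_rows = [
        {"table": name, "p_exact": freeman_halton(np.asarray(tab))}
        for name, tab in config.demographics.items()
    ]
    outputs["demographics"] = out / "demographics.csv"
    pd.DataFrame(demo_rows).to_csv(outputs["demographics"], index=False)

    # stage 8: manifest ------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in outputs.items()},
        "paired_results_n": len(paired_results),
        "map_summary": map_summary,
        "duration_auc": dur_auc,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["outputs"] = outputs
    results["manifest"] = manifest
    results["paired_table"] = table
    results["durations"] = durations
    results["kruskal_dunn"] = kd
    return results
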