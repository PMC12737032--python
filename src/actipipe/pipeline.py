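"""End-to-end study orchestration.

``run_study`` takes a cohort (a directory of raw CSVs or a synthetic
cohort spec), computes every requested activity series per recording,
derives circadian indicators and sleep scores from each, and assembles
the cross-pipeline similarity matrices and dendrograms, together with a
manifest that records all parameters for replayability. Identical
config + seed yields an identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .compare import (SimilarityMatrix, dendrogram, iou_matrix,
                      overlap_matrix, smape_matrix, to_newick)
from .core import (ActivitySeries, ConfigurationError, TriaxialRecording)
from .devices import DEVICE_SUITE_LABELS, device_suite
from .io import read_raw, regularize_timestamps
from .metrics import (MethodCombo, THRESHOLD_METRICS, ThresholdSpec,
                      compute_activity, pooled_sd_from_moments,
                      valid_combinations)
from .npcra import npcra_from_signal
from .preprocess import axis_bundle, preprocess
from .sleep import masda_score, total_sleep_time, vanhees_score
from .synth import SyntheticConfig, cohort_configs, generate_recording

logger = logging.getLogger("actipipe")

SCALAR_INDICATORS = ("L5_value", "M10_value", "RA", "IS", "IV")
VANHEES_LABEL = "vanHees(UFXYZ)"


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    synthetic: Optional[SyntheticConfig] = None
    n_subjects: int = 1
    raw_dir: Optional[str] = None
    pipelines: Sequence[str] = ("device_suite",)
    epoch_length: int = 60
    normalize: bool = True
    threshold_basis: str = "pooled"
    masda_threshold_frac: float = 0.25
    masda_gap_min: float = 30.0
    masda_bout_min: float = 30.0
    spt_threshold: float = 0.4
    run_sleep: bool = True
    outdir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.raw_dir is None):
            raise ConfigurationError(
                "exactly one input source (synthetic or raw_dir) is required")
        if not self.pipelines:
            raise ConfigurationError("at least one pipeline must be selected")
        if self.threshold_basis not in ("pooled", "per_recording"):
            raise ConfigurationError("threshold_basis must be pooled or per_recording")
        known = {"device_suite"} | {c.label for c in valid_combinations()}
        unknown = [p for p in self.pipelines if p not in known]
        if unknown:
            raise ConfigurationError(f"unknown pipeline(s): {unknown}")


@dataclass
class StudyResults:
    indicator_tables: Dict[str, pd.DataFrame]
    window_tables: Dict[str, pd.DataFrame]
    sleep_segments: Optional[pd.DataFrame]
    tst_table: Optional[pd.DataFrame]
    matrices: Dict[str, SimilarityMatrix]
    linkages: Dict[str, np.ndarray]
    newicks: Dict[str, str]
    manifest: dict
    failures: List[Tuple[str, str]] = field(default_factory=list)


def _combo_labels(config: StudyConfig) -> List[str]:
    labels: List[str] = []
    for p in config.pipelines:
        if p == "device_suite":
            labels.extend(DEVICE_SUITE_LABELS)
        else:
            labels.append(p)
    # stable de-duplication
    seen = set()
    return [x for x in labels if not (x in seen or seen.add(x))]


def _generalized_labels(config: StudyConfig) -> List[str]:
    return [p for p in config.pipelines if p != "device_suite"]


def _subject_sources(config: StudyConfig):
    """(subject_id, loader) pairs; loaders regenerate/reread on call so
    only one recording is held in memory at a time."""
    if config.synthetic is not None:
        cfgs = cohort_configs(config.synthetic, config.n_subjects, config.seed)
        return [(c.subject_id,
                 (lambda c=c: generate_recording(c)[0])) for c in cfgs]
    paths = sorted(Path(config.raw_dir).glob("*.csv"))
    if not paths:
        raise ConfigurationError(f"no raw CSV files in {config.raw_dir}")

    def _load(path=None):
        rec = read_raw(path)
        rec, _ = regularize_timestamps(rec)
        return rec

    return [(p.stem, (lambda p=p: _load(p))) for p in paths]


def _threshold_schemes(config: StudyConfig) -> List[str]:
    """Preprocessing schemes whose SD threshold must be pooled."""
    schemes = set()
    if "device_suite" in config.pipelines:
        schemes.add("FMpre")
    for label in _generalized_labels(config):
        combo = _parse_combo(label)
        if combo.metric in THRESHOLD_METRICS:
            schemes.add(combo.scheme)
    return sorted(schemes)


def _parse_combo(label: str) -> MethodCombo:
    metric, _, rest = label.partition("(")
    return MethodCombo(metric, rest.rstrip(")"))


def _pooled_thresholds(config: StudyConfig, sources) -> Dict[str, ThresholdSpec]:
    schemes = _threshold_schemes(config)
    if not schemes or config.threshold_basis != "pooled":
        return {}
    moments = {s: [0, 0.0, 0.0] for s in schemes}
    for _, loader in sources:
        rec = loader()
        for s in schemes:
            v = preprocess(rec, s).values
            moments[s][0] += v.size
            moments[s][1] += float(v.sum())
            moments[s][2] += float((v * v).sum())
    out = {}
    for s, (n, tot, tot_sq) in moments.items():
        sd = pooled_sd_from_moments(n, tot, tot_sq)
        level = 1.0 + sd if s == "UFM" else sd
        out[s] = ThresholdSpec(level=level, basis="pooled", scheme=s)
    return out


def _compute_combo(rec: TriaxialRecording, combo: MethodCombo,
                   epoch_length: int, thresholds: Dict[str, ThresholdSpec],
                   cache: dict) -> ActivitySeries:
    if combo.metric == "AI":
        key = ("bundle", combo.scheme)
        if key not in cache:
            cache[key] = axis_bundle(rec, filtered=combo.scheme == "FXYZ")
        return compute_activity(cache[key], "AI", epoch_length)
    key = ("sig", combo.scheme)
    if key not in cache:
        cache[key] = preprocess(rec, combo.scheme)
    sig = cache[key]
    thr = None
    if combo.metric in THRESHOLD_METRICS:
        thr = thresholds.get(combo.scheme)
        if thr is None:
            from .metrics import compute_threshold
            thr = compute_threshold(sig, basis="per_recording")
            thresholds[combo.scheme] = thr  # per-recording cache
    return compute_activity(sig, combo.metric, epoch_length, threshold=thr)


def run_study(config: StudyConfig) -> StudyResults:
    """Run the full study described by ``config``; see module docstring."""
    config.validate()
    sources = _subject_sources(config)
    if not sources:
        raise ConfigurationError("empty cohort")
    pooled = _pooled_thresholds(config, sources)
    labels = _combo_labels(config)

    npcra_rows: Dict[str, dict] = {}
    window_rows: Dict[str, dict] = {}
    sleep_rows: Dict[str, dict] = {}
    tst_rows: Dict[str, dict] = {}
    failures: List[Tuple[str, str]] = []

    for subject_id, loader in sources:
        try:
            rec = loader()
            cache: dict = {}
            per_rec_thresholds = dict(pooled)
            series: List[ActivitySeries] = []
            for label in labels:
                if label in DEVICE_SUITE_LABELS and "device_suite" in config.pipelines:
                    if not any(s.method == label for s in series):
                        series.extend(device_suite(
                            rec, config.epoch_length,
                            fmpre_threshold=pooled.get("FMpre")))
                else:
                    series.append(_compute_combo(
                        rec, _parse_combo(label), config.epoch_length,
                        per_rec_thresholds, cache))
            # de-duplicate while preserving the requested label order
            by_label = {s.method: s for s in series}
            series = [by_label[lab] for lab in labels]

            nrow, wrow = {}, {}
            for s in series:
                res = npcra_from_signal(s, normalize=config.normalize)
                nrow[s.method] = res
                wrow[s.method] = (res.l5, res.m10)
            npcra_rows[subject_id] = nrow
            window_rows[subject_id] = wrow

            if config.run_sleep:
                srow, trow = {}, {}
                for s in series:
                    score = masda_score(
                        s, threshold_frac=config.masda_threshold_frac,
                        gap_min=config.masda_gap_min,
                        bout_min=config.masda_bout_min)
                    srow[s.method] = score.segments
                    trow[s.method] = total_sleep_time(score)
                vh = vanhees_score(rec, spt_threshold=config.spt_threshold)
                srow[VANHEES_LABEL] = vh.segments
                trow[VANHEES_LABEL] = total_sleep_time(vh)
                sleep_rows[subject_id] = srow
                tst_rows[subject_id] = trow
        except Exception as exc:  # noqa: BLE001 - per-recording isolation
            logger.warning("subject %s failed: %s", subject_id, exc)
            failures.append((subject_id, str(exc)))

    if not npcra_rows:
        raise ConfigurationError("every recording failed; nothing to compare")

    subjects = list(npcra_rows)
    indicator_tables = {}
    getters = {
        "L5_value": lambda r: r.l5.mean_value,
        "M10_value": lambda r: r.m10.mean_value,
        "RA": lambda r: r.ra,
        "IS": lambda r: r.is_,
        "IV": lambda r: r.iv,
    }
    for ind, get in getters.items():
        indicator_tables[ind] = pd.DataFrame(
            {lab: [get(npcra_rows[s][lab]) for s in subjects]
             for lab in labels}, index=subjects)
    window_tables = {
        "L5_window": pd.DataFrame(
            {lab: [window_rows[s][lab][0] for s in subjects]
             for lab in labels}, index=subjects),
        "M10_window": pd.DataFrame(
            {lab: [window_rows[s][lab][1] for s in subjects]
             for lab in labels}, index=subjects),
    }

    matrices: Dict[str, SimilarityMatrix] = {}
    for ind in SCALAR_INDICATORS:
        matrices[f"smape_{ind}"] = smape_matrix(indicator_tables[ind])
    matrices["overlap_L5"] = overlap_matrix(window_tables["L5_window"], 5)
    matrices["overlap_M10"] = overlap_matrix(window_tables["M10_window"], 10)

    sleep_segments = tst_table = None
    if config.run_sleep and sleep_rows:
        sleep_labels = labels + [VANHEES_LABEL]
        sleep_segments = pd.DataFrame(
            {lab: [sleep_rows[s][lab] for s in subjects]
             for lab in sleep_labels}, index=subjects)
        tst_table = pd.DataFrame(
            {lab: [tst_rows[s][lab] for s in subjects]
             for lab in sleep_labels}, index=subjects)
        matrices["iou_sleep"] = iou_matrix(sleep_segments)

    linkages, newicks = {}, {}
    if len(labels) >= 2:
        for name, m in matrices.items():
            z, labs = dendrogram(m)
            linkages[name] = z
            newicks[name] = to_newick(z, labs)

    manifest = {
        "package": "actipipe",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "pipelines": labels,
        "subjects": subjects,
        "n_failed": len(failures),
        "failures": failures,
        "pooled_thresholds": {s: t.level for s, t in pooled.items()},
    }
    results = StudyResults(
        indicator_tables=indicator_tables,
        window_tables=window_tables,
        sleep_segments=sleep_segments,
        tst_table=tst_table,
        matrices=matrices,
        linkages=linkages,
        newicks=newicks,
        manifest=manifest,
        failures=failures,
    )
    if config.outdir:
        write_results(results, npcra_rows, config.outdir)
    return results


def _config_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # run-local, not part of the scientific config
    return d


def write_results(results: StudyResults, npcra_rows: Dict[str, dict],
                  outdir) -> None:
    """Write the bundle as open CSV/JSON/Newick files."""
    out = Path(outdir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    (out / "dendrograms").mkdir(parents=True, exist_ok=True)
    for name, m in results.matrices.items():
        m.to_frame().to_csv(out / "matrices" / f"{name}.csv")
    for name, nwk in results.newicks.items():
        (out / "dendrograms" / f"{name}.nwk").write_text(nwk + "\n")
    npcra_json = {
        s: {lab: res.to_dict() for lab, res in row.items()}
        for s, row in npcra_rows.items()}
    (out / "npcra.json").write_text(
        json.dumps(npcra_json, indent=1, sort_keys=True))
    if results.sleep_segments is not None:
        sleep_json = {
            s: {lab: [[int(a), int(b)] for a, b in
                      results.sleep_segments.loc[s, lab]]
                for lab in results.sleep_segments.columns}
            for s in results.sleep_segments.index}
        (out / "sleep.json").write_text(
            json.dumps(sleep_json, indent=1, sort_keys=True))
        results.tst_table.to_csv(out / "tst_hours.csv")
    (out / "manifest.json").write_text(
        json.dumps(results.manifest, indent=1, sort_keys=True, default=str))
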