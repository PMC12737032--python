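"""Shared fixtures.

The session-scoped cohort fixture runs the expensive synthetic-cohort
computations once (10 subjects x 4 days, a scaled-down analogue of a
42-subject, 10-day study) and keeps only the small per-subject products
(activity series, circadian indicators, sleep segments, ground truth),
never all raw recordings at once.
"""

from __future__ import annotations

import numpy as np
import pytest

import actipipe as ap
from actipipe.metrics import ThresholdSpec, pooled_sd_from_moments

COHORT_SEED = 7
N_SUBJECTS = 10
N_DAYS = 4


def make_constant_recording(xyz, n_seconds=120, rate=10.0, start_ms=0):
    """Recording holding one constant acceleration vector."""
    n = int(n_seconds * rate)
    ts = start_ms + np.round(np.arange(n) * 1000.0 / rate).astype(np.int64)
    x, y, z = (np.full(n, float(v)) for v in xyz)
    return ap.TriaxialRecording("const", ts, x, y, z, nominal_rate=rate)


@pytest.fixture(scope="session")
def base_config():
    return ap.SyntheticConfig(n_days=N_DAYS)


@pytest.fixture(scope="session")
def rec_and_truth():
    """One 2-day synthetic recording plus truth, reused across modules."""
    return ap.generate_recording(ap.SyntheticConfig(n_days=2, seed=1))


@pytest.fixture(scope="session")
def cohort_products(base_config):
    """Per-subject products of the device-suite pipeline on a synthetic
    cohort, with the ZCM/TAT threshold pooled across subjects."""
    configs = ap.cohort_configs(base_config, N_SUBJECTS, COHORT_SEED)

    # pass 1: pooled FMpre SD for the intersection threshold
    n_tot, s_tot, sq_tot = 0, 0.0, 0.0
    for cfg in configs:
        rec, _ = ap.generate_recording(cfg)
        v = ap.preprocess(rec, "FMpre").values
        n_tot += v.size
        s_tot += float(v.sum())
        sq_tot += float((v * v).sum())
    thr = ThresholdSpec(level=pooled_sd_from_moments(n_tot, s_tot, sq_tot),
                        basis="pooled", scheme="FMpre")

    products = []
    for cfg in configs:
        rec, truth = ap.generate_recording(cfg)
        series = {s.method: s
                  for s in ap.device_suite(rec, fmpre_threshold=thr)}
        npcra = {m: ap.npcra_from_signal(s) for m, s in series.items()}
        accel_enmo = ap.npcra_from_signal(ap.preprocess(rec, "ENMO"))
        masda = {m: ap.masda_score(s) for m, s in series.items()}
        vanhees = ap.vanhees_score(rec)
        products.append({
            "subject": cfg.subject_id,
            "truth": truth,
            "series": series,
            "npcra": npcra,
            "npcra_accel_enmo": accel_enmo,
            "masda": masda,
            "vanhees": vanhees,
        })
    return products
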