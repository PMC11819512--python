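"""Shared fixtures: constructed trains and a session-scoped synthetic benchmark."""

from __future__ import annotations

import numpy as np
import pytest

import nbhfsocial as nh


def train_from_times(times_s, freq=125.0, train_id="t", site="S"):
    """Build a train from explicit click times (seconds)."""
    return nh.ClickTrain(
        id=train_id,
        clicks=[nh.Click(time=float(t), freq=freq) for t in times_s],
        site=site,
    )


def train_from_rates(rates_cs, start=0.0, freq=125.0, train_id="t", site="S"):
    """Build a train whose instantaneous rates are exactly ``rates_cs``.

    Click i+1 follows click i after 1/rates_cs[i] seconds, so the profile's
    instantaneous rates reproduce the input.
    """
    times = [start]
    for r in rates_cs:
        times.append(times[-1] + 1.0 / float(r))
    return train_from_times(times, freq=freq, train_id=train_id, site=site)


@pytest.fixture(scope="session")
def benchmark90():
    """Default seeded 90-day benchmark: deployment, truth, and classifications."""
    cfg = nh.ScenarioConfig(seed=1, duration_days=90)
    trains, truth = nh.generate_deployment(cfg)
    duration_s = cfg.duration_days * 86400.0
    classified = nh.classify_deployment(trains, duration_s, nh.FilterConfig(), nh.SocialCriteria())
    return cfg, trains, truth, classified


@pytest.fixture(scope="session")
def easy5():
    """Well-separated 5-day scenario with its classifications."""
    cfg = nh.easy_scenario(seed=2, duration_days=5)
    trains, truth = nh.generate_deployment(cfg)
    classified = nh.classify_deployment(
        trains, cfg.duration_days * 86400.0, nh.FilterConfig(), nh.SocialCriteria()
    )
    return cfg, trains, truth, classified


def precision_recall(truth, classified):
    true_social = {r.train_id for r in truth if r.true_class == "social"}
    pred_social = {r.train_id for r in classified if r.decision == "social"}
    tp = len(true_social & pred_social)
    fp = len(pred_social - true_social)
    fn = len(true_social - pred_social)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall
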