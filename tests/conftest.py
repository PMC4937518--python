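"""Shared fixtures: the worked micro example and small synthetic datasets."""

from __future__ import annotations

import pytest

from xlpcp import profile_io
from xlpcp import peaks as peaks_mod
from xlpcp.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_worked_micro_example,
)


@pytest.fixture(scope="session")
def micro():
    return generate_worked_micro_example()


@pytest.fixture(scope="session")
def micro_means(micro):
    return sorted(
        profile_io.build_mean_profiles(micro.profiles), key=lambda m: m.group_id
    )


def extract_and_filter(micro, means):
    """Mean-profile peaks + per-replicate peaks of the micro example."""
    mw = {g.group_id: g.monomer_mw_kda for g in micro.groups}
    mean_peaks = []
    for mp in means:
        raw = peaks_mod.extract_peaks(
            mp, range(2, 9), micro.calibration, mw[mp.group_id]
        )
        mean_peaks += peaks_mod.filter_peaks(
            raw, float(mp.mean.max()), micro.calibration
        )
    rep_peaks = {}
    for rp in micro.profiles:
        pr = profile_io.process_replicate(rp)
        raw = peaks_mod.extract_peaks(
            pr, range(2, 9), micro.calibration, mw[rp.group_id],
            source=f"rep{rp.replicate_index}",
        )
        kept = peaks_mod.filter_peaks(
            raw, float(pr.intensities.max()), micro.calibration
        )
        rep_peaks.setdefault(rp.group_id, {})[rp.replicate_index] = kept
    return mean_peaks, rep_peaks


@pytest.fixture(scope="session")
def micro_peaks(micro, micro_means):
    return extract_and_filter(micro, micro_means)


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down study: 8 planted complexes, mild noise."""
    return generate_dataset(
        SyntheticConfig(seed=7, n_complexes=8, n_singletons=15)
    )


@pytest.fixture(scope="session")
def noiseless_config():
    """The noiseless channel: pure co-elution signal, no nuisance peaks."""
    return SyntheticConfig(
        seed=11,
        n_complexes=8,
        n_singletons=10,
        noise_cv=0.0,
        additive_noise_floor=0.0,
        apex_jitter_sd=0.0,
        dropout_prob=0.0,
        monomer_peak_prob=0.0,
        singleton_decoy_peak_prob=0.0,
        membrane_fraction=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate_dataset(noiseless_config)
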