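"""Table parsing, detection filters, smoothing/normalization, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlpcp import profile_io
from xlpcp.profile_io import (
    CalibrationError,
    InputError,
    ProteinGroup,
    ReplicateProfile,
    SchemaError,
    TableSchema,
    build_mean_profile,
    build_mean_profiles,
    fit_calibration,
    fraction_to_mw,
    minmax_normalize,
    qc_filter,
    read_protein_groups,
    smooth,
)
from xlpcp.synthetic import SyntheticConfig, generate_dataset, write_dataset


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_table(tmp_path_factory):
    ds = generate_dataset(
        SyntheticConfig(seed=3, n_complexes=1, complex_sizes=(3,), n_singletons=0,
                        dropout_prob=0.0)
    )
    out = tmp_path_factory.mktemp("tiny")
    paths = write_dataset(ds, out)
    return ds, paths


def test_read_counts_one_group_per_row_one_profile_per_replicate(tiny_table):
    ds, paths = tiny_table
    groups, profiles = read_protein_groups(
        paths["protein_groups"], condition="crosslinked"
    )
    assert len(groups) == 3
    assert len(profiles) == 9  # 3 rows x 3 replicates
    assert all(len(p.intensities) == 48 for p in profiles)
    groups_n, profiles_n = read_protein_groups(
        paths["protein_groups"], condition="native"
    )
    assert all(len(p.intensities) == 40 for p in profiles_n)


def test_read_round_trips_generator_values(tiny_table):
    ds, paths = tiny_table
    _, profiles = read_protein_groups(paths["protein_groups"], condition="crosslinked")
    by_key = {(p.group_id, p.replicate_index): p for p in profiles}
    for p in ds.profiles:
        if p.condition != "crosslinked":
            continue
        got = by_key[(p.group_id, p.replicate_index)]
        assert np.allclose(got.intensities, p.intensities, rtol=1e-6, atol=0.05)


def test_empty_and_unparseable_intensity_cells_become_zero(tmp_path, tiny_table):
    ds, paths = tiny_table
    import pandas as pd

    table = pd.read_csv(paths["protein_groups"], sep="\t", dtype=str)
    col = ds.schema.lfq_col("crosslinked", 1, 5)
    table.loc[0, col] = ""
    table.loc[1, col] = "not-a-number"
    path = tmp_path / "edited.tsv"
    table.to_csv(path, sep="\t", index=False)
    _, profiles = read_protein_groups(path, condition="crosslinked")
    by_key = {(p.group_id, p.replicate_index): p for p in profiles}
    gids = list(table[ds.schema.id_col])
    assert by_key[(gids[0], 1)].intensities[4] == 0.0
    assert by_key[(gids[1], 1)].intensities[4] == 0.0


def test_missing_mw_column_is_schema_error(tmp_path, tiny_table):
    ds, paths = tiny_table
    import pandas as pd

    table = pd.read_csv(paths["protein_groups"], sep="\t", dtype=str)
    table = table.drop(columns=[ds.schema.mw_col])
    path = tmp_path / "no_mw.tsv"
    table.to_csv(path, sep="\t", index=False)
    with pytest.raises(SchemaError, match="Mol. weight"):
        read_protein_groups(path, condition="crosslinked")


def test_duplicate_group_id_is_input_error(tmp_path, tiny_table):
    ds, paths = tiny_table
    import pandas as pd

    table = pd.read_csv(paths["protein_groups"], sep="\t", dtype=str)
    table = pd.concat([table, table.iloc[[0]]], ignore_index=True)
    path = tmp_path / "dup.tsv"
    table.to_csv(path, sep="\t", index=False)
    with pytest.raises(InputError, match="duplicate"):
        read_protein_groups(path, condition="crosslinked")


# ---------------------------------------------------------------------------
# qc filter
# ---------------------------------------------------------------------------


def _group(pid, peptides, contaminant=False, reverse=False):
    return ProteinGroup(
        group_id=pid,
        accessions=[pid],
        monomer_mw_kda=50.0,
        peptides_per_replicate=dict(enumerate(peptides, start=1)),
        is_contaminant=contaminant,
        is_reverse=reverse,
    )


@pytest.mark.parametrize(
    "peptides, contaminant, reverse, kept",
    [
        ((3, 2, 0), False, False, True),   # two replicates reach 2 peptides
        ((5, 1, 1), False, False, False),  # only one replicate reaches 2
        ((9, 9, 9), False, True, False),   # decoy hit always removed
        ((9, 9, 9), True, False, False),   # contaminant always removed
        ((2, 2, 2), False, False, True),
        ((2, 0, 0), False, False, False),
    ],
)
def test_qc_filter_detection_rule(peptides, contaminant, reverse, kept):
    g = _group("G1", peptides, contaminant, reverse)
    p = ReplicateProfile("G1", "crosslinked", 1, np.ones(8))
    got_g, got_p = qc_filter([g], [p])
    assert (len(got_g) == 1) == kept
    assert (len(got_p) == 1) == kept


def test_qc_filter_idempotent_and_monotone():
    groups = [
        _group(f"G{i}", peps)
        for i, peps in enumerate([(3, 3, 3), (2, 2, 0), (1, 1, 1), (5, 0, 0)])
    ]
    once = qc_filter(groups, [], 2, 2)
    twice = qc_filter(*once, 2, 2)
    assert [g.group_id for g in once[0]] == [g.group_id for g in twice[0]]
    # retained set shrinks (weakly) as thresholds grow
    sizes = [
        len(qc_filter(groups, [], mp, mr)[0])
        for mp, mr in [(1, 1), (2, 2), (3, 3), (4, 3)]
    ]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# smoothing / normalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "vec, expected",
    [
        ([5, 5, 5, 5], [5, 5, 5, 5]),
        ([0, 0, 3, 0, 0], [0, 1, 1, 1, 0]),
        ([4, 0], [2, 2]),
        ([7], [7]),
    ],
)
def test_smooth_three_fraction_sliding_mean(vec, expected):
    assert np.allclose(smooth(np.array(vec, float)), expected)


@pytest.mark.parametrize(
    "vec, expected",
    [
        ([2, 4, 6], [0, 0.5, 1]),
        ([7, 7, 7], [0, 0, 0]),  # constant = no signal
        ([0, 10, 5], [0, 1, 0.5]),
    ],
)
def test_minmax_normalize(vec, expected):
    assert np.allclose(minmax_normalize(np.array(vec, float)), expected)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0, 1e9, allow_nan=False), min_size=1, max_size=64)
)
def test_smooth_and_normalize_preserve_length_and_range(vec):
    v = np.array(vec)
    s = smooth(v)
    n = minmax_normalize(v)
    assert len(s) == len(v) and len(n) == len(v)
    assert n.min() >= 0.0 and n.max() <= 1.0
    if v.max() > v.min():
        assert n.min() == 0.0 and n.max() == 1.0


# ---------------------------------------------------------------------------
# mean profiles
# ---------------------------------------------------------------------------


def _rep(vec, rep=1, gid="G", cond="crosslinked"):
    return ReplicateProfile(gid, cond, rep, np.array(vec, float))


def test_mean_profile_of_processed_replicates_is_plain_mean_sd():
    mp = build_mean_profile([_rep([0, 1, 0], 1), _rep([0, 0, 1], 2)])
    assert np.allclose(mp.mean, [0, 0.5, 0.5])
    assert np.allclose(mp.sd, [0, np.sqrt(0.5), np.sqrt(0.5)])
    assert mp.n_replicates_detected == 2


def test_mean_profile_identical_replicates_has_zero_sd():
    mp = build_mean_profile([_rep([0, 1, 0], 1), _rep([0, 1, 0], 2)])
    assert np.allclose(mp.mean, [0, 1, 0])
    assert np.allclose(mp.sd, 0)


def test_mean_profile_single_replicate():
    mp = build_mean_profile([_rep([0.2, 1, 0.2], 1)])
    assert np.allclose(mp.mean, [0.2, 1, 0.2])
    assert np.allclose(mp.sd, 0)
    assert mp.n_replicates_detected == 1


def test_mean_profile_rejects_mixed_conditions():
    with pytest.raises(InputError, match="condition"):
        build_mean_profile([_rep([0, 1], 1), _rep([0, 1], 2, cond="native")])


def test_build_mean_profiles_processes_each_replicate_first():
    # raw replicate [0,0,3,0,0] smooths to [0,1,1,1,0] then normalizes
    mps = build_mean_profiles([_rep([0, 0, 3, 0, 0], 1)])
    assert np.allclose(mps[0].mean, [0, 1, 1, 1, 0])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_calibration_log_linear_interpolation_and_extrapolation():
    curve = fit_calibration([(10, 1000.0), (20, 100.0)])
    assert fraction_to_mw(curve, 15) == pytest.approx(10**2.5, rel=1e-9)
    assert fraction_to_mw(curve, 25) == pytest.approx(10**1.5, rel=1e-9)
    # query at a standard returns the standard (2-point fit is exact)
    assert fraction_to_mw(curve, 10) == pytest.approx(1000.0, rel=1e-9)


def test_calibration_strictly_decreasing_and_inverse():
    curve = fit_calibration([(4, 2000.0), (12, 600.0), (30, 40.0), (44, 8.0)])
    mws = [fraction_to_mw(curve, f) for f in range(1, 49)]
    assert all(a > b for a, b in zip(mws, mws[1:]))
    assert curve.mw_to_fraction(fraction_to_mw(curve, 17)) == pytest.approx(17)


def test_calibration_requires_two_standards_and_monotone_input():
    with pytest.raises(CalibrationError):
        fit_calibration([(10, 1000.0)])
    with pytest.raises(CalibrationError):
        fit_calibration([(10, 100.0), (20, 1000.0)])


# ---------------------------------------------------------------------------
# profile TSV round trip
# ---------------------------------------------------------------------------


def test_mean_profile_tsv_round_trip_is_bit_identical(tmp_path, micro_means):
    path = tmp_path / "profiles.tsv"
    profile_io.write_mean_profiles(micro_means, path)
    back = sorted(profile_io.read_mean_profiles(path), key=lambda m: m.group_id)
    assert len(back) == len(micro_means)
    for a, b in zip(micro_means, back):
        assert a.group_id == b.group_id and a.condition == b.condition
        assert a.n_replicates_detected == b.n_replicates_detected
        assert (a.mean == b.mean).all() and (a.sd == b.sd).all()
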