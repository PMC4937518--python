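"""Synthetic SEC-MS co-fractionation data with planted protein complexes.

The generator emulates the structure of a crosslinked/native protein
correlation profiling study so that every pipeline stage is testable without
the deposited raw data:

* each planted complex elutes at the SEC fraction corresponding to the
  calibrated apparent MW of its summed member monomer MWs (a denatured but
  crosslinked assembly runs at roughly the sum of its parts);
* member profiles are Gaussian elution peaks at that apex with a replicate-
  specific integer apex jitter, optional monomer peaks, multiplicative
  lognormal noise, an additive noise floor, and whole-replicate dropout;
* transmembrane-flagged proteins in the ``native`` condition collapse into
  the void region (or vanish) with a configurable probability, mimicking the
  membrane-protein dropout the crosslinking workflow rescues;
* literature-score tables assign within-complex pairs scores from a "true"
  distribution and random non-co-complex pairs scores from a null
  distribution;
* the planted complexes are exported as the known-complex catalogue.

Everything is deterministic given the seed: one pseudo-random stream is
consumed in a fixed order (global structure first, then per protein in id
order, per condition, per replicate, per fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .known_complexes import KnownComplex, write_catalogue
from .profile_io import (
    CalibrationCurve,
    ProteinGroup,
    ReplicateProfile,
    TableSchema,
    fit_calibration,
)


class ConfigError(ValueError):
    """The synthetic configuration is internally infeasible."""


@dataclass
class SyntheticConfig:
    """Study conditions for the simulator (defaults mirror the real design:
    48 crosslinked / 40 native fractions, 3 biological replicates)."""

    seed: int = 0
    n_fractions: int = 48  # crosslinked
    n_fractions_native: int = 40
    n_replicates: int = 3
    n_complexes: int = 30
    complex_sizes: tuple[int, ...] = (3, 4, 5, 6)  # drawn uniformly
    n_singletons: int = 60
    apex_jitter_sd: float = 0.3  # fractions, per replicate, rounded
    peak_width_range: tuple[float, float] = (2.0, 4.0)  # Gaussian SD, fractions
    monomer_peak_prob: float = 0.3
    monomer_peak_rel_amp: float = 0.3
    singleton_decoy_peak_prob: float = 0.5
    noise_cv: float = 0.2  # multiplicative lognormal CV
    additive_noise_floor: float = 0.01
    dropout_prob: float = 0.05  # per (protein, replicate, condition)
    membrane_fraction: float = 0.2
    native_tm_void_prob: float = 0.8
    db_true_score_dist: tuple[str, float, float] = ("beta", 8.0, 2.0)
    db_null_score_dist: tuple[str, float, float] = ("beta", 1.0, 9.0)
    db_coverage: float = 0.9  # chance a true pair appears in a given table
    n_contaminants: int = 0
    n_reverse: int = 0

    def validate(self) -> None:
        probs = (
            self.monomer_peak_prob, self.singleton_decoy_peak_prob,
            self.dropout_prob, self.membrane_fraction,
            self.native_tm_void_prob, self.db_coverage,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.n_fractions < 8 or self.n_fractions_native < 8:
            raise ConfigError("need at least 8 fractions")
        if min(self.peak_width_range) < 0.5:
            raise ConfigError("peak widths below half a fraction are unresolvable")
        if self.n_complexes < 0 or self.n_singletons < 0:
            raise ConfigError("negative counts")
        if self.n_complexes * max(self.complex_sizes, default=0) > 10**6:
            raise ConfigError("id space exhausted")


@dataclass
class ProteinTruth:
    complex_ids: set[str]
    apex_by_condition: dict[str, int | None]
    monomer_apex: int | None
    tm: bool


@dataclass
class GroundTruth:
    complexes: list[set[str]]  # member ids per planted complex
    protein_truth: dict[str, ProteinTruth]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    table: pd.DataFrame  # protein-groups table, both conditions
    profiles: list[ReplicateProfile]  # noiseless-channel-free, both conditions
    truth: GroundTruth
    catalogue: list[KnownComplex]
    db_tables: dict[str, pd.DataFrame]  # string / hippie / mentha
    calibration_table: pd.DataFrame
    calibration: CalibrationCurve
    calibration_native: CalibrationCurve
    schema: TableSchema = field(default_factory=TableSchema)


# default calibration: log-linear from ~2.8 MDa (fraction 4) to ~20 kDa
# (fraction 44), matching a high-pore SEC column's working range
_CAL_SLOPE = -0.053
_CAL_INTERCEPT = 3.6 + 0.053  # so log10(mw) = 3.6 - 0.053 * (f - 1)


def default_calibration_standards(n_fractions: int = 48) -> list[tuple[int, float]]:
    fractions = [f for f in (4, 12, 20, 28, 36, 44) if f <= n_fractions]
    return [
        (f, 10.0 ** (_CAL_INTERCEPT + _CAL_SLOPE * f)) for f in fractions
    ]


def _native_calibration(n_native: int, n_xl: int) -> CalibrationCurve:
    # same MW range compressed onto the native column's fraction count
    scale = (n_xl - 1) / (n_native - 1)
    return CalibrationCurve(
        standards=[],
        slope=_CAL_SLOPE * scale,
        intercept=_CAL_INTERCEPT + _CAL_SLOPE * (1 - scale),
    )


def _gaussian(n: int, apex: float, sd: float) -> np.ndarray:
    x = np.arange(1, n + 1, dtype=float)
    return np.exp(-0.5 * ((x - apex) / sd) ** 2)


def _draw(dist: tuple[str, float, float], rng: np.random.Generator) -> float:
    kind, a, b = dist
    if kind == "beta":
        return float(rng.beta(a, b))
    if kind == "uniform":
        return float(rng.uniform(a, b))
    raise ConfigError(f"unknown distribution kind {kind!r}")


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Simulate a full co-fractionation study from the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_xl = config.n_fractions
    n_nat = config.n_fractions_native
    calibration = fit_calibration(default_calibration_standards(n_xl))
    cal_native = _native_calibration(n_nat, n_xl)

    # ---- global structure ------------------------------------------------
    sizes = [int(rng.choice(config.complex_sizes)) for _ in range(config.n_complexes)]
    n_members = sum(sizes)
    n_proteins = n_members + config.n_singletons

    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    complexes: list[set[str]] = []
    members_of: dict[str, str] = {}
    cursor = 0
    for ci, size in enumerate(sizes):
        cid = f"CPX{ci + 1:03d}"
        member_ids = set(ids[cursor : cursor + size])
        cursor += size
        complexes.append(member_ids)
        for pid in member_ids:
            members_of[pid] = cid
    singleton_ids = ids[cursor:]

    # monomer MWs: members of one complex share a size scale so the summed
    # assembly MW always clears the dimer filter
    mw: dict[str, float] = {}
    for ci, member_ids in enumerate(complexes):
        base = float(np.exp(rng.normal(math.log(45.0), 0.6)))
        for pid in sorted(member_ids):
            mw[pid] = base * float(rng.uniform(0.85, 1.15))
    for pid in singleton_ids:
        mw[pid] = float(np.exp(rng.normal(math.log(45.0), 0.6)))

    tm_flag = {pid: bool(rng.random() < config.membrane_fraction) for pid in ids}

    def clip_fraction(x: float, n: int, lo: int = 1) -> int:
        return int(min(max(round(x), lo), n))

    # complex apexes from the calibrated summed MW, kept out of the void
    complex_apex_xl: dict[str, int] = {}
    complex_apex_nat: dict[str, int] = {}
    for ci, member_ids in enumerate(complexes):
        cid = f"CPX{ci + 1:03d}"
        total = sum(mw[p] for p in member_ids)
        complex_apex_xl[cid] = clip_fraction(
            calibration.mw_to_fraction(total), n_xl - 2, lo=6
        )
        complex_apex_nat[cid] = clip_fraction(
            cal_native.mw_to_fraction(total), n_nat - 2, lo=6
        )

    width_lo, width_hi = config.peak_width_range
    # one elution width per complex: co-complex members share a peak shape,
    # so the noiseless within-complex correlation is exactly 1
    complex_width = {
        f"CPX{ci + 1:03d}": float(rng.uniform(width_lo, width_hi))
        for ci in range(config.n_complexes)
    }

    # ---- per-protein structure ------------------------------------------
    truth: dict[str, ProteinTruth] = {}
    components: dict[tuple[str, str], list[tuple[float, float, float]]] = {}
    # (condition, pid) -> list of (apex, sd, amplitude)
    for pid in ids:
        cid = members_of.get(pid)
        sd = float(rng.uniform(width_lo, width_hi))
        monomer_frac_xl = clip_fraction(calibration.mw_to_fraction(mw[pid]), n_xl)
        monomer_frac_nat = clip_fraction(cal_native.mw_to_fraction(mw[pid]), n_nat)
        has_monomer = rng.random() < config.monomer_peak_prob
        comp_xl: list[tuple[float, float, float]] = []
        comp_nat: list[tuple[float, float, float]] = []
        apex_xl = apex_nat = None
        if cid is not None:
            apex_xl = complex_apex_xl[cid]
            apex_nat = complex_apex_nat[cid]
            comp_xl.append((apex_xl, complex_width[cid], 1.0))
            comp_nat.append((apex_nat, complex_width[cid], 1.0))
            if has_monomer:
                comp_xl.append((monomer_frac_xl, sd * 0.7, config.monomer_peak_rel_amp))
                comp_nat.append((monomer_frac_nat, sd * 0.7, config.monomer_peak_rel_amp))
        else:
            comp_xl.append((monomer_frac_xl, sd * 0.7, 1.0))
            comp_nat.append((monomer_frac_nat, sd * 0.7, 1.0))
            if rng.random() < config.singleton_decoy_peak_prob:
                # spurious high-MW co-elution (aggregate), above the dimer MW
                f_max = calibration.mw_to_fraction(2.2 * mw[pid])
                if f_max >= 6.0:
                    decoy = int(rng.integers(6, int(f_max) + 1))
                    apex_xl = decoy
                    comp_xl.append((decoy, sd, 1.0))
        # native membrane-protein collapse
        if tm_flag[pid] and rng.random() < config.native_tm_void_prob:
            if rng.random() < 0.5:
                comp_nat = [(2.0, 1.0, 1.0)]  # void aggregate
            else:
                comp_nat = []  # not extracted at all
            apex_nat = None
        components[("crosslinked", pid)] = comp_xl
        components[("native", pid)] = comp_nat
        truth[pid] = ProteinTruth(
            complex_ids={cid} if cid else set(),
            apex_by_condition={"crosslinked": apex_xl, "native": apex_nat},
            monomer_apex=monomer_frac_xl,
            tm=tm_flag[pid],
        )

    # ---- replicate profiles (single stream: pid, condition, replicate) ---
    profiles: list[ReplicateProfile] = []
    detected: dict[tuple[str, str, int], bool] = {}
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    abundance = {pid: 10.0 ** rng.uniform(6.0, 9.0) for pid in ids}
    for pid in ids:
        for condition, n_fr in (("crosslinked", n_xl), ("native", n_nat)):
            comps = components[(condition, pid)]
            for rep in range(1, config.n_replicates + 1):
                dropout = rng.random() < config.dropout_prob or not comps
                jitter = (
                    rng.normal(0.0, config.apex_jitter_sd, size=len(comps))
                    if config.apex_jitter_sd > 0
                    else np.zeros(len(comps))
                )
                mult = (
                    rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_fr)
                    if sigma > 0
                    else np.ones(n_fr)
                )
                add = (
                    np.abs(rng.normal(0.0, config.additive_noise_floor, size=n_fr))
                    if config.additive_noise_floor > 0
                    else np.zeros(n_fr)
                )
                if dropout:
                    vec = np.zeros(n_fr)
                else:
                    vec = np.zeros(n_fr)
                    for (apex, sd_c, amp), dj in zip(comps, jitter):
                        shifted = min(max(round(apex + dj), 1), n_fr)
                        vec += amp * _gaussian(n_fr, shifted, sd_c)
                    vec = (vec * mult + add) * abundance[pid]
                detected[(pid, condition, rep)] = not dropout
                profiles.append(
                    ReplicateProfile(
                        group_id=pid,
                        condition=condition,
                        replicate_index=rep,
                        intensities=vec,
                    )
                )

    # ---- protein-groups table -------------------------------------------
    schema = TableSchema()
    rows = []
    decoy_specs = [("CON_%03d" % i, True, False) for i in range(config.n_contaminants)]
    decoy_specs += [("REV_%03d" % i, False, True) for i in range(config.n_reverse)]
    for pid in ids:
        row: dict[str, object] = {
            schema.id_col: pid,
            schema.gene_col: f"GENE_{pid}",
            schema.mw_col: round(mw[pid], 3),
            schema.tm_col: int(tm_flag[pid]),
            schema.contaminant_col: "",
            schema.reverse_col: "",
        }
        for condition, n_fr in (("crosslinked", n_xl), ("native", n_nat)):
            for rep in range(1, config.n_replicates + 1):
                if detected[(pid, condition, rep)]:
                    row[schema.peptide_col(condition, rep)] = int(rng.integers(3, 15))
                    row[schema.ibaq_col(condition, rep)] = round(
                        abundance[pid] * float(rng.uniform(0.5, 2.0)), 3
                    )
                else:
                    row[schema.peptide_col(condition, rep)] = int(rng.integers(0, 2))
                    row[schema.ibaq_col(condition, rep)] = 0.0
        rows.append(row)
    profile_by_key = {
        (p.group_id, p.condition, p.replicate_index): p for p in profiles
    }
    for row, pid in zip(rows, ids):
        for condition, n_fr in (("crosslinked", n_xl), ("native", n_nat)):
            for rep in range(1, config.n_replicates + 1):
                vec = profile_by_key[(pid, condition, rep)].intensities
                for f in range(1, n_fr + 1):
                    row[schema.lfq_col(condition, rep, f)] = round(vec[f - 1], 1)
    for name, is_con, is_rev in decoy_specs:
        row = {
            schema.id_col: name,
            schema.gene_col: "",
            schema.mw_col: round(float(np.exp(rng.normal(math.log(45.0), 0.6))), 3),
            schema.tm_col: 0,
            schema.contaminant_col: "+" if is_con else "",
            schema.reverse_col: "+" if is_rev else "",
        }
        for condition, n_fr in (("crosslinked", n_xl), ("native", n_nat)):
            for rep in range(1, config.n_replicates + 1):
                row[schema.peptide_col(condition, rep)] = int(rng.integers(3, 15))
                row[schema.ibaq_col(condition, rep)] = 0.0
                for f in range(1, n_fr + 1):
                    row[schema.lfq_col(condition, rep, f)] = round(
                        float(rng.uniform(0, 1e6)), 1
                    )
        rows.append(row)
    table = pd.DataFrame(rows)

    # ---- catalogue and literature score tables ---------------------------
    catalogue = [
        KnownComplex(
            complex_id=f"CPX{ci + 1:03d}",
            name=f"planted complex {ci + 1}",
            member_accessions=set(member_ids),
        )
        for ci, member_ids in enumerate(complexes)
    ]
    true_pairs = sorted(
        {
            tuple(sorted(p))
            for member_ids in complexes
            for p in combinations(sorted(member_ids), 2)
        }
    )
    co_complex = set(true_pairs)
    n_null = 2 * len(true_pairs)
    db_tables = {}
    for db_name in ("string", "hippie", "mentha"):
        rows_db = []
        for a, b in true_pairs:
            if rng.random() < config.db_coverage:
                rows_db.append((a, b, round(_draw(config.db_true_score_dist, rng), 4)))
        for _ in range(n_null):
            a, b = rng.choice(ids, size=2, replace=False)
            if tuple(sorted((a, b))) in co_complex:
                continue
            rows_db.append(
                (str(a), str(b), round(_draw(config.db_null_score_dist, rng), 4))
            )
        db_tables[db_name] = pd.DataFrame(
            rows_db, columns=["acc_a", "acc_b", "score"]
        )

    calibration_table = pd.DataFrame(
        default_calibration_standards(n_xl), columns=["fraction", "kda"]
    ).round({"kda": 4})

    return SyntheticDataset(
        config=config,
        table=table,
        profiles=profiles,
        truth=GroundTruth(complexes=complexes, protein_truth=truth),
        catalogue=catalogue,
        db_tables=db_tables,
        calibration_table=calibration_table,
        calibration=calibration,
        calibration_native=cal_native,
        schema=schema,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the TSV dialects the pipeline reads; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"protein_groups": out / "proteinGroups.tsv"}
    dataset.table.to_csv(paths["protein_groups"], sep="\t", index=False)
    paths["calibration"] = out / "calibration.tsv"
    dataset.calibration_table.to_csv(paths["calibration"], sep="\t", index=False)
    paths["catalogue"] = out / "complexes.tsv"
    write_catalogue(dataset.catalogue, paths["catalogue"])
    for name, table in dataset.db_tables.items():
        paths[name] = out / f"{name}_scores.tsv"
        table.to_csv(paths[name], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# hand-computable worked micro example
# ---------------------------------------------------------------------------


@dataclass
class MicroExample:
    """Fixed 6-protein, 2-complex, 12-fraction dataset with known answers."""

    groups: list[ProteinGroup]
    profiles: list[ReplicateProfile]  # crosslinked, 3 replicates
    calibration: CalibrationCurve
    catalogue: list[KnownComplex]
    complex_apexes: dict[str, int]  # complex id -> planted apex
    singleton_apex: int
    expected_surviving_peaks: dict[str, list[int]]  # per group, apexes
    expected_candidate_pairs: int
    expected_coapex: dict[frozenset, float]


def generate_worked_micro_example() -> MicroExample:
    """Two planted complexes (A = {P1,P2,P3} at fraction 5, B = {P4,P5} at
    fraction 8), one isolated singleton (P6 at fraction 10), 12 fractions.

    P4 carries a well-separated void peak (removed by the void filter).
    P2, P3 and P5 carry additional sub-resolution shoulders (a sub-15% bump,
    a void shoulder, a near-dimer edge shoulder) which on this short grid
    merge into their main peaks, so the surviving peak set is exactly one
    peak per protein.  P4's apex shifts to fraction 9 in replicate 3 only,
    so the P4-P5 pair co-apexes in exactly 2 of 3 replicates (coapex 0.6)
    while P1/P2/P3 co-apex in all three (coapex 1.0).
    """
    n = 12
    # collinear standards: MW falls 4-fold every 3 fractions
    standards = [(2, 1200.0), (5, 300.0), (8, 75.0), (11, 18.75)]
    calibration = fit_calibration(standards)

    # complex A sums to ~300 kDa (= apparent MW at fraction 5); the
    # singleton P6 carries a spurious high-MW peak isolated from both apexes
    mw = {"P1": 95.0, "P2": 110.0, "P3": 95.0, "P4": 15.0, "P5": 10.0, "P6": 4.0}

    def gauss(apex: float, sd: float, amp: float = 1.0) -> np.ndarray:
        return amp * _gaussian(n, apex, sd)

    base = {
        "P1": gauss(5, 1.2),
        "P2": gauss(5, 1.2) + gauss(10, 0.8, 0.10),
        "P3": gauss(5, 1.2) + gauss(2, 1.0, 0.5),
        "P4": gauss(8, 1.0) + gauss(2, 0.8, 0.6),
        "P5": gauss(8, 1.0) + gauss(12, 0.8, 0.4),
        "P6": gauss(10, 1.0),
    }
    p4_shifted = gauss(9, 1.0) + gauss(2, 0.8, 0.6)

    profiles = []
    for pid, vec in base.items():
        for rep in (1, 2, 3):
            v = p4_shifted if (pid == "P4" and rep == 3) else vec
            profiles.append(
                ReplicateProfile(
                    group_id=pid,
                    condition="crosslinked",
                    replicate_index=rep,
                    intensities=v * 1e7,
                )
            )
    groups = [
        ProteinGroup(
            group_id=pid,
            accessions=[pid],
            monomer_mw_kda=mw[pid],
            peptides_per_replicate={1: 5, 2: 5, 3: 5},
        )
        for pid in base
    ]
    catalogue = [
        KnownComplex("CPXA", "planted complex A", {"P1", "P2", "P3"}),
        KnownComplex("CPXB", "planted complex B", {"P4", "P5"}),
    ]
    return MicroExample(
        groups=groups,
        profiles=profiles,
        calibration=calibration,
        catalogue=catalogue,
        complex_apexes={"CPXA": 5, "CPXB": 8},
        singleton_apex=10,
        expected_surviving_peaks={
            "P1": [5], "P2": [5], "P3": [5], "P4": [8], "P5": [8], "P6": [10],
        },
        expected_candidate_pairs=4,
        expected_coapex={
            frozenset({"P1", "P2"}): 1.0,
            frozenset({"P1", "P3"}): 1.0,
            frozenset({"P2", "P3"}): 1.0,
            frozenset({"P4", "P5"}): 0.6,
        },
    )
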