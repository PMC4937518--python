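"""Reading, filtering and preprocessing of SEC-MS protein-group profiles.

A co-fractionation experiment quantifies every protein group (MaxQuant's unit
of inference) across consecutive size-exclusion chromatography fractions, in
several biological replicates and under one or more extraction conditions
(``native`` vs formaldehyde-``crosslinked``).  This module parses the
tab-separated protein-groups table, applies the detection filters (minimum
peptide evidence in a minimum number of replicates, no contaminants or decoy
hits), turns each replicate's LFQ intensity vector into a smoothed, 0-1
normalized profile, aggregates replicates into a mean +/- SD profile, and fits
the fraction -> apparent-molecular-weight calibration from a table of protein
standards.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("native", "crosslinked")

#: default number of SEC fractions collected per condition
DEFAULT_N_FRACTIONS = {"native": 40, "crosslinked": 48}


class SchemaError(ValueError):
    """A mandatory column is missing from the protein-groups table."""


class InputError(ValueError):
    """The table content violates the format contract (e.g. duplicate ids)."""


class CalibrationError(ValueError):
    """Too few standards to fit a molecular-weight calibration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProteinGroup:
    """One MaxQuant-style protein group (the quantification unit)."""

    group_id: str
    accessions: list[str]
    gene_names: list[str] = field(default_factory=list)
    monomer_mw_kda: float = float("nan")
    #: replicate index (1-based) -> peptide count, for the condition read
    peptides_per_replicate: dict[int, int] = field(default_factory=dict)
    #: (condition, replicate) -> iBAQ intensity
    ibaq: dict[tuple[str, int], float] = field(default_factory=dict)
    is_contaminant: bool = False
    is_reverse: bool = False
    tm_helix_count: int = 0

    def __post_init__(self) -> None:
        if not math.isnan(self.monomer_mw_kda) and self.monomer_mw_kda <= 0:
            raise InputError(
                f"group {self.group_id}: monomer MW must be positive, "
                f"got {self.monomer_mw_kda}"
            )
        for rep, count in self.peptides_per_replicate.items():
            if count < 0 or int(count) != count:
                raise InputError(
                    f"group {self.group_id}: peptide count for replicate "
                    f"{rep} must be a nonnegative integer"
                )


@dataclass
class ReplicateProfile:
    """Raw LFQ intensity vector of one group in one replicate/condition."""

    group_id: str
    condition: str
    replicate_index: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.condition not in CONDITIONS:
            raise InputError(f"unknown condition {self.condition!r}")
        if np.any(self.intensities < 0):
            raise InputError(
                f"group {self.group_id} rep {self.replicate_index}: "
                "negative intensity"
            )


@dataclass
class MeanProfile:
    """Smoothed/normalized per-fraction mean and SD across replicates."""

    group_id: str
    condition: str
    mean: np.ndarray
    sd: np.ndarray
    n_replicates_detected: int


# ---------------------------------------------------------------------------
# table schema
# ---------------------------------------------------------------------------


@dataclass
class TableSchema:
    """Column mapping for the protein-groups TSV dialect.

    Patterns may contain ``{condition}``, ``{replicate}`` and ``{fraction}``
    placeholders which are filled with the condition name, the 1-based
    replicate index and the 1-based fraction number.
    """

    id_col: str = "Protein IDs"
    gene_col: str = "Gene names"
    lfq_pattern: str = "LFQ intensity {condition}_R{replicate}_F{fraction}"
    peptide_pattern: str = "Peptides {condition}_R{replicate}"
    ibaq_pattern: str = "iBAQ {condition}_R{replicate}"
    contaminant_col: str = "Potential contaminant"
    reverse_col: str = "Reverse"
    mw_col: str = "Mol. weight [kDa]"
    tm_col: str = "TM helices"
    n_replicates: int = 3

    def lfq_col(self, condition: str, replicate: int, fraction: int) -> str:
        return self.lfq_pattern.format(
            condition=condition, replicate=replicate, fraction=fraction
        )

    def peptide_col(self, condition: str, replicate: int) -> str:
        return self.peptide_pattern.format(condition=condition, replicate=replicate)

    def ibaq_col(self, condition: str, replicate: int) -> str:
        return self.ibaq_pattern.format(condition=condition, replicate=replicate)


def _parse_flag(value: object) -> bool:
    return str(value).strip() in {"+", "1", "True", "true", "yes"}


def read_protein_groups(
    path,
    schema: TableSchema | None = None,
    condition: str = "crosslinked",
    n_fractions: int | None = None,
) -> tuple[list[ProteinGroup], list[ReplicateProfile]]:
    """Parse a protein-groups TSV for one condition.

    Returns one :class:`ProteinGroup` per row and one
    :class:`ReplicateProfile` per (row, replicate).  Unparseable or empty
    intensity cells become 0 (the missing-value convention) with a logged
    warning.
    """
    schema = schema or TableSchema()
    if condition not in CONDITIONS:
        raise InputError(f"unknown condition {condition!r}")
    n_fractions = n_fractions or DEFAULT_N_FRACTIONS[condition]

    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    mandatory = [schema.id_col, schema.mw_col]
    mandatory += [
        schema.peptide_col(condition, r) for r in range(1, schema.n_replicates + 1)
    ]
    mandatory += [
        schema.lfq_col(condition, r, f)
        for r in range(1, schema.n_replicates + 1)
        for f in range(1, n_fractions + 1)
    ]
    missing = [c for c in mandatory if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing[:5]}")

    if table[schema.id_col].duplicated().any():
        dup = table[schema.id_col][table[schema.id_col].duplicated()].iloc[0]
        raise InputError(f"duplicate group id {dup!r}")

    groups: list[ProteinGroup] = []
    profiles: list[ReplicateProfile] = []
    n_bad_cells = 0
    for _, row in table.iterrows():
        gid = row[schema.id_col]
        accessions = [a for a in str(gid).split(";") if a]
        genes = (
            [g for g in str(row[schema.gene_col]).split(";") if g]
            if schema.gene_col in table.columns
            else []
        )
        peptides = {}
        for r in range(1, schema.n_replicates + 1):
            raw = row[schema.peptide_col(condition, r)]
            try:
                peptides[r] = int(float(raw)) if str(raw).strip() else 0
            except ValueError:
                peptides[r] = 0
        ibaq = {}
        for r in range(1, schema.n_replicates + 1):
            col = schema.ibaq_col(condition, r)
            if col in table.columns:
                try:
                    ibaq[(condition, r)] = float(row[col]) if str(row[col]).strip() else 0.0
                except ValueError:
                    ibaq[(condition, r)] = 0.0
        group = ProteinGroup(
            group_id=gid,
            accessions=accessions,
            gene_names=genes,
            monomer_mw_kda=float(row[schema.mw_col]),
            peptides_per_replicate=peptides,
            ibaq=ibaq,
            is_contaminant=(
                _parse_flag(row[schema.contaminant_col])
                if schema.contaminant_col in table.columns
                else False
            ),
            is_reverse=(
                _parse_flag(row[schema.reverse_col])
                if schema.reverse_col in table.columns
                else False
            ),
            tm_helix_count=(
                int(float(row[schema.tm_col]))
                if schema.tm_col in table.columns and str(row[schema.tm_col]).strip()
                else 0
            ),
        )
        groups.append(group)
        for r in range(1, schema.n_replicates + 1):
            vec = np.zeros(n_fractions)
            for f in range(1, n_fractions + 1):
                raw = str(row[schema.lfq_col(condition, r, f)]).strip()
                if not raw:
                    continue
                try:
                    vec[f - 1] = float(raw)
                except ValueError:
                    n_bad_cells += 1
            profiles.append(
                ReplicateProfile(
                    group_id=gid,
                    condition=condition,
                    replicate_index=r,
                    intensities=vec,
                )
            )
    if n_bad_cells:
        logger.warning("%d unparseable intensity cells set to 0", n_bad_cells)
    return groups, profiles


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------


def qc_filter(
    groups: list[ProteinGroup],
    profiles: list[ReplicateProfile],
    min_peptides: int = 2,
    min_replicates: int = 2,
) -> tuple[list[ProteinGroup], list[ReplicateProfile]]:
    """Keep groups identified with >= ``min_peptides`` peptides in >=
    ``min_replicates`` replicates that are neither contaminants nor decoys."""
    kept_ids = set()
    kept_groups = []
    for g in groups:
        n_good = sum(
            1 for c in g.peptides_per_replicate.values() if c >= min_peptides
        )
        if n_good >= min_replicates and not g.is_contaminant and not g.is_reverse:
            kept_ids.add(g.group_id)
            kept_groups.append(g)
    kept_profiles = [p for p in profiles if p.group_id in kept_ids]
    return kept_groups, kept_profiles


# ---------------------------------------------------------------------------
# per-replicate processing
# ---------------------------------------------------------------------------


def smooth(v: np.ndarray) -> np.ndarray:
    """Three-fraction sliding mean with truncated (size-2) edge windows."""
    v = np.asarray(v, dtype=float)
    return (
        pd.Series(v).rolling(window=3, center=True, min_periods=1).mean().to_numpy()
    )


def minmax_normalize(v: np.ndarray) -> np.ndarray:
    """Scale a profile so its minimum is 0 and its maximum 1.

    A constant profile carries no shape information and is mapped to all
    zeros rather than dividing by zero.
    """
    v = np.asarray(v, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def process_replicate(p: ReplicateProfile) -> ReplicateProfile:
    """Smooth then 0-1 normalize one replicate profile."""
    return replace(p, intensities=minmax_normalize(smooth(p.intensities)))


def build_mean_profile(
    replicates: list[ReplicateProfile], process: bool = False
) -> MeanProfile:
    """Aggregate >= 1 replicates of one group/condition into mean +/- SD.

    Expects replicates that have already been smoothed and normalized
    (``process=True`` applies :func:`process_replicate` first); the SD is
    the sample standard deviation (0 when only one replicate is supplied).
    """
    if not replicates:
        raise InputError("no replicates supplied")
    conditions = {p.condition for p in replicates}
    if len(conditions) > 1:
        raise InputError(f"mixed conditions {sorted(conditions)}")
    gids = {p.group_id for p in replicates}
    if len(gids) > 1:
        raise InputError(f"mixed groups {sorted(gids)}")
    lengths = {len(p.intensities) for p in replicates}
    if len(lengths) > 1:
        raise InputError("replicate profiles differ in length")
    if process:
        replicates = [process_replicate(p) for p in replicates]
    mat = np.vstack([p.intensities for p in replicates])
    sd = (
        mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(mat.shape[1])
    )
    n_detected = sum(1 for p in replicates if p.intensities.max() > 0)
    return MeanProfile(
        group_id=replicates[0].group_id,
        condition=replicates[0].condition,
        mean=mat.mean(axis=0),
        sd=sd,
        n_replicates_detected=n_detected,
    )


def build_mean_profiles(profiles: list[ReplicateProfile]) -> list[MeanProfile]:
    """Smooth + normalize raw replicates, then aggregate per (group, condition)."""
    by_key: dict[tuple[str, str], list[ReplicateProfile]] = {}
    for p in profiles:
        by_key.setdefault((p.group_id, p.condition), []).append(p)
    return [build_mean_profile(reps, process=True) for reps in by_key.values()]


# ---------------------------------------------------------------------------
# molecular-weight calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationCurve:
    """Log-linear fit of apparent MW (kDa) against SEC fraction number.

    Fitted by least squares on log10(kDa) of the standards; extrapolated
    linearly beyond the outermost standards, the usual practice for SEC
    column calibration.
    """

    standards: list[tuple[int, float]]
    slope: float
    intercept: float

    def fraction_to_mw(self, fraction: float) -> float:
        return float(10.0 ** (self.intercept + self.slope * fraction))

    def mw_to_fraction(self, mw_kda: float) -> float:
        """Inverse map (real-valued fraction); used by the simulator."""
        return float((math.log10(mw_kda) - self.intercept) / self.slope)


def fit_calibration(standards: list[tuple[int, float]]) -> CalibrationCurve:
    """Fit the fraction -> log10(kDa) line from (fraction, kDa) standards."""
    if len(standards) < 2:
        raise CalibrationError("need at least 2 MW standards")
    fr = np.array([s[0] for s in standards], dtype=float)
    mw = np.array([s[1] for s in standards], dtype=float)
    order = np.argsort(fr)
    if np.any(np.diff(mw[order]) >= 0):
        raise CalibrationError("standard MW must strictly decrease with fraction")
    slope, intercept = np.polyfit(fr, np.log10(mw), 1)
    return CalibrationCurve(
        standards=sorted(standards), slope=float(slope), intercept=float(intercept)
    )


def read_calibration(path) -> CalibrationCurve:
    """Read a calibration TSV with columns ``fraction`` and ``kda``."""
    table = pd.read_csv(path, sep="\t")
    for col in ("fraction", "kda"):
        if col not in table.columns:
            raise SchemaError(f"calibration table missing column {col!r}")
    return fit_calibration(
        [(int(r.fraction), float(r.kda)) for r in table.itertuples()]
    )


def fraction_to_mw(curve: CalibrationCurve, fraction: int) -> float:
    """Apparent MW (kDa) at a 1-based fraction number."""
    return curve.fraction_to_mw(fraction)


# ---------------------------------------------------------------------------
# profile TSV round-trip
# ---------------------------------------------------------------------------


def write_mean_profiles(profiles: list[MeanProfile], path) -> None:
    """Write normalized mean profiles to the long-format TSV dialect."""
    rows = []
    for mp in profiles:
        for i, (m, s) in enumerate(zip(mp.mean, mp.sd), start=1):
            rows.append(
                (mp.group_id, mp.condition, i, repr(float(m)), repr(float(s)),
                 mp.n_replicates_detected)
            )
    pd.DataFrame(
        rows,
        columns=["group_id", "condition", "fraction", "mean", "sd", "n_replicates"],
    ).to_csv(path, sep="\t", index=False)


def read_mean_profiles(path) -> list[MeanProfile]:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for (gid, cond), sub in table.groupby(["group_id", "condition"], sort=False):
        sub = sub.sort_values("fraction")
        out.append(
            MeanProfile(
                group_id=str(gid),
                condition=str(cond),
                mean=sub["mean"].to_numpy(dtype=float),
                sd=sub["sd"].to_numpy(dtype=float),
                n_replicates_detected=int(sub["n_replicates"].iloc[0]),
            )
        )
    return out
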