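"""Scoring of previously annotated complexes in each extraction condition.

A catalogued complex (CORUM-style: id, name, member accessions) is analyzed
when at least two of its members are detected in either the native or the
crosslinked data set.  Its per-condition coherence is the median Pearson
correlation over all unordered pairs of detected members' mean profiles;
complexes with fewer than two members detected natively but two or more
detected after crosslinking are flagged ``crosslinked_only`` (the membrane
complexes recovered only by the crosslinking workflow).

Fractional iBAQ intensities (protein iBAQ over the data-set total, void
fractions excluded) support the between-condition abundance comparison,
stratifiable by the transmembrane-helix annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from statistics import median

import pandas as pd

from .features import pearson
from .profile_io import MeanProfile


@dataclass
class KnownComplex:
    complex_id: str
    name: str
    member_accessions: set[str]


@dataclass
class ComplexConditionScore:
    complex_id: str
    name: str
    n_detected_native: int
    n_detected_crosslinked: int
    median_pcc_native: float | None
    median_pcc_crosslinked: float | None
    crosslinked_only: bool


def read_catalogue(path) -> list[KnownComplex]:
    """Catalogue TSV: complex_id, name, members (semicolon-joined)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        KnownComplex(
            complex_id=cid,
            name=nm,
            member_accessions={m for m in str(mem).split(";") if m},
        )
        for cid, nm, mem in zip(table["complex_id"], table["name"], table["members"])
    ]


def write_catalogue(catalogue: list[KnownComplex], path) -> None:
    pd.DataFrame(
        [
            (c.complex_id, c.name, ";".join(sorted(c.member_accessions)))
            for c in catalogue
        ],
        columns=["complex_id", "name", "members"],
    ).to_csv(path, sep="\t", index=False)


def detected_members(
    complex_: KnownComplex, detected_accessions: set[str]
) -> set[str]:
    return complex_.member_accessions & detected_accessions


def detectable_complexes(
    catalogue: list[KnownComplex],
    detected_native: set[str],
    detected_crosslinked: set[str],
) -> list[KnownComplex]:
    """Complexes with >= 2 detected members in at least one condition."""
    return [
        c
        for c in catalogue
        if len(detected_members(c, detected_native)) >= 2
        or len(detected_members(c, detected_crosslinked)) >= 2
    ]


def median_pair_pcc(
    complex_: KnownComplex, mean_profiles: dict[str, MeanProfile]
) -> float | None:
    """Median Pearson correlation over all unordered pairs of detected
    members' mean profiles; None when fewer than 2 members are detected.

    A protein group "detects" a member accession if the accession maps to a
    retained group's profile (the supplied dict is keyed by accession).
    """
    detected = sorted(a for a in complex_.member_accessions if a in mean_profiles)
    if len(detected) < 2:
        return None
    pccs = [
        pearson(mean_profiles[a].mean, mean_profiles[b].mean)
        for a, b in combinations(detected, 2)
    ]
    return float(median(pccs))


def score_complexes(
    catalogue: list[KnownComplex],
    profiles_native: dict[str, MeanProfile],
    profiles_crosslinked: dict[str, MeanProfile],
) -> list[ComplexConditionScore]:
    """Per-complex detection counts and median pair PCC in both conditions."""
    out = []
    for c in detectable_complexes(
        catalogue, set(profiles_native), set(profiles_crosslinked)
    ):
        n_nat = len(detected_members(c, set(profiles_native)))
        n_xl = len(detected_members(c, set(profiles_crosslinked)))
        out.append(
            ComplexConditionScore(
                complex_id=c.complex_id,
                name=c.name,
                n_detected_native=n_nat,
                n_detected_crosslinked=n_xl,
                median_pcc_native=median_pair_pcc(c, profiles_native),
                median_pcc_crosslinked=median_pair_pcc(c, profiles_crosslinked),
                crosslinked_only=n_nat < 2 <= n_xl,
            )
        )
    return out


def condition_scatter(scores: list[ComplexConditionScore]) -> pd.DataFrame:
    """Per-complex medians for the native-vs-crosslinked comparison plot."""
    return pd.DataFrame(
        [
            {
                "complex_id": s.complex_id,
                "name": s.name,
                "n_native": s.n_detected_native,
                "n_xl": s.n_detected_crosslinked,
                "median_pcc_native": s.median_pcc_native,
                "median_pcc_xl": s.median_pcc_crosslinked,
                "crosslinked_only": s.crosslinked_only,
            }
            for s in scores
        ],
        columns=[
            "complex_id", "name", "n_native", "n_xl",
            "median_pcc_native", "median_pcc_xl", "crosslinked_only",
        ],
    )


def fractional_intensity(
    ibaq_nonvoid: dict[str, float]
) -> dict[str, float]:
    """Each protein's share of the data set's total non-void iBAQ intensity.

    The caller sums iBAQ over non-void fractions only; a protein detected
    only in the void therefore contributes (and receives) 0.  Raises on an
    all-zero total, which would leave the shares undefined.
    """
    total = float(sum(ibaq_nonvoid.values()))
    if total <= 0.0:
        raise ValueError("total non-void iBAQ intensity is zero")
    return {k: v / total for k, v in ibaq_nonvoid.items()}
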