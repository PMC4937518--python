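"""Candidate peak-pair enumeration and the six interaction features.

Two peaks from different protein groups whose apexes fall within one
fraction of each other form a candidate pair.  Each pair is described by six
features:

* **coapex** - in how many of the three replicates both groups have a peak
  at exactly the same fraction, mapped {3: 1, 2: 0.6, 1: 0.3, 0: 0};
* **NCC** - maximum lagged cross-correlation of the two peak value vectors,
  normalized by the larger self-cross-correlation (peak energy); range [0,1];
* **PCC** - Pearson correlation of the two vectors over the union of the two
  peak windows; range [-1,1];
* three literature scores (STRING / HIPPIE / mentha-style), looked up per
  accession pair and aggregated over the groups' accessions by maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaks import Peak

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("coapex", "ncc", "pcc", "string", "hippie", "mentha")

COAPEX_VALUES = {3: 1.0, 2: 0.6, 1: 0.3, 0: 0.0}


@dataclass
class PeakPairFeatures:
    peak_a: Peak
    peak_b: Peak
    coapex: float = 0.0
    ncc: float = 0.0
    pcc: float = 0.0
    string_score: float = 0.0
    hippie_score: float = 0.0
    mentha_score: float = 0.0
    label: str | None = None  # "positive" | "negative" | None

    @property
    def group_a(self) -> str:
        return self.peak_a.group_id

    @property
    def group_b(self) -> str:
        return self.peak_b.group_id

    @property
    def key(self) -> tuple:
        return (
            self.group_a, self.peak_a.apex_fraction,
            self.group_b, self.peak_b.apex_fraction,
        )

    def feature_vector(self) -> np.ndarray:
        return np.array(
            [self.coapex, self.ncc, self.pcc,
             self.string_score, self.hippie_score, self.mentha_score]
        )


def candidate_pairs(
    peaks: list[Peak], max_apex_delta: int = 1, ordered: bool = False
) -> list[PeakPairFeatures]:
    """All pairs of peaks from distinct groups with apexes within +/- 1.

    Pairs are unordered by default (the features are symmetric); ``ordered``
    emits both orientations for count comparison against permutation-based
    conventions.  Output order is deterministic: by group ids, then apexes.
    """
    peaks = sorted(peaks, key=lambda p: (p.group_id, p.apex_fraction))
    out = []
    for i, a in enumerate(peaks):
        for b in peaks[i + 1 :]:
            if a.group_id == b.group_id:
                continue
            if abs(a.apex_fraction - b.apex_fraction) <= max_apex_delta:
                out.append(PeakPairFeatures(peak_a=a, peak_b=b))
                if ordered:
                    out.append(PeakPairFeatures(peak_a=b, peak_b=a))
    return out


def coapex(
    replicate_peaks_a: dict[int, list[Peak]],
    replicate_peaks_b: dict[int, list[Peak]],
    n_replicates: int = 3,
) -> float:
    """Coapex feature from per-replicate peak calls of the two groups.

    A replicate co-apexes when the two groups each have a peak at the same
    fraction in that replicate (exact equality).
    """
    n_shared = 0
    for r in range(1, n_replicates + 1):
        apexes_a = {p.apex_fraction for p in replicate_peaks_a.get(r, [])}
        apexes_b = {p.apex_fraction for p in replicate_peaks_b.get(r, [])}
        if apexes_a & apexes_b:
            n_shared += 1
    return COAPEX_VALUES[n_shared]


def ncc(peak_a: Peak | np.ndarray, peak_b: Peak | np.ndarray) -> float:
    """Normalized cross-correlation of two peak value vectors.

    max-lag cross-correlation divided by the larger of the two peak
    energies (a vector's self-cross-correlation is maximal at lag 0, where
    it equals its energy).  0 if either peak has zero energy.
    """
    a = peak_a.values if isinstance(peak_a, Peak) else np.asarray(peak_a, float)
    b = peak_b.values if isinstance(peak_b, Peak) else np.asarray(peak_b, float)
    e_a = float(np.dot(a, a))
    e_b = float(np.dot(b, b))
    if e_a == 0.0 or e_b == 0.0:
        return 0.0
    cross = float(np.correlate(a, b, mode="full").max())
    return cross / max(e_a, e_b)


def pcc(peak_a: Peak, peak_b: Peak) -> float:
    """Pearson correlation of the two peaks over the union of their windows.

    Zero-variance vectors carry no shape evidence and correlate 0.
    """
    lo = min(peak_a.lo_fraction, peak_b.lo_fraction)
    hi = max(peak_a.hi_fraction, peak_b.hi_fraction)
    a = peak_a.values[lo - 1 : hi]
    b = peak_b.values[lo - 1 : hi]
    return pearson(a, b)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention r = 0."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# literature score tables
# ---------------------------------------------------------------------------


def load_score_table(path, score_col: str | None = None) -> dict[frozenset, float]:
    """Load a pairwise interaction score TSV keyed by unordered accession pair.

    Columns ``acc_a``, ``acc_b`` and a score column (``score`` by default;
    a STRING-style ``combined_score`` on the 0-1000 scale is autodetected
    and divided by 1000).  Malformed rows are logged and skipped; duplicate
    pairs keep the maximum score.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if score_col is None:
        score_col = "combined_score" if "combined_score" in table.columns else "score"
    scale = 1000.0 if score_col == "combined_score" else 1.0
    scores: dict[frozenset, float] = {}
    n_bad = 0
    for row in table.itertuples(index=False):
        try:
            a = getattr(row, "acc_a")
            b = getattr(row, "acc_b")
            s = float(getattr(row, score_col)) / scale
        except (AttributeError, ValueError):
            n_bad += 1
            continue
        if not (0.0 <= s <= 1.0) or not a or not b:
            n_bad += 1
            continue
        key = frozenset((a, b))
        scores[key] = max(scores.get(key, 0.0), s)
    if n_bad:
        logger.warning("%d malformed score rows skipped in %s", n_bad, path)
    return scores


def _pair_score(
    acc_a: list[str], acc_b: list[str], table: dict[frozenset, float]
) -> float:
    best = 0.0
    for a in acc_a:
        for b in acc_b:
            if a == b:
                continue
            best = max(best, table.get(frozenset((a, b)), 0.0))
    return best


def join_db_scores(
    pairs: list[PeakPairFeatures],
    string_table: dict[frozenset, float],
    hippie_table: dict[frozenset, float],
    mentha_table: dict[frozenset, float],
    accessions_by_group: dict[str, list[str]],
) -> list[PeakPairFeatures]:
    """Fill the three database features in place; absent pairs score 0.

    A group's evidence is the maximum score over the cross-product of the
    two groups' accessions (a group is detected if any member accession is).
    """
    for pair in pairs:
        acc_a = accessions_by_group.get(pair.group_a, [pair.group_a])
        acc_b = accessions_by_group.get(pair.group_b, [pair.group_b])
        pair.string_score = _pair_score(acc_a, acc_b, string_table)
        pair.hippie_score = _pair_score(acc_a, acc_b, hippie_table)
        pair.mentha_score = _pair_score(acc_a, acc_b, mentha_table)
    return pairs


def compute_features(
    pairs: list[PeakPairFeatures],
    replicate_peaks: dict[str, dict[int, list[Peak]]],
    n_replicates: int = 3,
) -> list[PeakPairFeatures]:
    """Fill the three profile-derived features for every candidate pair."""
    for pair in pairs:
        pair.coapex = coapex(
            replicate_peaks.get(pair.group_a, {}),
            replicate_peaks.get(pair.group_b, {}),
            n_replicates=n_replicates,
        )
        pair.ncc = ncc(pair.peak_a, pair.peak_b)
        pair.pcc = pcc(pair.peak_a, pair.peak_b)
    return pairs


def pairs_to_table(pairs: list[PeakPairFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": p.group_a,
                "group_b": p.group_b,
                "apex_a": p.peak_a.apex_fraction,
                "apex_b": p.peak_b.apex_fraction,
                "coapex": p.coapex,
                "ncc": p.ncc,
                "pcc": p.pcc,
                "string": p.string_score,
                "hippie": p.hippie_score,
                "mentha": p.mentha_score,
            }
            for p in pairs
        ],
        columns=[
            "group_a", "group_b", "apex_a", "apex_b",
            "coapex", "ncc", "pcc", "string", "hippie", "mentha",
        ],
    )
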