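"""Structure-activity similarity (SAS) maps and activity-cliff analysis.

A SAS map scatters, for every unordered pair of compounds, structural
similarity (X) against the absolute pIC50 difference (Y) for one target.
Two thresholds — a similarity threshold ``t_sim`` (by default the dataset
mean pairwise similarity of each fingerprint scheme) and an activity
threshold ``t_act`` (default 1 log unit) — split the map into four regions:

=================  ==========================  =====================
region             similarity                  activity difference
=================  ==========================  =====================
activity cliff     high (> t_sim)              large (> t_act)
smooth SAR         high                        small
similarity cliff   low                         small
not descriptive    low                         large
=================  ==========================  =====================

Cliff severity is quantified by the structure-activity landscape index

    SALI(i, j) = |A_i - A_j| / (1 - sim(i, j))

which diverges as two compounds become structurally identical while their
activities differ; the divergent case is represented by an infinity
sentinel.  Counts per region are summarized per fingerprint scheme and as a
consensus (per-region mean across schemes), and compounds over-represented
in activity-cliff pairs are ranked as "activity cliff generators".
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fingerprints import (
    DEFAULT_ECFP4_LENGTH,
    SimilarityMatrix,
    mean_pairwise_similarity,
    pairwise_similarity_matrix,
)
from .io import ActivityTable

logger = logging.getLogger(__name__)

#: Sentinel for SALI of an identical-structure pair with differing activity.
SALI_INFINITY = math.inf

DEFAULT_T_ACT = 1.0


class RegionLabel(str, Enum):
    """The four mutually exclusive SAS-map regions."""

    ACTIVITY_CLIFF = "ACTIVITY_CLIFF"
    SMOOTH_SAR = "SMOOTH_SAR"
    SIMILARITY_CLIFF = "SIMILARITY_CLIFF"
    NOT_DESCRIPTIVE = "NOT_DESCRIPTIVE"


@dataclass
class LandscapeThresholds:
    """Similarity threshold per scheme plus one activity threshold (log units).

    ``t_sim`` is a mapping scheme → threshold in [0, 1].  ``t_act`` defaults
    to 1.0 log unit.  "High" always means strictly greater than the
    threshold, so a pair sitting exactly on a boundary falls on the low side.
    """

    t_sim: dict[str, float]
    t_act: float = DEFAULT_T_ACT

    def __post_init__(self) -> None:
        for scheme, t in self.t_sim.items():
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"t_sim[{scheme!r}] = {t} outside [0, 1]")
        if not self.t_act > 0:
            raise ValueError(f"t_act must be > 0, got {self.t_act}")


def sali(a_i: float, a_j: float, sim: float) -> float:
    """Structure-activity landscape index |A_i − A_j| / (1 − sim).

    For structurally identical pairs (sim = 1) the index is 0 when the
    activities agree and the infinity sentinel otherwise, so duplicate
    structures never crash the pipeline.
    """
    if not (0.0 <= sim <= 1.0):
        raise ValueError(f"similarity {sim} outside [0, 1]")
    dact = abs(a_i - a_j)
    if sim == 1.0:
        return 0.0 if dact == 0.0 else SALI_INFINITY
    return dact / (1.0 - sim)


def classify_pair(
    sim: float, dact: float, th: LandscapeThresholds, scheme: str
) -> RegionLabel:
    """Assign one pair to its SAS-map region under the given thresholds."""
    if not (0.0 <= sim <= 1.0) or not math.isfinite(dact):
        raise ValueError(f"invalid pair (sim={sim}, dact={dact})")
    t_sim = th.t_sim[scheme]
    high_sim = sim > t_sim
    large_act = dact > th.t_act
    if high_sim and large_act:
        return RegionLabel.ACTIVITY_CLIFF
    if high_sim:
        return RegionLabel.SMOOTH_SAR
    if large_act:
        return RegionLabel.NOT_DESCRIPTIVE
    return RegionLabel.SIMILARITY_CLIFF


@dataclass
class PairComparison:
    """One unordered compound pair in the landscape.

    ``i`` precedes ``j`` in table order.  ``similarity`` maps fingerprint
    scheme → Tanimoto value; ``activity_difference`` maps target →
    |A_i − A_j|; ``sali`` maps (scheme, target) → SALI; ``region`` maps
    (scheme, target) → assigned region.
    """

    i: str
    j: str
    similarity: dict[str, float]
    activity_difference: dict[str, float]
    sali: dict[tuple[str, str], float] = field(default_factory=dict)
    region: dict[tuple[str, str], RegionLabel] = field(default_factory=dict)


@dataclass
class SASMap:
    """All pairwise comparisons for one table plus the thresholds used."""

    pairs: list[PairComparison]
    thresholds: LandscapeThresholds
    schemes: list[str]
    targets: list[str]
    mean_similarity: dict[str, float]

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            for scheme in self.schemes:
                for target in self.targets:
                    rows.append(
                        {
                            "i": p.i,
                            "j": p.j,
                            "scheme": scheme,
                            "similarity": p.similarity[scheme],
                            "target": target,
                            "dact": p.activity_difference[target],
                            "sali": p.sali[(scheme, target)],
                            "region": p.region[(scheme, target)].value,
                        }
                    )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_long_dataframe().to_csv(path, index=False)


def build_sas_map(
    table: ActivityTable,
    targets: Sequence[str] | None = None,
    schemes: Sequence[str] = ("MACCS", "ECFP4", "PUBCHEM"),
    thresholds: LandscapeThresholds | None = None,
    t_act: float = DEFAULT_T_ACT,
    ecfp_length: int = DEFAULT_ECFP4_LENGTH,
    similarity_matrices: Mapping[str, SimilarityMatrix] | None = None,
) -> SASMap:
    """Build the full pairwise landscape for one activity table.

    When *thresholds* is None the similarity threshold of each scheme is set
    automatically to the dataset mean pairwise similarity under that scheme
    (each fingerprint has its own similarity scale, so a shared threshold
    would not be comparable across schemes), and the activity threshold to
    *t_act*.  Precomputed similarity matrices may be passed to avoid
    recomputation.
    """
    targets = list(targets) if targets is not None else list(table.targets)
    for t in targets:
        if t not in table.targets:
            raise KeyError(f"unknown target {t!r}")
    schemes = list(schemes)

    matrices: dict[str, SimilarityMatrix] = {}
    for scheme in schemes:
        if similarity_matrices is not None and scheme in similarity_matrices:
            matrices[scheme] = similarity_matrices[scheme]
        else:
            matrices[scheme] = pairwise_similarity_matrix(table, scheme, ecfp_length)

    mean_sim = {s: mean_pairwise_similarity(matrices[s]) for s in schemes}
    if thresholds is None:
        thresholds = LandscapeThresholds(t_sim=dict(mean_sim), t_act=t_act)
    else:
        missing = [s for s in schemes if s not in thresholds.t_sim]
        if missing:
            raise ValueError(f"thresholds missing schemes {missing}")

    acts = {t: [rec.activities[t] for rec in table.compounds] for t in targets}
    pairs: list[PairComparison] = []
    for ii, jj in itertools.combinations(range(len(table)), 2):
        sim = {s: matrices[s].pair(ii, jj) for s in schemes}
        dact = {t: abs(acts[t][ii] - acts[t][jj]) for t in targets}
        pair = PairComparison(
            i=table.ids[ii], j=table.ids[jj], similarity=sim, activity_difference=dact
        )
        for s in schemes:
            for t in targets:
                pair.sali[(s, t)] = sali(acts[t][ii], acts[t][jj], sim[s])
                pair.region[(s, t)] = classify_pair(sim[s], dact[t], thresholds, s)
        pairs.append(pair)

    return SASMap(
        pairs=pairs,
        thresholds=thresholds,
        schemes=schemes,
        targets=targets,
        mean_similarity=mean_sim,
    )


def consensus_counts(
    per_scheme: Mapping[str, Mapping[RegionLabel, int]],
) -> dict[RegionLabel, int]:
    """Per-region arithmetic mean of per-scheme counts, rounded to nearest.

    Rounding is half away from zero (so a mean of x.5 rounds up), which is
    the convention that makes per-region averages of integer counts behave
    like ordinary "schoolbook" rounding.  Because each region is rounded
    independently, the consensus row may miss the pair total by one; callers
    should treat the per-scheme counts as authoritative.
    """
    if len(per_scheme) < 2:
        raise ValueError("consensus requires at least two schemes")
    key_sets = {frozenset(c.keys()) for c in per_scheme.values()}
    if len(key_sets) != 1:
        raise ValueError("mismatched region keys across schemes")
    regions = next(iter(key_sets))
    out: dict[RegionLabel, int] = {}
    for region in regions:
        mean = sum(c[region] for c in per_scheme.values()) / len(per_scheme)
        out[region] = int(math.floor(mean + 0.5))  # half away from zero (counts >= 0)
    return out


@dataclass
class RegionSummary:
    """Region counts per scheme for one target, plus the scheme consensus."""

    target: str
    counts: dict[str, dict[RegionLabel, int]]
    consensus: dict[RegionLabel, int]
    total_pairs: int

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular layout: one row per scheme plus a consensus row, one
        column per region with count and percentage of total pairs."""
        rows = []
        for scheme, by_region in self.counts.items():
            row: dict[str, object] = {"target": self.target, "fingerprint": scheme}
            for region in RegionLabel:
                c = by_region[region]
                row[region.value] = c
                row[f"{region.value}_pct"] = round(100.0 * c / self.total_pairs, 1)
            rows.append(row)
        row = {"target": self.target, "fingerprint": "Consensus"}
        for region in RegionLabel:
            c = self.consensus[region]
            row[region.value] = c
            row[f"{region.value}_pct"] = round(100.0 * c / self.total_pairs, 1)
        rows.append(row)
        return pd.DataFrame(rows)


def summarize_regions(sas: SASMap, target: str) -> RegionSummary:
    """Tally pairs per (scheme, region) for one target and form the consensus."""
    if target not in sas.targets:
        raise KeyError(f"unknown target {target!r}")
    counts: dict[str, dict[RegionLabel, int]] = {
        s: {r: 0 for r in RegionLabel} for s in sas.schemes
    }
    for pair in sas.pairs:
        for scheme in sas.schemes:
            counts[scheme][pair.region[(scheme, target)]] += 1
    total = len(sas.pairs)
    for scheme in sas.schemes:
        assert sum(counts[scheme].values()) == total
    consensus = (
        consensus_counts(counts) if len(sas.schemes) >= 2 else dict(counts[sas.schemes[0]])
    )
    # independent per-region rounding: |error| <= 1/2 per region, so the
    # consensus row can miss the pair total by at most 2 (and by at most 1
    # when three schemes are averaged, since errors are multiples of 1/3)
    drift = abs(sum(consensus.values()) - total)
    if drift > 2:
        raise AssertionError(f"consensus drifts from total by {drift} (> 2)")
    if drift:
        logger.info(
            "consensus counts off the pair total by %d (region rounding)", drift
        )
    return RegionSummary(
        target=target, counts=counts, consensus=consensus, total_pairs=total
    )


def cliff_generator_frequencies(
    sas: SASMap, scheme: str, target: str
) -> dict[str, float]:
    """Rank compounds by how often they participate in activity-cliff pairs.

    For each compound the frequency is its number of activity-cliff pair
    memberships divided by the total memberships (2 × number of cliff
    pairs), so frequencies over all compounds sum to 1.  Returned in
    descending frequency order (ties broken by compound id for
    determinism).  A landscape with no activity cliffs yields an empty
    mapping with a warning.
    """
    memberships: dict[str, int] = {}
    n_cliffs = 0
    for pair in sas.pairs:
        if pair.region[(scheme, target)] is RegionLabel.ACTIVITY_CLIFF:
            n_cliffs += 1
            for cid in (pair.i, pair.j):
                memberships[cid] = memberships.get(cid, 0) + 1
    if n_cliffs == 0:
        logger.warning("no activity-cliff pairs for %s/%s", scheme, target)
        return {}
    denom = 2 * n_cliffs
    ranked = sorted(memberships.items(), key=lambda kv: (-kv[1], kv[0]))
    return {cid: count / denom for cid, count in ranked}


def consensus_generator_ranking(
    sas: SASMap, target: str
) -> pd.DataFrame:
    """Cross-scheme generator ranking by mean rank.

    Compounds absent from a scheme's cliff pairs get rank ``n_compounds_in
    that scheme's table + 1`` for that scheme, so consistently cliff-forming
    compounds rise to the top.
    """
    per_scheme = {
        s: cliff_generator_frequencies(sas, s, target) for s in sas.schemes
    }
    all_ids = sorted({cid for freqs in per_scheme.values() for cid in freqs})
    if not all_ids:
        return pd.DataFrame(columns=["compound_id", "mean_rank", *sas.schemes])
    rows = []
    for cid in all_ids:
        ranks = []
        row: dict[str, object] = {"compound_id": cid}
        for s in sas.schemes:
            freqs = per_scheme[s]
            ids_ranked = list(freqs)
            rank = ids_ranked.index(cid) + 1 if cid in freqs else len(all_ids) + 1
            ranks.append(rank)
            row[s] = freqs.get(cid, 0.0)
        row["mean_rank"] = sum(ranks) / len(ranks)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["mean_rank", "compound_id"], ignore_index=True
    )
    return df[["compound_id", "mean_rank", *sas.schemes]]
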