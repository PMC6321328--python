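"""Synthetic lead-optimization series with known landscape structure.

Real activity-cliff datasets are rarely redistributable, so the test bed for
the landscape pipeline is generated: a common scaffold is decorated with
enumerated R-groups, each substituent contributes additively to the pIC50 of
each target, Gaussian assay noise is added, and activity cliffs and
selectivity switches are injected deliberately by overriding the additive
model for designated analog pairs.  Because the construction is explicit,
the expected region of every designated pair is known and the pipeline's
recovery of cliffs, generators, and switches can be measured exactly.

The default series emulates the shape of a two-target lead-optimization
campaign on a 4-aminoquinoline scaffold: 50 compounds (5 R1 × 10 R3
substituents), one target with a rough landscape (large R-group effects and
five injected cliffs sharing a designated generator compound), the other
with a smooth, similarity-principle-conforming landscape, plus one injected
selectivity switch and one injected dual-impact pair.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from rdkit import Chem

from .io import ActivityTable, CompoundRecord
from .landscape import DEFAULT_T_ACT, LandscapeThresholds
from .dad import DADLabel, classify_dad_point

logger = logging.getLogger(__name__)

DEFAULT_ENUMERATION_CAP = 200


@dataclass(frozen=True)
class CliffInjection:
    """Force an exact pIC50 gap on one target between two designated analogs.

    The two compounds are designated by their substituent indices per
    position (e.g. ``{1: 0, 3: 2}`` = substituent 0 at R1, substituent 2 at
    R3).  After noise is applied, compound *b*'s activity on *target* is
    overridden to ``A_a − delta``, so the realized gap is exactly *delta*.

    When several injections share the same *b* on the same target — the
    standard way to plant an activity-cliff *generator*, a single outlier
    compound cliffing against several analogs — the last injection defines
    *b*'s activity and the earlier designated gaps are approximate (off by
    the activity spread among the *a* compounds).
    """

    a: tuple[tuple[int, int], ...]
    b: tuple[tuple[int, int], ...]
    target: str
    delta: float

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("forced activity gap must be > 0")


@dataclass
class SeriesSpec:
    """Recipe for one synthetic analog series.

    ``scaffold`` is a SMILES with one attachment dummy atom per position,
    map-numbered (``[*:1]``, ``[*:3]``, ...).  ``r_groups`` maps each
    position to its substituent fragments, each a SMILES with exactly one
    unnumbered dummy atom (``[*]C``, ``[*]OC``, ...).  ``contributions``
    maps target → position → per-substituent additive pIC50 contribution
    (same order as the fragment list).  Noise is i.i.d. Gaussian per
    (compound, target) in log units.
    """

    scaffold: str
    r_groups: dict[int, list[str]]
    base_activity: dict[str, float]
    contributions: dict[str, dict[int, list[float]]]
    noise_sd: float = 0.1
    cliff_injections: list[CliffInjection] = field(default_factory=list)
    seed: int = 0
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_products = 1
        for pos, frags in self.r_groups.items():
            if not frags:
                raise ValueError(f"position {pos} has no substituents")
            n_products *= len(frags)
        if n_products > self.enumeration_cap:
            raise ValueError(
                f"full enumeration yields {n_products} compounds, above the cap "
                f"of {self.enumeration_cap}"
            )
        for target, per_pos in self.contributions.items():
            if target not in self.base_activity:
                raise ValueError(f"contributions for undeclared target {target!r}")
            for pos, values in per_pos.items():
                if len(values) != len(self.r_groups[pos]):
                    raise ValueError(
                        f"target {target!r} position {pos}: {len(values)} "
                        f"contributions for {len(self.r_groups[pos])} substituents"
                    )

    @property
    def targets(self) -> list[str]:
        return list(self.base_activity)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SeriesSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        injections = [
            CliffInjection(
                a=tuple(sorted((int(k), int(v)) for k, v in inj["a"].items())),
                b=tuple(sorted((int(k), int(v)) for k, v in inj["b"].items())),
                target=inj["target"],
                delta=float(inj["delta"]),
            )
            for inj in raw.get("cliff_injections", [])
        ]
        return cls(
            scaffold=raw["scaffold"],
            r_groups={int(k): list(v) for k, v in raw["r_groups"].items()},
            base_activity={k: float(v) for k, v in raw["base_activity"].items()},
            contributions={
                t: {int(p): [float(x) for x in vals] for p, vals in per_pos.items()}
                for t, per_pos in raw["contributions"].items()
            },
            noise_sd=float(raw.get("noise_sd", 0.1)),
            cliff_injections=injections,
            seed=int(raw.get("seed", 0)),
            enumeration_cap=int(raw.get("enumeration_cap", DEFAULT_ENUMERATION_CAP)),
        )


@dataclass
class GroundTruth:
    """What the generator injected, keyed by the emitted compound ids."""

    assignments: dict[str, dict[int, int]]
    injected_pairs: list[dict]
    generator_id: str | None
    expected_dad_labels: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignments": {
                cid: {str(p): s for p, s in combo.items()}
                for cid, combo in self.assignments.items()
            },
            "injected_pairs": self.injected_pairs,
            "generator_id": self.generator_id,
            "expected_dad_labels": self.expected_dad_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _assemble(scaffold: Chem.Mol, fragments: Mapping[int, str],
              frag_cache: dict[tuple[int, str], Chem.Mol]) -> str:
    """Attach one fragment per position to the scaffold via single bonds."""
    combined = scaffold
    for pos, frag_smiles in fragments.items():
        key = (pos, frag_smiles)
        frag = frag_cache.get(key)
        if frag is None:
            frag = Chem.MolFromSmiles(frag_smiles)
            if frag is None:
                raise ValueError(f"invalid fragment SMILES {frag_smiles!r}")
            dummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
            if len(dummies) != 1:
                raise ValueError(
                    f"fragment {frag_smiles!r} must have exactly one attachment dummy"
                )
            frag = Chem.RWMol(frag)
            frag.GetAtoms()[dummies[0].GetIdx()].SetAtomMapNum(pos)
            frag_cache[key] = frag
        combined = Chem.CombineMols(combined, frag)
    product = Chem.molzip(combined)
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


def generate_series(spec: SeriesSpec) -> tuple[ActivityTable, GroundTruth]:
    """Enumerate the series and return the activity table with ground truth.

    Deterministic under a fixed ``spec.seed``.  Compound ids are "1", "2",
    ... in enumeration order (positions sorted, substituents in list order).
    """
    scaffold = Chem.MolFromSmiles(spec.scaffold)
    if scaffold is None:
        raise ValueError(f"invalid scaffold SMILES {spec.scaffold!r}")
    map_nums = {a.GetAtomMapNum() for a in scaffold.GetAtoms() if a.GetAtomicNum() == 0}
    if map_nums != set(spec.r_groups):
        raise ValueError(
            f"scaffold attachment points {sorted(map_nums)} do not match "
            f"r_group positions {sorted(spec.r_groups)}"
        )

    positions = sorted(spec.r_groups)
    rng = np.random.default_rng(spec.seed)
    frag_cache: dict[tuple[int, str], Chem.Mol] = {}

    records: list[CompoundRecord] = []
    assignments: dict[str, dict[int, int]] = {}
    activities_by_id: dict[str, dict[str, float]] = {}
    combo_to_id: dict[tuple[tuple[int, int], ...], str] = {}

    for idx, sub_indices in enumerate(
        itertools.product(*(range(len(spec.r_groups[p])) for p in positions)), start=1
    ):
        cid = str(idx)
        combo = dict(zip(positions, sub_indices))
        try:
            smiles = _assemble(
                scaffold,
                {p: spec.r_groups[p][s] for p, s in combo.items()},
                frag_cache,
            )
        except ValueError as exc:
            raise ValueError(f"assembly failed for compound {cid}: {exc}") from exc
        acts = {}
        for target in spec.targets:
            value = spec.base_activity[target]
            per_pos = spec.contributions.get(target, {})
            for p, s in combo.items():
                if p in per_pos:
                    value += per_pos[p][s]
            if spec.noise_sd > 0:
                value += rng.normal(0.0, spec.noise_sd)
            acts[target] = value
        assignments[cid] = combo
        activities_by_id[cid] = acts
        combo_to_id[tuple(sorted(combo.items()))] = cid
        records.append(CompoundRecord(compound_id=cid, smiles=smiles, activities=acts))

    injected_pairs: list[dict] = []
    membership: dict[str, int] = {}
    for inj in spec.cliff_injections:
        try:
            id_a, id_b = combo_to_id[inj.a], combo_to_id[inj.b]
        except KeyError as exc:
            raise ValueError(f"injection designates unknown combination {exc}") from exc
        if inj.target not in spec.targets:
            raise ValueError(f"injection target {inj.target!r} not declared")
        activities_by_id[id_b][inj.target] = (
            activities_by_id[id_a][inj.target] - inj.delta
        )
        injected_pairs.append(
            {"i": id_a, "j": id_b, "target": inj.target, "delta": inj.delta}
        )
        for cid in (id_a, id_b):
            membership[cid] = membership.get(cid, 0) + 1

    # rebuild records with overridden activities
    records = [
        CompoundRecord(
            compound_id=rec.compound_id,
            smiles=rec.smiles,
            activities=dict(activities_by_id[rec.compound_id]),
        )
        for rec in records
    ]
    generator_id = (
        max(membership, key=lambda cid: (membership[cid], cid)) if membership else None
    )

    table = ActivityTable(compounds=records, targets=spec.targets)
    truth = GroundTruth(
        assignments=assignments,
        injected_pairs=injected_pairs,
        generator_id=generator_id,
        expected_dad_labels=_expected_dad_labels(spec, combo_to_id),
    )
    return table, truth


def _noiseless_activities(
    spec: SeriesSpec, combo_to_id: dict[tuple[tuple[int, int], ...], str]
) -> dict[str, dict[str, float]]:
    """Modeled (noise-free, injection-applied) activities per compound."""
    acts: dict[str, dict[str, float]] = {}
    for combo, cid in combo_to_id.items():
        acts[cid] = {}
        for target in spec.targets:
            value = spec.base_activity[target]
            per_pos = spec.contributions.get(target, {})
            for p, s in combo:
                if p in per_pos:
                    value += per_pos[p][s]
            acts[cid][target] = value
    for inj in spec.cliff_injections:
        id_a, id_b = combo_to_id[inj.a], combo_to_id[inj.b]
        acts[id_b][inj.target] = acts[id_a][inj.target] - inj.delta
    return acts


def _expected_dad_labels(
    spec: SeriesSpec, combo_to_id: dict[tuple[tuple[int, int], ...], str]
) -> dict[str, str]:
    """Expected DAD label of each injected pair, from the noise-free model."""
    if len(spec.targets) < 2:
        return {}
    tx, ty = spec.targets[0], spec.targets[1]
    acts = _noiseless_activities(spec, combo_to_id)
    labels: dict[str, str] = {}
    for inj in spec.cliff_injections:
        id_a, id_b = combo_to_id[inj.a], combo_to_id[inj.b]
        dx = abs(acts[id_a][tx] - acts[id_b][tx])
        dy = abs(acts[id_a][ty] - acts[id_b][ty])
        labels[f"{id_a}-{id_b}"] = classify_dad_point(dx, dy, DEFAULT_T_ACT).value
    return labels


def expected_landscape(
    spec: SeriesSpec, th: LandscapeThresholds | None = None
) -> dict:
    """Predict region/DAD labels for the designated pairs of a series.

    The predictions hold with probability ≥ 0.99 per pair only when the
    noise is small relative to the activity threshold (``noise_sd ≤
    t_act/5``); otherwise a warning is emitted and the expectations are
    unreliable.  Injected-cliff pairs with ``delta > t_act`` are expected in
    the activity-cliff region (given their analog-level similarity exceeds
    the similarity threshold); analog pairs whose modeled activity gap
    stays well below ``t_act`` are expected in the smooth-SAR region.
    """
    t_act = th.t_act if th is not None else DEFAULT_T_ACT
    if spec.noise_sd > t_act / 5:
        logger.warning(
            "noise_sd %.3g exceeds t_act/5 = %.3g; expected labels are unreliable",
            spec.noise_sd,
            t_act / 5,
        )
    positions = sorted(spec.r_groups)
    combo_to_id = {
        tuple(sorted(zip(positions, sub_indices))): str(idx)
        for idx, sub_indices in enumerate(
            itertools.product(*(range(len(spec.r_groups[p])) for p in positions)),
            start=1,
        )
    }
    acts = _noiseless_activities(spec, combo_to_id)

    expected_cliffs: dict[str, list[tuple[str, str]]] = {t: [] for t in spec.targets}
    for inj in spec.cliff_injections:
        if inj.delta > t_act:
            expected_cliffs[inj.target].append(
                (combo_to_id[inj.a], combo_to_id[inj.b])
            )

    # analog pairs (single-position difference) with comfortably small modeled
    # gap on every target and no injection: expected smooth SAR
    injected_ids = {
        frozenset((combo_to_id[inj.a], combo_to_id[inj.b]))
        for inj in spec.cliff_injections
    }
    margin = 5 * spec.noise_sd * math.sqrt(2)
    expected_smooth: list[tuple[str, str]] = []
    for ca, cb in itertools.combinations(combo_to_id, 2):
        if sum(1 for x, y in zip(ca, cb) if x != y) != 1:
            continue
        ia, ib = combo_to_id[ca], combo_to_id[cb]
        if frozenset((ia, ib)) in injected_ids:
            continue
        if all(abs(acts[ia][t] - acts[ib][t]) + margin < t_act for t in spec.targets):
            expected_smooth.append((ia, ib))

    return {
        "activity_cliff_pairs": expected_cliffs,
        "smooth_sar_pairs": expected_smooth,
        "dad_labels": _expected_dad_labels(spec, combo_to_id),
    }


def default_series_spec(seed: int = 0, noise_sd: float = 0.1) -> SeriesSpec:
    """The package's reference synthetic series (50 compounds, two targets).

    A 4-aminoquinoline scaffold decorated at the exocyclic amine (R1, 5
    substituents) and an aromatic ring position (R3, 10 substituents).  The
    first target ("G9a") gets large R-group effects plus five injected
    cliffs of 2.8 log units that all share compound 12 (R1 index 1, R3
    index 1) — the designated activity-cliff generator, overridden to sit
    far below its analogs — one injected selectivity switch (2.5 log units
    on the first target, matched contributions on the second) and one
    injected dual pair (2.5 log units on both).  The second target
    ("DNMT1") gets small contributions, so its landscape stays smooth.
    Assay noise defaults to 0.1 log units.
    """
    r1 = ["[*]C", "[*]CCN(C)C", "[*]C1CCN(C)CC1", "[*]CCO", "[*]C1CCNCC1"]
    r3 = [
        "[*]OC",
        "[*]OCCCN1CCCC1",
        "[*]Cl",
        "[*]F",
        "[*]CC",
        "[*]OCC",
        "[*]N1CCCC1",
        "[*]N1CCCCC1",
        "[*]C(F)(F)F",
        "[*]OCCOC",
    ]
    contributions = {
        "G9a": {
            1: [0.0, 0.9, 1.4, -0.3, 0.6],
            3: [0.0, 1.1, -0.5, -0.2, 0.3, 0.4, 0.8, 0.9, -0.6, 0.2],
        },
        "DNMT1": {
            1: [0.0, 0.4, 0.2, -0.1, 0.1],
            3: [0.0, 0.5, -0.2, -0.1, 0.1, 0.2, 0.3, 0.2, -0.3, 0.1],
        },
    }

    def pair(a_r1: int, a_r3: int, b_r1: int, b_r3: int, target: str, delta: float):
        return CliffInjection(
            a=((1, a_r1), (3, a_r3)), b=((1, b_r1), (3, b_r3)),
            target=target, delta=delta,
        )

    injections = [
        # five cliffs sharing the designated generator (R1=1, R3=1): the
        # generator is the overridden outlier, cliffing against five analogs
        pair(1, 0, 1, 1, "G9a", 2.8),
        pair(1, 2, 1, 1, "G9a", 2.8),
        pair(1, 3, 1, 1, "G9a", 2.8),
        pair(1, 4, 1, 1, "G9a", 2.8),
        pair(1, 5, 1, 1, "G9a", 2.8),
        # selectivity switch: large on G9a, matched DNMT1 contributions (0.3 vs 0.2)
        pair(0, 6, 0, 7, "G9a", 2.5),
        # dual pair: forced on both targets
        pair(2, 8, 2, 9, "G9a", 2.5),
        pair(2, 8, 2, 9, "DNMT1", 2.5),
    ]
    return SeriesSpec(
        scaffold="[*:1]Nc1ccnc2cc([*:3])ccc12",
        r_groups={1: r1, 3: r3},
        base_activity={"G9a": 6.5, "DNMT1": 6.0},
        contributions=contributions,
        noise_sd=noise_sd,
        cliff_injections=injections,
        seed=seed,
    )


def recovery_series_spec(seed: int = 0, noise_sd: float = 0.1) -> SeriesSpec:
    """A flat series purpose-built for parameter-recovery experiments.

    Same scaffold and substituents as the reference series, but every
    R-group contribution is below half the activity threshold (maximum
    pairwise modeled gap 0.9 log units), so with zero noise and no
    injections the landscape contains no activity cliff at all.  On top of
    that flat background: five injected cliffs of 2.8 log units sharing the
    designated generator (compound 12), and one injected selectivity switch
    of 2.5 log units whose two compounds have nearly matched contributions
    on the second target.  Every activity cliff the pipeline finds should
    therefore trace back to an injection, making recovery rates and
    generator ranking exact measures of pipeline correctness.
    """
    base = default_series_spec(seed=seed, noise_sd=noise_sd)
    contributions = {
        "G9a": {
            1: [0.0, 0.2, -0.2, 0.1, -0.1],
            3: [0.0, 0.25, -0.25, 0.2, -0.2, 0.1, -0.1, 0.15, -0.15, 0.05],
        },
        "DNMT1": {
            1: [0.0, 0.15, -0.15, 0.1, -0.1],
            3: [0.0, 0.2, -0.1, 0.1, -0.2, 0.15, 0.1, 0.05, -0.15, 0.1],
        },
    }

    def pair(a_r1, a_r3, b_r1, b_r3, target, delta):
        return CliffInjection(
            a=((1, a_r1), (3, a_r3)), b=((1, b_r1), (3, b_r3)),
            target=target, delta=delta,
        )

    injections = [
        pair(1, 0, 1, 1, "G9a", 2.8),
        pair(1, 2, 1, 1, "G9a", 2.8),
        pair(1, 3, 1, 1, "G9a", 2.8),
        pair(1, 4, 1, 1, "G9a", 2.8),
        pair(1, 5, 1, 1, "G9a", 2.8),
        # selectivity switch: DNMT1 contributions differ by only 0.05
        pair(0, 6, 0, 7, "G9a", 2.5),
    ]
    return SeriesSpec(
        scaffold=base.scaffold,
        r_groups=base.r_groups,
        base_activity=base.base_activity,
        contributions=contributions,
        noise_sd=noise_sd,
        cliff_injections=injections,
        seed=seed,
    )
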