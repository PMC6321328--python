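"""Compound activity tables: reading, validation, and activity-scale helpers.

The central input of an activity-landscape analysis is a table of compounds,
each with a SMILES structure and a pIC50 (``-log10`` of the molar IC50) per
biological target.  This module models that table, validates it on load, and
provides the unit conversion and descriptive statistics the downstream maps
rely on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

#: pIC50 values outside this window are treated as unit errors (e.g. an IC50
#: entered in nM instead of M), not as chemistry.
PIC50_BOUNDS = (0.0, 14.0)

#: Multipliers to molar for the supported IC50 input units.
IC50_UNIT_FACTORS = {"M": 1.0, "uM": 1e-6, "nM": 1e-9}


class ActivityTableError(ValueError):
    """Raised when an activity table fails validation."""


def pic50_from_ic50(ic50: float, units: str = "M") -> float:
    """Convert an IC50 to pIC50 (``-log10`` of the molar concentration).

    Parameters
    ----------
    ic50
        Half-maximal inhibitory concentration, strictly positive.
    units
        One of ``M``, ``uM``, ``nM``; the value is converted to molar before
        the log.  Unit mix-ups are the dominant real-world failure mode, so
        the unit is explicit rather than assumed.
    """
    if units not in IC50_UNIT_FACTORS:
        raise ValueError(
            f"unknown IC50 units {units!r}; expected one of {sorted(IC50_UNIT_FACTORS)}"
        )
    if not math.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"IC50 must be finite and > 0, got {ic50!r}")
    return -math.log10(ic50 * IC50_UNIT_FACTORS[units])


def _standardize_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES and keep the largest covalent fragment.

    Salts and solvates are reduced to their largest fragment (by heavy-atom
    count); no neutralization or tautomer canonicalization is applied, so the
    structure stays as close as possible to what was drawn.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        logger.info("kept largest fragment of multi-fragment SMILES %r", smiles)
    return mol


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: an identifier, a structure, and one pIC50 per target."""

    compound_id: str
    smiles: str
    activities: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ActivityTableError("compound_id must be non-empty")
        lo, hi = PIC50_BOUNDS
        for target, value in self.activities.items():
            if not math.isfinite(value):
                raise ActivityTableError(
                    f"compound {self.compound_id}: pIC50 for {target} is not finite"
                )
            if not (lo <= value <= hi):
                raise ActivityTableError(
                    f"compound {self.compound_id}: pIC50 {value} for {target} outside "
                    f"[{lo}, {hi}] — check IC50 units"
                )

    def activity(self, target: str) -> float:
        try:
            return self.activities[target]
        except KeyError:
            raise KeyError(
                f"compound {self.compound_id} has no activity for target {target!r}"
            ) from None


@dataclass
class ActivityTable:
    """An ordered compound set with activities for one or more targets.

    Invariants enforced on construction: at least two compounds, unique
    compound ids, every compound parseable and reporting a pIC50 for every
    declared target (rows with missing activities are rejected, never
    imputed — the landscape is defined only on complete pairs).
    """

    compounds: list[CompoundRecord]
    targets: list[str]
    #: RDKit molecules, parallel to ``compounds`` (largest fragment kept).
    mols: list[Chem.Mol] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.compounds) < 2:
            raise ActivityTableError(
                f"need at least 2 compounds, got {len(self.compounds)}"
            )
        if not self.targets:
            raise ActivityTableError("at least one target must be declared")
        seen: set[str] = set()
        for rec in self.compounds:
            if rec.compound_id in seen:
                raise ActivityTableError(f"duplicate compound_id {rec.compound_id!r}")
            seen.add(rec.compound_id)
            missing = [t for t in self.targets if t not in rec.activities]
            if missing:
                raise ActivityTableError(
                    f"compound {rec.compound_id} missing pIC50 for {missing}"
                )
        if not self.mols:
            self.mols = []
            for rec in self.compounds:
                try:
                    self.mols.append(_standardize_smiles(rec.smiles))
                except ValueError as exc:
                    raise ActivityTableError(
                        f"compound {rec.compound_id}: {exc}"
                    ) from exc
        canon = [Chem.MolToSmiles(m) for m in self.mols]
        dupes = {s for s in canon if canon.count(s) > 1}
        if dupes:
            logger.warning(
                "%d duplicate structures present; they will produce similarity≈1 pairs",
                len(dupes),
            )

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def ids(self) -> list[str]:
        return [rec.compound_id for rec in self.compounds]

    @property
    def n_pairs(self) -> int:
        """Number of unordered compound pairs, n(n-1)/2."""
        n = len(self)
        return n * (n - 1) // 2

    def index_of(self, compound_id: str) -> int:
        for k, rec in enumerate(self.compounds):
            if rec.compound_id == compound_id:
                return k
        raise KeyError(f"unknown compound_id {compound_id!r}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": rec.compound_id,
                "smiles": rec.smiles,
                **{f"pIC50_{t}": rec.activities[t] for t in self.targets},
            }
            for rec in self.compounds
        ]
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        """Re-emit the validated table as CSV for provenance."""
        self.to_dataframe().to_csv(path, index=False)


def activity_range(table: ActivityTable, target: str) -> tuple[float, float]:
    """Return (min, max) pIC50 over all compounds for one target."""
    if target not in table.targets:
        raise KeyError(f"unknown target {target!r}; declared: {table.targets}")
    values = [rec.activities[target] for rec in table.compounds]
    return (min(values), max(values))


def _table_from_dataframe(df: pd.DataFrame, targets: Sequence[str]) -> ActivityTable:
    records = []
    for _, row in df.iterrows():
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                smiles=str(row["smiles"]),
                activities={t: float(row[f"pIC50_{t}"]) for t in targets},
            )
        )
    return ActivityTable(compounds=records, targets=list(targets))


def read_activity_table(
    path: str | Path,
    targets: Sequence[str] | None = None,
    smiles_path: str | Path | None = None,
) -> ActivityTable:
    """Read a compound activity table from CSV.

    The CSV must have columns ``compound_id``, ``smiles`` (unless structures
    are supplied separately via *smiles_path*, a whitespace-separated
    ``SMILES id`` file), and one ``pIC50_<target>`` column per target.  When
    *targets* is None every ``pIC50_*`` column is used, in column order.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"compound_id": str})

    if smiles_path is not None:
        smi = pd.read_csv(
            smiles_path, sep=r"\s+", header=None, names=["smiles", "compound_id"],
            dtype=str,
        )
        df = df.merge(smi, on="compound_id", how="left", validate="one_to_one")

    if targets is None:
        targets = [c[len("pIC50_"):] for c in df.columns if c.startswith("pIC50_")]
        if not targets:
            raise ActivityTableError("no pIC50_<target> columns found")
    for col in ["compound_id", "smiles", *[f"pIC50_{t}" for t in targets]]:
        if col not in df.columns:
            raise ActivityTableError(f"missing required column {col!r}")
    if df["smiles"].isna().any():
        bad = df.loc[df["smiles"].isna(), "compound_id"].tolist()
        raise ActivityTableError(f"no SMILES for compound ids {bad}")
    return _table_from_dataframe(df, targets)
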