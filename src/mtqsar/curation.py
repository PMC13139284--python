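"""Structure and bioactivity curation.

Implements the standard QSAR curation protocol: structures are parsed,
the largest organic fragment is kept (salt stripping), chemotypes such
as charge-separated nitro groups are normalized and aromaticity is
perceived, and mixtures, polymers, organometallics and unparseable
entries are rejected with machine-readable reasons.  Potencies are
moved to the negative-log molar (pIC50/pKi) scale, and duplicate
measurements of the same standardized structure on the same task and
endpoint are resolved: groups spreading more than 0.3 log units are
excluded outright, concordant groups are averaged.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: elements of the organic subset; anything else marks an organometallic
ORGANIC_ELEMENTS = frozenset(
    [1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53]
)  # H B C N O F Si P S Cl Se Br I

#: multiplicative factors to mol/L
UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}

#: maximum p-scale spread within a duplicate group before outright exclusion
DUPLICATE_SPREAD_LIMIT = 0.3

REQUIRED_COLUMNS = ["compound_id", "smiles", "task_id", "endpoint_type"]

_NORMALIZER = rdMolStandardize.Normalizer()


@dataclasses.dataclass
class StandardizationResult:
    smiles: str | None          # canonical standardized structure, or None
    reason: str | None          # rejection reason code when smiles is None
    salt_stripped: bool = False


@dataclasses.dataclass
class CurationReport:
    """Audit trail of one curation run.

    ``removed`` counts entries dropped per reason; averaged duplicate
    groups contribute group_size - 1 removals so that
    before == after + sum(removed.values()) holds exactly.
    """

    n_before: int = 0
    n_after: int = 0
    removed: dict = dataclasses.field(
        default_factory=lambda: {
            "unparseable": 0, "polymer": 0, "mixture": 0, "organometallic": 0,
            "discordant_duplicate": 0, "duplicate_averaged": 0,
        }
    )
    salt_stripped: int = 0
    n_averaged_groups: int = 0
    aromaticity_convention: str = "aromatic perception (RDKit sanitization)"

    def reconciles(self) -> bool:
        return self.n_before == self.n_after + sum(self.removed.values())


def standardize_structure(smiles: str) -> StandardizationResult:
    """Standardize one structure or reject it with a reason code.

    Keeps the largest fragment when it dominates (>= 2x the heavy atoms
    of the next largest: a salt); rejects multi-fragment inputs without
    a dominant parent as mixtures.  Polymers are recognized by
    repeat-unit dummy atoms, organometallics by elements outside the
    organic subset.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return StandardizationResult(None, "unparseable")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardizationResult(None, "unparseable")
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        return StandardizationResult(None, "polymer")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    salt_stripped = False
    if len(frags) > 1:
        sizes = sorted((f.GetNumHeavyAtoms() for f in frags), reverse=True)
        if sizes[0] < 2 * sizes[1]:
            return StandardizationResult(None, "mixture")
        mol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
        salt_stripped = True

    if any(a.GetAtomicNum() not in ORGANIC_ELEMENTS for a in mol.GetAtoms()):
        return StandardizationResult(None, "organometallic")

    try:
        mol = _NORMALIZER.normalize(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return StandardizationResult(None, "unparseable")
    return StandardizationResult(Chem.MolToSmiles(mol), None, salt_stripped)


def to_p_scale(value: float, units: str = "M", direction: str = "to_p") -> float:
    """Convert a potency to the negative-log molar scale, or back.

    ``to_p`` maps a concentration in the stated units to
    -log10(mol/L); ``from_p`` inverts the transform exactly, returning a
    concentration in the stated units.
    """
    if units not in UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit: {units!r}")
    factor = UNIT_FACTORS[units]
    if direction == "to_p":
        if not value > 0:
            raise ValueError(f"potency must be positive, got {value}")
        return -math.log10(value * factor)
    if direction == "from_p":
        return 10.0 ** (-value) / factor
    raise ValueError(f"direction must be 'to_p' or 'from_p', got {direction!r}")


def resolve_duplicates(p_values: Iterable[float]) -> tuple[float | None, str]:
    """Resolve one duplicate group of p-values sharing (structure, task,
    endpoint).

    Returns (resolved p-value or None, outcome code).  Spread is max-min;
    a spread above 0.3 log units discards the whole group ("discordant"),
    otherwise the arithmetic mean is kept ("averaged"; "kept" for
    singletons).
    """
    ps = sorted(p_values)
    if not ps:
        raise ValueError("empty duplicate group")
    if len(ps) == 1:
        return ps[0], "kept"
    if ps[-1] - ps[0] > DUPLICATE_SPREAD_LIMIT:
        return None, "discordant"
    return float(np.mean(ps)), "averaged"


def curate(raw: pd.DataFrame) -> tuple[pd.DataFrame, CurationReport]:
    """Run the full curation pipeline on a raw bioactivity table.

    Required columns: compound_id, smiles, task_id, endpoint_type, and
    either (value, units) or a precomputed p_value column.  Output rows
    are sorted by (task_id, smiles, endpoint_type) so the result is
    invariant to input row order.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    has_p = "p_value" in raw.columns
    if not has_p and not {"value", "units"}.issubset(raw.columns):
        raise ValueError("need either a p_value column or value + units columns")

    report = CurationReport(n_before=len(raw))
    records = []
    for row in raw.itertuples(index=False):
        std = standardize_structure(row.smiles)
        if std.smiles is None:
            report.removed[std.reason] += 1
            continue
        if std.salt_stripped:
            report.salt_stripped += 1
        p = row.p_value if has_p else to_p_scale(row.value, row.units, "to_p")
        records.append(
            dict(compound_id=row.compound_id, smiles=std.smiles,
                 task_id=row.task_id, endpoint_type=row.endpoint_type,
                 p_value=float(p))
        )

    out_rows = []
    std_df = pd.DataFrame(
        records, columns=["compound_id", "smiles", "task_id", "endpoint_type",
                          "p_value"]
    )
    if len(std_df):
        for (smi, task, endpoint), grp in std_df.groupby(
            ["smiles", "task_id", "endpoint_type"], sort=True
        ):
            p, outcome = resolve_duplicates(grp["p_value"])
            if outcome == "discordant":
                report.removed["discordant_duplicate"] += len(grp)
                continue
            if outcome == "averaged":
                report.removed["duplicate_averaged"] += len(grp) - 1
                report.n_averaged_groups += 1
            cid = sorted(grp["compound_id"])[0]
            out_rows.append(
                dict(compound_id=cid, smiles=smi, task_id=task,
                     endpoint_type=endpoint, p_value=p)
            )
    curated = pd.DataFrame(
        out_rows, columns=["compound_id", "smiles", "task_id", "endpoint_type",
                           "p_value"]
    )
    curated = curated.sort_values(
        ["task_id", "smiles", "endpoint_type"], ignore_index=True
    )
    report.n_after = len(curated)
    assert report.reconciles(), "curation report fails to reconcile"
    return curated, report
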